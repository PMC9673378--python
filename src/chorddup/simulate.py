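"""Synthetic input bundles with the statistical structure the analysis assumes.

The generator emulates a 3-amphioxus + 4-vertebrate species panel:
orthogroups with tunable per-lineage duplication probabilities and a
co-duplication enrichment factor, 2R ohnolog labelling of vertebrate
duplicates (plus teleost-only 3R cases), chromosomal gene placement with a
tandem fraction, condition-level expression where duplicates partition an
ancestral expression domain (subfunctionalization), lineage-monophyletic
gene trees with a scramble probability, and a two-namespace GO annotation
with per-term duplicability optionally shared between lineages.  Every
latent label is recorded in a truth table so each pipeline stage's estimate
can be checked against the parameter that generated it.

Co-duplication enrichment is implemented as the exact joint Bernoulli with
P(dup_A and dup_B) = f * P(dup_A) * P(dup_B) — the marginalized form of a
shared "duplicability" cause.  f values beyond the feasibility bound
min(pA, pB) / (pA * pB) raise with the bound in the message.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ConditionMap, default_condition_map
from .types import (
    ChorddupError,
    ExpressionMatrix,
    GeneRecord,
    GeneTreeRec,
    LineageConfig,
    OhnologList,
    OrthogroupTable,
    assign_ranks,
    default_lineage_config,
)

DEFAULT_CHROMOSOMES = {
    "Blan": 19, "Bflo": 19, "Bbel": 19,
    "Drer": 25, "Ggal": 28, "Mmus": 20, "Hsap": 23,
}


@dataclass
class SynthParams:
    """Generator parameters; the defaults are the study conditions.

    The lineage duplication probabilities are chosen so the realized
    per-species prevalence matches the real chordate panel (just under 20%
    of an amphioxus species' orthogroups duplicated, somewhat more in
    vertebrates: lineage-level p_dup times the per-species duplication
    share); roughly a third of orthogroups are lineage-specific; the
    enrichment factor defaults to the observed small-scale co-duplication
    ratio of 1.7; the ohnolog fraction reflects that most duplicated
    vertebrate orthogroups trace to the 2R WGDs.
    """

    seed: int = 0
    n_orthogroups: int = 5000
    species_lineage: Mapping[str, str] = field(default_factory=lambda: dict(
        default_lineage_config().species_to_lineage))
    n_chromosomes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    wgd_3r_species: tuple[str, ...] = ("Drer",)
    p_dup: Mapping[str, float] = field(default_factory=lambda: {
        "amphioxus": 0.30, "vertebrate": 0.38})
    enrichment_factor: float = 1.7
    p_lineage_specific: float = 0.35
    p_absent: float = 0.10
    p_species_dup: float = 0.6
    p_copy_extra: float = 0.45   # geometric parameter for extra copies
    p_ohnolog: float = 0.6
    p_3r_only: float = 0.05
    tandem_fraction: float = 0.25
    n_conditions: int = 7
    p_condition_present: float = 0.6
    subfunctionalization_prob: float = 0.7
    expr_mu: float = 2.0
    expr_sigma: float = 1.0
    dropout: float = 0.05
    n_replicates: int = 2
    presence_threshold: float = 1.0
    scramble_prob: float = 0.2
    go_n_terms: int = 120
    go_ogs_per_term: int = 80
    go_shared_duplicability: bool = True
    expression_pair: tuple[str, str] = ("Blan", "Drer")
    gene_length: int = 1000
    intergenic: int = 1000

    def lineage_config(self) -> LineageConfig:
        lineages = sorted(set(self.species_lineage.values()))
        if len(lineages) != 2:
            raise ChorddupError("the species panel needs exactly two lineages")
        # amphioxus first when present, mirroring the published orientation
        if "amphioxus" in lineages:
            lineages = ["amphioxus"] + [l for l in lineages if l != "amphioxus"]
        return LineageConfig(
            species_to_lineage=dict(self.species_lineage),
            focal_pair=(lineages[0], lineages[1]),
            wgd_3r_species=frozenset(self.wgd_3r_species),
        )


@dataclass
class SyntheticBundle:
    """Everything one simulate call produces, plus the latent truth."""

    params: SynthParams
    cfg: LineageConfig
    orthogroups: OrthogroupTable
    annotations: dict[str, list[GeneRecord]]
    ohnologs: OhnologList
    expression: dict[str, ExpressionMatrix]
    condition_map: ConditionMap
    go_parents: dict[str, set[str]]
    go_namespaces: dict[str, str]
    gene_go: dict[str, set[str]]
    go_source_species: str
    trees: list[GeneTreeRec]
    truth: pd.DataFrame
    tandem_truth: pd.DataFrame


def _joint_dup_probs(p_a: float, p_b: float, f: float) -> tuple[float, float, float, float]:
    p11 = f * p_a * p_b
    bound = min(p_a, p_b) / (p_a * p_b) if p_a * p_b > 0 else float("inf")
    if p11 > min(p_a, p_b) + 1e-12:
        raise ChorddupError(
            f"enrichment factor {f} infeasible for marginals ({p_a}, {p_b}); "
            f"feasibility bound is f <= {bound:.3f}"
        )
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    if p00 < -1e-12:
        raise ChorddupError("invalid joint duplication distribution")
    return p11, p10, p01, max(p00, 0.0)


def _presence(rng: np.random.Generator, species: Sequence[str], p_absent: float) -> list[str]:
    present = [sp for sp in species if rng.random() >= p_absent]
    if not present:
        present = [species[rng.integers(len(species))]]
    return present


def _dup_subset(rng: np.random.Generator, present: Sequence[str], p: float) -> list[str]:
    chosen = [sp for sp in present if rng.random() < p]
    if not chosen:
        chosen = [present[rng.integers(len(present))]]
    return chosen


def simulate_bundle(params: SynthParams) -> SyntheticBundle:
    """Generate a complete, self-consistent synthetic input bundle.

    Deterministic for a fixed seed: each component (orthogroups, ohnolog
    labels, placement, expression, trees, GO) draws from its own stream
    spawned from the master seed, so switching one component off does not
    shift the others.
    """
    cfg = params.lineage_config()
    lin_a, lin_b = cfg.focal_pair
    sp_a = cfg.lineage_species(lin_a)
    sp_b = cfg.lineage_species(lin_b)
    all_sp = sp_a + sp_b
    streams = np.random.SeedSequence(params.seed).spawn(6)
    rng_og, rng_ohno, rng_place, rng_expr, rng_tree, rng_go = (
        np.random.default_rng(s) for s in streams)

    p_a = params.p_dup[lin_a]
    p_b = params.p_dup[lin_b]
    p11, p10, p01, p00 = _joint_dup_probs(p_a, p_b, params.enrichment_factor)

    entries: dict[str, dict[str, list[str]]] = {}
    truth_rows = []
    copy_counts: dict[str, dict[str, int]] = {}

    for i in range(params.n_orthogroups):
        og = f"OG{i:05d}"
        specific = ""
        r3_only = False
        if rng_og.random() < params.p_lineage_specific:
            specific = lin_a if rng_og.random() < 0.5 else lin_b
            dup_a = specific == lin_a and rng_og.random() < p_a
            dup_b = specific == lin_b and rng_og.random() < p_b
        else:
            u = rng_og.random()
            if u < p11:
                dup_a, dup_b = True, True
            elif u < p11 + p10:
                dup_a, dup_b = True, False
            elif u < p11 + p10 + p01:
                dup_a, dup_b = False, True
            else:
                dup_a, dup_b = False, False
            if not dup_b and rng_og.random() < params.p_3r_only:
                r3_only = True

        present_a = _presence(rng_og, sp_a, params.p_absent) if specific != lin_b else []
        present_b = _presence(rng_og, sp_b, params.p_absent) if specific != lin_a else []
        counts: dict[str, int] = {sp: 1 for sp in present_a + present_b}
        if dup_a and present_a:
            for sp in _dup_subset(rng_og, present_a, params.p_species_dup):
                counts[sp] = 1 + int(rng_og.geometric(params.p_copy_extra))
        if dup_b and present_b:
            for sp in _dup_subset(rng_og, present_b, params.p_species_dup):
                counts[sp] = 1 + int(rng_og.geometric(params.p_copy_extra))
        if r3_only:
            for r3sp in params.wgd_3r_species:
                if r3sp in counts:
                    counts[r3sp] = 1 + int(rng_og.geometric(params.p_copy_extra))

        row = {sp: [f"{sp}_g{i:05d}_{j}" for j in range(counts.get(sp, 0))]
               for sp in all_sp}
        entries[og] = row
        copy_counts[og] = counts
        truth_rows.append({
            "orthogroup_id": og, "specific_lineage": specific,
            "dup_a": dup_a, "dup_b": dup_b, "r3_only": r3_only,
            "shared": specific == "" ,
        })

    table = OrthogroupTable(entries)
    truth = pd.DataFrame(truth_rows).set_index("orthogroup_id")

    # --- ohnolog labels -----------------------------------------------------
    ohno_records: list[tuple[str, str, str]] = []
    is_ohnolog = []
    for og in table:
        t = truth.loc[og]
        tag = False
        if t["dup_b"] and not t["r3_only"]:
            dup_sp = [sp for sp in sp_b if table.count(og, sp) >= 2]
            if dup_sp and rng_ohno.random() < params.p_ohnolog:
                sp = dup_sp[int(rng_ohno.integers(len(dup_sp)))]
                for g in table.genes(og, sp)[:2]:
                    ohno_records.append((sp, g, "2R"))
                tag = True
        if t["r3_only"]:
            for r3sp in params.wgd_3r_species:
                for g in table.genes(og, r3sp):
                    ohno_records.append((r3sp, g, "3R"))
        is_ohnolog.append(tag)
    truth["ohnolog"] = is_ohnolog
    ohnologs = OhnologList.from_records(ohno_records)

    # --- chromosomal placement ---------------------------------------------
    annotations: dict[str, list[GeneRecord]] = {}
    tandem_rows = []
    for sp in all_sp:
        n_chrom = params.n_chromosomes.get(sp, 19)
        # blocks: (chrom, sort_key, [genes]); tandem copies join the block of
        # the previous copy, so no later insertion can separate them.
        blocks: list[tuple[int, float, list[str]]] = []
        block_of_gene: dict[str, int] = {}
        for og in table:
            genes = table.genes(og, sp)
            if not genes:
                continue
            first = genes[0]
            chrom = int(rng_place.integers(n_chrom))
            blocks.append((chrom, float(rng_place.random()), [first]))
            block_of_gene[first] = len(blocks) - 1
            prev = first
            for g in genes[1:]:
                if rng_place.random() < params.tandem_fraction:
                    blocks[block_of_gene[prev]][2].append(g)
                    block_of_gene[g] = block_of_gene[prev]
                    tandem_rows.append({"species_id": sp, "orthogroup_id": og,
                                        "gene_id": g, "tandem": True})
                else:
                    same_chrom = rng_place.random() < 0.5
                    c = blocks[block_of_gene[prev]][0] if same_chrom \
                        else int(rng_place.integers(n_chrom))
                    blocks.append((c, float(rng_place.random()), [g]))
                    block_of_gene[g] = len(blocks) - 1
                    tandem_rows.append({"species_id": sp, "orthogroup_id": og,
                                        "gene_id": g, "tandem": False})
                prev = g
        per_chrom: dict[int, list[str]] = {}
        for chrom, key, genes in sorted(blocks, key=lambda b: (b[0], b[1])):
            per_chrom.setdefault(chrom, []).extend(genes)
        records = []
        step = params.gene_length + params.intergenic
        for chrom, genes in per_chrom.items():
            for k, g in enumerate(genes):
                start = 1 + k * step
                records.append(GeneRecord(g, sp, f"chr{chrom + 1}", start,
                                          start + params.gene_length - 1, "+"))
        annotations[sp] = assign_ranks(records)
    tandem_truth = pd.DataFrame(tandem_rows,
                                columns=["species_id", "orthogroup_id",
                                         "gene_id", "tandem"])

    # --- expression ---------------------------------------------------------
    cmap = default_condition_map()
    if params.n_conditions != len(cmap):
        pairs = tuple((f"condA_{k}", f"condB_{k}") for k in range(params.n_conditions))
        cmap = ConditionMap(pairs=pairs)
    exp_a, exp_b = params.expression_pair
    ancestral: dict[str, np.ndarray] = {}
    subfunc: dict[str, bool] = {}
    C = len(cmap)
    for og in table:
        v = rng_expr.random(C) < params.p_condition_present
        if not v.any():
            v[int(rng_expr.integers(C))] = True
        ancestral[og] = v
        subfunc[og] = bool(rng_expr.random() < params.subfunctionalization_prob)
    truth["n_ancestral_conditions"] = [int(ancestral[og].sum()) for og in table]
    truth["subfunctionalized"] = [subfunc[og] for og in table]

    expression: dict[str, ExpressionMatrix] = {}
    for side, sp in enumerate((exp_a, exp_b)):
        conds = cmap.side(side)
        extra = ["blastula", "female_gonads", "epidermis"] if side == 0 else []
        matrix_rows = {}
        gene_order = []
        for og in table:
            genes = table.genes(og, sp)
            if not genes:
                continue
            profiles = _copy_profiles(rng_expr, ancestral[og], genes, subfunc[og])
            for g, pres in profiles.items():
                tpm = np.zeros(len(conds) + len(extra))
                for ci in range(C):
                    if pres[ci] and rng_expr.random() >= params.dropout:
                        tpm[ci] = float(rng_expr.lognormal(params.expr_mu,
                                                           params.expr_sigma))
                for ei in range(len(extra)):
                    if rng_expr.random() < 0.5:
                        tpm[C + ei] = float(rng_expr.lognormal(params.expr_mu,
                                                               params.expr_sigma))
                matrix_rows[g] = tpm
                gene_order.append(g)
        all_conds = conds + extra
        samples, meta_rows = [], []
        for cond in all_conds:
            cclass = "dev_stage" if cond in ("embryo", "blastula") else "adult_tissue"
            for r in range(params.n_replicates):
                samples.append(f"{sp}_{cond}_r{r + 1}")
                meta_rows.append({"sample_id": f"{sp}_{cond}_r{r + 1}",
                                  "condition_id": cond, "condition_class": cclass})
        data = np.zeros((len(gene_order), len(samples)))
        for gi, g in enumerate(gene_order):
            base = matrix_rows[g]
            for si in range(len(all_conds)):
                for r in range(params.n_replicates):
                    noise = rng_expr.lognormal(0.0, 0.15) if base[si] > 0 else 0.0
                    data[gi, si * params.n_replicates + r] = base[si] * noise
        values = pd.DataFrame(data, index=gene_order, columns=samples)
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        expression[sp] = ExpressionMatrix(values=values, sample_meta=meta)

    # --- gene trees ---------------------------------------------------------
    trees = []
    scrambled_flags = {}
    for og in table:
        tips_a = [g for sp in sp_a for g in table.genes(og, sp)]
        tips_b = [g for sp in sp_b for g in table.genes(og, sp)]
        if len(tips_a) + len(tips_b) < 3:
            continue
        can_scramble = len(tips_a) >= 2 and len(tips_b) >= 2
        scramble = can_scramble and rng_tree.random() < params.scramble_prob
        newick = _build_tree(rng_tree, tips_a, tips_b, scramble)
        tip_species = {g: g.split("_")[0] for g in tips_a + tips_b}
        trees.append(GeneTreeRec(newick=newick, tip_species=tip_species,
                                 orthogroup_id=og))
        scrambled_flags[og] = scramble
    truth["tree_scrambled"] = [scrambled_flags.get(og, False) for og in table]
    truth["tree_scramblable"] = [
        og in scrambled_flags
        and len([g for sp in sp_a for g in table.genes(og, sp)]) >= 2
        and len([g for sp in sp_b for g in table.genes(og, sp)]) >= 2
        for og in table
    ]

    # --- GO annotation ------------------------------------------------------
    go_parents, go_namespaces, gene_go = _simulate_go(
        rng_go, params, table, truth, cfg)

    return SyntheticBundle(
        params=params, cfg=cfg, orthogroups=table, annotations=annotations,
        ohnologs=ohnologs, expression=expression, condition_map=cmap,
        go_parents=go_parents, go_namespaces=go_namespaces, gene_go=gene_go,
        go_source_species="Hsap" if "Hsap" in all_sp else sp_b[-1],
        trees=trees, truth=truth, tandem_truth=tandem_truth,
    )


def _copy_profiles(rng: np.random.Generator, ancestral: np.ndarray,
                   genes: Sequence[str], subfunctionalize: bool) -> dict[str, np.ndarray]:
    """Presence vectors per gene copy: single copies inherit the ancestral
    domain; duplicates either partition it (each ancestral condition goes to
    one copy) or inherit it fully."""
    if len(genes) == 1 or not subfunctionalize:
        return {g: ancestral.copy() for g in genes}
    out = {g: np.zeros_like(ancestral) for g in genes}
    idx = np.flatnonzero(ancestral)
    owners = rng.integers(len(genes), size=len(idx))
    for pos, owner in zip(idx, owners):
        out[genes[owner]][pos] = True
    return out


def _join_random(rng: np.random.Generator, nodes: list[str]) -> str:
    nodes = list(nodes)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0]


def _build_tree(rng: np.random.Generator, tips_a: list[str], tips_b: list[str],
                scramble: bool) -> str:
    """A lineage-monophyletic topology, or (when scrambling) one where a tip
    from each lineage is swapped across the two clades, which breaks
    monophyly of both lineages whenever each has >= 2 tips."""
    if scramble:
        ia = int(rng.integers(len(tips_a)))
        ib = int(rng.integers(len(tips_b)))
        side1 = [t for k, t in enumerate(tips_a) if k != ia] + [tips_b[ib]]
        side2 = [t for k, t in enumerate(tips_b) if k != ib] + [tips_a[ia]]
    else:
        side1, side2 = tips_a, tips_b
    if not side1:
        return _join_random(rng, side2) + ";"
    if not side2:
        return _join_random(rng, side1) + ";"
    return f"({_join_random(rng, side1)},{_join_random(rng, side2)});"


def _simulate_go(rng: np.random.Generator, params: SynthParams,
                 table: OrthogroupTable, truth: pd.DataFrame,
                 cfg: LineageConfig):
    """Two-namespace term DAG plus source-species annotations whose per-term
    duplicability is either shared between lineages or independent."""
    namespaces = ("molecular_function", "biological_process")
    go_parents: dict[str, set[str]] = {}
    go_namespaces: dict[str, str] = {}
    terms_by_ns: dict[str, list[str]] = {ns: [] for ns in namespaces}
    per_ns = max(2, params.go_n_terms // 2)
    for ns_i, ns in enumerate(namespaces):
        root = f"GO:{ns_i}000000"
        go_parents[root] = set()
        go_namespaces[root] = ns
        terms_by_ns[ns].append(root)
        for k in range(1, per_ns):
            term = f"GO:{ns_i}{k:06d}"
            parent = terms_by_ns[ns][int(rng.integers(len(terms_by_ns[ns])))]
            go_parents[term] = {parent}
            go_namespaces[term] = ns
            terms_by_ns[ns].append(term)

    src = "Hsap" if "Hsap" in table.species else cfg.lineage_species(cfg.focal_pair[1])[-1]
    tgt = params.expression_pair[0]
    shared_ogs = [og for og in table
                  if table.count(og, src) >= 1 and table.count(og, tgt) >= 1]
    if not shared_ogs:
        return go_parents, go_namespaces, {}
    dup_a = truth["dup_a"].astype(bool)
    dup_b = truth["dup_b"].astype(bool)

    gene_go: dict[str, set[str]] = {}
    annotatable = [t for ns in namespaces for t in terms_by_ns[ns][1:]]
    weights = np.empty(len(shared_ogs))
    da = dup_a.loc[shared_ogs].to_numpy()
    db = dup_b.loc[shared_ogs].to_numpy()
    for term in annotatable:
        if params.go_shared_duplicability:
            theta = 0.05 + 0.9 * rng.random()
            w = np.where(da, theta, 1 - theta) * np.where(db, theta, 1 - theta)
        else:
            ta = 0.05 + 0.9 * rng.random()
            tb = 0.05 + 0.9 * rng.random()
            w = np.where(da, ta, 1 - ta) * np.where(db, tb, 1 - tb)
        np.copyto(weights, w)
        prob = weights / weights.sum()
        m = min(params.go_ogs_per_term, len(shared_ogs))
        chosen = rng.choice(len(shared_ogs), size=m, replace=False, p=prob)
        for ci in chosen:
            for g in table.genes(shared_ogs[ci], src):
                gene_go.setdefault(g, set()).add(term)
    return go_parents, go_namespaces, gene_go


# ---------------------------------------------------------------------------
# Table-style counts fixture


@dataclass(frozen=True)
class SpeciesCountTargets:
    """Requested per-species totals for a constructive counts fixture."""

    total_genes: int
    dup_genes: int
    n_orthogroups: int
    dup_orthogroups: int
    orth_genes: int | None = None
    orth_dup_genes: int | None = None


def build_counts_fixture(targets: Mapping[str, SpeciesCountTargets],
                         cfg: LineageConfig) -> tuple[OrthogroupTable, dict[str, int]]:
    """Construct a minimal orthogroup table realizing exact per-species
    counts (gene totals, duplicated genes, orthogroup totals, duplicated
    orthogroups, and optionally the subset shared with the other lineage).

    Species totals may exceed the genes placed in orthogroups (the remainder
    are unassigned genes, returned in the totals mapping).  Shared
    orthogroups are realized by adding one gene of an opposite-lineage
    filler species (any configured species of the other lineage that is not
    itself a target).  Infeasible targets raise with the violated constraint.
    """
    entries: dict[str, dict[str, list[str]]] = {}
    totals: dict[str, int] = {}
    counter = 0

    def fresh(sp: str) -> str:
        nonlocal counter
        counter += 1
        return f"{sp}_fx{counter:06d}"

    for sp, t in targets.items():
        lineage = cfg.lineage_of(sp)
        other = cfg.focal_pair[1] if lineage == cfg.focal_pair[0] else cfg.focal_pair[0]
        fillers = [s for s in cfg.lineage_species(other) if s not in targets]
        if (t.orth_genes or 0) > 0 and not fillers:
            raise ChorddupError(
                f"no opposite-lineage filler species available for {sp}")
        filler = fillers[0] if fillers else None

        if t.dup_genes < 2 * t.dup_orthogroups:
            raise ChorddupError(
                f"{sp}: {t.dup_genes} duplicated genes cannot fill "
                f"{t.dup_orthogroups} duplicated orthogroups (need >= 2 each)")
        if t.dup_orthogroups == 0 and t.dup_genes > 0:
            raise ChorddupError(f"{sp}: duplicated genes without duplicated orthogroups")
        n_single = t.n_orthogroups - t.dup_orthogroups
        if n_single < 0:
            raise ChorddupError(f"{sp}: more duplicated orthogroups than orthogroups")
        if t.total_genes < t.dup_genes + n_single:
            raise ChorddupError(
                f"{sp}: total genes {t.total_genes} below the "
                f"{t.dup_genes + n_single} required by the orthogroup counts")

        v = t.orth_genes or 0
        vd = t.orth_dup_genes or 0
        if vd > v or vd > t.dup_genes:
            raise ChorddupError(f"{sp}: inconsistent shared-orthogroup gene counts")
        if v - vd > n_single:
            raise ChorddupError(
                f"{sp}: {v - vd} shared single-copy genes exceed the "
                f"{n_single} single-copy orthogroups")
        # split duplicated orthogroups into shared (k1) / non-shared (k2)
        non_shared_dup_genes = t.dup_genes - vd
        k2 = min(non_shared_dup_genes // 2,
                 t.dup_orthogroups - (1 if vd else 0))
        k1 = t.dup_orthogroups - k2
        if vd and 2 * k1 > vd:
            raise ChorddupError(f"{sp}: shared duplicated gene count {vd} too small "
                                f"for {k1} shared duplicated orthogroups")
        if not vd and k1 > 0:
            raise ChorddupError(
                f"{sp}: duplicated orthogroup targets need more non-shared "
                f"duplicated genes (2 per orthogroup)")

        def dup_og(n_og: int, n_genes: int, shared: bool, tag: str) -> None:
            nonlocal counter
            if n_og == 0:
                return
            sizes = [2] * n_og
            sizes[0] += n_genes - 2 * n_og
            for si, size in enumerate(sizes):
                og = f"{sp}_{tag}{si:06d}"
                row = {sp: [fresh(sp) for _ in range(size)]}
                if shared and filler:
                    row[filler] = [fresh(filler)]
                entries[og] = row

        dup_og(k1, vd, True, "sd")
        dup_og(k2, non_shared_dup_genes, False, "nd")
        for si in range(n_single):
            og = f"{sp}_sc{si:06d}"
            shared = si < (v - vd)
            row = {sp: [fresh(sp)]}
            if shared and filler:
                row[filler] = [fresh(filler)]
            entries[og] = row
        totals[sp] = t.total_genes

    table = OrthogroupTable(entries)
    for sp in table.species:
        totals.setdefault(sp, table.n_genes(sp))
    return table, totals
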