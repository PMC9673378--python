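"""Stage orchestration: run each analysis over a bundle directory.

Every stage reads its inputs from the bundle directory written by
``simulate`` (or by the user, in the same formats), writes plain TSV/JSON
artifacts under the output directory, and records a manifest (input hashes,
parameters, package version) so a rerun with the same seed is verifiable as
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import enrichment as enr
from . import evidence as ev
from . import expression as ex
from . import go as go_mod
from . import io as cio
from . import monophyly as mono
from . import profiles as prof
from . import synteny as syn
from .simulate import SynthParams, simulate_bundle
from .types import ChorddupError, LineageConfig, default_lineage_config

logger = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "enrich", "trees", "goterms", "expression",
          "synteny", "evidence", "all")


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run."""

    bundle_dir: Path
    out_dir: Path
    seed: int = 0
    presence_threshold: float = 1.0
    min_genes: int = 50
    mean_copy_threshold: float = 2.5
    min_fraction: float = 0.2
    tandem_gap: int = 0
    n_orthogroups: int = 5000
    lineage_config: LineageConfig = field(default_factory=default_lineage_config)

    def __post_init__(self) -> None:
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)
        if not (0 <= self.min_fraction <= 1):
            raise ChorddupError("min_fraction must be in [0, 1]")
        if self.presence_threshold < 0 or self.tandem_gap < 0:
            raise ChorddupError("thresholds must be non-negative")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, inputs: list[Path],
                    outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: str(v) if isinstance(v, (Path, LineageConfig)) else v
            for k, v in dataclasses.asdict(cfg).items()
        },
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": sorted(str(p) for p in outputs),
    }
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    with (cfg.out_dir / f"manifest_{stage}.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise ChorddupError(f"missing input {path}; run the {produced_by!r} stage first")
    return path


def run(stage: str, cfg: RunConfig) -> list[Path]:
    """Run one stage (or ``all``) and return the artifact paths written."""
    if stage not in STAGES:
        raise ChorddupError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage == "all":
        out: list[Path] = []
        for s in STAGES[:-1]:
            out.extend(run(s, cfg))
        return out
    return _STAGE_FUNCS[stage](cfg)


def _stage_simulate(cfg: RunConfig) -> list[Path]:
    params = SynthParams(seed=cfg.seed, n_orthogroups=cfg.n_orthogroups)
    bundle = simulate_bundle(params)
    d = cfg.bundle_dir
    d.mkdir(parents=True, exist_ok=True)
    cio.write_orthogroups(bundle.orthogroups, d / "orthogroups.tsv")
    cio.write_ohnologs(bundle.ohnologs, d / "ohnologs.tsv")
    for sp, ann in bundle.annotations.items():
        cio.write_gene_annotation(ann, d / f"genes_{sp}.bed", format="bed")
    for sp, m in bundle.expression.items():
        cio.write_expression(m, d / f"expression_{sp}.tsv", d / f"samples_{sp}.tsv")
    cio.write_gene_trees(bundle.trees, d / "gene_trees.nwk")
    cio.write_obo(bundle.go_parents, d / "ontology.obo", bundle.go_namespaces)
    cio.write_gene_go(bundle.gene_go, d / "gene_go.tsv")
    bundle.truth.to_csv(d / "truth.tsv", sep="\t")
    bundle.tandem_truth.to_csv(d / "tandem_truth.tsv", sep="\t", index=False)
    pd.DataFrame(bundle.condition_map.pairs,
                 columns=["condition_a", "condition_b"]).to_csv(
        d / "condition_map.tsv", sep="\t", index=False)
    outputs = sorted(d.glob("*"))
    _write_manifest(cfg, "simulate", [], outputs)
    return outputs


def _load_profile(cfg: RunConfig):
    table = cio.read_orthogroups(_require(cfg.bundle_dir / "orthogroups.tsv", "simulate"))
    ohno_path = cfg.bundle_dir / "ohnologs.tsv"
    ohno = cio.read_ohnologs(ohno_path) if ohno_path.exists() else None
    return table, prof.lineage_status(table, cfg.lineage_config, ohno)


def _stage_profile(cfg: RunConfig) -> list[Path]:
    table, profile = _load_profile(cfg)
    cnm = prof.copy_number_matrix(table)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    per_og = cnm.join(profile.table)
    p1 = cfg.out_dir / "orthogroup_profile.tsv"
    per_og.to_csv(p1, sep="\t", index_label="orthogroup_id")
    summary = prof.species_summary(table, cfg.lineage_config)
    p2 = cfg.out_dir / "species_summary.tsv"
    summary.to_csv(p2, sep="\t")
    _write_manifest(cfg, "profile", [cfg.bundle_dir / "orthogroups.tsv",
                                     cfg.bundle_dir / "ohnologs.tsv"], [p1, p2])
    return [p1, p2]


def _stage_enrich(cfg: RunConfig) -> list[Path]:
    _require(cfg.out_dir / "orthogroup_profile.tsv", "profile")
    table, profile = _load_profile(cfg)
    cnm = prof.copy_number_matrix(table)
    report = enr.coduplication_report(profile, cnm=cnm)
    p1 = cfg.out_dir / "coduplication_enrichment.tsv"
    report.to_csv(p1, sep="\t", index=False)
    outputs = [p1]
    try:
        assoc = enr.copy_number_association(profile, threshold=cfg.mean_copy_threshold)
        p2 = cfg.out_dir / "copy_number_association.json"
        with p2.open("w") as fh:
            json.dump({
                "spearman_rho": assoc.spearman_rho, "spearman_p": assoc.spearman_p,
                "chi2": assoc.chi2, "chi2_p": assoc.chi2_p,
                "contingency": assoc.contingency.tolist(), "n": assoc.n,
                "threshold": assoc.threshold,
            }, fh, indent=2)
        outputs.append(p2)
    except ChorddupError as e:
        logger.warning("copy-number association skipped: %s", e)
    _write_manifest(cfg, "enrich", [cfg.bundle_dir / "orthogroups.tsv"], outputs)
    return outputs


def _stage_trees(cfg: RunConfig) -> list[Path]:
    trees = cio.read_gene_trees(_require(cfg.bundle_dir / "gene_trees.nwk", "simulate"))
    results = [mono.lineage_monophyly(t, cfg.lineage_config) for t in trees]
    lin_a, lin_b = cfg.lineage_config.focal_pair
    df = pd.DataFrame([{
        "orthogroup_id": r.orthogroup_id or "",
        f"monophyletic_{lin_a}": r.lineage_monophyly[lin_a],
        f"monophyletic_{lin_b}": r.lineage_monophyly[lin_b],
        "both_monophyletic": r.both_monophyletic,
        "untestable": r.untestable,
    } for r in results])
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    p1 = cfg.out_dir / "monophyly.tsv"
    df.to_csv(p1, sep="\t", index=False)
    p2 = cfg.out_dir / "monophyly_rate.json"
    with p2.open("w") as fh:
        json.dump(mono.validation_rate(results), fh, indent=2)
    _write_manifest(cfg, "trees", [cfg.bundle_dir / "gene_trees.nwk"], [p1, p2])
    return [p1, p2]


def _stage_goterms(cfg: RunConfig) -> list[Path]:
    table, profile = _load_profile(cfg)
    parents, namespaces = cio.read_obo(_require(cfg.bundle_dir / "ontology.obo", "simulate"))
    gomap = cio.read_gene_go(_require(cfg.bundle_dir / "gene_go.tsv", "simulate"))
    source = "Hsap" if "Hsap" in table.species else table.species[-1]
    target = "Blan" if "Blan" in table.species else table.species[0]
    closed = go_mod.propagate_annotations(parents, gomap)
    target_map, source_sym = go_mod.transfer_annotations(closed, table, source, target)
    stats = go_mod.per_term_duplication(target_map, source_sym, table, profile,
                                        min_genes=cfg.min_genes, namespaces=namespaces)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    p1 = cfg.out_dir / "go_term_duplication.tsv"
    stats.to_csv(p1, sep="\t", index=False)
    p2 = cfg.out_dir / "go_parallelism.tsv"
    go_mod.parallelism_summary(stats).to_csv(p2, sep="\t", index=False)
    _write_manifest(cfg, "goterms", [cfg.bundle_dir / "ontology.obo",
                                     cfg.bundle_dir / "gene_go.tsv"], [p1, p2])
    return [p1, p2]


def _stage_expression(cfg: RunConfig) -> list[Path]:
    table, profile = _load_profile(cfg)
    cmap_path = _require(cfg.bundle_dir / "condition_map.tsv", "simulate")
    cmap_df = pd.read_csv(cmap_path, sep="\t")
    cmap = ex.ConditionMap(pairs=tuple(
        (r.condition_a, r.condition_b) for r in cmap_df.itertuples(index=False)))
    sp_a, sp_b = "Blan", "Drer"
    m_a = cio.read_expression(_require(cfg.bundle_dir / f"expression_{sp_a}.tsv", "simulate"),
                              cfg.bundle_dir / f"samples_{sp_a}.tsv")
    m_b = cio.read_expression(_require(cfg.bundle_dir / f"expression_{sp_b}.tsv", "simulate"),
                              cfg.bundle_dir / f"samples_{sp_b}.tsv")
    means_a = ex.condition_means(m_a)
    means_b = ex.condition_means(m_b)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []

    taus = ex.tau_table(means_a[[c for c in means_a.columns
                                 if c not in ex.DEFAULT_EXCLUDED_CONDITIONS]])
    p_tau = cfg.out_dir / f"tau_{sp_a}.tsv"
    taus.to_csv(p_tau, sep="\t", index_label="gene_id")
    outputs.append(p_tau)

    pa = ex.presence_profile(means_a, cmap.side(0), threshold=cfg.presence_threshold)
    pb = ex.presence_profile(means_b, cmap.side(1), threshold=cfg.presence_threshold)
    frames = [ex.expression_delta(table, pa, pb, sp_a, sp_b, mode="one_to_one"),
              ex.expression_delta(table, pa, pb, sp_a, sp_b, mode="union_vs_single")]
    deltas = pd.concat(frames, ignore_index=True)
    p_delta = cfg.out_dir / "expression_deltas.tsv"
    deltas.to_csv(p_delta, sep="\t", index=False)
    outputs.append(p_delta)

    stats = {}
    for mode, sub in deltas.groupby("mode"):
        if len(sub) >= 3:
            stats[mode] = ex.delta_distribution_stats(sub["delta"])
    p_stats = cfg.out_dir / "expression_delta_stats.json"
    with p_stats.open("w") as fh:
        json.dump(stats, fh, indent=2, default=str)
    outputs.append(p_stats)

    # group summary: single-copy vs duplicated genes of species A
    prof_t = profile.table
    g2og = table.gene_to_orthogroup
    mean_expr = means_a.mean(axis=1)
    dup_ogs = set(prof_t.index[prof_t["status_a"].isin(("small_scale_dup", "ohnolog"))])
    single_ogs = set(prof_t.index[prof_t["status_a"] == "single_copy"])
    groups = {
        "single_copy": [v for g, v in mean_expr.items() if g2og.get(g) in single_ogs],
        "small_scale_dup": [v for g, v in mean_expr.items() if g2og.get(g) in dup_ogs],
    }
    groups = {k: v for k, v in groups.items() if v}
    p_groups = cfg.out_dir / "expression_group_summary.tsv"
    ex.group_expression_summary(groups).to_csv(p_groups, sep="\t")
    outputs.append(p_groups)
    _write_manifest(cfg, "expression",
                    [cfg.bundle_dir / f"expression_{sp_a}.tsv",
                     cfg.bundle_dir / f"expression_{sp_b}.tsv"], outputs)
    return outputs


def _stage_synteny(cfg: RunConfig) -> list[Path]:
    table = cio.read_orthogroups(_require(cfg.bundle_dir / "orthogroups.tsv", "simulate"))
    sp_a, sp_b = "Blan", "Bflo"
    ann_a = cio.read_gene_annotation(
        _require(cfg.bundle_dir / f"genes_{sp_a}.bed", "simulate"), "bed", sp_a)
    ann_b = cio.read_gene_annotation(
        _require(cfg.bundle_dir / f"genes_{sp_b}.bed", "simulate"), "bed", sp_b)
    pairs = syn.one_to_one_pairs(table, sp_a, sp_b)
    points = syn.dotplot(pairs, ann_a, ann_b)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    p1 = cfg.out_dir / "dotplot_points.tsv"
    points.to_csv(p1, sep="\t", index=False)
    pair_cls, og_cls = syn.classify_duplicate_locations(table, ann_a, sp_a,
                                                        max_gap=cfg.tandem_gap)
    p2 = cfg.out_dir / "duplicate_locations_pairs.tsv"
    pair_cls.to_csv(p2, sep="\t", index=False)
    p3 = cfg.out_dir / "duplicate_locations_orthogroups.tsv"
    og_cls.to_csv(p3, sep="\t", index=False)
    homology = syn.chromosome_homology(points, min_fraction=cfg.min_fraction)
    p4 = cfg.out_dir / "chromosome_homology.tsv"
    homology.calls.to_csv(p4, sep="\t", index=False)
    p5 = cfg.out_dir / "chromosome_fractions.tsv"
    homology.fractions.to_csv(p5, sep="\t", index=False)
    _write_manifest(cfg, "synteny", [cfg.bundle_dir / "orthogroups.tsv"],
                    [p1, p2, p3, p4, p5])
    return [p1, p2, p3, p4, p5]


def _stage_evidence(cfg: RunConfig) -> list[Path]:
    sp = "Blan"
    m = cio.read_expression(_require(cfg.bundle_dir / f"expression_{sp}.tsv", "simulate"),
                            cfg.bundle_dir / f"samples_{sp}.tsv")
    expr_ev = ev.expression_evidence(m, threshold=cfg.presence_threshold)
    blast_path = cfg.bundle_dir / "blast_hits.tsv"
    seqsim = None
    if blast_path.exists():
        seqsim = ev.seqsim_evidence(cio.read_blast_table(blast_path))
    genes = sorted(m.values.index)
    table = ev.evidence_table(seqsim, expr_ev, genes)
    retained, summary = ev.retention(table)
    table["retained"] = [g in retained for g in table.index]
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    p1 = cfg.out_dir / "evidence.tsv"
    table.to_csv(p1, sep="\t")
    p2 = cfg.out_dir / "evidence_summary.json"
    with p2.open("w") as fh:
        json.dump(summary, fh, indent=2)
    _write_manifest(cfg, "evidence", [cfg.bundle_dir / f"expression_{sp}.tsv"],
                    [p1, p2])
    return [p1, p2]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "profile": _stage_profile,
    "enrich": _stage_enrich,
    "trees": _stage_trees,
    "goterms": _stage_goterms,
    "expression": _stage_expression,
    "synteny": _stage_synteny,
    "evidence": _stage_evidence,
}
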