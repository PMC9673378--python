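import pytest

from chorddup.simulate import SynthParams, simulate_bundle
from chorddup.types import LineageConfig, default_lineage_config


@pytest.fixture(scope="session")
def cfg() -> LineageConfig:
    return default_lineage_config()


@pytest.fixture(scope="session")
def small_bundle():
    """One shared moderate-size bundle for cross-module integration tests."""
    return simulate_bundle(SynthParams(seed=11, n_orthogroups=1500))


@pytest.fixture()
def two_lineage_cfg() -> LineageConfig:
    """Minimal 2+2 species panel for hand-built examples."""
    return LineageConfig(
        species_to_lineage={"A1": "amphioxus", "A2": "amphioxus",
                            "V1": "vertebrate", "V2": "vertebrate"},
        focal_pair=("amphioxus", "vertebrate"),
        wgd_3r_species=frozenset({"V1"}),
    )
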