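import numpy as np
import pytest

from lintseg.model import (
    ALLELE_A,
    ALLELE_B,
    CausalLocus,
    EffectModel,
    GenomeMap,
    founder,
)


@pytest.fixture
def small_map() -> GenomeMap:
    """One 10-Mbp chromosome with markers every 1 Mbp (11 markers incl. ends)."""
    return GenomeMap(
        chromosomes=[("chr1", 10_000_000)],
        marker_positions={"chr1": np.arange(1_000_000, 10_000_001, 1_000_000)},
        recomb_rate_cM_per_Mbp=1.0,
    )


@pytest.fixture
def one_locus(small_map) -> CausalLocus:
    return CausalLocus(
        id="L1", chromosome="chr1", position_bp=5_000_000, dysfunctional="A"
    )


@pytest.fixture
def recessive_model() -> EffectModel:
    """Large recessive lint% penalty at L1; L1 is also dominant-fuzzless."""
    return EffectModel(
        baseline_lint_pct=30.0,
        penalties={"L1": (0.0, 0.0, 25.0)},
        noise_sd=0.0,
        fuzz_dominant="L1",
    )


@pytest.fixture
def parents(small_map):
    return founder(small_map, ALLELE_A, "mutant"), founder(small_map, ALLELE_B, "wildtype")
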