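"""Preset founders, loci, effect models and population designs.

The four default causal loci are the At/Dt homoeologs of *MYB25-like*
(Chr-A12 / Chr-D12) and *HD1* (Chr-A06 / Chr-D06), placed mid-chromosome on
the desk-scale stand-in genome.  Founder lines carry loss-of-function sets:
'SL1-7-1' (fiberless mutant) at MYB25-like_At and HD1_At, 'T586' (dominant
fuzzless) at MYB25-like_At, 'Pima S-7' (recessive fuzzless) at MYB25-like_Dt
and HD1_At, 'Sicala V-2' (fuzzy commercial line) at none.

The default effect model is a calibration, not a measured model: per-locus
homozygous penalties are ordered MYB25-like_At > HD1_At > MYB25-like_Dt >
HD1_Dt to match the observed single-locus class means, with one epistatic
masking rule (the HD1_Dt penalty is expressed only when MYB25-like_At is
homozygous loss-of-function).  Everything is overridable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .model import (
    ALLELE_A,
    ALLELE_B,
    HD1_AT,
    HD1_DT,
    MYB25_AT,
    MYB25_DT,
    CausalLocus,
    EffectModel,
    GenomeMap,
    founder,
)
from .simulate import make_cross

LOCUS_CHROMS = {
    MYB25_AT: "Chr-A12",
    MYB25_DT: "Chr-D12",
    HD1_AT: "Chr-A06",
    HD1_DT: "Chr-D06",
}

#: loss-of-function allele sets of the founder lines; 'SL1-7-1' HD1_Dt status
#: is uncertain and controlled by the ``sl_hd1dt_dysfunctional`` switch.
FOUNDER_LOF: Mapping[str, frozenset] = {
    "SL1-7-1": frozenset({MYB25_AT, HD1_AT}),
    "Sicala V-2": frozenset(),
    "T586": frozenset({MYB25_AT}),
    "Pima S-7": frozenset({MYB25_DT, HD1_AT}),
}


def default_map(recomb_rate_cM_per_Mbp: float = 1.0) -> GenomeMap:
    return GenomeMap.default(recomb_rate_cM_per_Mbp=recomb_rate_cM_per_Mbp)


def cross_loci(
    parent_a: str,
    parent_b: str,
    gmap: GenomeMap | None = None,
    sl_hd1dt_dysfunctional: bool = False,
) -> list[CausalLocus]:
    """Causal loci with dysfunctionality resolved from the two founder names."""
    gmap = gmap or default_map()
    lof = {name: set(s) for name, s in FOUNDER_LOF.items()}
    if sl_hd1dt_dysfunctional and "SL1-7-1" in (parent_a, parent_b):
        lof["SL1-7-1"].add(HD1_DT)
    if parent_a not in lof or parent_b not in lof:
        raise KeyError(f"unknown founder; known: {sorted(lof)}")
    loci = []
    for lid, chrom in LOCUS_CHROMS.items():
        in_a, in_b = lid in lof[parent_a], lid in lof[parent_b]
        dys = "both" if (in_a and in_b) else "A" if in_a else "B" if in_b else None
        loci.append(
            CausalLocus(
                id=lid,
                chromosome=chrom,
                position_bp=gmap.length(chrom) // 2,
                allele_labels=(parent_a, parent_b),
                dysfunctional=dys,
            )
        )
    return loci


def default_effect_model(noise_sd: float = 2.0) -> EffectModel:
    """Four-locus additive-penalty calibration with HD1_Dt masked by MYB25-like_At."""
    return EffectModel(
        baseline_lint_pct=25.33,
        penalties={
            MYB25_AT: (0.0, 3.14, 13.25),
            HD1_AT: (0.0, 2.0, 8.50),
            MYB25_DT: (0.0, 1.0, 6.23),
            HD1_DT: (0.0, 0.5, 5.31),
        },
        masking_rules=[(HD1_DT, MYB25_AT, 2)],
        noise_sd=noise_sd,
        fuzz_dominant=MYB25_AT,
        fuzz_recessive=MYB25_DT,
    )


def st_f2_effect_model(noise_sd: float = 2.0) -> EffectModel:
    """Single-segregating-locus model for the 'SL1-7-1' x 'T586' F2.

    MYB25-like_At is fixed loss-of-function (both parents), so its penalty is
    folded into the baseline; HD1_At class means are 20.47 / 13.75 / 5.14 for
    0 / 1 / 2 loss-of-function alleles.
    """
    return EffectModel(
        baseline_lint_pct=20.47,
        penalties={
            MYB25_AT: (0.0, 0.0, 0.0),
            MYB25_DT: (0.0, 0.0, 0.0),
            HD1_AT: (0.0, 6.72, 15.33),
            HD1_DT: (0.0, 0.0, 0.0),
        },
        noise_sd=noise_sd,
        fuzz_dominant=MYB25_AT,
        fuzz_recessive=MYB25_DT,
    )


def cross_population(
    parent_a: str,
    parent_b: str,
    cross_type: str,
    n: int,
    seed: int,
    model: EffectModel | None = None,
    gmap: GenomeMap | None = None,
    sl_hd1dt_dysfunctional: bool = False,
):
    """Build a phenotyped population for a named founder pair."""
    gmap = gmap or default_map()
    loci = cross_loci(parent_a, parent_b, gmap, sl_hd1dt_dysfunctional)
    model = model or default_effect_model()
    a = founder(gmap, ALLELE_A, parent_a)
    b = founder(gmap, ALLELE_B, parent_b)
    return make_cross(
        (a, b), cross_type, n, model, gmap, loci, seed, parent_names=(parent_a, parent_b)
    )


#: the study's population designs: (parent A, parent B, cross type, n)
POPULATION_DESIGNS = {
    "SS_F2": ("SL1-7-1", "Sicala V-2", "F2", 108),
    "ST_F2": ("SL1-7-1", "T586", "F2", 101),
    "TPT_BC1F2": ("T586", "Pima S-7", "BC1F2", 118),
    "TPP_BC1F2": ("Pima S-7", "T586", "BC1F2", 126),
    "TP_F2": ("T586", "Pima S-7", "F2", 303),
}


def design_population(name: str, seed: int, model: EffectModel | None = None, gmap=None):
    if name not in POPULATION_DESIGNS:
        raise KeyError(f"unknown design {name!r}; known: {sorted(POPULATION_DESIGNS)}")
    pa, pb, ctype, n = POPULATION_DESIGNS[name]
    return cross_population(pa, pb, ctype, n, seed, model=model, gmap=gmap)
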