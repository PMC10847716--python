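"""End-to-end simulation scenarios used for calibration and validation.

``detection_scan`` reproduces the study's extreme-pool design at desk scale:
an F2 of 101 plants segregating one large-effect locus that is dominant for
the fuzzless seed trait and (near-)recessive for lint%, with both 19-member
bulks drawn from the fuzzless segregants by lint% rank.  Conditioning the
bulks on the fuzzless trait is what produces the characteristic scan
signature at the causal locus — alternate-allele frequency ~1.0 in the low
bulk (homozygous mutants) and ~0.5 in the high bulk (heterozygous carriers)
— and is the mechanistic basis of the >0.8 / ~0.5 candidate rule.

``null_scan`` runs the same machinery on a population with no causal effect,
splitting it into two random bulks for false-positive calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bsa
from .model import ALLELE_B, MYB25_AT, EffectModel, founder, ALLELE_A
from .presets import cross_loci, default_map
from .simulate import make_cross, simulate_pool_counts


def detection_effect_model(noise_sd: float = 2.0) -> EffectModel:
    """One large-effect locus: recessive for lint% (class means 39/39/6), dominant fuzzless."""
    return EffectModel(
        baseline_lint_pct=39.0,
        penalties={MYB25_AT: (0.0, 0.0, 33.0)},
        noise_sd=noise_sd,
        fuzz_dominant=MYB25_AT,
    )


@dataclass
class ScanResult:
    windows: object
    regions: object
    causal_chrom: str
    causal_pos: int
    detected: bool


def _scan(pop, low, high, gmap, mean_depth, window_bp, step_bp, min_snps, rng):
    counts_low = simulate_pool_counts(
        low, gmap, mean_depth, rng, ref_origin=ALLELE_B, pool_id="low"
    )
    counts_high = simulate_pool_counts(
        high, gmap, mean_depth, rng, ref_origin=ALLELE_B, pool_id="high"
    )
    f1 = bsa.pool_frequency(counts_low)
    f2 = bsa.pool_frequency(counts_high)
    lengths = dict(gmap.chromosomes)
    windows = bsa.windowed_frequencies(
        f1, f2, window_bp, step_bp, min_snps_per_window=min_snps, chrom_lengths=lengths
    )
    regions = bsa.call_candidates(windows)
    return windows, regions


def detection_scan(
    seed: int,
    n: int = 101,
    n_per_pool: int = 19,
    mean_depth: float = 25.0,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_snps: int = 10,
) -> ScanResult:
    """One seeded extreme-pool scan replicate; ``detected`` is True when the
    top candidate region contains the true causal position."""
    gmap = default_map()
    loci = cross_loci("SL1-7-1", "Sicala V-2", gmap)
    model = detection_effect_model()
    a = founder(gmap, ALLELE_A, "SL1-7-1")
    b = founder(gmap, ALLELE_B, "Sicala V-2")
    pop = make_cross((a, b), "F2", n, model, gmap, loci, seed)
    fuzzless = [i for i in pop.individuals if i.fuzzless]
    low, high = bsa.select_pools(fuzzless, ("rank", None), ("rank", None), n_per_pool=n_per_pool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    windows, regions = _scan(pop, low, high, gmap, mean_depth, window_bp, step_bp, min_snps, rng)
    causal = next(l for l in loci if l.id == MYB25_AT)
    top = bsa.top_region(regions)
    detected = (
        top is not None
        and top["chrom"] == causal.chromosome
        and top["start"] <= causal.position_bp <= top["end"]
    )
    return ScanResult(windows, regions, causal.chromosome, causal.position_bp, bool(detected))


def null_scan(
    seed: int,
    n: int = 101,
    mean_depth: float = 25.0,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
    min_snps: int = 10,
):
    """Scan of a no-causal-locus F2 split into two random bulks.

    Returns (windows, regions, candidate_window_fraction): candidate windows
    per assessable window under the default calling rule.
    """
    gmap = default_map()
    loci = cross_loci("SL1-7-1", "Sicala V-2", gmap)
    model = EffectModel(baseline_lint_pct=30.0, penalties={}, noise_sd=2.0)
    a = founder(gmap, ALLELE_A, "SL1-7-1")
    b = founder(gmap, ALLELE_B, "Sicala V-2")
    pop = make_cross((a, b), "F2", n, model, gmap, loci, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
    perm = rng.permutation(n)
    half = n // 2
    low = [pop.individuals[i] for i in perm[:half]]
    high = [pop.individuals[i] for i in perm[half:]]
    windows, regions = _scan(pop, low, high, gmap, mean_depth, window_bp, step_bp, min_snps, rng)
    ok = windows["ok"]
    m1 = windows.loc[ok, "mean_freq_pool1"]
    m2 = windows.loc[ok, "mean_freq_pool2"]
    cand = ((m1 > 0.8) & m2.between(0.35, 0.65)) | ((m2 > 0.8) & m1.between(0.35, 0.65))
    frac = float(cand.mean()) if ok.any() else 0.0
    return windows, regions, frac
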