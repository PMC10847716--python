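"""Synthetic-data generators: Mendelian crosses, pooled read counts, germplasm panels.

Meiosis follows the Haldane map function without interference: the
recombination fraction between adjacent markers at map distance ``d``
Morgans is ``r = (1 - exp(-2 d)) / 2``, and chromosomes assort
independently.  Pooled sequencing is emulated at the read-count level
(depth ~ Poisson, alternate count ~ Binomial at the pool's true allele
fraction); no sequence-level reads are simulated.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bsa import PoolCounts
from .model import (
    ALLELE_A,
    ALLELE_B,
    CausalLocus,
    EffectModel,
    GenomeMap,
    Individual,
    Population,
)
from .panel import PanelAccession

CROSS_TYPES = ("F1", "F2", "BC1F2", "F2:3", "SIBCROSS_F2")


def _recomb_fractions(gmap: GenomeMap, chrom: str) -> np.ndarray:
    pos = gmap.positions(chrom)
    d_morgan = gmap.recomb_rate_cM_per_Mbp / 100.0 * np.diff(pos) / 1e6
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def simulate_gametes(
    parent: Individual, gmap: GenomeMap, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` recombinant gametes; returns per chromosome an ``(n, m)`` allele matrix."""
    out: dict[str, np.ndarray] = {}
    for chrom in gmap.chrom_names:
        pos = gmap.positions(chrom)
        if pos.size == 0:
            raise ValueError(f"empty marker set on chromosome {chrom}")
        hap = parent.haplotypes[chrom]
        m = pos.size
        start = rng.integers(0, 2, size=(n, 1))
        if m == 1:
            idx = start
        else:
            r = _recomb_fractions(gmap, chrom)
            switches = rng.random((n, m - 1)) < r
            idx = (start + np.concatenate(
                [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        out[chrom] = hap[idx, np.arange(m)]
    return out


def simulate_gamete(
    parent: Individual, gmap: GenomeMap, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One recombinant haplotype set (one allele vector per chromosome)."""
    return {c: g[0] for c, g in simulate_gametes(parent, gmap, 1, rng).items()}


def _mate_one(p1: Individual, p2: Individual, gmap: GenomeMap, rng: np.random.Generator) -> Individual:
    g1 = simulate_gamete(p1, gmap, rng)
    g2 = simulate_gamete(p2, gmap, rng)
    return Individual(haplotypes={c: np.stack([g1[c], g2[c]]).astype(np.uint8) for c in gmap.chrom_names})


def _mate_batch(
    p1: Individual, p2: Individual, gmap: GenomeMap, n: int, rng: np.random.Generator
) -> list[Individual]:
    g1 = simulate_gametes(p1, gmap, n, rng)
    g2 = simulate_gametes(p2, gmap, n, rng)
    return [
        Individual(
            haplotypes={c: np.stack([g1[c][i], g2[c][i]]).astype(np.uint8) for c in gmap.chrom_names}
        )
        for i in range(n)
    ]


def assign_phenotype(
    individual: Individual,
    model: EffectModel,
    loci: Sequence[CausalLocus],
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> Individual:
    """Fill ``lint_pct`` (truncated at 0; 0 = fiberless) and ``fuzzless`` in place."""
    dosages = {l.id: individual.dosage(l, gmap) for l in loci}
    expected = model.expected_lint(dosages)
    noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    individual.lint_pct = float(max(0.0, expected + noise))
    individual.fuzzless = model.is_fuzzless(dosages)
    return individual


def _phenotype_batch(
    individuals: list[Individual],
    model: EffectModel,
    loci: Sequence[CausalLocus],
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> None:
    n = len(individuals)
    dosage = {
        l.id: np.array([ind.dosage(l, gmap) for ind in individuals], dtype=np.int64)
        for l in loci
    }
    if model.explicit_classes is not None:
        expected = np.array(
            [
                model.expected_lint({lid: int(dosage[lid][i]) for lid in dosage})
                for i in range(n)
            ]
        )
    else:
        expected = np.full(n, model.baseline_lint_pct, dtype=float)
        for l in loci:
            trip = model.penalties.get(l.id)
            if trip is None:
                continue
            pen = np.asarray(trip, dtype=float)[dosage[l.id]]
            active = np.ones(n, dtype=bool)
            for masked, masking, required in model.masking_rules:
                if masked == l.id:
                    active &= dosage[masking] == required
            expected -= np.where(active, pen, 0.0)
        expected = np.maximum(expected, 0.0)
    noise = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 else 0.0
    lint = np.maximum(0.0, expected + noise)
    dom = dosage.get(model.fuzz_dominant, np.zeros(n, dtype=np.int64)) if model.fuzz_dominant else np.zeros(n, dtype=np.int64)
    rec = dosage.get(model.fuzz_recessive, np.zeros(n, dtype=np.int64)) if model.fuzz_recessive else np.zeros(n, dtype=np.int64)
    fuzzless = (dom >= 1) | (rec == 2)
    for i, ind in enumerate(individuals):
        ind.lint_pct = float(lint[i]) if np.ndim(lint) else float(lint)
        ind.fuzzless = bool(fuzzless[i])


def make_cross(
    parents: tuple[Individual, Individual],
    cross_type: str,
    n: int,
    model: EffectModel,
    gmap: GenomeMap,
    loci: Sequence[CausalLocus],
    seed: int,
    parent_names: tuple[str, str] = ("A", "B"),
) -> Population:
    """Generate a phenotyped cross generation.

    Cross types: ``F1`` (A x B progeny), ``F2`` (self of one F1), ``BC1F2``
    (self of one (F1 x parent A) offspring; parent A is the recurrent
    parent), ``F2:3`` (self of the named plant passed as ``parents[0]``) and
    ``SIBCROSS_F2`` (F2 of a cross between the two named segregants).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cross_type not in CROSS_TYPES:
        raise ValueError(f"unknown cross_type {cross_type!r}; expected one of {CROSS_TYPES}")
    for locus in loci:
        locus.validate_on(gmap)
    rng = np.random.default_rng(seed)
    a, b = parents
    if cross_type == "F1":
        children = _mate_batch(a, b, gmap, n, rng)
    elif cross_type == "F2":
        f1 = _mate_one(a, b, gmap, rng)
        children = _mate_batch(f1, f1, gmap, n, rng)
    elif cross_type == "BC1F2":
        f1 = _mate_one(a, b, gmap, rng)
        bc1 = _mate_one(f1, a, gmap, rng)
        children = _mate_batch(bc1, bc1, gmap, n, rng)
    elif cross_type == "F2:3":
        children = _mate_batch(a, a, gmap, n, rng)
    else:  # SIBCROSS_F2
        f1 = _mate_one(a, b, gmap, rng)
        children = _mate_batch(f1, f1, gmap, n, rng)
    _phenotype_batch(children, model, loci, gmap, rng)
    for i, child in enumerate(children):
        child.pedigree_tag = f"{cross_type}-{i + 1}"
    return Population(
        individuals=children,
        cross_type=cross_type,
        parents=parent_names,
        seed=seed,
        gmap=gmap,
        loci=list(loci),
        model=model,
    )


def simulate_pool_counts(
    pool: Sequence[Individual],
    gmap: GenomeMap,
    mean_depth: float,
    rng: np.random.Generator,
    snp_positions: Mapping[str, np.ndarray] | None = None,
    ref_origin: int = ALLELE_B,
    pool_id: str = "pool",
) -> PoolCounts:
    """Pooled short-read counts over SNP positions.

    Per SNP: depth ~ Poisson(mean_depth) (floored at 1), alternate count
    ~ Binomial(depth, f) where f is the non-reference allele fraction among
    the ``2 * len(pool)`` pooled chromosomes.  ``ref_origin`` names which
    parent's genome plays the role of the mapping reference (alternate
    alleles are the other parent's).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if ref_origin not in (ALLELE_A, ALLELE_B):
        raise ValueError("ref_origin must be 0 or 1")
    frames = []
    for chrom in gmap.chrom_names:
        pos = gmap.positions(chrom)
        if snp_positions is not None:
            want = np.asarray(snp_positions.get(chrom, []), dtype=np.int64)
            if want.size == 0:
                continue
            keep = np.isin(pos, want)
            if keep.sum() != want.size:
                raise ValueError(f"some requested SNP positions on {chrom} are not map markers")
        else:
            keep = np.ones(pos.size, dtype=bool)
        alleles = np.concatenate([ind.haplotypes[chrom][:, keep] for ind in pool], axis=0)
        f = np.mean(alleles != ref_origin, axis=0)
        depth = rng.poisson(mean_depth, size=f.size)
        depth = np.maximum(depth, 1)
        alt = rng.binomial(depth, f)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return PoolCounts(pool_id=pool_id, records=records)


def simulate_panel(
    n_accessions: int,
    genes: Sequence[str],
    lp_freqs: Mapping[str, float] | float = 0.5,
    group_means: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 4.0,
    fuzzless_fraction: float = 81 / 723,
    fuzzless_penalty: float = 12.0,
    het_rate: float = 0.0,
    snps_per_gene: int = 12,
    baseline_lint_pct: float = 31.0,
    seed: int = 0,
) -> list[PanelAccession]:
    """Germplasm panel with per-gene LP/lp/HET haplotypes and lint% values.

    Each accession independently draws, per gene, a heterozygous state with
    probability ``het_rate``, otherwise the lp haplotype with probability
    ``lp_freqs[gene]`` and the LP haplotype with the complement.  Haplotypes
    are realised as fixed distinguishing SNP-code vectors (0/1/2) over the
    gene +/- 2 kb site set.  lint% is ``baseline + sum of per-gene group-mean
    effects (het = midpoint) - fuzzless penalty (if fuzzless) + noise``,
    clipped at 0.  Generator-truth haplotypes are recorded for oracle
    comparisons.
    """
    if not (0 <= fuzzless_fraction <= 1) or not (0 <= het_rate <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if snps_per_gene < 1:
        raise ValueError("snps_per_gene must be >= 1")
    if isinstance(lp_freqs, (int, float)):
        lp_freqs = {g: float(lp_freqs) for g in genes}
    if group_means is None:
        group_means = {g: {"LP": 0.5, "lp": 0.0} for g in genes}
    for g in genes:
        if g not in lp_freqs or g not in group_means:
            raise ValueError(f"gene {g} missing from lp_freqs or group_means")
        if not (0 <= lp_freqs[g] <= 1):
            raise ValueError(f"lp_freqs[{g}] outside [0, 1]")
    rng = np.random.default_rng(seed)

    patterns: dict[str, dict[str, np.ndarray]] = {}
    for g in genes:
        lp_pat = (rng.random(snps_per_gene) < 0.7).astype(np.int8) * 2
        if lp_pat.sum() == 0:
            lp_pat[rng.integers(snps_per_gene)] = 2
        lp_hap = lp_pat
        lp_pat0 = np.zeros(snps_per_gene, dtype=np.int8)
        het = np.where(lp_hap != lp_pat0, 1, 0).astype(np.int8)
        patterns[g] = {"LP": lp_pat0, "lp": lp_hap, "HET": het}

    accessions: list[PanelAccession] = []
    for i in range(n_accessions):
        genotypes: dict[str, np.ndarray] = {}
        truth: dict[str, str] = {}
        effect = 0.0
        for g in genes:
            if rng.random() < het_rate:
                state = "HET"
                effect += 0.5 * (group_means[g]["LP"] + group_means[g]["lp"])
            elif rng.random() < lp_freqs[g]:
                state = "lp"
                effect += group_means[g]["lp"]
            else:
                state = "LP"
                effect += group_means[g]["LP"]
            truth[g] = state
            genotypes[g] = patterns[g][state].copy()
        fuzzless = rng.random() < fuzzless_fraction
        lint = baseline_lint_pct + effect - (fuzzless_penalty if fuzzless else 0.0)
        if noise_sd > 0:
            lint += rng.normal(0.0, noise_sd)
        accessions.append(
            PanelAccession(
                id=f"acc{i + 1:04d}",
                fuzz_status="fuzzless" if fuzzless else "fuzzy",
                genotypes=genotypes,
                lint_pct=float(max(0.0, lint)),
                true_haplotypes=truth,
            )
        )
    return accessions
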