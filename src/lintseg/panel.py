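"""Diversity-panel haplotype analysis and favourable-allele pyramiding.

For each of the four lint%-associated genes, panel accessions are grouped by
their SNP pattern over the gene +/- 2 kb into two major homozygous haplotype
groups plus a heterozygous class; the group with the higher mean lint% is
labelled LP (favourable) and the other lp.  Haplotype-lint% association uses
the Mann-Whitney rank test; pyramiding counts LP alleles per accession
across the four genes and compares the observed 0..4 distribution with the
Binomial(4, 0.5) expectation (6.25 / 25 / 37.5 / 25 / 6.25 %).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MISSING = -1
EXACT_ENUMERATION_MAX_N = 12


@dataclass
class SnpFilterSpec:
    """Site-level quality filters applied before haplotype analysis."""

    min_maf: float = 0.05
    min_depth: int = 3
    max_depth: int = 50
    min_quality: float = 20.0
    max_missing_rate: float = 0.20

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if not (0 <= self.min_maf <= 1) or not (0 <= self.max_missing_rate <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass
class PanelAccession:
    """One panel member: per-gene SNP genotype codes, lint% and fuzz status.

    Genotype codes per SNP: 0/2 homozygous, 1 heterozygous, -1 missing.
    ``true_haplotypes`` is set only for synthetic accessions (generator truth).
    """

    id: str
    genotypes: dict[str, np.ndarray]
    lint_pct: float
    fuzz_status: str = "fuzzy"
    species: str = "G. hirsutum"
    true_haplotypes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.lint_pct < 0:
            raise ValueError("lint_pct must be >= 0")
        if self.fuzz_status not in ("fuzzy", "fuzzless"):
            raise ValueError("fuzz_status must be 'fuzzy' or 'fuzzless'")


@dataclass
class HaplotypeCall:
    accession_id: str
    gene: str
    call: str  # "LP" | "lp" | "HET"
    pattern: tuple[int, ...] | None = None


def filter_snps(site_table: pd.DataFrame, spec: SnpFilterSpec | None = None) -> pd.DataFrame:
    """Retain sites passing all four filters (MAF, depth range, quality, missingness)."""
    if spec is None:
        spec = SnpFilterSpec()
    if len(site_table) == 0:
        raise ValueError("empty site table")
    need = {"maf", "mean_depth", "quality", "missing_rate"}
    missing = need - set(site_table.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    keep = (
        (site_table["maf"] >= spec.min_maf)
        & (site_table["mean_depth"] >= spec.min_depth)
        & (site_table["mean_depth"] <= spec.max_depth)
        & (site_table["quality"] >= spec.min_quality)
        & (site_table["missing_rate"] <= spec.max_missing_rate)
    )
    return site_table[keep]


def mann_whitney(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for group1) and two-sided p.

    U is computed from midrank sums.  For n1+n2 <= 12 the two-sided p is the
    exact doubled tail over all rank assignments (a permutation null, so
    ties are handled exactly); otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    n = n1 + n2
    if n <= EXACT_ENUMERATION_MAX_N:
        us = np.array(
            [sum(ranks[list(c)]) - n1 * (n1 + 1) / 2 for c in itertools.combinations(range(n), n1)]
        )
        eps = 1e-9
        lower = np.mean(us <= u1 + eps)
        upper = np.mean(us >= u1 - eps)
        p = min(1.0, 2.0 * min(lower, upper))
        return u1, float(p)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return u1, p


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    both = (a != MISSING) & (b != MISSING)
    return int(np.sum(a[both] != b[both]))


def assign_haplotypes(
    panel: Sequence[PanelAccession],
    gene: str,
    het_threshold: float = 0.20,
) -> list[HaplotypeCall]:
    """Assign LP / lp / HET haplotype calls for one gene.

    Accessions heterozygous at more than ``het_threshold`` of the gene's
    polymorphic sites are HET.  Remaining accessions cluster by exact SNP
    pattern; the two largest pattern groups are the major haplotypes, with
    the higher-mean-lint% group labelled LP.  Minor patterns join the nearer
    major pattern by Hamming distance (ties become HET).  A gene with zero
    polymorphic sites yields no calls and a warning.
    """
    ids = [a.id for a in panel]
    G = np.stack([a.genotypes[gene] for a in panel]).astype(np.int64)
    lint = np.array([a.lint_pct for a in panel], dtype=float)
    poly = np.array(
        [len({int(v) for v in G[:, j] if v != MISSING}) >= 2 for j in range(G.shape[1])]
    )
    if not poly.any():
        warnings.warn(f"gene {gene}: no polymorphic SNP among accessions; no haplotype calls")
        return []
    P = G[:, poly]
    nonmiss = P != MISSING
    with np.errstate(invalid="ignore"):
        het_frac = np.where(
            nonmiss.sum(axis=1) > 0, (P == 1).sum(axis=1) / np.maximum(nonmiss.sum(axis=1), 1), 1.0
        )
    is_het = het_frac > het_threshold
    hom_idx = np.flatnonzero(~is_het)
    groups: dict[tuple[int, ...], list[int]] = {}
    for i in hom_idx:
        groups.setdefault(tuple(int(v) for v in P[i]), []).append(int(i))
    if len(groups) < 2:
        raise ValueError(f"gene {gene}: fewer than 2 distinct homozygous SNP patterns")
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    (pat_a, idx_a), (pat_b, idx_b) = ordered[0], ordered[1]
    mean_a, mean_b = lint[idx_a].mean(), lint[idx_b].mean()
    if mean_a >= mean_b:
        lp_pattern, hi_pattern = pat_b, pat_a
    else:
        lp_pattern, hi_pattern = pat_a, pat_b
    calls: list[HaplotypeCall] = []
    hi_arr, lp_arr = np.array(hi_pattern), np.array(lp_pattern)
    for i, acc_id in enumerate(ids):
        if is_het[i]:
            calls.append(HaplotypeCall(acc_id, gene, "HET", None))
            continue
        pat = tuple(int(v) for v in P[i])
        if pat == hi_pattern:
            calls.append(HaplotypeCall(acc_id, gene, "LP", pat))
        elif pat == lp_pattern:
            calls.append(HaplotypeCall(acc_id, gene, "lp", pat))
        else:
            d_hi = _hamming(P[i], hi_arr)
            d_lp = _hamming(P[i], lp_arr)
            if d_hi < d_lp:
                calls.append(HaplotypeCall(acc_id, gene, "LP", pat))
            elif d_lp < d_hi:
                calls.append(HaplotypeCall(acc_id, gene, "lp", pat))
            else:
                calls.append(HaplotypeCall(acc_id, gene, "HET", pat))
    return calls


def calls_by_accession(calls: Mapping[str, Sequence[HaplotypeCall]]) -> dict[str, dict[str, str]]:
    """Reindex {gene: [HaplotypeCall]} into {accession_id: {gene: call}}."""
    out: dict[str, dict[str, str]] = {}
    for gene, gene_calls in calls.items():
        for c in gene_calls:
            out.setdefault(c.accession_id, {})[gene] = c.call
    return out


def stratified_group_means(
    panel: Sequence[PanelAccession],
    calls: Mapping[str, Sequence[HaplotypeCall]],
) -> pd.DataFrame:
    """Mean lint% and accession share per (gene, fuzz stratum, haplotype).

    Shares are percentages of the called accessions within each
    (gene, stratum) cell row and sum to ~100 per row; empty strata yield NaN.
    """
    by_id = {a.id: a for a in panel}
    rows = []
    for gene, gene_calls in calls.items():
        df = pd.DataFrame(
            {
                "fuzz": [by_id[c.accession_id].fuzz_status for c in gene_calls],
                "hap": [c.call for c in gene_calls],
                "lint": [by_id[c.accession_id].lint_pct for c in gene_calls],
            }
        )
        for fuzz in ("fuzzless", "fuzzy"):
            sub = df[df["fuzz"] == fuzz]
            total = len(sub)
            row: dict = {"gene": gene, "fuzz_status": fuzz, "n": total}
            for hap in ("lp", "HET", "LP"):
                grp = sub[sub["hap"] == hap]
                row[f"mean_{hap}"] = grp["lint"].mean() if len(grp) else np.nan
                row[f"pct_{hap}"] = 100.0 * len(grp) / total if total else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


PYRAMIDING_POLICIES = ("count_het_as_non_LP", "exclude_het_accessions")


@dataclass
class PyramidingResult:
    table: pd.DataFrame  # index k = number of LP alleles
    pairwise_p: dict[tuple[int, int], float]
    het_policy: str
    n_analyzable: int


def pyramiding_analysis(
    panel: Sequence[PanelAccession],
    calls: Mapping[str, Sequence[HaplotypeCall]],
    het_policy: str = "count_het_as_non_LP",
) -> PyramidingResult:
    """LP-allele pyramiding across genes versus the binomial expectation.

    Accessions need a call at every gene; under ``exclude_het_accessions``
    any HET call drops the accession, under ``count_het_as_non_LP`` a HET
    locus simply does not count as LP.  Expected percentages are the
    Binomial(n_genes, 0.5) masses; observed percentages are computed on the
    analyzable accessions.  Mann-Whitney two-sided p-values compare lint%
    between every pair of non-empty k-groups.
    """
    if het_policy not in PYRAMIDING_POLICIES:
        raise ValueError(f"het_policy must be one of {PYRAMIDING_POLICIES}")
    genes = list(calls)
    by_acc = calls_by_accession(calls)
    lint_of = {a.id: a.lint_pct for a in panel}
    ks, lints = [], []
    for acc_id, gene_calls in by_acc.items():
        if acc_id not in lint_of or any(g not in gene_calls for g in genes):
            continue
        states = [gene_calls[g] for g in genes]
        if het_policy == "exclude_het_accessions" and "HET" in states:
            continue
        ks.append(sum(s == "LP" for s in states))
        lints.append(lint_of[acc_id])
    if not ks:
        raise ValueError("no analyzable accessions under this policy")
    ks_arr = np.array(ks)
    lint_arr = np.array(lints)
    n_genes = len(genes)
    rows = []
    for k in range(n_genes + 1):
        sel = lint_arr[ks_arr == k]
        rows.append(
            {
                "k": k,
                "n": int(sel.size),
                "observed_pct": 100.0 * sel.size / ks_arr.size,
                # exact Binomial(n_genes, 1/2) mass
                "expected_pct": 100.0 * math.comb(n_genes, k) / 2**n_genes,
                "mean_lint_pct": float(sel.mean()) if sel.size else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    pairwise: dict[tuple[int, int], float] = {}
    for k1 in range(n_genes + 1):
        for k2 in range(k1 + 1, n_genes + 1):
            g1 = lint_arr[ks_arr == k1]
            g2 = lint_arr[ks_arr == k2]
            if g1.size and g2.size:
                _, p = mann_whitney(g1, g2)
                pairwise[(k1, k2)] = p
    return PyramidingResult(
        table=table, pairwise_p=pairwise, het_policy=het_policy, n_analyzable=int(ks_arr.size)
    )
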