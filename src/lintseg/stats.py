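"""Genotype-class statistics: lint%, segregation chi-square, group means with
compact significance letters, and binned phenotype distribution tables.

Conventions follow the field's standard presentation of segregating
populations: per-marker genotype classes with sample sizes, mean lint%,
pairwise two-tailed t-tests summarised as compact letters (two classes share
a letter iff their difference is non-significant at ``alpha``), and lint%
distribution tables whose first column counts the exactly-zero (fiberless)
individuals followed by half-open (lo, hi] bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def lint_percent(lint_weight, seed_cotton_weight):
    """lint% = 100 x lint weight / unginned seed-cotton weight."""
    lw = np.asarray(lint_weight, dtype=float)
    sw = np.asarray(seed_cotton_weight, dtype=float)
    if np.any(sw <= 0):
        raise ValueError("seed_cotton_weight must be positive")
    if np.any(lw < 0):
        raise ValueError("lint_weight must be non-negative")
    if np.any(lw > sw):
        raise ValueError("lint_weight cannot exceed seed_cotton_weight")
    out = 100.0 * lw / sw
    return float(out) if out.ndim == 0 else out


@dataclass
class SegregationTest:
    observed: list[int]
    expected_ratio: list[float]
    chi2: float
    df: int
    p_value: float


def chi_square_segregation(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> SegregationTest:
    """Goodness-of-fit chi-square against a Mendelian ratio, no continuity correction.

    Expected counts are the ratio scaled to the observed total; the p-value
    is the upper tail of the chi-square distribution with k-1 df.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2 or obs.size != ratio.size:
        raise ValueError("need >= 2 categories and matching ratio length")
    if np.any(ratio <= 0):
        raise ValueError("expected ratio entries must be positive")
    if obs.sum() == 0:
        raise ValueError("observed counts are all zero")
    exp = ratio / ratio.sum() * obs.sum()
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return SegregationTest(
        observed=[int(o) for o in obs],
        expected_ratio=[float(r) for r in ratio],
        chi2=chi2,
        df=df,
        p_value=p,
    )


def bin_table(lint_pcts: Sequence[float], bin_edges: Sequence[float]) -> pd.Series:
    """Counts per lint% bin: {0}, (0, e1], (e1, e2], ..., plus an overflow bin."""
    x = np.asarray(lint_pcts, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0) or edges.size == 0 or edges[0] <= 0:
        raise ValueError("bin_edges must be positive and strictly increasing")
    if np.any(x < 0):
        raise ValueError("negative lint% value")
    labels = ["0"]
    counts = [int(np.sum(x == 0.0))]
    prev = 0.0
    for e in edges:
        labels.append(f"{prev:g}<x<={e:g}")
        counts.append(int(np.sum((x > prev) & (x <= e))))
        prev = e
    labels.append(f">{edges[-1]:g}")
    counts.append(int(np.sum(x > edges[-1])))
    return pd.Series(counts, index=labels, name="count")


def _pairwise_p(groups: list[np.ndarray], equal_var: bool) -> np.ndarray:
    """Two-tailed two-sample t-test p-values; identical degenerate samples -> p=1."""
    k = len(groups)
    p = np.ones((k, k))
    import warnings

    for i in range(k):
        for j in range(i + 1, k):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            pij = float(res.pvalue)
            if np.isnan(pij):
                # zero variance in both samples: identical constants are
                # indistinguishable (p=1), different constants are disjoint (p=0)
                pij = 1.0 if np.mean(groups[i]) == np.mean(groups[j]) else 0.0
            p[i, j] = p[j, i] = pij
    return p


def letter_display(means: Sequence[float], pmat: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Compact letter display via insert-and-absorb.

    Two classes share at least one letter iff their pairwise p >= alpha.
    Letters are named in ascending-mean order ('a' on the lowest-mean group).
    """
    k = len(means)
    if k == 0:
        return []
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if pmat[i, j] < alpha:
                for s in [s for s in sets if i in s and j in s]:
                    sets.remove(s)
                    for new in (s - {i}, s - {j}):
                        if new and not any(new <= other for other in sets):
                            sets.append(new)
                    sets = [a for a in sets if not any(a < b for b in sets if b is not a)]
    order = np.argsort(np.asarray(means, dtype=float), kind="stable")
    rank = {int(c): r for r, c in enumerate(order)}
    sets.sort(key=lambda s: min(rank[c] for c in s))
    letters = [""] * k
    for li, s in enumerate(sets):
        ch = chr(ord("a") + li)
        for c in s:
            letters[c] += ch
    return ["".join(sorted(l)) for l in letters]


@dataclass
class ClassSummary:
    label: str
    n: int
    mean_lint_pct: float
    letter: str | None
    too_small: bool = False


@dataclass
class GenotypeClassSummary:
    marker_id: str
    classes: list[ClassSummary]
    bins: pd.DataFrame | None = None
    alpha: float = 0.05
    pairwise_p: pd.DataFrame | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "class": [c.label for c in self.classes],
                "n": [c.n for c in self.classes],
                "mean_lint_pct": [c.mean_lint_pct for c in self.classes],
                "letter": [c.letter if c.letter is not None else "" for c in self.classes],
            }
        )
        if self.bins is not None:
            bdf = self.bins.reset_index().rename(columns={"index": "class"})
            df = bdf.merge(df, on="class")
        return df


def genotype_class_summary(
    genotypes: Sequence[str],
    lint_pcts: Sequence[float],
    bin_edges: Sequence[float] | None = None,
    alpha: float = 0.05,
    equal_var: bool = False,
    marker_id: str = "",
) -> GenotypeClassSummary:
    """Per-genotype-class n, mean lint%, significance letters and bin counts.

    Classes with n < 2 are reported with their mean but no letter (flagged)
    and are excluded from pairwise testing.  The default t-test is Welch
    (unequal variances); set ``equal_var=True`` for pooled variances.
    """
    geno = pd.Series(genotypes)
    lint = np.asarray(lint_pcts, dtype=float)
    if len(geno) != lint.size:
        raise ValueError("genotype and lint% vectors must have equal length")
    keep = geno.notna().to_numpy()
    geno, lint = geno[keep].reset_index(drop=True), lint[keep]
    if len(geno) == 0:
        raise ValueError("no non-missing genotype classes")
    labels = list(dict.fromkeys(geno))
    groups = {lab: lint[(geno == lab).to_numpy()] for lab in labels}
    testable = [lab for lab in labels if groups[lab].size >= 2]
    tested = [groups[lab] for lab in testable]
    if testable:
        pmat = _pairwise_p(tested, equal_var=equal_var)
        letters = letter_display([g.mean() for g in tested], pmat, alpha=alpha)
    else:
        pmat, letters = np.ones((0, 0)), []
    letter_of = dict(zip(testable, letters))
    classes = [
        ClassSummary(
            label=lab,
            n=int(groups[lab].size),
            mean_lint_pct=float(groups[lab].mean()),
            letter=letter_of.get(lab),
            too_small=groups[lab].size < 2,
        )
        for lab in labels
    ]
    bins = None
    if bin_edges is not None:
        bins = pd.DataFrame({lab: bin_table(groups[lab], bin_edges) for lab in labels}).T
    pdf = pd.DataFrame(pmat, index=testable, columns=testable) if testable else None
    return GenotypeClassSummary(
        marker_id=marker_id, classes=classes, bins=bins, alpha=alpha, pairwise_p=pdf
    )
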