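"""Bulk-segregant allele-frequency scanning.

Two DNA bulks are formed from phenotypically extreme segregants, per-SNP
alternate-allele frequencies are computed from pooled read counts, smoothed
in overlapping sliding windows, and candidate trait-associated regions are
called with a two-pool frequency rule: a window is a candidate iff one
pool's mean frequency exceeds ``high_threshold`` (default 0.8) while the
other pool's sits in a band around 0.5 (default [0.35, 0.65]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps_pool1", "n_snps_pool2", "n_snps",
    "mean_freq_pool1", "mean_freq_pool2", "ok",
]
REGION_COLUMNS = ["chrom", "start", "end", "extreme_pool", "peak_freq", "n_windows"]


@dataclass
class PoolCounts:
    """Per-SNP biallelic read counts for one sequenced DNA bulk."""

    pool_id: str
    records: pd.DataFrame  # columns chrom, pos, ref_count, alt_count

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "ref_count", "alt_count"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"PoolCounts records missing columns {sorted(missing)}")
        rec = self.records.copy()
        if (rec["ref_count"] < 0).any() or (rec["alt_count"] < 0).any():
            raise ValueError("negative read counts")
        rec = rec.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.records = rec


def select_pools(
    population,
    low_rule: tuple[str, float | None],
    high_rule: tuple[str, float | None],
    n_per_pool: int | None = None,
):
    """Select the low- and high-lint% bulks from a population.

    Rules are ``(mode, value)`` with mode one of ``threshold`` (lint% below /
    above ``value``), ``rank`` (the ``n_per_pool`` most extreme) or
    ``fiberless`` (lint% == 0 exactly; low pool only).  With ``n_per_pool``
    set, the most extreme qualifying individuals are taken; ties are broken
    by pedigree tag so selection is stable.  Pools are disjoint.
    """

    def qualifying(inds, rule, side):
        mode, value = rule
        if mode == "fiberless":
            sel = [i for i in inds if i.lint_pct == 0.0]
        elif mode == "threshold":
            if value is None:
                raise ValueError("threshold rule needs a value")
            if side == "low":
                sel = [i for i in inds if i.lint_pct < value]
            else:
                sel = [i for i in inds if i.lint_pct > value]
        elif mode == "rank":
            if n_per_pool is None:
                raise ValueError("rank rule needs n_per_pool")
            sel = list(inds)
        else:
            raise ValueError(f"unknown pool rule mode {mode!r}")
        if side == "low":
            sel.sort(key=lambda i: (i.lint_pct, i.pedigree_tag))
        else:
            sel.sort(key=lambda i: (-i.lint_pct, i.pedigree_tag))
        return sel

    inds = population.individuals if hasattr(population, "individuals") else list(population)
    low_q = qualifying(inds, low_rule, "low")
    if n_per_pool is not None:
        if len(low_q) < n_per_pool:
            raise ValueError(
                f"low pool: only {len(low_q)} qualifying individuals, need {n_per_pool}"
            )
        low = low_q[:n_per_pool]
    else:
        low = low_q
    taken = set(id(i) for i in low)
    rest = [i for i in inds if id(i) not in taken]
    high_q = qualifying(rest, high_rule, "high")
    if n_per_pool is not None:
        if len(high_q) < n_per_pool:
            raise ValueError(
                f"high pool: only {len(high_q)} qualifying individuals, need {n_per_pool}"
            )
        high = high_q[:n_per_pool]
    else:
        high = high_q
    if not low:
        raise ValueError("low pool: no qualifying individuals")
    if not high:
        raise ValueError("high pool: no qualifying individuals")
    return low, high


def pool_frequency(counts: PoolCounts, min_depth: int = 1) -> pd.DataFrame:
    """Per-SNP alternate-allele frequency table, dropping SNPs below ``min_depth``."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    rec = counts.records
    depth = rec["ref_count"] + rec["alt_count"]
    keep = depth >= min_depth
    if not keep.any():
        raise ValueError(f"pool {counts.pool_id}: zero SNPs retained at min_depth={min_depth}")
    out = pd.DataFrame(
        {
            "chrom": rec.loc[keep, "chrom"].to_numpy(),
            "pos": rec.loc[keep, "pos"].to_numpy(),
            "freq": (rec.loc[keep, "alt_count"] / depth[keep]).to_numpy(),
            "depth": depth[keep].to_numpy(),
        }
    )
    return out


def window_starts(length_bp: int, window_bp: int, step_bp: int) -> list[int]:
    """1-based start positions tiling a chromosome with overlapping windows.

    Full windows start at 1, 1+step, ...; if the last full window ends short
    of the chromosome end, one final truncated window is appended.
    """
    starts = []
    s = 1
    while s + window_bp - 1 <= length_bp:
        starts.append(s)
        s += step_bp
    if not starts:
        return [1]
    if starts[-1] + window_bp - 1 < length_bp:
        starts.append(starts[-1] + step_bp)
    return starts


def windowed_frequencies(
    freqs_pool1: pd.DataFrame,
    freqs_pool2: pd.DataFrame,
    window_bp: int,
    step_bp: int,
    min_snps_per_window: int = 10,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Unweighted mean pool frequencies in overlapping windows.

    Windows with fewer than ``min_snps_per_window`` SNPs in either pool are
    emitted with ``ok=False`` and are excluded from candidate calling.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if step_bp > window_bp or step_bp <= 0:
        raise ValueError("step_bp must be in (0, window_bp] (windows must overlap or tile)")
    if min_snps_per_window < 1:
        raise ValueError("min_snps_per_window must be >= 1")
    chroms = sorted(set(freqs_pool1["chrom"]) | set(freqs_pool2["chrom"]))
    rows = []
    for chrom in chroms:
        f1 = freqs_pool1[freqs_pool1["chrom"] == chrom].sort_values("pos")
        f2 = freqs_pool2[freqs_pool2["chrom"] == chrom].sort_values("pos")
        if chrom_lengths is not None and chrom in chrom_lengths:
            length = int(chrom_lengths[chrom])
        else:
            length = int(max(f1["pos"].max() if len(f1) else 1, f2["pos"].max() if len(f2) else 1))
        pos1 = f1["pos"].to_numpy()
        pos2 = f2["pos"].to_numpy()
        cum1 = np.concatenate([[0.0], np.cumsum(f1["freq"].to_numpy())])
        cum2 = np.concatenate([[0.0], np.cumsum(f2["freq"].to_numpy())])
        for s in window_starts(length, window_bp, step_bp):
            e = min(s + window_bp - 1, length)
            a1, b1 = np.searchsorted(pos1, [s, e + 1])
            a2, b2 = np.searchsorted(pos2, [s, e + 1])
            n1, n2 = int(b1 - a1), int(b2 - a2)
            m1 = (cum1[b1] - cum1[a1]) / n1 if n1 else np.nan
            m2 = (cum2[b2] - cum2[a2]) / n2 if n2 else np.nan
            rows.append(
                (chrom, s, e, n1, n2, min(n1, n2), m1, m2,
                 n1 >= min_snps_per_window and n2 >= min_snps_per_window)
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def call_candidates(
    windows: pd.DataFrame,
    high_threshold: float = 0.8,
    mid_band: tuple[float, float] = (0.35, 0.65),
) -> pd.DataFrame:
    """Call candidate regions from windowed pool frequencies.

    A window is a candidate iff one pool's mean exceeds ``high_threshold``
    while the other pool's lies inside ``mid_band``; maximal runs of
    consecutive candidate windows with the same extreme pool merge into one
    region.  Regions are sorted by chromosome and start.
    """
    lo, hi = mid_band
    if not (0 <= lo < hi <= high_threshold <= 1):
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= high_threshold <= 1")
    if len(windows) == 0:
        raise ValueError("empty window list")
    w = windows.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    m1 = w["mean_freq_pool1"].to_numpy(dtype=float)
    m2 = w["mean_freq_pool2"].to_numpy(dtype=float)
    ok = w["ok"].to_numpy(dtype=bool) & np.isfinite(m1) & np.isfinite(m2)
    cand1 = ok & (m1 > high_threshold) & (m2 >= lo) & (m2 <= hi)
    cand2 = ok & (m2 > high_threshold) & (m1 >= lo) & (m1 <= hi)
    extreme = np.where(cand1, 1, np.where(cand2, 2, 0))
    regions = []
    run: dict | None = None
    for i in range(len(w)):
        if extreme[i] == 0:
            if run is not None:
                regions.append(run)
                run = None
            continue
        peak = m1[i] if extreme[i] == 1 else m2[i]
        row = w.iloc[i]
        if (
            run is not None
            and run["chrom"] == row["chrom"]
            and run["extreme_pool"] == extreme[i]
            and run["last_index"] == i - 1
        ):
            run["end"] = max(run["end"], int(row["end"]))
            run["peak_freq"] = max(run["peak_freq"], peak)
            run["n_windows"] += 1
            run["last_index"] = i
        else:
            if run is not None:
                regions.append(run)
            run = {
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "extreme_pool": int(extreme[i]),
                "peak_freq": float(peak),
                "n_windows": 1,
                "last_index": i,
            }
    if run is not None:
        regions.append(run)
    out = pd.DataFrame(regions, columns=REGION_COLUMNS + ["last_index"]) if regions else pd.DataFrame(
        columns=REGION_COLUMNS + ["last_index"]
    )
    out = out.drop(columns=["last_index"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def top_region(regions: pd.DataFrame) -> pd.Series | None:
    """The strongest candidate region (highest peak frequency, then widest)."""
    if len(regions) == 0:
        return None
    order = regions.sort_values(["peak_freq", "n_windows"], ascending=False, kind="stable")
    return order.iloc[0]


def plot_scan(
    windows: pd.DataFrame,
    path: str,
    regions: pd.DataFrame | None = None,
    pool_labels: tuple[str, str] = ("low pool", "high pool"),
) -> None:
    """Per-chromosome windowed pool-frequency tracks with candidate regions shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(windows["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        w = windows[windows["chrom"] == chrom]
        mid = (w["start"] + w["end"]) / 2e6
        ax.plot(mid, w["mean_freq_pool1"], lw=1, label=pool_labels[0])
        ax.plot(mid, w["mean_freq_pool2"], lw=1, label=pool_labels[1])
        if regions is not None:
            for _, r in regions[regions["chrom"] == chrom].iterrows():
                ax.axvspan(r["start"] / 1e6, r["end"] / 1e6, color="0.85")
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("SNP freq")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mbp)")
    axes[0, 0].legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
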