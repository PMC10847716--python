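"""Readers and writers for the pipeline's plain-text artifacts.

Coordinates are 1-based inclusive internally (the VCF convention); BED-like
outputs are converted to 0-based half-open at the boundary.  Pooled counts
travel either as a 5-column TSV (chrom, pos, pool, ref_count, alt_count) or
as a minimal two-sample VCF whose AD FORMAT field carries ref,alt depths.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bsa import PoolCounts
from .panel import MISSING, PanelAccession


def write_population_tsv(population, path) -> None:
    population.to_dataframe().to_csv(path, sep="\t", index=False)


def read_population_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pool_counts_tsv(pools: Sequence[PoolCounts], path) -> None:
    frames = []
    for p in pools:
        df = p.records.copy()
        df.insert(2, "pool", p.pool_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pool_counts_tsv(path) -> list[PoolCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        PoolCounts(pool_id=str(pool), records=sub.drop(columns="pool").reset_index(drop=True))
        for pool, sub in df.groupby("pool", sort=False)
    ]


def write_pool_vcf(
    path,
    pool1: PoolCounts,
    pool2: PoolCounts,
    sample_names: tuple[str, str] = ("low", "high"),
    ref_base: str = "A",
    alt_base: str = "T",
) -> None:
    """Minimal biallelic VCF with per-pool AD depths.

    Both pools must cover the same (chrom, pos) set; the REF/ALT bases are
    placeholders (counts, not sequence, are the payload).
    """
    r1 = pool1.records.set_index(["chrom", "pos"])
    r2 = pool2.records.set_index(["chrom", "pos"])
    if not r1.index.equals(r2.index):
        raise ValueError("pools must cover identical SNP sets for VCF export")
    chroms = list(dict.fromkeys(c for c, _ in r1.index))
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for c in chroms:
        max_pos = int(max(p for cc, p in r1.index if cc == c))
        lines.append(f"##contig=<ID={c},length={max_pos + 1}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )
    for (chrom, pos) in r1.index:
        a1 = r1.loc[(chrom, pos)]
        a2 = r2.loc[(chrom, pos)]
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\tAD\t"
            f"{int(a1.ref_count)},{int(a1.alt_count)}\t{int(a2.ref_count)},{int(a2.alt_count)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pool_vcf(path, pool_sample_names: tuple[str, str]) -> tuple[PoolCounts, PoolCounts]:
    """Load two pools' AD counts from a VCF; multiallelic/indel records are
    skipped with a counted warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in pool_sample_names:
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF (has {samples})")
    idx = [samples.index(n) for n in pool_sample_names]
    rows1, rows2 = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks AD depths")
        for rows, i in zip((rows1, rows2), idx):
            ref, alt = int(ad[i][0]), int(ad[i][1])
            rows.append((v.CHROM, v.POS, max(ref, 0), max(alt, 0)))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/indel record(s)")
    if not rows1:
        raise ValueError("no usable biallelic SNP records in VCF")
    cols = ["chrom", "pos", "ref_count", "alt_count"]
    return (
        PoolCounts(pool_sample_names[0], pd.DataFrame(rows1, columns=cols)),
        PoolCounts(pool_sample_names[1], pd.DataFrame(rows2, columns=cols)),
    )


def read_panel_vcf(
    vcf_path,
    genes: Sequence[tuple[str, str, int, int]],
    phenotypes: pd.DataFrame,
    flank_bp: int = 2000,
) -> list[PanelAccession]:
    """Build panel accessions from a multi-sample VCF plus a phenotype table.

    ``genes`` are ``(name, chrom, start, end)`` gene bodies (1-based
    inclusive); SNPs within each gene +/- ``flank_bp`` are collected.
    ``phenotypes`` needs columns ``id``, ``lint_pct`` and optionally
    ``fuzz_status``.  Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt),
    -1 (missing); multiallelic/indel records are skipped with a counted
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    codes: dict[str, list[np.ndarray]] = {name: [] for name, *_ in genes}
    intervals = [(name, chrom, max(1, start - flank_bp), end + flank_bp) for name, chrom, start, end in genes]
    n_skipped = 0
    # cyvcf2 region queries need an index; plain-text VCFs are scanned linearly
    for v in vcf:
        hits = [name for name, chrom, lo, hi in intervals if v.CHROM == chrom and lo <= v.POS <= hi]
        if not hits:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(v.gt_types)
        code = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
        for name in hits:
            codes[name].append(code)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/indel record(s)")
    pheno = phenotypes.set_index(phenotypes["id"].astype(str))
    panel = []
    for i, sample in enumerate(samples):
        if sample not in pheno.index:
            raise ValueError(f"sample {sample!r} missing from the phenotype table")
        row = pheno.loc[sample]
        genotypes = {
            name: (np.array([site[i] for site in sites], dtype=np.int8) if sites else np.empty(0, dtype=np.int8))
            for name, sites in codes.items()
        }
        panel.append(
            PanelAccession(
                id=sample,
                genotypes=genotypes,
                lint_pct=float(row["lint_pct"]),
                fuzz_status=str(row.get("fuzz_status", "fuzzy")),
            )
        )
    return panel


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    out = windows.copy()
    out["start"] = out["start"] - 1  # BED-like: 0-based half-open
    out.to_csv(path, sep="\t", index=False)


def write_regions_tsv(regions: pd.DataFrame, path) -> None:
    out = regions.copy()
    if len(out):
        out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", index=False)


def write_panel_tsv(panel: Sequence[PanelAccession], path) -> None:
    rows = []
    for a in panel:
        row = {
            "id": a.id,
            "species": a.species,
            "fuzz_status": a.fuzz_status,
            "lint_pct": a.lint_pct,
        }
        for gene, codes in a.genotypes.items():
            row[f"geno_{gene}"] = ",".join(str(int(c)) for c in codes)
            if a.true_haplotypes is not None:
                row[f"true_{gene}"] = a.true_haplotypes[gene]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> list[PanelAccession]:
    df = pd.read_csv(path, sep="\t")
    geno_cols = [c for c in df.columns if c.startswith("geno_")]
    true_cols = [c for c in df.columns if c.startswith("true_")]
    panel = []
    for _, row in df.iterrows():
        genotypes = {
            c[len("geno_"):]: np.array([int(v) for v in str(row[c]).split(",")], dtype=np.int8)
            for c in geno_cols
        }
        truth = {c[len("true_"):]: row[c] for c in true_cols} if true_cols else None
        panel.append(
            PanelAccession(
                id=str(row["id"]),
                species=str(row["species"]),
                fuzz_status=str(row["fuzz_status"]),
                lint_pct=float(row["lint_pct"]),
                genotypes=genotypes,
                true_haplotypes=truth,
            )
        )
    return panel
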