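"""Pipeline driver: simulate -> bsa -> genostats -> panel, with a manifest.

All randomness flows from ``root_seed`` through named per-stage child
streams; re-running an identical config reproduces byte-identical TSV
outputs, which the manifest records with SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bsa, io, panel as panel_mod, presets, stats
from .simulate import simulate_panel, simulate_pool_counts

STAGES = ("simulate", "bsa", "genostats", "panel")


@dataclass
class RunConfig:
    root_seed: int = 0
    output_dir: str = "lintseg_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "root_seed": self.root_seed,
            "output_dir": self.output_dir,
            "stages": list(self.stages),
            "simulation": dict(self.simulation),
            "scan": dict(self.scan),
            "stats": dict(self.stats),
            "panel": dict(self.panel),
        }


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    manifest: dict = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "root_seed": config.root_seed,
        "stages": {},
    }
    files: dict[str, Path] = {}

    sim = config.simulation
    design = sim.get("design", "ST_F2")
    gmap = presets.default_map(sim.get("recomb_rate_cM_per_Mbp", 1.0))

    population = None
    pools = None
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            if stage == "simulate":
                seed = _stage_seed(config.root_seed, "simulate")
                if design == "ST_F2":
                    model = presets.st_f2_effect_model(sim.get("noise_sd", 2.0))
                elif design == "SS_F2":
                    from .scenarios import detection_effect_model

                    model = detection_effect_model(sim.get("noise_sd", 2.0))
                else:
                    model = presets.default_effect_model(sim.get("noise_sd", 2.0))
                population = presets.design_population(design, seed, model=model, gmap=gmap)
                io.write_population_tsv(population, out / "population.tsv")
                files["population.tsv"] = out / "population.tsv"
                low_rule = tuple(sim.get("low_rule", ("rank", None)))
                high_rule = tuple(sim.get("high_rule", ("rank", None)))
                n_per_pool = sim.get("n_per_pool", 19)
                # bulks are drawn among fuzzless segregants by default (the
                # study's design; for crosses fixed fuzzless this is everyone)
                source = population.individuals
                if sim.get("pools_from_fuzzless", True):
                    fuzzless = [i for i in source if i.fuzzless]
                    if len(fuzzless) >= 2 * (n_per_pool or 1):
                        source = fuzzless
                low, high = bsa.select_pools(source, low_rule, high_rule, n_per_pool)
                rng = np.random.default_rng(_stage_seed(config.root_seed, "pools"))
                depth = sim.get("mean_depth", 25.0)
                pools = (
                    simulate_pool_counts(low, gmap, depth, rng, pool_id="low"),
                    simulate_pool_counts(high, gmap, depth, rng, pool_id="high"),
                )
                io.write_pool_counts_tsv(pools, out / "pool_counts.tsv")
                io.write_pool_vcf(out / "pool_counts.vcf", *pools)
                files["pool_counts.tsv"] = out / "pool_counts.tsv"
                files["pool_counts.vcf"] = out / "pool_counts.vcf"
                manifest["stages"]["simulate"] = {"seed": seed, "design": design}
            elif stage == "bsa":
                if pools is None:
                    loaded = io.read_pool_counts_tsv(out / "pool_counts.tsv")
                    pools = (loaded[0], loaded[1])
                scan = config.scan
                f1 = bsa.pool_frequency(pools[0], scan.get("min_depth", 1))
                f2 = bsa.pool_frequency(pools[1], scan.get("min_depth", 1))
                windows = bsa.windowed_frequencies(
                    f1,
                    f2,
                    scan.get("window_bp", 1_000_000),
                    scan.get("step_bp", 500_000),
                    scan.get("min_snps_per_window", 10),
                    chrom_lengths=dict(gmap.chromosomes),
                )
                regions = bsa.call_candidates(
                    windows,
                    scan.get("high_threshold", 0.8),
                    tuple(scan.get("mid_band", (0.35, 0.65))),
                )
                io.write_windows_tsv(windows, out / "windows.tsv")
                io.write_regions_tsv(regions, out / "regions.tsv")
                bsa.plot_scan(windows, out / "scan.png", regions)
                files["windows.tsv"] = out / "windows.tsv"
                files["regions.tsv"] = out / "regions.tsv"
                manifest["stages"]["bsa"] = {"n_windows": int(len(windows)), "n_regions": int(len(regions))}
            elif stage == "genostats":
                df = io.read_population_tsv(out / "population.tsv")
                st = config.stats
                edges = st.get("bin_edges", [5, 10, 15, 20, 25, 30])
                tables = []
                locus_cols = [c for c in df.columns if c in presets.LOCUS_CHROMS]
                for locus in locus_cols:
                    if df[locus].nunique() < 2:
                        continue
                    labels = df[locus].map({0: f"{locus}:func/func", 1: f"{locus}:func/lof", 2: f"{locus}:lof/lof"})
                    summ = stats.genotype_class_summary(
                        labels, df["lint_pct"], bin_edges=edges,
                        alpha=st.get("alpha", 0.05), marker_id=locus,
                    )
                    tables.append(summ.to_dataframe())
                if tables:
                    import pandas as pd

                    pd.concat(tables, ignore_index=True).to_csv(
                        out / "genotype_stats.tsv", sep="\t", index=False
                    )
                    files["genotype_stats.tsv"] = out / "genotype_stats.tsv"
                fuzz = df["fuzzless"].sum(), (1 - df["fuzzless"]).sum()
                seg = stats.chi_square_segregation(list(fuzz), config.stats.get("ratio", [3, 1]))
                (out / "segregation.json").write_text(
                    json.dumps({"observed": seg.observed, "chi2": seg.chi2, "p": seg.p_value}, indent=1)
                )
                files["segregation.json"] = out / "segregation.json"
                manifest["stages"]["genostats"] = {"n_tables": len(tables)}
            elif stage == "panel":
                pcfg = config.panel
                seed = _stage_seed(config.root_seed, "panel")
                genes = pcfg.get("genes", list(presets.LOCUS_CHROMS))
                accessions = simulate_panel(
                    n_accessions=pcfg.get("n_accessions", 723),
                    genes=genes,
                    lp_freqs=pcfg.get("lp_freqs", 0.5),
                    noise_sd=pcfg.get("noise_sd", 4.0),
                    het_rate=pcfg.get("het_rate", 0.07),
                    seed=seed,
                )
                io.write_panel_tsv(accessions, out / "panel.tsv")
                files["panel.tsv"] = out / "panel.tsv"
                calls = {g: panel_mod.assign_haplotypes(accessions, g) for g in genes}
                strat = panel_mod.stratified_group_means(accessions, calls)
                strat.to_csv(out / "haplotype_group_means.tsv", sep="\t", index=False)
                files["haplotype_group_means.tsv"] = out / "haplotype_group_means.tsv"
                fuzzy = [a for a in accessions if a.fuzz_status == "fuzzy"]
                fuzzy_ids = {a.id for a in fuzzy}
                fuzzy_calls = {
                    g: [c for c in cs if c.accession_id in fuzzy_ids] for g, cs in calls.items()
                }
                pyr = panel_mod.pyramiding_analysis(
                    fuzzy, fuzzy_calls, pcfg.get("het_policy", "count_het_as_non_LP")
                )
                pyr.table.to_csv(out / "pyramiding.tsv", sep="\t")
                files["pyramiding.tsv"] = out / "pyramiding.tsv"
                manifest["stages"]["panel"] = {
                    "seed": seed,
                    "n_analyzable": pyr.n_analyzable,
                }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["files"] = {
        name: _sha256(p) for name, p in sorted(files.items()) if p.suffix != ".png"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
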