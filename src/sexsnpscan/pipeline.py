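"""End-to-end pipeline: sync -> site stats -> window track -> block ->
effect and expression summaries, with a single JSON summary.

The configuration carries every threshold the scan uses; defaults are the
settings of the pooled XY design this package targets (intermediate range
0.3-0.7, fixed range <=0.1 / >=0.9, coverage >=10 in each pool, 10 kb
windows).  Every run logs its seed, thresholds, and a hash of the resolved
configuration so outputs can be traced to settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .diffstats import SiteStat, fisher_exact_2x2, site_fst, window_mean
from .effects import read_effects, summarize_effects
from .expression import enrichment_report, read_expression
from .pool_io import read_sync, site_frequencies
from .regions import (
    GenomicRegion,
    call_block,
    summarize_region,
    window_count_summary,
    write_bed,
)
from .sexsnp import Thresholds, classify_site, window_scan, windows_to_frame, write_igv_track

logger = logging.getLogger("sexsnpscan")

__all__ = ["PipelineConfig", "run_pipeline", "scan_frequencies"]


@dataclass
class PipelineConfig:
    sync: Optional[str] = None
    effects: Optional[str] = None
    expression: Optional[str] = None
    outdir: str = "results/pipeline"
    pool_order: tuple[str, str] = ("male", "female")
    polarity: str = "xy"
    intermediate: tuple[float, float] = (0.3, 0.7)
    fixed_low: float = 0.1
    fixed_high: float = 0.9
    min_cov: int = 10
    window_bp: int = 10_000
    count_threshold: int = 5
    min_run_windows: int = 50
    max_gap_windows: int = 20
    chrom_lengths: Optional[dict[str, int]] = None  # None: inferred from sync
    genome_length_bp: Optional[int] = None  # None: sum of chrom_lengths
    min_fpkm: float = 0.05
    background: str = "genomewide"
    compute_fisher: bool = True
    seed: int = 0

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(
            intermediate=tuple(self.intermediate),
            fixed_low=self.fixed_low,
            fixed_high=self.fixed_high,
            min_cov=self.min_cov,
            polarity=self.polarity,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pool_order" in raw:
            raw["pool_order"] = tuple(raw["pool_order"])
        if "intermediate" in raw:
            raw["intermediate"] = tuple(raw["intermediate"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def scan_frequencies(cfg: PipelineConfig):
    """Stream the sync file into per-site frequency records."""
    for rec in read_sync(cfg.sync, pool_order=cfg.pool_order):
        freqs = site_frequencies(rec)
        if freqs.ok:
            yield rec, freqs


def _infer_chrom_lengths(freq_rows: pd.DataFrame, window_bp: int) -> dict[str, int]:
    out = {}
    for chrom, grp in freq_rows.groupby("chrom", sort=True):
        max_pos = int(grp["pos"].max())
        out[chrom] = ((max_pos + window_bp - 1) // window_bp) * window_bp
    return out


def run_pipeline(cfg: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute every stage and return the JSON summary (also written to
    ``outdir/summary.json``).  Raises ``FileNotFoundError`` for missing
    inputs; any stage error propagates with the stage named."""
    for name in ("sync", "effects", "expression"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {name} path {p!r}")
    if cfg.sync is None:
        raise ValueError("a sync input is required")
    logger.info(
        "pipeline start: version=%s seed=%d config_hash=%s", __version__, cfg.seed, cfg.config_hash()
    )
    logger.info(
        "thresholds: intermediate=%s fixed=(<=%s, >=%s) min_cov=%d window=%d bp polarity=%s",
        cfg.intermediate, cfg.fixed_low, cfg.fixed_high, cfg.min_cov, cfg.window_bp, cfg.polarity,
    )
    if dry_run:
        return {"dry_run": True, "config_hash": cfg.config_hash()}

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = cfg.thresholds

    # stage: scan (per-site stats + classification)
    site_rows, stat_objs, snps, eligible = [], [], [], []
    for rec, freqs in scan_frequencies(cfg):
        fst = site_fst(freqs)
        fisher_p = None
        if cfg.compute_fisher:
            n_major_m = rec.counts_male[
                {"A": 0, "T": 1, "C": 2, "G": 3}[freqs.major_allele]
            ]
            n_major_f = rec.counts_female[
                {"A": 0, "T": 1, "C": 2, "G": 3}[freqs.major_allele]
            ]
            if freqs.cov_male > 0 and freqs.cov_female > 0:
                fisher_p = fisher_exact_2x2(
                    n_major_m, freqs.n_minor_male, n_major_f, freqs.n_minor_female
                )
        stat = SiteStat(freqs.chrom, freqs.pos, fst, fisher_p)
        stat_objs.append(stat)
        site_rows.append(
            (
                freqs.chrom, freqs.pos, freqs.f_male, freqs.f_female,
                freqs.cov_male, freqs.cov_female, fst, fisher_p, stat.neg_log10_p,
            )
        )
        if freqs.cov_male >= cfg.min_cov and freqs.cov_female >= cfg.min_cov:
            eligible.append((freqs.chrom, freqs.pos))
        snp = classify_site(freqs, thresholds)
        if snp is not None:
            snps.append(snp)
    sites_df = pd.DataFrame(
        site_rows,
        columns=[
            "chrom", "pos", "f_male", "f_female", "cov_male", "cov_female",
            "fst", "fisher_p", "neg_log10_p",
        ],
    )
    sites_df.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    window_mean(stat_objs, cfg.window_bp).to_csv(
        outdir / "fst_windows.tsv", sep="\t", index=False
    )

    chrom_lengths = cfg.chrom_lengths or _infer_chrom_lengths(sites_df, cfg.window_bp)
    genome_length = cfg.genome_length_bp or sum(chrom_lengths.values())
    windows = window_scan(snps, eligible, chrom_lengths, cfg.window_bp)
    windows_to_frame(windows).to_csv(outdir / "sexsnp_windows.tsv", sep="\t", index=False)
    write_igv_track(windows, outdir / "sexsnp_windows.igv", feature="sex_snp_density")
    logger.info("scan: %d sites, %d qualifying sex-pattern SNPs", len(sites_df), len(snps))

    # stage: block calling
    regions = call_block(
        windows, cfg.count_threshold, cfg.min_run_windows, cfg.max_gap_windows
    )
    write_bed(regions, outdir / "regions.bed")
    block: Optional[GenomicRegion] = max(regions, key=lambda r: r.length_bp) if regions else None
    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_sites": int(len(sites_df)),
        "n_sex_snps": len(snps),
        "mean_fst_polymorphic": float(sites_df["fst"].dropna().mean())
        if sites_df["fst"].notna().any()
        else None,
        "n_regions_called": len(regions),
        "block": None,
        "effects": None,
        "expression": None,
    }
    if block is not None:
        reg = summarize_region(windows, block, genome_length)
        wsum = window_count_summary(windows, block, top_k=300)
        summary["block"] = {
            "chrom": block.chrom,
            "start_bp": block.start_bp,
            "end_bp": block.end_bp,
            "length_mb": block.length_mb,
            "n_snps_inside": reg.n_snps_inside,
            "n_snps_outside": reg.n_snps_outside,
            "density_inside_per_mb": reg.density_inside,
            "density_outside_per_mb": reg.density_outside,
            "mean_snps_per_window_inside": wsum["mean_inside"],
            "sd_snps_per_window_inside": wsum["sd_inside"],
            "mean_snps_per_window_outside": wsum["mean_outside"],
            "sd_snps_per_window_outside": wsum["sd_outside"],
            "top300_windows_inside": wsum.get("top_k_inside"),
        }
        logger.info(
            "block: %s:%d-%d, %.3f/Mb inside vs %.3f/Mb outside",
            block.chrom, block.start_bp, block.end_bp, reg.density_inside, reg.density_outside,
        )

    # stage: effect summary
    if cfg.effects is not None and block is not None:
        ann = read_effects(cfg.effects)
        snp_pos = [(s.chrom, s.pos) for s in snps]
        eff = summarize_effects(ann, snp_pos, block, genome_length)
        eff.to_csv(outdir / "effects_summary.tsv", sep="\t", index=False)
        summary["effects"] = {
            r["effect_class"]: {
                "count_inside": int(r["count_inside"]),
                "count_outside": int(r["count_outside"]),
                "density_inside_per_mb": r["density_inside_per_mb"],
                "density_outside_per_mb": r["density_outside_per_mb"],
            }
            for _, r in eff.iterrows()
        }

    # stage: expression enrichment
    if cfg.expression is not None and block is not None:
        from .expression import classify_table

        expr = read_expression(cfg.expression)
        bias = enrichment_report(expr, block, cfg.min_fpkm, cfg.background)
        classes = classify_table(expr, min_fpkm=cfg.min_fpkm)
        n_male_all = int((classes == "male").sum())
        n_female_all = int((classes == "female").sum())
        n_tie = int((classes == "tie").sum())
        n_excluded = int((classes == "excluded").sum())
        n_classified = n_male_all + n_female_all
        n_nonexcluded = len(expr) - n_excluded
        pd.DataFrame(
            [
                {
                    "male_in": bias.male_in,
                    "female_in": bias.female_in,
                    "male_bg": bias.male_bg,
                    "female_bg": bias.female_bg,
                    "ties": n_tie,
                    "excluded": n_excluded,
                    # percentages against both plausible denominators, which
                    # differ whenever ties are present
                    "pct_female_of_classified": 100.0 * n_female_all / n_classified
                    if n_classified
                    else None,
                    "pct_female_of_nonexcluded": 100.0 * n_female_all / n_nonexcluded
                    if n_nonexcluded
                    else None,
                    "background": bias.background,
                    "chi2": bias.chi2,
                    "p": bias.p,
                }
            ]
        ).to_csv(outdir / "expression_report.tsv", sep="\t", index=False)
        summary["expression"] = {
            "male_in": bias.male_in,
            "female_in": bias.female_in,
            "male_bg": bias.male_bg,
            "female_bg": bias.female_bg,
            "background": bias.background,
            "chi2": bias.chi2,
            "p": bias.p,
        }
        if bias.chi2 is not None:
            logger.info("expression: chi2=%.3f p=%.4g", bias.chi2, bias.p)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
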