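"""Synthetic Pool-seq study generator.

Emulates a two-pool (male/female) sequencing design over a small two-
chromosome genome carrying a non-recombining proto-Y block: inside the
block, Y-specific alleles sit at chromosome frequency 0.5 in the male pool
(every male is X/Y) and are absent from females; the rest of the genome
carries shared background polymorphism at equal frequency in both sexes.
Read counts are binomial draws at Poisson-distributed coverage, matching
the coverage means of a ~33x male / ~37x female pooled experiment.

Only variant positions are emitted (sparse sync), which keeps an 80 Mb
genome desk-scale; per-window counts of coverage-eligible positions are
drawn from the coverage model so window densities can also be normalized
per eligible base.  All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.stats import poisson as _poisson

from .pool_io import PoolSiteCounts, write_sync
from .regions import GenomicRegion

__all__ = [
    "SimConfig",
    "simulate_site_xy",
    "simulate_sites",
    "frequencies_frame",
    "simulate_expression",
    "simulate_effects",
    "simulate_genome",
]

_BASES = np.array(["A", "T", "C", "G"])
_BASE_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


def _default_effect_probs() -> dict[str, float]:
    # per-variant effect-class probabilities; the rare disruptive classes
    # are set so the block's qualifying-SNP density yields counts on the
    # order of tens of stop/start/splice changes per ~10 Mb block
    return {
        "OTHER": 0.98957,
        "NON_SYNONYMOUS": 0.0092,
        "STOP_GAIN": 0.0005,
        "STOP_LOST": 0.0002,
        "START_LOST": 0.00016,
        "SPLICE_SITE": 0.00011,
    }


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the pooled design this generator emulates: 58 males
    and 33 females, mean coverage 33x (male pool) and 37x (female pool),
    an 8.8 Mb differentiated block spanning 10.1-18.9 Mb of a 40 Mb sex
    chromosome plus a 40 Mb autosomal background chromosome.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"LG1": 40_000_000, "LG2": 40_000_000}
    )
    block_chrom: str = "LG1"
    block_start: int = 10_100_001  # 1-based; block = (10.1, 18.9] Mb
    block_end: int = 18_900_000
    n_males: int = 58
    n_females: int = 33
    cov_male_mean: float = 33.0
    cov_female_mean: float = 37.0
    rho_xy: float = 2.0e-3  # per-bp rate of Y-specific sites inside the block
    rho_bg: float = 2.5e-5  # per-bp rate of shared background SNPs
    eps: float = 0.002  # per-read error
    x_polymorphism: float = 0.0  # optional female-pool frequency at XY sites
    nb_dispersion: Optional[float] = None  # NB size parameter; None = Poisson
    # expression
    n_genes: int = 21_000
    n_genes_inside: int = 230
    frac_female_inside: float = 0.69
    frac_female_genome: float = 0.60
    expression_fold: float = 2.0
    fpkm_sigma: float = 1.2
    p_silent: float = 0.03  # both-sexes FPKM below the 0.05 floor
    p_zero_low: float = 0.05  # lower sex exactly 0 (undefined-bias rule)
    # effects
    effect_probs: dict[str, float] = field(default_factory=_default_effect_probs)
    # windows
    window_bp: int = 10_000
    min_cov: int = 10

    def __post_init__(self):
        if self.block_chrom not in self.chrom_lengths:
            raise ValueError(f"block chromosome {self.block_chrom!r} not in genome")
        if not (1 <= self.block_start <= self.block_end <= self.chrom_lengths[self.block_chrom]):
            raise ValueError("block interval outside its chromosome")
        for r in (self.rho_xy, self.rho_bg, self.eps, self.x_polymorphism):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("pool sizes must be >= 1")

    @property
    def block(self) -> GenomicRegion:
        return GenomicRegion(self.block_chrom, self.block_start, self.block_end)

    @property
    def genome_length_bp(self) -> int:
        return sum(self.chrom_lengths.values())


def _draw_cov(rng: np.random.Generator, mean: float, n: int, nb_k: Optional[float]):
    if nb_k is None:
        return rng.poisson(mean, size=n)
    p = nb_k / (nb_k + mean)
    return rng.negative_binomial(nb_k, p, size=n)


def simulate_site_xy(
    cov_m: int,
    cov_f: int,
    eps: float,
    rng: np.random.Generator,
    chrom: str = "LG1",
    pos: int = 1,
    ref: str = "A",
    alt: str = "T",
) -> PoolSiteCounts:
    """One X/Y fixed-difference site: the Y allele is carried by every male
    on his single Y, so its chromosome frequency is 0.5 in the male pool
    and 0 in females.  Male alt reads ~ Binomial(cov_m, 0.5(1-eps)+0.5 eps);
    female alt reads ~ Binomial(cov_f, eps)."""
    p_alt_m = 0.5 * (1.0 - eps) + 0.5 * eps
    alt_m = int(rng.binomial(cov_m, p_alt_m)) if cov_m > 0 else 0
    alt_f = int(rng.binomial(cov_f, eps)) if cov_f > 0 else 0
    counts_m = [0, 0, 0, 0, 0, 0]
    counts_f = [0, 0, 0, 0, 0, 0]
    counts_m[_BASE_IDX[ref]] = cov_m - alt_m
    counts_m[_BASE_IDX[alt]] = alt_m
    counts_f[_BASE_IDX[ref]] = cov_f - alt_f
    counts_f[_BASE_IDX[alt]] = alt_f
    return PoolSiteCounts(chrom, pos, ref, tuple(counts_m), tuple(counts_f))


def simulate_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw all variant sites of one synthetic genome.

    Returns a frame sorted by (chrom, pos) with columns chrom, pos, ref,
    alt, cov_male, cov_female, alt_male, alt_female, site_class
    ('XY_fixed_diff' | 'background').
    """
    chroms: list[np.ndarray] = []
    frames = []
    for chrom in cfg.chrom_lengths:
        length = cfg.chrom_lengths[chrom]
        # background sites, whole chromosome
        n_bg = rng.poisson(cfg.rho_bg * length)
        pos_bg = np.unique(rng.integers(1, length + 1, size=n_bg))
        # Y-specific sites, block only
        if chrom == cfg.block_chrom:
            block_len = cfg.block_end - cfg.block_start + 1
            n_xy = rng.poisson(cfg.rho_xy * block_len)
            pos_xy = np.unique(rng.integers(cfg.block_start, cfg.block_end + 1, size=n_xy))
            pos_bg = np.setdiff1d(pos_bg, pos_xy, assume_unique=True)
        else:
            pos_xy = np.array([], dtype=int)
        pos = np.concatenate([pos_xy, pos_bg])
        cls = np.array(["XY_fixed_diff"] * len(pos_xy) + ["background"] * len(pos_bg))
        order = np.argsort(pos, kind="stable")
        pos, cls = pos[order], cls[order]
        n = len(pos)
        cov_m = _draw_cov(rng, cfg.cov_male_mean, n, cfg.nb_dispersion)
        cov_f = _draw_cov(rng, cfg.cov_female_mean, n, cfg.nb_dispersion)
        is_xy = cls == "XY_fixed_diff"
        p_m = np.where(is_xy, 0.5 * (1 - cfg.eps) + 0.5 * cfg.eps, 0.0)
        p_f = np.where(
            is_xy,
            cfg.eps + cfg.x_polymorphism * (1 - 2 * cfg.eps),
            0.0,
        )
        # shared-frequency background polymorphism
        p_shared = rng.uniform(0.05, 0.95, size=n)
        p_m = np.where(is_xy, p_m, p_shared)
        p_f = np.where(is_xy, p_f, p_shared)
        alt_m = rng.binomial(cov_m, p_m)
        alt_f = rng.binomial(cov_f, p_f)
        ref = _BASES[rng.integers(0, 4, size=n)]
        alt = _BASES[(np.vectorize(_BASE_IDX.get)(ref) + rng.integers(1, 4, size=n)) % 4] if n else ref
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "cov_male": cov_m,
                    "cov_female": cov_f,
                    "alt_male": alt_m,
                    "alt_female": alt_f,
                    "site_class": cls,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def sites_to_pool_counts(sites: pd.DataFrame) -> Iterator[PoolSiteCounts]:
    """Materialize sync records from a simulated site frame."""
    for row in sites.itertuples(index=False):
        counts_m = [0, 0, 0, 0, 0, 0]
        counts_f = [0, 0, 0, 0, 0, 0]
        counts_m[_BASE_IDX[row.ref]] = int(row.cov_male - row.alt_male)
        counts_m[_BASE_IDX[row.alt]] = int(row.alt_male)
        counts_f[_BASE_IDX[row.ref]] = int(row.cov_female - row.alt_female)
        counts_f[_BASE_IDX[row.alt]] = int(row.alt_female)
        yield PoolSiteCounts(
            row.chrom, int(row.pos), row.ref, tuple(counts_m), tuple(counts_f)
        )


def frequencies_frame(sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorized biallelic site frequencies for a simulated site frame.

    Equivalent to mapping pool_io.site_frequencies over the sync records
    (asserted in tests); the pooled-minor allele is the frequency axis,
    ties broken by alphabetical base order.
    """
    alt_tot = sites["alt_male"] + sites["alt_female"]
    cov_tot = sites["cov_male"] + sites["cov_female"]
    ref_tot = cov_tot - alt_tot
    alt_is_minor = (alt_tot < ref_tot) | (
        (alt_tot == ref_tot) & (sites["alt"].to_numpy() > sites["ref"].to_numpy())
    )
    minor = np.where(alt_is_minor, sites["alt"], sites["ref"])
    major = np.where(alt_is_minor, sites["ref"], sites["alt"])
    n_min_m = np.where(alt_is_minor, sites["alt_male"], sites["cov_male"] - sites["alt_male"])
    n_min_f = np.where(
        alt_is_minor, sites["alt_female"], sites["cov_female"] - sites["alt_female"]
    )
    cov_m = sites["cov_male"].to_numpy()
    cov_f = sites["cov_female"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        f_m = np.where(cov_m > 0, n_min_m / cov_m, 0.0)
        f_f = np.where(cov_f > 0, n_min_f / cov_f, 0.0)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "major_allele": major,
            "minor_allele": minor,
            "f_male": f_m,
            "f_female": f_f,
            "cov_male": cov_m,
            "cov_female": cov_f,
            "n_minor_male": n_min_m,
            "n_minor_female": n_min_f,
        }
    )


def simulate_expression(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic gene-model expression table and its true bias labels.

    ``n_genes_inside`` gene models are placed inside the block, the rest
    uniformly outside; each is female-biased with the inside/genome
    fraction, with a lognormal baseline and a fixed fold change toward the
    biased sex.  A small fraction is silent in both sexes (excluded by the
    FPKM floor) and another has zero expression in the lower sex, which
    exercises the undefined-bias rule.
    """
    n_in = cfg.n_genes_inside
    n_out = cfg.n_genes - n_in
    gene_len = rng.integers(1_000, 20_000, size=cfg.n_genes)
    # inside-block placements
    start_in = rng.integers(cfg.block_start, cfg.block_end - gene_len[:n_in], size=n_in)
    chrom_in = np.repeat(cfg.block_chrom, n_in)
    # outside placements: uniform over the genome, rejecting block midpoints
    chrom_names = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n_out, p=lengths / lengths.sum())
    len_out = gene_len[n_in:]
    L_arr = np.array([cfg.chrom_lengths[c] for c in chrom_names])[chrom_idx]
    hi = np.maximum(2, L_arr - len_out)
    start_out = rng.integers(1, hi)
    # vectorized rejection of block-midpoint placements
    on_block_chrom = np.array(chrom_names, dtype=object)[chrom_idx] == cfg.block_chrom
    for _ in range(64):
        mid = start_out + len_out / 2
        bad = on_block_chrom & (mid >= cfg.block_start) & (mid <= cfg.block_end)
        if not bad.any():
            break
        start_out[bad] = rng.integers(1, hi[bad])
    chrom = np.concatenate([chrom_in, np.array(chrom_names, dtype=object)[chrom_idx]])
    start = np.concatenate([start_in, start_out])
    end = start + gene_len

    inside = np.zeros(cfg.n_genes, dtype=bool)
    inside[:n_in] = True
    p_female = np.where(inside, cfg.frac_female_inside, cfg.frac_female_genome)
    female_biased = rng.random(cfg.n_genes) < p_female
    base = rng.lognormal(mean=0.0, sigma=cfg.fpkm_sigma, size=cfg.n_genes)
    high = base * cfg.expression_fold
    fpkm_f = np.where(female_biased, high, base)
    fpkm_m = np.where(female_biased, base, high)
    # silent genes: both below the floor
    silent = rng.random(cfg.n_genes) < cfg.p_silent
    low_vals = rng.uniform(0.0, 0.049, size=(cfg.n_genes, 2))
    fpkm_m = np.where(silent, low_vals[:, 0], fpkm_m)
    fpkm_f = np.where(silent, low_vals[:, 1], fpkm_f)
    # zero-in-lower-sex genes (undefined-bias rule still assigns the bias)
    zero_low = (~silent) & (rng.random(cfg.n_genes) < cfg.p_zero_low)
    fpkm_m = np.where(zero_low & female_biased, 0.0, fpkm_m)
    fpkm_f = np.where(zero_low & ~female_biased, 0.0, fpkm_f)

    gene_id = np.array([f"model_{i:05d}" for i in range(cfg.n_genes)])
    df = pd.DataFrame(
        {
            "gene_id": gene_id,
            "chrom": chrom,
            "start": start,
            "end": end,
            "fpkm_male": fpkm_m,
            "fpkm_female": fpkm_f,
        }
    )
    # a gene is truly excluded whenever its emitted FPKMs fall below the
    # 0.05 floor in both sexes (forced-silent or a tiny lognormal baseline)
    below_floor = (fpkm_m < 0.05) & (fpkm_f < 0.05)
    true_bias = pd.Series(
        np.where(below_floor, "excluded", np.where(female_biased, "female", "male")),
        index=gene_id,
        name="true_bias",
    )
    # deterministic genome order
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return df, true_bias


def simulate_effects(sites: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign an effect class to every simulated variant site."""
    classes = list(cfg.effect_probs)
    probs = np.array([cfg.effect_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(len(classes), size=len(sites), p=probs)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "gene": [
                f"gene_{c}_{int(p) // 50_000:04d}"
                for c, p in zip(sites["chrom"], sites["pos"])
            ],
            "effect_class": np.array(classes)[drawn],
        }
    )


def _eligible_window_counts(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-window counts of coverage-eligible positions under the coverage
    model: each bp is eligible with P(cov_m >= min_cov) * P(cov_f >= min_cov)."""
    p_elig = float(
        _poisson.sf(cfg.min_cov - 1, cfg.cov_male_mean)
        * _poisson.sf(cfg.min_cov - 1, cfg.cov_female_mean)
    )
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        n_win = (length + cfg.window_bp - 1) // cfg.window_bp
        for i in range(n_win):
            start = i * cfg.window_bp + 1
            end = min((i + 1) * cfg.window_bp, length)
            rows.append(
                (chrom, start, end, int(rng.binomial(end - start + 1, p_elig)))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_eligible_positions"])


def simulate_genome(cfg: SimConfig, seed: int, outdir) -> dict[str, Path]:
    """Run the whole generator and write the study bundle to ``outdir``:
    sync.gz, effects.tsv, expression.tsv, eligible_windows.tsv, truth.json.
    Byte-identical outputs under identical (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sites = simulate_sites(cfg, rng)
    effects = simulate_effects(sites, cfg, rng)
    expr, true_bias = simulate_expression(cfg, rng)
    eligible = _eligible_window_counts(cfg, rng)

    paths = {
        "sync": outdir / "pools.sync.gz",
        "effects": outdir / "effects.tsv",
        "expression": outdir / "expression.tsv",
        "eligible_windows": outdir / "eligible_windows.tsv",
        "truth": outdir / "truth.json",
    }
    write_sync(sites_to_pool_counts(sites), paths["sync"])
    effects.to_csv(paths["effects"], sep="\t", index=False)
    expr.to_csv(paths["expression"], sep="\t", index=False)
    eligible.to_csv(paths["eligible_windows"], sep="\t", index=False)
    truth = {
        "seed": seed,
        "block": {"chrom": cfg.block_chrom, "start": cfg.block_start, "end": cfg.block_end},
        "chrom_lengths": cfg.chrom_lengths,
        "n_sites": int(len(sites)),
        "sites": [
            [str(c), int(p), str(k)]
            for c, p, k in zip(sites["chrom"], sites["pos"], sites["site_class"])
        ],
        "gene_bias": true_bias.to_dict(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, sort_keys=True)
    return paths
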