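"""Per-site differentiation statistics between the two sex pools.

Two statistics, both computed on the biallelic reduction of a site:

* ``site_fst`` — the classical pi-based pool F_ST: per-pool heterozygosity
  with the finite-coverage correction C/(C-1), averaged within pools and
  compared with the heterozygosity of the pooled counts,
  F_ST = (pi_total - pi_within) / pi_total, clamped to [0, 1].
* ``site_fisher`` — two-sided Fisher's exact test on the 2x2 table of
  (major, minor) allele counts in males vs females, with the "sum of small
  p" two-sided convention: p is the sum of hypergeometric probabilities no
  larger than that of the observed table.  The enumeration is exact integer
  arithmetic, so the <= rule has no floating-point ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log10
from typing import Iterable, Optional

import pandas as pd

from .pool_io import PoolSiteCounts, SiteFrequencies, site_frequencies

__all__ = ["SiteStat", "site_fst", "site_fisher", "fisher_exact_2x2", "window_mean"]


@dataclass(frozen=True)
class SiteStat:
    chrom: str
    pos: int
    fst: Optional[float]  # None when undefined
    fisher_p: Optional[float]

    @property
    def neg_log10_p(self) -> Optional[float]:
        if self.fisher_p is None:
            return None
        return -log10(self.fisher_p)


def _pi(f: float, cov: int) -> float:
    """Finite-coverage-corrected heterozygosity of a biallelic pool."""
    return (cov / (cov - 1)) * (1.0 - f * f - (1.0 - f) * (1.0 - f))


def site_fst(freqs: SiteFrequencies) -> Optional[float]:
    """Classical pool F_ST of a site, or None when undefined.

    Undefined when either pool has coverage < 2 (the C/(C-1) correction
    needs two reads) or when the site is monomorphic across both pools
    (pi_total = 0).  Negative estimates are clamped to 0.
    """
    c_m, c_f = freqs.cov_male, freqs.cov_female
    if c_m < 2 or c_f < 2 or not freqs.ok:
        return None
    pi_m = _pi(freqs.f_male, c_m)
    pi_f = _pi(freqs.f_female, c_f)
    c_t = c_m + c_f
    f_t = (freqs.n_minor_male + freqs.n_minor_female) / c_t
    pi_t = _pi(f_t, c_t)
    if pi_t == 0.0:
        return None
    fst = (pi_t - (pi_m + pi_f) / 2.0) / pi_t
    return min(1.0, max(0.0, fst))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Enumerates the hypergeometric support of the fixed margins with exact
    integer probabilities (numerators over a common binomial denominator)
    and sums every outcome whose probability is <= that of the observed
    table.  Requires both row sums > 0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = a + b, c + d
    if r1 == 0 or r2 == 0:
        raise ValueError("degenerate table: a row sum is zero")
    n = r1 + r2
    c1 = a + c  # first-column margin
    lo, hi = max(0, c1 - r2), min(c1, r1)
    # integer numerators: P(x) = C(r1, x) * C(r2, c1 - x) / C(n, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            total += num
    return total / comb(n, c1)


def site_fisher(rec: PoolSiteCounts) -> Optional[float]:
    """Fisher's exact p on the major/minor allele counts of the two pools.

    None (site skipped) when a pool has zero nucleotide coverage.
    """
    freqs = site_frequencies(rec)
    if not freqs.ok or freqs.cov_male == 0 or freqs.cov_female == 0:
        return None
    # biallelic reduction: major vs minor allele counts per pool
    idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    a = rec.counts_male[idx[freqs.major_allele]]
    b = rec.counts_male[idx[freqs.minor_allele]]
    c = rec.counts_female[idx[freqs.major_allele]]
    d = rec.counts_female[idx[freqs.minor_allele]]
    if a + b == 0 or c + d == 0:
        return None
    return fisher_exact_2x2(a, b, c, d)


def window_mean(stats: Iterable[SiteStat], window_bp: int) -> pd.DataFrame:
    """Non-overlapping window means of F_ST and -log10 Fisher p.

    Windows tile each chromosome as [1..w], [w+1..2w], ...; sites with an
    undefined statistic do not contribute to that statistic's mean.  Windows
    containing sites but no computable value report NA.  Input must be
    sorted by (chrom, pos).

    Returns a DataFrame with columns chrom, win_start, win_end, mean_fst,
    mean_neglog10p, n_sites.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    last = None
    for s in stats:
        if last is not None and s.chrom == last[0] and s.pos < last[1]:
            raise ValueError("stats must be sorted by chrom, pos")
        last = (s.chrom, s.pos)
        rows.append((s.chrom, s.pos, s.fst, s.neg_log10_p))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "fst", "neglog10p"])
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "win_start", "win_end", "mean_fst", "mean_neglog10p", "n_sites"]
        )
    df["win"] = (df["pos"] - 1) // window_bp
    out = (
        df.groupby(["chrom", "win"], sort=True)
        .agg(
            mean_fst=("fst", "mean"),
            mean_neglog10p=("neglog10p", "mean"),
            n_sites=("pos", "size"),
        )
        .reset_index()
    )
    out["win_start"] = out["win"] * window_bp + 1
    out["win_end"] = (out["win"] + 1) * window_bp
    return out[["chrom", "win_start", "win_end", "mean_fst", "mean_neglog10p", "n_sites"]]
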