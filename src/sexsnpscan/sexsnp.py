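"""Sex-pattern SNP classification and windowed density scan.

A sex-pattern SNP is the read-count signature of a sex-specific allele in a
pooled design: the shared (pooled-minor) allele sits at intermediate
frequency in the heterogametic pool and is fixed or nearly fixed (for
either allele) in the homogametic pool.  Under male heterogamety (XY) the
male pool is the intermediate one; the ``polarity`` switch flips this for
ZW systems.

Qualifying SNPs are counted in non-overlapping windows (10 kb by default);
positions with coverage below ``min_cov`` in either pool are ineligible and
never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .pool_io import SiteFrequencies

__all__ = [
    "Thresholds",
    "SexPatternSNP",
    "WindowStat",
    "classify_site",
    "classify_frame",
    "window_scan",
    "write_igv_track",
]


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds; all four bounds are inclusive."""

    intermediate: tuple[float, float] = (0.3, 0.7)
    fixed_low: float = 0.1
    fixed_high: float = 0.9
    min_cov: int = 10
    polarity: str = "xy"  # "xy": male pool intermediate; "zw": female pool

    def __post_init__(self):
        lo, hi = self.intermediate
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"bad intermediate range {self.intermediate}")
        if self.polarity not in ("xy", "zw"):
            raise ValueError(f"polarity must be 'xy' or 'zw', got {self.polarity!r}")


@dataclass(frozen=True)
class SexPatternSNP:
    chrom: str
    pos: int
    f_intermediate_pool: float
    f_fixed_pool: float
    allele: str  # the shared allele axis (pooled minor allele)


@dataclass
class WindowStat:
    chrom: str
    win_index: int  # 0-based tile index
    start: int  # 1-based inclusive
    end: int
    n_sex_snps: int = 0
    n_eligible_positions: int = 0


def classify_site(
    freqs: SiteFrequencies, thresholds: Thresholds = Thresholds()
) -> Optional[SexPatternSNP]:
    """Return a :class:`SexPatternSNP` if the site qualifies, else None.

    The same allele (the pooled minor allele carried by ``freqs``) must be
    intermediate in one pool and fixed/nearly fixed in the other; a site
    where either pool has coverage below ``min_cov`` never qualifies.
    """
    t = thresholds
    if not freqs.ok:
        return None
    if freqs.cov_male < t.min_cov or freqs.cov_female < t.min_cov:
        return None
    if t.polarity == "xy":
        f_int, f_fix = freqs.f_male, freqs.f_female
    else:
        f_int, f_fix = freqs.f_female, freqs.f_male
    lo, hi = t.intermediate
    if lo <= f_int <= hi and (f_fix <= t.fixed_low or f_fix >= t.fixed_high):
        return SexPatternSNP(
            chrom=freqs.chrom,
            pos=freqs.pos,
            f_intermediate_pool=f_int,
            f_fixed_pool=f_fix,
            allele=freqs.minor_allele,
        )
    return None


def classify_frame(
    freq_df: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.Series:
    """Vectorized qualification mask over a frame of site frequencies.

    ``freq_df`` needs columns f_male, f_female, cov_male, cov_female.
    Agrees with :func:`classify_site` record-by-record (asserted in tests).
    """
    t = thresholds
    f_int = freq_df["f_male"] if t.polarity == "xy" else freq_df["f_female"]
    f_fix = freq_df["f_female"] if t.polarity == "xy" else freq_df["f_male"]
    lo, hi = t.intermediate
    covered = (freq_df["cov_male"] >= t.min_cov) & (freq_df["cov_female"] >= t.min_cov)
    return (
        covered
        & f_int.between(lo, hi)
        & ((f_fix <= t.fixed_low) | (f_fix >= t.fixed_high))
    )


def _n_windows(length: int, window_bp: int) -> int:
    return (length + window_bp - 1) // window_bp


def window_scan(
    snps: Iterable[SexPatternSNP],
    eligible_positions: Iterable[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 10_000,
) -> list[WindowStat]:
    """Count qualifying SNPs per non-overlapping window.

    Windows tile every chromosome in ``chrom_lengths`` (the sequence
    dictionary) as [1..w], [w+1..2w], ...; every tile is emitted even when
    empty.  ``eligible_positions`` streams (chrom, pos) for every position
    passing the coverage filter, feeding ``n_eligible_positions``; a
    qualifying SNP is assumed to come from that eligible stream (the
    classifier enforces the coverage filter).

    Raises on unsorted SNP input and on positions naming a chromosome
    absent from the sequence dictionary.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    windows: dict[str, list[WindowStat]] = {}
    for chrom, length in chrom_lengths.items():
        windows[chrom] = [
            WindowStat(
                chrom=chrom,
                win_index=i,
                start=i * window_bp + 1,
                end=min((i + 1) * window_bp, length),
            )
            for i in range(_n_windows(length, window_bp))
        ]

    def _window_of(chrom: str, pos: int) -> WindowStat:
        if chrom not in windows:
            raise ValueError(f"unknown chromosome {chrom!r}")
        idx = (pos - 1) // window_bp
        tiles = windows[chrom]
        if idx >= len(tiles):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome length")
        return tiles[idx]

    for chrom, pos in eligible_positions:
        _window_of(chrom, pos).n_eligible_positions += 1

    last: Optional[tuple[str, int]] = None
    for snp in snps:
        if last is not None and snp.chrom == last[0] and snp.pos < last[1]:
            raise ValueError("SNP input must be sorted by chrom, pos")
        last = (snp.chrom, snp.pos)
        _window_of(snp.chrom, snp.pos).n_sex_snps += 1

    return [w for chrom in chrom_lengths for w in windows[chrom]]


def windows_to_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (w.chrom, w.win_index, w.start, w.end, w.n_sex_snps, w.n_eligible_positions)
            for w in windows
        ],
        columns=["chrom", "win_index", "start", "end", "n_sex_snps", "n_eligible_positions"],
    )


def write_igv_track(
    records: Sequence[SexPatternSNP] | Sequence[WindowStat],
    path,
    feature: str = "sex_snp",
    track_name: str = "sexsnpscan",
) -> None:
    """Write an IGV ``.igv`` tab track (Chromosome, Start, End, Feature, value).

    Starts are converted to 0-based half-open coordinates (IGV convention);
    per-SNP rows carry value 1, window rows carry the SNP count.  An empty
    input produces a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (IGV convention)\n")
        fh.write(f"Chromosome\tStart\tEnd\tFeature\t{track_name}\n")
        for rec in records:
            if isinstance(rec, WindowStat):
                fh.write(
                    f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{feature}\t{rec.n_sex_snps}\n"
                )
            else:
                fh.write(f"{rec.chrom}\t{rec.pos - 1}\t{rec.pos}\t{feature}\t1\n")
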