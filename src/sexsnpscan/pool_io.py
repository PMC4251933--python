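"""Reading and writing Popoolation2-style ``sync`` allele-count files.

A sync file records, per genomic position, the read counts of the six
symbols ``A:T:C:G:N:del`` for each sequenced pool.  Here exactly two pools
are expected — one per sex — and coverage is defined as the sum of the four
nucleotide counts (``N`` and deletion columns are parsed but never enter
frequency arithmetic, matching Popoolation2's own convention).

Positions are 1-based throughout, as in the sync format itself.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = [
    "SYNC_BASES",
    "PoolSiteCounts",
    "SiteFrequencies",
    "SyncParseError",
    "read_sync",
    "write_sync",
    "site_frequencies",
]

#: order of the count fields in a sync column
SYNC_BASES = ("A", "T", "C", "G", "N", "del")

# indices of the four nucleotides within a sync count vector
_NUC_IDX = (0, 1, 2, 3)
_NUC = ("A", "T", "C", "G")


class SyncParseError(ValueError):
    """Malformed sync input; carries the offending line number."""


@dataclass(frozen=True)
class PoolSiteCounts:
    """Per-site A:T:C:G:N:del read counts for the male and female pools."""

    chrom: str
    pos: int  # 1-based
    ref: str
    counts_male: tuple[int, int, int, int, int, int]
    counts_female: tuple[int, int, int, int, int, int]

    @property
    def cov_male(self) -> int:
        return sum(self.counts_male[i] for i in _NUC_IDX)

    @property
    def cov_female(self) -> int:
        return sum(self.counts_female[i] for i in _NUC_IDX)

    def pooled_nucleotide_counts(self) -> dict[str, int]:
        """Summed male+female counts for A, C, G, T (frequency alleles)."""
        return {
            base: self.counts_male[i] + self.counts_female[i]
            for i, base in zip(_NUC_IDX, _NUC)
        }


@dataclass(frozen=True)
class SiteFrequencies:
    """Biallelic reduction of a site: pooled major/minor alleles and the
    minor-allele frequency in each pool.

    The same allele axis (the pooled minor allele) is used for both pools,
    so downstream intermediate/fixed classification always compares the
    frequency of one and the same allele.  ``ok`` is False when neither
    pool has nucleotide coverage; such sites are excluded downstream.
    """

    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    f_male: float
    f_female: float
    cov_male: int
    cov_female: int
    n_minor_male: int
    n_minor_female: int
    multiallelic: bool = False
    ok: bool = True


def _parse_counts(field: str, lineno: int) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncParseError(
            f"line {lineno}: expected 6 colon-separated counts, got {field!r}"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError:
        raise SyncParseError(f"line {lineno}: non-integer count in {field!r}") from None
    if any(c < 0 for c in counts):
        raise SyncParseError(f"line {lineno}: negative count in {field!r}")
    return counts


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sync(
    path, pool_order: tuple[str, str] = ("male", "female")
) -> Iterator[PoolSiteCounts]:
    """Stream :class:`PoolSiteCounts` from a (possibly gzipped) sync file.

    ``pool_order`` names the sexes of the 4th and 5th columns; the default
    follows the convention of listing the male pool first.  Malformed lines
    raise :class:`SyncParseError` naming the 1-based line number.
    """
    if tuple(sorted(pool_order)) != ("female", "male"):
        raise ValueError(f"pool_order must name 'male' and 'female', got {pool_order}")
    male_col = 3 if pool_order[0] == "male" else 4
    female_col = 7 - male_col  # the other of columns 3/4
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SyncParseError(
                    f"line {lineno}: expected >=5 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"line {lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise SyncParseError(f"line {lineno}: position must be >=1, got {pos}")
            yield PoolSiteCounts(
                chrom=chrom,
                pos=pos,
                ref=ref,
                counts_male=_parse_counts(fields[male_col], lineno),
                counts_female=_parse_counts(fields[female_col], lineno),
            )


def write_sync(
    records: Iterable[PoolSiteCounts],
    path,
    pool_order: tuple[str, str] = ("male", "female"),
) -> None:
    """Write records to sync format (gzipped if the path ends in .gz).

    Round-trips byte-identically with :func:`read_sync` for canonical files.
    Gzip output is written with a zeroed mtime so identical inputs produce
    identical bytes.
    """
    buf = io.StringIO()
    for rec in records:
        cols = {"male": rec.counts_male, "female": rec.counts_female}
        buf.write(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    rec.ref,
                    ":".join(map(str, cols[pool_order[0]])),
                    ":".join(map(str, cols[pool_order[1]])),
                ]
            )
            + "\n"
        )
    data = buf.getvalue().encode()
    path = str(path)
    if path.endswith(".gz"):
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(data)
    else:
        with open(path, "wb") as raw:
            raw.write(data)


def site_frequencies(rec: PoolSiteCounts) -> SiteFrequencies:
    """Reduce a site to its two highest-count pooled alleles and compute the
    minor-allele frequency in each pool.

    Ties in pooled counts are broken by alphabetical base order.  Sites with
    more than two observed alleles keep the top two and are flagged
    ``multiallelic``.  Frequencies are allele count / nucleotide coverage;
    a pool with zero coverage gets frequency 0.0 and downstream filters use
    the stored coverages.  When both pools have zero coverage the record is
    returned with ``ok=False``.
    """
    pooled = rec.pooled_nucleotide_counts()
    cov_m, cov_f = rec.cov_male, rec.cov_female
    if cov_m == 0 and cov_f == 0:
        return SiteFrequencies(
            rec.chrom, rec.pos, "N", "N", 0.0, 0.0, 0, 0, 0, 0, ok=False
        )
    # sort by (count desc, base asc) — alphabetical tie-break
    ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    major, minor = ranked[0][0], ranked[1][0]
    multi = sum(1 for _, c in pooled.items() if c > 0) > 2
    idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    n_min_m = rec.counts_male[idx[minor]]
    n_min_f = rec.counts_female[idx[minor]]
    f_m = n_min_m / cov_m if cov_m > 0 else 0.0
    f_f = n_min_f / cov_f if cov_f > 0 else 0.0
    return SiteFrequencies(
        chrom=rec.chrom,
        pos=rec.pos,
        major_allele=major,
        minor_allele=minor,
        f_male=f_m,
        f_female=f_f,
        cov_male=cov_m,
        cov_female=cov_f,
        n_minor_male=n_min_m,
        n_minor_female=n_min_f,
        multiallelic=multi,
    )
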