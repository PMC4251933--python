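"""Sex-biased expression classification and block-enrichment testing.

Gene models are classified from per-sex FPKM: excluded when expression is
below ``min_fpkm`` in both sexes, otherwise biased toward the sex with the
larger FPKM (a gene expressed in one sex and silent in the other is still
counted as biased toward the expressed sex); equal non-trivial FPKMs are
ties and enter neither class.  Enrichment of female-biased models inside a
genomic region is tested with a Yates-corrected chi-square on the 2x2 table
of (male, female) counts inside the region against a background — by
default the genome-wide totals (which include the region), configurable to
the outside-only counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .regions import GenomicRegion

__all__ = [
    "BiasTable",
    "classify_bias",
    "classify_table",
    "read_expression",
    "yates_chi2",
    "enrichment_report",
]

EXPRESSION_COLUMNS = ("gene_id", "chrom", "start", "end", "fpkm_male", "fpkm_female")


def read_expression(path) -> pd.DataFrame:
    """Read the expression TSV (gene_id, chrom, start, end, fpkm_male,
    fpkm_female); validates columns and non-negative FPKMs."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing required columns: {missing}")
    if (df["fpkm_male"] < 0).any() or (df["fpkm_female"] < 0).any():
        raise ValueError("negative FPKM values")
    return df


def classify_bias(fpkm_male: float, fpkm_female: float, min_fpkm: float = 0.05) -> str:
    """Bias class of one gene model: 'male', 'female', 'excluded' or 'tie'."""
    if fpkm_male < 0 or fpkm_female < 0 or not (
        np.isfinite(fpkm_male) and np.isfinite(fpkm_female)
    ):
        raise ValueError("FPKM values must be finite and non-negative")
    if fpkm_male < min_fpkm and fpkm_female < min_fpkm:
        return "excluded"
    if fpkm_male == fpkm_female:
        return "tie"
    return "male" if fpkm_male > fpkm_female else "female"


def classify_table(df: pd.DataFrame, min_fpkm: float = 0.05) -> pd.Series:
    """Vectorized :func:`classify_bias` over an expression frame."""
    m = df["fpkm_male"].to_numpy(float)
    f = df["fpkm_female"].to_numpy(float)
    if (m < 0).any() or (f < 0).any() or not np.isfinite(m).all() or not np.isfinite(f).all():
        raise ValueError("FPKM values must be finite and non-negative")
    out = np.where(m > f, "male", np.where(f > m, "female", "tie"))
    out = np.where((m < min_fpkm) & (f < min_fpkm), "excluded", out)
    return pd.Series(out, index=df.index, name="bias")


@dataclass
class BiasTable:
    male_in: int
    female_in: int
    male_bg: int  # background counts (genome-wide or outside-only)
    female_bg: int
    background: str  # "genomewide" | "outside"
    chi2: Optional[float]
    p: Optional[float]


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square for the 2x2 table [[a, b], [c, d]].

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E, with the
    truncation at zero so exactly proportional tables score 0; p is the
    upper tail of chi-square with 1 df.  Raises on a zero margin.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("cell counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero margin")
    exp = np.outer(rows, cols) / obs.sum()
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float((adj**2 / exp).sum())
    return stat, float(_chi2_dist.sf(stat, df=1))


def enrichment_report(
    records: pd.DataFrame,
    region: GenomicRegion,
    min_fpkm: float = 0.05,
    background: str = "genomewide",
) -> BiasTable:
    """Female-bias enrichment of a region against the chosen background.

    Gene models are assigned to the region by midpoint.  The test compares
    (male, female) biased counts inside the region with either genome-wide
    totals (default) or the outside-only counts.  When the region holds no
    classified models the test is reported as NA (None, None).
    """
    if background not in ("genomewide", "outside"):
        raise ValueError(f"background must be 'genomewide' or 'outside', got {background!r}")
    bias = classify_table(records, min_fpkm=min_fpkm)
    mid = (records["start"].to_numpy(float) + records["end"].to_numpy(float)) / 2.0
    inside = (
        (records["chrom"].astype(str) == region.chrom).to_numpy()
        & (mid >= region.start_bp)
        & (mid <= region.end_bp)
    )
    male_in = int(((bias == "male") & inside).sum())
    female_in = int(((bias == "female") & inside).sum())
    if background == "genomewide":
        male_bg = int((bias == "male").sum())
        female_bg = int((bias == "female").sum())
    else:
        male_bg = int(((bias == "male") & ~inside).sum())
        female_bg = int(((bias == "female") & ~inside).sum())
    if male_in + female_in == 0:
        return BiasTable(male_in, female_in, male_bg, female_bg, background, None, None)
    stat, p = yates_chi2(male_in, female_in, male_bg, female_bg)
    return BiasTable(male_in, female_in, male_bg, female_bg, background, stat, p)
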