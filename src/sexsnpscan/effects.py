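"""Effect-class summaries of sex-pattern SNPs.

Consumes a variant effect-annotation table (e.g. exported from a SnpEff
run) as TSV, restricts it to qualifying sex-pattern SNPs, and tallies
effect classes with per-megabase densities inside and outside the called
block.  Stop-codon "changes" pool gains and losses, as is conventional in
summaries of putatively disruptive variants.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import pandas as pd

from .regions import GenomicRegion, region_density

__all__ = ["EFFECT_CLASSES", "SNPEFF_CLASS_MAP", "read_effects", "summarize_effects"]

EFFECT_CLASSES = (
    "STOP_GAIN",
    "STOP_LOST",
    "START_LOST",
    "SPLICE_SITE",
    "NON_SYNONYMOUS",
    "OTHER",
)

# fixed mapping from common annotation-tool terms to the closed vocabulary
SNPEFF_CLASS_MAP = {
    "STOP_GAIN": "STOP_GAIN",
    "STOP_GAINED": "STOP_GAIN",
    "STOP_LOST": "STOP_LOST",
    "START_LOST": "START_LOST",
    "SPLICE_SITE": "SPLICE_SITE",
    "SPLICE_SITE_ACCEPTOR": "SPLICE_SITE",
    "SPLICE_SITE_DONOR": "SPLICE_SITE",
    "SPLICE_ACCEPTOR_VARIANT": "SPLICE_SITE",
    "SPLICE_DONOR_VARIANT": "SPLICE_SITE",
    "NON_SYNONYMOUS": "NON_SYNONYMOUS",
    "NON_SYNONYMOUS_CODING": "NON_SYNONYMOUS",
    "MISSENSE_VARIANT": "NON_SYNONYMOUS",
    "OTHER": "OTHER",
}

_REQUIRED = ("chrom", "pos", "gene", "effect_class")


def read_effects(path) -> pd.DataFrame:
    """Read and validate an effect-annotation TSV.

    Requires columns chrom, pos, gene, effect_class (extra columns such as
    ref_codon/alt_codon pass through).  Unknown class strings map to OTHER
    with a warning; duplicate (chrom, pos, gene, effect_class) rows are
    dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"effects table missing required columns: {missing}")
    norm = df["effect_class"].astype(str).str.upper().str.replace(" ", "_")
    mapped = norm.map(SNPEFF_CLASS_MAP)
    unknown = sorted(norm[mapped.isna()].unique())
    if unknown:
        warnings.warn(f"unknown effect classes mapped to OTHER: {unknown}")
    df = df.assign(effect_class=mapped.fillna("OTHER"))
    dup = df.duplicated(subset=list(_REQUIRED))
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate effect rows")
        df = df[~dup]
    return df.reset_index(drop=True)


def summarize_effects(
    annotations: pd.DataFrame,
    sex_snp_positions: Iterable[tuple[str, int]],
    region: GenomicRegion,
    genome_length_bp: int,
    include_stop_pooled: bool = True,
) -> pd.DataFrame:
    """Per-class counts and per-Mb densities inside/outside the region.

    Only annotations whose (chrom, pos) is a qualifying sex-pattern SNP are
    tallied.  Densities use the region length inside and genome length
    minus region length outside.  With ``include_stop_pooled`` an extra
    STOP_ANY row pools STOP_GAIN + STOP_LOST.
    """
    region_mb_bp = region.length_bp
    outside_bp = genome_length_bp - region_mb_bp
    if outside_bp <= 0:
        raise ValueError("region length must be smaller than genome length")
    qualifying = set(sex_snp_positions)
    keep = annotations.apply(
        lambda r: (str(r["chrom"]), int(r["pos"])) in qualifying, axis=1
    ) if len(annotations) else pd.Series([], dtype=bool)
    ann = annotations[keep] if len(annotations) else annotations
    inside_mask = (
        (ann["chrom"].astype(str) == region.chrom)
        & (ann["pos"] >= region.start_bp)
        & (ann["pos"] <= region.end_bp)
    ) if len(ann) else pd.Series([], dtype=bool)

    rows = []
    classes: list[tuple[str, Optional[list[str]]]] = [(c, [c]) for c in EFFECT_CLASSES]
    if include_stop_pooled:
        classes.append(("STOP_ANY", ["STOP_GAIN", "STOP_LOST"]))
    for label, members in classes:
        if len(ann):
            sel = ann["effect_class"].isin(members)
            n_in = int((sel & inside_mask).sum())
            n_out = int((sel & ~inside_mask).sum())
        else:
            n_in = n_out = 0
        rows.append(
            {
                "effect_class": label,
                "count_inside": n_in,
                "count_outside": n_out,
                "density_inside_per_mb": region_density(n_in, region_mb_bp),
                "density_outside_per_mb": region_density(n_out, outside_bp),
            }
        )
    return pd.DataFrame(rows)
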