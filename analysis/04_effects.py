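"""Effect-class tallies of sex-pattern SNPs inside vs outside the block.

Restricts the simulated effect-annotation table to qualifying sex-pattern
SNPs and tallies stop/start/splice/non-synonymous classes with per-Mb
densities on each side of the called block.
"""

import pandas as pd

from sexsnpscan.effects import read_effects, summarize_effects
from sexsnpscan.regions import GenomicRegion

bed = pd.read_csv("results/scan/regions.bed", sep="\t",
                  names=["chrom", "start0", "end", "name"])
block = GenomicRegion(bed.iloc[0]["chrom"], int(bed.iloc[0]["start0"]) + 1,
                      int(bed.iloc[0]["end"]))
windows = pd.read_csv("results/scan/sexsnp_windows.tsv", sep="\t")
genome_bp = int(windows.groupby("chrom")["end"].max().sum())
sites = pd.read_csv("results/scan/sites.tsv", sep="\t")
qual = sites[(sites.f_male.between(0.3, 0.7))
             & ((sites.f_female <= 0.1) | (sites.f_female >= 0.9))
             & (sites.cov_male >= 10) & (sites.cov_female >= 10)]
ann = read_effects("results/sim/effects.tsv")
table = summarize_effects(ann, list(zip(qual.chrom.astype(str), qual.pos.astype(int))),
                          block, genome_bp)
table.to_csv("results/scan/effects_summary.tsv", sep="\t", index=False)
print(table.to_string(index=False))
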