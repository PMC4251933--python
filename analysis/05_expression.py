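"""Female-bias enrichment of the called block.

Classifies each simulated gene model as male- or female-biased from its
per-sex FPKM (floor 0.05; a gene silent in one sex counts toward the
expressed sex) and tests enrichment of female bias inside the block with a
Yates-corrected chi-square against the genome-wide bias counts.
"""

import pandas as pd

from sexsnpscan.expression import enrichment_report, read_expression
from sexsnpscan.regions import GenomicRegion

bed = pd.read_csv("results/scan/regions.bed", sep="\t",
                  names=["chrom", "start0", "end", "name"])
block = GenomicRegion(bed.iloc[0]["chrom"], int(bed.iloc[0]["start0"]) + 1,
                      int(bed.iloc[0]["end"]))
expr = read_expression("results/sim/expression.tsv")
bias = enrichment_report(expr, block, min_fpkm=0.05, background="genomewide")
n_in = bias.male_in + bias.female_in
print(f"inside block: {bias.male_in} male-biased ({bias.male_in / n_in:.1%}), "
      f"{bias.female_in} female-biased ({bias.female_in / n_in:.1%})")
print(f"genome-wide:  {bias.male_bg} male-biased, {bias.female_bg} female-biased")
print(f"Yates chi2 = {bias.chi2:.2f}, p = {bias.p:.4g}"
      + ("  (significant female-bias enrichment)" if bias.p < 0.05 else ""))
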