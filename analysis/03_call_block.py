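"""Call the differentiated block from the window track and summarize it.

Reads results/scan/sexsnp_windows.tsv, calls maximal runs of windows with
>= 5 sex-pattern SNPs (bridging up to 20 cold windows, dropping runs under
50 windows), and prints the block's per-Mb density contrast and per-window
mean/SD — the headline arithmetic of a proto-Y scan.
"""

import pandas as pd

from sexsnpscan.regions import call_block, summarize_region, window_count_summary, write_bed
from sexsnpscan.sexsnp import WindowStat

df = pd.read_csv("results/scan/sexsnp_windows.tsv", sep="\t")
windows = [
    WindowStat(r.chrom, int(r.win_index), int(r.start), int(r.end),
               int(r.n_sex_snps), int(r.n_eligible_positions))
    for r in df.itertuples(index=False)
]
regions = call_block(windows)
write_bed(regions, "results/scan/regions.bed")
if not regions:
    print("no differentiated block called")
else:
    block = max(regions, key=lambda r: r.length_bp)
    genome_bp = int(df.groupby("chrom")["end"].max().sum())
    s = summarize_region(windows, block, genome_bp)
    w = window_count_summary(windows, block, top_k=300)
    print(f"block: {block.chrom}:{block.start_bp}-{block.end_bp} ({block.length_mb:.1f} Mb)")
    print(f"  {s.n_snps_inside} SNPs inside ({s.density_inside}/Mb), "
          f"{s.n_snps_outside} outside ({s.density_outside}/Mb)")
    print(f"  per-window mean {s.mean_inside:.2f} (SD {s.sd_inside:.2f}) inside vs "
          f"{s.mean_outside:.2f} (SD {s.sd_outside:.2f}) outside")
    print(f"  {w['top_k_inside']} of the top-300 windows fall inside the block")
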