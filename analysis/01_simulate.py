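"""Generate the synthetic proto-Y study bundle.

Writes a two-pool sync file (male/female), an effect-annotation table, a
per-sex expression table, per-window eligible-position counts and a truth
file under results/sim/.  The design: 80 Mb genome (LG1 + LG2, 40 Mb
each), an 8.8 Mb Y-differentiated block at 10.1-18.9 Mb of LG1, pools of
58 males / 33 females at mean coverage 33x / 37x.
"""

import json
import sys

from sexsnpscan.simulate import SimConfig, simulate_genome

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = SimConfig()
paths = simulate_genome(cfg, seed=seed, outdir="results/sim")
truth = json.load(open(paths["truth"]))
print(f"seed {seed}: {truth['n_sites']} variant sites "
      f"({sum(1 for s in truth['sites'] if s[2] == 'XY_fixed_diff')} Y-specific, "
      f"block {truth['block']['chrom']}:{truth['block']['start']}-{truth['block']['end']})")
for k, v in paths.items():
    print(f"  {k}: {v}")
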