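# Methods

## The model

The package targets the earliest stage of sex-chromosome evolution: an XY
pair whose Y is differentiated only inside a region of suppressed
recombination (e.g. a young inversion). With pooled sequencing of the two
sexes, a Y-specific allele appears at chromosome frequency 0.5 in the male
pool (each male is X/Y) and 0 in the female pool. After binomial read
sampling at finite coverage, such sites show the *sex-pattern* signature:
intermediate frequency in males, fixed or nearly fixed in females. The
scan classifies sites by that signature, measures their density in 10-kb
windows, calls the differentiated block as a run of dense windows, and
then asks two follow-up questions: do putatively disruptive mutations
accumulate inside the block, and is expression inside the block already
female-biased (incomplete dosage compensation)?

## Statistics

**Pooled F_ST.** Per site, the classical π-based estimator on the
biallelic reduction: for pool *i* with nucleotide coverage Cᵢ and
minor-allele frequency fᵢ, πᵢ = Cᵢ/(Cᵢ−1)·(1 − fᵢ² − (1−fᵢ)²);
π_within is the mean of the two pools and π_total is computed the same way
from the summed counts; F_ST = (π_total − π_within)/π_total, clamped to
[0, 1]. Undefined when either pool has coverage < 2 (the finite-coverage
correction needs two reads) or when π_total = 0. Because of the finite-C
correction, F_ST is not invariant under scaling all counts by a constant;
it is invariant only in the C→∞ limit.

**Fisher's exact test.** Two-sided, on the 2×2 table of major/minor
allele counts in the two pools, with the "sum of small p" convention: the
p-value sums the hypergeometric probabilities of every table (at the
observed margins) whose probability does not exceed the observed table's.
The enumeration uses exact integer numerators over a common binomial
denominator, so the ≤ comparison is unambiguous; a floating-point
implementation with a relative-epsilon comparison can differ on near-tied
tables, which is why the package carries its own enumeration and treats
`scipy.stats.fisher_exact` as a cross-check only.

**Yates χ².** χ² = Σ max(|O−E|−0.5, 0)²/E over the four cells, 1 df
upper-tail p. The truncation at zero (so exactly proportional tables
score 0) is one of two common conventions; it matches
`scipy.stats.chi2_contingency(correction=True)`, which the tests assert.

## Classification rules and their parameters

| parameter | default | meaning |
|---|---|---|
| intermediate range | [0.3, 0.7] | heterogametic-pool frequency band, bounds inclusive |
| fixed range | ≤ 0.1 or ≥ 0.9 | homogametic-pool band, bounds inclusive |
| min_cov | 10 reads | required in **each** pool for a position to be eligible |
| window | 10 kb | non-overlapping tiles [1..w], [w+1..2w], … |
| polarity | xy | which pool must be intermediate (zw swaps) |
| min_fpkm | 0.05 | expression floor; below it in both sexes → excluded |

Both pools are compared on the *same* allele axis — the pooled minor
allele — so a site fixed for different alleles in the two pools cannot
qualify twice. The coverage rule is applied per pool (an "in both sexes"
phrasing could also be read as jointly; requiring each pool is the
stricter reading and matches the reliability requirement of the
frequency bands); it is configurable. A gene with FPKM above the floor in
one sex and zero in the other is counted as biased toward the expressed
sex (the "undefined bias" rule); equal non-trivial FPKMs are ties and are
counted in neither class.

**Block caller.** Maximal runs of windows with ≥ 5 sex-pattern SNPs,
bridging up to 20 consecutive sub-threshold windows, discarding runs
under 50 windows; the region spans the first to last hot window. The
defaults are set from the expected per-window counts of the default
simulation (≈19–20 SNPs per in-block window vs ≪ 1 outside), where they
recover a planted 8.8 Mb block to window resolution; for a genome with a
weaker contrast the threshold should be lowered together with a higher
`max_gap`. Window↔region membership is by window midpoint, which avoids
double counting at boundaries.

**Enrichment background.** The χ² table compares in-block (male, female)
bias counts against genome-wide totals *including* the block. Comparing a
subset against a total that contains it slightly overlaps the two rows
and makes the test conservative; the `background="outside"` switch gives
the disjoint inside-vs-outside construction. The genome-wide background is
the default because it reproduces the enrichment statistic of the study
design this pipeline mirrors (χ² = 5.58 on counts 68/162 vs 7977/13375,
asserted in the tests).

## The synthetic study generator

`simulate.SimConfig` defaults define the emulated design: an 80 Mb
genome (two 40 Mb chromosomes), a block at 10.1–18.9 Mb of LG1, pools of
58 males and 33 females, Poisson coverage with means 33 (males) and 37
(females), per-read error 0.002. Inside the block, Y-specific sites occur
at 2.0×10⁻³ per bp and male alt reads are Binomial(cov, 0.5(1−ε)+0.5ε)
(every male an obligate X/Y, so no inter-individual variance in the
pool), female alt reads Binomial(cov, ε). Background SNPs occur at
2.5×10⁻⁵ per bp genome-wide with one shared frequency per site drawn
Uniform(0.05, 0.95) in both sexes — these can qualify by chance, which
produces the realistic non-zero outside density. Only variant positions
are emitted (sparse sync); per-window eligible-position counts are drawn
from the coverage model (Binomial(10⁴, P(cov ≥ 10 in both pools))) so
densities can also be normalized per eligible base. Negative-binomial
coverage overdispersion and an X-polymorphism rate at Y sites (non-zero
"nearly fixed" female frequencies) are available but off by default.

Expression: 21,000 gene models, 230 placed inside the block, female-biased
with probability 0.69 inside and 0.60 outside; a lognormal(0, 1.2)
baseline with a 2-fold change toward the biased sex; 3% of genes silent
in both sexes (exercising the FPKM floor) and 5% with zero expression in
the lower sex (exercising the undefined-bias rule). These scales give the
enrichment test ≈70% power at α = 0.05, with type-I error ≤ 5% when the
inside fraction equals the genome fraction (both checked over 200 seeds
in the tests). Effect classes are drawn per variant site from a fixed
categorical (non-synonymous 9.2×10⁻³; stop gain 5×10⁻⁴; stop loss
2×10⁻⁴; start loss 1.6×10⁻⁴; splice site 1.1×10⁻⁴; rest OTHER), chosen
so a block of this size carries tens of disruptive changes.

What the generator does **not** emulate: read-level artifacts (mapping
bias, indels, paralogy), linkage between sites, coalescent history,
inter-family variation in the pools, and X-linked polymorphism by
default. Passing tests therefore demonstrate that the *pipeline
arithmetic and classifiers* behave correctly under the stated sampling
model, not that the thresholds are optimal for any particular real
genome. Quantities that depend on real data (genome-wide mean F_ST, the
exact per-window mean inside a real block) are reproduced only as
qualitative analogues: the simulated inside/outside density contrast
(≈1900/Mb vs ≈0.06/Mb) mirrors a real proto-Y contrast of
≈2077/Mb vs ≈24/Mb in shape, not in the outside level, because real
data add reference and mapping artifacts the generator omits.

## Numerical and design choices

- Positions are 1-based inclusive internally (sync convention); BED and
  IGV outputs convert to 0-based half-open and say so in a header.
- Multi-allelic sites keep the two highest pooled-count alleles
  (alphabetical tie-break) and are flagged; frequencies are counts over
  the full 4-nucleotide coverage.
- Negative F_ST estimates are clamped to 0; sample (n−1) SD everywhere.
- Densities are reported rounded to 3 decimals; all other arithmetic is
  double precision.
- Per-Mb "outside" densities use (genome length − block length); the
  genome length is a config input since assembled vs anchored length is a
  data-set property.
- Determinism: one `numpy.random.Generator` per run, gzip written with
  zeroed mtime, sorted JSON keys — identical (config, seed) gives
  byte-identical outputs.
- Genome-wide bias percentages are reported against both plausible
  denominators (all classified models vs all non-excluded models) when
  they differ; the enrichment test itself uses counts, not percentages.

## Limitations

- The scan classifies directly from allele counts; it does not require
  sites to be pre-called by a genotype caller, so error-prone sites that
  a caller would remove can enter the background (the coverage filter is
  the only site-quality gate).
- The block caller is a simple run-length rule; it reports maximal runs
  and will merge two nearby blocks separated by fewer than `max_gap`
  cold windows.
- Effect classes are consumed from a table; no consequence prediction is
  performed, and unknown class strings are folded into OTHER.
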