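import dataclasses
import json

import numpy as np
import pytest

from sexsnpscan.regions import call_block
from sexsnpscan.sexsnp import SexPatternSNP, Thresholds, classify_frame, window_scan
from sexsnpscan.simulate import (
    SimConfig,
    frequencies_frame,
    simulate_genome,
    simulate_site_xy,
    simulate_sites,
)
from sexsnpscan.pool_io import site_frequencies
from sexsnpscan.simulate import sites_to_pool_counts

SMALL = dict(
    chrom_lengths={"LG1": 4_000_000, "LG2": 2_000_000},
    block_start=1_000_001,
    block_end=2_000_000,
    n_genes=400,
    n_genes_inside=40,
)


def scan_windows(cfg, sites):
    ff = frequencies_frame(sites)
    mask = classify_frame(ff, Thresholds())
    snps = [
        SexPatternSNP(r.chrom, int(r.pos), r.f_male, r.f_female, r.minor_allele)
        for r in ff[mask].itertuples(index=False)
    ]
    elig = ff[(ff.cov_male >= 10) & (ff.cov_female >= 10)]
    return window_scan(snps, list(zip(elig.chrom, elig.pos)), cfg.chrom_lengths)


class TestSimulateSiteXY:
    def test_high_coverage_frequencies(self, rng):
        # law of large numbers at cov 1000, eps 0: f_male -> 0.5, f_female = 0
        rec = simulate_site_xy(100_000, 1000, 0.0, rng)
        f = site_frequencies(rec)
        sigma3 = 3 * 0.5 / np.sqrt(100_000)
        assert abs(f.f_male - 0.5) < sigma3
        assert f.f_female == 0.0

    def test_zero_coverage_pool(self, rng):
        rec = simulate_site_xy(0, 30, 0.0, rng)
        assert rec.cov_male == 0 and rec.cov_female == 30

    def test_qualifying_fraction_at_study_coverages(self, rng):
        # Monte-Carlo: at Poisson coverage 33/37 and eps=0.002, at least 95%
        # of Y-pattern sites pass the classifier
        n = 100_000
        cov_m = rng.poisson(33.0, n)
        cov_f = rng.poisson(37.0, n)
        alt_m = rng.binomial(cov_m, 0.5)
        alt_f = rng.binomial(cov_f, 0.002)
        f_m = np.divide(alt_m, cov_m, out=np.zeros(n), where=cov_m > 0)
        f_f = np.divide(alt_f, cov_f, out=np.zeros(n), where=cov_f > 0)
        qual = (
            (cov_m >= 10) & (cov_f >= 10)
            & (f_m >= 0.3) & (f_m <= 0.7)
            & ((f_f <= 0.1) | (f_f >= 0.9))
        )
        assert qual.mean() >= 0.95


class TestSimulateSites:
    def test_frequencies_frame_matches_pool_io(self, rng):
        cfg = SimConfig(**SMALL)
        sites = simulate_sites(cfg, rng).head(300)
        ff = frequencies_frame(sites)
        for (_, row), rec in zip(ff.iterrows(), sites_to_pool_counts(sites)):
            ref = site_frequencies(rec)
            assert row["minor_allele"] == ref.minor_allele
            assert row["f_male"] == pytest.approx(ref.f_male)
            assert row["f_female"] == pytest.approx(ref.f_female)

    def test_block_density_contrast(self, rng):
        cfg = SimConfig()
        sites = simulate_sites(cfg, rng)
        ff = frequencies_frame(sites)
        mask = classify_frame(ff, Thresholds())
        inside = mask & (ff.chrom == "LG1") & ff.pos.between(cfg.block_start, cfg.block_end)
        d_in = inside.sum() / 8.8
        d_out = (mask & ~inside).sum() / (cfg.genome_length_bp / 1e6 - 8.8)
        assert d_in / max(d_out, 1e-9) > 50

    def test_counts_scale_linearly_with_rate(self):
        counts = []
        for rate in (5e-4, 1e-3, 2e-3):
            cfg = SimConfig(**SMALL, rho_xy=rate)
            rng = np.random.default_rng(5)
            sites = simulate_sites(cfg, rng)
            counts.append((sites["site_class"] == "XY_fixed_diff").sum())
        assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.15)
        assert counts[2] / counts[1] == pytest.approx(2.0, rel=0.15)

    def test_null_genome_calls_no_block(self, rng):
        cfg = SimConfig(rho_xy=0.0)
        windows = scan_windows(cfg, simulate_sites(cfg, rng))
        assert call_block(windows) == []

    def test_zw_polarity_finds_nothing_in_xy_block(self, rng):
        cfg = SimConfig()
        ff = frequencies_frame(simulate_sites(cfg, rng))
        mask = classify_frame(ff, Thresholds(polarity="zw"))
        inside = mask & (ff.chrom == "LG1") & ff.pos.between(cfg.block_start, cfg.block_end)
        # intermediate-in-females / fixed-in-males is not the planted signal
        assert inside.sum() < 0.01 * (ff.chrom == "LG1").sum()


class TestSimulateGenome:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(**SMALL)
        p1 = simulate_genome(cfg, seed=3, outdir=tmp_path / "a")
        p2 = simulate_genome(cfg, seed=3, outdir=tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes(), k

    def test_truth_covers_every_sync_site(self, tmp_path):
        from sexsnpscan.pool_io import read_sync

        cfg = SimConfig(**SMALL)
        paths = simulate_genome(cfg, seed=4, outdir=tmp_path)
        truth = json.load(open(paths["truth"]))
        truth_sites = {(c, p) for c, p, _ in truth["sites"]}
        sync_sites = [(r.chrom, r.pos) for r in read_sync(paths["sync"])]
        assert len(sync_sites) == len(set(sync_sites)) == len(truth_sites)
        assert set(sync_sites) == truth_sites

    def test_block_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="block"):
            SimConfig(chrom_lengths={"LG1": 1_000_000}, block_start=1, block_end=2_000_000)

    def test_expression_bias_fractions(self, rng):
        from sexsnpscan.expression import classify_table
        from sexsnpscan.simulate import simulate_expression

        cfg = SimConfig()
        df, true_bias = simulate_expression(cfg, rng)
        bias = classify_table(df)
        assert len(df) == cfg.n_genes
        # observed female fraction among classified genes tracks the target
        frac = (bias == "female").sum() / bias.isin(["male", "female"]).sum()
        assert frac == pytest.approx(cfg.frac_female_genome, abs=0.02)
        # true labels agree with FPKM-derived classes for non-excluded genes
        merged = df.assign(bias=bias).set_index("gene_id").join(true_bias)
        live = merged[merged["true_bias"] != "excluded"]
        assert (live["bias"] == live["true_bias"]).all()
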