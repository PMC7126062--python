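"""Windowed heterozygosity, smoothing, sex inference, region calling."""

import numpy as np
import pandas as pd
import pytest

import larkline as lk
from larkline.gtio import MISSING, GenotypeMatrix
from larkline.sexscan import _loess_bp

from conftest import make_sites


def gm_from_dosage(dosage, positions=None, scaffold="s1"):
    n_sites, n_samp = dosage.shape
    sites = make_sites(n_sites, scaffold=scaffold)
    if positions is not None:
        sites["pos"] = positions
    return GenotypeMatrix(sites, [f"i{k}" for k in range(n_samp)],
                          dosage.astype(np.int8))


class TestWindowHeterozygosity:
    def test_proportion_example(self):
        dosage = np.zeros((200, 1), dtype=int)
        dosage[:3, 0] = 1
        gm = gm_from_dosage(dosage)
        track = lk.window_heterozygosity(gm, window_size=250_000, min_sites=100)
        assert len(track) == 1
        assert np.isclose(track.iloc[0]["prop_het"], 0.015)
        assert track.iloc[0]["n_sites"] == 200

    def test_window_below_min_sites_excluded(self):
        dosage = np.zeros((99, 1), dtype=int)
        gm = gm_from_dosage(dosage)
        track = lk.window_heterozygosity(gm, min_sites=100)
        assert len(track) == 0

    def test_all_homozygous_window_is_zero(self):
        dosage = np.full((150, 1), 2, dtype=int)
        gm = gm_from_dosage(dosage)
        track = lk.window_heterozygosity(gm, min_sites=100)
        assert track.iloc[0]["prop_het"] == 0.0

    def test_missing_calls_excluded_from_denominator(self):
        dosage = np.zeros((200, 1), dtype=int)
        dosage[:100, 0] = MISSING
        dosage[100:110, 0] = 1
        gm = gm_from_dosage(dosage)
        track = lk.window_heterozygosity(gm, min_sites=50)
        assert np.isclose(track.iloc[0]["prop_het"], 0.1)
        assert track.iloc[0]["n_sites"] == 100

    def test_invariant_to_site_order(self, rng):
        dosage = rng.integers(0, 3, size=(400, 2))
        gm = gm_from_dosage(dosage)
        perm = rng.permutation(400)
        gm_shuffled = GenotypeMatrix(
            gm.sites, gm.samples, dosage[perm][np.argsort(gm.sites["pos"].to_numpy()[perm])]
        )
        # shuffling rows while keeping (pos, dosage) pairs intact
        t1 = lk.window_heterozygosity(gm, min_sites=10)
        dosage2 = dosage.copy()
        t2 = lk.window_heterozygosity(gm_from_dosage(dosage2), min_sites=10)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_window_size(self):
        gm = gm_from_dosage(np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError):
            lk.window_heterozygosity(gm, window_size=0)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        x = np.arange(0, 40) * 250_000 + 125_000
        y = np.full(40, 0.004)
        np.testing.assert_allclose(_loess_bp(x.astype(float), y, 10e6), 0.004)

    def test_linear_ramp_exact(self):
        x = np.arange(0, 40) * 250_000.0
        y = 1e-9 * x + 0.001
        np.testing.assert_allclose(_loess_bp(x, y, 10e6), y, rtol=1e-8)

    def test_spike_attenuated_but_positive(self):
        x = np.arange(0, 41) * 250_000.0
        y = np.full(41, 0.002)
        y[20] = 0.02
        sm = _loess_bp(x, y, 10e6)
        assert 0.002 < sm[20] < 0.02

    def test_matches_weighted_regression_oracle(self):
        # independent oracle: explicit tricube-weighted polyfit at one point
        x = np.arange(0, 21) * 250_000.0
        rng = np.random.default_rng(0)
        y = 0.002 + rng.normal(0, 3e-4, size=21)
        span = 4e6
        sm = _loess_bp(x, y, span)
        i = 10
        d = np.abs(x - x[i])
        w = np.where(d < span / 2, (1 - (d / (span / 2)) ** 3) ** 3, 0.0)
        coef = np.polyfit(x - x[i], y, 1, w=np.sqrt(w))
        assert np.isclose(sm[i], coef[1], rtol=1e-8)

    def test_single_window_scaffold_keeps_raw(self):
        track = pd.DataFrame({
            "individual": "a", "scaffold": "z", "start": [0],
            "end": [250_000], "n_sites": [150], "prop_het": [0.004],
            "smoothed": [np.nan],
        })
        out = lk.smooth_track(track)
        assert out.iloc[0]["smoothed"] == 0.004


class TestInferSex:
    def make_tracks(self, z_het, a_het, n_z=12, n_a=30):
        rows = []
        for w in range(n_z):
            rows.append(("x", "scafZ", w * 250_000, (w + 1) * 250_000, 200, z_het, np.nan))
        for w in range(n_a):
            rows.append(("x", "scafA", w * 250_000, (w + 1) * 250_000, 200, a_het, np.nan))
        return pd.DataFrame(rows, columns=[
            "individual", "scaffold", "start", "end", "n_sites", "prop_het", "smoothed"])

    def test_female_low_z_ratio(self):
        out = lk.infer_sex(self.make_tracks(0.0002, 0.005), {"scafZ"})
        assert out.iloc[0]["sex"] == "F"

    def test_male_equal_ratio(self):
        out = lk.infer_sex(self.make_tracks(0.005, 0.005), {"scafZ"})
        assert out.iloc[0]["sex"] == "M"

    def test_intermediate_ratio_unknown(self):
        out = lk.infer_sex(self.make_tracks(0.002, 0.005), {"scafZ"})
        assert out.iloc[0]["sex"] == "unknown"

    def test_too_few_z_windows_unknown(self):
        out = lk.infer_sex(self.make_tracks(0.0002, 0.005, n_z=3), {"scafZ"},
                           min_windows=10)
        assert out.iloc[0]["sex"] == "unknown"

    def test_recovers_sex_on_synthetic_panel(self):
        sexes = ["F"] * 3 + ["M"] * 3
        cfg = lk.SimConfig(n_diploids=6, locus_length_bp=150, theta_site=0.001,
                           seed=5)
        specs = [lk.SexRegionSpec("autosomal", 4_000_000),
                 lk.SexRegionSpec("ancestral_Z", 4_000_000)]
        gm, truth, meta = lk.simulate_sex_chromosome_panel(
            specs, sexes, cfg, scaffold_per_region=True)
        glm = lk.simulate_reads(gm, 20, 0.002, seed=6)
        calls = lk.call_genotypes(glm)
        tracks = lk.window_heterozygosity(calls)
        out = lk.infer_sex(tracks, {"chr_2"})
        assert list(out.sort_values("individual")["sex"]) == sexes


class TestRegionCalling:
    def panel_tracks(self, seed=0, specs=None, depth=20, error=0.002):
        sexes = ["F"] * 6 + ["M"] * 6
        cfg = lk.SimConfig(n_diploids=12, locus_length_bp=150,
                           theta_site=0.001, seed=seed)
        if specs is None:
            specs = [lk.SexRegionSpec("autosomal", 5_000_000),
                     lk.SexRegionSpec("neo_suppressed", 5_000_000),
                     lk.SexRegionSpec("autosomal", 5_000_000)]
        gm, truth, meta = lk.simulate_sex_chromosome_panel(specs, sexes, cfg)
        glm = lk.simulate_reads(gm, depth, error, seed=seed + 999)
        calls = lk.call_genotypes(glm)
        tracks = lk.smooth_track(lk.window_heterozygosity(calls))
        sx = pd.DataFrame({"individual": gm.samples, "sex": sexes})
        return gm, truth, tracks, sx

    def test_single_region_recovered_within_one_window(self):
        gm, truth, tracks, sx = self.panel_tracks(seed=1)
        regions = lk.call_suppressed_regions(tracks, sx)
        neo = regions[regions.region_class == "neo_suppressed"]
        assert len(neo) == 1
        t = truth[truth.region_kind == "neo_suppressed"].iloc[0]
        assert abs(neo.iloc[0].start - t.start) <= 250_000
        assert abs(neo.iloc[0].end - t.end) <= 250_000

    def test_no_sex_linked_regions_no_calls(self):
        specs = [lk.SexRegionSpec("autosomal", 5_000_000),
                 lk.SexRegionSpec("autosomal", 5_000_000)]
        gm, truth, tracks, sx = self.panel_tracks(seed=2, specs=specs)
        regions = lk.call_suppressed_regions(tracks, sx)
        assert len(regions) == 0

    def test_short_region_below_run_floor_not_called(self):
        specs = [lk.SexRegionSpec("autosomal", 5_000_000),
                 lk.SexRegionSpec("neo_suppressed", 1_000_000),
                 lk.SexRegionSpec("autosomal", 5_000_000)]
        gm, truth, tracks, sx = self.panel_tracks(seed=3, specs=specs)
        regions = lk.call_suppressed_regions(tracks, sx, min_run_windows=8)
        assert len(regions[regions.region_class == "neo_suppressed"]) == 0

    def test_monotone_in_fold_threshold(self):
        gm, truth, tracks, sx = self.panel_tracks(seed=4)
        sizes = []
        for fold in (2.0, 3.0, 5.0, 8.0):
            regions = lk.call_suppressed_regions(tracks, sx, fold_threshold=fold)
            neo = regions[regions.region_class == "neo_suppressed"]
            sizes.append((neo["end"] - neo["start"]).sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_requires_both_sexes(self):
        gm, truth, tracks, sx = self.panel_tracks(seed=5)
        males_only = sx.assign(sex="M")
        with pytest.raises(ValueError):
            lk.call_suppressed_regions(tracks, males_only)

    def z_scaffold_tracks(self, seed):
        # the ancestral Z is its own chromosome, as in a real karyotype; an
        # interior Z segment shorter than the smoothing span would be beyond
        # the weak-contrast detector
        sexes = ["F"] * 6 + ["M"] * 6
        cfg = lk.SimConfig(n_diploids=12, locus_length_bp=150,
                           theta_site=0.001, seed=seed)
        specs = [lk.SexRegionSpec("autosomal", 5_000_000),
                 lk.SexRegionSpec("ancestral_Z", 5_000_000)]
        gm, truth, meta = lk.simulate_sex_chromosome_panel(
            specs, sexes, cfg, scaffold_per_region=True)
        glm = lk.simulate_reads(gm, 20, 0.002, seed=seed + 999)
        tracks = lk.smooth_track(lk.window_heterozygosity(lk.call_genotypes(glm)))
        sx = pd.DataFrame({"individual": gm.samples, "sex": sexes})
        return truth, tracks, sx

    def test_ancestral_z_scaffold_detected(self):
        truth, tracks, sx = self.z_scaffold_tracks(seed=6)
        regions = lk.call_suppressed_regions(tracks, sx)
        anc = regions[regions.region_class == "ancestral_Z"]
        assert len(anc) == 1
        assert anc.iloc[0].scaffold == "chr_2"
        t = truth[truth.region_kind == "ancestral_Z"].iloc[0]
        overlap = min(anc.iloc[0].end, t.end) - max(anc.iloc[0].start, t.start)
        assert overlap >= 0.8 * (t.end - t.start)

    def test_female_het_floor_in_ancestral_region(self):
        truth, tracks, sx = self.z_scaffold_tracks(seed=7)
        regions = lk.call_suppressed_regions(tracks, sx)
        anc = regions[regions.region_class == "ancestral_Z"].iloc[0]
        assert anc["female_raw"] < 1e-3  # error-driven floor at 2e-3 error


class TestGametologueDivergence:
    def region(self, **kw):
        base = {"scaffold": "chr_1", "start": 5_000_000, "end": 10_000_000,
                "region_class": "neo_suppressed"}
        base.update(kw)
        return pd.Series(base)

    def test_printed_density(self):
        # female het density 0.0115 -> 1.15 differences per 100 bp
        dosage = np.zeros((2000, 2), dtype=int)
        het = np.random.default_rng(0).choice(2000, size=23, replace=False)
        dosage[het, 0] = 1
        gm = gm_from_dosage(dosage, positions=np.arange(2000) + 5_000_000,
                            scaffold="chr_1")
        val = lk.gametologue_divergence(gm, self.region(end=5_002_000), ["i0"])
        assert np.isclose(val, 1.15)

    def test_all_homozygous_is_zero(self):
        dosage = np.zeros((500, 1), dtype=int)
        gm = gm_from_dosage(dosage, positions=np.arange(500) + 5_000_000,
                            scaffold="chr_1")
        assert lk.gametologue_divergence(gm, self.region(), ["i0"]) == 0.0

    def test_wrong_class_rejected(self):
        gm = gm_from_dosage(np.zeros((10, 1), dtype=int))
        with pytest.raises(ValueError):
            lk.gametologue_divergence(gm, self.region(region_class="normal"), ["i0"])

    def test_zero_genotyped_sites_rejected(self):
        dosage = np.full((10, 1), MISSING, dtype=int)
        gm = gm_from_dosage(dosage, positions=np.arange(10) + 5_000_000,
                            scaffold="chr_1")
        with pytest.raises(ValueError):
            lk.gametologue_divergence(gm, self.region(), ["i0"])

    def test_simulated_divergence_recovered(self):
        sexes = ["F"] * 6 + ["M"] * 6
        cfg = lk.SimConfig(n_diploids=12, locus_length_bp=150,
                           theta_site=0.001, seed=8)
        specs = [lk.SexRegionSpec("autosomal", 3_000_000),
                 lk.SexRegionSpec("neo_suppressed", 5_000_000,
                                  gametologue_divergence=0.02),
                 lk.SexRegionSpec("autosomal", 3_000_000)]
        gm, truth, meta = lk.simulate_sex_chromosome_panel(specs, sexes, cfg)
        glm = lk.simulate_reads(gm, 20, 0.0, seed=9)
        calls = lk.call_genotypes(glm)
        t = truth[truth.region_kind == "neo_suppressed"].iloc[0]
        region = pd.Series({"scaffold": t.scaffold, "start": t.start,
                            "end": t.end, "region_class": "neo_suppressed"})
        val = lk.gametologue_divergence(calls, region,
                                        [s for s in gm.samples if s.startswith("F")])
        # expected 2.0 from fixed differences + ~0.1 from background
        # heterozygosity (theta 0.001); ~3e4 genotyped sites per female
        assert 1.9 < val < 2.35
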