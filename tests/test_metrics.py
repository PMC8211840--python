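"""Balance metrics, stutter statistics, sensitivity and cross-reactivity."""

import numpy as np
import pandas as pd
import pytest

from poppystr import genotyping as g, metrics as vm
from poppystr.synthetic import (SimulationConfig, StutterParams,
                                generate_varieties, simulate_profiles)


def calls_frame(entries):
    """entries: (sample, assay, marker, zygosity, heights dict)"""
    return pd.DataFrame(
        [{"sample_id": s, "variety": "V", "marker": m, "assay": a,
          "dose_ng": 1.25, "zygosity": z,
          "allele1": sorted(h)[0] if h else None,
          "allele2": sorted(h)[-1] if h else None, "heights": h,
          "flags": ""} for s, a, m, z, h in entries])


class TestNormalize:
    def test_heterozygote_heights_averaged(self):
        calls = calls_frame([("S1", "A", "M1", "het",
                              {"8": 1000, "9": 800})])
        out = vm.normalize_profile(calls)
        assert out["norm_height"].iloc[0] == 900.0

    def test_homozygote_height_halved(self):
        calls = calls_frame([("S1", "A", "M1", "hom", {"8": 1000})])
        out = vm.normalize_profile(calls)
        assert out["norm_height"].iloc[0] == 500.0

    def test_equal_het_peaks_keep_their_height(self):
        calls = calls_frame([("S1", "A", "M1", "het",
                              {"8": 700, "9": 700})])
        assert vm.normalize_profile(calls)["norm_height"].iloc[0] == 700.0


class TestIelb:
    def make_norm(self, heights):
        return pd.DataFrame(
            [{"sample_id": "S1", "variety": "V", "assay": "A",
              "marker": f"M{i}", "dose_ng": 1.25, "norm_height": h}
             for i, h in enumerate(heights)])

    def test_hand_arithmetic(self):
        out = vm.ielb(self.make_norm([1000, 2000, 3000]))
        assert out["ielb"].tolist() == [0.5, 1.0, 1.5]

    def test_equal_heights_all_one(self):
        out = vm.ielb(self.make_norm([1500] * 4))
        assert np.allclose(out["ielb"], 1.0)

    def test_profile_mean_is_one_identity(self, rng):
        out = vm.ielb(self.make_norm(rng.uniform(100, 5000, size=9)))
        assert out["ielb"].mean() == pytest.approx(1.0)


class TestIcb:
    def test_min_over_max(self, panel):
        markers = [m for m in panel if m.assay == "MTP1"
                   and m.dye == "6-FAM"][:2]
        norm = pd.DataFrame(
            [{"sample_id": "S1", "variety": "V", "assay": "MTP1",
              "marker": m.name, "dose_ng": 1.25, "norm_height": h}
             for m, h in zip(markers, (800, 1000))])
        out = vm.icb(norm, panel)
        assert out["icb"].iloc[0] == pytest.approx(0.8)

    def test_single_locus_dye_returns_one_with_flag(self, panel):
        m = next(iter(panel))
        norm = pd.DataFrame([{"sample_id": "S1", "variety": "V",
                              "assay": m.assay, "marker": m.name,
                              "dose_ng": 1.25, "norm_height": 1234.0}])
        out = vm.icb(norm, panel)
        assert out["icb"].iloc[0] == 1.0 and out["single_locus"].iloc[0]

    def test_scale_invariant(self, panel, rng):
        markers = [m for m in panel if m.assay == "MTP1"][:6]
        h = rng.uniform(200, 4000, size=len(markers))
        def frame(scale):
            return pd.DataFrame(
                [{"sample_id": "S1", "variety": "V", "assay": "MTP1",
                  "marker": m.name, "dose_ng": 1.25,
                  "norm_height": scale * x}
                 for m, x in zip(markers, h)])
        a = vm.icb(frame(1.0), panel)
        b = vm.icb(frame(7.3), panel)
        assert np.allclose(a["icb"], b["icb"])


class TestHetBalance:
    def het_call(self, panel, h_small, h_large):
        m = next(iter(panel))
        small, large = m.alleles[0], m.alleles[1]
        return calls_frame([("S1", m.assay, m.name, "het",
                             {small: h_small, large: h_large})]), m

    def test_hmw_lower_gives_hb_below_one(self, panel):
        calls, m = self.het_call(panel, 1200, 900)
        out = vm.het_balance(calls, panel).iloc[0]
        assert out["Hb"] == pytest.approx(0.75)
        assert out["Hb_prime"] == pytest.approx(0.75)

    def test_hmw_higher_gives_hb_above_one(self, panel):
        calls, m = self.het_call(panel, 900, 1200)
        out = vm.het_balance(calls, panel).iloc[0]
        assert out["Hb"] == pytest.approx(4 / 3)
        assert out["Hb_prime"] == pytest.approx(0.75)

    def test_equal_heights_both_one(self, panel):
        calls, _ = self.het_call(panel, 1000, 1000)
        out = vm.het_balance(calls, panel).iloc[0]
        assert out["Hb"] == out["Hb_prime"] == 1.0

    def test_hb_prime_is_min_of_hb_and_reciprocal(self, panel, rng):
        for _ in range(25):
            h1, h2 = rng.integers(100, 5000, size=2)
            calls, _ = self.het_call(panel, int(h1), int(h2))
            out = vm.het_balance(calls, panel).iloc[0]
            assert out["Hb_prime"] == pytest.approx(
                min(out["Hb"], 1 / out["Hb"]))
            assert out["Hb_prime"] <= 1.0


@pytest.fixture(scope="module")
def calls(panel):
    truth = generate_varieties(panel, 6, 6, allele_pool_size=2,
                               residual_het_rate=0.4, seed=50)
    cfg = SimulationConfig(seed=51, dropout=None)
    peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, 1.25)
    inventory = {m.name: list(m.alleles) for m in panel}
    _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
    return g.call_genotypes(g.apply_threshold(peaks, 200), ladder, panel)


class TestMetricIdentitiesOnSimulation:
    """IELB/ICB/Hb' identities asserted over simulated profiles."""

    def test_mean_ielb_is_one_per_complete_profile(self, calls):
        norm = vm.normalize_profile(calls)
        out = vm.ielb(norm)
        means = out.groupby(["sample_id", "assay"])["ielb"].mean()
        assert np.allclose(means, 1.0)

    def test_hb_prime_bounded_and_consistent(self, calls, panel):
        het = vm.het_balance(calls, panel)
        assert len(het) > 100
        assert (het["Hb_prime"] <= 1.0 + 1e-12).all()
        assert np.allclose(het["Hb_prime"],
                           np.minimum(het["Hb"], 1 / het["Hb"]))

    def test_balance_metrics_scale_invariant_under_global_gain(
            self, panel):
        truth = generate_varieties(panel, 3, 3, allele_pool_size=2,
                                   residual_het_rate=0.4, seed=52)
        inventory = {m.name: list(m.alleles) for m in panel}
        _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
        outs = []
        for gain in (1.0, 2.5):
            cfg = SimulationConfig(
                seed=53, dropout=None,
                dye_gains={d: gain for d in
                           {m.dye for m in panel}})
            peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, 1.25)
            calls = g.call_genotypes(g.apply_threshold(peaks, 0), ladder,
                                     panel)
            norm = vm.normalize_profile(calls)
            outs.append((vm.ielb(norm)["ielb"].to_numpy(),
                         vm.icb(norm, panel)["icb"].to_numpy(),
                         vm.het_balance(calls, panel)["Hb_prime"]
                         .to_numpy()))
        for a, b in zip(*outs):
            # integer rfu rounding dominates for the smallest peaks
            assert np.allclose(a, b, rtol=0.03, atol=5e-4)


class TestStutterStats:
    def test_ratio_definition(self):
        obs = pd.DataFrame([{"sample_id": "S1", "marker": "M",
                             "parent_allele": "10", "parent_repeats": 10,
                             "type": "n-k", "phi_S": 80, "phi_A": 1600,
                             "S_R": 80 / 1600}])
        out = vm.stutter_stats(obs)
        assert out["groups"][("M", "n-k")].mean == pytest.approx(0.05)

    def test_single_observation_summary(self):
        obs = pd.DataFrame([{"sample_id": "S1", "marker": "M",
                             "parent_allele": "10", "parent_repeats": 10,
                             "type": "n-k", "phi_S": 50, "phi_A": 1000,
                             "S_R": 0.05}])
        s = vm.stutter_stats(obs)["groups"][("M", "n-k")]
        assert s.mean == s.median == 0.05
        assert s.sd == 0.0 and s.n == 1

    def test_threshold_is_mean_plus_three_sd(self, rng):
        vals = rng.normal(0.06, 0.01, size=200)
        obs = pd.DataFrame({"sample_id": "S", "marker": "M",
                            "parent_allele": "9", "parent_repeats": 9,
                            "type": "n-k", "phi_S": 1, "phi_A": 1,
                            "S_R": vals})
        out = vm.stutter_stats(obs)
        s = out["groups"][("M", "n-k")]
        assert out["thresholds"][("M", "n-k")] == pytest.approx(
            s.mean + 3 * s.sd)

    def test_filter_at_mean_plus_3sd_removes_gaussian_stutters(self, rng):
        # >= 99% of Gaussian stutter ratios fall under mean + 3*SD
        vals = rng.normal(0.08, 0.015, size=5000)
        thr = vals.mean() + 3 * vals.std(ddof=1)
        assert (vals <= thr).mean() >= 0.99

    def test_slope_recovery_from_simulator(self, panel):
        # S_R = 0.02 + 0.004 * NR: regression on per-allele means recovers
        # the slope within 15% at ~1000 observations
        cfg = SimulationConfig(seed=60,
                               stutter={"n-k": StutterParams(0.02, 0.004)},
                               series_1bp_ratios=(0.0, 0.0, 0.0),
                               dropout=None)
        truth = generate_varieties(panel, 8, 6, allele_pool_size=3,
                                   residual_het_rate=0.3, seed=61)
        peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, 1.25)
        inventory = {m.name: list(m.alleles) for m in panel}
        _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
        thresh = g.apply_threshold(peaks, 200)
        calls = g.call_genotypes(thresh, ladder, panel,
                                 stutter_thresholds={m.name: 0.0
                                                     for m in panel})
        obs = g.classify_stutters(thresh, calls, panel)
        obs = obs[obs["type"] == "n-k"]
        assert len(obs) >= 1000
        am = (obs.groupby(["parent_allele", "parent_repeats"])["S_R"]
              .mean().reset_index())
        slope = np.polyfit(am["parent_repeats"], am["S_R"], 1)[0]
        assert abs(slope - 0.004) / 0.004 < 0.15


class TestSensitivity:
    def test_noise_free_high_dose_all_full_profiles(self, panel):
        truth = generate_varieties(panel, 3, 3, allele_pool_size=2,
                                   residual_het_rate=0.3, seed=70)
        cfg = SimulationConfig(seed=71, dropout=None)
        peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, 1.25)
        inventory = {m.name: list(m.alleles) for m in panel}
        _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
        calls = g.call_genotypes(g.apply_threshold(peaks, 200), ladder,
                                 panel)
        rep = vm.sensitivity_report(calls, truth.genotypes, panel)
        assert rep["full_profiles"].iloc[0] == rep["n_samples"].iloc[0]
        assert rep["locus_dropouts"].iloc[0] == 0

    def test_dose_below_d50_drops_most_loci(self, panel):
        truth = generate_varieties(panel, 4, 5, allele_pool_size=2,
                                   residual_het_rate=0.3, seed=72)
        cfg = SimulationConfig(seed=73)  # d50 = 0.2 ng
        peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, 0.05)
        inventory = {m.name: list(m.alleles) for m in panel}
        _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
        calls = g.call_genotypes(g.apply_threshold(peaks, 50), ladder,
                                 panel)
        rep = vm.sensitivity_report(calls, truth.genotypes, panel)
        n_loci = len(calls)
        assert rep["locus_dropouts"].iloc[0] > 0.5 * n_loci

    def test_hb_prime_degrades_with_dose(self, panel):
        truth = generate_varieties(panel, 6, 6, allele_pool_size=2,
                                   residual_het_rate=0.6, seed=74)
        inventory = {m.name: list(m.alleles) for m in panel}
        _, ladder = g.build_ladder(inventory, truth.genotypes, panel)
        frames = []
        for dose in (1.25, 0.078):
            cfg = SimulationConfig(seed=75, dropout=None)
            peaks, _ = simulate_profiles(truth.genotypes, panel, cfg, dose)
            frames.append(g.call_genotypes(
                g.apply_threshold(peaks, 25), ladder, panel))
        calls = pd.concat(frames, ignore_index=True)
        rep = vm.sensitivity_report(calls, truth.genotypes, panel)
        rep = rep.set_index("dose_ng")
        assert rep.loc[0.078, "Hb_prime_mean"] \
            <= rep.loc[1.25, "Hb_prime_mean"] + 0.02


class TestCrossReactivity:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["taxon", "marker", "height_rfu"])

    def test_all_below_threshold_counts_zero(self):
        peaks = self.frame([("P. rhoeas", "M1", 150),
                            ("P. rhoeas", "M2", 199)])
        out = vm.cross_reactivity(peaks, 200)
        assert out["n_markers_amplifying"].iloc[0] == 0

    def test_marker_counted_once_regardless_of_peaks(self):
        peaks = self.frame([("P. glaucum", "M1", 201),
                            ("P. glaucum", "M1", 900),
                            ("P. glaucum", "M1", 2500)])
        out = vm.cross_reactivity(peaks, 200)
        assert out["n_markers_amplifying"].iloc[0] == 1

    def test_constructed_13_of_27_markers(self):
        rows = [("P. bracteatum", f"M{i:02d}", 500) for i in range(13)]
        rows += [("P. bracteatum", f"M{i:02d}", 50) for i in range(13, 27)]
        out = vm.cross_reactivity(self.frame(rows), 200)
        assert out["n_markers_amplifying"].iloc[0] == 13

    def test_near_threshold_reported_separately(self):
        peaks = self.frame([("H. lupulus", "M1", 210),
                            ("H. lupulus", "M2", 5000)])
        out = vm.cross_reactivity(peaks, 200, near_factor=1.5).iloc[0]
        assert out["n_markers_amplifying"] == 2
        assert out["near_threshold_markers"] == "M1"
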