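import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hiphoptools import (AnalysisConfig, ScreenMatrix, adjust_madl,
                         average_tags, background_filter,
                         fd_significance_threshold, genewise_z_hiplab,
                         genewise_z_nibr, harmonize_orientation,
                         log2_ratio_hiplab, log2_ratio_nibr,
                         median_polish_normalize, normalize_by_study,
                         robust_z, select_best_tag, significance_mask)
from hiphoptools.scoring import QCReport

from .conftest import make_tag_table
from .oracles import (genewise_z_row, median_polish_batch_effects,
                      robust_z_column)


class TestMedianPolish:
    def test_identical_arrays_unchanged_up_to_offset(self):
        sig = {(f"g{i}", "up"): {"c1": 100.0 * (i + 1), "c2": 100.0 * (i + 1),
                                 "t1": 100.0 * (i + 1)} for i in range(5)}
        table = make_tag_table(sig)
        out = median_polish_normalize(table)
        r_in = np.log2(table.records["signal"])
        r_out = np.log2(out.records["signal"])
        offsets = r_out - r_in
        assert np.allclose(offsets, offsets.iloc[0], atol=1e-9)

    def test_pure_array_shift_removed(self):
        rng = np.random.default_rng(0)
        base = {f"g{i}": float(2 ** rng.normal(8, 1)) for i in range(20)}
        sig = {(g, "up"): {"c1": v, "c2": v, "c3": v * 2.0}  # +1 log2 shift
               for g, v in base.items()}
        out = median_polish_normalize(make_tag_table(sig))
        wide = out.records.pivot_table(index="strain_id", columns="array_id",
                                       values="signal")
        np.testing.assert_allclose(wide["c3"], wide["c1"], rtol=1e-6)

    def test_planted_batch_offsets_recovered_vs_oracle(self, rng):
        # 20 strains x 6 arrays, batches at +0.5 / -0.5 log2 units
        strains = [f"g{i}" for i in range(20)]
        arrays = [f"a{j}" for j in range(6)]
        batch = {a: ("b+" if j < 3 else "b-") for j, a in enumerate(arrays)}
        base = rng.normal(8, 1, size=20)
        log2sig = base[:, None] + rng.normal(0, 0.05, size=(20, 6))
        log2sig[:, :3] += 0.5
        log2sig[:, 3:] -= 0.5
        role = {a: ("control" if j < 5 else "treatment")
                for j, a in enumerate(arrays)}
        sig = {(g, "up"): {a: float(2 ** log2sig[i, j])
                           for j, a in enumerate(arrays)}
               for i, g in enumerate(strains)}
        table = make_tag_table(sig, role=role, batch=batch)
        out = median_polish_normalize(table)
        _, _, b_eff = median_polish_batch_effects(
            log2sig, [batch[a] for a in arrays])
        assert b_eff["b+"] - b_eff["b-"] == pytest.approx(1.0, abs=0.05)
        # corrected data: batch medians agree
        wide = np.log2(out.records.pivot_table(index="strain_id",
                                               columns="array_id",
                                               values="signal"))
        diff = np.median(wide[arrays[:3]].to_numpy()) \
            - np.median(wide[arrays[3:]].to_numpy())
        assert abs(diff) < 0.05

    def test_single_array_returned_unchanged(self):
        sig = {("g1", "up"): {"c1": 100.0}, ("g2", "up"): {"c1": 50.0}}
        table = make_tag_table(sig)
        out = median_polish_normalize(table)
        pd.testing.assert_frame_equal(out.records, table.records)


class TestStudyNormalization:
    def test_identical_arrays_unchanged(self):
        sig = {(f"g{i}", "up"): {"c1": 10.0 + i, "c2": 10.0 + i}
               for i in range(10)}
        table = make_tag_table(sig)
        out = normalize_by_study(table)
        np.testing.assert_allclose(out.records["signal"],
                                   table.records["signal"], rtol=1e-12)

    def test_monotone_transform_equalizes_distributions(self, rng):
        vals = np.sort(2 ** rng.normal(8, 1, 30))
        sig = {(f"g{i:02d}", "up"): {"c1": float(vals[i]),
                                     "c2": float(vals[i] ** 1.2)}
               for i in range(30)}
        out = normalize_by_study(make_tag_table(sig))
        wide = out.records.pivot_table(index="strain_id", columns="array_id",
                                       values="signal")
        np.testing.assert_allclose(np.sort(wide["c1"]), np.sort(wide["c2"]),
                                   rtol=1e-10)

    def test_planted_scale_factor_removed(self, rng):
        base = 2 ** rng.normal(8, 1, 25)
        sig = {(f"g{i:02d}", "up"): {"c1": float(base[i]),
                                     "c2": float(2.0 * base[i])}
               for i in range(25)}
        out = normalize_by_study(make_tag_table(sig))
        wide = out.records.pivot_table(index="strain_id", columns="array_id",
                                       values="signal")
        np.testing.assert_allclose(wide["c2"] / wide["c1"], 1.0, rtol=1e-9)


class TestBackgroundFilter:
    def test_tag_at_background_level_fails(self):
        sig = {("g1", "up"): {"c1": 50.0}, ("g2", "up"): {"c1": 5000.0}}
        table = make_tag_table(sig, background={"c1": [50.0] * 10})
        q = background_filter(table).set_index(["strain_id", "tag"])
        # MAD=0 boundary: threshold == 50, signal 50 is not > threshold
        assert not q.loc[("g1", "up"), "passes_background"]
        assert q.loc[("g2", "up"), "passes_background"]

    def test_planted_dead_tags_exactly_flagged(self, rng):
        bg_level = 60.0
        sig = {}
        dead = {f"g{i:02d}" for i in range(0, 20, 5)}
        for i in range(20):
            g = f"g{i:02d}"
            level = bg_level if g in dead else 5000.0
            sig[(g, "up")] = {"c1": level * float(2 ** rng.normal(0, 0.05)),
                              "c2": level * float(2 ** rng.normal(0, 0.05))}
        bg = {a: list(bg_level * 2 ** rng.normal(0, 0.05, 30))
              for a in ("c1", "c2")}
        q = background_filter(make_tag_table(sig, background=bg))
        failed = set(q.loc[~q["passes_background"], "strain_id"])
        assert failed == dead

    def test_no_background_features_passes_all_with_warning(self):
        sig = {("g1", "up"): {"c1": 10.0}}
        report = QCReport()
        q = background_filter(make_tag_table(sig), report=report)
        assert q["passes_background"].all()
        assert report.warnings


class TestBestTag:
    def test_constant_tag_beats_noisy_tag(self):
        sig = {("g1", "up"): {"c1": 100.0, "c2": 100.0, "c3": 100.0},
               ("g1", "down"): {"c1": 50.0, "c2": 150.0, "c3": 100.0}}
        best = select_best_tag(make_tag_table(sig))
        assert best.loc[best["strain_id"] == "g1", "tag"].item() == "up"
        assert best.loc[best["strain_id"] == "g1", "robust_cv"].item() == 0.0

    def test_tie_goes_to_uptag(self):
        series = {"c1": 90.0, "c2": 100.0, "c3": 110.0}
        sig = {("g1", "up"): dict(series), ("g1", "down"): dict(series)}
        best = select_best_tag(make_tag_table(sig))
        assert best.loc[best["strain_id"] == "g1", "tag"].item() == "up"

    def test_bad_tags_mostly_avoided_on_generated_fixture(self):
        from hiphoptools import SimulationConfig, generate_tag_intensities
        hits = total = 0
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_strains=100, n_classes=2,
                                   bad_tag_fraction=0.3,
                                   bad_tag_noise_factor=8.0,
                                   n_treatment_screens=2, n_control_arrays=6,
                                   n_background_features=10)
            table, _ = generate_tag_intensities(cfg)
            # ground truth: regenerate the bad-tag draw pattern via variance
            ctl = table.records[(table.records["role"] == "control")
                                & table.records["used"]]
            sd = np.log2(ctl.set_index(["strain_id", "tag", "array_id"])["signal"]) \
                .groupby(["strain_id", "tag"]).std()
            best = select_best_tag(table)
            for _, row in best.iterrows():
                pair_sd = sd.loc[row["strain_id"]]
                if pair_sd.max() / pair_sd.min() < 2:
                    continue  # both tags comparable; no planted contrast
                total += 1
                hits += row["tag"] == pair_sd.idxmin()
        assert total > 20
        assert hits / total >= 0.95


class TestTagAveraging:
    def test_mean_of_two_tags(self):
        sig = {("g1", "up"): {"c1": 100.0, "t1": 100.0},
               ("g1", "down"): {"c1": 200.0, "t1": 300.0}}
        bg = {"c1": [1.0] * 5, "t1": [1.0] * 5}
        avg = average_tags(make_tag_table(sig, background=bg))
        assert avg.loc["g1", "c1"] == 150.0
        assert avg.loc["g1", "t1"] == 200.0

    def test_single_passing_tag_passthrough_and_oracle(self, rng):
        sig = {}
        for i in range(10):
            sig[(f"g{i}", "up")] = {"c1": float(2 ** rng.normal(8, 1)),
                                    "c2": float(2 ** rng.normal(8, 1))}
            if i % 2 == 0:
                sig[(f"g{i}", "down")] = {"c1": float(2 ** rng.normal(8, 1)),
                                          "c2": float(2 ** rng.normal(8, 1))}
        bg = {"c1": [1.0] * 5, "c2": [1.0] * 5}
        table = make_tag_table(sig, background=bg)
        avg = average_tags(table)
        for i in range(10):
            g = f"g{i}"
            expected = np.mean([sig[(g, t)]["c1"] for t in ("up", "down")
                                if (g, t) in sig])
            assert avg.loc[g, "c1"] == pytest.approx(expected, rel=1e-12)


class TestLogRatios:
    @pytest.mark.parametrize("ctrls,trt,expected", [
        ([100.0, 100.0, 100.0], 100.0, 0.0),
        ([200.0, 200.0], 50.0, 2.0),
        ([90.0, 100.0, 110.0], 400.0, -2.0),
    ])
    def test_hiplab_convention(self, ctrls, trt, expected):
        controls = pd.DataFrame({f"c{i}": [v] for i, v in enumerate(ctrls)},
                                index=["g1"])
        r = log2_ratio_hiplab(controls, pd.Series({"g1": trt}))
        assert r["g1"] == pytest.approx(expected)

    @pytest.mark.parametrize("reps,ctrls,expected", [
        ([100.0], [100.0], 0.0),
        ([50.0, 50.0], [200.0, 200.0], -2.0),
    ])
    def test_nibr_convention(self, reps, ctrls, expected):
        t = pd.DataFrame({f"t{i}": [v] for i, v in enumerate(reps)}, index=["g"])
        c = pd.DataFrame({f"c{i}": [v] for i, v in enumerate(ctrls)}, index=["g"])
        assert log2_ratio_nibr(t, c)["g"] == pytest.approx(expected)

    def test_nonpositive_signal_dropped(self):
        controls = pd.DataFrame({"c1": [100.0, 100.0]}, index=["g1", "g2"])
        trt = pd.Series({"g1": 0.0, "g2": 50.0})
        r = log2_ratio_hiplab(controls, trt)
        assert list(r.index) == ["g2"]


class TestRobustZ:
    def test_hand_computed_column(self):
        m = ScreenMatrix(pd.DataFrame({"s": [1.0, 2.0, 3.0]},
                                      index=["a", "b", "c"]))
        z = robust_z(m)
        np.testing.assert_allclose(z.values["s"], [-1.0, 0.0, 1.0])

    def test_output_median_zero_mad_one_exactly(self, rng):
        # odd column length: median and MAD of the output are exact
        vals = rng.normal(size=(101, 6))
        m = ScreenMatrix(pd.DataFrame(vals))
        z = robust_z(m).values
        for col in z.columns:
            x = z[col].to_numpy()
            assert float(np.median(x)) == 0.0
            assert float(np.median(np.abs(x))) == 1.0

    def test_matches_bruteforce_oracle(self, random_matrix):
        z = robust_z(random_matrix)
        for col in random_matrix.values.columns:
            expected = robust_z_column(random_matrix.values[col].tolist())
            np.testing.assert_allclose(z.values[col], expected, atol=1e-12)

    def test_degenerate_screen_excluded_and_reported(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        report = QCReport()
        z = robust_z(ScreenMatrix(df), report=report)
        assert list(z.values.columns) == ["ok"]
        assert report.degenerate_screens == ["flat"]

    def test_orientation_preserved(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0]})
        z = robust_z(ScreenMatrix(df, orientation="sensitivity_negative"))
        assert z.orientation == "sensitivity_negative"


class TestAdjustMADL:
    @pytest.mark.parametrize("p,factor", [(0.01, 1.0), (0.5, 0.1), (0.05, 1.0)])
    def test_capped_factor(self, p, factor):
        m = ScreenMatrix(pd.DataFrame({"s": [-4.0, 2.0, 1.0]},
                                      index=list("abc")),
                         value_kind="madl", orientation="sensitivity_negative")
        pv = pd.DataFrame({"s": [p, p, p]}, index=list("abc"))
        a = adjust_madl(m, pv)
        np.testing.assert_allclose(a.values["s"], m.values["s"] * factor)
        assert a.value_kind == "a_madl"

    def test_never_increases_magnitude(self, rng):
        vals = rng.normal(size=(30, 5))
        pv = pd.DataFrame(rng.uniform(1e-6, 1.0, size=(30, 5)))
        m = ScreenMatrix(pd.DataFrame(vals), value_kind="madl",
                         orientation="sensitivity_negative")
        a = adjust_madl(m, pv)
        assert (a.values.abs().to_numpy() <= np.abs(vals) + 1e-15).all()

    def test_missing_p_leaves_value(self):
        m = ScreenMatrix(pd.DataFrame({"s": [3.0]}, index=["a"]),
                         value_kind="madl", orientation="sensitivity_negative")
        a = adjust_madl(m, pd.DataFrame(index=["a"]))
        assert a.values.loc["a", "s"] == 3.0


class TestGenewiseZ:
    def test_constant_strain_flagged(self):
        df = pd.DataFrame(np.full((1, 12), 3.0),
                          index=["flat"], columns=[f"s{i}" for i in range(12)])
        m = ScreenMatrix(df, value_kind="a_madl",
                         orientation="sensitivity_negative")
        report = QCReport()
        z, scales = genewise_z_nibr(m, report=report)
        assert "flat" in report.invariant_strains
        assert z.values.empty or "flat" not in z.values.index

    def test_sigma_matches_central70_of_standard_normal(self, rng):
        # Monte-Carlo: SD of the middle 70% of N(0,1) ~= 0.5376
        draws = rng.normal(size=(1, 4000))
        m = ScreenMatrix(pd.DataFrame(draws, index=["g"]),
                         value_kind="a_madl", orientation="sensitivity_negative")
        _, scales = genewise_z_nibr(m)
        lo, hi = stats.norm.ppf(0.15), stats.norm.ppf(0.85)
        a, b = (lo - 0) / 1, (hi - 0) / 1
        expected = stats.truncnorm.std(a, b, loc=0, scale=1)
        assert scales["sigma"].iloc[0] == pytest.approx(expected, rel=0.10)

    def test_scale_invariance(self, rng):
        vals = rng.normal(size=(3, 20))
        m1 = ScreenMatrix(pd.DataFrame(vals), value_kind="a_madl",
                          orientation="sensitivity_negative")
        m2 = ScreenMatrix(pd.DataFrame(vals * 2.0), value_kind="a_madl",
                          orientation="sensitivity_negative")
        z1, _ = genewise_z_nibr(m1)
        z2, _ = genewise_z_nibr(m2)
        pd.testing.assert_frame_equal(z1.values, z2.values)

    def test_hiplab_rowwise_matches_oracle(self, random_matrix):
        z = genewise_z_hiplab(random_matrix)
        for strain in z.values.index:
            expected = genewise_z_row(random_matrix.values.loc[strain].tolist())
            np.testing.assert_allclose(z.values.loc[strain], expected,
                                       atol=1e-12)

    def test_hiplab_symmetric_row(self):
        df = pd.DataFrame([np.arange(1.0, 12.0)], index=["g"])
        z = genewise_z_hiplab(ScreenMatrix(df))
        x = z.values.loc["g"].to_numpy()
        assert float(np.median(x)) == 0.0
        assert float(np.median(np.abs(x))) == 1.0


class TestSignificance:
    def test_hiplab_boundary_inclusive(self):
        thr = fd_significance_threshold(0.001)
        assert thr == pytest.approx(3.0902, abs=1e-4)
        df = pd.DataFrame({"s": [thr, 0.0, thr - 1e-9]}, index=list("abc"))
        mask = significance_mask(ScreenMatrix(df))
        assert mask.loc["a", "s"]
        assert not mask.loc["b", "s"]
        assert not mask.loc["c", "s"]

    @pytest.mark.parametrize("z,expected", [(-4.9, False), (-5.1, True)])
    def test_nibr_cutoff_minus5(self, z, expected):
        df = pd.DataFrame({"s": [z]}, index=["g"])
        m = ScreenMatrix(df, value_kind="z", orientation="sensitivity_negative")
        assert bool(significance_mask(m).loc["g", "s"]) is expected

    def test_raw_log2ratio_rejected(self):
        m = ScreenMatrix(pd.DataFrame({"s": [1.0]}), value_kind="raw_log2ratio")
        with pytest.raises(ValueError):
            significance_mask(m)


class TestHarmonize:
    def test_flip_and_idempotence(self):
        df = pd.DataFrame({"s": [-5.0, 2.0]}, index=["a", "b"])
        m = ScreenMatrix(df, value_kind="z", orientation="sensitivity_negative")
        h1 = harmonize_orientation(m)
        assert h1.orientation == "sensitivity_positive"
        np.testing.assert_allclose(h1.values["s"], [5.0, -2.0])
        h2 = harmonize_orientation(h1)
        pd.testing.assert_frame_equal(h1.values, h2.values)

    def test_positive_input_unchanged(self, random_matrix):
        h = harmonize_orientation(random_matrix)
        pd.testing.assert_frame_equal(h.values, random_matrix.values)


def test_mad_scaled_config_switch(rng):
    vals = rng.normal(size=(51, 3))
    m = ScreenMatrix(pd.DataFrame(vals))
    z_raw = robust_z(m, AnalysisConfig(mad_scaled=False))
    z_scaled = robust_z(m, AnalysisConfig(mad_scaled=True))
    np.testing.assert_allclose(z_raw.values.to_numpy(),
                               z_scaled.values.to_numpy() * 1.4826022185056018,
                               atol=1e-12)
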