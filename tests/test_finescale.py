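import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

import predspace as ps
from predspace.finescale import conditional_loglik, estimable_terms
from predspace.screening import Step
from predspace.solar import solar_elevation_deg

from conftest import simulate_choice_table


def _make_steps(lengths, turns=None, animal="a0"):
    turns = [None] * len(lengths) if turns is None else turns
    t0 = pd.Timestamp("2014-05-01")
    out = []
    for i, (L, tr) in enumerate(zip(lengths, turns)):
        out.append(Step(animal_id=animal,
                        start_time=t0 + pd.Timedelta(hours=2 * i),
                        end_time=t0 + pd.Timedelta(hours=2 * i + 2),
                        x0=0, y0=0, x1=L, y1=0, length_m=L,
                        bearing_rad=0.0, turn_rad=tr))
    return out


class TestMoveDistributions:
    def test_degenerate_sampler(self):
        steps = _make_steps([50.0] * 40)
        dists = ps.empirical_move_dists(steps, "cat")
        rng = np.random.default_rng(0)
        lengths, _ = dists.sample(10, rng)
        assert np.all(lengths == 50.0)

    def test_pooled_count(self):
        steps = _make_steps([10] * 20) + _make_steps([20] * 25, animal="a1")
        dists = ps.empirical_move_dists(steps, "cat")
        assert dists.step_lengths.size == 45

    def test_too_few_steps(self):
        with pytest.raises(ValueError, match=">= 30"):
            ps.empirical_move_dists(_make_steps([10] * 5), "cat")

    def test_simulated_moments(self, lmap):
        cfg = ps.SimAnimalConfig.for_species("dingo", n_steps=400,
                                             rest_prob=0.0, spike_rate=0.0)
        tr, _ = ps.simulate_track(lmap, cfg, seed=31)
        scr = ps.screen_track(tr, ps.ScreeningParams.for_species("dingo"),
                              ref_elev=500.0)
        steps = ps.build_steps(scr)
        dists = ps.empirical_move_dists(steps, "dingo")
        # gamma(2, 400) truncated above 20 m: mean ~ 800, generous MC bounds
        m = dists.step_lengths.mean()
        assert 650 < m < 950
        assert abs(np.mean(dists.turn_angles)) < 0.2  # symmetric kernel


class TestGenerateControlSteps:
    def test_k_zero(self):
        dists = ps.MoveDistributions("cat", np.array([10.0]),
                                     np.array([0.0]))
        out = ps.generate_control_steps((0, 0), 0.0, dists, K=0)
        assert out.shape == (0, 2)

    def test_degenerate_collinear(self):
        dists = ps.MoveDistributions("cat", np.array([100.0]),
                                     np.array([0.0]))
        out = ps.generate_control_steps((5, 5), np.pi / 2, dists, K=8,
                                        rng=np.random.default_rng(0))
        assert np.allclose(out[:, 0], 5.0)
        assert np.allclose(out[:, 1], 105.0)

    def test_lengths_match_empirical_distribution(self):
        rng = np.random.default_rng(1)
        sample = rng.gamma(2, 300, 400)
        dists = ps.MoveDistributions("dingo", sample,
                                     rng.vonmises(0, 0.5, 400))
        out = ps.generate_control_steps((0, 0), 0.3, dists, K=10_000,
                                        rng=np.random.default_rng(2))
        drawn = np.hypot(out[:, 0], out[:, 1])
        assert ks_2samp(drawn, sample).pvalue > 0.01


class TestFitClogit:
    def test_null_loglik_closed_form(self, dingo_choices):
        n = dingo_choices["stratum"].nunique()
        ll0 = conditional_loglik(dingo_choices, ps.DESIGN_TERMS,
                                 np.zeros(len(ps.DESIGN_TERMS)))
        assert ll0 == pytest.approx(-n * np.log(21), rel=1e-12)

    def test_three_strata_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        df = simulate_choice_table(3, 6, [1.0], rng, binary_cols=[0])
        if estimable_terms(df, ["c0"]) != ["c0"]:
            df = simulate_choice_table(3, 6, [1.0],
                                       np.random.default_rng(4),
                                       binary_cols=[0])
        fit = ps.fit_clogit(df, ["c0"])
        grid = np.linspace(-6, 6, 240_001)
        lls = np.array([
            conditional_loglik(df, ["c0"], np.array([b]))
            for b in np.linspace(-6, 6, 1201)
        ])
        coarse = np.linspace(-6, 6, 1201)[np.argmax(lls)]
        fine = np.linspace(coarse - 0.02, coarse + 0.02, 4001)
        lls_f = np.array([conditional_loglik(df, ["c0"], np.array([b]))
                          for b in fine])
        best = fine[np.argmax(lls_f)]
        assert abs(fit.params["c0"] - best) < 1e-4

    def test_stratum_constant_covariate_rejected(self):
        rng = np.random.default_rng(5)
        df = simulate_choice_table(5, 4, [0.5], rng)
        df["const_in_stratum"] = df["stratum"].map(
            {s: i for i, s in enumerate(df["stratum"].unique())}).astype(
            float)
        with pytest.raises(ValueError, match="constant within every stratum"):
            ps.fit_clogit(df, ["c0", "const_in_stratum"])

    def test_matches_stratified_cox(self):
        """One event per stratum: the conditional-logistic likelihood equals
        the stratified Cox partial likelihood; estimates must agree."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        df = simulate_choice_table(150, 10, [0.8, -0.5], rng)
        fit = ps.fit_clogit(df, ["c0", "c1"])
        d = df.copy()
        d["T"] = 2.0 - d["used"]
        cph = CoxPHFitter()
        cph.fit(d[["T", "used", "c0", "c1", "stratum"]], duration_col="T",
                event_col="used", strata=["stratum"])
        assert np.allclose(fit.params.values, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se.values, cph.standard_errors_.values,
                           atol=1e-4)

    def test_invariant_to_stratum_constant_shift(self):
        rng = np.random.default_rng(7)
        df = simulate_choice_table(60, 8, [0.7], rng)
        fit1 = ps.fit_clogit(df, ["c0"])
        shifted = df.copy()
        offsets = {s: rng.normal(0, 5)
                   for s in shifted["stratum"].unique()}
        shifted["c0"] = shifted["c0"] + shifted["stratum"].map(offsets)
        fit2 = ps.fit_clogit(shifted, ["c0"])
        assert fit1.params["c0"] == pytest.approx(fit2.params["c0"],
                                                  abs=1e-8)

    def test_odds_ratio_is_exp_beta(self):
        rng = np.random.default_rng(8)
        df = simulate_choice_table(80, 8, [0.6], rng)
        fit = ps.fit_clogit(df, ["c0"])
        assert fit.odds_ratios["c0"] == pytest.approx(
            np.exp(fit.params["c0"]))


class TestFitClogitRanef:
    def _two_animal_df(self, rng, dev=(0.0, 0.0), n_strata=150):
        frames = []
        for i, d in enumerate(dev):
            frames.append(simulate_choice_table(
                n_strata, 10, [0.5 + d, 0.4], rng, animal=f"an{i}",
                binary_cols=[0]))
        df = pd.concat(frames, ignore_index=True)
        return df.rename(columns={"c0": "woodland"})

    def test_boundary_variance_returns_fixed_fit(self):
        rng = np.random.default_rng(9)
        df = self._two_animal_df(rng)
        rf = ps.fit_clogit_ranef(df, ["woodland", "c1"])
        fx = ps.fit_clogit(df, ["woodland", "c1"])
        if rf.ranef_variance == 0.0:
            assert np.allclose(rf.params.values, fx.params.values,
                               atol=1e-6)
        else:  # tiny estimated variance: fixed effects still agree closely
            assert np.allclose(rf.params.values, fx.params.values, atol=0.05)
        assert rf.info.get("intercept_cancels", False) or \
            rf.info.get("ranef_boundary", False)

    def test_positive_variance_detected(self):
        rng = np.random.default_rng(10)
        devs = rng.normal(0, 0.8, 8)
        frames = [
            simulate_choice_table(120, 10, [0.5 + d, 0.4], rng,
                                  animal=f"an{i}", binary_cols=[0])
            for i, d in enumerate(devs)
        ]
        df = pd.concat(frames, ignore_index=True).rename(
            columns={"c0": "woodland"})
        rf = ps.fit_clogit_ranef(df, ["woodland", "c1"])
        assert rf.ranef_variance is not None and rf.ranef_variance > 0
        # per-animal predictions track the generating deviations
        blups = rf.info["blups"]
        assert np.corrcoef(blups.values, devs - devs.mean())[0, 1] > 0.6

    def test_single_individual_rejected(self):
        rng = np.random.default_rng(11)
        df = simulate_choice_table(30, 5, [0.5], rng).rename(
            columns={"c0": "woodland"})
        with pytest.raises(ValueError, match="individuals"):
            ps.fit_clogit_ranef(df, ["woodland"])


class TestSubsets:
    def test_all_diurnal_skips_nocturnal(self):
        rng = np.random.default_rng(12)
        df = simulate_choice_table(60, 5, [0.5], rng)
        # local solar noon at 121.56 E is ~03:54 UTC
        df["timestamp"] = pd.Timestamp("2014-05-01T04:00:00")
        out = ps.subset_fits(df, "diel", terms=["c0"])
        assert set(out) == {"diurnal"}
        assert isinstance(out["diurnal"], ps.SelectionFit)

    def test_small_sex_subset_skipped(self):
        rng = np.random.default_rng(13)
        big = simulate_choice_table(80, 5, [0.5], rng, animal="m0")
        small = simulate_choice_table(5, 5, [0.5], rng, animal="f0")
        df = pd.concat([big, small], ignore_index=True)
        out = ps.subset_fits(df, "sex", terms=["c0"],
                             sex_map={"m0": "M", "f0": "F"})
        assert isinstance(out["M"], ps.SelectionFit)
        assert isinstance(out["F"], str) and "skipped" in out["F"]

    def test_solar_elevation_sanity(self):
        # midnight UTC ~ 08:06 local solar time: sun up; 16:00 UTC ~ midnight
        noonish = solar_elevation_deg(["2014-05-01T04:00:00"])[0]
        nightish = solar_elevation_deg(["2014-05-01T16:00:00"])[0]
        assert noonish > 30
        assert nightish < -30


class TestFeatureCorrelations:
    def test_identical_columns(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"a": rng.normal(0, 1, 100)})
        df["b"] = df["a"]
        out = ps.feature_correlations(df, ["a", "b"])
        assert out["matrix"].loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b", 1.0) in [
            (i, j, round(r, 6)) for i, j, r in out["flagged"]]

    def test_balanced_dummies_formula(self):
        # two dummies of a 3-level factor with counts (n0, n1, n2):
        # r = -sqrt(p1 p2 / ((1-p1)(1-p2)))
        lv = np.repeat([0, 1, 2], [40, 30, 30])
        df = pd.DataFrame({"d1": (lv == 1).astype(float),
                           "d2": (lv == 2).astype(float)})
        out = ps.feature_correlations(df, ["d1", "d2"], threshold=0.9)
        p1, p2 = 0.3, 0.3
        expect = -np.sqrt(p1 * p2 / ((1 - p1) * (1 - p2)))
        assert out["matrix"].loc["d1", "d2"] == pytest.approx(expect)

    def test_symmetric_unit_diagonal(self, dingo_choices):
        out = ps.feature_correlations(dingo_choices)
        m = out["matrix"].to_numpy()
        finite = np.isfinite(m)
        assert np.allclose(m[finite], m.T[finite])
        d = np.diag(m)
        assert np.allclose(d[np.isfinite(d)], 1.0)

    def test_zero_variance_reported(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        out = ps.feature_correlations(df, ["a", "b"])
        assert out["degenerate"] == ["a"]


def test_design_reference_level_absent(dingo_choices):
    """Rows in the reference state (off-road grassland, moderate cover,
    off-hydro) have all-zero design rows: the reference is the implicit
    baseline, never a column."""
    ref = dingo_choices[
        (dingo_choices.road_veg == "offroad_grass")
        & (~dingo_choices.on_hydro)
        & (dingo_choices.cover == "moderate")
    ]
    assert len(ref) > 0
    assert (ref[ps.DESIGN_TERMS].to_numpy() == 0).all()
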