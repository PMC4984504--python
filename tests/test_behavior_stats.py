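import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from divetrace import (
    SimulationConfig,
    annotate_excursions,
    detect_excursions,
    simulate_track,
)
from divetrace.behavior_stats import (
    CategoryCounts,
    boxcox_transform,
    build_category_counts,
    correlate,
    fit_count_model,
    fit_lme,
    sample_temperature_windows,
    tukey_contrasts,
)
from divetrace.errors import DegenerateDataError

from conftest import make_series


def nb_counts(rng, n_ind=16, rr_dusk=1.0, base=0.02, expo=240.0, alpha=0.3, sigma=0.4):
    """NB2 counts with an individual log-normal random intercept."""
    out = []
    for i in range(n_ind):
        b = rng.normal(0, sigma)
        for cat, rr in [("day", 1.0), ("dusk", rr_dusk)]:
            mu = base * rr * expo * np.exp(b)
            r = 1.0 / alpha
            y = int(rng.negative_binomial(r, r / (r + mu)))
            out.append(CategoryCounts(f"i{i:02d}", cat, y, expo))
    return out


class TestCategoryCounts:
    def test_diel_bookkeeping(self, default_sim, detected):
        cfg, series_list, _ = default_sim
        counts = build_category_counts(detected, series_list, "diel", cfg.lat, cfg.lon)
        df = pd.DataFrame([(c.individual_id, c.category, c.count, c.exposure) for c in counts],
                          columns=["ind", "cat", "n", "expo"])
        per_ind = df.groupby("ind")
        for ind, g in per_ind:
            n_me = sum(1 for e in detected if e.individual_id == ind)
            assert g["n"].sum() == n_me  # counts partition the ME total
            assert g["expo"].sum() == pytest.approx(24.0 * 30, rel=0.01)
            assert set(g["cat"]) == {"dawn", "day", "dusk", "night"}

    def test_month_covariate_is_mean_sst(self, default_sim, detected):
        cfg, series_list, _ = default_sim
        counts = build_category_counts(detected, series_list, "month")
        assert all(c.covariate is not None for c in counts)
        assert all(20.0 < c.covariate < 30.0 for c in counts)

    def test_dusk_preference_shows_in_rates(self):
        cfg = SimulationConfig(
            n_individuals=6, days=40, seed=77, me_rate_per_day=0.8,
            diel_rate_multipliers={"dawn": 1.0, "day": 1.0, "dusk": 5.0, "night": 1.0},
        )
        series_list, _ = simulate_track(cfg)
        excs = []
        for s in series_list:
            excs.extend(detect_excursions(s))
        annotate_excursions(excs, cfg.lat, cfg.lon)
        counts = build_category_counts(excs, series_list, "diel", cfg.lat, cfg.lon)
        df = pd.DataFrame([(c.category, c.count, c.exposure) for c in counts],
                          columns=["cat", "n", "expo"])
        rates = df.groupby("cat").apply(
            lambda g: g["n"].sum() / g["expo"].sum(), include_groups=False
        )
        assert rates.idxmax() == "dusk"


class TestCountModel:
    def test_rate_ratio_recovery(self):
        # season-long exposures and mild dispersion keep the single-draw
        # sampling error of the log rate ratio well inside +-25%
        rng = np.random.default_rng(101)
        fit = fit_count_model(
            nb_counts(rng, rr_dusk=3.0, base=0.08, expo=720.0, alpha=0.05, sigma=0.3)
        )
        rr = float(np.exp(fit.params["category[T.dusk]"]))
        assert 2.4 <= rr <= 3.75  # within 25% of the generative truth
        assert fit.tests["category"]["p"] < 0.05

    def test_offset_scaling_shifts_rates_exactly(self):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, rr_dusk=2.0)
        doubled = [CategoryCounts(c.individual_id, c.category, c.count, 2 * c.exposure)
                   for c in counts]
        f1 = fit_count_model(counts)
        f2 = fit_count_model(doubled)
        assert f2.predict_rate("day") == pytest.approx(f1.predict_rate("day") / 2, rel=1e-3)
        # rate ratios unchanged
        assert f2.params["category[T.dusk]"] == pytest.approx(
            f1.params["category[T.dusk]"], abs=1e-3
        )

    def test_covariate_model(self):
        rng = np.random.default_rng(6)
        counts = []
        for i in range(12):
            b = rng.normal(0, 0.3)
            for sst in (24.0, 27.0, 30.0):
                mu = np.exp(-8.0 + 0.35 * sst + b) * 720.0
                r = 1 / 0.3
                counts.append(
                    CategoryCounts(f"i{i}", f"m{sst}", int(rng.negative_binomial(r, r / (r + mu))),
                                   720.0, covariate=sst)
                )
        fit = fit_count_model(counts, use_covariate=True)
        assert fit.params["covariate"] == pytest.approx(0.35, abs=0.1)
        assert fit.tests["covariate"]["p"] < 0.05

    def test_agrees_with_independent_mixed_model_fit(self, tmp_path):
        # cross-check the Gauss-Hermite ML fitter against glmmTMB
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the cross-check oracle")
        rng = np.random.default_rng(3)
        counts = nb_counts(rng, rr_dusk=3.0)
        df = pd.DataFrame(
            [(c.individual_id, c.category, c.count, c.exposure) for c in counts],
            columns=["individual", "category", "count", "exposure"],
        )
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmmTMB(count ~ category + offset(log(exposure)) + (1|individual),\n"
            "             family = nbinom2, data = d)\n"
            "cat(fixef(m)$cond['categorydusk'], '\\n')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        reference = float(out.stdout.strip().split()[-1])
        fit = fit_count_model(counts)
        assert fit.params["category[T.dusk]"] == pytest.approx(reference, abs=0.02)


class TestTemperatureWindows:
    def _setup(self, seed=0, **kw):
        cfg = SimulationConfig(n_individuals=1, days=15, seed=seed, me_rate_per_day=0.4, **kw)
        series_list, _ = simulate_track(cfg)
        s = series_list[0]
        excs = detect_excursions(s)
        return s, excs

    def test_exclusion_zone_respected(self):
        s, excs = self._setup(seed=21)
        wins = sample_temperature_windows(s, excs, width_min=300, n_per_individual=30, seed=1)
        for w in wins:
            if w.kind != "non_me":
                continue
            for e in excs:
                assert not (
                    w.start <= e.end_time + pd.Timedelta(hours=1)
                    and w.end >= e.start_time - pd.Timedelta(hours=1)
                )

    def test_pre_me_window_ends_at_start_record(self):
        s, excs = self._setup(seed=21)
        wins = sample_temperature_windows(s, excs, width_min=300, seed=1)
        pre = [w for w in wins if w.kind == "pre_me"]
        assert len(pre) >= 1
        assert {w.end for w in pre} <= {e.start_time for e in excs}

    def test_deterministic_given_seed(self):
        s, excs = self._setup(seed=22)
        w1 = sample_temperature_windows(s, excs, 300, 20, seed=9)
        w2 = sample_temperature_windows(s, excs, 300, 20, seed=9)
        assert [(w.kind, w.start) for w in w1] == [(w.kind, w.start) for w in w2]

    def test_insufficient_windows_warns(self):
        s, excs = self._setup(seed=23)
        with pytest.warns(UserWarning, match="eligible"):
            sample_temperature_windows(s, excs, width_min=300, n_per_individual=10_000, seed=0)

    def test_pre_dive_cooling_detected(self):
        cfg = SimulationConfig(n_individuals=4, days=20, seed=31, me_rate_per_day=0.5,
                               pre_me_cooling_c=0.3)
        series_list, _ = simulate_track(cfg)
        pre, non = [], []
        for s in series_list:
            excs = detect_excursions(s)
            for w in sample_temperature_windows(s, excs, 300, 50, seed=2):
                (pre if w.kind == "pre_me" else non).append(w.mean_temperature)
        assert np.mean(pre) < np.mean(non)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_exclusion_property_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        n = 600
        depths = np.full(n, 50.0)
        # drop 1-3 random qualifying excursions into the series
        me_spans = []
        for _ in range(rng.integers(1, 4)):
            j0 = int(rng.integers(40, n - 40))
            if any(abs(j0 - a) < 30 for a, _ in me_spans):
                continue
            depths[j0 + 1 : j0 + 7] = 400.0
            me_spans.append((j0, j0 + 7))
        s = make_series(depths)
        excs = detect_excursions(s)
        wins = sample_temperature_windows(s, excs, width_min=60, n_per_individual=20, seed=3)
        guard = pd.Timedelta(hours=1)
        for w in wins:
            if w.kind != "non_me":
                continue
            for e in excs:
                assert not (w.start <= e.end_time + guard and w.end >= e.start_time - guard)


class TestBoxCox:
    def test_identity_branch(self):
        y = np.array([1.0, 2.0, 5.0])
        from scipy.special import boxcox as bc

        assert bc(y, 1.0) == pytest.approx(y - 1.0)

    def test_log_branch(self):
        y = np.array([1.0, 2.0, 5.0])
        from scipy.special import boxcox as bc

        assert bc(y, 0.0) == pytest.approx(np.log(y))

    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(0)
        lam, _ = boxcox_transform(np.exp(rng.normal(size=500)))
        assert -0.25 <= lam <= 0.25

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_transform([1.0, 0.0, 2.0])


def lme_data(rng, means, n_ind=10, n_per=5, re_sd=0.5):
    rows = []
    for i in range(n_ind):
        b = rng.normal(0, re_sd)
        for g, m in enumerate(means):
            for _ in range(n_per):
                rows.append({"individual": f"i{i}", "grp": str(g + 1), "y": m + b + rng.normal()})
    return pd.DataFrame(rows)


class TestLme:
    def test_power_with_one_sd_effect(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(40):
            df = lme_data(rng, [0.0, 1.0, 0.5], n_per=8)
            fit = fit_lme(df, "y", ["grp"])
            rejections += fit.tests["grp"]["p"] < 0.05
        assert rejections / 40 > 0.9

    def test_null_rejection_near_nominal(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 120
        for _ in range(reps):
            df = lme_data(rng, [0.0, 0.0, 0.0], n_per=5)
            fit = fit_lme(df, "y", ["grp"])
            rejections += fit.tests["grp"]["p"] < 0.05
        assert 0.005 < rejections / reps < 0.11

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(3)
        df = lme_data(rng, [0.0])
        with pytest.raises(ValueError, match="single level"):
            fit_lme(df, "y", ["grp"])

    def test_additive_two_factor_model(self):
        rng = np.random.default_rng(4)
        df = lme_data(rng, [0.0, 2.0], n_per=6)
        df["grp2"] = rng.choice(["a", "b", "c"], size=len(df))
        fit = fit_lme(df, "y", ["grp", "grp2"])
        assert fit.tests["grp"]["p"] < 0.05
        assert fit.tests["grp2"]["p"] > 0.05


class TestTukey:
    def test_separated_group_gets_own_letter(self):
        rng = np.random.default_rng(0)
        df = lme_data(rng, [0.0, 0.0, 5.0], n_ind=10, n_per=5)
        fit = fit_lme(df, "y", ["grp"])
        tab = tukey_contrasts(fit, "grp")
        letters = tab.attrs["letters"]
        assert letters["1"] == letters["2"]
        assert letters["3"] != letters["1"]
        assert letters["3"] == "a"  # 'a' labels the largest mean

    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(1)
        df = lme_data(rng, [0.0, 0.0, 0.0])
        fit = fit_lme(df, "y", ["grp"])
        tab = tukey_contrasts(fit, "grp")
        assert len(set(tab.attrs["letters"].values())) == 1

    def test_letters_consistent_with_adjusted_p(self):
        rng = np.random.default_rng(2)
        df = lme_data(rng, [0.0, 0.6, 1.8, 3.0], n_ind=12, n_per=6)
        fit = fit_lme(df, "y", ["grp"])
        tab = tukey_contrasts(fit, "grp")
        letters = tab.attrs["letters"]
        for _, row in tab.iterrows():
            shared = set(letters[row.level_a]) & set(letters[row.level_b])
            if row.p_adjusted < 0.05:
                assert not shared
            else:
                assert shared

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(3)
        df = lme_data(rng, [0.0, 0.8, 1.6])
        fit = fit_lme(df, "y", ["grp"])
        tab = tukey_contrasts(fit, "grp")
        import scipy.stats as st

        raw = 2 * st.norm.sf(np.abs(tab["z"]))
        assert (tab["p_adjusted"] >= raw - 1e-9).all()


class TestCorrelate:
    def test_perfect_linear(self):
        assert correlate([1, 2, 3, 4], [3, 5, 7, 9])[0] == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 4, 20)
        y = np.exp(x)
        assert correlate(x, y, "spearman")[0] == pytest.approx(1.0)
        assert correlate(x, y, "pearson")[0] < 1.0

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateDataError):
            correlate([1.0, 1.0, 1.0], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.lists(hst.integers(min_value=0, max_value=5), min_size=4, max_size=25),
        hst.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_spearman_equals_rank_then_pearson(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs, dtype=float)
        y = rng.normal(size=len(x))
        if np.std(x) == 0:
            return
        import scipy.stats as st

        r_s, _ = correlate(x, y, "spearman")
        rx, ry = st.rankdata(x), st.rankdata(y)  # midrank ties
        r_oracle, _ = st.pearsonr(rx, ry)
        assert r_s == pytest.approx(r_oracle)
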