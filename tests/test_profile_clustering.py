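import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from divetrace import (
    cross_tabulate,
    fit_kmeans,
    make_phase_profile,
    r2_by_k,
    split_phases,
    standardize_profile,
)
from divetrace.errors import DegenerateDataError
from divetrace.profile_clustering import PhaseProfile

from conftest import make_series


def _phase(depths, interval=120.0, kind="descent"):
    t = np.arange(len(depths)) * interval
    return PhaseProfile("x", kind, t, np.asarray(depths, dtype=float))


class TestSplitPhases:
    def _split(self, depths):
        from divetrace import detect_excursions

        return split_phases(detect_excursions(make_series(depths))[0])

    def test_apex_shared_by_both_phases(self):
        d, a = self._split([180, 210, 300, 500, 350, 240, 190])
        assert d.depth.tolist() == [180, 210, 300, 500]
        assert a.depth.tolist() == [500, 350, 240, 190]
        assert d.depth[-1] == a.depth[0]
        assert a.t_s[0] == 0.0

    def test_duplicate_apex_uses_first_occurrence(self):
        d, a = self._split([180, 210, 500, 500, 400, 240, 190])
        assert len(d.depth) == 3
        assert a.depth.tolist() == [500, 500, 400, 240, 190]

    def test_symmetric_dive_mirrors(self):
        d, a = self._split([180, 250, 350, 500, 350, 250, 180])
        assert d.depth.tolist() == a.depth[::-1].tolist()


class TestStandardize:
    def test_three_point_example(self):
        p = _phase([180, 300, 500])
        assert standardize_profile(p, P=3) == pytest.approx([0, 0.375, 1.0])

    def test_five_point_resampling(self):
        p = _phase([180, 300, 500])
        assert standardize_profile(p, P=5) == pytest.approx([0, 0.1875, 0.375, 0.6875, 1.0])

    def test_orientation_convention(self):
        desc = standardize_profile(_phase([180, 300, 500]))
        asc = standardize_profile(_phase([500, 300, 180], kind="ascent"))
        assert desc[0] == 0 and desc[-1] == 1
        assert asc[0] == 1 and asc[-1] == 0

    @pytest.mark.parametrize("a,b,c,d", [(2.0, 5.0, 3.0, -100.0), (0.5, 0.0, 10.0, 7.0)])
    def test_affine_invariance(self, a, b, c, d):
        depths = np.array([180.0, 260, 310, 500, 470])
        t = np.arange(5) * 120.0
        base = standardize_profile(PhaseProfile("x", "descent", t, depths))
        scaled = standardize_profile(PhaseProfile("x", "descent", a * t + b, c * depths + d))
        assert base == pytest.approx(scaled)

    def test_zero_depth_range_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            standardize_profile(_phase([300.0, 300.0, 300.0]))


class TestVelocity:
    def test_descent_endpoint_velocity(self):
        assert _phase([180, 290, 400, 500]).mean_vertical_velocity == pytest.approx(
            (500 - 180) / 360.0
        )

    def test_ascent_velocity_positive_magnitude(self):
        p = _phase([500] + [450, 380, 300, 250, 220, 200.5, 190], kind="ascent")
        assert p.mean_vertical_velocity == pytest.approx((500 - 190) / 840.0)

    def test_flat_phase_zero(self):
        assert _phase([300.0, 300.0]).mean_vertical_velocity == 0.0


def _archetype_ascents(n_per, noise_sd, rng, P=20):
    """Standardized ascent vectors from the three shape archetypes."""
    X, labels = [], []
    for label, shape in enumerate(["linear", "transition_point", "variable"]):
        for _ in range(n_per):
            depths = make_phase_profile(
                shape, 600.0, 190.0, 1200.0, 60.0, rng=rng, kind="ascent"
            )
            p = PhaseProfile("x", "ascent", np.arange(len(depths)) * 60.0, depths)
            v = standardize_profile(p, P) + rng.normal(0, noise_sd, P)
            X.append(v)
            labels.append(label)
    return np.array(X), np.array(labels)


class TestKmeans:
    def test_two_separated_families_recovered(self):
        rng = np.random.default_rng(0)
        f1 = np.linspace(0, 1, 20)
        f2 = np.linspace(0, 1, 20) ** 4
        X = np.vstack(
            [f1 + rng.normal(0, 0.01, 20) for _ in range(20)]
            + [f2 + rng.normal(0, 0.01, 20) for _ in range(20)]
        )
        model = fit_kmeans(X, 2, seed=0)
        assert model.r_squared > 0.99
        assert len(set(model.assignments[:20])) == 1
        assert len(set(model.assignments[20:])) == 1

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_kmeans(np.ones((10, 20)), 2)

    def test_k_exceeding_distinct_vectors_rejected(self):
        X = np.vstack([np.zeros(5), np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError, match="distinct"):
            fit_kmeans(X, 3)

    def test_canonical_labels_by_membership(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [np.zeros(4) + rng.normal(0, 0.01, 4) for _ in range(30)]
            + [np.ones(4) + rng.normal(0, 0.01, 4) for _ in range(10)]
        )
        model = fit_kmeans(X, 2, seed=0)
        assert (model.assignments[:30] == 0).all()  # majority cluster is 0

    def test_three_ascent_archetypes_recovered(self):
        rng = np.random.default_rng(7)
        X, labels = _archetype_ascents(40, 0.05, rng)
        model = fit_kmeans(X, 3, seed=0)
        assert adjusted_rand_score(labels, model.assignments) >= 0.9

    def test_matches_exhaustive_partition_search(self):
        # oracle: best 2-cluster within_ss by enumerating all bipartitions
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(8, 4))
        best = np.inf
        idx = np.arange(8)
        for r in range(1, 5):
            for subset in itertools.combinations(idx, r):
                m = np.zeros(8, dtype=bool)
                m[list(subset)] = True
                ss = ((X[m] - X[m].mean(0)) ** 2).sum() + ((X[~m] - X[~m].mean(0)) ** 2).sum()
                best = min(best, ss)
        model = fit_kmeans(X, 2, seed=0, n_restarts=50)
        assert model.within_ss == pytest.approx(best, rel=1e-9)


class TestR2ByK:
    def test_elbow_at_three_archetypes(self):
        rng = np.random.default_rng(11)
        X, _ = _archetype_ascents(30, 0.03, rng)
        r2 = r2_by_k(X, seed=0)
        gains = {k: r2[k] - r2[k - 1] for k in range(3, 11)}
        assert r2[3] - r2[2] == max(gains.values())
        assert all(gains[k] < 0.5 * (r2[3] - r2[2]) for k in range(4, 11))

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(40, 10))
        r2 = r2_by_k(X, seed=0, n_restarts=10)
        vals = list(r2.values())
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_k_equals_n_explains_everything(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(6, 4))
        model = fit_kmeans(X, 6, seed=0)
        assert model.r_squared == pytest.approx(1.0)


class TestCrossTabulate:
    # observed pairing counts between three ascent and three descent shapes
    COUNTS = np.array([[149, 116, 24], [152, 51, 24], [55, 35, 4]])

    def _assignments(self):
        asc, desc = [], []
        for i in range(3):
            for j in range(3):
                asc += [i] * self.COUNTS[i, j]
                desc += [j] * self.COUNTS[i, j]
        return np.array(desc), np.array(asc)

    def test_printed_table_arithmetic(self):
        desc, asc = self._assignments()
        tab = cross_tabulate(desc, asc)
        assert tab.loc["ascent_1", "descent_1_n"] == 149
        assert tab.loc["ascent_1", "descent_1_pct"] == 24.43
        assert tab.loc[["ascent_1", "ascent_2", "ascent_3"], "row_total"].tolist() == [289, 227, 94]
        assert tab.loc["column_total", ["descent_1_n", "descent_2_n", "descent_3_n"]].tolist() == [356, 202, 52]
        assert tab.loc["column_total", "row_total"] == 610

    def test_percentages_sum_to_100(self):
        desc, asc = self._assignments()
        tab = cross_tabulate(desc, asc)
        pct = tab.loc[["ascent_1", "ascent_2", "ascent_3"],
                      ["descent_1_pct", "descent_2_pct", "descent_3_pct"]].to_numpy()
        assert pct.sum() == pytest.approx(100.0, abs=0.05)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate(np.zeros(5), np.zeros(4))
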