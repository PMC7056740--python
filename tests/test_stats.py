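"""Agreement, canonical variates, reference intervals, Mann-Whitney, and
stain-index tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcd4flow as t
from tcd4flow.errors import NumericalError, ValidationError
from tcd4flow.stats import default_age_bands


class TestAgreement:
    def test_identical_analyses(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        rep = t.agreement({"p": (a, a.copy())})
        row = rep.per_population.iloc[0]
        assert row["mnb"] == 0.0
        assert row["r2"] == pytest.approx(1.0)
        assert bool(row["concordant"])

    def test_uniform_20pct_bias(self):
        a = np.array([5.0, 10.0, 20.0, 40.0])
        rep = t.agreement({"p": (a, 1.2 * a)})
        row = rep.per_population.iloc[0]
        assert row["mnb"] == pytest.approx(20.0)
        assert not row["concordant"]  # outside the +/-15% band

    def test_uniform_10pct_bias_concordant(self):
        a = np.array([5.0, 10.0, 20.0, 40.0])
        rep = t.agreement({"p": (a, 1.1 * a)})
        row = rep.per_population.iloc[0]
        assert row["mnb"] == pytest.approx(10.0)
        assert bool(row["concordant"])

    def test_low_r2_discordant_despite_zero_mnb(self):
        # construct b = a + noise with r^2 < 0.9 but symmetric bias ~ 0
        a = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        delta = np.array([3.5, -2.4, 9.0, -5.6, 12.5, -9.0])
        b = a + delta
        mnb = float(np.mean(100 * (b - a) / a))
        r = np.corrcoef(a, b)[0, 1]
        assert abs(mnb) < 15 and r**2 < 0.9  # direct oracle on the vectors
        rep = t.agreement({"p": (a, b)})
        row = rep.per_population.iloc[0]
        assert not row["concordant"]

    def test_zero_reference_pairs_excluded(self):
        a = np.array([0.0, 10.0, 20.0])
        b = np.array([5.0, 10.0, 20.0])
        with pytest.warns(UserWarning, match="zero reference"):
            rep = t.agreement({"p": (a, b)})
        assert rep.per_population.iloc[0]["mnb"] == 0.0

    def test_absent_population_reported_separately(self):
        rep = t.agreement({"gone": (np.array([]), np.array([1.0]))})
        assert rep.not_identified == ("gone",)
        assert len(rep.per_population) == 0

    def test_mnb_sign_flips_with_direction(self):
        a = np.array([10.0, 20.0])
        b = 1.1 * a
        fwd = t.agreement({"p": (a, b)}).per_population.iloc[0]["mnb"]
        rev = t.agreement({"p": (b, a)}).per_population.iloc[0]["mnb"]
        assert fwd == pytest.approx(10.0)
        assert rev == pytest.approx(-100.0 / 11.0)  # small-bias approx: -10%
        assert math.copysign(1, fwd) != math.copysign(1, rev)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            t.AgreementConfig(r2_min=0.0)
        with pytest.raises(ValidationError):
            t.AgreementConfig(mnb_band=-1.0)

    def test_default_band_is_15_percent(self):
        assert t.AgreementConfig().mnb_band == 15.0
        assert t.AgreementConfig().r2_min == 0.9
        assert t.AgreementConfig().p_max == 0.05


class TestCanonicalVariates:
    def test_single_separating_marker(self):
        rng = np.random.default_rng(1)
        g1 = np.column_stack([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
        g2 = np.column_stack([rng.normal(8, 1, 200), rng.normal(0, 1, 200)])
        rep = t.canonical_variates({"a": g1, "b": g2}, markers=["m1", "m2"])
        assert rep["ca1_contributions"]["m1"] > 95.0

    def test_identical_groups_warn(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0, 1, size=(50, 3))
        with pytest.warns(UserWarning, match="identical"):
            t.canonical_variates(
                {"a": g.copy(), "b": g.copy(), "c": g.copy()},
                markers=["x", "y", "z"],
            )

    def test_planted_two_marker_closed_form(self):
        """Contributions match the analytic 2x2 generalized eigenproblem
        built from the *planted* parameters."""
        rng = np.random.default_rng(3)
        n = 40000
        sw_pop = np.array([[1.0, 0.3], [0.3, 2.0]])  # within-group covariance
        delta = np.array([1.0, 2.0])  # mean difference
        L = np.linalg.cholesky(sw_pop)
        g1 = rng.normal(size=(n, 2)) @ L.T - delta / 2
        g2 = rng.normal(size=(n, 2)) @ L.T + delta / 2

        # analytic oracle (population quantities, incl. the standardization)
        total_cov = sw_pop + np.outer(delta, delta) / 4.0
        d = np.diag(1.0 / np.sqrt(np.diag(total_cov)))
        sw_std = d @ sw_pop @ d
        delta_std = d @ delta
        w = np.linalg.solve(sw_std, delta_std)  # Fisher direction
        oracle = 100.0 * w**2 / np.sum(w**2)

        rep = t.canonical_variates({"a": g1, "b": g2}, markers=["m1", "m2"])
        got = np.array([rep["ca1_contributions"]["m1"], rep["ca1_contributions"]["m2"]])
        np.testing.assert_allclose(got, oracle, atol=2.0)

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            t.canonical_variates({"a": np.zeros((5, 2))}, markers=["x", "y"])

    def test_centroids_separate(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(0, 1, size=(100, 2))
        g2 = rng.normal(4, 1, size=(100, 2))
        rep = t.canonical_variates({"a": g1, "b": g2}, markers=["x", "y"])
        gap = abs(rep["centroids"]["a"][0] - rep["centroids"]["b"][0])
        within_sd = max(
            rep["projections"]["a"][:, 0].std(), rep["projections"]["b"][:, 0].std()
        )
        assert gap > 2 * within_sd


class TestReferenceIntervals:
    def test_constant_cohort(self):
        df = pd.DataFrame({"popA": [500.0] * 12})
        ages = [25.0] * 12
        table = t.reference_intervals(df, ages)
        row = table.lookup("popA", "18-40y")
        for c in ("min", "p10", "p25", "p50", "p75", "p90", "max"):
            assert row[c] == 500.0

    def test_type7_percentile_oracle(self):
        """values 1..100: p10 = 10.9 under linear (type-7) interpolation."""
        # hand evaluation: h = (n-1)*q + 1 = 99*0.1 + 1 = 10.9
        # -> x[10] + 0.9*(x[11]-x[10]) = 10 + 0.9 = 10.9
        df = pd.DataFrame({"popA": np.arange(1.0, 101.0)})
        table = t.reference_intervals(df, [30.0] * 100)
        row = table.lookup("popA", "18-40y")
        assert row["p10"] == pytest.approx(10.9)
        assert row["p50"] == pytest.approx(50.5)
        assert row["p90"] == pytest.approx(90.1)

    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {f"pop{i}": rng.lognormal(6, 0.5, 40) for i in range(5)}
        )
        ages = list(rng.uniform(18, 39, 20)) + list(rng.uniform(40, 59, 20))
        table = t.reference_intervals(df, ages)
        for _, row in table.table.iterrows():
            seq = [row["min"], row["p10"], row["p25"], row["p50"], row["p75"],
                   row["p90"], row["max"]]
            assert all(x <= y + 1e-12 for x, y in zip(seq, seq[1:]))

    def test_cb_label_band(self):
        df = pd.DataFrame({"popA": [100.0, 200.0, 300.0]})
        table = t.reference_intervals(df, ["cb", "cb", "cb"])
        assert table.lookup("popA", "cb")["n"] == 3

    def test_low_n_flag(self):
        df = pd.DataFrame({"popA": np.arange(5.0)})
        table = t.reference_intervals(df, [30.0] * 5, min_band_n=10)
        assert bool(table.lookup("popA", "18-40y")["low_n"])

    def test_negative_age_rejected(self):
        df = pd.DataFrame({"popA": [1.0]})
        with pytest.raises(ValidationError, match="negative"):
            t.reference_intervals(df, [-1.0])

    def test_band_spec_validation(self):
        with pytest.raises(ValidationError, match="overlap"):
            t.AgeBandSpec(bands=(("a", 0.0, 5.0), ("b", 4.0, 10.0)))

    def test_default_bands_cover_lifespan(self):
        bands = default_age_bands()
        assert bands.band_of(0.5) == "2mo-2y"
        assert bands.band_of(17.9) == "10-18y"
        assert bands.band_of(18.0) == "18-40y"
        assert bands.band_of(85.0) == "80+y"
        assert bands.band_of("cb") == "cb"

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame({"popA": np.arange(1.0, 21.0)})
        table = t.reference_intervals(df, [30.0] * 20)
        table.to_csv(tmp_path / "ri.csv")
        back = t.ReferenceIntervalTable.from_csv(tmp_path / "ri.csv")
        assert back.lookup("popA", "18-40y")["p50"] == table.lookup(
            "popA", "18-40y"
        )["p50"]


class TestFlagProfile:
    @pytest.fixture
    def intervals(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"popA": rng.normal(1000, 100, 40), "popB": rng.normal(500, 50, 40)}
        )
        return t.reference_intervals(df, [30.0] * 40)

    def test_median_is_normal(self, intervals):
        med = intervals.lookup("popA", "18-40y")["p50"]
        flags = t.flag_profile({"popA": med}, 30.0, intervals)
        assert flags.iloc[0]["flag"] == "normal"

    def test_below_minimum_is_low(self, intervals):
        lo = intervals.lookup("popA", "18-40y")["min"]
        flags = t.flag_profile({"popA": lo - 100}, 30.0, intervals)
        assert flags.iloc[0]["flag"] == "low"

    def test_above_p90_is_high(self, intervals):
        hi = intervals.lookup("popA", "18-40y")["p90"]
        flags = t.flag_profile({"popA": hi + 1000}, 30.0, intervals)
        assert flags.iloc[0]["flag"] == "high"

    def test_age_outside_bands_is_error(self, intervals):
        with pytest.raises(ValidationError, match="outside all bands"):
            t.flag_profile({"popA": 1000}, 500.0, intervals)

    def test_immunodeficiency_like_profile_flags_low(self):
        """Cohort at template scale; patient scaled x0.3 -> majority low."""
        rng = np.random.default_rng(7)
        pops = [f"pop{i}" for i in range(10)]
        base = rng.uniform(200, 2000, 10)
        cohort = pd.DataFrame(
            {p: rng.normal(base[i], base[i] * 0.1, 30) for i, p in enumerate(pops)}
        )
        intervals = t.reference_intervals(cohort, [30.0] * 30)
        patient = {p: 0.3 * base[i] for i, p in enumerate(pops)}
        flags = t.flag_profile(patient, 30.0, intervals)
        assert (flags["flag"] == "low").mean() > 0.5


def _brute_force_mw_p(a, b):
    """Exhaustive two-sided Mann-Whitney p over all group assignments."""
    combined = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        gt = sum(1 for xi in x for yi in y if xi > yi)
        eq = sum(1 for xi in x for yi in y if xi == yi)
        return gt + 0.5 * eq

    u_obs = u_stat(a, b)
    us = []
    for comb in itertools.combinations(range(len(combined)), n1):
        mask = np.zeros(len(combined), dtype=bool)
        mask[list(comb)] = True
        us.append(u_stat(combined[mask], combined[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))


class TestCompareGroups:
    def test_disjoint_groups_oracle(self):
        # a = {1,2,3}, b = {4,5,6}: U = 0, exact two-sided p = 2/20 = 0.1
        out = t.compare_groups([1, 2, 3], [4, 5, 6])
        assert out["U"] == 0.0
        assert out["p"] == pytest.approx(0.1)
        assert not out["significant"]
        assert out["method"].startswith("exact")

    def test_identical_groups(self):
        out = t.compare_groups([1, 2, 3], [1, 2, 3])
        assert out["U"] == pytest.approx(9 / 2)  # n^2/2 with ties at 0.5
        assert out["p"] == pytest.approx(1.0)

    def test_normal_approx_close_to_exact_n8(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = t.compare_groups(a, b)
        assert exact["method"] == "exact-distribution"
        approx = t.compare_groups(a, b, exact_limit=0)
        assert approx["method"] == "normal"
        assert abs(approx["p"] - exact["p"]) < 0.01

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_equals_brute_force_small(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7), rng.integers(2, 7)
        a = rng.integers(0, 10, n1).astype(float)  # ties likely
        b = rng.integers(0, 10, n2).astype(float)
        out = t.compare_groups(a, b)
        assert out["p"] == pytest.approx(_brute_force_mw_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_no_ties_equals_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)
        out = t.compare_groups(a, b)
        assert out["method"] == "exact-distribution"
        assert out["p"] == pytest.approx(_brute_force_mw_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            t.compare_groups([], [1.0])

    def test_significance_flag(self):
        out = t.compare_groups(list(range(10)), list(range(20, 30)))
        assert out["significant"] and out["p"] < 0.05

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=6),
        st.lists(st.integers(0, 50), min_size=2, max_size=6),
    )
    @settings(max_examples=25, deadline=None)
    def test_exact_matches_brute_force_property(self, a, b):
        out = t.compare_groups(a, b)
        assert out["p"] == pytest.approx(
            _brute_force_mw_p(np.asarray(a, float), np.asarray(b, float)),
            abs=1e-12,
        )


class TestStainIndex:
    def test_no_separation_is_zero(self):
        rng = np.random.default_rng(9)
        v = rng.normal(100, 10, 500)
        assert t.stain_index(v, v) == 0.0

    def test_hand_arithmetic_oracle(self):
        # median pos 300, median neg 100, SD neg 50 -> (300-100)/(2*50) = 2
        neg = np.array([50.0, 100.0, 150.0])  # median 100, sd (ddof=1) 50
        pos = np.array([100.0, 300.0, 500.0])  # median 300
        assert np.std(neg, ddof=1) == pytest.approx(50.0)
        assert t.stain_index(pos, neg) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        neg = rng.normal(100, 20, 1000)
        pos = rng.normal(500, 30, 1000)
        si = t.stain_index(pos, neg)
        assert t.stain_index(10 * pos, 10 * neg) == pytest.approx(si)

    def test_zero_sd_undefined(self):
        with pytest.raises(NumericalError):
            t.stain_index([1.0, 2.0], [5.0, 5.0, 5.0])
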