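"""Precision, detectability, exact CIs, cross-reactivity, time binning."""

import math

import numpy as np
import pandas as pd
import pytest

from plexquant import (clopper_pearson, cross_reactivity_score, cv_from_log2,
                       cv_linear, design_pools, detectability,
                       identify_cross_reactant, precision, time_bin)
from plexquant.qc import QCError


class TestCVLinear:
    def test_zero_variance(self):
        assert cv_linear([5, 5, 5]) == 0.0

    def test_hand_arithmetic(self):
        assert cv_linear([90, 110]) == pytest.approx(14.1421, abs=1e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 10, 20)
        assert cv_linear(2 * v) == pytest.approx(cv_linear(v))

    def test_needs_two_values(self):
        with pytest.raises(QCError):
            cv_linear([5.0])


class TestCVFromLog2:
    def test_zero_sd(self):
        assert cv_from_log2(0.0) == 0.0

    def test_hand_arithmetic(self):
        sigma = 0.1 * math.log(2)
        expected = 100 * math.sqrt(math.exp(sigma ** 2) - 1)
        assert cv_from_log2(0.1) == pytest.approx(expected)
        assert cv_from_log2(0.1) == pytest.approx(6.94, abs=0.01)

    def test_agrees_with_linear_cv_on_lognormal_draws(self):
        rng = np.random.default_rng(42)
        log2_draws = rng.normal(loc=10.0, scale=0.25, size=100_000)
        linear = 2.0 ** log2_draws
        cv_direct = cv_linear(linear)
        cv_conv = cv_from_log2(float(np.std(log2_draws, ddof=1)))
        assert cv_conv == pytest.approx(cv_direct, rel=0.02)


class TestPrecision:
    def _matrix(self):
        return pd.DataFrame(
            [[100, 100, 100, 200, 220, 180],
             [50, 60, 40, 10, 10, 10]],
            index=["t0", "t1"],
            columns=["a1", "a2", "a3", "b1", "b2", "b3"], dtype=float)

    def test_identical_replicates_zero_cv(self):
        m = pd.DataFrame([[7.0, 7.0, 7.0]], index=["t"],
                         columns=["w1", "w2", "w3"])
        rep = precision(m, {"g": ["w1", "w2", "w3"]})
        assert rep.table.loc["t", "cv_percent"] == 0.0

    def test_mean_across_groups(self):
        m = self._matrix()
        rep = precision(m, {"a": ["a1", "a2", "a3"], "b": ["b1", "b2", "b3"]})
        cv_a = cv_linear([100, 100, 100])
        cv_b = cv_linear([200, 220, 180])
        assert rep.table.loc["t0", "cv_percent"] == \
            pytest.approx((cv_a + cv_b) / 2)

    def test_below_lod_excluded(self):
        m = pd.DataFrame([[10.0, 100.0, 110.0]], index=["t"],
                         columns=["w1", "w2", "w3"])
        rep = precision(m, {"g": ["w1", "w2", "w3"]}, lods={"t": 50.0})
        assert rep.table.loc["t", "n_excluded"] == 1
        assert rep.table.loc["t", "cv_percent"] == \
            pytest.approx(cv_linear([100, 110]))

    def test_all_below_lod_reported_missing(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["t"],
                         columns=["w1", "w2", "w3"])
        rep = precision(m, {"g": ["w1", "w2", "w3"]}, lods={"t": 50.0})
        assert math.isnan(rep.table.loc["t", "cv_percent"])

    def test_negative_binomial_cv_matches_theory(self):
        # NB with mean mu and size r has CV = sqrt(1/mu + 1/r)
        mu, r = 400.0, 20.0
        theory = 100 * math.sqrt(1 / mu + 1 / r)
        rng = np.random.default_rng(7)
        cvs = []
        for _ in range(100):
            draws = rng.negative_binomial(r, r / (r + mu), size=9)
            cvs.append(cv_linear(draws))
        assert np.mean(cvs) == pytest.approx(theory, rel=0.10)


class TestDetectability:
    def _inputs(self, above):
        npq = pd.DataFrame([above], index=["t"], dtype=float,
                           columns=[f"w{i}" for i in range(len(above))])
        lods = pd.DataFrame({"p1": [0.0]}, index=["t"])
        plates = {w: "p1" for w in npq.columns}
        return npq, lods, plates

    def test_all_above(self):
        rep = detectability(*self._inputs([1.0, 2.0, 3.0, 4.0]))
        assert rep.table.loc["t", "percent_above_lod"] == 100.0
        assert bool(rep.table.loc["t", "detectable"])

    def test_exactly_half_not_detectable(self):
        rep = detectability(*self._inputs([1.0, 1.0, -1.0, -1.0]))
        assert rep.table.loc["t", "percent_above_lod"] == 50.0
        assert not bool(rep.table.loc["t", "detectable"])

    def test_at_lod_not_above(self):
        rep = detectability(*self._inputs([0.0, 0.0, 1.0]))
        assert rep.table.loc["t", "percent_above_lod"] == pytest.approx(100 / 3)

    def test_monotone_rescale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 2, size=(4, 30))
        npq = pd.DataFrame(vals, index=list("abcd"),
                           columns=[f"w{i}" for i in range(30)])
        lods = pd.DataFrame({"p1": [9.0, 10.0, 11.0, 12.0]},
                            index=list("abcd"))
        plates = {w: "p1" for w in npq.columns}
        base = detectability(npq, lods, plates).table["percent_above_lod"]
        scaled = detectability(3 * npq + 1, 3 * lods + 1, plates) \
            .table["percent_above_lod"]
        pd.testing.assert_series_equal(base, scaled)

    def test_missing_plate_lod_errors(self):
        npq, lods, plates = self._inputs([1.0])
        with pytest.raises(QCError):
            detectability(npq, lods, {"w0": "p2"})

    def test_panel_fraction_detectable(self):
        # 195 of 204 targets constructed detectable -> 95.6% of the panel
        rng = np.random.default_rng(5)
        n_targets, n_samples = 204, 50
        vals = np.full((n_targets, n_samples), 1.0)
        vals[:9, :] = -1.0  # nine targets entirely below LOD
        npq = pd.DataFrame(vals, index=[f"t{i}" for i in range(n_targets)],
                           columns=[f"w{i}" for i in range(n_samples)])
        lods = pd.DataFrame({"p1": np.zeros(n_targets)}, index=npq.index)
        rep = detectability(npq, lods, {w: "p1" for w in npq.columns})
        assert rep.n_detectable == 195
        assert 100 * rep.n_detectable / n_targets == pytest.approx(95.6,
                                                                   abs=0.05)


class TestClopperPearson:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and hi < 100.0

    def test_all_successes_upper_bound_hundred(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 100.0 and lo > 0.0

    def test_printed_interval_195_of_204(self):
        lo, hi = clopper_pearson(195, 204)
        assert round(lo, 1) == 91.8
        assert round(hi, 1) == 98.0

    def test_printed_interval_85_of_92(self):
        lo, hi = clopper_pearson(85, 92)
        assert round(lo, 1) == 84.9
        assert round(hi, 1) == 96.9

    def test_invalid_inputs(self):
        with pytest.raises(QCError):
            clopper_pearson(5, 0)
        with pytest.raises(QCError):
            clopper_pearson(-1, 10)

    def test_conservative_coverage(self):
        rng = np.random.default_rng(11)
        n, p, reps = 50, 0.9, 2000
        xs = rng.binomial(n, p, size=reps)
        covered = 0
        for x in np.unique(xs):
            lo, hi = clopper_pearson(int(x), n)
            if lo <= 100 * p <= hi:
                covered += int((xs == x).sum())
        assert covered / reps >= 0.95


class TestCrossReactivity:
    SIGNALS = {"S1_P01": 1000.0, "S2_P01": 1000.0, "S1_P02": 60.0,
               "S2_P02": 50.0, "S1_P03": 50.0, "S2_P03": 40.0}

    def test_hand_arithmetic(self):
        res = cross_reactivity_score("t", self.SIGNALS,
                                     ["S1_P01", "S2_P01"])
        assert res.background == pytest.approx(50.0)
        assert res.score_percent == pytest.approx(100 * 10 / 950, rel=1e-6)

    def test_flat_nontarget_pools_score_zero(self):
        sig = {"a": 500.0, "b": 500.0, "x": 7.0, "y": 7.0, "z": 7.0}
        res = cross_reactivity_score("t", sig, ["a", "b"])
        assert res.score_percent == 0.0

    def test_scale_invariance(self):
        res1 = cross_reactivity_score("t", self.SIGNALS,
                                      ["S1_P01", "S2_P01"])
        scaled = {k: 7 * v for k, v in self.SIGNALS.items()}
        res2 = cross_reactivity_score("t", scaled, ["S1_P01", "S2_P01"])
        assert res1.score_percent == pytest.approx(res2.score_percent)

    def test_failed_assay_flagged(self):
        sig = {"a": 10.0, "b": 10.0, "x": 50.0, "y": 60.0, "z": 70.0}
        res = cross_reactivity_score("t", sig, ["a", "b"])
        assert res.score_percent is None
        assert "assay_failed" in res.flags

    def test_requires_enough_pools(self):
        with pytest.raises(QCError):
            cross_reactivity_score("t", self.SIGNALS, ["S1_P01"])


@pytest.fixture(scope="module")
def design():
    return design_pools([f"P{i}" for i in range(40)], 9, seed=1)


class TestIdentifyCrossReactant:

    def test_self_identification(self, design):
        target = "P7"
        hits = design.pools_of(target)
        assert identify_cross_reactant(hits, design) == target

    def test_disjoint_hits_return_none(self, design):
        p1 = design.pools_of("P1")[0]
        # find a set2 pool sharing no member with p1
        members1 = set(design.pool_members(p1))
        for pid in design.pool_ids:
            if pid.startswith("S2") and \
                    not members1 & set(design.pool_members(pid)):
                assert identify_cross_reactant([p1, pid], design) is None
                return
        pytest.skip("no disjoint pool found in this design")

    def test_same_set_hits_return_none(self, design):
        assert identify_cross_reactant(["S1_P01", "S1_P02"], design) is None

    def test_wrong_hit_count_returns_none(self, design):
        assert identify_cross_reactant(["S1_P01"], design) is None
        assert identify_cross_reactant(
            ["S1_P01", "S2_P01", "S2_P02"], design) is None


class TestTimeBin:
    @pytest.mark.parametrize("offset,label", [
        (0, "t0"), (-5, "t-1"), (-2, "t-1"), (-7, "t-1"),
        (2, "t1"), (7, "t1"), (8, "t2"), (20, "t2"),
        (1, "unclassified"), (-1, "unclassified"), (-8, "unclassified"),
        (21, "unclassified"),
    ])
    def test_windows(self, offset, label):
        assert time_bin(offset) == label
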