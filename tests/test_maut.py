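"""Exponential value functions, weighting, aggregation and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import rhizorank as rr
from rhizorank import maut
from rhizorank.errors import CompletenessError, ConfigError, DomainError


def spec(vmin, vmid, vmax, direction="increasing", attr="a",
         criterion="plant_growth"):
    return rr.AttributeSpec(attr, criterion, vmin, vmid, vmax,
                            direction=direction)


@st.composite
def valid_specs(draw):
    vmin = draw(st.floats(-100, 100))
    rng = draw(st.floats(0.1, 200))
    frac = draw(st.floats(0.05, 0.95).filter(lambda u: abs(u - 0.5) > 1e-3))
    direction = draw(st.sampled_from(["increasing", "decreasing"]))
    return spec(vmin, vmin + frac * rng, vmin + rng, direction)


class TestCurvature:
    def test_symmetric_midpoint_is_linear(self):
        assert math.isinf(rr.solve_curvature(spec(0, 0.5, 1)))

    def test_bisection_hits_midpoint(self):
        s = spec(0, 0.25, 1)
        rho = rr.solve_curvature(s, tol=1e-10)
        assert rr.savf_score(0.25, s, rho) == pytest.approx(0.5, abs=1e-9)

        # independent root: brentq on the closed-form midpoint equation
        f = lambda c: (1 - np.exp(-0.25 * c)) / (1 - np.exp(-c)) - 0.5
        c_oracle = brentq(f, 1e-6, 100, xtol=1e-12)
        assert rho == pytest.approx(1.0 / c_oracle, rel=1e-6)

    def test_curvature_grows_as_midpoint_approaches_min(self):
        rhos = [rr.solve_curvature(spec(0, m, 1)) for m in (0.4, 0.3, 0.2, 0.1)]
        assert all(r > 0 for r in rhos)
        assert rhos == sorted(rhos, reverse=True)  # |rho| -> 0+: more concave

    def test_invalid_anchors(self):
        with pytest.raises(DomainError):
            spec(0, 0.5, 0.5)
        with pytest.raises(DomainError):
            spec(0, 0.0, 1.0)


class TestSavfScore:
    def test_anchor_values(self):
        s = spec(2, 3, 7)
        assert rr.savf_score(2, s) == pytest.approx(0.0, abs=1e-9)
        assert rr.savf_score(3, s) == pytest.approx(0.5, abs=1e-9)
        assert rr.savf_score(7, s) == pytest.approx(1.0, abs=1e-9)

    def test_linear_case(self):
        assert rr.savf_score(0.25, spec(0, 0.5, 1)) == pytest.approx(0.25)

    def test_decreasing_direction_flip(self):
        s = spec(0, 0.5, 1, direction="decreasing")
        assert rr.savf_score(0.0, s) == pytest.approx(1.0)
        assert rr.savf_score(1.0, s) == pytest.approx(0.0)

    def test_out_of_range_clamped(self):
        s = spec(0, 0.25, 1)
        assert rr.savf_score(-5.0, s) == 0.0
        assert rr.savf_score(42.0, s) == 1.0

    @given(valid_specs())
    @settings(max_examples=100, deadline=None)
    def test_anchors_monotonicity_bounds(self, s):
        rho = rr.solve_curvature(s)
        lo, mid, hi = ((1.0, 0.5, 0.0) if s.direction == "decreasing"
                       else (0.0, 0.5, 1.0))
        assert rr.savf_score(s.v_min, s, rho) == pytest.approx(lo, abs=1e-9)
        assert rr.savf_score(s.v_mid, s, rho) == pytest.approx(mid, abs=1e-9)
        assert rr.savf_score(s.v_max, s, rho) == pytest.approx(hi, abs=1e-9)
        grid = np.linspace(s.v_min, s.v_max, 100)
        vals = rr.savf_score(grid, s, rho)
        assert np.all(vals >= 0) and np.all(vals <= 1)
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-12) if s.direction == "increasing" \
            else np.all(diffs <= 1e-12)

    def test_linear_limit_convergence(self):
        s = spec(0, 0.5 + 1e-8, 1)
        rho = rr.solve_curvature(s)
        grid = np.linspace(0, 1, 10)
        np.testing.assert_allclose(rr.savf_score(grid, s, rho), grid,
                                   atol=1e-6)


class TestScoreMatrix:
    def _perf(self, data, attrs):
        values = pd.DataFrame(data, index=pd.Index(["X", "Y"], name="strain"),
                              columns=attrs)
        prov = pd.DataFrame({"source_assay": "t", "units": "u"},
                            index=pd.Index(attrs, name="attribute"))
        return rr.PerformanceMatrix(values, prov)

    def test_extremes(self):
        specs = [spec(0, 0.3, 1, attr="a"), spec(0, 0.3, 1, attr="b")]
        top = self._perf([[1.0, 1.0], [0.0, 0.0]], ["a", "b"])
        sm = rr.score_matrix(top, specs)
        assert (sm.values.loc["X"] == 1.0).all()
        assert (sm.values.loc["Y"] == 0.0).all()

    def test_matches_independent_evaluation(self):
        s = spec(1.0, 2.0, 5.0, attr="a")
        perf = self._perf([[1.8, 0.0], [4.2, 0.0]], ["a", "b"])
        specs = [s, spec(0, 0.25, 1, attr="b")]
        sm = rr.score_matrix(perf, specs)
        # independent closed form with an independently solved curvature
        f = lambda c: (1 - np.exp(-0.25 * c)) / (1 - np.exp(-c)) - 0.5
        c = brentq(f, 1e-6, 100, xtol=1e-14)  # u = 0.25 for both specs
        for strain, x in (("X", 1.8), ("Y", 4.2)):
            t = (x - 1.0) / 4.0
            expected = (1 - np.exp(-t * c)) / (1 - np.exp(-c))
            assert sm.values.at[strain, "a"] == pytest.approx(expected,
                                                              abs=1e-9)

    def test_missing_spec_rejected(self):
        perf = self._perf([[1.0, 1.0], [0.0, 0.0]], ["a", "b"])
        with pytest.raises(CompletenessError, match="b"):
            rr.score_matrix(perf, [spec(0, 0.3, 1, attr="a")])

    def test_clamp_recorded(self):
        perf = self._perf([[2.0, 0.5], [-1.0, 0.5]], ["a", "b"])
        sm = rr.score_matrix(perf, [spec(0, 0.3, 1, attr="a"),
                                    spec(0, 0.3, 1, attr="b")])
        assert sm.clamped.at["X", "a"] and sm.clamped.at["Y", "a"]
        assert not sm.clamped.at["X", "b"]


class TestWeights:
    def test_equal_split(self):
        specs = [spec(0, 0.3, 1, attr=a, criterion=c) for a, c in
                 [("a", "plant_growth"), ("b", "colonization"),
                  ("c", "persistence")]]
        sc = rr.ScenarioWeights("s", {"plant_growth": 1, "colonization": 1,
                                      "persistence": 1})
        w = rr.attribute_weights(sc, specs)
        assert all(v == pytest.approx(1 / 3) for v in w.values())

    def test_uneven_criterion_sizes(self):
        specs = ([spec(0, .3, 1, attr=f"g{i}", criterion="plant_growth")
                  for i in range(9)]
                 + [spec(0, .3, 1, attr=f"c{i}", criterion="colonization")
                    for i in range(4)]
                 + [spec(0, .3, 1, attr=f"p{i}", criterion="persistence")
                    for i in range(25)])
        sc = rr.ScenarioWeights("s", {"plant_growth": 0.5,
                                      "colonization": 0.25,
                                      "persistence": 0.25})
        w = rr.attribute_weights(sc, specs)
        assert w["g0"] == pytest.approx(0.5 / 9)
        assert w["c0"] == pytest.approx(0.0625)
        assert w["p0"] == pytest.approx(0.01)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)

    def test_raw_weights_normalised(self):
        sc = rr.ScenarioWeights("s", {"plant_growth": 2, "colonization": 1,
                                      "persistence": 1})
        assert sc.criterion_weights["plant_growth"] == pytest.approx(0.5)

    def test_weighted_empty_criterion_rejected(self):
        specs = [spec(0, 0.3, 1, attr="a", criterion="plant_growth")]
        sc = rr.ScenarioWeights("s", {"plant_growth": 1, "colonization": 1,
                                      "persistence": 0})
        with pytest.raises(ConfigError, match="colonization"):
            rr.attribute_weights(sc, specs)


def _scores(data, attrs, strains=("X", "Y")):
    return maut.ScoreMatrix(
        values=pd.DataFrame(data, index=pd.Index(strains, name="strain"),
                            columns=attrs),
        clamped=pd.DataFrame(False, index=list(strains), columns=attrs))


class TestTotals:
    def _specs3(self):
        return [spec(0, .3, 1, attr="a", criterion="plant_growth"),
                spec(0, .3, 1, attr="b", criterion="colonization"),
                spec(0, .3, 1, attr="c", criterion="persistence")]

    def test_equal_weights_mean(self):
        specs = self._specs3()
        sm = _scores([[0.2, 0.5, 0.8], [1, 1, 1]], ["a", "b", "c"])
        res = rr.total_scores(sm, {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, specs)
        assert res.table.at["X", "total"] == pytest.approx(0.5)
        assert res.table.at["Y", "total"] == pytest.approx(1.0)
        assert res.table.at["Y", "rank"] == 1

    def test_total_equals_sum_of_subtotals(self):
        specs = self._specs3()
        sm = _scores([[0.2, 0.5, 0.8], [0.9, 0.1, 0.3]], ["a", "b", "c"])
        res = rr.total_scores(sm, {"a": 0.5, "b": 0.3, "c": 0.2}, specs)
        subs = res.table[[c for c in res.table.columns
                          if c.startswith("subtotal")]].sum(axis=1)
        np.testing.assert_allclose(res.table["total"], subs)

    def test_weights_must_sum_to_one(self):
        sm = _scores([[0.2, 0.5, 0.8], [1, 1, 1]], ["a", "b", "c"])
        with pytest.raises(DomainError):
            rr.total_scores(sm, {"a": 0.5, "b": 0.5, "c": 0.5}, self._specs3())

    def test_tie_flag_and_lexicographic_order(self):
        specs = self._specs3()
        sm = _scores([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]], ["a", "b", "c"],
                     strains=("ZZ", "AA"))
        res = rr.total_scores(sm, {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}, specs)
        assert res.table.at["AA", "rank"] == 1  # lexicographic tiebreak
        assert res.table["tied"].all()

    def test_duplicated_attribute_weight_split_invariance(self):
        specs = self._specs3()
        sm = _scores([[0.2, 0.5, 0.8], [0.9, 0.1, 0.3]], ["a", "b", "c"])
        res1 = rr.total_scores(sm, {"a": 0.5, "b": 0.25, "c": 0.25}, specs)
        # duplicate attribute 'a' into two identical halves
        specs2 = specs + [spec(0, .3, 1, attr="a2", criterion="plant_growth")]
        sm2 = _scores([[0.2, 0.2, 0.5, 0.8], [0.9, 0.9, 0.1, 0.3]],
                      ["a", "a2", "b", "c"])
        res2 = rr.total_scores(sm2, {"a": 0.25, "a2": 0.25, "b": 0.25,
                                     "c": 0.25}, specs2)
        np.testing.assert_allclose(res1.table["total"], res2.table["total"])

    @given(st.floats(0.01, 100))
    @settings(max_examples=30, deadline=None)
    def test_ranking_invariant_under_weight_rescaling(self, k):
        specs = self._specs3()
        sm = _scores([[0.2, 0.5, 0.8], [0.9, 0.1, 0.3]], ["a", "b", "c"])
        base = rr.ScenarioWeights("s", {"plant_growth": 0.5,
                                        "colonization": 0.3,
                                        "persistence": 0.2})
        scaled = rr.ScenarioWeights("s", {c: k * w for c, w in
                                          base.criterion_weights.items()})
        r1 = rr.rank_scenario(sm, base, specs)
        r2 = rr.rank_scenario(sm, scaled, specs)
        pd.testing.assert_series_equal(r1.ranks, r2.ranks)


class TestScenarioComparison:
    def _setup(self):
        specs = [spec(0, .3, 1, attr="a", criterion="plant_growth"),
                 spec(0, .3, 1, attr="b", criterion="colonization"),
                 spec(0, .3, 1, attr="c", criterion="persistence")]
        # X dominates criteria 1-2, Y dominates criterion 3 strongly enough
        # to prevail once all criteria weigh the same
        sm = _scores([[0.9, 0.9, 0.0], [0.5, 0.5, 1.0]], ["a", "b", "c"])
        return specs, sm

    def test_reversal_between_weighting_schemes(self):
        specs, sm = self._setup()
        growth_heavy = rr.rank_scenario(sm, rr.ScenarioWeights(
            "s1", {"plant_growth": 0.5, "colonization": 0.25,
                   "persistence": 0.25}), specs)
        equal = rr.rank_scenario(sm, rr.ScenarioWeights(
            "s3", {"plant_growth": 1 / 3, "colonization": 1 / 3,
                   "persistence": 1 / 3}), specs)
        assert growth_heavy.top_strain() == "X"
        assert equal.top_strain() == "Y"
        cmp_ = rr.compare_scenarios([growth_heavy, equal])
        assert cmp_.has_reversals

    def test_identical_scenarios_no_reversal(self):
        specs, sm = self._setup()
        w = {"plant_growth": 1 / 3, "colonization": 1 / 3,
             "persistence": 1 / 3}
        r1 = rr.rank_scenario(sm, rr.ScenarioWeights("s1", w), specs)
        r2 = rr.rank_scenario(sm, rr.ScenarioWeights("s2", w), specs)
        cmp_ = rr.compare_scenarios([r1, r2])
        assert not cmp_.has_reversals
        pd.testing.assert_series_equal(cmp_.totals["s1"], cmp_.totals["s2"],
                                       check_names=False)

    def test_single_strain_always_rank_one(self):
        specs = [spec(0, .3, 1, attr="a", criterion="plant_growth")]
        sm = maut.ScoreMatrix(
            values=pd.DataFrame({"a": [0.4]},
                                index=pd.Index(["X"], name="strain")),
            clamped=pd.DataFrame({"a": [False]}, index=["X"]))
        sc = rr.ScenarioWeights("s", {"plant_growth": 1})
        res = rr.rank_scenario(sm, sc, specs)
        assert res.table.at["X", "rank"] == 1


class TestYamlConfig:
    def test_round_trip(self, tmp_path):
        specs = rr.default_attribute_specs()
        scenarios = rr.default_scenarios()
        path = tmp_path / "cfg.yaml"
        maut.dump_maut_config(specs, scenarios, path)
        specs2, scen2 = rr.load_maut_config(path)
        assert [s.attribute_id for s in specs2] == \
            [s.attribute_id for s in specs]
        assert len(specs2) == 38
        assert scen2[0].criterion_weights == \
            scenarios[0].criterion_weights
        assert all(s2 == s1 for s1, s2 in zip(specs, specs2))
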