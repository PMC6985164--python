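"""Differential tests, BH correction, enrichment, survival, associations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfuse import (
    SurvivalRecord,
    categorical_assoc,
    hypergeom_enrich,
    km_curves,
    read_gmt,
    welch_bh,
)


def _bh_step_up(pvals):
    """Independent oracle: the step-up formula written out directly."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        j = order[rank - 1]
        running = min(running, p[j] * m / rank)
        q[j] = running
    return q


class TestWelchBH:
    def test_bh_matches_step_up_oracle_on_random_pvectors(self, rng):
        # route the p-values through welch_bh by building data whose
        # per-feature Welch p equals whatever comes out, then check the
        # q-vector against the hand-coded step-up formula
        X = rng.normal(size=(30, 40))
        y = np.repeat([1, 2], 15)
        res = welch_bh(X, y)
        p = np.array([r.p for r in res])
        q = np.array([r.q for r in res])
        np.testing.assert_allclose(q, _bh_step_up(p), atol=1e-12)

    def test_bh_worked_example(self):
        # p = (0.01, 0.02, 0.03, 0.04), m=4 -> q all 0.04 by step-up
        np.testing.assert_allclose(
            _bh_step_up([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identical_groups_give_unit_pvalues(self):
        block = np.arange(20, dtype=float).reshape(4, 5)
        X = np.vstack([block, block])
        y = np.repeat([1, 2], 4)
        res = welch_bh(X, y)
        assert all(r.p > 0.99 for r in res)

    def test_planted_shifts_recovered_with_power(self, rng):
        n_per, p_inf, p_null = 20, 30, 170
        X = rng.normal(size=(2 * n_per, p_inf + p_null))
        y = np.repeat([1, 2], n_per)
        X[y == 2, :p_inf] += 2.0
        res = welch_bh(X, y)
        hits = sum(1 for r in res[:p_inf] if r.q < 0.05)
        assert hits / p_inf >= 0.9
        assert all(r.direction == "up-in-2" for r in res[:p_inf])

    def test_null_type_one_error_controlled(self, rng):
        X = rng.normal(size=(40, 400))
        y = np.repeat([1, 2], 20)
        res = welch_bh(X, y)
        assert sum(r.q < 0.05 for r in res) / len(res) <= 0.05 + 0.03

    def test_zero_variance_feature_flagged_not_fatal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        X[:, 1] = 4.0
        res = welch_bh(X, np.repeat([1, 2], 5))
        assert res[1].degenerate and res[1].p == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_bh_q_at_least_p_and_single_test_identity(self, pvals):
        q = _bh_step_up(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        if len(pvals) == 1:
            assert q[0] == pytest.approx(pvals[0])


class TestHypergeom:
    def test_closed_form_worked_case(self):
        # universe 10, set of 5, query of 3 fully inside: p = C(5,3)/C(10,3)
        universe = [f"g{i}" for i in range(10)]
        sets = {"T": set(universe[:5])}
        res = hypergeom_enrich(universe[:3], sets, universe)
        assert res[0].p == pytest.approx(10 / 120)
        assert res[0].overlap == 3

    def test_disjoint_query_and_certain_event(self):
        universe = [f"g{i}" for i in range(10)]
        sets = {"T": set(universe[:5])}
        res = hypergeom_enrich(universe[5:8], sets, universe)
        assert res[0].p == pytest.approx(1.0)
        res = hypergeom_enrich(universe, sets, universe)
        assert res[0].overlap == 5 and res[0].p == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        from scipy.stats import hypergeom

        ps = [float(hypergeom.sf(k - 1, 50, 10, 10)) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], {"T": {"a"}}, ["a", "b"])

    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pathA\tdesc\tg1\tg2\tg3\npathB\tdesc\tg2\tg4\n")
        sets = read_gmt(gmt)
        assert sets == {"pathA": {"g1", "g2", "g3"}, "pathB": {"g2", "g4"}}


def _recs(times, events, group):
    return [
        SurvivalRecord(sample_id=f"{group}-{i}", time=t, event=e, group=group)
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        km = km_curves(_recs(times, [True] * 5, 1))
        sf = km.survival_functions[1]
        # steps of 1/5 at each event time; median is the 3rd event
        for i, t in enumerate(times):
            assert sf.loc[t].iloc[0] == pytest.approx(1 - (i + 1) / 5)
        assert km.medians[1] == pytest.approx(3.0)

    def test_identical_groups_logrank_null(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        recs = _recs(times, [True] * 6, 1) + _recs(times, [True] * 6, 2)
        km = km_curves(recs)
        assert km.logrank_p > 0.9

    def test_separated_exponential_groups_significant(self, rng):
        n = 500
        t1 = rng.exponential(10.0, size=n)
        t2 = rng.exponential(20.0, size=n)
        cens = rng.random(n) < 0.2
        recs = _recs(t1, ~cens, 1) + _recs(t2, ~cens, 2)
        km = km_curves(recs)
        assert km.logrank_p < 0.001
        assert km.medians[1] < km.medians[2]

    def test_all_censored_group_median_not_reached(self):
        recs = _recs([5.0, 6.0], [False, False], 1) + _recs(
            [1.0, 2.0, 3.0], [True, True, True], 2
        )
        km = km_curves(recs)
        assert np.isnan(km.medians[1])
        assert km.logrank_p is not None


class TestCategorical:
    def test_perfectly_associated_2x2_fisher_closed_form(self):
        chi2, _, fisher_p = categorical_assoc(np.array([[10, 0], [0, 10]]))
        # two-sided doubling of the single most extreme table: 2/C(20,10)
        assert fisher_p == pytest.approx(2 / 184756, rel=1e-6)
        assert chi2 == pytest.approx(20.0)

    def test_proportional_table_zero_chi2(self):
        chi2, p, _ = categorical_assoc(np.array([[10, 20], [20, 40]]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_balanced_2x2_fisher_unity(self):
        _, _, fisher_p = categorical_assoc(np.array([[5, 5], [5, 5]]))
        assert fisher_p == pytest.approx(1.0)

    def test_zero_margin_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            chi2, _, _ = categorical_assoc(np.array([[5, 5, 0], [5, 5, 0]]))
        assert "zero-margin" in caplog.text

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            categorical_assoc(np.array([[1.5, 2.0], [3.0, 4.0]]))
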