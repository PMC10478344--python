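"""Scoring keys, screening, scale/octant scoring and omega reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circumplex_ssm import (
    OctantGeometry,
    ScoringKey,
    ScreeningRules,
    omega_total,
    score_octants,
    score_scale,
    screen_protocols,
)
from circumplex_ssm.instruments import omega_from_loadings


def make_key(n_items=10, lo=0, hi=4, aggregation="sum", scale="s"):
    items = [f"i{j}" for j in range(n_items)]
    return ScoringKey(
        instrument="test", item_ids=items, scale_map={scale: items},
        response_min=lo, response_max=hi, aggregation=aggregation,
    )


def frame(values, items=None, ids=None):
    values = np.asarray(values, dtype=float)
    items = items or [f"i{j}" for j in range(values.shape[1])]
    ids = ids or [f"p{j}" for j in range(values.shape[0])]
    return pd.DataFrame(values, columns=items, index=ids)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


class TestScreening:
    def make_responses(self, n=10, n_items=100):
        rng = np.random.default_rng(0)
        return frame(rng.integers(0, 5, size=(n, n_items)),
                     items=[f"i{j}" for j in range(n_items)],
                     ids=[f"p{j}" for j in range(n)])

    def test_clean_data_retains_everyone(self):
        responses = self.make_responses()
        validity = pd.Series(0.0, index=responses.index)
        res = screen_protocols(responses, validity, ScreeningRules())
        assert res.retained.shape[0] == responses.shape[0]
        assert res.ledger.reasons == {}
        assert res.ledger.counts == {"missingness": 0, "infrequency": 0, "manual": 0}

    def test_missingness_threshold_is_strict(self):
        # exactly 2% blank is retained; strictly more is excluded
        responses = self.make_responses(n=3, n_items=100)
        responses.iloc[0, :2] = np.nan  # exactly 2.0%
        responses.iloc[1, :3] = np.nan  # 3%
        validity = pd.Series(0.0, index=responses.index)
        res = screen_protocols(responses, validity, ScreeningRules(max_missing_fraction=0.02))
        assert "p0" in res.retained.index
        assert res.ledger.reasons == {"p1": "missingness"}

    def test_rule_attribution_order_is_missingness_first(self):
        responses = self.make_responses(n=4)
        responses.iloc[0, :10] = np.nan  # caught by missingness even though careless
        validity = pd.Series([99.0, 99.0, 0.0, 0.0], index=responses.index)
        rules = ScreeningRules(infrequency_norm_mean=1.0, infrequency_norm_sd=1.0,
                               manual_exclusions=["p1", "p3"])
        res = screen_protocols(responses, validity, rules)
        assert res.ledger.reasons == {
            "p0": "missingness", "p1": "infrequency", "p3": "manual",
        }
        assert res.ledger.counts == {"missingness": 1, "infrequency": 1, "manual": 1}

    def test_screening_is_idempotent(self):
        responses = self.make_responses(n=20)
        responses.iloc[:5, :30] = np.nan
        validity = pd.Series(np.r_[np.zeros(15), np.full(5, 50.0)], index=responses.index)
        rules = ScreeningRules(infrequency_norm_mean=0.5, infrequency_norm_sd=1.0)
        first = screen_protocols(responses, validity, rules)
        second = screen_protocols(first.retained, validity[first.retained.index], rules)
        assert second.ledger.n_excluded == 0
        assert second.retained.index.equals(first.retained.index)

    def test_unknown_manual_id_and_empty_matrix_raise(self):
        responses = self.make_responses(n=3)
        validity = pd.Series(0.0, index=responses.index)
        with pytest.raises(ValueError, match="unknown participants"):
            screen_protocols(responses, validity, ScreeningRules(manual_exclusions=["zz"]))
        with pytest.raises(ValueError, match="empty"):
            screen_protocols(responses.iloc[:0], validity, ScreeningRules())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class TestScoring:
    def test_true_false_sum_scale_maximum(self):
        # 24 endorsed true/false items score 24
        key = make_key(n_items=24, lo=0, hi=1, aggregation="sum")
        responses = frame(np.ones((2, 24)))
        assert score_scale(responses, key, "s").tolist() == [24.0, 24.0]

    def test_mean_scale_constant_case(self):
        key = make_key(n_items=8, lo=1, hi=5, aggregation="mean")
        responses = frame(np.full((3, 8), 3.0))
        assert score_scale(responses, key, "s").tolist() == [3.0, 3.0, 3.0]

    def test_prorated_sum_with_one_missing(self):
        # 10-item sum scale, 1 missing, answered mean 2.0 -> prorated sum 20
        key = make_key(n_items=10, lo=0, hi=4, aggregation="sum")
        row = np.full((1, 10), 2.0)
        row[0, 3] = np.nan
        assert score_scale(frame(row), key, "s").iloc[0] == pytest.approx(20.0)

    def test_score_missing_when_under_proration_limit(self):
        key = make_key(n_items=10, lo=0, hi=4, aggregation="sum")
        row = np.full((1, 10), 2.0)
        row[0, :3] = np.nan  # 70% answered < 80%
        assert np.isnan(score_scale(frame(row), key, "s").iloc[0])

    def test_unknown_scale_and_out_of_bounds_raise(self):
        key = make_key(n_items=5, lo=0, hi=4)
        responses = frame(np.full((2, 5), 2.0))
        with pytest.raises(KeyError):
            score_scale(responses, key, "nope")
        responses.iloc[0, 0] = 9.0
        with pytest.raises(ValueError, match="out of bounds"):
            score_scale(responses, key, "s")

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 4), min_size=6, max_size=6),
            min_size=1, max_size=8,
        )
    )
    def test_prorated_sum_equals_plain_sum_when_complete(self, data):
        key = make_key(n_items=6, lo=0, hi=4, aggregation="sum")
        responses = frame(np.asarray(data, dtype=float))
        scores = score_scale(responses, key, "s")
        assert np.allclose(scores, responses.sum(axis=1))


class TestOctantScoring:
    def octant_key(self, responses_min=0, responses_max=8, per_octant=2):
        geometry = OctantGeometry()
        octant_map = {
            code: [f"{code}_{j}" for j in range(per_octant)] for code in geometry.codes
        }
        items = [i for code in geometry.codes for i in octant_map[code]]
        return ScoringKey(
            instrument="circ", item_ids=items, scale_map=dict(octant_map),
            response_min=responses_min, response_max=responses_max,
            aggregation="mean", octant_map=octant_map,
        )

    def test_constant_responses_give_constant_octants(self):
        key = self.octant_key()
        responses = frame(np.zeros((3, 16)), items=key.item_ids)
        table = score_octants(responses, key)
        assert list(table.columns) == list(OctantGeometry().codes)
        assert (table.to_numpy() == 0).all()
        responses8 = frame(np.full((3, 16), 8.0), items=key.item_ids)
        assert (score_octants(responses8, key).to_numpy() == 8).all()

    def test_octant_scoring_matches_scale_path(self):
        key = self.octant_key()
        rng = np.random.default_rng(7)
        values = rng.integers(0, 9, size=(20, 16)).astype(float)
        values[rng.random(values.shape) < 0.05] = np.nan
        responses = frame(values, items=key.item_ids)
        table = score_octants(responses, key)
        for code in OctantGeometry().codes:
            pd.testing.assert_series_equal(
                table[code], score_scale(responses, key, code), check_names=False
            )

    def test_missing_octant_in_key_raises(self):
        key = self.octant_key()
        key.octant_map = {k: v for k, v in key.octant_map.items() if k != "PA"}
        responses = frame(np.zeros((3, 16)), items=key.item_ids)
        with pytest.raises(ValueError, match="PA|octant"):
            score_octants(responses, key)

    def test_octant_scores_recover_latents(self, geometry):
        # items built from known octant latents (loading .9): the octant
        # composites correlate > .95 with the latents at n = 2000
        rng = np.random.default_rng(11)
        n, lam = 2000, 0.9
        angles = geometry.angles_rad
        g, X, Y = rng.standard_normal((3, n))
        eps = rng.standard_normal((n, 8))
        latents = (np.sqrt(0.3) * g[:, None]
                   + np.sqrt(0.3) * (np.cos(angles) * X[:, None] + np.sin(angles) * Y[:, None])
                   + np.sqrt(0.4) * eps)
        key = self.octant_key(responses_min=-10, responses_max=10, per_octant=4)
        cols = {}
        for k_idx, code in enumerate(geometry.codes):
            items = lam * latents[:, [k_idx]] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 4))
            for j, name in enumerate(key.octant_map[code]):
                cols[name] = items[:, j]
        responses = pd.DataFrame(cols)[key.item_ids]
        table = score_octants(responses, key)
        for k_idx, code in enumerate(geometry.codes):
            r = np.corrcoef(table[code], latents[:, k_idx])[0, 1]
            assert r > 0.95


# ---------------------------------------------------------------------------
# omega_t reliability
# ---------------------------------------------------------------------------


def congeneric_items(rng, n, loadings):
    f = rng.standard_normal(n)
    lam = np.asarray(loadings)
    noise = rng.standard_normal((n, len(lam))) * np.sqrt(1 - lam**2)
    return frame(f[:, None] * lam + noise,
                 items=[f"i{j}" for j in range(len(lam))],
                 ids=[f"p{j}" for j in range(n)])


class TestOmega:
    def test_parallel_items_match_closed_form(self):
        # 4 parallel items, loading .7: omega = (4*.7)^2/((4*.7)^2 + 4*(1-.49))
        expected = (4 * 0.7) ** 2 / ((4 * 0.7) ** 2 + 4 * (1 - 0.49))
        items = congeneric_items(np.random.default_rng(3), 20000, [0.7] * 4)
        res = omega_total(items, "parallel")
        assert res.omega_t == pytest.approx(expected, abs=0.02)
        assert expected == pytest.approx(0.79, abs=0.005)

    def test_limit_cases(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(2000)
        near_one = frame(np.column_stack([base + 1e-4 * rng.standard_normal(2000)
                                          for _ in range(4)]))
        assert omega_total(near_one).omega_t > 0.99
        independent = frame(rng.standard_normal((4000, 5)))
        assert omega_total(independent).omega_t < 0.15

    def test_invariance_under_reorder_and_scaling(self):
        rng = np.random.default_rng(5)
        items = congeneric_items(rng, 3000, [0.8, 0.7, 0.6, 0.5, 0.75])
        res = omega_total(items)
        shuffled = omega_total(items[list(items.columns[::-1])])
        scaled = omega_total(items * 3.7)
        assert shuffled.omega_t == pytest.approx(res.omega_t, abs=1e-4)
        assert scaled.omega_t == pytest.approx(res.omega_t, abs=1e-4)

    def test_preconditions(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="3 items"):
            omega_total(frame(rng.standard_normal((100, 2))))
        with pytest.raises(ValueError, match="complete rows"):
            omega_total(frame(rng.standard_normal((30, 4))))

    def test_omega_from_loadings_formula(self):
        lam = np.array([0.7, 0.7, 0.7, 0.7])
        psi = 1 - lam**2
        assert omega_from_loadings(lam, psi) == pytest.approx(7.84 / 9.88, abs=1e-12)
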