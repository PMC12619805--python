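import numpy as np
import pytest

from biochemom.bioassay import BioactivitySummary
from biochemom.models import fit_pls_model, pls_fit
from biochemom.selection import (
    SR_CAP, SelectionScores, assign_direction, select_candidates,
    selectivity_ratio, vip_scores,
)
from tests.test_models import standardize
from tests.test_preprocess import make_table


def fitted_model(rng, n=12, p=5, a=2):
    X = standardize(rng.normal(size=(n, p)))
    y = X @ rng.normal(size=p) + rng.normal(0, 0.3, n)
    y = y - y.mean()
    return pls_fit(X, y, max_components=a), X


class TestVip:
    def test_single_feature_is_one(self, rng):
        x = standardize(rng.normal(size=(10, 1)))
        y = x.ravel() + rng.normal(0, 0.1, 10)
        model = pls_fit(x, y - y.mean(), max_components=1)
        assert vip_scores(model)[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_weights_all_one(self):
        # y depends on all 3 standardized columns identically
        base = np.array([[1, 1, 1], [2, 2, 2], [4, 4, 4], [5, 5, 5]], float)
        X = standardize(base + 0.0)
        y = X[:, 0].copy()
        model = pls_fit(X, y, max_components=1)
        np.testing.assert_allclose(vip_scores(model), 1.0, atol=1e-10)

    def test_direct_formula_oracle(self, rng):
        model, _ = fitted_model(rng, p=5, a=2)
        W, T, q = model.weights, model.x_scores, model.y_loadings
        ssy = np.array([q[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(2)])
        wn = W / np.sqrt((W ** 2).sum(axis=0))
        expected = np.sqrt(5 * (wn ** 2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-10)

    def test_sum_of_squares_equals_p(self, rng):
        for p in (3, 7, 15):
            model, _ = fitted_model(rng, n=20, p=p, a=3)
            assert np.sum(vip_scores(model) ** 2) == pytest.approx(p, abs=1e-8)


class TestSelectivityRatio:
    def test_brute_force_oracle(self, rng):
        model, X = fitted_model(rng, n=6, p=4, a=2)
        sr, _ = selectivity_ratio(model, X)
        t = X @ model.coef / np.linalg.norm(model.coef)
        for j in range(4):
            # explicit least-squares projection of column j on the TP score
            pj = float(X[:, j] @ t / (t @ t))
            v_exp = np.sum((t * pj) ** 2)
            v_res = np.sum((X[:, j] - t * pj) ** 2)
            assert sr[j] == pytest.approx(v_exp / v_res, abs=1e-10)

    def _single_direction_model(self, X):
        """Model whose regression vector loads only on column 0, so the
        target-projection score is exactly X[:, 0]."""
        from biochemom.models import PlsModel
        p = X.shape[1]
        coef = np.zeros(p)
        coef[0] = 1.0
        return PlsModel(n_components=1, weights=coef[:, None],
                        x_loadings=coef[:, None], x_scores=X[:, :1].copy(),
                        y_loadings=np.array([1.0]), coef=coef)

    def test_column_proportional_to_tp_is_capped(self, rng):
        X = standardize(rng.normal(size=(10, 4)))
        X[:, 2] = 2.5 * X[:, 0]       # proportional to the TP score
        model = self._single_direction_model(X)
        sr, capped = selectivity_ratio(model, X)
        assert sr[0] == SR_CAP and 0 in capped
        assert sr[2] == SR_CAP and 2 in capped

    def test_orthogonal_column_scores_zero(self, rng):
        X = standardize(rng.normal(size=(10, 4)))
        t = X[:, 0]
        v = rng.normal(size=10)
        X[:, 1] = v - (v @ t) / (t @ t) * t   # orthogonal to the TP score
        model = self._single_direction_model(X)
        sr, _ = selectivity_ratio(model, X)
        assert sr[1] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_positive_y_scaling(self, rng):
        X = standardize(rng.normal(size=(15, 5)))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.2, 15)
        y = y - y.mean()
        m1 = pls_fit(X, y, 2)
        m2 = pls_fit(X, 7.0 * y, 2)
        np.testing.assert_allclose(selectivity_ratio(m1, X)[0],
                                   selectivity_ratio(m2, X)[0], atol=1e-8)

    def test_duplicated_feature_scores_identically(self, rng):
        X = standardize(rng.normal(size=(12, 4)))
        X = np.column_stack([X, X[:, 0]])
        y = X[:, 0] + rng.normal(0, 0.3, 12)
        model = pls_fit(X, y - y.mean(), 2)
        sr, _ = selectivity_ratio(model, X)
        vip = vip_scores(model)
        assert sr[0] == pytest.approx(sr[4], abs=1e-8)
        assert vip[0] == pytest.approx(vip[4], abs=1e-8)


def bio_sorted(values):
    return [BioactivitySummary(f"S{i}", float(v), 0.0, float(np.log(v)))
            for i, v in enumerate(values)]


class TestAssignDirection:
    def test_area_decreasing_in_ic50_is_positive_activity(self):
        ic50 = np.linspace(57, 117, 12)
        areas = (200 - ic50)[:, None]  # more area in the most active samples
        table = make_table(areas)
        direction, top, bottom = assign_direction(["F0"], table, bio_sorted(ic50), k=5)
        assert direction["F0"] == "positive_activity"
        assert top["F0"] > bottom["F0"]

    def test_constant_feature_ties_to_negative(self, caplog):
        ic50 = np.linspace(57, 117, 12)
        table = make_table(np.full((12, 1), 3.0))
        with caplog.at_level("WARNING"):
            direction, _, _ = assign_direction(["F0"], table, bio_sorted(ic50), k=5)
        assert direction["F0"] == "negative_activity"
        assert any("tied" in r.message for r in caplog.records)

    def test_k_too_large_rejected(self):
        ic50 = np.linspace(57, 117, 8)
        table = make_table(np.ones((8, 1)))
        with pytest.raises(ValueError, match="k=5"):
            assign_direction(["F0"], table, bio_sorted(ic50), k=5)

    def test_spiked_active_always_positive(self):
        from biochemom.synthetic import ScenarioSpec, generate_dataset
        hits, total = 0, 0
        for seed in range(50):
            spec = ScenarioSpec(seed=seed, n_features=50, n_contaminant_spikes=0)
            table, _, bio, truth = generate_dataset(spec)
            direction, _, _ = assign_direction(
                sorted(truth.active_ids), table, bio, k=5)
            total += len(direction)
            hits += sum(d == "positive_activity" for d in direction.values())
        assert hits == total


def scores_with(n_sr, n_extra_vip, p=20):
    """n_sr features pass both; n_extra_vip more pass only VIP."""
    sr = np.full(p, 0.1)
    vip = np.full(p, 0.5)
    sr[:n_sr] = 0.8
    vip[: n_sr + n_extra_vip] = 1.5
    return SelectionScores(
        feature_ids=[f"F{j}" for j in range(p)], vip=vip, sr=sr,
        vip_threshold=1.0, sr_threshold=0.5,
        direction={f"F{j}": "negative_activity" for j in range(p)},
        sr_capped=[],
    )


class TestSelectCandidates:
    def table(self, p=20):
        return make_table(np.ones((2, p)) + np.arange(p))

    def test_union_of_8_sr_and_4_extra_vip_is_12(self):
        report = select_candidates(scores_with(8, 4), self.table(), mode="union")
        assert len(report.candidates) == 12

    def test_intersection_is_8(self):
        report = select_candidates(scores_with(8, 4), self.table(), mode="intersection")
        assert len(report.candidates) == 8

    def test_all_below_thresholds_empty(self):
        report = select_candidates(scores_with(0, 0), self.table(), mode="union")
        assert report.candidates == []

    def test_candidates_carry_mz_rt_and_lasso_coef(self):
        table = self.table()
        report = select_candidates(
            scores_with(2, 0), table, mode="union", lasso_coefs={"F0": -0.3})
        by_id = {c.feature_id: c for c in report.candidates}
        assert by_id["F0"].lasso_coef == -0.3
        assert by_id["F1"].mz == pytest.approx(table.mz[1])
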