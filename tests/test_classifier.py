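import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from faskel import (
    CohortSpec,
    ConvergenceError,
    PlattParams,
    SVMConfig,
    decision_value,
    generate_cohort,
    platt_fit,
    platt_prob,
    predict_label,
    train_linear_svm,
    weight_map,
)
from faskel.classifier import solve_svc_dual
from faskel.imaging import CommonMask, compute_common_mask, vectorize


def qp_oracle_svm(X, y, C=1.0):
    """Independent solve of the C-SVM dual as a generic QP (SLSQP)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (X @ X.T) * np.outer(y, y)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = minimize(
        obj,
        np.full(n, min(C, 1.0) / 2),
        jac=grad,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    alpha = res.x
    w = X.T @ (alpha * y)
    free = (alpha > 1e-6) & (alpha < C - 1e-6)
    if free.any():
        b = np.mean(y[free] - X[free] @ w)
    else:
        b = 0.0
    return w, b, alpha


class TestSVMTraining:
    def test_one_dimensional_closed_form(self):
        # two points x=0 (control), x=2 (patient): max-margin slab gives w=1, b=-1
        model = train_linear_svm(np.array([[0.0], [2.0]]), [-1, +1], SVMConfig(C=1.0))
        assert model.w == pytest.approx([1.0], abs=1e-8)
        assert model.b == pytest.approx(-1.0, abs=1e-8)
        assert decision_value(model, np.array([0.0])) == pytest.approx(-1.0)
        assert decision_value(model, np.array([2.0])) == pytest.approx(1.0)

    def test_symmetric_two_dimensional(self):
        model = train_linear_svm(
            np.array([[-1.0, 0.0], [1.0, 0.0]]), [-1, +1], SVMConfig(C=1.0)
        )
        assert model.w == pytest.approx([1.0, 0.0], abs=1e-8)
        assert model.b == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_qp_oracle_on_2d_toy_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = 14
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=n) > 0, 1, -1)
        if np.all(y == y[0]):
            y[0] *= -1
        model = train_linear_svm(X, y, SVMConfig(C=1.0, tolerance=1e-8))
        w_ref, b_ref, _ = qp_oracle_svm(X, y, C=1.0)
        assert model.w == pytest.approx(w_ref, abs=1e-4)
        assert model.b == pytest.approx(b_ref, abs=1e-4)

    def test_large_c_approaches_hard_margin(self):
        # separable 2-D set: for large C the solution is the max-margin plane
        X = np.array([[0.0, 1.0], [1.0, 2.0], [3.0, 0.0], [4.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        soft = train_linear_svm(X, y, SVMConfig(C=1e6, tolerance=1e-10))
        w_ref, b_ref, _ = qp_oracle_svm(X, y, C=1e6)
        assert soft.w == pytest.approx(w_ref, abs=1e-4)
        assert soft.b == pytest.approx(b_ref, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.eye(3), [1, 1, 1])

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError):
            train_linear_svm(X, [-1, 1])

    def test_max_iter_exhaustion_reports_iterations(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.where(rng.random(40) < 0.5, 1, -1)
        y[0], y[1] = 1, -1
        with pytest.raises(ConvergenceError) as exc:
            train_linear_svm(X, y, SVMConfig(tolerance=1e-12, max_iter=3))
        assert exc.value.n_iter == 3

    def test_duality_gap_small(self, rng):
        X = rng.normal(size=(25, 8))
        y = np.where(X[:, 0] > 0, 1, -1)
        y[0] *= -1
        cfg = SVMConfig(C=1.0, tolerance=1e-8)
        model = train_linear_svm(X, y, cfg)
        w, b, a = model.w, model.b, model.dual_coefs
        primal = 0.5 * w @ w + cfg.C * np.sum(np.clip(1 - y * (X @ w + b), 0, None))
        K = X @ X.T
        dual = a.sum() - 0.5 * a @ (K * np.outer(y, y)) @ a
        assert primal - dual == pytest.approx(0.0, abs=1e-5)
        assert np.all(a >= -1e-12) and np.all(a <= cfg.C + 1e-12)

    def test_feature_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 6))
        y = np.where(rng.random(12) < 0.5, 1, -1)
        y[0], y[1] = 1, -1
        perm = rng.permutation(6)
        cfg = SVMConfig(tolerance=1e-10)
        m1 = train_linear_svm(X, y, cfg)
        m2 = train_linear_svm(X[:, perm], y, cfg)
        assert m2.w == pytest.approx(m1.w[perm], abs=1e-8)
        assert m2.b == pytest.approx(m1.b, abs=1e-8)

    def test_removing_non_support_subject_leaves_model_unchanged(self, rng):
        X = rng.normal(size=(20, 4)) + np.where(rng.random(20) < 0.5, 2, -2)[:, None]
        y = np.where(X[:, 0].round() > 0, 1, -1)
        y[0], y[1] = 1, -1
        m1 = train_linear_svm(X, y, SVMConfig(tolerance=1e-10))
        non_sv = np.flatnonzero(m1.dual_coefs < 1e-10)
        if non_sv.size == 0:
            pytest.skip("no non-support subject in this draw")
        keep = np.arange(20) != non_sv[0]
        m2 = train_linear_svm(X[keep], y[keep], SVMConfig(tolerance=1e-10))
        assert m2.w == pytest.approx(m1.w, abs=1e-5)
        assert m2.b == pytest.approx(m1.b, abs=1e-5)

    def test_precomputed_gram_matches_direct_fit(self, rng):
        X = rng.normal(size=(10, 30))
        y = np.where(rng.random(10) < 0.5, 1, -1)
        y[0], y[1] = 1, -1
        m1 = train_linear_svm(X, y)
        m2 = train_linear_svm(X, y, gram=X @ X.T)
        assert m2.w == pytest.approx(m1.w)
        assert m2.b == pytest.approx(m1.b)


class TestDecisionValues:
    @pytest.fixture
    def toy_model(self):
        return train_linear_svm(np.array([[0.0], [2.0]]), [-1, +1])

    def test_decision_example_and_tie_rule(self, toy_model):
        f = decision_value(toy_model, np.array([2.0]))
        assert f == pytest.approx(1.0)
        assert predict_label(f) == 1  # patient
        assert predict_label(0.0) == -1  # boundary goes to control
        assert predict_label(-0.3) == -1

    def test_affine_structure(self, toy_model, rng):
        x1, x2 = rng.normal(size=(2, 1))
        lhs = decision_value(toy_model, x1 + x2)
        rhs = decision_value(toy_model, x1) + decision_value(toy_model, x2)
        assert lhs - rhs == pytest.approx(-toy_model.b)

    def test_length_mismatch_rejected(self, toy_model):
        with pytest.raises(ValueError):
            decision_value(toy_model, np.array([1.0, 2.0]))


class TestWeightMap:
    def test_round_trip_exact(self, rng):
        mask = CommonMask(rng.random((4, 4, 4)) > 0.5)
        X = rng.normal(size=(8, mask.n_voxels))
        y = np.where(rng.random(8) < 0.5, 1, -1)
        y[0], y[1] = 1, -1
        model = train_linear_svm(X, y)
        img = weight_map(model, mask)
        assert np.array_equal(img.data.ravel()[mask.indices], model.w)
        assert np.all(img.data.ravel()[~np.isin(np.arange(64), mask.indices)] == 0)

    def test_mask_size_mismatch_rejected(self, rng):
        mask = CommonMask(np.ones((2, 2, 2), dtype=bool))
        model = train_linear_svm(rng.normal(size=(4, 5)), [1, -1, 1, -1])
        with pytest.raises(ValueError):
            weight_map(model, mask)

    def test_effect_region_weights_negative_under_fa_reduction(self, effect_cohort):
        subjects = effect_cohort.subjects
        mask = compute_common_mask([s.image for s in subjects])
        fm = vectorize([s.image for s in subjects], mask, [s.subject_id for s in subjects])
        y = [1 if s.label == "patient" else -1 for s in subjects]
        model = train_linear_svm(fm, y)
        wimg = weight_map(model, mask)
        assert wimg.data[effect_cohort.effect_mask].mean() < 0

    def test_null_cohort_weights_uniform_over_random_regions(self, small_template):
        # no effect: mean |w| inside a random region ~ mean |w| outside
        ratios = []
        for seed in range(20):
            cohort = generate_cohort(
                small_template,
                CohortSpec(n_pairs=8, effect_delta=0.0, noise_sd=0.02, seed=100 + seed),
            )
            subjects = cohort.subjects
            mask = compute_common_mask([s.image for s in subjects])
            fm = vectorize([s.image for s in subjects], mask, [s.subject_id for s in subjects])
            y = [1 if s.label == "patient" else -1 for s in subjects]
            model = train_linear_svm(fm, y)
            rng = np.random.default_rng(seed)
            inside = rng.random(mask.n_voxels) < 0.2
            w = np.abs(model.w)
            ratios.append(w[inside].mean() / w[~inside].mean())
        assert abs(np.mean(ratios) - 1.0) < 0.1


def platt_oracle(f, y):
    """Independent 2-parameter logistic fit with Platt's smoothed targets."""
    f = np.asarray(f, float)
    y = np.asarray(y, float)
    n_pos, n_neg = int((y > 0).sum()), int((y < 0).sum())
    t = np.where(y > 0, (n_pos + 1) / (n_pos + 2), 1 / (n_neg + 2))

    def nll(p):
        z = p[0] * f + p[1]
        return np.sum(t * z + np.logaddexp(0, -z))

    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x


class TestPlattScaling:
    def test_symmetric_input_gives_half_at_zero(self):
        params = platt_fit([-1, -1, 1, 1], [-1, -1, 1, 1])
        assert platt_prob(params, 0.0) == pytest.approx(0.5, abs=1e-6)
        assert params.A < 0

    def test_matches_independent_logistic_oracle(self):
        f = [-2.0, -1.0, 1.0, 2.0]
        y = [-1, -1, 1, 1]
        params = platt_fit(f, y)
        a_ref, b_ref = platt_oracle(f, y)
        probs = platt_prob(params, np.asarray(f))
        ref = 1 / (1 + np.exp(a_ref * np.asarray(f) + b_ref))
        assert probs == pytest.approx(ref, abs=1e-5)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_monotone_and_bounded(self, f1, f2):
        params = PlattParams(A=-1.3, B=0.2)
        p1, p2 = platt_prob(params, f1), platt_prob(params, f2)
        assert 0.0 < p1 < 1.0
        if f1 < f2:
            assert p1 <= p2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            platt_fit([1.0, 2.0], [1, 1])

    def test_scaling_on_cv_outputs_orders_by_decision_value(self, rng):
        f = rng.normal(size=60) + np.where(rng.random(60) < 0.5, 1.0, -1.0)
        y = np.where(f + 0.3 * rng.normal(size=60) > 0, 1, -1)
        if len(set(y)) == 1:
            y[0] *= -1
        params = platt_fit(f, y)
        probs = platt_prob(params, np.sort(f))
        assert np.all(np.diff(probs) >= 0)


class TestSerialization:
    def test_save_model_writes_weight_map_and_metadata(self, tmp_path, rng):
        mask = CommonMask(np.ones((3, 3, 3), dtype=bool))
        X = rng.normal(size=(6, 27))
        y = [1, -1, 1, -1, 1, -1]
        model = train_linear_svm(X, y)
        from faskel.classifier import save_model

        save_model(model, mask, tmp_path)
        assert (tmp_path / "svm_weights.nii.gz").exists()
        import json

        meta = json.loads((tmp_path / "svm_meta.json").read_text())
        assert meta["bias"] == pytest.approx(model.b)
        assert len(meta["dual_coefs"]) == 6
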