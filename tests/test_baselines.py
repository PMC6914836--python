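"""GLM, FDR, whole-brain lasso and searchlight contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from deeplight.baselines import (
    build_design,
    fdr_threshold,
    glm_fit,
    lasso_fit,
    lasso_predict,
    searchlight_decode,
    searchlight_map,
    sphere_offsets,
)
from deeplight.hrf import double_gamma_hrf
from deeplight.preprocess import BrainMask
from deeplight.synth import sphere_mask


def _events(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


# ---------------------------------------------------------------------------
# design matrix and GLM


def test_design_has_one_hrf_regressor_per_state_plus_intercept():
    events = _events([(0.0, 10.0, "body"), (20.0, 10.0, "face")])
    design = build_design(events, n_volumes=40, tr=1.0)
    assert design.X.shape == (40, 3)
    assert design.names == ["body", "face", "intercept"]


def test_empty_events_rejected():
    with pytest.raises(ValueError, match="empty"):
        build_design(_events([]), 10, 1.0)


def test_brief_event_regressor_peaks_at_hrf_delay():
    """A 1-TR event's regressor is the HRF itself: peak 5-7 s after onset."""
    events = _events([(10.0, 1.0, "face")])
    design = build_design(events, n_volumes=60, tr=1.0, intercept=False)
    peak_time = float(np.argmax(design.X[:, 0])) - 10.0
    assert 5.0 <= peak_time <= 7.0


def test_block_regressor_peaks_where_hrf_crosses_zero():
    """For a sustained block the response accumulates while the HRF is
    positive, so the regressor peaks near the HRF's zero crossing (~15 s)."""
    events = _events([(5.0, 20.0, "face")])
    design = build_design(events, n_volumes=80, tr=1.0, intercept=False)
    t = np.linspace(0, 30, 3001)
    h = double_gamma_hrf(t)
    zero_cross = t[np.flatnonzero((h[:-1] > 0) & (h[1:] <= 0))[0]]
    peak_time = float(np.argmax(design.X[:, 0])) - 5.0
    assert abs(peak_time - zero_cross) <= 2.0


def test_glm_recovers_planted_coefficients_exactly(rng):
    events = _events([(0.0, 10.0, "body"), (20.0, 10.0, "face")])
    design = build_design(events, n_volumes=50, tr=1.0)
    beta_true = rng.normal(size=(3, 7))
    Y = design.X @ beta_true  # noiseless
    fit = glm_fit(Y, design)
    np.testing.assert_allclose(fit.beta, beta_true, atol=1e-9)
    # residuals orthogonal to the design at machine precision
    resid = Y - design.X @ fit.beta
    np.testing.assert_allclose(design.X.T @ resid, 0.0, atol=1e-8)


def test_glm_null_p_values_are_uniform(rng):
    events = _events([(0.0, 10.0, "body"), (30.0, 10.0, "face")])
    design = build_design(events, n_volumes=120, tr=1.0)
    Y = rng.normal(size=(120, 4000))  # pure noise
    fit = glm_fit(Y, design)
    frac = float(np.mean(fit.p[0] < 0.05))
    assert frac == pytest.approx(0.05, abs=0.015)


def test_duplicate_predictor_column_raises_named_error():
    events = _events([(0.0, 10.0, "body")])
    design = build_design(events, n_volumes=30, tr=1.0)
    design.X = np.column_stack([design.X, design.X[:, 0]])
    design.names.append("body_copy")
    with pytest.raises(ValueError, match="rank deficient"):
        glm_fit(np.random.default_rng(0).normal(size=(30, 3)), design)


# ---------------------------------------------------------------------------
# FDR


def test_bh_hand_computation_on_toy_vector():
    # step-up: p_(1)=0.001 <= 0.1*1/3; larger ones fail
    mask = fdr_threshold(np.array([0.001, 0.2, 0.9]), q=0.1)
    np.testing.assert_array_equal(mask, [True, False, False])


def test_bh_degenerate_vectors():
    assert not fdr_threshold(np.ones(5), q=0.1).any()
    assert fdr_threshold(np.zeros(5), q=0.1).all()


def test_bh_matches_step_up_rule_on_random_p(rng):
    p = rng.random(200)
    mask = fdr_threshold(p, q=0.1)
    order = np.argsort(p)
    ranked = p[order]
    crit = 0.1 * np.arange(1, 201) / 200
    below = np.flatnonzero(ranked <= crit)
    k = below.max() + 1 if below.size else 0
    expected = np.zeros(200, dtype=bool)
    expected[order[:k]] = True
    np.testing.assert_array_equal(mask, expected)


# ---------------------------------------------------------------------------
# whole-brain lasso


def test_huge_lambda_zeroes_all_coefficients(rng):
    X = rng.normal(size=(60, 20))
    y = (rng.random(60) > 0.5).astype(int)
    model = lasso_fit(X, y, lam=1e5)
    np.testing.assert_array_equal(model.beta, 0.0)


def test_objective_is_monotone_non_increasing(rng):
    X = rng.normal(size=(80, 30))
    y = (X[:, 0] + 0.3 * rng.normal(size=80) > 0).astype(int)
    model = lasso_fit(X, y, lam=2.0)
    for history in model.objective_history:
        diffs = np.diff(history)
        assert (diffs <= 1e-10).all()


def test_unpenalized_fit_matches_sklearn_logistic(rng):
    # overlapping classes keep the unpenalized MLE finite and well-conditioned
    X = rng.normal(size=(300, 4))
    y = (X @ np.array([1.0, -1.0, 0.5, 0.0]) + 2.0 * rng.normal(size=300) > 0).astype(int)
    ours = lasso_fit(X, y, lam=0.0, max_iter=5000, tol=1e-12)
    ref = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10).fit(X, y)
    np.testing.assert_allclose(ours.beta[1], ref.coef_[0], rtol=1e-3, atol=1e-3)
    np.testing.assert_allclose(ours.intercept[1], ref.intercept_[0], rtol=1e-3, atol=1e-3)


def test_sparse_support_recovery(rng):
    """5 informative voxels among 500 noise voxels: support recovered, >90% sparse."""
    n, n_noise = 300, 500
    informative = rng.normal(size=(n, 5))
    beta_true = np.array([3.0, -3.0, 2.5, 3.5, -2.5])
    y = (informative @ beta_true + 0.5 * rng.normal(size=n) > 0).astype(int)
    X = np.column_stack([informative, rng.normal(size=(n, n_noise))])
    model = lasso_fit(X, y, lam=8.0, max_iter=1000)
    support = np.flatnonzero(model.beta[1] != 0.0)
    assert set(range(5)) <= set(support)
    assert np.mean(model.beta[1] == 0.0) > 0.90


def test_lasso_predict_probabilities_and_ties(rng):
    X = rng.normal(size=(10, 3))
    y = np.array([0, 1] * 5)
    model = lasso_fit(X, y, lam=1e6)  # all-zero beta, near-zero intercepts
    labels, probs = lasso_predict(model, X, return_probabilities=True)
    np.testing.assert_allclose(probs, 0.5, atol=0.05)
    assert (labels == 0).all()  # ties broken toward the lowest index


# ---------------------------------------------------------------------------
# searchlight


def test_sphere_offsets_match_bruteforce_enumeration():
    offs = sphere_offsets(5.6, voxel_size=(2.0, 2.0, 2.0))
    expected = []
    for dx in range(-3, 4):
        for dy in range(-3, 4):
            for dz in range(-3, 4):
                if np.sqrt((2 * dx) ** 2 + (2 * dy) ** 2 + (2 * dz) ** 2) <= 5.6:
                    expected.append((dx, dy, dz))
    assert sorted(map(tuple, offs)) == sorted(expected)
    assert len(offs) == len(expected)


def _informative_dataset(rng, n_per_class=30, shape=(7, 7, 4)):
    """Only voxels inside a small ROI at (2,2,1) separate the two classes."""
    roi = sphere_mask(shape, (2, 2, 1), 1.5)
    X = rng.normal(size=(2 * n_per_class, *shape))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1][:, roi] += 0.0  # keep array layout explicit
    signal = np.zeros(shape)
    signal[roi] = 2.5
    X[n_per_class:] += signal
    return X, y, roi


def test_searchlight_peak_lies_in_informative_roi(rng):
    X, y, roi = _informative_dataset(rng)
    result = searchlight_map(X, y, radius_mm=5.6, folds=3, seed=0)
    cx, cy, cz = result.best_location
    near = sphere_mask(roi.shape, (cx, cy, cz), 2.9)
    assert (near & roi).any(), f"best location {result.best_location} not near ROI"
    assert result.best_accuracy > 0.9


def test_shuffled_labels_give_chance_level_map(rng):
    X, y, _ = _informative_dataset(rng, n_per_class=20)
    y_perm = rng.permutation(y)
    result = searchlight_map(X, y_perm, radius_mm=4.0, folds=4, seed=1)
    mean_acc = np.nanmean(result.accuracy_map)
    assert abs(mean_acc - 0.5) < 0.06


def test_accuracies_bounded_and_best_is_map_maximum(rng):
    X, y, _ = _informative_dataset(rng, n_per_class=15)
    result = searchlight_map(X, y, radius_mm=4.0, folds=3, seed=0)
    valid = result.accuracy_map[np.isfinite(result.accuracy_map)]
    assert ((valid >= 0) & (valid <= 1)).all()
    best_acc, preds = searchlight_decode(result)
    assert best_acc == np.nanmax(result.accuracy_map)
    assert best_acc == result.accuracy_map[result.best_location]
    assert np.mean(preds == y) == pytest.approx(best_acc)


def test_mask_restricts_sphere_membership(rng):
    X = rng.normal(size=(40, 5, 5, 3))
    y = np.repeat([0, 1], 20)
    mask = np.zeros((5, 5, 3), dtype=bool)
    mask[2, 2, 1] = True  # a single in-mask voxel: every sphere has < 2 voxels
    with pytest.raises(ValueError, match="at least 2"):
        searchlight_map(X, y, mask=BrainMask(mask, ((2, 2), (2, 2), (1, 1))), radius_mm=4.0)
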