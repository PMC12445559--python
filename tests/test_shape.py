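import numpy as np
import pytest

from kneessm.conventions import rotation_matrix
from kneessm.shape import GPAConvergenceError, ShapePCA, gpa_align
from oracles import pairwise_gpa_mean


def _random_shapes(rng, n=10, k=129, spread=2.0):
    base = rng.normal(0, 20, size=(k, 2))
    return [base + rng.normal(0, spread, size=(k, 2)) for _ in range(n)]


def _similarity(points, angle, shift, scale):
    return scale * points @ rotation_matrix(angle).T + np.asarray(shift)


# -- GPA --------------------------------------------------------------------


def test_gpa_removes_similarity_differences(rng):
    base = rng.normal(0, 15, size=(50, 2))
    twin = _similarity(base, 73.0, (40.0, -12.0), 3.1)
    res = gpa_align([base, twin])
    rmsd = np.sqrt(((res.aligned[0] - res.aligned[1]) ** 2).mean())
    assert rmsd <= 1e-8


def test_gpa_idempotent(rng):
    shapes = _random_shapes(rng, n=6)
    first = gpa_align(shapes)
    second = gpa_align(first.aligned)
    assert np.sqrt(((second.aligned - first.aligned) ** 2).mean()) <= 1e-10
    assert np.sqrt(((second.mean - first.mean) ** 2).mean()) <= 1e-10


def test_gpa_mean_matches_pairwise_procrustes_oracle(rng):
    shapes = _random_shapes(rng, n=10)
    res = gpa_align(shapes)
    oracle = pairwise_gpa_mean(shapes)
    # the oracle mean is defined up to rotation: align it before comparing
    aligned_oracle = gpa_align([oracle, res.mean]).aligned
    rmsd = np.sqrt(((aligned_oracle[0] - aligned_oracle[1]) ** 2).mean())
    assert rmsd <= 1e-6


def test_gpa_invariant_to_preprocessing_any_input(rng):
    shapes = _random_shapes(rng, n=5)
    res1 = gpa_align(shapes)
    shapes[2] = _similarity(shapes[2], -141.0, (999.0, 3.0), 0.02)
    res2 = gpa_align(shapes)
    assert np.sqrt(((res1.aligned - res2.aligned) ** 2).mean()) <= 1e-8


def test_gpa_input_validation(rng):
    with pytest.raises(ValueError):
        gpa_align([rng.normal(size=(10, 2))])  # a single shape
    with pytest.raises(ValueError):
        gpa_align([rng.normal(size=(10, 2)), rng.normal(size=(11, 2))])
    with pytest.raises(ValueError):
        gpa_align([np.zeros((10, 2)), rng.normal(size=(10, 2))])  # coincident points
    with pytest.raises(GPAConvergenceError):
        gpa_align(_random_shapes(rng, n=8, spread=8.0), tol=0.0, max_iter=3)


# -- PCA model --------------------------------------------------------------


def test_planted_single_mode_is_recovered(rng):
    base = rng.normal(0, 20, size=(60, 2))
    base -= base.mean(axis=0)
    direction = rng.normal(size=120)
    # orthogonalise against translation/rotation/scale so alignment keeps it
    sims = np.stack([
        np.tile([1.0, 0.0], 60), np.tile([0.0, 1.0], 60),
        np.column_stack([-base[:, 1], base[:, 0]]).ravel(), base.ravel(),
    ])
    q, _ = np.linalg.qr(sims.T)
    direction -= q @ (q.T @ direction)
    direction /= np.linalg.norm(direction)
    zs = rng.normal(0, 1.5, size=80)
    shapes = [base + (z * direction).reshape(-1, 2) for z in zs]
    res = ShapePCA(shapes).fit()
    # the aligned frame is canonically rotated, so compare frame-free: the
    # first mode's direction cosine against the planted field, measured in
    # the aligned frame via the rotation that maps base into it
    from scipy.linalg import orthogonal_procrustes

    base_cs = base / np.sqrt((base ** 2).sum())
    rot, _ = orthogonal_procrustes(base_cs, res.gpa.mean)
    planted_aligned = (direction.reshape(-1, 2) @ rot).reshape(-1)
    planted_aligned /= np.linalg.norm(planted_aligned)
    assert abs(res.modes[0] @ planted_aligned) >= 0.999
    # and the training scores must reproduce the planted coefficients
    scores = res.score(np.stack(shapes))[:, 0]
    corr = np.corrcoef(scores, zs)[0, 1]
    assert abs(corr) >= 0.999
    assert res.variance_explained(1) > 0.95


def test_mode_orthonormality_and_variance_accounting(fitted_model):
    m = fitted_model
    gram = m.modes @ m.modes.T
    assert np.abs(gram - np.eye(m.n_modes)).max() <= 1e-8
    assert np.all(np.diff(m.variances) <= 1e-12)
    total = m.training_matrix.var(axis=0, ddof=1).sum()
    assert m.variances.sum() == pytest.approx(total, rel=1e-6)


def test_variance_explained_boundaries(fitted_model):
    m = fitted_model
    assert m.variance_explained(m.n_modes) == pytest.approx(1.0, abs=1e-12)
    fracs = [m.variance_explained(k) for k in range(1, 12)]
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))
    with pytest.raises(ValueError):
        m.variance_explained(0)
    with pytest.raises(ValueError):
        m.variance_explained(m.n_modes + 1)


def test_identical_shapes_flagged_degenerate(template):
    res = ShapePCA([template.points.copy() for _ in range(5)]).fit()
    assert res.degenerate
    assert np.allclose(res.variances, 0.0)
    assert np.all(np.isnan(res.score(template.points)))


def test_fit_requires_three_shapes(rng):
    with pytest.raises(ValueError):
        ShapePCA(_random_shapes(rng, n=2)).fit()


# -- scoring and reconstruction --------------------------------------------


def test_mean_shape_scores_to_zero(fitted_model):
    scores = fitted_model.score(fitted_model.mean_shape.reshape(-1, 2))
    assert np.abs(scores).max() <= 1e-8


def test_synthetic_two_sd_displacement_scores_exactly(fitted_model):
    m = fitted_model
    shape = (m.mean_shape + 2.0 * m.raw_sds[0] * m.modes[0]).reshape(-1, 2)
    scores = m.score(shape)
    assert scores[0] == pytest.approx(2.0, abs=1e-8)
    assert np.abs(scores[1:]).max() <= 1e-8


def test_training_scores_standardized(fitted_model, small_cohort):
    scores = fitted_model.score(small_cohort.knee_arrays())
    assert np.abs(scores.mean(axis=0)).max() <= 1e-8
    assert np.abs(scores.std(axis=0, ddof=1) - 1.0).max() <= 1e-6


def test_reconstruct_round_trip(fitted_model):
    m = fitted_model
    scores = np.zeros(m.n_modes)
    np.testing.assert_allclose(
        m.reconstruct(scores).points.reshape(-1), m.mean_shape, atol=1e-12)
    scores[:10] = [1.2, -0.4, 0.0, 2.0, -1.1, 0.3, 0.0, 0.9, -2.2, 0.5]
    rebuilt = m.reconstruct(scores)
    again = m.score(rebuilt)
    np.testing.assert_allclose(again, scores, atol=1e-8)


def test_reconstruction_error_decreases_with_modes(fitted_model, small_cohort):
    m = fitted_model
    target = m.gpa.aligned[3]
    scores = m.score(target)
    errs = []
    for k in (1, 3, 5, 10, 20):
        partial = np.zeros(m.n_modes)
        partial[:k] = scores[:k]
        rec = m.reconstruct(partial).points
        errs.append(np.sqrt(((rec - target) ** 2).mean()))
    assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))
    with pytest.raises(ValueError):
        m.reconstruct(np.zeros(4), k_modes=m.n_modes + 1)


def test_model_json_round_trip(fitted_model, tmp_path):
    from kneessm.shape import ShapeModelResults

    path = tmp_path / "model.json"
    fitted_model.to_json(path)
    back = ShapeModelResults.from_json(path)
    np.testing.assert_allclose(back.mean_shape, fitted_model.mean_shape)
    np.testing.assert_allclose(back.modes, fitted_model.modes)
    np.testing.assert_allclose(back.variances, fitted_model.variances)
    assert back.n_training == fitted_model.n_training
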