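import numpy as np
import pandas as pd
import pytest

from kneessm.alignment import hka_angle
from kneessm.synthetic import (
    DEFAULT_SHAPE_MODE_SDS,
    CohortParams,
    DegenerateGeometryError,
    generate_cohort,
    generate_individual,
    planted_fields,
    shoelace_area,
)
from kneessm.template import OSTEOPHYTE_SITES, make_template


def _quiet_params(**kw):
    """A configuration with every stochastic deformation switched off."""
    base = dict(
        n_individuals=5, seed=0, varus_effect_sd=0.0, varus_mean_male=0.0,
        varus_mean_female=0.0, jsn_varus_coupling=0.0, osteophyte_rate=0.0,
        noise_sd=0.0, shape_mode_sds=(),
    )
    base.update(kw)
    return CohortParams(**base)


def test_parameter_validation():
    with pytest.raises(ValueError):
        CohortParams(n_individuals=0, seed=1)
    with pytest.raises(ValueError):
        CohortParams(n_individuals=10, prop_male=1.2)
    with pytest.raises(ValueError):
        CohortParams(n_individuals=10, noise_sd=-0.1)
    with pytest.raises(ValueError):
        CohortParams(n_individuals=10, mode_effects={99: 0.4})


def test_same_seed_gives_bit_identical_cohorts():
    p = CohortParams(n_individuals=40, seed=123)
    a = generate_cohort(p)
    b = generate_cohort(p)
    np.testing.assert_array_equal(a.knee_arrays(), b.knee_arrays())
    pd.testing.assert_frame_equal(a.truth, b.truth)
    for ia, ib in zip(a.individuals, b.individuals):
        np.testing.assert_array_equal(ia.body_landmarks.femoral_head_ring,
                                      ib.body_landmarks.femoral_head_ring)


def test_quiet_configuration_reproduces_template_exactly(template):
    cohort = generate_cohort(_quiet_params())
    for ind in cohort.individuals:
        np.testing.assert_array_equal(ind.knee_landmarks.points, template.points)
        assert ind.true_varus_angle == 0.0
        assert hka_angle(ind.body_landmarks) == pytest.approx(0.0, abs=1e-9)


def test_noise_free_hka_equals_minus_varus_exactly():
    p = CohortParams(n_individuals=40, seed=5, noise_sd=0.0)
    cohort = generate_cohort(p)
    for ind in cohort.individuals:
        hka = hka_angle(ind.body_landmarks)
        assert hka == pytest.approx(-ind.true_varus_angle, abs=1e-6)


def test_age_marginal_within_monte_carlo_error():
    p = CohortParams(n_individuals=1000, seed=9)
    cohort = generate_cohort(p)
    ages = cohort.truth["age"]
    se = p.sd_age / np.sqrt(len(ages))
    assert abs(ages.mean() - p.mean_age) < 3 * se


def test_covariate_marginals_converge_at_large_n():
    p = CohortParams(n_individuals=10_000, seed=77)
    t = generate_cohort(p).truth
    n = len(t)
    assert abs(t["age"].mean() - p.mean_age) < 4 * p.sd_age / np.sqrt(n)
    assert abs(t["age"].std(ddof=1) - p.sd_age) < 4 * p.sd_age / np.sqrt(2 * n)
    males = t["sex"] == "male"
    assert abs(males.mean() - p.prop_male) < 4 * np.sqrt(0.25 / n)
    assert abs(t.loc[males, "height"].mean() - p.height_mean_male) \
        < 4 * p.height_sd_male / np.sqrt(males.sum())
    assert abs(t.loc[~males, "weight"].mean() - p.weight_mean_female) \
        < 4 * p.weight_sd_female / np.sqrt((~males).sum())
    assert t["ethnicity"].value_counts(normalize=True)["White"] == pytest.approx(
        0.968, abs=0.01)


def test_truth_table_records_latents_and_positive_mjsw():
    cohort = generate_cohort(CohortParams(n_individuals=100, seed=2))
    t = cohort.truth
    assert {"true_varus_angle", "true_mjsw", "z_mode2", "z_mode10"} <= set(t.columns)
    assert (t["true_mjsw"] > 0).all()
    assert all((np.asarray(i.osteophyte_areas) >= 0).all() for i in cohort.individuals)


def test_osteophyte_displacement_realises_requested_shoelace_area(template, rng):
    from kneessm.synthetic import apply_osteophyte

    for site, idx in OSTEOPHYTE_SITES.items():
        target = float(rng.uniform(1.0, 8.0))
        bumped = apply_osteophyte(template.points, site, target, template.segment_map)
        poly = np.vstack([template.points[idx], bumped[idx][::-1]])
        assert shoelace_area(poly) == pytest.approx(target, rel=1e-9)


def test_planted_fields_orthonormal_and_similarity_free(template):
    fields = planted_fields(template)
    gram = fields @ fields.T
    assert np.abs(gram - np.eye(len(fields))).max() < 1e-10
    pts = template.points - template.points.mean(axis=0)
    sims = np.stack([
        np.tile([1.0, 0.0], len(pts)), np.tile([0.0, 1.0], len(pts)),
        np.column_stack([-pts[:, 1], pts[:, 0]]).ravel(), pts.ravel(),
    ])
    sims = sims / np.linalg.norm(sims, axis=1, keepdims=True)
    assert np.abs(fields @ sims.T).max() < 1e-10


def test_varus_rotation_moves_distal_tibia_medially(template):
    p = _quiet_params(varus_mean_male=4.0, varus_mean_female=4.0)
    cohort = generate_cohort(p)
    ind = cohort.individuals[0]
    tib = template.segment_map["tibia"]
    distal = tib[template.points[tib, 1].argmin()]
    # varus (positive angle): ankle ends up medial (+x) of its template spot
    assert ind.knee_landmarks.points[distal, 0] > template.points[distal, 0]
    # and the medial joint space narrows via the rotation alone
    assert ind.true_mjsw < 5.0


def test_embedded_regime_realises_drawn_grades():
    from kneessm.grading import measure_mjsw, rkoa_assess

    p = _quiet_params(n_individuals=400, seed=31, mode_effects={3: 0.5},
                      shape_mode_sds=DEFAULT_SHAPE_MODE_SDS)
    cohort = generate_cohort(p)
    drawn = cohort.truth["drawn_grade"].to_numpy()
    realised = np.array([
        min(rkoa_assess(i.osteophyte_areas,
                        measure_mjsw(i.knee_landmarks)).rkoa_grade, 3)
        for i in cohort.individuals
    ])
    assert (realised == drawn).all()
    assert 0 < drawn.mean() < 1  # both healthy and diseased knees present


def test_degenerate_geometry_raises_after_retries():
    p = CohortParams(n_individuals=2, seed=0, noise_sd=40.0)
    rng = np.random.default_rng(0)
    with pytest.raises(DegenerateGeometryError):
        for _ in range(50):
            generate_individual(p, rng, "x")


def test_default_grade_distribution_is_dominated_by_grade_zero():
    from kneessm.grading import measure_mjsw, rkoa_assess

    cohort = generate_cohort(CohortParams(n_individuals=800, seed=4))
    grades = pd.Series([
        rkoa_assess(i.osteophyte_areas, measure_mjsw(i.knee_landmarks)).rkoa_grade
        for i in cohort.individuals
    ])
    frac = grades.value_counts(normalize=True)
    assert 0.72 < frac.get(0, 0) < 0.90
    assert frac.get(1, 0) > 0.05
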