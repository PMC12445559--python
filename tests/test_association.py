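import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from kneessm.association import (
    GRADE_CATEGORIES,
    RKOAAssociation,
    bonferroni_threshold,
    build_frame,
    fit_contrast,
    fit_interaction,
    merge_grades,
)


def _sim_frame(rng, n=2000, beta=0.0, base_rate=0.15, n_ksms=10,
               sex_beta_delta=0.0, grade="1"):
    """Directly simulated analysis frame: standard-normal scores and a
    logistic outcome on ksm1 (optionally sex-modified)."""
    scores = rng.standard_normal((n, n_ksms))
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    b = beta + np.where(sex == "male", sex_beta_delta, 0.0)
    alpha = np.log(base_rate / (1 - base_rate))
    p = 1 / (1 + np.exp(-(alpha + b * scores[:, 0])))
    y = rng.random(n) < p
    frame = pd.DataFrame(scores, columns=[f"ksm{j+1}" for j in range(n_ksms)])
    frame["rkoa_grade"] = np.where(y, grade, "0")
    frame["grade"] = merge_grades(frame["rkoa_grade"])
    frame["sex"] = sex
    frame["age"] = rng.normal(64, 7.5, n)
    frame["height"] = rng.normal(170, 9, n)
    frame["weight"] = rng.normal(75, 15, n)
    frame["ethnicity"] = "White"
    frame["hka"] = rng.normal(-0.6, 2.0, n)
    frame["fta"] = frame["hka"] + 5.5
    return frame


# -- bookkeeping primitives --------------------------------------------------


@pytest.mark.parametrize("alpha, m, expected",
                         [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)])
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.0, 10)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_grade_merge_produces_four_categories():
    merged = merge_grades([0, 1, 2, 3, 4, 4, 0])
    assert list(merged.categories) == list(GRADE_CATEGORIES)
    assert list(merged) == ["0", "1", "2", "3-4", "3-4", "3-4", "0"]
    with pytest.raises(ValueError):
        merge_grades([0, 7])


def _components(rng, n=60):
    ids = pd.Index([f"i{k}" for k in range(n)], name="id")
    scores = pd.DataFrame(rng.standard_normal((n, 10)),
                          columns=[f"ksm{j+1}" for j in range(10)], index=ids)
    assessments = pd.DataFrame(
        {"rkoa_grade": rng.choice([0, 0, 0, 1, 2, 3, 4], size=n)}, index=ids)
    covariates = pd.DataFrame({
        "sex": rng.choice(["male", "female"], size=n),
        "age": rng.normal(64, 7, n), "height": rng.normal(170, 9, n),
        "weight": rng.normal(75, 15, n), "ethnicity": "White"}, index=ids)
    angles = pd.DataFrame({"hka": rng.normal(0, 2, n),
                           "fta": rng.normal(5, 2, n)}, index=ids)
    return scores, assessments, covariates, angles


def test_build_frame_merges_and_tracks_attrition(rng):
    scores, assessments, covariates, angles = _components(rng)
    angles.loc[angles.index[:5], "hka"] = np.nan
    frame = build_frame(scores, assessments, covariates, angles)
    assert set(frame["grade"].cat.categories) == set(GRADE_CATEGORIES)
    att = frame.attrs["attrition"]
    assert att["rows_in"] == att["rows_out"] + att["dropped_incomplete"]
    assert att["missing_hka"] == 5
    # missing HKA rows stay in Model 1-2 but leave Model 3
    r2 = fit_contrast(frame, "ksm1", "1v0", 2)
    r3 = fit_contrast(frame, "ksm1", "1v0", 3)
    assert r3["n_cases"] + r3["n_controls"] <= r2["n_cases"] + r2["n_controls"] - 1


def test_build_frame_rejects_duplicates_and_disjoint_ids(rng):
    scores, assessments, covariates, angles = _components(rng)
    dup = pd.concat([scores, scores.iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        build_frame(dup, assessments, covariates, angles)
    other = assessments.copy()
    other.index = pd.Index([f"z{k}" for k in range(len(other))], name="id")
    with pytest.raises(ValueError):
        build_frame(scores, other, covariates, angles)


# -- estimation properties ---------------------------------------------------


def test_null_log_odds_shrink_with_sample_size(rng):
    small = fit_contrast(_sim_frame(rng, n=500), "ksm1", "1v0", 1)
    big = fit_contrast(_sim_frame(rng, n=50_000), "ksm1", "1v0", 1)
    assert abs(big["log_or"]) < 0.05
    assert big["ci_low"] < 1.0 < big["ci_high"]


def test_per_sd_invariance_under_rescaling(rng):
    frame = _sim_frame(rng, n=3000, beta=0.4)
    base = fit_contrast(frame, "ksm1", "1v0", 2)
    rescaled = frame.copy()
    col = rescaled["ksm1"] * 7.3
    rescaled["ksm1"] = (col - col.mean()) / col.std(ddof=1)
    redone = fit_contrast(rescaled, "ksm1", "1v0", 2)
    # the original column is standardized up to sampling noise; standardise
    # it exactly for the comparison
    exact = frame.copy()
    c0 = exact["ksm1"]
    exact["ksm1"] = (c0 - c0.mean()) / c0.std(ddof=1)
    ref = fit_contrast(exact, "ksm1", "1v0", 2)
    assert redone["log_or"] == pytest.approx(ref["log_or"], abs=1e-8)
    assert redone["p"] == pytest.approx(ref["p"], abs=1e-10)


def test_type_one_error_rate_at_nominal_level():
    """Null rejections at p<0.05 should occur in about 5% of replicates."""
    rng = np.random.default_rng(1234)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        row = fit_contrast(_sim_frame(rng, n=2000), "ksm1", "1v0", 1)
        rejections += row["p"] < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_wald_interval_coverage_is_nominal():
    """95% CIs should cover the true OR in 94-96% of replicates at n=5000."""
    rng = np.random.default_rng(4321)
    beta = 0.4
    covered = 0
    reps = 2000
    for _ in range(reps):
        row = fit_contrast(_sim_frame(rng, n=5000, beta=beta), "ksm1", "1v0", 1)
        covered += row["ci_low"] <= np.exp(beta) <= row["ci_high"]
    assert 0.94 <= covered / reps <= 0.96


def test_interaction_p_uniform_under_equal_sex_effects():
    from scipy.stats import kstest

    rng = np.random.default_rng(99)
    ps = [fit_interaction(_sim_frame(rng, n=2000, beta=0.3), "ksm1", "1v0", 2)
          for _ in range(200)]
    assert kstest(ps, "uniform").pvalue > 0.01


def test_interaction_detects_male_only_effect():
    rng = np.random.default_rng(7)
    hits = 0
    reps = 60
    for _ in range(reps):
        frame = _sim_frame(rng, n=5000, beta=0.0, sex_beta_delta=0.4)
        hits += fit_interaction(frame, "ksm1", "1v0", 2) < 0.05
    assert hits / reps > 0.80


def test_stratified_fits_match_saturated_interaction_model(rng):
    frame = _sim_frame(rng, n=4000, beta=0.3, sex_beta_delta=0.25)
    male = fit_contrast(frame, "ksm1", "1v0", 1, stratum="male")
    female = fit_contrast(frame, "ksm1", "1v0", 1, stratum="female")
    sub = frame[frame["grade"].isin(["0", "1"])].copy()
    sub["outcome"] = (sub["grade"] == "1").astype(int)
    res = smf.logit("outcome ~ ksm1 * C(sex)", data=sub).fit(disp=0)
    b_female = res.params["ksm1"]
    b_male = b_female + res.params["ksm1:C(sex)[T.male]"]
    assert female["log_or"] == pytest.approx(b_female, abs=1e-6)
    assert male["log_or"] == pytest.approx(b_male, abs=1e-6)


def test_interaction_requires_both_sexes(rng):
    frame = _sim_frame(rng, n=500)
    frame["sex"] = "male"
    with pytest.raises(ValueError):
        fit_interaction(frame, "ksm1", "1v0", 2)


# -- full sweep ---------------------------------------------------------------


def test_run_all_bookkeeping(rng):
    frame = _sim_frame(rng, n=1200, beta=0.6)
    # make all four grade categories non-empty
    frame.loc[frame.index[:40], "rkoa_grade"] = "2"
    frame.loc[frame.index[40:70], "rkoa_grade"] = "3"
    frame["grade"] = merge_grades(frame["rkoa_grade"])
    results = RKOAAssociation(frame).fit()
    t = results.table
    assert len(t) == 10 * 3 * 3 * 3
    assert set(t["stratum"]) == {"combined", "male", "female"}
    assert results.threshold == 0.005
    # interaction p only on adjusted combined rows
    has_int = t["interaction_p"].notna()
    assert set(t.loc[has_int, "model"]) <= {2, 3}
    assert set(t.loc[has_int, "stratum"]) == {"combined"}
    # the embedded ksm1 effect must be flagged significant somewhere
    assert results.significant().query("ksm == 'ksm1'").shape[0] > 0


def test_permuted_outcomes_rarely_reach_bonferroni():
    rng = np.random.default_rng(55)
    frame = _sim_frame(rng, n=1500, beta=0.8)
    hits = 0
    total = 0
    for _ in range(10):
        perm = frame.copy()
        perm["grade"] = rng.permutation(perm["grade"].to_numpy())
        for ksm in [f"ksm{j+1}" for j in range(10)]:
            row = fit_contrast(perm, ksm, "1v0", 1)
            hits += row["p"] < 0.005
            total += 1
    assert hits / total <= 0.03
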