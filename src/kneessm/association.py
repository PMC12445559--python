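"""Per-grade logistic regression of knee shape mode (KSM) scores on rKOA.

For each KSM and each rKOA grade contrast (grade g vs grade 0), three
binary logistic models are fitted:

* **Model 1** — unadjusted (KSM only);
* **Model 2** — adjusted for age, sex, height, weight and ethnic category;
* **Model 3** — Model 2 plus the hip-knee-ankle (HKA) angle.

Odds ratios are per 1 SD increase in the KSM (the scoring contract of the
shape model guarantees SD units), with Wald 95% confidence intervals and
p-values.  Grades 3 and 4 are merged into a single "3-4" category before
modelling.  Sex-by-KSM effect modification is tested by adding a product
term to the adjusted models.  A Bonferroni threshold of alpha / m (0.005
for alpha = 0.05 and the m = 10 KSM exposures) flags significance.

Separation or non-convergence never aborts a sweep: the affected row is
flagged and carries NaN estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import PerfectSeparationError

GRADE_CATEGORIES = ("0", "1", "2", "3-4")
CONTRASTS = ("1v0", "2v0", "34v0")
STRATA = ("combined", "male", "female")
_CONTRAST_GRADE = {"1v0": "1", "2v0": "2", "34v0": "3-4"}

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m (0.05 / 10 = 0.005)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


def merge_grades(grades) -> pd.Series:
    """Map numeric rKOA grades {0,1,2,3,4} to the modelling categories
    {'0','1','2','3-4'}."""
    s = pd.Series(grades)
    out = s.astype(object).copy()
    out[s.isin([3, 4, "3", "4"])] = "3-4"
    out[s.isin([0, 1, 2])] = s[s.isin([0, 1, 2])].astype(int).astype(str)
    bad = ~out.isin(GRADE_CATEGORIES)
    if bad.any():
        raise ValueError(f"unrecognised rKOA grades: {sorted(set(out[bad]))}")
    return pd.Categorical(out, categories=GRADE_CATEGORIES)


def build_frame(scores: pd.DataFrame, assessments: pd.DataFrame,
                covariates: pd.DataFrame, angles: pd.DataFrame) -> pd.DataFrame:
    """Join per-individual scores, rKOA assessments, covariates and alignment
    angles into one analysis frame keyed by id.

    Grades 3 and 4 are merged; rows missing any of the KSM / grade /
    demographic columns are dropped (complete-case), while rows missing only
    HKA are retained and excluded from Model-3 fits at fit time.  Attrition
    counts are attached as ``frame.attrs['attrition']``.
    """
    parts = [scores, assessments, covariates, angles]
    for p in parts:
        if p.index.name != "id":
            raise ValueError("all inputs must be indexed by 'id'")
        if p.index.has_duplicates:
            dupes = p.index[p.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate ids in input: {dupes}")
    frame = (scores.join(assessments, how="inner")
                   .join(covariates, how="inner")
                   .join(angles, how="left"))
    if frame.empty:
        raise ValueError("joined frame is empty: the id sets do not overlap")
    frame = frame.copy()
    frame["grade"] = merge_grades(frame["rkoa_grade"])
    ksm_cols = [c for c in frame.columns if c.startswith("ksm")]
    needed = ksm_cols + ["grade", "age", "sex", "height", "weight", "ethnicity"]
    n0 = len(frame)
    complete = frame.dropna(subset=needed)
    attrition = {
        "rows_in": n0,
        "dropped_incomplete": n0 - len(complete),
        "missing_hka": int(complete["hka"].isna().sum()) if "hka" in complete else len(complete),
        "rows_out": len(complete),
    }
    counts = complete["grade"].value_counts()
    empty = [c for c in GRADE_CATEGORIES if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty grade cells after merge: {empty}")
    complete = complete.copy()
    complete.attrs["attrition"] = attrition
    return complete


#: ethnicity levels rarer than this within a fit subset are collapsed into
#: the reference level to avoid quasi-separation at small sample sizes
MIN_ETHNICITY_COUNT = 10


def _formula(ksm: str, model: int, stratum: str, frame: pd.DataFrame,
             interaction: bool = False, alignment_var: str = "hka") -> str:
    terms = [ksm]
    if model >= 2:
        terms += ["age", "height", "weight"]
        if stratum == "combined":
            terms.append("C(sex)")
        if frame["ethnicity"].nunique() > 1:
            eth_ref = frame["ethnicity"].value_counts().idxmax()
            terms.append(f"C(ethnicity, Treatment(reference='{eth_ref}'))")
    if model >= 3:
        terms.append(alignment_var)
    if interaction:
        terms.append(f"{ksm}:C(sex)")
    return "outcome ~ " + " + ".join(terms)


def _subset(frame: pd.DataFrame, contrast: str, stratum: str, model: int,
            alignment_var: str = "hka") -> pd.DataFrame:
    grade = _CONTRAST_GRADE[contrast]
    sub = frame[frame["grade"].isin(["0", grade])].copy()
    if stratum != "combined":
        sub = sub[sub["sex"] == stratum]
    if model >= 3:
        sub = sub.dropna(subset=[alignment_var])
    sub["outcome"] = (sub["grade"] == grade).astype(int)
    if model >= 2 and "ethnicity" in sub:
        # collapse sparse ethnic categories into the reference level so the
        # adjusted models stay estimable at small cohort sizes
        counts = sub["ethnicity"].value_counts()
        if len(counts):
            rare = counts[counts < MIN_ETHNICITY_COUNT].index
            sub["ethnicity"] = sub["ethnicity"].astype(object).replace(
                {r: counts.idxmax() for r in rare})
    return sub


def _flagged_row(ksm, contrast, model, stratum, flag, n_cases=0, n_controls=0):
    return {
        "ksm": ksm, "contrast": contrast, "model": model, "stratum": stratum,
        "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
        "log_or": np.nan, "se": np.nan, "interaction_p": np.nan,
        "n_cases": n_cases, "n_controls": n_controls, "flag": flag,
    }


def fit_contrast(frame: pd.DataFrame, ksm: str, contrast: str, model: int,
                 stratum: str = "combined", alignment_var: str = "hka") -> dict:
    """Fit one binary logistic contrast; returns a tidy row dict.

    OR = exp(beta_ksm) per SD, with Wald 95% CI.  Separation or
    non-convergence yields a flagged row with NaN estimates.
    """
    if model not in (1, 2, 3):
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    sub = _subset(frame, contrast, stratum, model, alignment_var)
    n_cases = int(sub["outcome"].sum())
    n_controls = int((1 - sub["outcome"]).sum())
    if n_cases == 0 or n_controls == 0:
        return _flagged_row(ksm, contrast, model, stratum,
                            f"empty_cell:{contrast}:{stratum}", n_cases, n_controls)
    formula = _formula(ksm, model, stratum, sub, alignment_var=alignment_var)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.logit(formula, data=sub).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            return _flagged_row(ksm, contrast, model, stratum, "non_convergence",
                                n_cases, n_controls)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return _flagged_row(ksm, contrast, model, stratum,
                            f"separation_or_singular:{type(exc).__name__}",
                            n_cases, n_controls)
    beta = float(res.params[ksm])
    se = float(res.bse[ksm])
    with np.errstate(over="ignore"):  # near-separated fits can overflow exp
        or_, lo, hi = np.exp([beta, beta - Z95 * se, beta + Z95 * se])
    return {
        "ksm": ksm, "contrast": contrast, "model": model, "stratum": stratum,
        "or": float(or_),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(res.pvalues[ksm]),
        "log_or": beta, "se": se, "interaction_p": np.nan,
        "n_cases": n_cases, "n_controls": n_controls, "flag": "",
    }


def fit_interaction(frame: pd.DataFrame, ksm: str, contrast: str,
                    model: int = 2, alignment_var: str = "hka") -> float:
    """Wald p-value for the sex-by-KSM product term added to an adjusted
    (Model 2 or 3) combined-sex fit."""
    if model not in (2, 3):
        raise ValueError("interaction terms belong to the adjusted models (2 or 3)")
    sub = _subset(frame, contrast, "combined", model, alignment_var)
    for grp in ("0", _CONTRAST_GRADE[contrast]):
        sexes = set(sub.loc[sub["grade"] == grp, "sex"])
        if len(sexes) < 2:
            raise ValueError(f"both sexes required in grade {grp} for interaction testing")
    formula = _formula(ksm, model, "combined", sub, interaction=True,
                       alignment_var=alignment_var)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.logit(formula, data=sub).fit(disp=0, maxiter=200)
    term = [name for name in res.params.index if name.startswith(f"{ksm}:C(sex)")]
    if len(term) != 1:
        raise RuntimeError(f"could not locate the sex-by-{ksm} term")
    return float(res.pvalues[term[0]])


class RKOAAssociation:
    """Association model between KSM scores and rKOA grade.

    Parameters
    ----------
    frame : DataFrame
        Analysis frame from :func:`build_frame` (or equivalent): ksm1..ksmN
        score columns in SD units, ``rkoa_grade`` or pre-merged ``grade``,
        demographics and ``hka``/``fta`` columns.
    n_ksms : int
        Number of leading modes analysed (default 10).
    """

    def __init__(self, frame: pd.DataFrame, n_ksms: int = 10):
        frame = frame.copy()
        if "grade" not in frame:
            frame["grade"] = merge_grades(frame["rkoa_grade"])
        self.frame = frame
        self.ksm_cols = [f"ksm{j + 1}" for j in range(n_ksms)]
        missing = [c for c in self.ksm_cols if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks score columns: {missing}")

    @classmethod
    def from_components(cls, scores, assessments, covariates, angles,
                        n_ksms: int = 10) -> "RKOAAssociation":
        return cls(build_frame(scores, assessments, covariates, angles), n_ksms=n_ksms)

    def fit(self, models=(1, 2, 3), strata=STRATA, contrasts=CONTRASTS,
            interactions: bool = True, alpha: float = 0.05,
            alignment_var: str = "hka") -> "AssociationResults":
        """Run the full sweep: every KSM x contrast x model x stratum.

        Interaction p-values are computed for the adjusted models in the
        combined stratum.  Per-row failures are flagged, never raised.
        """
        rows = []
        for ksm in self.ksm_cols:
            for contrast in contrasts:
                for model in models:
                    for stratum in strata:
                        try:
                            row = fit_contrast(self.frame, ksm, contrast, model,
                                               stratum, alignment_var)
                        except Exception as exc:  # pragma: no cover - sweep guard
                            row = _flagged_row(ksm, contrast, model, stratum,
                                               f"error:{type(exc).__name__}")
                        if interactions and model >= 2 and stratum == "combined":
                            try:
                                row["interaction_p"] = fit_interaction(
                                    self.frame, ksm, contrast, model, alignment_var)
                            except (ValueError, RuntimeError):
                                row["interaction_p"] = np.nan
                        rows.append(row)
        table = pd.DataFrame(rows)
        threshold = bonferroni_threshold(alpha, len(self.ksm_cols))
        table["significant"] = table["p"] < threshold
        return AssociationResults(table, threshold=threshold,
                                  attrition=self.frame.attrs.get("attrition"))


class AssociationResults:
    """Tidy odds-ratio table with convenience accessors."""

    def __init__(self, table: pd.DataFrame, threshold: float,
                 attrition: dict | None = None):
        self.table = table
        self.threshold = threshold
        self.attrition = attrition

    def betas(self, contrast: str, model: int, stratum: str = "combined") -> pd.Series:
        """log-ORs for the ten KSMs of one contrast/model/stratum, ordered
        ksm1..ksmN (input to the composite shape builder)."""
        sel = self.table.query(
            "contrast == @contrast and model == @model and stratum == @stratum"
        ).set_index("ksm")["log_or"]
        return sel.reindex(sorted(sel.index, key=lambda k: int(k[3:])))

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]

    def summary(self) -> str:
        t = self.table
        lines = [
            "KSM ~ rKOA logistic association sweep",
            "=" * 60,
            f"rows: {len(t)}   flagged: {(t['flag'] != '').sum()}   "
            f"Bonferroni threshold: {self.threshold:g}",
        ]
        if self.attrition:
            lines.append(f"attrition: {self.attrition}")
        ok = t[t["flag"] == ""]
        for (contrast, model), grp in ok.groupby(["contrast", "model"], sort=True):
            comb = grp[grp["stratum"] == "combined"]
            sig = comb[comb["significant"]]
            lines.append(
                f"  {contrast} model {model}: "
                + (", ".join(f"{r.ksm} OR={r['or']:.2f}" for r in sig.itertuples(index=False))
                   if len(sig) else "no Bonferroni-significant KSMs")
            )
        return "\n".join(lines)

    def forest_plot(self, contrast: str, out_path=None, stratum: str = "combined"):
        """Forest plot of ORs (log scale) for one grade contrast, one panel
        row per KSM, models side by side."""
        from matplotlib.backends.backend_agg import FigureCanvasAgg
        from matplotlib.figure import Figure

        sub = self.table.query(
            "contrast == @contrast and stratum == @stratum and flag == ''"
        )
        fig = Figure(figsize=(6, 6))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        offsets = {1: -0.22, 2: 0.0, 3: 0.22}
        colors = {1: "0.6", 2: "C0", 3: "C3"}
        ksms = sorted(sub["ksm"].unique(), key=lambda k: int(k[3:]))
        for model, grp in sub.groupby("model"):
            grp = grp.set_index("ksm").reindex(ksms)
            y = np.arange(len(ksms)) + offsets[model]
            ax.errorbar(
                grp["or"], y,
                xerr=[grp["or"] - grp["ci_low"], grp["ci_high"] - grp["or"]],
                fmt="o", ms=3, color=colors[model], label=f"Model {model}")
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_yticks(np.arange(len(ksms)))
        ax.set_yticklabels(ksms)
        ax.invert_yaxis()
        ax.set_xlabel("OR per SD (95% CI)")
        ax.set_title(f"rKOA {contrast}, {stratum}")
        ax.legend(fontsize=8)
        if out_path is not None:
            fig.savefig(out_path, dpi=150)
        return fig
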