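"""Subject-level statistics for the ImP / glycemic-status analyses.

Covers the full statistical chain applied to the joined clinical +
microbiome + nutrition table: cohort exclusions (with Grubbs outlier
testing), surrogate insulin-resistance indices, basal-metabolic-rate-based
energy-intake plausibility, histidine intake and diet-quality scores,
exposure quartiles with multinomial odds ratios, covariate-adjusted partial
correlations, Benjamini-Hochberg FDR, linear group comparisons, and
residualized random-forest taxon importance.

Covariate models are nested: Model 1 adjusts for age, sex, BMI and
ethnicity; Model 2 adds creatinine clearance; Model 3 adds diabetes status.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "ExclusionAccounting",
    "IndexCoefficients",
    "MODEL_COVARIATES",
    "grubbs_outliers",
    "apply_cohort_exclusions",
    "derive_indices",
    "harris_benedict_bmr",
    "energy_intake_exclusion",
    "compute_histidine_intake",
    "compute_diet_scores",
    "quartile_stratify",
    "fit_multinomial_or",
    "partial_correlation",
    "bh_fdr",
    "log_transform_policy",
    "linear_group_comparison",
    "rf_motu_importance",
    "design_matrix",
    "residualize",
]

GROUPS = ("healthy", "prediabetes", "type2diabetes")

MODEL_COVARIATES: dict[int, list[str]] = {
    1: ["age", "sex", "bmi", "ethnicity"],
    2: ["age", "sex", "bmi", "ethnicity", "creatinine_clearance"],
    3: ["age", "sex", "bmi", "ethnicity", "creatinine_clearance", "diabetes_status"],
}


@dataclass
class AssociationResult:
    """One association estimate with its uncertainty and multiplicity info."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    q: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------- exclusions


def grubbs_outliers(values, alpha: float = 0.05) -> list[int]:
    """Iterative one-at-a-time Grubbs test; returns indices of outliers.

    At each step G = max|x - mean| / sd is compared with the t-based
    critical value ((n-1)/sqrt(n)) sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}; the extreme point is removed and the test
    repeated until no rejection. A zero-variance sample flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    active = list(range(x.size))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(np.argmax(dev))
        G = dev[i_max] / sd
        n = len(active)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        if G > crit:
            flagged.append(active.pop(i_max))
        else:
            break
    return sorted(flagged)


@dataclass
class ExclusionAccounting:
    """Per-rule exclusion counts, in rule order; counts sum to in - out."""

    n_input: int
    n_retained: int
    counts: dict[str, int]


def apply_cohort_exclusions(
    records: pd.DataFrame,
    rules: Sequence[tuple[str, Callable[[pd.DataFrame], pd.Series]]],
) -> tuple[pd.DataFrame, ExclusionAccounting]:
    """Apply exclusion rules in order; a record counts under the first rule
    it matches. Each rule maps the remaining records to a boolean exclusion
    mask."""
    if not len(rules):
        raise ValueError("rules list must be non-empty")
    kept = records
    counts: dict[str, int] = {}
    for name, rule in rules:
        mask = np.asarray(rule(kept), dtype=bool)
        counts[name] = int(mask.sum())
        kept = kept.loc[~mask]
    return kept, ExclusionAccounting(
        n_input=len(records), n_retained=len(kept), counts=counts
    )


# ----------------------------------------------------------- derived indices


@dataclass
class IndexCoefficients:
    """Published-formula coefficients for the surrogate indices (configurable).

    The HOMA entries implement the closed-form HOMA1 surrogate (the iterative
    HOMA2 computer model is not reimplemented); Stumvoll ISI uses the
    BMI/insulin-120/glucose-120 formulation; MDRD uses the 175 re-expressed
    coefficients with serum creatinine in mg/dl.
    """

    glucose_mmol_to_mgdl: float = 18.016
    tg_mmol_to_mgdl: float = 88.57
    insulin_mU_to_pmol: float = 6.0
    homa_denominator: float = 22.5
    homa_b_numerator: float = 20.0
    homa_b_glucose_offset: float = 3.5
    stumvoll: tuple[float, float, float, float] = (0.226, -0.0032, -0.0000645, -0.0037)
    mdrd_factor: float = 175.0
    mdrd_creatinine_exp: float = -1.154
    mdrd_age_exp: float = -0.203
    mdrd_female_factor: float = 0.742


def _check_positive(df: pd.DataFrame, fields: Sequence[str]) -> None:
    for f in fields:
        if f in df and np.any(df[f].dropna() <= 0):
            raise ValueError(f"non-positive values in field '{f}'")


def derive_indices(
    records: pd.DataFrame, coefficients: IndexCoefficients | None = None
) -> pd.DataFrame:
    """Surrogate metabolic indices from fasting (and post-load) analytes.

    TyG = ln(TG[mg/dl] x glucose[mg/dl] / 2); QUICKI = 1 / (log10 insulin +
    log10 glucose[mg/dl]); HOMA-IR surrogate = glucose[mmol/l] x
    insulin[mU/l] / 22.5; HOMA-B surrogate = 20 insulin / (glucose - 3.5);
    Stumvoll ISI and MDRD eGFR from the configured coefficients. Unit
    conversions are applied internally; inputs stay mmol/l and mU/l.
    """
    c = coefficients or IndexCoefficients()
    single = isinstance(records, pd.Series)
    df = records.to_frame().T if single else records
    _check_positive(df, ["glucose", "insulin", "triglycerides"])

    glu_mgdl = df["glucose"].astype(float) * c.glucose_mmol_to_mgdl
    ins = df["insulin"].astype(float)
    out = pd.DataFrame(index=df.index)
    out["homa_ir"] = df["glucose"].astype(float) * ins / c.homa_denominator
    glu = df["glucose"].astype(float)
    out["homa_b"] = np.where(
        glu > c.homa_b_glucose_offset,
        c.homa_b_numerator * ins / (glu - c.homa_b_glucose_offset),
        np.nan,
    )
    out["quicki"] = 1.0 / (np.log10(ins) + np.log10(glu_mgdl))
    tg_mgdl = df["triglycerides"].astype(float) * c.tg_mmol_to_mgdl
    out["tyg"] = np.log(tg_mgdl * glu_mgdl / 2.0)
    if {"glucose_120", "insulin_120"} <= set(df.columns):
        c0, c1, c2, c3 = c.stumvoll
        out["stumvoll_isi"] = (
            c0
            + c1 * df["bmi"].astype(float)
            + c2 * df["insulin_120"].astype(float) * c.insulin_mU_to_pmol
            + c3 * df["glucose_120"].astype(float)
        )
    if "serum_creatinine" in df.columns:
        egfr = (
            c.mdrd_factor
            * df["serum_creatinine"].astype(float) ** c.mdrd_creatinine_exp
            * df["age"].astype(float) ** c.mdrd_age_exp
        )
        female = df["sex"].astype(str).str.lower().isin(["female", "f", "woman"])
        out["mdrd_egfr"] = np.where(female, egfr * c.mdrd_female_factor, egfr)
    return out.iloc[0] if single else out


# ------------------------------------------------------------------ nutrition

# Harris-Benedict basal metabolic rate, original coefficients (kcal/day)
_HB_COEFFS = {
    "male": (66.4730, 13.7516, 5.0033, 6.7550),
    "female": (655.0955, 9.5634, 1.8496, 4.6756),
}


def harris_benedict_bmr(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    """Harris-Benedict BMR in kcal/day from sex, weight, height and age."""
    key = str(sex).lower()
    key = {"m": "male", "man": "male", "f": "female", "woman": "female"}.get(key, key)
    if key not in _HB_COEFFS:
        raise ValueError(f"unknown sex code: {sex!r}")
    if weight_kg <= 0 or height_cm <= 0 or age_years <= 0:
        raise ValueError("anthropometrics must be positive")
    a, w, h, y = _HB_COEFFS[key]
    return a + w * weight_kg + h * height_cm - y * age_years


def energy_intake_exclusion(energy_kcal: float, bmr_kcal: float,
                            low: float = 0.5, high: float = 3.5) -> bool:
    """True (exclude) iff declared energy < low*BMR or > high*BMR."""
    if np.any(np.asarray(bmr_kcal) <= 0):
        raise ValueError("BMR must be positive")
    return bool(energy_kcal < low * bmr_kcal or energy_kcal > high * bmr_kcal)


def compute_histidine_intake(
    intakes: pd.DataFrame | pd.Series, composition: pd.Series
) -> pd.Series | float:
    """Daily histidine intake (g/day) = sum over food groups of
    intake (g/day) x histidine content (mg/g), converted to grams."""
    single = isinstance(intakes, pd.Series)
    df = intakes.to_frame().T if single else intakes
    missing = [g for g in df.columns if g not in composition.index]
    if missing:
        raise KeyError(f"no histidine content for group(s): {missing[:5]}")
    his = (df * composition.loc[df.columns]).sum(axis=1) / 1000.0
    return float(his.iloc[0]) if single else his.rename("histidine_g")


#: Simplified diet-quality components: (groups, direction, cutpoint g/day).
#: Each component scores 1 when the summed intake is on the healthy side of
#: its cut-point; scores are sums of component points. These are
#: configurable simplifications, not the published EPIC score definitions.
DEFAULT_SCORE_CONFIGS: dict[str, list[tuple[list[str], str, float]]] = {
    "aHEI": [
        (["vegetables"], "higher", 200.0),
        (["fruits"], "higher", 150.0),
        (["cereals_wholegrain", "bread_wholemeal"], "higher", 75.0),
        (["nuts_seeds", "legumes", "soy_products"], "higher", 30.0),
        (["red_meat", "processed_meat"], "lower", 80.0),
        (["soft_drinks", "fruit_juice"], "lower", 250.0),
    ],
    "DASH": [
        (["vegetables"], "higher", 200.0),
        (["fruits"], "higher", 150.0),
        (["dairy_milk", "dairy_yogurt"], "higher", 150.0),
        (["cereals_wholegrain", "bread_wholemeal"], "higher", 75.0),
        (["red_meat", "processed_meat"], "lower", 80.0),
        (["sugar_confectionery", "soft_drinks"], "lower", 150.0),
    ],
    "mediterranean": [
        (["vegetables"], "higher", 200.0),
        (["fruits", "nuts_seeds"], "higher", 150.0),
        (["legumes"], "higher", 25.0),
        (["fish_white", "fish_fatty", "shellfish"], "higher", 40.0),
        (["vegetable_oils"], "higher", 15.0),
        (["red_meat", "processed_meat"], "lower", 80.0),
        (["dairy_milk", "cheese", "butter_animal_fat"], "lower", 250.0),
    ],
}


def compute_diet_scores(
    intakes: pd.DataFrame,
    score_configs: Mapping[str, list[tuple[list[str], str, float]]] | None = None,
) -> pd.DataFrame:
    """Diet-quality scores from food-group intakes.

    DDS is the number of distinct food groups with nonzero intake; the other
    scores are configurable sums of threshold sub-scores. The configuration
    hash is recorded in the result's .attrs["config_hash"].
    """
    configs = DEFAULT_SCORE_CONFIGS if score_configs is None else dict(score_configs)
    out = pd.DataFrame(index=intakes.index)
    out["DDS"] = (intakes > 0).sum(axis=1).astype(int)
    for name, components in configs.items():
        score = pd.Series(0, index=intakes.index, dtype=int)
        for groups, direction, cut in components:
            if direction not in ("higher", "lower"):
                raise ValueError(f"bad direction {direction!r} in score {name}")
            missing = [g for g in groups if g not in intakes.columns]
            if missing:
                raise ValueError(f"score {name}: unknown food group(s) {missing}")
            total = intakes[groups].sum(axis=1)
            score += (total >= cut).astype(int) if direction == "higher" else (
                total <= cut
            ).astype(int)
        out[name] = score
    digest = hashlib.sha1(
        json.dumps({k: v for k, v in sorted(configs.items())}, default=str).encode()
    ).hexdigest()[:12]
    out.attrs["config_hash"] = digest
    return out


# ------------------------------------------------------------- associations


def quartile_stratify(values) -> pd.Series:
    """Quartile labels Q1..Q4 at the empirical 25/50/75 percentiles
    (linear interpolation); ties go to the lower quartile."""
    v = pd.Series(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to form quartiles")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    code = 1 + (v > q25).astype(int) + (v > q50).astype(int) + (v > q75).astype(int)
    return code.map(lambda k: f"Q{k}").rename("quartile")


def design_matrix(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns; object/categorical covariates are
    dummy-coded with the first level dropped."""
    parts = []
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True).astype(float))
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Least-squares residuals of y on [1, covariates]; returns
    (residuals, effective number of covariates = design rank - 1)."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean(), 0
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient covariate matrix; projecting on its column space")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta, rank - 1


def partial_correlation(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None, method: str = "pearson"
) -> AssociationResult:
    """Correlation of x and y after projecting out covariates (+ intercept).

    The Spearman variant ranks all variables before the projection. The
    p-value is from the t distribution with n - 2 - k degrees of freedom
    (k = effective number of covariates); the CI is a Fisher-z interval.
    """
    x = np.asarray(pd.Series(x), dtype=float)
    y = np.asarray(pd.Series(y), dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if C is not None:
        ok &= np.isfinite(C).all(axis=1)
        C = C[ok]
    x, y = x[ok], y[ok]
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        if C is not None:
            C = np.apply_along_axis(stats.rankdata, 0, C)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    rx, k = residualize(x, C)
    ry, _ = residualize(y, C)
    n = len(x)
    if n <= k + 2:
        raise ValueError("too few observations for the partial correlation")
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float((rx * ry).sum() / denom) if denom > 0 else np.nan
    df = n - 2 - k
    if np.isnan(r) or abs(r) >= 1.0:
        p = 0.0 if abs(r) >= 1.0 else np.nan
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    if n - k - 3 > 0 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - k - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo = hi = np.nan
    return AssociationResult(estimate=r, ci_low=lo, ci_high=hi, p=p, n=n,
                             extra={"method": method, "df": df})


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TransformResult:
    values: np.ndarray
    transformed: bool
    degenerate: bool
    shapiro_p: float


def log_transform_policy(values, alpha: float = 0.05) -> TransformResult:
    """Natural-log transform applied iff Shapiro-Wilk on the raw values has
    p < alpha; constant vectors are flagged degenerate and left untouched."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3 or np.ptp(finite) == 0:
        return TransformResult(values=x, transformed=False, degenerate=True, shapiro_p=np.nan)
    p = float(stats.shapiro(finite).pvalue)
    if p < alpha:
        if np.any(finite <= 0):
            raise ValueError("cannot log-transform non-positive values")
        return TransformResult(values=np.log(x), transformed=True, degenerate=False, shapiro_p=p)
    return TransformResult(values=x, transformed=False, degenerate=False, shapiro_p=p)


def fit_multinomial_or(
    outcome: pd.Series,
    exposure_quartiles: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference_class: str = "healthy",
) -> dict[tuple[str, str], AssociationResult]:
    """Multinomial logistic odds ratios for Q2..Q4 vs Q1 per outcome class.

    The outcome reference class (healthy) and exposure reference (Q1) carry
    no coefficients; ORs are exponentiated ML coefficients with Wald 95%
    CIs. Non-convergence (e.g. separation) is flagged on every result, with
    estimates set to NaN rather than silently reported.
    """
    import statsmodels.api as sm

    data = pd.DataFrame({"outcome": outcome, "quartile": exposure_quartiles})
    if covariates is not None:
        data = data.join(pd.DataFrame(covariates))
    data = data.dropna()
    classes = [reference_class] + sorted(set(data["outcome"]) - {reference_class})
    endog = data["outcome"].map({c: i for i, c in enumerate(classes)}).to_numpy()
    qd = pd.get_dummies(data["quartile"]).reindex(
        columns=["Q1", "Q2", "Q3", "Q4"], fill_value=0
    ).drop(columns="Q1").astype(float)
    # quartile levels absent from the data carry no estimable coefficient
    present_q = [c for c in qd.columns if qd[c].sum() > 0]
    qd = qd[present_q]
    exog = pd.concat([qd, data.drop(columns=["outcome", "quartile"]).astype(float)], axis=1)
    exog.insert(0, "const", 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(endog, exog.to_numpy()).fit(method="newton", maxiter=200, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params)  # (n_exog, n_classes - 1)
    bse = np.asarray(res.bse)
    zcrit = stats.norm.ppf(0.975)
    out: dict[tuple[str, str], AssociationResult] = {}
    col_names = list(exog.columns)
    for ci, cls in enumerate(classes[1:]):
        for q in present_q:
            j = col_names.index(q)
            b, se = params[j, ci], bse[j, ci]
            wald_p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan
            out[(cls, q)] = AssociationResult(
                estimate=float(np.exp(b)) if converged else np.nan,
                ci_low=float(np.exp(b - zcrit * se)) if converged else np.nan,
                ci_high=float(np.exp(b + zcrit * se)) if converged else np.nan,
                p=wald_p if converged else np.nan,
                n=len(data),
                converged=converged,
            )
    return out


def linear_group_comparison(
    response,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: str = "healthy",
) -> AssociationResult:
    """Least-squares comparison of a response across the three glycemic
    groups (reference = healthy), with covariate adjustment.

    The reported p is the joint Wald F-test over the group indicator
    coefficients; the estimate and CI are for the last (most affected)
    group versus the reference. Per-group coefficients are in .extra.
    """
    import statsmodels.api as sm

    data = pd.DataFrame({"y": pd.Series(response, dtype=float), "group": group})
    if covariates is not None:
        data = data.join(pd.DataFrame(covariates))
    data = data.dropna()
    levels = [reference] + [g for g in GROUPS if g != reference and g in set(data["group"])]
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    dummies = pd.get_dummies(
        data["group"].astype(pd.CategoricalDtype(levels)), drop_first=True
    ).astype(float)
    dummies.columns = [f"group_{c}" for c in dummies.columns]
    X = pd.concat([dummies, data.drop(columns=["y", "group"]).astype(float)], axis=1)
    X.insert(0, "const", 1.0)
    res = sm.OLS(data["y"].to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    gcols = [i for i, c in enumerate(names) if c.startswith("group_")]
    R = np.zeros((len(gcols), len(names)))
    for row, i in enumerate(gcols):
        R[row, i] = 1.0
    joint = res.f_test(R)
    last = gcols[-1]
    ci = res.conf_int()[last]
    return AssociationResult(
        estimate=float(res.params[last]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(joint.pvalue),
        n=int(res.nobs),
        extra={
            "coefficients": {names[i]: float(res.params[i]) for i in gcols},
            "per_group_p": {names[i]: float(res.pvalues[i]) for i in gcols},
        },
    )


# ------------------------------------------------------------ random forest


@dataclass
class RFConfig:
    """Random-forest settings for taxon importance on ImP residuals."""

    n_folds: int = 100
    n_trees: int = 100
    max_leaf_nodes: int = 50
    mtry: int | float | None = None  # None = sklearn default (all features)
    seed: int = 0


def rf_motu_importance(
    residuals, motu: pd.DataFrame, config: RFConfig | None = None
) -> pd.DataFrame:
    """Mean node-purity importance of taxa for predicting ImP residuals.

    A regression forest (bounded leaf count) is refit on the training side
    of each of n_folds cross-validation folds and the impurity-decrease
    importances are averaged; each taxon also gets a Spearman correlation
    against the residuals with BH-FDR across taxa. Returned sorted by
    importance."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import KFold

    cfg = config or RFConfig()
    y = np.asarray(pd.Series(residuals), dtype=float)
    X = motu.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 taxa")
    n = len(y)
    n_folds = cfg.n_folds
    if n < n_folds:
        warnings.warn(f"reducing folds from {n_folds} to {n}")
        n_folds = n
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    imp = np.zeros(X.shape[1])
    for fold_i, (train, _) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_leaf_nodes=cfg.max_leaf_nodes,
            max_features=cfg.mtry if cfg.mtry is not None else 1.0,
            random_state=cfg.seed + fold_i,
            n_jobs=1,
        ).fit(X[train], y[train])
        imp += rf.feature_importances_
    imp /= n_folds

    rho = np.empty(X.shape[1])
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            rho[j], pvals[j] = 0.0, 1.0
        else:
            rho[j], pvals[j] = stats.spearmanr(X[:, j], y)
    out = pd.DataFrame(
        {
            "importance": imp,
            "spearman_rho": rho,
            "p": pvals,
            "q": bh_fdr(pvals),
        },
        index=motu.columns,
    )
    return out.sort_values("importance", ascending=False)
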