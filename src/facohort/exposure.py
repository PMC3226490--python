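"""Exposure models: annual means, predictive fits, and cohort assignment.

The measured subsample provides seasonal 7-day FA levels per dwelling.  The
annual level is the arithmetic mean of the seasonal levels (requiring a
configurable minimum number of seasons).  Three predictive models are fitted
on the measured dwellings — a linear model on natural-log levels, a logistic
model for the "high" class (above the observed median), and a multinomial
model for tertile classes — and the selected model assigns an annual level and
exposure class to every cohort member, time-weighting over residence changes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .config import DWELLING_PREDICTORS
from .design import dwelling_design
from .diagnostics import auc, classification_diagnostics, hosmer_lemeshow
from .errors import FacohortError, SchemaError, SeparationError

logger = logging.getLogger(__name__)

LOQ_UGM3 = 2.4  # quantification limit of the passive sampler, µg/m³

__all__ = [
    "compute_annual_mean",
    "annual_means",
    "handle_below_loq",
    "exposure_thresholds",
    "univariate_screen",
    "fit_linear_exposure_model",
    "fit_logistic_exposure_model",
    "fit_multinomial_tertile_model",
    "select_model_aic",
    "classify_linear_predictions",
    "assign_cohort_exposure",
    "ExposureModelFit",
]


# ---------------------------------------------------------------------------
# annual means
# ---------------------------------------------------------------------------

def compute_annual_mean(measurements: pd.DataFrame, min_seasons: int = 3):
    """Annual mean FA (µg/m³) for one dwelling, or ``None`` if too few seasons.

    The annual level is the arithmetic mean of the per-season levels.  A
    duplicated season is ambiguous input and raises.
    """
    if not 1 <= min_seasons <= 4:
        raise ValueError("min_seasons must lie in 1..4")
    ids = measurements["dwelling_id"].unique()
    if len(ids) != 1:
        raise ValueError("measurements must belong to a single dwelling")
    seasons = measurements["season"]
    if seasons.duplicated().any():
        dup = seasons[seasons.duplicated()].iloc[0]
        raise FacohortError(f"duplicated season '{dup}' for dwelling {ids[0]}")
    n = len(measurements)
    if n < min_seasons:
        return None
    return {
        "dwelling_id": ids[0],
        "annual_mean": float(measurements["fa_level"].mean()),
        "n_seasons": int(n),
    }


def annual_means(
    measurements: pd.DataFrame,
    min_seasons: int = 3,
    loq_policy: str = "half_loq",
) -> pd.DataFrame:
    """Per-dwelling annual means; dwellings with too few seasons are excluded."""
    meas = handle_below_loq(measurements, loq_policy)
    rows = []
    for _, grp in meas.groupby("dwelling_id", sort=True):
        rec = compute_annual_mean(grp, min_seasons=min_seasons)
        if rec is not None:
            rows.append(rec)
    out = pd.DataFrame(rows, columns=["dwelling_id", "annual_mean", "n_seasons"])
    n_excluded = measurements["dwelling_id"].nunique() - len(out)
    if n_excluded:
        logger.info("annual_means: %d dwelling(s) excluded (<%d seasons)", n_excluded, min_seasons)
    return out


def handle_below_loq(measurements: pd.DataFrame, policy: str = "half_loq") -> pd.DataFrame:
    """Substitute below-quantification-limit levels according to ``policy``.

    ``half_loq`` replaces flagged values with LOQ/2 = 1.2 µg/m³, ``loq`` with
    2.4 µg/m³, ``as_reported`` leaves them untouched (warning logged).
    """
    if policy not in ("half_loq", "loq", "as_reported"):
        raise ValueError(f"unknown below-LOQ policy '{policy}'")
    out = measurements.copy()
    if "below_loq" not in out.columns:
        return out
    flagged = out["below_loq"].astype(int) == 1
    n = int(flagged.sum())
    if n == 0:
        return out
    if policy == "as_reported":
        logger.warning("handle_below_loq: %d below-LOQ value(s) kept as reported", n)
        return out
    value = LOQ_UGM3 / 2.0 if policy == "half_loq" else LOQ_UGM3
    out.loc[flagged, "fa_level"] = value
    logger.info("handle_below_loq: %d value(s) replaced by %.1f µg/m³", n, value)
    return out


def exposure_thresholds(annual_mean_values) -> dict:
    """Median and tertile cut-points (µg/m³) of the observed annual levels."""
    v = np.asarray(annual_mean_values, dtype=float)
    t1, t2 = np.quantile(v, [1 / 3, 2 / 3])
    return {"median": float(np.median(v)), "tertiles": (float(t1), float(t2))}


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class ExposureModelFit:
    """A fitted predictive model of FA with its diagnostics.

    ``params``/``bse``/``pvalues`` are indexed by design-column name (plus
    ``const``); for the multinomial fit they are DataFrames with one column per
    non-reference class.
    """

    kind: str  # linear_log | logistic_median | multinomial_tertile
    predictors: tuple
    params: object
    bse: object
    pvalues: object
    conf_int: object
    aic: float
    n: int
    row_ids: tuple
    thresholds: dict
    sigma: float | None = None
    vif: pd.Series | None = None
    hl_statistic: float | None = None
    hl_pvalue: float | None = None
    diagnostics: dict = field(default_factory=dict)
    or_table: pd.DataFrame | None = None
    season_adjust: bool = True

    @property
    def n_params(self) -> int:
        p = self.params
        return int(p.size)

    def design(self, dwellings: pd.DataFrame) -> pd.DataFrame:
        X = dwelling_design(dwellings, self.predictors, season_adjust=self.season_adjust)
        X = sm.add_constant(X, has_constant="add")
        names = self.params.index if hasattr(self.params, "index") else self.params.index
        return X[list(names)]

    def predict_level(self, dwellings: pd.DataFrame) -> pd.Series:
        """Predicted annual FA level in µg/m³ (linear model only)."""
        if self.kind != "linear_log":
            raise FacohortError("predict_level requires the linear model")
        X = self.design(dwellings)
        lp = X.to_numpy() @ np.asarray(self.params, dtype=float)
        return pd.Series(np.exp(lp), index=dwellings.index, name="predicted_level")

    def predict_prob_high(self, dwellings: pd.DataFrame) -> pd.Series:
        if self.kind != "logistic_median":
            raise FacohortError("predict_prob_high requires the logistic model")
        X = self.design(dwellings)
        lp = X.to_numpy() @ np.asarray(self.params, dtype=float)
        return pd.Series(1.0 / (1.0 + np.exp(-lp)), index=dwellings.index, name="p_high")

    def to_dict(self) -> dict:
        def _ser(x):
            if isinstance(x, pd.DataFrame):
                return {c: x[c].round(6).to_dict() for c in x.columns}
            if isinstance(x, pd.Series):
                return x.round(6).to_dict()
            return x

        return {
            "kind": self.kind,
            "predictors": list(self.predictors),
            "params": _ser(self.params),
            "bse": _ser(self.bse),
            "pvalues": _ser(self.pvalues),
            "aic": round(float(self.aic), 4),
            "n": self.n,
            "sigma": None if self.sigma is None else round(float(self.sigma), 6),
            "vif": _ser(self.vif),
            "hl_statistic": self.hl_statistic,
            "hl_pvalue": self.hl_pvalue,
            "diagnostics": {k: (None if v is None else float(v)) for k, v in self.diagnostics.items()
                            if not isinstance(v, (list, tuple, dict))},
            "thresholds": {"median": self.thresholds["median"],
                           "tertiles": list(self.thresholds["tertiles"])},
            "or_table": None if self.or_table is None else self.or_table.round(6).to_dict("index"),
        }


def _merge_tables(annual: pd.DataFrame, dwellings: pd.DataFrame) -> pd.DataFrame:
    merged = annual.merge(dwellings, on="dwelling_id", how="left", validate="one_to_one")
    missing = merged[merged[dwellings.columns[1]].isna()]["dwelling_id"].tolist()
    if missing:
        raise SchemaError(f"annual levels reference unknown dwellings: {missing[:5]}")
    return merged


def univariate_screen(
    annual: pd.DataFrame,
    dwellings: pd.DataFrame,
    alpha: float = 0.20,
    forced_in=(),
) -> dict:
    """Predictors whose univariate linear model on log levels has p ≤ alpha.

    Each predictor is tested as a group (F test of its dummy block against the
    intercept-only model); constant predictors are excluded with a warning.
    The returned report lists every predictor with its p-value.
    """
    merged = _merge_tables(annual, dwellings)
    y = np.log(merged["annual_mean"].to_numpy(dtype=float))
    pvals = {}
    kept = []
    for name in DWELLING_PREDICTORS:
        X = dwelling_design(merged, [name], season_adjust=False)
        if X.shape[1] == 0 or (X.nunique() <= 1).all():
            warnings.warn(f"predictor '{name}' is constant; excluded from screening")
            pvals[name] = np.nan
            continue
        res = sm.OLS(y, sm.add_constant(X)).fit()
        p = float(res.f_pvalue)
        pvals[name] = p
        if p <= alpha:
            kept.append(name)
    for name in forced_in:
        if name not in kept:
            kept.append(name)
    kept = [n for n in DWELLING_PREDICTORS if n in kept]
    return {"candidates": tuple(kept), "pvalues": pvals, "alpha": alpha,
            "forced_in": tuple(forced_in)}


def _design_for_fit(merged, candidates, season_adjust):
    X = dwelling_design(merged, candidates, season_adjust=season_adjust)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the collinear columns by greedy QR-style elimination
        bad = []
        cols = list(Xc.columns)
        for k in range(1, len(cols) + 1):
            sub = Xc[cols[:k]].to_numpy()
            if np.linalg.matrix_rank(sub) < k - len(bad):
                bad.append(cols[k - 1])
        raise FacohortError(f"rank-deficient design; collinear column(s): {bad}")
    return Xc


def fit_linear_exposure_model(
    annual: pd.DataFrame,
    dwellings: pd.DataFrame,
    candidates=DWELLING_PREDICTORS,
    season_adjust: bool = True,
) -> ExposureModelFit:
    """OLS of natural-log annual level on the candidate predictors.

    Reports coefficients with Wald SEs and 95% CIs, the residual SD, AIC and
    per-column variance inflation factors.  The window-opening term, when
    present, is adjusted for season of declaration.
    """
    merged = _merge_tables(annual, dwellings)
    Xc = _design_for_fit(merged, candidates, season_adjust)
    if len(merged) <= Xc.shape[1] + 5:
        raise FacohortError("too few observations for the number of parameters")
    y = np.log(merged["annual_mean"].to_numpy(dtype=float))
    res = sm.OLS(y, Xc).fit()
    vif = pd.Series(
        [variance_inflation_factor(Xc.to_numpy(), i) for i in range(1, Xc.shape[1])],
        index=Xc.columns[1:],
        name="vif",
    )
    thresholds = exposure_thresholds(merged["annual_mean"])
    fit = ExposureModelFit(
        kind="linear_log",
        predictors=tuple(candidates),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        aic=float(res.aic),
        n=int(res.nobs),
        row_ids=tuple(merged["dwelling_id"]),
        thresholds=thresholds,
        sigma=float(np.sqrt(res.scale)),
        vif=vif,
        season_adjust=season_adjust,
    )
    # in-sample discrimination: classify predictions against the observed median
    pred = np.exp(res.fittedvalues)
    classes = classify_linear_predictions(pred, thresholds["median"])
    obs = np.where(merged["annual_mean"] > thresholds["median"], "high", "low")
    diag = classification_diagnostics(classes, obs)
    diag["auc"] = auc(pred, (obs == "high").astype(int))
    fit.diagnostics = diag
    return fit


def _check_separation(res, Xc):
    bad = ~np.isfinite(res.params) | (np.abs(res.params) > 30) | ~np.isfinite(res.bse)
    if bad.any():
        cols = list(np.asarray(Xc.columns)[np.asarray(bad)])
        raise SeparationError(
            f"complete or quasi-complete separation; offending column(s): {cols}", cols
        )


def fit_logistic_exposure_model(
    annual: pd.DataFrame,
    dwellings: pd.DataFrame,
    candidates=DWELLING_PREDICTORS,
    threshold: float | None = None,
    season_adjust: bool = True,
    hl_groups: int = 10,
) -> ExposureModelFit:
    """ML logistic fit for the probability of the "high" FA class.

    The class is defined by annual level strictly above ``threshold`` (the
    observed median by default).  Reports ORs with Wald 95% CIs, AIC, the
    Hosmer–Lemeshow test and discrimination diagnostics (sens/spec/PPV/NPV/
    accuracy/AUC) at the 0.5 fitted-probability cut.
    """
    merged = _merge_tables(annual, dwellings)
    thresholds = exposure_thresholds(merged["annual_mean"])
    cut = thresholds["median"] if threshold is None else float(threshold)
    y = (merged["annual_mean"].to_numpy(dtype=float) > cut).astype(int)
    if y.min() == y.max():
        raise FacohortError("both exposure classes must be non-empty")
    Xc = _design_for_fit(merged, candidates, season_adjust)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    _check_separation(res, Xc)
    ci = res.conf_int()
    or_table = pd.DataFrame(
        {
            "OR": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": res.pvalues,
        }
    ).drop(index="const")
    p_hat = np.asarray(res.predict(Xc))
    try:
        hl_stat, hl_p = hosmer_lemeshow(p_hat, y, n_groups=hl_groups)
    except (FacohortError, ValueError) as exc:  # degenerate grouping / tiny n
        logger.info("Hosmer–Lemeshow unavailable: %s", exc)
        hl_stat = hl_p = None
    classes = np.where(p_hat > 0.5, "high", "low")
    obs = np.where(y == 1, "high", "low")
    diag = classification_diagnostics(classes, obs)
    diag["auc"] = auc(p_hat, y)
    return ExposureModelFit(
        kind="logistic_median",
        predictors=tuple(candidates),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=ci,
        aic=float(res.aic),
        n=int(res.nobs),
        row_ids=tuple(merged["dwelling_id"]),
        thresholds=thresholds,
        hl_statistic=None if hl_stat is None else float(hl_stat),
        hl_pvalue=None if hl_p is None else float(hl_p),
        diagnostics=diag,
        or_table=or_table,
        season_adjust=season_adjust,
    )


def fit_multinomial_tertile_model(
    annual: pd.DataFrame,
    dwellings: pd.DataFrame,
    candidates=DWELLING_PREDICTORS,
    season_adjust: bool = True,
) -> ExposureModelFit:
    """3-class multinomial logit on tertile classes (lowest tertile reference)."""
    merged = _merge_tables(annual, dwellings)
    thresholds = exposure_thresholds(merged["annual_mean"])
    t1, t2 = thresholds["tertiles"]
    v = merged["annual_mean"].to_numpy(dtype=float)
    y = np.where(v > t2, 2, np.where(v > t1, 1, 0))
    if len(np.unique(y)) < 3:
        raise FacohortError("all three tertile classes must be non-empty")
    Xc = _design_for_fit(merged, candidates, season_adjust)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"multinomial fit failed: {exc}") from exc
    params = pd.DataFrame(
        np.asarray(res.params), index=Xc.columns, columns=["tertile2", "tertile3"]
    )
    bse = pd.DataFrame(np.asarray(res.bse), index=Xc.columns, columns=params.columns)
    pvalues = pd.DataFrame(np.asarray(res.pvalues), index=Xc.columns, columns=params.columns)
    return ExposureModelFit(
        kind="multinomial_tertile",
        predictors=tuple(candidates),
        params=params,
        bse=bse,
        pvalues=pvalues,
        conf_int=None,
        aic=float(res.aic),
        n=int(res.nobs),
        row_ids=tuple(merged["dwelling_id"]),
        thresholds=thresholds,
        season_adjust=season_adjust,
    )


def select_model_aic(fits) -> ExposureModelFit:
    """Minimum-AIC fit; ties broken by fewer parameters, then predictor order.

    All candidates must have been fitted on the identical observation set.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one candidate fit")
    rows = {f.row_ids for f in fits}
    if len(rows) > 1:
        raise FacohortError("candidate fits were computed on differing observation sets")
    table = [(round(f.aic, 10), f.n_params, tuple(f.predictors)) for f in fits]
    logger.info("AIC table: %s", table)
    return min(enumerate(fits), key=lambda kv: (round(kv[1].aic, 10), kv[1].n_params,
                                                tuple(kv[1].predictors)))[1]


def aic_search(
    annual: pd.DataFrame,
    dwellings: pd.DataFrame,
    candidates,
    fit_fn=fit_linear_exposure_model,
    forced=(),
    exhaustive_limit: int = 12,
):
    """AIC subset selection over predictor groups.

    Exhaustive when the candidate set has at most ``exhaustive_limit`` groups,
    backward elimination otherwise.  Returns the winning fit.
    """
    candidates = [c for c in candidates if c not in forced]
    if len(candidates) <= exhaustive_limit:
        fits = []
        for k in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, k):
                preds = tuple(forced) + combo
                preds = tuple(n for n in DWELLING_PREDICTORS if n in preds)
                try:
                    fits.append(fit_fn(annual, dwellings, preds))
                except (FacohortError, SeparationError):
                    continue
        return select_model_aic(fits)
    current = tuple(forced) + tuple(candidates)
    best = fit_fn(annual, dwellings, current)
    improved = True
    while improved and len(current) > len(forced):
        improved = False
        for drop in [c for c in current if c not in forced]:
            preds = tuple(c for c in current if c != drop)
            try:
                fit = fit_fn(annual, dwellings, preds)
            except (FacohortError, SeparationError):
                continue
            if fit.aic < best.aic:
                best, current, improved = fit, preds, True
    return best


# ---------------------------------------------------------------------------
# classification & cohort assignment
# ---------------------------------------------------------------------------

def classify_linear_predictions(predicted_levels, observed_median: float) -> np.ndarray:
    """"high" iff the predicted level strictly exceeds the observed median."""
    pred = np.asarray(predicted_levels, dtype=float)
    return np.where(pred > observed_median, "high", "low")


def _parse_history(entry):
    if isinstance(entry, str):
        parts = [p for p in entry.split(";") if p]
        return [(d, float(f)) for d, f in (p.split(":") for p in parts)]
    return list(entry)


def assign_cohort_exposure(
    subjects: pd.DataFrame,
    dwellings: pd.DataFrame,
    fit: ExposureModelFit,
    mover_policy: str = "time_weighted",
) -> pd.DataFrame:
    """Predicted annual FA exposure for every cohort member.

    Per-dwelling levels come from the linear model; the subject's annual level
    is the residence-time-weighted mean (or the longest-occupied dwelling's
    level under ``mover_policy='longest'``).  Class cut-points are the ones
    frozen in the fit (from the measured sample) and are never re-estimated.
    The ``high_all_year`` flag requires every occupied dwelling to be in the
    high class.
    """
    if mover_policy not in ("time_weighted", "longest"):
        raise ValueError(f"unknown mover policy '{mover_policy}'")
    levels = fit.predict_level(dwellings)
    levels.index = dwellings["dwelling_id"]
    level_map = levels.to_dict()
    cut = fit.thresholds["median"]
    t1, t2 = fit.thresholds["tertiles"]

    dangling = []
    rows = []
    for sid, entry in zip(subjects["subject_id"], subjects["residence_history"]):
        hist = _parse_history(entry)
        unknown = [d for d, _ in hist if d not in level_map]
        if unknown:
            dangling.append(sid)
            continue
        if mover_policy == "longest":
            d_star = max(hist, key=lambda df_: df_[1])[0]
            annual = level_map[d_star]
        else:
            annual = sum(frac * level_map[d] for d, frac in hist)
        per_dwelling_high = [level_map[d] > cut for d, _ in hist]
        rows.append(
            {
                "subject_id": sid,
                "annual_level": annual,
                "class_median": "high" if annual > cut else "low",
                "class_tertile": 3 if annual > t2 else (2 if annual > t1 else 1),
                "high_all_year": int(all(per_dwelling_high)),
            }
        )
    if dangling:
        raise SchemaError(
            f"residence histories reference unknown dwellings for subjects {dangling[:5]}"
            + ("..." if len(dangling) > 5 else "")
        )
    return pd.DataFrame(rows)
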