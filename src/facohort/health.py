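"""Associations between assigned FA exposure and LRI outcomes.

Binary logistic regression for any-LRI vs never, and a three-level multinomial
logit (never LRI as the reference stratum) for non-wheezy and wheezy LRI.
Exposure enters either continuously (µg/m³, reported per interquartile-range
increase) or as the median/tertile class.  Covariates are screened at
univariate p ≤ 0.20 with literature-based confounders forced in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import OUTCOME_LEVELS, SUBJECT_COVARIATES
from .design import subject_design
from .errors import FacohortError, SeparationError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5th percentile

__all__ = [
    "covariate_screen",
    "fit_binary_lri",
    "fit_multinomial_lri",
    "iqr_scaled_or",
    "iqr_width",
    "AssociationResult",
]


def iqr_width(q25: float, q75: float) -> float:
    """Interquartile width q75 − q25 (µg/m³)."""
    if not q75 > q25:
        raise ValueError(f"inverted quartiles: q25={q25}, q75={q75}")
    return float(q75) - float(q25)


def iqr_scaled_or(beta: float, se: float, iqr: float):
    """OR and Wald 95% CI for an ``iqr``-unit increase of a continuous exposure."""
    if iqr <= 0:
        raise ValueError("iqr must be positive")
    lo = np.exp((beta - Z95 * se) * iqr)
    hi = np.exp((beta + Z95 * se) * iqr)
    return float(np.exp(beta * iqr)), float(lo), float(hi)


@dataclass
class AssociationResult:
    """Adjusted association estimates from one outcome model."""

    model_kind: str  # binary_logistic | multinomial_logistic
    table: pd.DataFrame  # term, [stratum,] coef, se, OR, ci_low, ci_high, p
    fa_or_per_iqr: dict  # stratum -> (OR, lo, hi); binary uses stratum 'LRI'
    iqr_used: float | None
    n_used: int
    reference_stratum: str
    n_dropped_missing: int = 0
    exposure_term: str = "fa_level"
    llf: float = field(default=np.nan)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "reference_stratum": self.reference_stratum,
            "n_used": self.n_used,
            "n_dropped_missing": self.n_dropped_missing,
            "iqr_used": self.iqr_used,
            "fa_or_per_iqr": {
                k: {"OR": v[0], "ci_low": v[1], "ci_high": v[2]}
                for k, v in self.fa_or_per_iqr.items()
            },
            "table": self.table.round(6).to_dict("records"),
        }


def _binary_outcome(subjects: pd.DataFrame) -> np.ndarray:
    bad = set(subjects["outcome"].unique()) - set(OUTCOME_LEVELS)
    if bad:
        raise FacohortError(f"unknown outcome level(s): {sorted(bad)}")
    return (subjects["outcome"] != "never_LRI").astype(int).to_numpy()


def covariate_screen(
    subjects: pd.DataFrame,
    alpha: float = 0.20,
    forced_in=("ses",),
) -> dict:
    """Covariates with univariate logistic p ≤ alpha (any-LRI outcome), plus forced ones.

    Each covariate is tested as a group by the likelihood-ratio p-value of its
    univariate logistic model; constant covariates are excluded with a warning.
    """
    y = _binary_outcome(subjects)
    pvals = {}
    kept = []
    for name in SUBJECT_COVARIATES:
        X = subject_design(subjects, [name])
        if X.shape[1] == 0 or (X.nunique() <= 1).all():
            warnings.warn(f"covariate '{name}' is constant; excluded from screening")
            pvals[name] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        p = float(res.llr_pvalue)
        pvals[name] = p
        if p <= alpha:
            kept.append(name)
    for name in forced_in:
        if name not in kept and name in SUBJECT_COVARIATES:
            kept.append(name)
    kept = [n for n in SUBJECT_COVARIATES if n in kept]
    return {"candidates": tuple(kept), "pvalues": pvals, "alpha": alpha,
            "forced_in": tuple(forced_in)}


def _exposure_column(subjects, exposure, coding):
    """Numeric exposure column(s) aligned to subjects, per the chosen coding."""
    e = exposure.reindex(subjects["subject_id"])
    if coding == "continuous":
        return pd.DataFrame({"fa_level": e.to_numpy(dtype=float)}, index=subjects.index)
    if coding == "median":
        return pd.DataFrame({"fa_high": (e == "high").astype(float).to_numpy()},
                            index=subjects.index)
    if coding == "tertile":
        v = e.to_numpy()
        return pd.DataFrame(
            {
                "fa_tertile2": (v == 2).astype(float),
                "fa_tertile3": (v == 3).astype(float),
            },
            index=subjects.index,
        )
    raise ValueError(f"unknown exposure coding '{coding}'")


def _drop_missing(subjects, E, Z):
    mask = ~(E.isna().any(axis=1) | Z.isna().any(axis=1))
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("complete-case analysis: %d subject(s) dropped for missing values",
                    n_dropped)
    return mask, n_dropped


def _check_separation(params, bse, columns):
    arr_p, arr_b = np.asarray(params, dtype=float), np.asarray(bse, dtype=float)
    bad = ~np.isfinite(arr_p) | (np.abs(arr_p) > 30) | ~np.isfinite(arr_b)
    if bad.any():
        idx = np.unique(np.nonzero(bad)[0])
        cols = [columns[i] for i in idx]
        raise SeparationError(f"separation in outcome model; column(s): {cols}", cols)


def fit_binary_lri(
    subjects: pd.DataFrame,
    exposure: pd.Series,
    covariates=SUBJECT_COVARIATES,
    exposure_coding: str = "continuous",
    iqr: float | None = None,
) -> AssociationResult:
    """Adjusted logistic regression of any-LRI on exposure and covariates.

    With continuous coding the FA effect is reported per IQR increase; ``iqr``
    defaults to the IQR of the assigned exposure itself (value logged).
    """
    y = _binary_outcome(subjects)
    E = _exposure_column(subjects, exposure, exposure_coding)
    Z = subject_design(subjects, covariates)
    mask, n_dropped = _drop_missing(subjects, E, Z)
    X = pd.concat([E, Z], axis=1)[mask]
    y = y[np.asarray(mask)]
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"binary LRI fit failed: {exc}") from exc
    _check_separation(res.params, res.bse, list(Xc.columns))

    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": Xc.columns,
            "coef": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "OR": np.exp(np.asarray(res.params)),
            "ci_low": np.exp(np.asarray(ci[0])),
            "ci_high": np.exp(np.asarray(ci[1])),
            "p": np.asarray(res.pvalues),
        }
    )
    fa_or = {}
    iqr_used = None
    if exposure_coding == "continuous":
        if iqr is None:
            vals = E["fa_level"][mask].to_numpy()
            iqr_used = iqr_width(*np.quantile(vals, [0.25, 0.75]))
            logger.info("fa_or_per_iqr scaled by assigned-exposure IQR = %.3f µg/m³", iqr_used)
        else:
            iqr_used = float(iqr)
        fa_or["LRI"] = iqr_scaled_or(res.params["fa_level"], res.bse["fa_level"], iqr_used)
    else:
        for col in E.columns:
            fa_or[col] = (
                float(np.exp(res.params[col])),
                float(np.exp(ci.loc[col, 0])),
                float(np.exp(ci.loc[col, 1])),
            )
    return AssociationResult(
        model_kind="binary_logistic",
        table=table,
        fa_or_per_iqr=fa_or,
        iqr_used=iqr_used,
        n_used=int(res.nobs),
        reference_stratum="no_LRI",
        n_dropped_missing=n_dropped,
        llf=float(res.llf),
    )


def fit_multinomial_lri(
    subjects: pd.DataFrame,
    exposure: pd.Series,
    covariates=SUBJECT_COVARIATES,
    exposure_coding: str = "continuous",
    iqr: float | None = None,
) -> AssociationResult:
    """Three-level multinomial logit with never-LRI as the reference stratum."""
    outcome = subjects["outcome"]
    missing_levels = set(OUTCOME_LEVELS) - set(outcome.unique())
    if missing_levels:
        raise FacohortError(f"empty outcome stratum(s): {sorted(missing_levels)}")
    y = outcome.map({lv: i for i, lv in enumerate(OUTCOME_LEVELS)}).to_numpy()
    E = _exposure_column(subjects, exposure, exposure_coding)
    Z = subject_design(subjects, covariates)
    mask, n_dropped = _drop_missing(subjects, E, Z)
    X = pd.concat([E, Z], axis=1)[mask]
    y = y[np.asarray(mask)]
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(y, Xc).fit(disp=0, maxiter=500)
        except Exception as exc:
            raise SeparationError(f"multinomial LRI fit failed: {exc}") from exc
    params = np.asarray(res.params)  # (k, 2): columns are strata 1, 2
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    _check_separation(params, bse, list(Xc.columns))

    strata = ("non_wLRI", "wLRI")
    records = []
    for j, stratum in enumerate(strata):
        for i, term in enumerate(Xc.columns):
            b, s = params[i, j], bse[i, j]
            records.append(
                {
                    "stratum": stratum,
                    "term": term,
                    "coef": b,
                    "se": s,
                    "OR": np.exp(b),
                    "ci_low": np.exp(b - Z95 * s),
                    "ci_high": np.exp(b + Z95 * s),
                    "p": pvals[i, j],
                }
            )
    table = pd.DataFrame(records)

    fa_or = {}
    iqr_used = None
    cols = list(Xc.columns)
    if exposure_coding == "continuous":
        if iqr is None:
            vals = E["fa_level"][mask].to_numpy()
            iqr_used = iqr_width(*np.quantile(vals, [0.25, 0.75]))
            logger.info("fa_or_per_iqr scaled by assigned-exposure IQR = %.3f µg/m³", iqr_used)
        else:
            iqr_used = float(iqr)
        i = cols.index("fa_level")
        for j, stratum in enumerate(strata):
            fa_or[stratum] = iqr_scaled_or(params[i, j], bse[i, j], iqr_used)
    else:
        for col in E.columns:
            i = cols.index(col)
            for j, stratum in enumerate(strata):
                b, s = params[i, j], bse[i, j]
                fa_or[f"{stratum}:{col}"] = (
                    float(np.exp(b)),
                    float(np.exp(b - Z95 * s)),
                    float(np.exp(b + Z95 * s)),
                )
    return AssociationResult(
        model_kind="multinomial_logistic",
        table=table,
        fa_or_per_iqr=fa_or,
        iqr_used=iqr_used,
        n_used=int(res.nobs),
        reference_stratum="never_LRI",
        n_dropped_missing=n_dropped,
        llf=float(res.llf),
    )
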