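"""Design-matrix builders shared by the generator and the model fitters.

Dummy columns are named ``field[level]`` with the first listed level as the
reference; binary fields ("0"/"1") and continuous fields keep their own name.
Using a single builder on both sides guarantees that coefficients estimated by
the exposure models live on exactly the scale the generator uses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    DWELLING_LEVELS,
    DWELLING_PREDICTORS,
    SEASONS,
    SUBJECT_COVARIATES,
    SUBJECT_LEVELS,
)
from .errors import SchemaError

_CONTINUOUS_DWELLING = ("window_open_hours",)


def _encode_field(values: pd.Series, name: str, levels: tuple) -> pd.DataFrame:
    values = values.astype(str)
    bad = set(values.unique()) - set(levels)
    if bad:
        raise SchemaError(f"unknown level(s) {sorted(bad)} for field '{name}'")
    if levels == ("0", "1"):
        return pd.DataFrame({name: (values == "1").astype(float)})
    cols = {}
    for level in levels[1:]:
        cols[f"{name}[{level}]"] = (values == level).astype(float)
    return pd.DataFrame(cols)


def dwelling_design(
    dwellings: pd.DataFrame,
    predictors=None,
    season_adjust: bool = True,
) -> pd.DataFrame:
    """Dummy-coded design matrix for the dwelling predictors.

    When ``window_open_hours`` is among the predictors and ``season_adjust``
    is true, season-of-declaration dummies are appended so the window-opening
    coefficient is adjusted for the season in which it was declared.
    """
    if predictors is None:
        predictors = DWELLING_PREDICTORS
    blocks = []
    for name in predictors:
        if name not in dwellings.columns:
            raise SchemaError(f"dwelling table lacks predictor column '{name}'")
        if name in _CONTINUOUS_DWELLING:
            vals = pd.to_numeric(dwellings[name], errors="coerce")
            if vals.isna().any() or (vals < 0).any():
                raise SchemaError(f"'{name}' must be non-negative numeric")
            blocks.append(vals.astype(float).to_frame(name))
        else:
            blocks.append(_encode_field(dwellings[name], name, DWELLING_LEVELS[name]))
    if season_adjust and "window_open_hours" in predictors:
        blocks.append(
            _encode_field(
                dwellings["season_of_declaration"],
                "season_of_declaration",
                SEASONS,
            )
        )
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=dwellings.index)
    X.index = dwellings.index
    return X


def subject_design(subjects: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Dummy-coded design matrix for the subject covariates."""
    if covariates is None:
        covariates = SUBJECT_COVARIATES
    blocks = []
    for name in covariates:
        if name not in subjects.columns:
            raise SchemaError(f"subject table lacks covariate column '{name}'")
        blocks.append(_encode_field(subjects[name], name, SUBJECT_LEVELS[name]))
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=subjects.index)
    X.index = subjects.index
    return X


def linear_predictor(X: pd.DataFrame, coeffs: dict, intercept: float = 0.0) -> np.ndarray:
    """`intercept + X @ coeffs` restricted to the columns named in ``coeffs``.

    Coefficient keys absent from ``X`` raise; design columns without a
    coefficient contribute zero (reference levels are implicit).
    """
    lp = np.full(len(X), float(intercept))
    for key, beta in coeffs.items():
        if key == "intercept":  # passed separately; ignore if present in the dict
            continue
        if key not in X.columns:
            raise SchemaError(f"coefficient '{key}' has no matching design column")
        lp += beta * X[key].to_numpy()
    return lp
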