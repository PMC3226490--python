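"""Synthetic birth-cohort generator.

Emulates the statistical structure the downstream analysis assumes: dwellings
drawn from published marginal determinant frequencies, a log-normal annual
indoor-formaldehyde (FA) level driven by the published linear-model
coefficients, seasonal 7-day measurements in a randomly selected subsample of
dwellings, residence changes during the first year, and a three-category
lower-respiratory-infection outcome (never LRI / non-wheezy LRI / wheezy LRI)
driven by published adjusted odds ratios.

Three named RNG streams (``dwellings``, ``measurements``, ``outcomes``) are
derived from the configured seed so that, e.g., changing the outcome model
never perturbs the simulated dwellings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SEASONS, SynthConfig
from .design import dwelling_design, linear_predictor, subject_design
from .errors import ConfigError

__all__ = [
    "rng_stream",
    "generate_dwellings",
    "generate_true_fa",
    "generate_seasonal_measurements",
    "generate_subjects",
    "generate_outcomes",
    "make_cohort",
    "CohortTruth",
]


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG stream derived from a base seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _draw_categorical(rng, levels, probs, n):
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)


def _freqs_for(config_freqs: dict, field: str, levels) -> np.ndarray:
    if field not in config_freqs:
        raise ConfigError(f"predictor_freqs missing entry for field '{field}'")
    freqs = config_freqs[field]
    missing = [lv for lv in levels if lv not in freqs]
    if missing:
        raise ConfigError(f"frequencies for field '{field}' missing levels {missing}")
    return np.array([freqs[lv] for lv in levels], dtype=float)


def generate_dwellings(
    n: int, config: SynthConfig, seed: int | None = None, id_offset: int = 0
) -> pd.DataFrame:
    """Draw ``n`` dwellings with independent predictors from the configured marginals."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = rng_stream(config.seed if seed is None else seed, "dwellings")
    from .config import DWELLING_LEVELS

    cols = {"dwelling_id": [f"D{int(i) + 1 + id_offset:05d}" for i in range(n)]}
    for field, levels in DWELLING_LEVELS.items():
        p = _freqs_for(config.predictor_freqs, field, levels)
        cols[field] = _draw_categorical(rng, levels, p, n)
    shape, scale = config.window_open_gamma
    cols["window_open_hours"] = np.round(rng.gamma(shape, scale, size=n), 2)
    df = pd.DataFrame(cols)
    return df


def generate_true_fa(
    dwellings: pd.DataFrame, config: SynthConfig, seed: int | None = None
) -> pd.Series:
    """True annual log-FA per dwelling: intercept + Σ coeffs + N(0, residual_sd)."""
    rng = rng_stream(config.seed if seed is None else seed, "true_fa")
    X = dwelling_design(dwellings, season_adjust=False)
    lp = linear_predictor(X, config.exposure_coeffs, config.exposure_intercept)
    noise = rng.normal(0.0, config.residual_sd, size=len(dwellings))
    return pd.Series(lp + noise, index=pd.Index(dwellings["dwelling_id"], name="dwelling_id"),
                     name="log_fa")


def generate_seasonal_measurements(
    true_fa: pd.Series,
    config: SynthConfig,
    seed: int | None = None,
    loq: float = 2.4,
) -> pd.DataFrame:
    """One 7-day measurement per season per dwelling, with seasonal offsets,
    multiplicative log-scale noise and per-season missingness."""
    offsets = config.seasonal_offsets
    if abs(sum(offsets.values())) > 1e-8:
        raise ConfigError("seasonal_offsets must sum to 0")
    rng = rng_stream(config.seed if seed is None else seed, "measurements")
    rows = []
    ids = np.asarray(true_fa.index)
    base = np.asarray(true_fa, dtype=float)
    for season in SEASONS:
        noise = rng.normal(0.0, config.measurement_noise_sd, size=len(ids))
        present = rng.random(len(ids)) >= config.missing_season_prob
        level = np.exp(base + offsets[season] + noise)
        rows.append(
            pd.DataFrame(
                {
                    "dwelling_id": ids[present],
                    "season": season,
                    "fa_level": np.round(level[present], 3),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["below_loq"] = (df["fa_level"] < loq).astype(int)
    df = df.sort_values(["dwelling_id", "season"], kind="mergesort").reset_index(drop=True)
    return df


def generate_subjects(config: SynthConfig, seed: int | None = None):
    """Draw subject covariates, residence histories and the measured subsample.

    Returns ``(subjects, dwellings)``: every subject has a primary dwelling;
    movers (probability ``move_prob``) acquire a second, freshly drawn dwelling
    with a uniform within-year split point.  The measured subsample consists of
    ``n_measured_dwellings`` subjects drawn uniformly without replacement; all
    dwellings they occupied are measured (missing completely at random by
    construction).
    """
    base_seed = config.seed if seed is None else seed
    rng = rng_stream(base_seed, "subjects")
    n = config.n_subjects
    from .config import SUBJECT_LEVELS

    cols = {"subject_id": [f"S{i + 1:05d}" for i in range(n)]}
    for field, levels in SUBJECT_LEVELS.items():
        p = _freqs_for(config.covariate_freqs, field, levels)
        cols[field] = _draw_categorical(rng, levels, p, n)
    subjects = pd.DataFrame(cols)

    dwellings = generate_dwellings(n, config, seed=base_seed)
    movers = rng.random(n) < config.move_prob
    n_movers = int(movers.sum())
    extra = generate_dwellings(
        max(n_movers, 1), config, seed=base_seed + 1, id_offset=n
    ).iloc[:n_movers]
    split = rng.uniform(0.05, 0.95, size=n_movers)

    history = []
    extra_ids = extra["dwelling_id"].to_numpy()
    j = 0
    for i in range(n):
        primary = dwellings["dwelling_id"].iat[i]
        if movers[i]:
            frac = round(float(split[j]), 4)
            history.append([(primary, frac), (extra_ids[j], round(1.0 - frac, 4))])
            j += 1
        else:
            history.append([(primary, 1.0)])
    subjects["residence_history"] = history

    measured_idx = rng.choice(n, size=config.n_measured_dwellings, replace=False)
    measured = np.zeros(n, dtype=int)
    measured[measured_idx] = 1
    subjects["measured"] = measured

    all_dwellings = pd.concat([dwellings, extra], ignore_index=True)
    return subjects, all_dwellings


def generate_outcomes(
    subjects: pd.DataFrame,
    exposure_per_subject: pd.Series,
    config: SynthConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill the three-level outcome from a multinomial logit on covariates + FA.

    ``exposure_per_subject`` is the annual FA level in µg/m³ indexed by
    subject_id; the never-LRI stratum is the reference with linear predictor 0.
    """
    rng = rng_stream(config.seed if seed is None else seed, "outcomes")
    exposure = exposure_per_subject.reindex(subjects["subject_id"])
    if exposure.isna().any():
        missing = exposure.index[exposure.isna()].tolist()[:5]
        raise ConfigError(f"exposure missing for subjects {missing}")
    Z = subject_design(subjects)
    etas = [np.zeros(len(subjects))]
    for stratum in ("non_wLRI", "wLRI"):
        coeffs = config.outcome_logits[stratum]
        eta = linear_predictor(Z, coeffs, coeffs.get("intercept", 0.0))
        eta = eta + config.fa_effect_per_unit[stratum] * exposure.to_numpy()
        etas.append(eta)
    eta = np.column_stack(etas)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(subjects))
    cum = np.cumsum(p, axis=1)
    draw = (u[:, None] > cum).sum(axis=1)
    out = subjects.copy()
    out["outcome"] = np.array(["never_LRI", "non_wLRI", "wLRI"], dtype=object)[draw]
    return out


@dataclass
class CohortTruth:
    """Hidden generating quantities kept out of the written tables (for tests)."""

    true_log_fa: pd.Series  # per dwelling
    true_exposure: pd.Series  # per subject, µg/m³ (time-weighted over residences)


def make_cohort(config: SynthConfig, seed: int | None = None):
    """Generate a full synthetic cohort.

    Returns ``(dwellings, measurements, subjects, truth)`` where measurements
    cover only dwellings occupied by the measured subsample.
    """
    base_seed = config.seed if seed is None else seed
    subjects, dwellings = generate_subjects(config, seed=base_seed)
    true_fa = generate_true_fa(dwellings, config, seed=base_seed)

    # time-weighted true exposure per subject, on the level scale
    level = np.exp(true_fa)
    expo = np.zeros(len(subjects))
    for i, hist in enumerate(subjects["residence_history"]):
        expo[i] = sum(frac * level.loc[d] for d, frac in hist)
    true_exposure = pd.Series(expo, index=pd.Index(subjects["subject_id"]), name="true_fa_level")

    measured_dwellings: list[str] = []
    for hist, flag in zip(subjects["residence_history"], subjects["measured"]):
        if flag:
            measured_dwellings.extend(d for d, _ in hist)
    measurements = generate_seasonal_measurements(
        true_fa.loc[measured_dwellings], config, seed=base_seed
    )

    subjects = generate_outcomes(subjects, true_exposure, config, seed=base_seed)
    cols = ["subject_id", "outcome"] + [
        c for c in subjects.columns if c not in ("subject_id", "outcome")
    ]
    return dwellings, measurements, subjects[cols], CohortTruth(true_fa, true_exposure)
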