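"""Model-discrimination and calibration diagnostics.

These primitives back the exposure-model evaluation: the Mann–Whitney form of
the ROC area, 2×2 confusion-matrix rates with "high FA" as the positive class,
and the Hosmer–Lemeshow goodness-of-fit test over deciles of fitted risk.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .errors import FacohortError

logger = logging.getLogger(__name__)

__all__ = ["auc", "classification_diagnostics", "hosmer_lemeshow"]


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann–Whitney form.

    Equals the probability that a randomly chosen positive outranks a randomly
    chosen negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise FacohortError("AUC undefined: one outcome class is absent")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_diagnostics(predicted, observed, positive="high") -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy from the 2×2 table.

    Rates whose denominator is empty (a class absent from the observed or
    predicted labels) are reported as NaN rather than raising.
    """
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    p = predicted == positive
    o = observed == positive
    tp = int((p & o).sum())
    tn = int((~p & ~o).sum())
    fp = int((p & ~o).sum())
    fn = int((~p & o).sum())

    def _rate(num, den):
        return num / den if den > 0 else math.nan

    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "ppv": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
        "accuracy": _rate(tp + tn, tp + tn + fp + fn),
    }


def hosmer_lemeshow(fitted_probs, outcomes, n_groups: int = 10):
    """Hosmer–Lemeshow χ² test over groups of fitted risk.

    Observations are grouped by quantiles of the fitted probability (ties stay
    in one group); the statistic is Σ (O−E)² / (E(1−E/n_g)) with ``g − 2``
    degrees of freedom.  Groups with zero expected count in either cell are
    merged with their neighbour (logged).
    """
    p = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("fitted_probs and outcomes must have the same length")
    if len(p) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} observations")
    if np.ptp(p) == 0:
        raise FacohortError("Hosmer–Lemeshow undefined: all fitted probabilities equal")

    # quantile bin edges on the fitted risk; duplicates collapse tied groups
    qs = np.quantile(p, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(qs[1:-1])
    group = np.searchsorted(edges, p, side="right")

    stat = 0.0
    g_used = 0
    pending_n = pending_o = pending_e = 0.0
    for g in range(int(group.max()) + 1):
        mask = group == g
        n_g = pending_n + mask.sum()
        if n_g == 0:
            continue
        obs = pending_o + y[mask].sum()
        exp = pending_e + p[mask].sum()
        # defer degenerate groups (all-0 or all-1 expectation) into the next one
        if exp <= 0 or exp >= n_g:
            logger.info("Hosmer–Lemeshow: merging degenerate risk group %d", g)
            pending_n, pending_o, pending_e = n_g, obs, exp
            continue
        pending_n = pending_o = pending_e = 0.0
        var = exp * (1.0 - exp / n_g)
        stat += (obs - exp) ** 2 / var
        g_used += 1
    if pending_n > 0 and g_used > 0:
        logger.info("Hosmer–Lemeshow: trailing degenerate group merged backwards")
        # fold leftover into the statistic against its own expectation if possible
        if 0 < pending_e < pending_n:
            stat += (pending_o - pending_e) ** 2 / (pending_e * (1 - pending_e / pending_n))
            g_used += 1
    df = max(g_used - 2, 1)
    p_value = float(stats.chi2.sf(stat, df))
    return float(stat), p_value
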