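"""Diagnostic and prognostic evaluation of per-sample scores.

Diagnostic: ROC/AUC over the full threshold sweep (AUC equals the
normalized Mann-Whitney U with ties counted 1/2), Youden-index cutoff,
Welch two-group t-test. Prognostic: Kaplan-Meier curves for high/low score
groups, two-group log-rank test, and a fixed-horizon ROC in which the
positive class is graft loss before the horizon and samples censored
before the horizon are excluded (exclusion counted and reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """ROC sweep with the Youden operating point.

    Thresholds classify by the ``score >= cutoff`` convention; sensitivity
    and specificity are parallel to ``thresholds``.
    """

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0

    @property
    def youden_j(self) -> float:
        return self.sens_at_cutoff + self.spec_at_cutoff - 1.0

    def to_dict(self) -> dict:
        return {
            "auc": float(self.auc),
            "youden_cutoff": float(self.youden_cutoff),
            "sensitivity_at_cutoff": float(self.sens_at_cutoff),
            "specificity_at_cutoff": float(self.spec_at_cutoff),
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
            "n_excluded": int(self.n_excluded),
        }


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass
class SurvivalReport:
    """KM curves per score group plus log-rank and fixed-horizon ROC."""

    km_curves: dict[str, KMCurve]
    logrank_chi2: float
    logrank_p: float
    grouping_rule: str
    horizon_roc: RocResult | None = None

    def to_dict(self) -> dict:
        payload = {
            "logrank_chi2": float(self.logrank_chi2),
            "logrank_p": float(self.logrank_p),
            "grouping_rule": self.grouping_rule,
            "groups": {name: {"times": curve.times.tolist(),
                              "survival": curve.survival.tolist(),
                              "n_at_risk": curve.n_at_risk.tolist()}
                       for name, curve in self.km_curves.items()},
        }
        if self.horizon_roc is not None:
            payload["horizon_roc"] = self.horizon_roc.to_dict()
        return payload


def roc_auc(scores, binary_labels) -> RocResult:
    """ROC over all score thresholds; AUC as normalized pairwise wins."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be non-empty for ROC")
    if np.ptp(scores) == 0:
        logger.warning("constant scores: AUC degenerates to 0.5")
        thr = np.array([np.inf, scores[0]])
        return RocResult(0.5, thr, np.array([0.0, 1.0]), np.array([1.0, 0.0]),
                         youden_cutoff=float(scores[0]), sens_at_cutoff=1.0,
                         spec_at_cutoff=0.0, n_pos=n_pos, n_neg=n_neg)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    sens, spec = tpr, 1.0 - fpr
    j = sens - fpr
    best = np.flatnonzero(j == j.max())
    # ties toward higher specificity = smaller fpr = earlier sweep position
    pick = best[np.argmin(fpr[best])]
    cutoff = thresholds[pick]
    if np.isinf(cutoff):
        cutoff = float(scores.max()) + 1.0
    return RocResult(auc=auc, thresholds=thresholds, sensitivity=sens,
                     specificity=spec, youden_cutoff=float(cutoff),
                     sens_at_cutoff=float(sens[pick]),
                     spec_at_cutoff=float(spec[pick]),
                     n_pos=n_pos, n_neg=n_neg)


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """The cutoff maximizing sensitivity + specificity - 1."""
    return roc.youden_cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff


def compare_groups(scores, two_group_labels) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test between score groups."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(two_group_labels)
    groups = sorted(pd.unique(labels), key=str)
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {list(groups)}")
    a = scores[labels == groups[0]]
    b = scores[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t_stat, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t_stat), float(p)


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator; censored-only times shrink the
    risk set without a downward step."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("empty survival input")
    if (times < 0).any():
        raise ValidationError("negative survival times")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("events must be 0/1")
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table
    grid = np.concatenate(([0.0], table.index.to_numpy(dtype=float)))
    grid = np.unique(grid)
    survival = fitter.survival_function_at_times(grid).to_numpy(dtype=float)
    at_risk = np.array([table.loc[t, "at_risk"] if t in table.index else len(times)
                        for t in grid], dtype=int)
    return KMCurve(times=grid, survival=survival, n_at_risk=at_risk)


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank statistic (1 df chi-square)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(group_labels)
    groups = sorted(pd.unique(labels), key=str)
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, got {list(groups)}")
    if events.sum() == 0:
        raise ValidationError("log-rank undefined with no events")
    mask = labels == groups[0]
    res = _lifelines_logrank(times[mask], times[~mask],
                             event_observed_A=events[mask],
                             event_observed_B=events[~mask])
    return float(res.test_statistic), float(res.p_value)


def fixed_horizon_roc(scores, times, events, horizon: float) -> RocResult:
    """ROC for the binary outcome "graft loss before the horizon".

    Positives: event with time <= horizon. Negatives: followed beyond the
    horizon (time > horizon). Samples censored at or before the horizon
    are excluded and counted in ``n_excluded``.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    positive = (events == 1) & (times <= horizon)
    negative = times > horizon
    excluded = ~(positive | negative)
    n_excluded = int(excluded.sum())
    if n_excluded:
        logger.warning("fixed-horizon ROC: excluding %d sample(s) censored "
                       "before the %.0f-day horizon", n_excluded, horizon)
    usable = positive | negative
    if positive.sum() == 0 or negative.sum() == 0:
        raise ValidationError(
            f"no usable {'positives' if positive.sum() == 0 else 'negatives'} "
            f"at horizon {horizon} ({n_excluded} excluded)"
        )
    roc = roc_auc(scores[usable], positive[usable].astype(int))
    roc.n_excluded = n_excluded
    return roc


def split_by_score(scores: pd.Series, rule: str = "median") -> pd.Series:
    """Dichotomize scores into 'high'/'low' groups.

    ``rule`` is 'median', a quantile like 'q0.75', or a float cutoff
    rendered as 'cutoff:<value>'; ties classify as high (>= cutoff).
    """
    scores = pd.Series(scores, dtype=float)
    if rule == "median":
        cut = float(scores.median())
    elif rule.startswith("q"):
        cut = float(scores.quantile(float(rule[1:])))
    elif rule.startswith("cutoff:"):
        cut = float(rule.split(":", 1)[1])
    else:
        raise ValidationError(f"unknown split rule {rule!r}")
    groups = pd.Series(np.where(scores >= cut, "high", "low"), index=scores.index)
    if groups.nunique() < 2:
        raise ValidationError(f"split rule {rule!r} leaves a single group")
    return groups


def survival_report(
    scores: pd.Series,
    times,
    events,
    horizon: float | None = None,
    split: str = "median",
) -> SurvivalReport:
    """High/low-score KM curves, log-rank test, optional horizon ROC."""
    scores = pd.Series(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = split_by_score(scores, split)
    curves = {name: km_curve(times[(groups == name).to_numpy()],
                             events[(groups == name).to_numpy()])
              for name in ("high", "low")}
    chi2, p = logrank_test(times, events, groups.to_numpy())
    horizon_roc = None
    if horizon is not None:
        horizon_roc = fixed_horizon_roc(scores.to_numpy(), times, events, horizon)
    return SurvivalReport(km_curves=curves, logrank_chi2=chi2, logrank_p=p,
                          grouping_rule=split, horizon_roc=horizon_roc)
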