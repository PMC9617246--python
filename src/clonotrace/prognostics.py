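"""Survival biomarker evaluation: ROC/AUC, Youden cutoff, Kaplan-Meier,
and the log-rank test.

All estimators are implemented directly (not delegated) so their tie and
censoring conventions are explicit:

* ROC dichotomizes the outcome at a horizon — death within the horizon is
  the positive class; patients censored before the horizon are excluded.
  AUC uses the Mann-Whitney convention (ties count 1/2).
* Kaplan-Meier is the product-limit estimator; censored patients leave the
  risk set after their censoring time.
* The log-rank statistic sums observed-minus-expected deaths under the
  hypergeometric model at each distinct event time; p from chi-square df=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2


class SurvivalInputError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float           # follow-up, days
    event: bool           # True = death observed
    marker: float         # baseline biomarker value

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("time must be positive")
        if not math.isfinite(self.marker):
            raise ValueError("marker must be finite")


def read_survival_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    required = {"id", "time_days", "event", "marker"}
    missing = required - set(df.columns)
    if missing:
        raise SurvivalInputError(f"survival CSV missing columns: {sorted(missing)}")
    return [
        SurvivalRecord(str(r.id), float(r.time_days), bool(r.event), float(r.marker))
        for r in df.itertuples()
    ]


@dataclass
class RocCurve:
    thresholds: np.ndarray     # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


def dichotomize_at_horizon(records: Sequence[SurvivalRecord],
                           horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """(labels, markers) with death-within-horizon positive; early-censored excluded."""
    labels, markers = [], []
    for rec in records:
        if rec.event and rec.time <= horizon:
            labels.append(1)
        elif rec.time >= horizon:
            labels.append(0)
        else:
            continue  # censored before horizon: outcome unknown
        markers.append(rec.marker)
    return np.asarray(labels), np.asarray(markers, dtype=float)


def roc_auc(records: Sequence[SurvivalRecord], horizon: float) -> RocCurve:
    """Empirical ROC of the marker for death within ``horizon``."""
    labels, markers = dichotomize_at_horizon(records, horizon)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SurvivalInputError("need both outcome classes within the horizon")

    thresholds = np.unique(markers)[::-1]
    sens = np.empty(len(thresholds) + 2)
    spec = np.empty(len(thresholds) + 2)
    # calls positive when marker >= threshold; pad with all-neg / all-pos ends
    sens[0], spec[0] = 0.0, 1.0
    for k, thr in enumerate(thresholds, start=1):
        called = markers >= thr
        sens[k] = (called & (labels == 1)).sum() / n_pos
        spec[k] = (~called & (labels == 0)).sum() / n_neg
    sens[-1], spec[-1] = 1.0, 0.0

    # Mann-Whitney AUC with half-credit ties
    pos = markers[labels == 1]
    neg = markers[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (n_pos * n_neg)

    pad = np.concatenate([[np.inf], thresholds, [-np.inf]])
    return RocCurve(thresholds=pad, sensitivity=sens, specificity=spec,
                    auc=float(auc), n_pos=n_pos, n_neg=n_neg)


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the higher threshold (fewer positive calls).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    finite = np.isfinite(curve.thresholds)
    j_f, thr_f = j[finite], curve.thresholds[finite]
    sens_f, spec_f = curve.sensitivity[finite], curve.specificity[finite]
    best_j = j_f.max()
    ties = np.flatnonzero(np.isclose(j_f, best_j))
    pick = ties[np.argmax(thr_f[ties])]
    return CutoffResult(threshold=float(thr_f[pick]), youden_j=float(j_f[pick]),
                        sensitivity=float(sens_f[pick]), specificity=float(spec_f[pick]))


@dataclass
class KaplanMeierCurve:
    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray
    deaths: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Product-limit survival estimate with at-risk bookkeeping."""
    if not records:
        raise SurvivalInputError("need at least one record")
    times = np.asarray([r.time for r in records])
    events = np.asarray([r.event for r in records])
    event_times = np.unique(times[events])
    surv, risk, died = [], [], []
    s = 1.0
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risk.append(n_at_risk)
        died.append(d)
    return KaplanMeierCurve(times=event_times, survival=np.asarray(surv),
                            at_risk=np.asarray(risk, dtype=int),
                            deaths=np.asarray(died, dtype=int))


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    df: int = 1


def logrank_test(records_a: Sequence[SurvivalRecord],
                 records_b: Sequence[SurvivalRecord]) -> LogRankResult:
    """Two-sample log-rank test (chi-square, df=1)."""
    if not records_a or not records_b:
        raise SurvivalInputError("both groups must be non-empty")
    times_a = np.asarray([r.time for r in records_a])
    events_a = np.asarray([r.event for r in records_a])
    times_b = np.asarray([r.time for r in records_b])
    events_b = np.asarray([r.event for r in records_b])

    all_event_times = np.unique(np.concatenate([times_a[events_a], times_b[events_b]]))
    if all_event_times.size == 0:
        raise SurvivalInputError("no events in either group; log-rank undefined")

    o_minus_e = 0.0
    var_sum = 0.0
    for t in all_event_times:
        n_a = int((times_a >= t).sum())
        n_b = int((times_b >= t).sum())
        n = n_a + n_b
        d_a = int(((times_a == t) & events_a).sum())
        d_b = int(((times_b == t) & events_b).sum())
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        if n > 1:
            var_sum += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var_sum == 0:
        # all deaths occur when one group exhausts the risk set; no information
        return LogRankResult(statistic=0.0, p_value=1.0)
    stat = o_minus_e ** 2 / var_sum
    return LogRankResult(statistic=float(stat), p_value=float(chi2.sf(stat, df=1)))


def evaluate_marker(records: Sequence[SurvivalRecord], horizon: float) -> dict:
    """Full biomarker workup: ROC, Youden cutoff, stratified KM + log-rank."""
    curve = roc_auc(records, horizon)
    cutoff = youden_cutoff(curve)
    high = [r for r in records if r.marker >= cutoff.threshold]
    low = [r for r in records if r.marker < cutoff.threshold]
    result = {
        "auc": curve.auc,
        "positive_class": "death_within_horizon",
        "cutoff": cutoff.threshold,
        "youden_j": cutoff.youden_j,
        "n_high": len(high),
        "n_low": len(low),
    }
    if high and low:
        try:
            lr = logrank_test(high, low)
            result["logrank_statistic"] = lr.statistic
            result["logrank_p"] = lr.p_value
        except SurvivalInputError:
            result["logrank_p"] = None
    return result
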