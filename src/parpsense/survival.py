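"""Progression-free-survival analysis: Kaplan-Meier curves, log-rank
comparison, and the 120-day clinical-benefit dichotomization.

Estimation is delegated to lifelines; this module wraps it in the small
surface the rest of the package needs and adds the benefit threshold used
to validate sensitivity predictions: a patient is considered to have
benefited from a PARP inhibitor when their PFS strictly exceeds 120 days
(the longest PFS observed among benign-variant carriers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .classifier import ClassificationResult
from .models import Cohort

__all__ = [
    "BENEFIT_DAYS",
    "SurvivalCurve",
    "LogRankResult",
    "km_fit",
    "logrank_test",
    "benefit_flag",
    "concordance_report",
]

#: PFS threshold (days) separating clinical benefit from non-benefit.
BENEFIT_DAYS = 120


@dataclass
class SurvivalCurve:
    """A product-limit survival estimate.

    ``event_times`` are the distinct observed event times; ``survival_prob``
    the step values S(t) at those times; ``at_risk`` the number at risk
    just before each event time.  ``median`` is the smallest event time
    with S(t) <= 0.5, or None when the curve never falls that far.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    median: Optional[float]
    n: int

    def survival_at(self, t: float) -> float:
        """S(t), the probability of remaining progression-free past t."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    groups: list[dict]


def km_fit(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Events and censorings tied at the same day follow the standard
    convention: events count first, censored subjects remain at risk
    through that day's events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_fit requires at least one subject")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 1):
        raise ValueError("times must be >= 1 day")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_table = kmf.event_table
    steps = event_table[event_table["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival_prob = sf.loc[steps.index].to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=int)
    median = kmf.median_survival_time_
    return SurvivalCurve(
        event_times=event_times,
        survival_prob=survival_prob,
        at_risk=at_risk,
        censor_times=np.sort(times[~events]),
        median=None if np.isinf(median) else float(median),
        n=int(times.size),
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> LogRankResult:
    """Two-sample Mantel-Cox log-rank test (chi-squared, df = 1)."""
    (ta, ea), (tb, eb) = group_a, group_b
    ta, tb = np.asarray(ta, dtype=float), np.asarray(tb, dtype=float)
    ea, eb = np.asarray(ea, dtype=bool), np.asarray(eb, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        groups=[
            {"label": "A", "n": int(ta.size), "events": int(ea.sum())},
            {"label": "B", "n": int(tb.size), "events": int(eb.sum())},
        ],
    )


def benefit_flag(pfs_days: int, benefit_days: int = BENEFIT_DAYS) -> bool:
    """True when the patient derived clinical benefit: PFS strictly over
    the threshold (a PFS of exactly 120 days is no benefit)."""
    if pfs_days < 1:
        raise ValueError(f"pfs_days must be >= 1, got {pfs_days!r}")
    return pfs_days > benefit_days


def concordance_report(
    cohort: Cohort,
    predictions: dict[str, ClassificationResult],
    benefit_days: int = BENEFIT_DAYS,
) -> pd.DataFrame:
    """Cross-tabulate predicted label against the clinical-benefit flag.

    Returns one row per patient with the final label, PFS, benefit flag
    and a concordance verdict: an S prediction is concordant with
    benefit, an R prediction with no benefit, and U is always recorded as
    'uncertain'.
    """
    rows = []
    for case in cohort:
        if case.patient_id not in predictions:
            raise KeyError(f"no prediction for patient {case.patient_id!r}")
        label = predictions[case.patient_id].final_label
        benefit = benefit_flag(case.pfs_days, benefit_days)
        if label == "U":
            verdict = "uncertain"
        else:
            verdict = "concordant" if (label == "S") == benefit else "discordant"
        rows.append(
            {
                "patient_id": case.patient_id,
                "final_label": label,
                "pfs_days": case.pfs_days,
                "pfs_event": case.pfs_event,
                "benefit": benefit,
                "concordance": verdict,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "final_label", "pfs_days", "pfs_event", "benefit", "concordance"],
    )
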