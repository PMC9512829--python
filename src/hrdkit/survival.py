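"""Outcome analysis by biomarker stratum: Kaplan-Meier, log-rank, Cox, RR.

Thin, validated wrappers around lifelines.  Kaplan-Meier medians that are
never reached are reported as not estimable (None), mirroring the "NE"
convention of clinical tables.  Cox fits use Efron tie handling (event
times at month resolution tie often) and emit a warning when the events-
per-term ratio drops below 10.  Response rate is the proportion of complete
or partial responders among evaluable patients, with an exact binomial CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance_stats import clopper_pearson

__all__ = [
    "KMResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "response_rate",
]


@dataclass
class KMResult:
    survival: pd.DataFrame  # index: time, column: survival probability
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        s = self.survival[self.survival.index <= t]
        return 1.0 if s.empty else float(s.iloc[-1, 0])


def km_estimate(
    times, events, conf_level: float = 0.95, label: str = "KM"
) -> KMResult:
    """Product-limit estimator with log-log CIs and the survival median.

    The median is the earliest time with S(t) <= 0.5 and is None (not
    estimable) when the curve never reaches 0.5.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter(alpha=1 - conf_level, label=label)
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    to_opt = lambda x: None if np.isinf(x) else x
    return KMResult(
        survival=kmf.survival_function_,
        median=to_opt(median),
        median_ci=(to_opt(lo), to_opt(hi)),
        n=len(times),
        n_events=int(events.sum()),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    from lifelines.statistics import logrank_test as _lr

    res = _lr(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    outcomes: pd.DataFrame,
    terms: list[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties); one row per model term.

    Categorical terms are one-hot encoded against their first level.
    Returns columns hr, ci_lower, ci_upper, p, coef, se.  Raises on
    non-convergence or detected separation.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = outcomes[[duration_col, event_col] + terms].copy()
    if df[duration_col].min() <= 0:
        raise ValueError("durations must be positive")
    n_events = int(df[event_col].sum())
    df = pd.get_dummies(df, columns=[t for t in terms if df[t].dtype == object],
                        drop_first=True, dtype=float)
    n_terms = df.shape[1] - 2
    if n_events < 10 * n_terms:
        warnings.warn(
            f"only {n_events} events for {n_terms} model terms (< 10 per "
            "term); hazard-ratio estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter(alpha=1 - conf_level)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, RuntimeWarning, Warning) as exc:
        msg = str(exc)
        kind = "separation detected" if "complete separation" in msg.lower() else "fit failed"
        raise ValueError(f"Cox model {kind}: {msg}") from None
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_lower": summary[f"exp(coef) lower {conf_level * 100:g}%"],
            "ci_upper": summary[f"exp(coef) upper {conf_level * 100:g}%"],
            "p": summary["p"],
            "coef": summary["coef"],
            "se": summary["se(coef)"],
        }
    )
    out.index.name = "term"
    return out


def response_rate(
    responses, conf_level: float = 0.95
) -> tuple[float, tuple[float, float], int]:
    """Proportion of complete/partial responders among evaluable patients.

    ``not_evaluable`` entries are excluded from the denominator.  Returns
    (proportion, exact CI, n evaluable).
    """
    responses = list(responses)
    evaluable = [r for r in responses if r != "not_evaluable"]
    if not evaluable:
        raise ValueError("no evaluable patients")
    x = sum(r in ("complete", "partial") for r in evaluable)
    n = len(evaluable)
    return x / n, clopper_pearson(x, n, conf_level), n
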