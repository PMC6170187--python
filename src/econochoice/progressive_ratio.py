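"""Progressive-ratio (PR5) schedule math and breakpoint analysis.

Under the PR5 schedule the press requirement per pellet follows the printed
sequence 1, 5, 10, 15, 20, ... with each requirement held for three trials.
A session ends at the 30-minute cap or after 5 minutes without a press; the
breakpoint is the number of trials (pellets) completed before termination.
Inter-press-interval (IPI) distributions index motor vigor independently of
the breakpoint and are compared between fiber conditions with a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .errors import InputError
from .inactivation_stats import AnovaTable, rm_anova
from .session_io import PREventLog

__all__ = [
    "pr_requirement",
    "cumulative_requirement",
    "breakpoint",
    "total_presses",
    "ipi_distribution",
    "ipi_histogram",
    "ks_two_sample",
    "consumption_summary",
]

SESSION_CAP = 1800.0  # 30 min
IDLE_CAP = 300.0  # 5 min without a press ends the session


def pr_requirement(trial_index: int) -> int:
    """Presses required for the given 1-based trial under PR5.

    The requirement sequence (1, 5, 10, 15, 20, ...) advances every three
    trials: trials 1-3 need 1 press, 4-6 need 5, 7-9 need 10, and so on.
    """
    if trial_index < 1:
        raise InputError("trial_index is 1-based")
    step = (trial_index - 1) // 3  # 0 for trials 1-3, 1 for 4-6, ...
    return 1 if step == 0 else 5 * step


def cumulative_requirement(n_trials: int) -> int:
    """Total presses needed to complete the first ``n_trials`` trials."""
    return sum(pr_requirement(i) for i in range(1, n_trials + 1))


def breakpoint(
    log: PREventLog,
    session_cap: float = SESSION_CAP,
    idle_cap: float = IDLE_CAP,
) -> int:
    """Trials completed (pellets earned) before the session terminated.

    Termination is whichever comes first: the session cap, or the end of an
    idle period of ``idle_cap`` without a press (measured from the previous
    press, or from session start if there was none).  Presses stamped after
    the termination time are ignored with a warning.
    """
    presses = np.asarray(log.press_times, dtype=float)
    # find termination time
    t_end = min(session_cap, log.session_length if log.session_length > 0 else session_cap)
    last = 0.0
    for t in presses:
        if t - last > idle_cap:
            break
        last = t
    t_idle = last + idle_cap
    t_term = min(t_end, t_idle)
    usable = presses[presses <= t_term]
    if usable.size < presses.size:
        warnings.warn(
            f"{presses.size - usable.size} press(es) after termination "
            f"time {t_term:.1f}s ignored",
            stacklevel=2,
        )
    n_presses = int(usable.size)
    completed = 0
    needed = 0
    while True:
        needed += pr_requirement(completed + 1)
        if needed > n_presses:
            return completed
        completed += 1


def total_presses(
    log: PREventLog,
    session_cap: float = SESSION_CAP,
    idle_cap: float = IDLE_CAP,
) -> int:
    presses = np.asarray(log.press_times, dtype=float)
    return int((presses <= min(session_cap, log.session_length or session_cap)).sum())


def ipi_distribution(logs: PREventLog | Iterable[PREventLog]) -> np.ndarray:
    """Pooled inter-press intervals (successive press-time differences)."""
    if isinstance(logs, PREventLog):
        logs = [logs]
    ipis = [np.diff(log.press_times) for log in logs if log.press_times.size >= 2]
    if not ipis:
        return np.array([])
    return np.concatenate(ipis)


def ipi_histogram(
    ipis: np.ndarray, bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray, ECDF]:
    """Histogram (fixed-width bins from 0) and ECDF of inter-press intervals."""
    ipis = np.asarray(ipis, dtype=float)
    if ipis.size == 0:
        return np.array([0.0]), np.array([], dtype=int), ECDF(np.array([np.nan]))
    n_bins = int(np.ceil(ipis.max() / bin_width)) or 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(ipis, bins=edges)
    return edges, counts, ECDF(ipis)


def ks_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "asymp",
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b| and p.

    The asymptotic Kolmogorov p-value is the default; ``method='exact'`` is
    available for small samples (recommended below ~30 per group), and
    ``'auto'`` picks for you.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def consumption_summary(
    table: pd.DataFrame,
    response: str = "grams",
) -> tuple[dict[str, float], AnovaTable]:
    """Condition means and the 1-factor RM ANOVA for the consumption test.

    ``table`` is long-form with columns ``rat``, ``run``, ``fiber`` and the
    response; rat and run enter as blocking factors (4 rats x 2 runs x 2
    fiber states gives the canonical denominator df of 10).
    """
    means = table.groupby("fiber", observed=True)[response].mean().to_dict()
    anova = rm_anova(
        table, response=response, factors=["fiber"], blocks=["rat", "run"]
    )
    return {k: float(v) for k, v in means.items()}, anova
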