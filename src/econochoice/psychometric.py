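"""Per-session probit choice model, indifference points, and choice curves.

The choice model assumes a linear indifference curve, so behavior depends on
the offers only through the log ratio of the offered quantities.  For a trial
offering ``qty_x`` of flavor x against ``qty_y`` of flavor y the probability
of choosing x is

    P(choose x) = Phi((ln(qty_x / qty_y) - mu) / sigma)

with Phi the standard normal CDF.  The maximum-likelihood ``mu_hat`` estimates
the log indifference point (IP = exp(mu_hat), the offer ratio at which the
animal is indifferent) and ``sigma_hat`` the inverse slope of the psychometric
curve (larger sigma = noisier valuation).  Each session x laser state is fit
independently; forced offers (a zero on one side) have no defined log ratio
and are excluded from fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import InputError
from .session_io import Offer, Session, TrialRecord

__all__ = [
    "ProbitFit",
    "RelativeChoiceCurve",
    "fit_probit",
    "fit_probit_counts",
    "probit_nll",
    "apply_exclusion",
    "default_bin_edges",
    "choice_curve_relative",
    "pooled_curve_fit",
    "shift_to_unity_prediction",
    "rt_by_relative_offer",
    "early_subset",
]

#: Below this fitted sigma the data are treated as separable (non-converged).
SEPARATION_SIGMA = 1e-3


@dataclass(frozen=True)
class ProbitFit:
    """Fitted probit parameters for one session x laser state."""

    mu_hat: float
    sigma_hat: float
    n_trials_used: int
    converged: bool
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def ip(self) -> float:
        """Indifference point on the ratio scale, exp(mu_hat)."""
        return math.exp(self.mu_hat)

    def oriented(self) -> "ProbitFit":
        """Mirror the fit so the IP is expressed as non-preferred:preferred (>= 1)."""
        if self.mu_hat >= 0:
            return self
        return replace(self, mu_hat=-self.mu_hat)


def probit_nll(
    mu: float | np.ndarray,
    sigma: float | np.ndarray,
    x: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
) -> np.ndarray:
    """Negative binomial log-likelihood of the probit choice model.

    ``x`` are distinct log offer ratios, ``n`` trial counts and ``k`` counts of
    x-choices per ratio.  ``mu``/``sigma`` broadcast against each other, so a
    parameter grid can be evaluated in one call.
    """
    mu = np.asarray(mu, dtype=float)[..., None]
    sigma = np.asarray(sigma, dtype=float)[..., None]
    z = (x - mu) / sigma
    ll = k * special.log_ndtr(z) + (n - k) * special.log_ndtr(-z)
    return -np.sum(ll, axis=-1)


def _irls_probit(x: np.ndarray, n: np.ndarray, k: np.ndarray, max_iter: int = 50):
    """Fisher-scoring fit of Phi(a + b*x) to binomial counts.

    Returns (a, b, ok).  ``ok`` is False when scoring failed to converge or
    produced a non-finite step; callers then fall back to direct optimization.
    """
    a, b = 0.0, 1.0
    X = np.column_stack([np.ones_like(x), x])
    eps = 1e-10
    for _ in range(max_iter):
        eta = a + b * x
        p = np.clip(special.ndtr(eta), eps, 1 - eps)
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        z = eta + (k / n - p) / np.maximum(phi, eps)
        try:
            beta, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)
        except np.linalg.LinAlgError:
            return a, b, False
        if not np.all(np.isfinite(beta)):
            return a, b, False
        step = abs(beta[0] - a) + abs(beta[1] - b)
        a, b = float(beta[0]), float(beta[1])
        if step < 1e-10:
            return a, b, True
        if abs(a) > 1e4 or abs(b) > 1e4:  # diverging towards separation
            return a, b, True
    return a, b, False


def fit_probit_counts(
    x: np.ndarray, n: np.ndarray, k: np.ndarray
) -> ProbitFit:
    """Fit the probit choice model to offer-aggregated counts."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    total = int(n.sum())
    if total == 0:
        raise InputError("zero usable trials")
    if np.unique(x).size < 2:
        return ProbitFit(0.0, float("nan"), total, converged=False,
                         exclusion_reason="fewer than 2 distinct offers")
    if k.sum() == 0 or k.sum() == n.sum():
        return ProbitFit(0.0, float("nan"), total, converged=False,
                         exclusion_reason="all choices identical")

    a, b, ok = _irls_probit(x, n, k)
    if not ok:
        def nll_ab(beta):
            z = beta[0] + beta[1] * x
            return -np.sum(k * special.log_ndtr(z) + (n - k) * special.log_ndtr(-z))

        res = optimize.minimize(nll_ab, np.array([a, b]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        a, b = float(res.x[0]), float(res.x[1])
        ok = bool(res.success)
    if b <= 0:
        return ProbitFit(0.0, float("nan"), total, converged=False,
                         exclusion_reason="non-increasing choice curve")
    mu, sigma = -a / b, 1.0 / b
    if sigma < SEPARATION_SIGMA:
        return ProbitFit(mu, sigma, total, converged=False,
                         exclusion_reason="separable data")
    return ProbitFit(mu, sigma, total, converged=ok)


def _aggregate(trials: Iterable[TrialRecord]):
    counts: dict[float, list[int]] = {}
    for t in trials:
        r = t.offer.log_ratio
        cell = counts.setdefault(r, [0, 0])
        cell[0] += 1
        cell[1] += t.choice == "x"
    xs = np.array(sorted(counts))
    n = np.array([counts[r][0] for r in xs], dtype=float)
    k = np.array([counts[r][1] for r in xs], dtype=float)
    return xs, n, k


def _usable(trials: Iterable[TrialRecord], laser_filter: str) -> list[TrialRecord]:
    if laser_filter not in ("on", "off", "all"):
        raise ValueError(f"laser_filter must be on/off/all, got {laser_filter!r}")
    out = []
    for t in trials:
        if t.offer.forced:
            continue
        if laser_filter == "on" and not t.laser_on:
            continue
        if laser_filter == "off" and t.laser_on:
            continue
        out.append(t)
    return out


def fit_probit(
    trials: Sequence[TrialRecord] | Session, laser_filter: str = "all"
) -> ProbitFit:
    """Maximum-likelihood (mu_hat, sigma_hat) for one session x laser state.

    Forced offers are removed before fitting.  Degenerate data (all choices
    identical, separable, or a single distinct offer) yield a non-converged
    fit rather than an exception; zero usable trials raise
    :class:`~econochoice.errors.InputError`.
    """
    if isinstance(trials, Session):
        trials = trials.trials
    usable = _usable(trials, laser_filter)
    if not usable:
        raise InputError("zero usable (non-forced) trials after filtering")
    xs, n, k = _aggregate(usable)
    return fit_probit_counts(xs, n, k)


def apply_exclusion(
    fits: Sequence[ProbitFit], max_ip_ratio: float = 6.0
) -> list[ProbitFit]:
    """Mark fits whose oriented IP exceeds ``max_ip_ratio`` (strictly) as excluded.

    Fits are oriented so the IP is expressed non-preferred:preferred (>= 1)
    before comparison; the boundary value itself is retained.
    """
    out = []
    for f in fits:
        if f.oriented().ip > max_ip_ratio:
            out.append(replace(f, excluded=True,
                               exclusion_reason=f"IP > {max_ip_ratio}:1"))
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# IP-aligned averaged curves
# ---------------------------------------------------------------------------

@dataclass
class RelativeChoiceCurve:
    """Binned, IP-aligned choice (or reaction-time) curve pooled over sessions.

    The x-axis is the log offer ratio *relative* to each contributing
    session's fitted log IP; 0 therefore marks indifference by construction.
    ``choice_frac`` is the mean fraction of choices of the non-preferred
    flavor per bin (NaN where a bin received no trials).
    """

    bin_edges: np.ndarray
    choice_frac: np.ndarray
    mean_rt: np.ndarray
    n: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def missing_bins(self) -> np.ndarray:
        return np.flatnonzero(self.n == 0)


def default_bin_edges(width: float = 0.5, span: float = 4.5) -> np.ndarray:
    """Symmetric bins of the given width on the relative natural-log scale,
    with one bin centered on 0."""
    half = width / 2
    edges = np.arange(half, span + 1e-9, width)
    return np.concatenate([-edges[::-1], edges])


def _oriented_trail(session: Session, fit: ProbitFit, laser_filter: str):
    """Yield (relative log-ratio, chose-nonpreferred, rt, sigma) per usable trial."""
    flip = fit.mu_hat < 0
    mu = abs(fit.mu_hat)
    for t in _usable(session.trials, laser_filter):
        r = t.offer.log_ratio
        chose_x = t.choice == "x"
        if flip:
            r, chose_x = -r, not chose_x
        yield r - mu, chose_x, t.reaction_time, r


def _binned(
    pairs: Sequence[tuple[Session, ProbitFit]],
    bin_edges: np.ndarray | None,
    laser_filter: str,
    value_fn,
) -> RelativeChoiceCurve:
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    nbins = bin_edges.size - 1
    sums = np.zeros(nbins)
    rt_sums = np.zeros(nbins)
    rt_n = np.zeros(nbins, dtype=int)
    counts = np.zeros(nbins, dtype=int)
    for session, fit in pairs:
        if not fit.converged or fit.excluded:
            raise InputError(
                "every contributing session needs a converged, non-excluded fit"
            )
        for rel, chose_np, rt, raw in _oriented_trail(session, fit, laser_filter):
            idx = np.searchsorted(bin_edges, rel, side="right") - 1
            if idx < 0 or idx >= nbins:
                continue
            counts[idx] += 1
            sums[idx] += value_fn(chose_np, fit, raw)
            if rt is not None:
                rt_sums[idx] += rt
                rt_n[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mean_rt = np.where(rt_n > 0, rt_sums / np.maximum(rt_n, 1), np.nan)
    frac[counts == 0] = np.nan
    return RelativeChoiceCurve(bin_edges, frac, mean_rt, counts)


def choice_curve_relative(
    pairs: Sequence[tuple[Session, ProbitFit]],
    bin_edges: np.ndarray | None = None,
    laser_filter: str = "all",
) -> RelativeChoiceCurve:
    """Pooled fraction of non-preferred choices by IP-relative offer bin."""
    return _binned(pairs, bin_edges, laser_filter,
                   lambda chose_np, fit, raw: float(chose_np))


def shift_to_unity_prediction(
    pairs: Sequence[tuple[Session, ProbitFit]],
    bin_edges: np.ndarray | None = None,
    laser_filter: str = "all",
) -> RelativeChoiceCurve:
    """Predicted pooled curve were every session's IP shifted to 1:1.

    Each session's choice probabilities are recomputed on its own offer grid
    with mu set to 0 and its fitted sigma kept, then binned on the same
    IP-relative axis as the observed curve.
    """
    return _binned(
        pairs, bin_edges, laser_filter,
        lambda chose_np, fit, raw: float(special.ndtr(raw / fit.sigma_hat)),
    )


def rt_by_relative_offer(
    pairs: Sequence[tuple[Session, ProbitFit]],
    bin_edges: np.ndarray | None = None,
    laser_filter: str = "all",
) -> RelativeChoiceCurve:
    """Mean reaction time by IP-relative offer bin (rt channel of the curve)."""
    return _binned(pairs, bin_edges, laser_filter,
                   lambda chose_np, fit, raw: float(chose_np))


def pooled_curve_fit(curve: RelativeChoiceCurve) -> ProbitFit:
    """Probit refit of a pooled aligned curve, for display overlays.

    Treats each non-empty bin as a binomial observation at its center; by
    construction of the alignment the refit mu is near 0.
    """
    ok = curve.n > 0
    x = curve.bin_centers[ok]
    n = curve.n[ok].astype(float)
    k = np.round(curve.choice_frac[ok] * n)
    return fit_probit_counts(x, n, k)


def early_subset(session: Session, k_per_offer: int = 4) -> Session:
    """First ``k_per_offer`` occurrences of each offer x laser state, in order.

    With the full 11-offer menu and both laser states, ``k_per_offer=4``
    yields the 88-trial early-session subset used to probe within-session
    time effects.  Offers with fewer occurrences contribute what they have,
    with a warning.
    """
    taken: dict[tuple[int, int, bool], int] = {}
    trials = []
    for t in session.trials:
        key = (t.offer.qty_x, t.offer.qty_y, t.laser_on)
        c = taken.get(key, 0)
        if c < k_per_offer:
            taken[key] = c + 1
            trials.append(t)
    short = [k for k, c in taken.items() if c < k_per_offer]
    if short:
        warnings.warn(
            f"{len(short)} offer x laser cells had fewer than {k_per_offer} "
            "occurrences; subset is partial",
            stacklevel=2,
        )
    return replace(session, trials=trials)
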