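"""Statistical battery for the inactivation analyses.

Centered on balanced repeated-measures ANOVAs with categorical blocking:
every experimental replication (a blocked/patent session pair) contributes
one observation to each treatment cell, and replications enter the model as
a blocking factor.  Because each block contains every treatment cell, the
treatment contrasts are orthogonal to the block space and the decomposition
is computed by sequential least-squares projection on an explicitly
constructed sum-to-zero design (QR); this also handles the three-way layout
with blocks nested in the Time factor, where block indicators alias the Time
main effect and a single regression formula would be rank-deficient.

Also here: paired-t simple effects, t-based confidence intervals, the
type-II error of the paired t-test against a shift-to-1:1 alternative, the
split-half bootstrap null for the preference threshold, and the
sliding-threshold exclusion curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, InputError
from .psychometric import fit_probit_counts
from .session_io import CONDITIONS, Session, SessionPairRecord

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "rm_anova",
    "pairs_to_long",
    "PairedTResult",
    "simple_effects",
    "MeanCI",
    "mean_ci",
    "power_shift_to_unity",
    "ThresholdResult",
    "bootstrap_ip_threshold",
    "SlidingCurve",
    "sliding_exclusion_curve",
    "percent_change",
    "condition_means",
    "pair_summary_ip",
    "filter_records_by_ip",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with blocking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaRow:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    blocks: list[str]
    response_transform: str
    n_obs: int
    residual_ss: float

    def term(self, name: str) -> AnovaRow:
        for row in self.rows:
            if row.term == name:
                return row
        raise KeyError(name)

    @property
    def df_den(self) -> int:
        return self.rows[0].df_den

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.rows])
        df.attrs["blocks"] = self.blocks
        df.attrs["response_transform"] = self.response_transform
        return df


def _sum_contrasts(series: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for a categorical series (levels-1 cols)."""
    levels = sorted(pd.unique(series))
    L = len(levels)
    if L < 2:
        raise DesignError(f"factor {series.name!r} has fewer than 2 levels")
    index = {lv: i for i, lv in enumerate(levels)}
    M = np.zeros((len(series), L - 1))
    for row, v in enumerate(series):
        i = index[v]
        if i < L - 1:
            M[row, i] = 1.0
        else:
            M[row, :] = -1.0
    return M, levels


def _interaction_cols(mats: Sequence[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def _check_balance(
    data: pd.DataFrame,
    factors: list[str],
    blocks: list[str],
    block_nested_in: str | None = None,
) -> None:
    crossed = [f for f in factors if f != block_nested_in]
    cell_cols = blocks + crossed
    counts = data.groupby(cell_cols, observed=True).size()
    expected_cells = 1
    for c in cell_cols:
        expected_cells *= data[c].nunique()
    if len(counts) != expected_cells or counts.nunique() != 1:
        raise DesignError(
            "unbalanced design: every block must contain every "
            f"{' x '.join(crossed)} cell the same number of times"
        )
    if block_nested_in is not None:
        per_block = data.groupby(blocks[0], observed=True)[block_nested_in].nunique()
        if (per_block != 1).any():
            raise DesignError(
                f"blocks must be nested in {block_nested_in!r}: each block "
                "may occupy only one level"
            )


def rm_anova(
    data: pd.DataFrame | Sequence[SessionPairRecord],
    response: str = "value",
    factors: Sequence[str] = ("laser", "fiber"),
    blocks: Sequence[str] = ("block",),
    block_nested_in: str | None = None,
    transform: str = "linear",
) -> AnovaTable:
    """Balanced blocked ANOVA: per-term F, df and p against the residual.

    ``data`` is long-form (one row per observation) or a list of
    :class:`SessionPairRecord` (converted via :func:`pairs_to_long`).
    ``factors`` are fully crossed treatments; ``blocks`` enter additively as
    categorical effects.  ``block_nested_in`` names a factor (e.g. ``time``)
    within which the single block factor is nested: block contrasts are then
    restricted to the within-level subspace so the nesting factor's main
    effect remains estimable.  ``transform`` is ``linear`` (response used as
    is) or ``log`` (natural log, for ratio-scale responses); the choice is
    recorded on the returned table.
    """
    if not isinstance(data, pd.DataFrame):
        data = pairs_to_long(data)
    factors = list(factors)
    blocks = list(blocks)
    if block_nested_in is not None and len(blocks) != 1:
        raise DesignError("nesting supports a single block factor")
    for col in factors + blocks + [response]:
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
    _check_balance(data, factors, blocks, block_nested_in)

    y = np.asarray(data[response], dtype=float)
    if transform == "log":
        if np.any(y <= 0):
            raise InputError("log transform requires a strictly positive response")
        y = np.log(y)
    elif transform != "linear":
        raise ValueError(f"transform must be 'linear' or 'log', got {transform!r}")

    n = len(y)
    main_mats: dict[str, np.ndarray] = {}
    for f in factors:
        main_mats[f], _ = _sum_contrasts(data[f])

    # term order: factor mains, block effects, then interactions by degree
    terms: list[tuple[str, np.ndarray]] = [(f, main_mats[f]) for f in factors]

    block_terms: list[tuple[str, np.ndarray]] = []
    for b in blocks:
        B, _ = _sum_contrasts(data[b])
        if block_nested_in is not None:
            # restrict block contrasts to the subspace orthogonal to the
            # nesting factor (blocks indicators otherwise alias its main effect)
            T = np.column_stack([np.ones(n), main_mats[block_nested_in]])
            B = B - T @ np.linalg.lstsq(T, B, rcond=None)[0]
            q, r = np.linalg.qr(B)
            keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
            B = q[:, keep]
        block_terms.append((f"block({b})", B))
    terms.extend(block_terms)

    from itertools import combinations

    for degree in range(2, len(factors) + 1):
        for combo in combinations(factors, degree):
            terms.append(("*".join(combo), _interaction_cols([main_mats[f] for f in combo])))

    X_parts = [np.ones((n, 1))]
    spans = []  # (term, col_start, col_stop)
    start = 1
    for name, M in terms:
        X_parts.append(M)
        spans.append((name, start, start + M.shape[1]))
        start += M.shape[1]
    X = np.hstack(X_parts)
    if X.shape[1] >= n:
        raise DesignError("saturated design: no residual degrees of freedom")

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = np.flatnonzero(diag <= 1e-8 * diag.max())
    if bad.size:
        col = bad[0]
        aliased = next((t for t, a, b in spans if a <= col < b), "intercept")
        raise DesignError(f"singular design: term {aliased!r} is aliased")

    effects = Q.T @ y
    rss = float(y @ y - effects @ effects)
    df_res = n - X.shape[1]
    ms_res = rss / df_res

    rows = []
    for name, a, b in spans:
        ss = float(np.sum(effects[a:b] ** 2))
        df_num = b - a
        F = (ss / df_num) / ms_res if ms_res > 0 else 0.0
        F = max(F, 0.0)
        p = float(stats.f.sf(F, df_num, df_res)) if ms_res > 0 else 1.0
        rows.append(AnovaRow(name, F, df_num, df_res, p, ss))
    return AnovaTable(rows, blocks, transform, n, rss)


def pairs_to_long(records: Sequence[SessionPairRecord]) -> pd.DataFrame:
    """Long-form frame (block, laser, fiber, value) from 4-condition records."""
    rows = []
    for rec in records:
        for cond in CONDITIONS:
            fiber = "blocked" if cond.startswith("B") else "patent"
            laser = "on" if cond.endswith("on") else "off"
            rows.append(
                {"block": rec.block_id, "laser": laser, "fiber": fiber,
                 "value": rec.values[cond]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple effects and confidence intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    name: str
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


#: the four canonical simple-effect comparisons of the 2x2 design
DEFAULT_COMPARISONS = (
    ("laser on vs off | blocked", "B-on", "B-off"),
    ("laser on vs off | patent", "P-on", "P-off"),
    ("patent vs blocked | laser off", "P-off", "B-off"),
    ("patent vs blocked | laser on", "P-on", "B-on"),
)


def simple_effects(
    records: Sequence[SessionPairRecord],
    comparisons: Sequence[tuple[str, str, str]] = DEFAULT_COMPARISONS,
    transform: str = "linear",
) -> list[PairedTResult]:
    """Two-sided paired t-tests between pairs of conditions, per block."""
    results = []
    for name, cond_a, cond_b in comparisons:
        a = np.array([r.values[cond_a] for r in records], dtype=float)
        b = np.array([r.values[cond_b] for r in records], dtype=float)
        if transform == "log":
            a, b = np.log(a), np.log(b)
        d = a - b
        n = d.size
        if n < 2:
            raise InputError("paired t-test needs at least 2 blocks")
        sd = d.std(ddof=1)
        if sd == 0:
            warnings.warn(f"{name}: zero-variance differences", stacklevel=2)
            if d.mean() == 0:
                results.append(PairedTResult(name, 0.0, n - 1, 1.0, 0.0, n))
            else:
                results.append(
                    PairedTResult(name, math.inf if d.mean() > 0 else -math.inf,
                                  n - 1, 0.0, float(d.mean()), n)
                )
            continue
        t, p = stats.ttest_rel(a, b)
        results.append(PairedTResult(name, float(t), n - 1, float(p), float(d.mean()), n))
    return results


@dataclass(frozen=True)
class MeanCI:
    mean: float
    lower: float
    upper: float
    level: float
    scale: str

    def __iter__(self):
        return iter((self.mean, self.lower, self.upper))


def mean_ci(values: Sequence[float], level: float = 0.95, scale: str = "linear") -> MeanCI:
    """t-based confidence interval of the mean on the configured scale.

    ``scale='log'`` computes the interval for the log-values and maps it back
    through exp, i.e. an interval for the geometric mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 values for a confidence interval")
    if scale == "log":
        v = np.log(v)
    m = v.mean()
    se = v.std(ddof=1) / math.sqrt(v.size)
    tcrit = stats.t.ppf(0.5 + level / 2, v.size - 1)
    lo, hi = m - tcrit * se, m + tcrit * se
    if scale == "log":
        m, lo, hi = math.exp(m), math.exp(lo), math.exp(hi)
    return MeanCI(float(m), float(lo), float(hi), level, scale)


def power_shift_to_unity(
    paired_log_ips: np.ndarray, alpha: float = 0.05
) -> float:
    """Type-II error (beta) of the paired t-test if laser shifted IPs to 1:1.

    ``paired_log_ips`` has one row per session pair, columns (laser-off,
    laser-on) log IPs.  The alternative keeps the observed laser-off values
    and sets every laser-on log IP to 0 (an IP of 1:1), so the hypothesized
    mean difference is the mean laser-off log IP; the difference sd is taken
    from the observed paired differences.  Computed from the noncentral t
    distribution.
    """
    arr = np.asarray(paired_log_ips, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InputError("paired_log_ips must be (n >= 2, 2)")
    off, on = arr[:, 0], arr[:, 1]
    sd = (off - on).std(ddof=1)
    n = arr.shape[0]
    if sd == 0:
        warnings.warn("zero variance of paired differences; beta = 0", stacklevel=2)
        return 0.0
    effect = off.mean()  # mean difference under the shift-to-1:1 alternative
    ncp = abs(effect) / (sd / math.sqrt(n))  # beta is symmetric in the sign
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.cdf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # at extreme noncentrality scipy's lower tail can underflow to NaN;
    # the term is then negligibly small
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 0.0
    return float(min(max(upper - lower, 0.0), 1.0))


# ---------------------------------------------------------------------------
# split-half bootstrap preference threshold
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    threshold_ratio: float
    null_distribution: np.ndarray  # |delta log IP| samples
    alpha: float
    n_boot: int
    seed: int | None
    n_skipped: int


def bootstrap_ip_threshold(
    blocked_sessions: Sequence[Session],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ThresholdResult:
    """Split-half bootstrap null for "how far from 1:1 is meaningful".

    Per resample, each blocked-fiber session's non-forced trials are split at
    random into two halves, stratified by offer and laser state so both
    halves remain fittable; the probit is fit to each half and the absolute
    difference of the two log IPs recorded.  The threshold is exp of the
    (1 - alpha) quantile of the pooled null distribution: preference ratios
    below it are indistinguishable from 1:1 at the session level.
    """
    rng = np.random.default_rng(seed)
    # per session: per stratum (log ratio, laser) -> boolean choice array
    prepared = []
    for s in blocked_sessions:
        strata: dict[tuple[float, bool], list[bool]] = {}
        for t in s.trials:
            if t.offer.forced:
                continue
            strata.setdefault((t.offer.log_ratio, t.laser_on), []).append(
                t.choice == "x"
            )
        prepared.append(
            [(x, np.array(ch, dtype=bool)) for (x, _), ch in sorted(strata.items())]
        )

    deltas: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        for strata in prepared:
            xs1, n1, k1 = [], [], []
            xs2, n2, k2 = [], [], []
            for x, choices in strata:
                m = choices.size
                h = m // 2
                if h == 0:
                    continue
                perm = rng.permutation(m)
                first = choices[perm[:h]]
                second = choices[perm[h:]]
                xs1.append(x); n1.append(h); k1.append(int(first.sum()))
                xs2.append(x); n2.append(m - h); k2.append(int(second.sum()))
            try:
                f1 = fit_probit_counts(np.array(xs1), np.array(n1), np.array(k1))
                f2 = fit_probit_counts(np.array(xs2), np.array(n2), np.array(k2))
            except InputError:
                skipped += 1
                continue
            if not (f1.converged and f2.converged):
                skipped += 1
                continue
            deltas.append(abs(f1.mu_hat - f2.mu_hat))
    null = np.array(deltas)
    if null.size == 0:
        raise InputError("no successful split-half fits; sessions too sparse")
    threshold = float(np.exp(np.quantile(null, 1 - alpha)))
    return ThresholdResult(threshold, null, alpha, n_boot, seed, skipped)


# ---------------------------------------------------------------------------
# sliding-threshold exclusion curves
# ---------------------------------------------------------------------------

@dataclass
class SlidingCurve:
    """Mean laser-on minus laser-off difference vs IP-exclusion threshold."""

    thresholds: np.ndarray
    mean_diff: dict[str, np.ndarray]  # fiber -> per-threshold mean difference
    n_retained: dict[str, np.ndarray]
    measure: str


def _fiber_rank_ip(rec: SessionPairRecord, fiber: str) -> float:
    off, on = (f"{fiber}-off", f"{fiber}-on")
    return math.sqrt(rec.values[off] * rec.values[on])


def sliding_exclusion_curve(
    records: Sequence[SessionPairRecord],
    ip_records: Sequence[SessionPairRecord] | None = None,
    max_removed_frac: float = 0.9,
    min_retained: int = 3,
) -> SlidingCurve:
    """Sweep an IP-exclusion threshold and track the mean on-off difference.

    Sessions whose ranking IP (geometric mean of the fiber's laser-on and
    -off IPs, taken from ``ip_records`` when the measured records are slopes)
    is at or below the threshold are removed; the mean laser-on minus
    laser-off difference (log IP for ``measure='ip'``, raw values for
    slopes) is recomputed per fiber from the remainder.  The sweep stops at
    ``max_removed_frac`` removed or fewer than ``min_retained`` sessions.
    """
    if ip_records is None:
        ip_records = records
        if records and records[0].measure != "ip":
            raise InputError("ip_records required when records are not IPs")
    if len(ip_records) != len(records):
        raise InputError("records and ip_records must align one-to-one")
    measure = records[0].measure if records else "ip"

    ranks = {
        fiber: np.array([_fiber_rank_ip(r, f) for r in ip_records])
        for fiber, f in (("blocked", "B"), ("patent", "P"))
    }
    diffs = {}
    for fiber, f in (("blocked", "B"), ("patent", "P")):
        on = np.array([r.values[f"{f}-on"] for r in records], dtype=float)
        off = np.array([r.values[f"{f}-off"] for r in records], dtype=float)
        diffs[fiber] = np.log(on) - np.log(off) if measure == "ip" else on - off

    pooled = np.sort(np.concatenate(list(ranks.values())))
    cutoff = np.quantile(pooled, max_removed_frac)
    thresholds = np.concatenate([[pooled[0] - 1e-9], pooled[pooled <= cutoff]])

    mean_diff = {f: np.full(thresholds.size, np.nan) for f in ranks}
    n_ret = {f: np.zeros(thresholds.size, dtype=int) for f in ranks}
    for i, thr in enumerate(thresholds):
        for fiber in ranks:
            keep = ranks[fiber] > thr
            n_ret[fiber][i] = int(keep.sum())
            if keep.sum() >= min_retained:
                mean_diff[fiber][i] = float(diffs[fiber][keep].mean())
    return SlidingCurve(thresholds, mean_diff, n_ret, measure)


# ---------------------------------------------------------------------------
# small summaries
# ---------------------------------------------------------------------------

def percent_change(mean_ref: float, mean_alt: float) -> float:
    """100 * (alt - ref) / ref."""
    if mean_ref == 0:
        raise InputError("reference mean is zero")
    return 100.0 * (mean_alt - mean_ref) / mean_ref


def condition_means(records: Sequence[SessionPairRecord]) -> dict[str, float]:
    return {
        c: float(np.mean([r.values[c] for r in records])) for c in CONDITIONS
    }


def pair_summary_ip(record: SessionPairRecord) -> float:
    """Geometric mean of the four condition IPs: the per-pair preference size."""
    vals = record.as_row()
    return float(np.exp(np.mean(np.log(vals))))


def filter_records_by_ip(
    records: Sequence[SessionPairRecord],
    threshold: float,
    ip_records: Sequence[SessionPairRecord] | None = None,
) -> list[SessionPairRecord]:
    """Drop session pairs whose per-pair preference is <= threshold.

    ``ip_records`` supplies the IPs when ``records`` hold another measure
    (e.g. inverse slopes) for the same replications.
    """
    if ip_records is None:
        ip_records = records
    if len(ip_records) != len(records):
        raise InputError("records and ip_records must align one-to-one")
    return [
        rec for rec, ipr in zip(records, ip_records)
        if pair_summary_ip(ipr) > threshold
    ]
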