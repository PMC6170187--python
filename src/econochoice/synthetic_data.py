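"""Generators for synthetic choice sessions, experiments, and PR logs.

The generator emulates the statistical structure that the analysis chain
assumes so that every downstream stage can be exercised without animals:

* Bernoulli choices drawn from a probit function of the log offer ratio with
  a session-specific latent log IP and inverse slope;
* the 11-offer menu (9 graded ratios plus the two forced 1:0 / 0:1 offers),
  each offer x laser state appearing once per shuffled block so laser-on
  trials are exactly 50% and early-session subsets are well defined;
* a full experiment design: rats x runs x pellet pairs, each pair run for a
  warm-up day followed by counterbalanced blocked / patent fiber days;
* transitive latent preferences: per-rat latent flavor values generate pair
  IPs obeying IP(a:c) = IP(a:b) * IP(b:c) exactly, with optional log-normal
  between-session jitter on top;
* progressive-ratio sessions as an inhomogeneous Poisson press process whose
  hazard decays with pellets earned.

The laser manipulation is parameterized as a shrinkage of the latent log IP
toward 0 (``laser_ip_shrink``, the hypothesis that inactivation pushes
preferences toward 1:1) plus a multiplicative inflation of sigma
(``laser_sigma_scale``, the hypothesis that inactivation makes valuation
noisier).  An additional additive log-IP shift toward zero
(``laser_log_ip_shift``) expresses an exact multiplicative IP change, e.g.
ln(1/0.9) for a uniform 10% shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .session_io import Offer, PREventLog, Session, TrialRecord

__all__ = [
    "SessionParams",
    "ExperimentDesign",
    "standard_offer_menu",
    "simulate_session",
    "simulate_experiment",
    "sample_triplet_log_ips",
    "simulate_pr_session",
    "simulate_pr_experiment",
    "simulate_consumption",
]

_BASE_RATIOS = [(1, 8), (1, 6), (1, 4), (1, 3), (1, 2), (1, 1),
                (2, 1), (3, 1), (4, 1), (6, 1), (8, 1)]


def standard_offer_menu(shifted: bool = False) -> list[Offer]:
    """The 11-offer session menu: 9 graded ratios plus the forced offers.

    The graded ratios span 1:6..6:1, or 1:4..8:1 (``shifted=True``) for
    strongly preferred pairs, drawn from the canonical offer set.
    """
    ratios = _BASE_RATIOS[2:] if shifted else _BASE_RATIOS[1:-1]
    offers = [Offer(qx, qy) for qx, qy in ratios]
    offers.append(Offer(1, 0))
    offers.append(Offer(0, 1))
    return offers


@dataclass
class SessionParams:
    """Latent parameters for one simulated session.

    ``true_log_ip`` is mu in the probit model (natural-log units; the sign
    encodes which flavor is preferred), ``true_sigma`` the inverse slope.
    ``laser_ip_shrink`` is the fraction lambda in [0, 1] by which laser-on
    trials shrink the log IP toward 0 (0 = no effect, 1 = indifference);
    ``laser_sigma_scale`` multiplies sigma on laser-on trials.
    """

    true_log_ip: float
    true_sigma: float
    offers: list[Offer] | None = None
    reps_per_offer_per_laser: int = 10
    laser_ip_shrink: float = 0.0
    laser_sigma_scale: float = 1.0
    laser_log_ip_shift: float = 0.0
    forced_error_rate: float = 0.02
    rt_base: float = 1.2
    rt_noise: float = 0.25
    rt_difficulty: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.laser_ip_shrink <= 1.0:
            raise ParameterError("laser_ip_shrink must lie in [0, 1]")
        if self.laser_sigma_scale <= 0:
            raise ParameterError("laser_sigma_scale must be > 0")
        if self.true_sigma <= 0:
            raise ParameterError("true_sigma must be > 0")

    def effective_mu(self, laser_on: bool) -> float:
        mu = self.true_log_ip
        if not laser_on:
            return mu
        mu = (1.0 - self.laser_ip_shrink) * mu
        if self.laser_log_ip_shift:
            mu = math.copysign(max(abs(mu) - self.laser_log_ip_shift, 0.0), mu)
        return mu

    def effective_sigma(self, laser_on: bool) -> float:
        return self.true_sigma * (self.laser_sigma_scale if laser_on else 1.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(
    params: SessionParams,
    rng: np.random.Generator | None = None,
    *,
    rat_id: str = "sim",
    run_index: int = 1,
    pellet_pair: tuple[str, str] = ("x", "y"),
    fiber_state: str = "blocked",
    day_index: int | None = None,
    warmup: bool = False,
) -> Session:
    """Draw one full session of Bernoulli probit choices.

    Offers are scheduled in shuffled blocks containing each offer x laser
    state exactly once, so the laser-on fraction is exactly 1/2 and the first
    ``4 * 22`` trials contain four occurrences of every offer x laser cell.
    """
    if rng is None:
        rng = _rng(params.seed)
    offers = params.offers
    if offers is None:
        offers = standard_offer_menu(shifted=abs(params.true_log_ip) > math.log(3))
    block = [(o, laser) for o in offers for laser in (False, True)]
    schedule: list[tuple[Offer, bool]] = []
    for _ in range(params.reps_per_offer_per_laser):
        order = rng.permutation(len(block))
        schedule.extend(block[i] for i in order)

    # vectorized choice draws
    mus = np.array([params.effective_mu(laser) for _, laser in schedule])
    sigmas = np.array([params.effective_sigma(laser) for _, laser in schedule])
    p_x = np.empty(len(schedule))
    forced = np.array([o.forced for o, _ in schedule])
    log_ratios = np.array(
        [0.0 if o.forced else o.log_ratio for o, _ in schedule]
    )
    from scipy.special import ndtr

    p_x[~forced] = ndtr((log_ratios[~forced] - mus[~forced]) / sigmas[~forced])
    # forced offers: pick the stocked side, up to a lapse rate
    forced_x = np.array([o.qty_x > 0 for o, _ in schedule])
    p_x[forced] = np.where(forced_x[forced], 1 - params.forced_error_rate,
                           params.forced_error_rate)
    chose_x = rng.random(len(schedule)) < p_x
    rts = params.rt_base + params.rt_noise * rng.standard_normal(len(schedule))
    if params.rt_difficulty:
        rts += params.rt_difficulty * np.abs(log_ratios - mus) * ~forced
    rts = np.clip(rts, 0.05, 5.0)

    trials = [
        TrialRecord(
            trial_index=i + 1,
            offer=o,
            laser_on=laser,
            choice="x" if chose_x[i] else "y",
            reaction_time=float(rts[i]),
            fiber_patent=(fiber_state == "patent"),
        )
        for i, (o, laser) in enumerate(schedule)
    ]
    return Session(
        rat_id=rat_id,
        run_index=run_index,
        pellet_pair=pellet_pair,
        fiber_state=fiber_state,
        trials=trials,
        day_index=day_index,
        warmup=warmup,
        true_log_ip=params.true_log_ip,
        true_sigma=params.true_sigma,
    )


@dataclass
class ExperimentDesign:
    """Shape and latent structure of a full inactivation experiment.

    Each rat runs ``n_runs`` triplets of flavors; within a run the three
    pellet pairs are each tested for three consecutive days (warm-up, then
    blocked / patent counterbalanced).  Latent per-flavor log values (sd
    ``log_value_sd``) generate transitive pair IPs; each test session adds
    independent N(0, ip_jitter_sd^2) drift to its pair's log IP.  Session
    sigmas are log-normal around ``sigma_median``.
    """

    n_rats: int = 6
    n_runs: int = 3
    flavors_per_run: int = 3
    log_value_sd: float = 0.5
    ip_jitter_sd: float = 0.1
    sigma_median: float = 0.85
    sigma_log_sd: float = 0.2

    def n_pairs(self) -> int:
        pairs_per_run = self.flavors_per_run * (self.flavors_per_run - 1) // 2
        return self.n_rats * self.n_runs * pairs_per_run


def simulate_experiment(
    design: ExperimentDesign,
    params_template: SessionParams | None = None,
    seed: int | None = None,
    include_warmups: bool = True,
) -> list[Session]:
    """Simulate every session of a rats x runs x pairs x days experiment.

    ``params_template`` supplies trial-level settings (reps per offer, laser
    effect parameters, RT model); its ``true_log_ip`` / ``true_sigma`` are
    overridden per session by the latent design.  Fiber order across the two
    test days is counterbalanced by alternating cells of the design.
    """
    rng = _rng(seed)
    if params_template is None:
        params_template = SessionParams(true_log_ip=0.0, true_sigma=design.sigma_median)
    sessions: list[Session] = []
    counter = 0
    for r in range(design.n_rats):
        rat = f"rat{r + 1}"
        for run in range(1, design.n_runs + 1):
            flavors = [f"run{run}_f{j}" for j in range(design.flavors_per_run)]
            log_values = {
                f: rng.normal(0.0, design.log_value_sd) for f in flavors
            }
            pairs = [
                (flavors[i], flavors[j])
                for i in range(len(flavors))
                for j in range(i + 1, len(flavors))
            ]
            for fa, fb in pairs:
                # mu = log of x:y offer ratio at indifference = value(y) - value(x)
                mu_pair = log_values[fb] - log_values[fa]
                day_order = (
                    ("blocked", "patent") if counter % 2 == 0 else ("patent", "blocked")
                )
                counter += 1
                day_plan = [("blocked", True)] if include_warmups else []
                day_plan += [(fs, False) for fs in day_order]
                for day, (fiber, is_warm) in enumerate(day_plan, start=1):
                    mu = mu_pair + rng.normal(0.0, design.ip_jitter_sd)
                    sigma = design.sigma_median * math.exp(
                        rng.normal(0.0, design.sigma_log_sd)
                    )
                    params = replace(
                        params_template, true_log_ip=mu, true_sigma=sigma, seed=None
                    )
                    sessions.append(
                        simulate_session(
                            params,
                            rng,
                            rat_id=rat,
                            run_index=run,
                            pellet_pair=(fa, fb),
                            fiber_state=fiber,
                            day_index=day,
                            warmup=is_warm,
                        )
                    )
    return sessions


def sample_triplet_log_ips(
    design: ExperimentDesign, n_triplets: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Latent jittered log IPs (AC, AB, BC) for independent flavor triplets.

    Flavors are ordered by latent value (A highest), so the noiseless log IPs
    satisfy log IP(A:C) = log IP(A:B) + log IP(B:C) exactly; each returned
    value adds independent session jitter.  Shape (n_triplets, 3).
    """
    rng = _rng(rng)
    v = np.sort(rng.normal(0.0, design.log_value_sd, size=(n_triplets, 3)), axis=1)
    va, vb, vc = v[:, 2], v[:, 1], v[:, 0]
    base = np.column_stack([va - vc, va - vb, vb - vc])
    return base + rng.normal(0.0, design.ip_jitter_sd, size=base.shape)


# ---------------------------------------------------------------------------
# progressive ratio
# ---------------------------------------------------------------------------

def simulate_pr_session(
    press_rate: float = 1.0,
    satiety_decay: float = 0.0,
    session_cap: float = 1800.0,
    idle_cap: float = 300.0,
    engagement_time: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PREventLog:
    """Simulate lever pressing under the PR5 schedule.

    While the animal is engaged, inter-press intervals are exponential with
    hazard ``press_rate * exp(-satiety_decay * pellets_earned)`` (Hz); a
    pellet is delivered when the running press requirement (1, 5, 10, 15, ...
    held for three trials each) is met.  ``engagement_time`` is the moment
    the animal disengages and pressing stops for good — a motivational
    deficit that lowers the breakpoint without changing the tempo of
    pressing (the inter-press-interval distribution) while it lasts.
    Generation stops at disengagement, the session cap, or when a sampled
    interval exceeds the idle cap.
    """
    from .progressive_ratio import pr_requirement

    rng = _rng(seed)
    quit_time = engagement_time if engagement_time is not None else math.inf
    presses: list[float] = []
    pellets: list[float] = []
    t = 0.0
    earned = 0
    presses_this_trial = 0
    while True:
        rate = press_rate * math.exp(-satiety_decay * earned)
        if rate <= 0:
            break
        gap = rng.exponential(1.0 / rate)
        if gap > idle_cap or t + gap > min(session_cap, quit_time):
            break
        t += gap
        presses.append(t)
        presses_this_trial += 1
        if presses_this_trial >= pr_requirement(earned + 1):
            earned += 1
            presses_this_trial = 0
            pellets.append(t)
    end = min(session_cap, (presses[-1] + idle_cap) if presses else idle_cap)
    return PREventLog(np.array(presses), np.array(pellets), end)


def simulate_pr_experiment(
    n_rats: int = 4,
    n_runs: int = 2,
    press_rate: float = 0.5,
    satiety_decay: float = 0.0,
    engagement_mean: float = 700.0,
    patent_engagement_factor: float = 0.45,
    rat_rate_sd: float = 0.15,
    session_engagement_sd: float = 0.25,
    seed: int | None = None,
):
    """Breakpoint / press counts for a counterbalanced blocked-vs-patent PR test.

    Each rat runs ``n_runs`` blocked/patent session pairs.  A patent fiber
    shortens the mean engagement time by ``patent_engagement_factor`` — the
    animal gives up earlier — while the press tempo is unaffected, so
    breakpoints drop but the inter-press-interval distribution does not.
    Rats carry a stable rate offset (``rat_rate_sd``, absorbed by the rat
    blocking factor) and engagement varies log-normally from day to day
    (``session_engagement_sd``).  Returns ``(table, logs)`` where ``table``
    is a pandas DataFrame with columns rat, run, fiber, breakpoint, presses.
    """
    import pandas as pd

    from .progressive_ratio import breakpoint as bp

    rng = _rng(seed)
    rows = []
    logs = {}
    for r in range(n_rats):
        rat_rate = press_rate * math.exp(rng.normal(0.0, rat_rate_sd))
        for run in range(1, n_runs + 1):
            order = ("blocked", "patent") if (r + run) % 2 == 0 else ("patent", "blocked")
            for fiber in order:
                engage = engagement_mean * (
                    patent_engagement_factor if fiber == "patent" else 1.0
                )
                engage *= math.exp(rng.normal(0.0, session_engagement_sd))
                log = simulate_pr_session(rat_rate, satiety_decay,
                                          engagement_time=engage, seed=rng)
                rows.append(
                    {
                        "rat": f"rat{r + 1}",
                        "run": run,
                        "fiber": fiber,
                        "breakpoint": bp(log),
                        "presses": int(log.press_times.size),
                    }
                )
                logs[(f"rat{r + 1}", run, fiber)] = log
    return pd.DataFrame(rows), logs


def simulate_consumption(
    n_rats: int = 4,
    n_runs: int = 2,
    mean_grams: float = 12.0,
    patent_effect: float = 0.0,
    rat_sd: float = 1.5,
    noise_sd: float = 1.0,
    seed: int | None = None,
):
    """Grams consumed in a 30-min free-feeding test, rats x runs x fiber."""
    import pandas as pd

    rng = _rng(seed)
    rows = []
    for r in range(n_rats):
        rat_mean = mean_grams + rng.normal(0.0, rat_sd)
        for run in range(1, n_runs + 1):
            for fiber in ("blocked", "patent"):
                grams = rat_mean + (patent_effect if fiber == "patent" else 0.0)
                grams += rng.normal(0.0, noise_sd)
                rows.append(
                    {"rat": f"rat{r + 1}", "run": run, "fiber": fiber,
                     "grams": max(grams, 0.0)}
                )
    return pd.DataFrame(rows)
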