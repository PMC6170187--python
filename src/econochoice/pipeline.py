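"""End-to-end orchestration: simulate or load, fit, analyze, report.

The pipeline reproduces the full behavioral-analysis chain on one dataset:

1. obtain sessions (simulate a full experiment, or load trial logs);
2. fit the probit per session x laser state, orient each blocked/patent
   session pair so its IPs read non-preferred:preferred, and drop pairs with
   an IP beyond the offer range (> 6:1);
3. run the IP and inverse-slope ANOVAs (2-way Laser x Fiber with replication
   blocking, the 3-way with Time, the early-session subset), simple effects,
   condition means and confidence intervals, the shift-to-1:1 power, the
   split-half bootstrap threshold and its strong-preference re-analysis, and
   the sliding exclusion curves;
4. order pellet triplets, compare transitivity and on/off distances;
5. analyze progressive-ratio breakpoints, press counts, inter-press
   intervals and the consumption test.

Every stochastic stage draws from one run seed; identical config + seed
gives byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import inactivation_stats as istats
from . import progressive_ratio as pr
from . import psychometric as psy
from . import synthetic_data as synth
from . import transitivity as trans
from .errors import EconoChoiceError, InputError
from .session_io import (
    CONDITIONS,
    Session,
    SessionPairRecord,
    build_session_pairs,
    read_trial_log,
    write_source_table,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "generate_report",
           "fit_session_pairs", "sessions_to_records",
           "replicate_experiment_pvalues", "analyze_source_tables"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; round-trips losslessly to YAML."""

    mode: str = "simulate"  # simulate | load
    seed: int = 0
    outdir: str | None = None
    # simulated design
    n_rats: int = 6
    n_runs: int = 3
    reps_per_offer_per_laser: int = 10
    laser_ip_shrink: float = 0.0
    laser_sigma_scale: float = 1.0
    laser_log_ip_shift: float = 0.0
    ip_jitter_sd: float = 0.1
    log_value_sd: float = 0.5
    # load mode
    trial_log_dir: str | None = None
    # analysis switches
    transform: str = "linear"
    n_boot: int = 1000
    alpha: float = 0.05
    max_ip_ratio: float = 6.0
    k_per_offer: int = 4
    bin_width: float = 0.5
    run_bootstrap: bool = True
    run_pr: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise EconoChoiceError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PairFits:
    """Oriented per-condition fits for one blocked/patent replication."""

    block_id: int
    rat_id: str
    run_index: int
    pellet_pair: tuple[str, str]
    fits: dict[str, psy.ProbitFit]  # condition -> oriented fit
    raw_mu: dict[str, float]  # condition -> unoriented mu_hat
    flipped: bool
    blocked_session: Session | None = None
    patent_session: Session | None = None


def fit_session_pairs(
    pairs: Sequence[tuple[Session, Session]],
    max_ip_ratio: float = 6.0,
) -> tuple[list[PairFits], int, int]:
    """Fit all four conditions of each pair, orient, and apply the IP cap.

    Orientation is decided per replication from the mean of the four fitted
    mus, so all four condition IPs of a pair read non-preferred:preferred on
    the same side.  A pair is dropped when any fit fails to converge
    (counted in ``n_failed``) or any oriented IP exceeds ``max_ip_ratio``
    (counted in ``n_excluded``).
    """
    kept: list[PairFits] = []
    n_excluded = 0
    n_failed = 0
    block = 0
    for blocked, patent in pairs:
        fits = {}
        raw_mu = {}
        try:
            for cond, session, laser in (
                ("B-off", blocked, "off"),
                ("B-on", blocked, "on"),
                ("P-off", patent, "off"),
                ("P-on", patent, "on"),
            ):
                fits[cond] = psy.fit_probit(session, laser_filter=laser)
                raw_mu[cond] = fits[cond].mu_hat
        except InputError:
            n_failed += 1
            continue
        if not all(f.converged for f in fits.values()):
            n_failed += 1
            continue
        flip = sum(f.mu_hat for f in fits.values()) < 0
        if flip:
            fits = {
                c: dataclasses.replace(f, mu_hat=-f.mu_hat) for c, f in fits.items()
            }
        if max(f.ip for f in fits.values()) > max_ip_ratio:
            n_excluded += 1
            continue
        block += 1
        kept.append(
            PairFits(block, blocked.rat_id, blocked.run_index,
                     blocked.pellet_pair, fits, raw_mu, flip,
                     blocked_session=blocked, patent_session=patent)
        )
    return kept, n_excluded, n_failed


def sessions_to_records(
    pair_fits: Sequence[PairFits],
) -> tuple[list[SessionPairRecord], list[SessionPairRecord]]:
    """IP and inverse-slope SessionPairRecord lists from oriented pair fits."""
    ip_records = [
        SessionPairRecord(
            pf.block_id, {c: pf.fits[c].ip for c in CONDITIONS}, "ip"
        )
        for pf in pair_fits
    ]
    sigma_records = [
        SessionPairRecord(
            pf.block_id, {c: pf.fits[c].sigma_hat for c in CONDITIONS},
            "inverse_slope",
        )
        for pf in pair_fits
    ]
    return ip_records, sigma_records


def _records_long_with_time(
    records: Sequence[SessionPairRecord], time_of_block: dict[int, int]
) -> pd.DataFrame:
    df = istats.pairs_to_long(records)
    df["time"] = df["block"].map(time_of_block)
    return df


def _anova_dict(table: istats.AnovaTable) -> dict:
    return {
        "blocks": table.blocks,
        "transform": table.response_transform,
        "terms": {
            r.term: {"F": round(r.F, 6), "df_num": r.df_num,
                     "df_den": r.df_den, "p": round(r.p, 8)}
            for r in table.rows
        },
    }


@dataclass
class PipelineResult:
    config: RunConfig
    n_pairs: int
    n_excluded: int
    n_failed: int
    ip_records: list[SessionPairRecord]
    sigma_records: list[SessionPairRecord]
    summary: dict
    triplets: list[trans.TripletRecord] = field(default_factory=list)
    pr_table: pd.DataFrame | None = None


def _build_triplets(pair_fits: Sequence[PairFits]) -> list[trans.TripletRecord]:
    groups: dict[tuple[str, int], list[PairFits]] = {}
    for pf in pair_fits:
        groups.setdefault((pf.rat_id, pf.run_index), []).append(pf)
    triplets = []
    for (rat, run), members in sorted(groups.items()):
        if len(members) != 3:
            continue  # an excluded pair breaks the triplet
        cond_tables = {
            cond: {
                pf.pellet_pair: math.exp(-pf.raw_mu[cond]) for pf in members
            }
            for cond in CONDITIONS
        }
        # Label A/B/C from the geometric-mean IP over all four conditions:
        # a reference built symmetrically from every condition makes the
        # labeling's selection bias common to all conditions, so it cancels
        # from every laser/fiber contrast on T.
        ref_table = {
            pf.pellet_pair: math.exp(
                -np.mean([pf.raw_mu[c] for c in CONDITIONS])
            )
            for pf in members
        }
        try:
            triplets.append(
                trans.order_triplet(ref_table, f"{rat}:run{run}", cond_tables)
            )
        except InputError:
            continue
    return triplets


def run_pipeline(config: RunConfig) -> PipelineResult:
    t0 = time.monotonic()
    rng_seed = np.random.SeedSequence(config.seed)
    sim_seed, boot_seed, pr_seed, cons_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in rng_seed.spawn(4)
    )
    log = lambda msg: print(f"[pipeline +{time.monotonic() - t0:6.1f}s] {msg}",
                            file=sys.stderr)

    # ---- stage: data -----------------------------------------------------
    if config.mode == "simulate":
        design = synth.ExperimentDesign(
            n_rats=config.n_rats, n_runs=config.n_runs,
            ip_jitter_sd=config.ip_jitter_sd, log_value_sd=config.log_value_sd,
        )
        template = synth.SessionParams(
            true_log_ip=0.0, true_sigma=design.sigma_median,
            reps_per_offer_per_laser=config.reps_per_offer_per_laser,
            laser_ip_shrink=config.laser_ip_shrink,
            laser_sigma_scale=config.laser_sigma_scale,
            laser_log_ip_shift=config.laser_log_ip_shift,
        )
        sessions = synth.simulate_experiment(design, template, seed=sim_seed)
    elif config.mode == "load":
        if not config.trial_log_dir:
            raise EconoChoiceError("load mode requires trial_log_dir")
        paths = sorted(Path(config.trial_log_dir).glob("*.tsv"))
        if not paths:
            raise InputError(f"no .tsv trial logs in {config.trial_log_dir}")
        sessions = [read_trial_log(p) for p in paths]
    else:
        raise EconoChoiceError(f"unknown mode {config.mode!r}")
    log(f"{len(sessions)} sessions")

    pairs, unmatched = build_session_pairs(sessions)
    pair_fits, n_excluded, n_failed = fit_session_pairs(pairs, config.max_ip_ratio)
    ip_records, sigma_records = sessions_to_records(pair_fits)
    if len(ip_records) < 3:
        raise InputError("fewer than 3 analyzable session pairs")
    log(f"{len(pairs)} pairs, {len(ip_records)} kept "
        f"({n_excluded} excluded, {n_failed} failed, {len(unmatched)} unmatched)")

    # outdir is a filesystem detail, not part of the analysis identity
    config_echo = {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "outdir"}
    summary: dict = {
        "config": config_echo,
        "n_sessions": len(sessions),
        "n_pairs": len(pairs),
        "n_pairs_kept": len(ip_records),
        "n_pairs_excluded_ip": n_excluded,
        "n_pairs_failed_fit": n_failed,
    }

    # ---- stage: IP / slope ANOVAs ---------------------------------------
    summary["ip_anova"] = _anova_dict(
        istats.rm_anova(ip_records, transform=config.transform)
    )
    summary["sigma_anova"] = _anova_dict(istats.rm_anova(sigma_records))
    summary["condition_means_ip"] = {
        k: round(v, 6) for k, v in istats.condition_means(ip_records).items()
    }
    summary["condition_means_sigma"] = {
        k: round(v, 6) for k, v in istats.condition_means(sigma_records).items()
    }
    summary["simple_effects_ip"] = [
        dataclasses.asdict(r) for r in istats.simple_effects(
            ip_records, transform=config.transform)
    ]
    ip_p = np.array([[r.values["P-off"], r.values["P-on"]] for r in ip_records])
    ci = istats.mean_ci(ip_p[:, 0], scale="linear")
    summary["ci_patent_off_ip"] = [round(ci.mean, 6), round(ci.lower, 6),
                                   round(ci.upper, 6)]
    summary["percent_change_patent_ip"] = round(
        istats.percent_change(ip_p[:, 0].mean(), ip_p[:, 1].mean()), 4
    )
    summary["beta_shift_to_unity"] = float(
        istats.power_shift_to_unity(np.log(ip_p), alpha=config.alpha)
    )
    log("2-way ANOVAs done")

    # ---- stage: time (3-way) and early-session --------------------------
    time_of_block = {pf.block_id: pf.run_index for pf in pair_fits}
    if config.n_runs >= 2 or config.mode == "load":
        n_times = len(set(time_of_block.values()))
        if n_times >= 2:
            long_t = _records_long_with_time(ip_records, time_of_block)
            summary["ip_time_anova"] = _anova_dict(
                istats.rm_anova(
                    long_t, factors=["laser", "fiber", "time"],
                    blocks=["block"], block_nested_in="time",
                    transform=config.transform,
                )
            )

    early_pairs = [
        (psy.early_subset(b, config.k_per_offer),
         psy.early_subset(p, config.k_per_offer))
        for b, p in pairs
    ]
    early_fits, _, _ = fit_session_pairs(early_pairs, config.max_ip_ratio)
    if len(early_fits) >= 3:
        early_ip, early_sigma = sessions_to_records(early_fits)
        summary["early_ip_anova"] = _anova_dict(
            istats.rm_anova(early_ip, transform=config.transform))
        summary["early_sigma_anova"] = _anova_dict(istats.rm_anova(early_sigma))
    log("time/early ANOVAs done")

    # ---- stage: bootstrap threshold and strong-preference subset --------
    if config.run_bootstrap:
        blocked_sessions = [b for (b, _p) in pairs if not b.warmup]
        thr = istats.bootstrap_ip_threshold(
            blocked_sessions, n_boot=config.n_boot, alpha=config.alpha,
            seed=boot_seed,
        )
        summary["bootstrap_threshold"] = {
            "threshold_ratio": round(thr.threshold_ratio, 6),
            "alpha": thr.alpha, "n_boot": thr.n_boot, "seed": thr.seed,
            "n_skipped": thr.n_skipped,
        }
        strong_ip = istats.filter_records_by_ip(ip_records, thr.threshold_ratio)
        strong_sigma = istats.filter_records_by_ip(
            sigma_records, thr.threshold_ratio, ip_records)
        summary["n_pairs_strong"] = len(strong_ip)
        if len(strong_ip) >= 3:
            summary["strong_ip_anova"] = _anova_dict(
                istats.rm_anova(strong_ip, transform=config.transform))
            summary["strong_sigma_anova"] = _anova_dict(
                istats.rm_anova(strong_sigma))
        log(f"bootstrap threshold {thr.threshold_ratio:.3f}")

    curve_ip = istats.sliding_exclusion_curve(ip_records)
    curve_sigma = istats.sliding_exclusion_curve(sigma_records, ip_records)
    summary["sliding_curve_points"] = int(curve_ip.thresholds.size)

    # ---- stage: transitivity --------------------------------------------
    triplets = _build_triplets(pair_fits)
    distances: dict[str, list[float]] = {"blocked": [], "patent": []}
    if len(triplets) >= 3:
        rows = []
        for t in triplets:
            for cond in CONDITIONS:
                rows.append({
                    "block": t.triplet_id,
                    "laser": "on" if cond.endswith("on") else "off",
                    "fiber": "blocked" if cond.startswith("B") else "patent",
                    "value": trans.transitivity_stat(t, cond),
                })
        summary["transitivity_anova"] = _anova_dict(
            istats.rm_anova(pd.DataFrame(rows)))
        drows = []
        for t in triplets:
            for fiber, pfx in (("blocked", "B"), ("patent", "P")):
                d = trans.pair_distance(
                    trans.transitivity_coords(t, f"{pfx}-on"),
                    trans.transitivity_coords(t, f"{pfx}-off"),
                )
                distances[fiber].append(d)
                drows.append({"block": t.triplet_id, "fiber": fiber, "value": d})
        summary["distance_anova"] = _anova_dict(
            istats.rm_anova(pd.DataFrame(drows), factors=["fiber"],
                            blocks=["block"]))
        summary["n_triplets"] = len(triplets)
        log(f"{len(triplets)} triplets analyzed")

    # ---- stage: progressive ratio + consumption --------------------------
    pr_table = None
    if config.run_pr and config.mode == "simulate":
        pr_table, pr_logs = synth.simulate_pr_experiment(seed=pr_seed)
        summary["pr_breakpoint_anova"] = _anova_dict(
            istats.rm_anova(pr_table, response="breakpoint", factors=["fiber"],
                            blocks=["rat", "run"]))
        summary["pr_presses_anova"] = _anova_dict(
            istats.rm_anova(pr_table, response="presses", factors=["fiber"],
                            blocks=["rat", "run"]))
        ipi = {
            fiber: pr.ipi_distribution(
                [log_ for key, log_ in pr_logs.items() if key[2] == fiber])
            for fiber in ("blocked", "patent")
        }
        if ipi["blocked"].size and ipi["patent"].size:
            D, p = pr.ks_two_sample(ipi["blocked"], ipi["patent"])
            summary["ipi_ks"] = {"D": round(D, 6), "p": round(p, 6),
                                 "n_blocked": int(ipi["blocked"].size),
                                 "n_patent": int(ipi["patent"].size)}
        cons = synth.simulate_consumption(seed=cons_seed)
        means, cons_anova = pr.consumption_summary(cons)
        summary["consumption_means"] = {k: round(v, 4) for k, v in means.items()}
        summary["consumption_anova"] = _anova_dict(cons_anova)
        log("PR + consumption done")

    result = PipelineResult(
        config=config, n_pairs=len(pairs), n_excluded=n_excluded,
        n_failed=n_failed, ip_records=ip_records, sigma_records=sigma_records,
        summary=summary, triplets=triplets, pr_table=pr_table,
    )

    if config.outdir:
        _write_outputs(result, curve_ip, curve_sigma, pair_fits)
        log(f"outputs written to {config.outdir}")
    return result


def analyze_source_tables(
    ip_table: str | Path | None = None,
    slope_table: str | Path | None = None,
    triplet_table: str | Path | None = None,
    transform: str = "linear",
    alpha: float = 0.05,
) -> dict:
    """Recompute the ANOVA battery from per-replication condition tables.

    Runs on the compact 4-column (B-off, B-on, P-off, P-on) tables such
    experiments publish, with no simulation or trial-level data: the 2-way
    Laser x Fiber ANOVA, condition means, simple effects, confidence
    interval and shift-to-1:1 power for IPs; the same ANOVA for inverse
    slopes; and the transitivity + distance ANOVAs from a triplet table.
    Returns a summary dict in the same shape as :func:`run_pipeline`.
    """
    from .session_io import read_source_table

    summary: dict = {"config": {"mode": "tables", "transform": transform}}
    if ip_table is not None:
        records = read_source_table(ip_table, measure="ip")
        summary["n_pairs_kept"] = len(records)
        summary["ip_anova"] = _anova_dict(
            istats.rm_anova(records, transform=transform))
        summary["condition_means_ip"] = {
            k: round(v, 6) for k, v in istats.condition_means(records).items()
        }
        summary["simple_effects_ip"] = [
            dataclasses.asdict(r)
            for r in istats.simple_effects(records, transform=transform)
        ]
        arr = np.array([[r.values["P-off"], r.values["P-on"]] for r in records])
        ci = istats.mean_ci(arr[:, 0])
        summary["ci_patent_off_ip"] = [round(ci.mean, 6), round(ci.lower, 6),
                                       round(ci.upper, 6)]
        summary["percent_change_patent_ip"] = round(
            istats.percent_change(arr[:, 0].mean(), arr[:, 1].mean()), 4)
        summary["beta_shift_to_unity"] = float(
            istats.power_shift_to_unity(np.log(arr), alpha=alpha))
    if slope_table is not None:
        records = read_source_table(slope_table, measure="inverse_slope")
        summary["sigma_anova"] = _anova_dict(istats.rm_anova(records))
        summary["condition_means_sigma"] = {
            k: round(v, 6) for k, v in istats.condition_means(records).items()
        }
    if triplet_table is not None:
        triplets = trans.read_triplet_table(triplet_table)
        rows, drows = [], []
        for t in triplets:
            for cond in CONDITIONS:
                rows.append({
                    "block": t.triplet_id,
                    "laser": "on" if cond.endswith("on") else "off",
                    "fiber": "blocked" if cond.startswith("B") else "patent",
                    "value": trans.transitivity_stat(t, cond),
                })
            for fiber, pfx in (("blocked", "B"), ("patent", "P")):
                drows.append({
                    "block": t.triplet_id, "fiber": fiber,
                    "value": trans.pair_distance(
                        trans.transitivity_coords(t, f"{pfx}-on"),
                        trans.transitivity_coords(t, f"{pfx}-off")),
                })
        summary["n_triplets"] = len(triplets)
        summary["transitivity_anova"] = _anova_dict(
            istats.rm_anova(pd.DataFrame(rows)))
        summary["distance_anova"] = _anova_dict(
            istats.rm_anova(pd.DataFrame(drows), factors=["fiber"],
                            blocks=["block"]))
    return summary


def replicate_experiment_pvalues(
    n_experiments: int,
    seed: int,
    reps_per_offer_per_laser: int = 7,
    laser_log_ip_shift: float = 0.0,
    laser_ip_shrink: float = 0.0,
    patent_only: bool = True,
    transform: str = "linear",
) -> pd.DataFrame:
    """Replicate the full experiment chain and collect its key p-values.

    Each replicate simulates a complete rats x runs x pairs experiment,
    fits every session x laser state, applies orientation and the 6:1 IP
    cap, and runs the 2-way Laser x Fiber ANOVA plus the patent-fiber
    laser-on vs -off simple effect.  Any laser effect parameters apply to
    patent-fiber sessions only when ``patent_only`` (the optogenetic
    manipulation cannot act through a blocked fiber).  Returns one row per
    replicate: interaction_p, laser_p, fiber_p, simple_patent_p, n_pairs.

    Used for calibration (type-I error under the null) and power probes
    (e.g. a 10% multiplicative IP shift via
    ``laser_log_ip_shift=-ln(0.9)``).
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_experiments)
    for ss in seeds:
        exp_seed = int(ss.generate_state(1)[0] % (2**31))
        design = synth.ExperimentDesign()
        template = synth.SessionParams(
            true_log_ip=0.0, true_sigma=design.sigma_median,
            reps_per_offer_per_laser=reps_per_offer_per_laser,
        )
        rng = np.random.default_rng(exp_seed)
        sessions = synth.simulate_experiment(design, template, seed=rng,
                                             include_warmups=False)
        if laser_log_ip_shift or laser_ip_shrink:
            # re-simulate affected sessions with the laser effect switched on
            affected = []
            for s in sessions:
                if patent_only and s.fiber_state != "patent":
                    affected.append(s)
                    continue
                params = synth.SessionParams(
                    true_log_ip=s.true_log_ip, true_sigma=s.true_sigma,
                    reps_per_offer_per_laser=reps_per_offer_per_laser,
                    laser_log_ip_shift=laser_log_ip_shift,
                    laser_ip_shrink=laser_ip_shrink,
                )
                affected.append(synth.simulate_session(
                    params, rng, rat_id=s.rat_id, run_index=s.run_index,
                    pellet_pair=s.pellet_pair, fiber_state=s.fiber_state,
                    day_index=s.day_index,
                ))
            sessions = affected
        pairs, _ = build_session_pairs(sessions)
        pair_fits, _, _ = fit_session_pairs(pairs)
        if len(pair_fits) < 3:
            continue
        ip_records, _ = sessions_to_records(pair_fits)
        table = istats.rm_anova(ip_records, transform=transform)
        simple = istats.simple_effects(
            ip_records,
            comparisons=[("patent on-off", "P-on", "P-off")],
            transform="log",
        )[0]
        rows.append({
            "interaction_p": table.term("laser*fiber").p,
            "laser_p": table.term("laser").p,
            "fiber_p": table.term("fiber").p,
            "simple_patent_p": simple.p,
            "n_pairs": len(ip_records),
        })
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, curve_ip, curve_sigma, pair_fits) -> None:
    out = Path(result.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_source_table(result.ip_records, out / "ip_records.tsv")
    write_source_table(result.sigma_records, out / "sigma_records.tsv")
    rows = []
    for pf in pair_fits:
        for cond in CONDITIONS:
            f = pf.fits[cond]
            rows.append({
                "block": pf.block_id, "rat": pf.rat_id, "run": pf.run_index,
                "pair": ":".join(pf.pellet_pair), "condition": cond,
                "mu": f.mu_hat, "sigma": f.sigma_hat, "ip": f.ip,
                "n": f.n_trials_used, "converged": int(f.converged),
                "excluded": int(f.excluded),
            })
    pd.DataFrame(rows).to_csv(out / "fits.tsv", sep="\t", index=False,
                              float_format="%.6g")
    for name, curve in (("sliding_ip.tsv", curve_ip),
                        ("sliding_sigma.tsv", curve_sigma)):
        pd.DataFrame({
            "threshold": curve.thresholds,
            "mean_diff_blocked": curve.mean_diff["blocked"],
            "mean_diff_patent": curve.mean_diff["patent"],
            "n_blocked": curve.n_retained["blocked"],
            "n_patent": curve.n_retained["patent"],
        }).to_csv(out / name, sep="\t", index=False, float_format="%.6g")
    # IP-aligned pooled curves per condition (choice fraction and RT), plus
    # the shift-to-1:1 prediction from the laser-off fits
    edges = psy.default_bin_edges(width=result.config.bin_width)
    curve_cols = {"bin_center": (edges[:-1] + edges[1:]) / 2}
    for cond in CONDITIONS:
        contrib = []
        for pf in pair_fits:
            session = (pf.blocked_session if cond.startswith("B")
                       else pf.patent_session)
            if session is None:
                continue
            raw_fit = dataclasses.replace(pf.fits[cond], mu_hat=pf.raw_mu[cond])
            contrib.append((session, raw_fit))
        if not contrib:
            continue
        laser = "on" if cond.endswith("on") else "off"
        curve = psy.choice_curve_relative(contrib, edges, laser_filter=laser)
        curve_cols[f"{cond}_choice_frac"] = curve.choice_frac
        curve_cols[f"{cond}_mean_rt"] = curve.mean_rt
        curve_cols[f"{cond}_n"] = curve.n
        if cond.endswith("off"):
            pred = psy.shift_to_unity_prediction(contrib, edges,
                                                 laser_filter=laser)
            curve_cols[f"{cond}_unity_prediction"] = pred.choice_frac
    pd.DataFrame(curve_cols).to_csv(out / "aligned_curves.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    if result.triplets:
        trans.write_triplet_table(result.triplets, out / "triplets.tsv")
    if result.pr_table is not None:
        result.pr_table.to_csv(out / "pr_sessions.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "report.txt").write_text(generate_report(result.summary))


def generate_report(summary: dict) -> str:
    """Human-readable tabulation of every statistic with df and provenance."""
    lines = ["economic-choice inactivation analysis", "=" * 38, ""]
    if not summary:
        return "\n".join(lines + ["(no results)", ""])
    cfg = summary.get("config", {})
    lines.append(f"mode: {cfg.get('mode', '?')}   seed: {cfg.get('seed', '?')}")
    lines.append(
        f"pairs: {summary.get('n_pairs_kept', 0)} kept / "
        f"{summary.get('n_pairs', 0)} "
        f"({summary.get('n_pairs_excluded_ip', 0)} excluded by IP cap)"
    )
    lines.append("")
    for key in sorted(summary):
        if key.endswith("_anova"):
            a = summary[key]
            lines.append(f"[{key}]  transform={a['transform']}  "
                         f"blocks={','.join(map(str, a['blocks']))}")
            for term, row in a["terms"].items():
                lines.append(
                    f"  {term:<28} F({row['df_num']},{row['df_den']}) = "
                    f"{row['F']:8.3f}   p = {row['p']:.4g}"
                )
            lines.append("")
    if "condition_means_ip" in summary:
        means = summary["condition_means_ip"]
        lines.append("condition mean IPs: " + "  ".join(
            f"{c}={means[c]:.3f}" for c in CONDITIONS))
    if "condition_means_sigma" in summary:
        means = summary["condition_means_sigma"]
        lines.append("condition mean inverse slopes: " + "  ".join(
            f"{c}={means[c]:.3f}" for c in CONDITIONS))
    if "bootstrap_threshold" in summary:
        b = summary["bootstrap_threshold"]
        lines.append(
            f"bootstrap preference threshold: {b['threshold_ratio']:.3f}:1 "
            f"(alpha={b['alpha']}, n_boot={b['n_boot']}, seed={b['seed']}, "
            f"skipped fits={b['n_skipped']})"
        )
    if "beta_shift_to_unity" in summary:
        lines.append(
            f"type-II error vs shift-to-1:1 alternative: "
            f"beta = {summary['beta_shift_to_unity']:.3g}"
        )
    if "ipi_ks" in summary:
        k = summary["ipi_ks"]
        lines.append(
            f"IPI KS test: D({k['n_blocked']},{k['n_patent']}) = {k['D']:.3f}, "
            f"p = {k['p']:.3f}"
        )
    lines.append("")
    return "\n".join(lines)
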