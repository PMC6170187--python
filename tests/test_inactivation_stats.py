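"""ANOVA decomposition, simple effects, CIs, power, bootstrap, sliding curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from econochoice.errors import DesignError, InputError
from econochoice.inactivation_stats import (
    bootstrap_ip_threshold,
    condition_means,
    filter_records_by_ip,
    mean_ci,
    pair_summary_ip,
    pairs_to_long,
    percent_change,
    power_shift_to_unity,
    rm_anova,
    simple_effects,
    sliding_exclusion_curve,
)
from econochoice.session_io import CONDITIONS, SessionPairRecord
from econochoice.synthetic_data import SessionParams, simulate_session


def random_records(n, rng, measure="ip"):
    return [
        SessionPairRecord(i + 1, dict(zip(CONDITIONS, rng.uniform(0.8, 4.0, 4))),
                          measure)
        for i in range(n)
    ]


def projection_anova_oracle(df, response, factors, blocks):
    """Brute-force sequential SS from explicit dummy design matrices.

    Independent of the package path: builds full-dummy (overparameterized)
    matrices with pandas, accumulates them term by term, and takes each
    term's SS as the drop in residual SS from numpy lstsq fits.
    """
    y = df[response].to_numpy(dtype=float)
    n = len(y)

    def dummies(cols):
        d = pd.get_dummies(df[cols].astype(str).agg("|".join, axis=1))
        return d.to_numpy(dtype=float)

    terms = [(f, [f]) for f in factors]
    terms += [(f"block({b})", [b]) for b in blocks]
    from itertools import combinations

    for deg in range(2, len(factors) + 1):
        for combo in combinations(factors, deg):
            terms.append(("*".join(combo), list(combo)))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X = np.ones((n, 1))
    prev = rss(X)
    out = {}
    ranks = {}
    for name, cols in terms:
        X = np.hstack([X, dummies(cols)])
        cur = rss(X)
        out[name] = prev - cur
        ranks[name] = np.linalg.matrix_rank(X)
        prev = cur
    df_resid = n - np.linalg.matrix_rank(X)
    ms_resid = prev / df_resid
    result = {}
    rank_prev = 1
    for name, _ in terms:
        df_term = ranks[name] - rank_prev
        rank_prev = ranks[name]
        result[name] = (out[name] / df_term) / ms_resid
    return result, df_resid


class TestRmAnovaDf:
    @pytest.mark.parametrize(
        "n_blocks,factors,expected_df",
        [(50, 2, 147), (31, 2, 90), (15, 2, 42), (15, 1, 14)],
    )
    def test_crossed_layouts(self, n_blocks, factors, expected_df, rng):
        recs = random_records(n_blocks, rng)
        if factors == 2:
            table = rm_anova(recs)
        else:
            df = pairs_to_long(recs)
            df = df[df["laser"] == "off"]
            table = rm_anova(df, factors=["fiber"], blocks=["block"])
        assert table.df_den == expected_df

    def test_nested_time_layout(self, rng):
        rows = []
        for b in range(50):
            t = b % 3
            for laser in ("off", "on"):
                for fiber in ("blocked", "patent"):
                    rows.append({"block": b, "time": t, "laser": laser,
                                 "fiber": fiber, "value": rng.normal()})
        table = rm_anova(pd.DataFrame(rows), factors=["laser", "fiber", "time"],
                         blocks=["block"], block_nested_in="time")
        assert table.df_den == 141
        assert table.term("time").df_num == 2
        assert table.term("laser*fiber*time").df_num == 2

    def test_two_blocking_factors(self, rng):
        rows = [
            {"rat": r, "run": run, "fiber": f, "value": rng.normal()}
            for r in range(4) for run in range(2) for f in ("blocked", "patent")
        ]
        table = rm_anova(pd.DataFrame(rows), factors=["fiber"],
                         blocks=["rat", "run"])
        assert table.df_den == 10


class TestRmAnovaValues:
    def test_constant_response_zero_F(self):
        recs = [SessionPairRecord(i + 1, {c: 2.0 for c in CONDITIONS})
                for i in range(10)]
        table = rm_anova(recs)
        for term in ("laser", "fiber", "laser*fiber"):
            assert table.term(term).F == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_projection_oracle(self, rng):
        recs = random_records(8, rng)
        df = pairs_to_long(recs)
        table = rm_anova(df)
        oracle, df_resid = projection_anova_oracle(
            df, "value", ["laser", "fiber"], ["block"])
        assert table.df_den == df_resid
        for term in ("laser", "fiber", "laser*fiber", "block(block)"):
            assert table.term(term).F == pytest.approx(oracle[term], abs=1e-6)

    def test_nested_agrees_with_projection_oracle(self, rng):
        rows = []
        for b in range(9):
            t = b % 3
            for laser in ("off", "on"):
                for fiber in ("blocked", "patent"):
                    rows.append({"block": b, "time": t, "laser": laser,
                                 "fiber": fiber, "value": rng.normal()})
        df = pd.DataFrame(rows)
        table = rm_anova(df, factors=["laser", "fiber", "time"],
                         blocks=["block"], block_nested_in="time")
        # oracle with time entered before the nested blocks
        oracle, df_resid = projection_anova_oracle(
            df, "value", ["time", "laser", "fiber"], ["block"])
        assert table.df_den == df_resid
        for term in ("laser", "fiber", "time"):
            assert table.term(term).F == pytest.approx(oracle[term], abs=1e-6)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        recs = random_records(12, rng)
        df = pairs_to_long(recs)
        table = rm_anova(df)
        fit = ols("value ~ C(block) + C(laser) * C(fiber)", df).fit()
        sm_tab = anova_lm(fit, typ=2)
        for term, key in [("laser", "C(laser)"), ("fiber", "C(fiber)"),
                          ("laser*fiber", "C(laser):C(fiber)")]:
            assert table.term(term).F == pytest.approx(sm_tab.loc[key, "F"],
                                                       abs=1e-6)
            assert table.term(term).p == pytest.approx(
                sm_tab.loc[key, "PR(>F)"], abs=1e-9)

    def test_log_transform_mode_recorded_and_applied(self, rng):
        recs = random_records(10, rng)
        lin = rm_anova(recs, transform="linear")
        log = rm_anova(recs, transform="log")
        assert lin.response_transform == "linear"
        assert log.response_transform == "log"
        assert lin.term("laser").F != pytest.approx(log.term("laser").F)
        df = pairs_to_long(recs)
        df["value"] = np.log(df["value"])
        manual = rm_anova(df, transform="linear")
        assert log.term("laser").F == pytest.approx(manual.term("laser").F,
                                                    abs=1e-10)

    def test_unbalanced_rejected(self, rng):
        df = pairs_to_long(random_records(6, rng)).iloc[:-1]
        with pytest.raises(DesignError, match="unbalanced"):
            rm_anova(df)

    def test_duplicated_factor_rejected(self, rng):
        # a factor that copies another can never form a full balanced cross
        df = pairs_to_long(random_records(6, rng))
        df["copy"] = df["laser"]
        with pytest.raises(DesignError):
            rm_anova(df, factors=["laser", "copy"])

    def test_block_not_nested_rejected(self, rng):
        rows = []
        for b in range(6):
            for t in range(2):  # each block appears in both time levels
                for laser in ("off", "on"):
                    rows.append({"block": b, "time": t, "laser": laser,
                                 "value": rng.normal()})
        with pytest.raises(DesignError, match="nested"):
            rm_anova(pd.DataFrame(rows), factors=["laser", "time"],
                     blocks=["block"], block_nested_in="time")


class TestSimpleEffects:
    def _records_from_matrix(self, mat):
        return [SessionPairRecord(i + 1, dict(zip(CONDITIONS, row)))
                for i, row in enumerate(mat)]

    def test_identical_vectors_t0_p1(self, rng):
        vals = rng.uniform(1, 3, 10)
        mat = np.column_stack([vals] * 4)
        with pytest.warns(UserWarning):
            res = simple_effects(self._records_from_matrix(mat))
        for r in res:
            assert r.t == 0.0 and r.p == 1.0

    def test_constructed_t_equals_3(self):
        d = np.array([2, 2, 2, 2, 0, 0, 0, 0, 1.0])  # mean 1, sd 1, n 9
        base = np.full(9, 2.0)
        mat = np.column_stack([base, base + d, base, base])
        res = simple_effects(self._records_from_matrix(mat))
        on_vs_off_blocked = res[0]
        assert on_vs_off_blocked.t == pytest.approx(3.0, abs=1e-12)
        assert on_vs_off_blocked.df == 8

    def test_matches_exhaustive_sign_flip_permutation(self, rng):
        """Direction and approximate p agree with the exhaustive sign-flip
        test at n = 10."""
        import itertools

        a = rng.uniform(1, 3, 10)
        b = a + rng.normal(0.3, 0.4, 10)
        mat = np.column_stack([a, b, a, a])
        res = simple_effects(self._records_from_matrix(mat))[0]
        d = b - a
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert np.sign(t_obs) == np.sign(res.t)
        count = 0
        for signs in itertools.product((1, -1), repeat=10):
            ds = d * np.array(signs)
            t = ds.mean() / (ds.std(ddof=1) / np.sqrt(10))
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        p_perm = count / 2**10
        assert res.p == pytest.approx(p_perm, abs=0.06)


class TestMeanCI:
    def test_degenerate_all_equal(self):
        ci = mean_ci([3.0, 3.0, 3.0])
        assert (ci.mean, ci.lower, ci.upper) == (3.0, 3.0, 3.0)

    def test_closed_form_n4(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        ci = mean_ci(vals)
        se = np.std(vals, ddof=1) / 2
        t3 = stats.t.ppf(0.975, 3)
        assert ci.mean == pytest.approx(2.5)
        assert ci.lower == pytest.approx(2.5 - t3 * se, abs=1e-12)
        assert ci.upper == pytest.approx(2.5 + t3 * se, abs=1e-12)

    def test_nesting_of_levels(self, rng):
        vals = rng.normal(size=20)
        ci90 = mean_ci(vals, level=0.90)
        ci95 = mean_ci(vals, level=0.95)
        assert ci95.lower < ci90.lower < ci90.upper < ci95.upper

    def test_log_scale_is_geometric(self, rng):
        vals = rng.uniform(1, 4, 15)
        ci = mean_ci(vals, scale="log")
        assert ci.mean == pytest.approx(stats.gmean(vals))
        assert ci.scale == "log"


class TestPowerShiftToUnity:
    def test_null_effect_beta_is_one_minus_alpha(self, rng):
        on = rng.normal(0.0, 0.2, 30)
        paired = np.column_stack([np.zeros(30), on])  # off IPs already 1:1
        beta = power_shift_to_unity(paired, alpha=0.05)
        assert beta == pytest.approx(0.95, abs=0.01)

    def test_beta_decreases_with_n(self, rng):
        base_off = rng.normal(0.35, 0.01, 200) + 0.0
        base_on = base_off + rng.normal(0, 0.5, 200)
        betas = [
            power_shift_to_unity(np.column_stack([base_off[:n], base_on[:n]]))
            for n in (10, 30, 100, 200)
        ]
        assert all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))

    def test_matches_simulation_oracle(self, rng):
        """Noncentral-t beta agrees with brute-force simulated t-tests."""
        n, effect, sd = 12, 0.45, 0.5
        off = np.full(n, effect)
        on = off + rng.normal(0, sd, n)
        paired = np.column_stack([off, on])
        beta = power_shift_to_unity(paired)
        sd_obs = (off - on).std(ddof=1)
        sims = rng.normal(effect, sd_obs, size=(40000, n))
        t = sims.mean(1) / (sims.std(1, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        beta_sim = np.mean(np.abs(t) < tcrit)
        assert beta == pytest.approx(beta_sim, abs=0.02)

    def test_zero_variance_warns_beta_zero(self):
        paired = np.column_stack([np.full(5, 0.5), np.full(5, 0.2)])
        with pytest.warns(UserWarning):
            assert power_shift_to_unity(paired) == 0.0


class TestBootstrapThreshold:
    def _sessions(self, n, reps, sigma, seed0=0):
        return [
            simulate_session(SessionParams(
                true_log_ip=0.3 * ((i % 3) - 1), true_sigma=sigma,
                reps_per_offer_per_laser=reps, seed=seed0 + i))
            for i in range(n)
        ]

    def test_reproducible_bit_for_bit(self):
        sessions = self._sessions(4, 6, 0.7)
        a = bootstrap_ip_threshold(sessions, n_boot=25, seed=5)
        b = bootstrap_ip_threshold(sessions, n_boot=25, seed=5)
        assert a.threshold_ratio == b.threshold_ratio
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)

    def test_steep_sessions_threshold_near_unity(self):
        # near-deterministic choices with the IP pinned on an offered ratio:
        # split halves agree closely, so the threshold collapses toward 1
        sessions = [
            simulate_session(SessionParams(
                true_log_ip=0.0, true_sigma=0.2,
                reps_per_offer_per_laser=60, seed=40 + i))
            for i in range(4)
        ]
        res = bootstrap_ip_threshold(sessions, n_boot=40, seed=1)
        assert 1.0 <= res.threshold_ratio < 1.12

    def test_threshold_shrinks_with_more_trials(self):
        small = bootstrap_ip_threshold(self._sessions(4, 8, 0.7, 10),
                                       n_boot=60, seed=2)
        big = bootstrap_ip_threshold(self._sessions(4, 32, 0.7, 20),
                                     n_boot=60, seed=2)
        assert big.threshold_ratio < small.threshold_ratio


class TestSlidingCurve:
    def test_identical_records_flat_curve(self):
        vals = {"B-off": 2.0, "B-on": 2.2, "P-off": 2.0, "P-on": 2.2}
        recs = [SessionPairRecord(i + 1, dict(vals)) for i in range(10)]
        curve = sliding_exclusion_curve(recs)
        expected = np.log(2.2) - np.log(2.0)
        for fiber in ("blocked", "patent"):
            vals_ok = curve.mean_diff[fiber][~np.isnan(curve.mean_diff[fiber])]
            np.testing.assert_allclose(vals_ok, expected, atol=1e-12)

    def test_below_min_threshold_is_full_sample(self, rng):
        recs = random_records(20, rng)
        curve = sliding_exclusion_curve(recs)
        on = np.array([r.values["B-on"] for r in recs])
        off = np.array([r.values["B-off"] for r in recs])
        assert curve.mean_diff["blocked"][0] == pytest.approx(
            np.mean(np.log(on) - np.log(off)))
        assert curve.n_retained["blocked"][0] == 20

    def test_retained_counts_match_brute_force(self, rng):
        recs = random_records(30, rng)
        curve = sliding_exclusion_curve(recs)
        for i, thr in enumerate(curve.thresholds):
            for fiber, pfx in (("blocked", "B"), ("patent", "P")):
                brute = sum(
                    np.sqrt(r.values[f"{pfx}-on"] * r.values[f"{pfx}-off"]) > thr
                    for r in recs
                )
                assert curve.n_retained[fiber][i] == brute

    def test_pair_filter_threshold(self, rng):
        recs = random_records(30, rng)
        kept = filter_records_by_ip(recs, 1.45)
        assert all(pair_summary_ip(r) > 1.45 for r in kept)
        dropped = [r for r in recs if r not in kept]
        assert all(pair_summary_ip(r) <= 1.45 for r in dropped)


class TestPercentChange:
    @pytest.mark.parametrize("ref,alt,expected", [
        (2.0, 2.0, 0.0), (2.0, 2.1, 5.0), (1.649, 1.654, 0.30321),
    ])
    def test_values(self, ref, alt, expected):
        assert percent_change(ref, alt) == pytest.approx(expected, abs=1e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(InputError):
            percent_change(0.0, 1.0)


def test_condition_means(rng):
    recs = random_records(7, rng)
    means = condition_means(recs)
    for c in CONDITIONS:
        assert means[c] == pytest.approx(
            np.mean([r.values[c] for r in recs]))
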