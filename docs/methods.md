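# Methods

## The behavioral model

The package analyzes two-alternative economic choice in rodents: on each
trial an animal chooses between `qty_x` pellets of flavor *x* and `qty_y`
pellets of flavor *y*. Assuming linear indifference curves, behavior depends
on the offers only through their log quantity ratio, and the probability of
choosing *x* is modeled as a cumulative-normal (probit) function of it:

    P(choose x) = Phi((ln(qty_x / qty_y) - mu) / sigma)

Each session × laser state is fit independently by maximum likelihood on
offer-aggregated Bernoulli counts (Fisher scoring with a Nelder–Mead
fallback; forced 1:0 / 0:1 offers have no defined log ratio and are removed
before fitting). `exp(mu_hat)` estimates the indifference point (IP) — the
offer ratio, non-preferred : preferred, at which choice is at chance — and
`sigma_hat` the inverse slope of the psychometric curve, an index of
valuation noise. Fits are flagged non-converged rather than raised when the
data are degenerate: all choices identical, a single distinct offer, a
non-increasing choice curve, or separable data (`sigma_hat < 1e-3`; no
ridge penalty is applied by default so IPs are never silently shrunk).

Sessions whose preference lies outside the tested offer range cannot be
estimated reliably; a replication (blocked/patent session pair) is dropped
when any of its four condition IPs exceeds 6:1 after orientation. The
orientation (which flavor counts as preferred) is decided once per
replication from the mean of the four fitted `mu` values, so all four
condition IPs of a pair read non-preferred : preferred on the same side.
The cap is strict (`IP > 6` excludes; exactly 6 is retained).

## Repeated-measures ANOVA with blocking

The experimental unit is the replication: a blocked-fiber and a
patent-fiber session of the same rat and pellet pair on consecutive days,
each split into laser-on and laser-off trials. Treatments (Laser, Fiber and
their interaction) are tested against the within-replication residual with
replications as a categorical blocking factor. Because every block contains
every treatment cell exactly once, treatment contrasts are orthogonal to the
block space and the sum-of-squares type is immaterial.

`rm_anova` builds an explicit sum-to-zero design — factor mains, additive
block effects, then interactions — and decomposes the response by QR-based
sequential projection. This is implemented directly rather than through a
regression formula because the three-way layout (Laser × Fiber × Time, with
replications nested in Time) makes block indicators alias the Time main
effect: the block contrasts are first orthogonalized against the nesting
factor, restoring a full-rank design with the correct degrees of freedom
(e.g. 50 blocks in 3 time levels × 2 × 2 cells → 141 denominator df). All
terms, including Time, are tested against the residual. Unbalanced input is
an explicit error, never a silent fallback to another sum-of-squares type;
statsmodels OLS/`anova_lm` and a brute-force projection oracle verify the
decomposition in the test suite.

A calibration property worth knowing: the two laser conditions of one
fiber come from the *same day's session*, while the two fibers are
different days. Any between-day drift in preferences therefore enters the
Fiber contrast only, and the single pooled residual of this classic blocked
design then slightly over-covers the within-day terms (Laser and the
interaction test a touch conservatively, rejection ≈4% at nominal 5% under
the generator's default 0.1 log-unit day jitter) and under-covers Fiber
(≈7%). This is a property of the analysis design being reproduced — a
split-plot structure analyzed with one error stratum — not of the
implementation; a mixed-model treatment is deliberately out of scope.

Response transform: ANOVAs on IPs default to the untransformed (linear)
scale, matching arithmetic condition means such as the ones reported for
this design; an explicit `transform="log"` mode ships alongside, and every
table records which was used. Inverse-slope ANOVAs run on untransformed
`sigma_hat`. Simple effects are two-sided paired t-tests per block, the
four canonical comparisons (laser within each fiber, fiber within each
laser state) by default, with no multiple-testing adjustment (recorded as a
deliberate choice in the output metadata).

## Power against the shift-to-1:1 alternative

The type-II error reported for the paired comparison uses the noncentral t
distribution: the alternative keeps the observed laser-off log IPs and sets
every laser-on log IP to 0 (a 1:1 preference), so the hypothesized mean
difference is the mean laser-off log IP, while the difference SD is taken
from the observed pairs. At the design's scale (≈50 pairs, mean log IP
≈0.4–0.6, difference SD ≈0.25) the resulting beta is far below 1e-10: a
full collapse of preferences to indifference would essentially never be
missed. scipy's noncentral-t lower tail can underflow to NaN at extreme
noncentrality; it is then treated as 0.

## Split-half bootstrap preference threshold

To decide which preferences are distinguishable from 1:1 at all, each
blocked-fiber session's non-forced trials are repeatedly split at random
into two halves — stratified by offer and laser state so both halves stay
fittable — and the probit is fit to each half. The absolute difference of
the two log IPs is a draw from the "same preference measured twice" null;
the threshold is `exp` of its (1 − alpha) quantile, pooled over sessions
and resamples (default `n_boot = 1000`, alpha 0.05; resamples whose half-fits
fail are skipped and counted). Session pairs whose summary IP (geometric
mean of the four condition IPs — a symmetric per-pair summary, since no
per-pair statistic is canonical) falls at or below the threshold are removed
for the strong-preference re-analysis. The sliding exclusion curve
generalizes this: it sweeps the threshold over the observed per-fiber
ranking IPs (geometric mean of that fiber's on/off IPs) up to 90% removal
and tracks the mean laser-on − laser-off difference among survivors.

## Transitivity

For three flavors labeled A, B, C in decreasing preference, consistent
valuation implies `ln IP(A:C) = ln IP(A:B) + ln IP(B:C)`; the statistic
`T = ln IP_AC − ln IP_AB − ln IP_BC` measures the departure, and the
transitivity plane plots `y = ln IP_AC` against `x = ln IP_AB + ln IP_BC`
(identity line ⇔ T = 0; `y − x ≡ T`). Laser effects on the stability of the
value space are probed through Euclidean distances between a triplet's
laser-on and laser-off points, compared across fibers with a one-factor
blocked ANOVA.

Labeling choice: each triplet is labeled once and the labeling held fixed
across all four conditions. The reference is the geometric mean of the four
condition IPs per pair, **not** a single condition. Selecting "the largest
IP" from one condition inflates that condition's T by a selection bias that
is shared with conditions measured in the same sessions (the blocked pair)
but not with the other fiber's sessions — in null simulations this
manifested as a spurious fiber effect on T. A reference built symmetrically
from every condition makes the bias common to all four conditions, where it
cancels from every contrast. Intransitive-looking samples are labeled and
analyzed, never discarded.

## Progressive ratio

The press requirement follows the printed schedule 1, 5, 10, 15, 20, …,
advancing every three trials; the name "PR5" is not used to infer any other
ramp. A session ends at the 30-minute cap or after five minutes without a
press, and the breakpoint is the number of *completed* trials (pellets) at
termination — whether the trial in progress should count is unstated, so
the completed-trials convention is used. Presses between a pellet and the
next trial count toward the next requirement (no dead time is modeled).
Inter-press intervals pool successive press-time differences within
sessions (0.5 s histogram bins); the blocked/patent comparison uses the
two-sample Kolmogorov–Smirnov test with the asymptotic p-value (an exact
mode is available for samples under ~30). The consumption control reuses
the blocked ANOVA with rat and run as blocking factors (4 rats × 2 runs ×
2 fiber states → denominator df 10).

## The synthetic-data generator

The generator stands in for the animals and defines the conditions under
which the pipeline is validated:

- **Design**: 6 rats × 3 runs × 3 pellet pairs per run; each pair gets a
  warm-up day then blocked/patent test days, counterbalanced → 54
  replications before exclusions (the study scale).
- **Offers**: the 11-offer menu — nine graded ratios (1:6…6:1, or 1:4…8:1
  for strongly preferred pairs) plus the two forced offers. Offers are
  scheduled in shuffled blocks containing each offer × laser state once, so
  laser-on trials are exactly 50% and the early-session subset (first
  k = 4 of each offer × laser cell, 88 trials) is exactly the session's
  first 4 blocks.
- **Trials per session**: `reps_per_offer_per_laser = 10` → 220 trials,
  inside the task's typical 150–350 range.
- **Preferences**: per-rat latent log flavor values, SD 0.5, give pairwise
  |log IP| SD ≈ 0.71 — IPs spanning ~1:1 to beyond 6:1 with a few
  over-the-cap exclusions per experiment and a mean retained IP near 1.9,
  matching the reported IP range qualitatively. Latent IPs are transitive
  by construction (value differences); each session adds N(0, 0.1²) log-IP
  jitter (between-day drift is uncharacterized; 0.1 is a modeling choice).
- **Inverse slopes**: log-normal around a median of 0.85 (log-SD 0.2),
  bracketing the reported condition means of 0.83–0.84.
- **Laser effects**: `laser_ip_shrink` (λ) shrinks the log IP toward 0 on
  laser-on trials — the shift-toward-1:1 hypothesis — and
  `laser_sigma_scale` inflates sigma — the noisier-valuation hypothesis.
  λ = 0 and scale = 1 is the exact null. An additive `laser_log_ip_shift`
  toward 0 expresses an exact multiplicative IP change (e.g. ln(1/0.9) for
  a uniform 10% shift), which λ alone cannot.
- **Reaction times**: base 1.2 s + Gaussian noise (SD 0.25 s), optional
  difficulty term proportional to |log ratio − mu|; clipped to [0.05, 5] s.
  This only exercises the RT curve machinery and models no decision theory.
- **Progressive ratio**: while engaged, presses form a renewal process with
  exponential intervals (default hazard 0.5 Hz, optional satiety decay per
  pellet, off by default); the animal disengages for good at a
  session-specific engagement time (default mean 700 s, log-normal
  day-to-day variability). The patent fiber shortens engagement (factor
  0.45) but leaves press tempo untouched, so breakpoints drop while the
  inter-press-interval distributions stay matched — the dissociation the
  positive control is designed to show. Calibrated to the task's press
  counts (a few hundred presses and breakpoints in the teens-to-twenties
  per 30-min session).

What the generator does **not** emulate: learning or satiety within choice
sessions, nosepoke aborts, sequential choice dependencies, RT–value
coupling beyond the optional difficulty term, and any drift in inverse
slope. Passing tests therefore demonstrate that the analysis chain is
correct and calibrated under the assumed generative model, not that the
model captures every feature of real behavioral data.

## Validation results computed by the suite

- Parameter recovery: the probit fit matches a dense grid-search likelihood
  oracle and statsmodels' trial-level probit (reparameterized) to 4
  decimals; median |log-IP error| across 100 sessions at 20 reps per offer
  per laser state sits at ≈0.05 — which is the Cramér–Rao bound for this
  menu at the calibrated sigma, so no estimator would do materially better.
- Type-I calibration: 500 complete null experiments (simulate → fit →
  exclude → ANOVA) reject the Laser × Fiber interaction at ≈4–5%,
  within a ±2% band of the nominal 5% (slightly conservative for the
  reason given in the ANOVA calibration note above).
- Power: a uniform 10% IP shift confined to patent/laser-on conditions is
  detected (interaction or patent simple effect, p < 0.05) in a majority of
  replicate experiments; beta for the shift-to-1:1 alternative is < 1e-10.
- Design identities: denominator df 147 / 90 / 141 / 42 / 14 / 10 for the
  six canonical layouts, exactly.

Problem sizes used by the heavier checks (500 replicates at 7 reps per
offer per laser for calibration; 30 replicates at the full 10 for power;
bootstrap demonstrations at n_boot 200) were fixed as single-CPU-friendly
analysis choices; library defaults remain at study scale.

## Reproducing published statistics from source tables

`read_source_table` ingests per-replication 4-column condition tables
(B-off, B-on, P-off, P-on, columns by position) and the ANOVA battery,
condition means, simple effects and power computations run on them
directly, with the linear/log response switch resolved by whichever mode
matches a published table's F statistics. The original per-session tables
are not redistributed with this package; the corresponding acceptance tests
fail with a pointer to `data/source_tables/` until the files
(`ip_pairs.tsv`, `inverse_slope_pairs.tsv`, `triplet_ips.tsv`) are supplied
by the user.

## Numerical and interface conventions

Natural logarithms throughout. Trial logs are TSV with a `#key=value`
header block (columns trial, qty_x, qty_y, laser 0/1, choice x/y, rt);
source tables accept tab or multi-space delimiters, columns by position;
forced trials are stored like any other trial and downstream stages decide
inclusion. All randomness flows from one named seed via spawned
`SeedSequence` streams; identical config + seed reproduces outputs
byte-for-byte. Aligned-curve bins default to width 0.5 on the relative
natural-log scale with a bin centered on 0 (the original display bins are
unpublished; width is configurable). Empty curve bins are reported as
missing, not zero.
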