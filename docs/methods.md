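# Methods

## Scope and intent

`worklistsim` quantifies how the ordering policy of a single
chest-radiograph reporting queue changes report turnaround time (RTAT),
overall and per finding class, when an imperfect multi-label classifier
supplies the ordering. The classifier itself is out of scope: it enters
only through per-finding (TPR, FPR) operating points or AUC values. No
image data, network inference, or PACS integration is involved.

## Simulation model

Each simulated day is an independent replication of 24 h of clinical
routine. Time is continuous minutes from the day's start; hour of day is
`floor(t/60) mod 24`.

**Arrivals.** Exam acquisition times accumulate sampled inter-arrival
gaps starting at minute 0, stopping at minute 1440. Gaps are drawn from
a discrete hour-of-day-conditioned distribution (below), conditioned on
the hour of the previous event.

**Labels and predictions.** Each exam carries independent Bernoulli
findings at the catalog prevalences (stored as exact fractions,
positives/600). Predictions flip per-finding coins at TPR (truly
present) or FPR (truly absent), independently across findings and exams.
Urgency is the minimum urgency rank among positive flags; an exam with
no flags falls to the normal tier (rank K+1 = 9).

**Service.** A single virtual radiologist finalizes reports at times
`c0 + Σ gaps`, gaps drawn from the reporting distribution at the hour of
the previous completion. Each completion removes the *current* head of
the worklist — the reading of a specific exam is not pinned at service
start, which matches measuring reporting speed as deltas between report
finalization timestamps. If a completion would fire on an empty list the
radiologist idles and the next completion is scheduled one fresh gap
after the next arrival; the gap distribution already embeds pauses and
interruptions, so no separate idle model exists. Arrivals stop at minute
1440 but service continues until the list is empty, so each day's
backlog drains to zero and days are exchangeable.

**Event ordering.** Events are processed in time order; when an arrival
and a completion coincide, the completion is processed first (otherwise
a just-acquired top-priority exam could be reported at its own
acquisition instant, giving a zero turnaround). Under `prio_maxwait`,
overdue promotion runs at every event before the head is popped; between
events nothing can be selected, so event-driven promotion is exact.

**Randomness.** Four named streams — arrival, labels, classifier,
service — are seeded independently, with per-day substreams derived via
`SeedSequence([stream_seed, day_index])`. A single master seed expands
to the four stream seeds through `SeedSequence(master).generate_state(4)`
masked to 31 bits. Strategies sharing seeds consume the arrival, label
and service streams identically (the classifier stream is consumed only
by prediction-based strategies), so arrival times and the per-day
multiset of completion times are policy-invariant: paired contrasts
isolate the policy effect (common random numbers).

## Worklist semantics

The queue is ordered by (priority tier ascending, insertion order) —
stable priority insertion. Tiers: 0 = promoted, 1..8 = finding urgency,
9 = normal. FIFO is the degenerate case of a uniform tier.
`promote_overdue(now, t_max)` lifts every exam with `now − acquisition >
t_max` into tier 0; promoted exams order among themselves by acquisition
time (oldest first) — "move to the front" is ambiguous for several
promoted exams, and oldest-first is the natural aging rule. Promotion is
idempotent at fixed `now`, and an exam whose report completes is never
returned to the list. The engine is verified against a brute-force
reference that re-sorts the full pending set with a stable sort at every
step, including exhaustively over all arrival orders of five
equal-priority exams.

## Timing distributions

Both gap distributions are 24 × 150 count matrices: 1-minute bins with
integer edges on support (0, 150]; bin *j* is represented by its upper
edge *j* + 1 min when sampling. When built from timestamps, each
consecutive pair contributes one delta attributed to the hour of the
earlier event, and deltas above 2 h 30 min are discarded as outliers
(they reflect scanner downtime or overnight breaks, not the processes
being modelled). An hour with no observations falls back to the pooled
all-hours distribution when sampled, avoiding a dead clock.

The synthetic generator discretizes a lognormal (or gamma) to these
bins, truncated and renormalized to the support, and draws multinomial
counts (200 000 per hour row) so synthetic histograms carry realistic
finite-sample granularity. Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| day_mean_arrival_delta | 12 min | mean acquisition gap, 07–19 h |
| night_mean_arrival_delta | 45 min | mean acquisition gap otherwise |
| arrival_dispersion | 1.0 | lognormal σ (gamma: CV) of arrival gaps |
| reporting_mean_delta | 12.390625 min | mean reporting gap, all hours |
| reporting_dispersion | 1.0 | spread of reporting gaps |
| distribution_family | lognormal | gap family |

This yields ≈76 exams/day (≈60 by day, ≈16 by night). The heavy
lognormal tail plus the 150-min truncation make the *effective* night
arrival mean ≈36 min; all moments quoted for histograms are
post-truncation.

**Calibration.** The default reporting mean is not chosen directly: it
is the output of `calibrate_reporting_mean`, which bisects on the
reporting mean until a FIFO run (fixed evaluation seed 1, 500 days,
tolerance 1 % for the frozen default; the function's defaults are 200
days and the 10 % tolerance of its contract) reproduces a target
grand-mean RTAT of 80 min — the average turnaround measured in the
hospital regime the defaults emulate. The frozen value 12.390625 min
gives FIFO grand means of 77–83 min across independent seeds at 500
days. The response is steep near saturation (the daytime queue is
near-critical at ρ ≈ 1), which is exactly what stretches a
few-minute read into an 80-minute average; bisection is robust because
the response is monotone in the reporting mean.

## Classifier surrogates

Bundled operating points: *lowFPR* (FPR 0.05 everywhere; TPR 0.82, 0.71,
0.86, 0.75, 0.61, 0.75, 0.51, 0.51 in urgency order) and *lowFNR* (TPR
0.95 everywhere; FPR 0.20, 0.24, 0.21, 0.27, 0.39, 0.18, 0.72, 0.78).
For sweeps, each finding's ROC is the equal-variance binormal curve
`TPR = Φ(μ + Φ⁻¹(FPR))`, `μ = √2·Φ⁻¹(AUC)` — the standard minimal
one-parameter family through a given AUC. The default AUCs (0.965,
0.940, 0.973, 0.949, 0.913, 0.949, 0.881, 0.881) are backed out of the
lowFPR operating point by inverting that relation, keeping sweeps
anchored to the same classifier the presets describe; re-sampling the
default curves at FPR 0.05 returns the preset exactly. The sweep applies
one common FPR to every finding, consistent with the presets' common-FPR
convention. Classifier inference latency is treated as zero (tens to
hundreds of milliseconds against minute-scale queueing).

## Statistics

Per-class summaries count an exam in every class whose *true* flag is
set; label-free exams form the normal class, so classes overlap and
their counts sum to more than the number of exams. Welch's t-test is
implemented from the defining formulas (statistic, Welch–Satterthwaite
degrees of freedom, two-sided p from the t distribution) and is verified
against an independent statistical library to 1e-10 relative tolerance,
plus a null-calibration check that its p-values are uniform. Tests are
per class at α = 0.05 without multiplicity correction, matching
per-finding reporting practice.

## What the synthetic generator does and does not show

The generator reproduces the qualitative structure of real worklist
timing — day/night load asymmetry, heavy-tailed reporting gaps, a
near-saturated daytime queue calibrated to an 80-min FIFO average — but
not any particular hospital's empirical histograms. Consequently the
package's headline comparisons are structural: FIFO class-blindness,
the mean-vs-max trade-off of prioritization, the universal max-RTAT
reduction under the waiting-time cap, strict urgency ordering under a
perfect classifier, and the U-shaped FPR sweep with an interior optimum.
Absolute per-class numbers shift with the timing model; with the
defaults the simulated optimum of the sweep lies at FPR ≈ 0.1–0.2 rather
than 0.05, because the binormal surrogate at these AUCs is more
favorable at moderate FPR than the empirical curves it stands in for.
Other idealizations: findings co-occur independently (under the default
prevalences this gives ≈15 % normal exams, below the ≈31 % a correlated
real cohort shows — co-occurrence is simply not modelled); days are
independent with a nightly drain-to-zero; one reader, no shift
structure beyond the hour-conditioned gaps; severity grades and referral
priorities are absent.

## Numerical and design choices

* Deltas are discrete minutes (1-min bins); all times else are float
  minutes. Serialized times round to 3 decimals for stable CSV diffs.
* `t_max` for `prio_maxwait` has no canonical value; the package
  default is 360 min (6 h), chosen as a round bound well above the
  calibrated ~80-min average but far below the >1000-min worst cases it
  is meant to cut. It is a required, explicit config parameter.
* Degenerate inputs fail loudly: fewer than two timestamps, non-monotone
  timestamps, an entirely empty histogram, rates outside [0, 1],
  duplicate exam ids, an unreachable calibration target (reported with
  its bracket response).
* Problem sizes in the test suite: strategy comparisons use 1350 days
  (~1.05 × 10⁵ exams) per strategy; the acceptance script uses 500 days
  for the FIFO grand mean. At ~10 µs/exam the full suite runs in well
  under a minute.
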