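# Methods

This note documents the models implemented in `signalgame`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not capture.

## Signal space

Pad coordinates are normalized to the unit square with `v = 0` at the
**bottom** edge.  This orientation is forced by the colorspace: the
red corner (a* = +128) must be bottom-left, and the conditional lightness
rule (L* = 75 on the bottom half, 120 − 90·v above) is only continuous at
mid-pad — and only keeps L* within [30, 100] — when v is measured
bottom-up.  Both chroma axes are normalized by their own pad dimension,
which is the dimensionally consistent reading and identical on a square
pad.

CIELAB → sRGB rendering uses the standard D65 / 2° observer transform
(scikit-image) with per-channel clamping to [0, 1].  Much of the pad is
far outside the sRGB gamut (e.g. the red corner at L*=75, a*=b*=128);
clamping is the simplest deterministic gamut policy and the choice is
isolated in `lab_to_rgb` should a perceptual gamut mapping ever be
wanted.  No ΔE-based model of human color discrimination is attempted.

## Game engine

- Targets are drawn uniformly at random each round, with no balancing and
  no minimum gap between repeats.
- The winning criterion ("3 of the last 4 occurrences correct, for all
  six referents") is evaluated incrementally from an append-only ledger,
  and only immediately after a correct guess.  A referent with fewer than
  four occurrences is never established, so no dyad can win before 24
  main rounds.  Practice outcomes never enter the winning ledger.
- A receiver timeout (no guess) is recorded as an **incorrect** outcome.
  Treating it as a non-event would let a dyad protect an established
  referent by withholding guesses, which contradicts the design's
  explicit possibility of negative progress.
- Round wall time is modeled as a lognormal response latency (log-mean
  2.0, log-SD 0.45 → median ≈ 7.4 s, mean ≈ 8.2 s), truncated at the
  round cap (90 s practice, 30 s main), plus 2 s of feedback.  No claim
  is made about the shape of human latencies beyond right-skew with a
  hard cap; the parameters give hour-long games of roughly 350 rounds,
  in the range the paradigm produces.  The 1 s hold-to-send dwell is
  treated as part of response latency.
- The engine emits one signal per round.  Logs originating elsewhere may
  contain several sends per round; the metrics layer then uses the last
  send before the guess (the signal the guess responded to), switchable
  to first-send.
- All randomness flows from one master seed through named substreams
  (scheduler, sender, receiver, latency), so every log, cohort and
  pipeline output is bit-reproducible.

## Synthetic dyads

The agents are not models of particular humans; they are the simplest
mechanisms that generate the statistical structure the analysis assumes,
so that every metric and model in the package can be exercised — and its
estimators validated — without human data.

**Sender.**  With color feedback, productions are iconic-anchor points
plus isotropic Gaussian motor noise (`sigma_motor = 0.03` pad units,
rejection-truncated to the square).  Anchors are config-overridable and
default to well-separated positions whose colors are canonical for the
six referents (red for strawberry, yellow for banana, …), standing in
for the qualitative outcome of a color-association norming survey; all
sit ≥ 0.08 from every edge so truncation is negligible.  Without color
feedback there is nothing to anchor to: the sender keeps an arbitrary
per-referent convention that random-walks by `sigma_drift = 0.10` per
reuse and is forgotten (resampled uniformly) with probability
`p_forget = 0.10`.  Successive same-referent distances are therefore
≈ `sigma_motor·√π` ≈ 0.053 in color conditions versus ≈ 0.16 in the dot
condition — the production-stability gap the stability analyses measure.

**Receiver.**  Guesses maximize a mixture of exemplar similarity and an
iconic prior: score(r) = (1−λ)·maxₑ exp(−‖x−e‖²/τ²) + λ·prior(r), with a
lapse rate `epsilon_guess = 0.05` and uniform tie-breaking.  Exemplars
are (view, referent) feedback pairs, capped at `memory_capacity = 4` per
referent (oldest evicted) and stored as *fuzzy copies*: encoding noise of
SD `sigma_memory_pad = 0.18` pad units (dot views) or
`sigma_memory_lab = 20` CIELAB units (color views) is added at storage.
The prior — available only when the view *is* a color, weight
`lambda_prior = 0.6` — is the Gaussian similarity (bandwidth
`tau_lab = 45`) between the seen color and each referent's anchor color;
it requires no memory at all.

The encoding noise is the model's memory-load bottleneck and the crux of
the condition structure: a receiver who can lean on the iconic prior
(High) is nearly immune to it, a receiver facing *stable* arbitrary
signals (One-sided) is partially protected because fresh exemplars keep
arriving near the same spot, and a receiver facing drifting arbitrary
signals (Low) gets little usable signal from memory at all.  With the
defaults above, simulated cohorts reproduce the qualitative pattern the
paradigm is known for: High dyads win in minutes; One-sided dyads are
markedly more stable in production and faster than Low but struggle to
hold all six referents simultaneously; Low dyads rarely win within the
hour.  These defaults were fixed once, on the grounds above, during
generator design.

What the generator does **not** emulate: senders exploring the pad before
the first send, audience design (senders reacting to receiver errors),
role asymmetries in motivation or fatigue, and any fitting of agent
parameters to real logs (deliberately out of scope).  Passing tests
therefore show that the pipeline's measures and estimators behave
correctly on data with the assumed structure — not that humans have these
parameters.

## Metrics

- The established-count series applies the 3-of-4 criterion to all rounds
  in scope up to each round.  The success index includes practice rounds
  and dummy rounds by default; both are toggleable, giving the four
  sensitivity variants.
- Dummy rounds for won games: floor((3600 − total) / mean length of the
  final four rounds).  The floor is used because a dyad cannot play a
  partial round; round length includes the 2 s feedback because elapsed
  wall time is what fills the hour.
- A referent needs ≥ 4 occurrences to be established, in the index as in
  the game; with exactly 3 all-correct occurrences it does not count.
- Accuracy defaults to main rounds only, with an all-rounds variant;
  timeouts count as incorrect.  Signal-set-size proportions pool rounds
  within condition and never include dummy rounds.
- All metrics are pure functions of the log; recomputation is
  bit-identical.

## Statistical models

- Per-dyad contrasts (success index, accuracy, game length) are OLS with
  treatment coding; the reference level is configurable and defaults to
  Low iconicity.
- The stability model is `distance ~ condition + (1|dyad) + (1|referent)`
  fitted by REML with Satterthwaite degrees of freedom (lmerTest).  Both
  marginal and conditional r² are reported (variance-partition form),
  since a single unlabeled r² is ambiguous for mixed models.
- The round-by-round pair is fitted with glmmTMB: binomial on
  1{s > 0} and negative binomial (nbinom2, ML dispersion) on the
  positive counts, each with scaled-round × condition interactions and
  dyad random intercepts.  Round number is z-scored over the full pooled
  table.  Wald z inference; r² is not reported for the GLMMs.
- Convergence problems (singular fits, non-PD Hessians) are surfaced as
  warnings and recorded in the returned table's `attrs`, never hidden.
  Note that near-separation — e.g. a condition whose dyads almost always
  have some referent established — produces the huge binomial
  coefficients characteristic of such data; they are reported as fitted.
- The R bridge writes the data to a temporary CSV, runs a self-contained
  script under `Rscript --vanilla`, and reads back JSON; an R error
  aborts with the captured stderr.

## Problem sizes and numerical checks

The test suite validates the ledger against an exhaustive re-scan oracle
on 1,000 random 100-round sequences, checks the success-index bounds on
10,000 short random engine sessions, recovers `sigma_motor` within 10%
from 100 dyads × 100 rounds via the method-of-moments estimator
σ̂ = mean distance ∕ √π (the closed form is itself verified by Monte
Carlo), and checks the condition ordering of the success index and
stability means over 50 cohorts of 6 dyads per condition — a desk-scale
replicate chosen because 300 dyads per condition already pin the means
far more tightly than the orderings require.  The acceptance script uses
the full 22/22/24 study design for its cohort.  Statistical calibration
(type-I error of the High-vs-Low contrast ≈ 5%) uses 1,000 null
simulations at the study's group sizes.

## Known limitations

- The agents' similarity kernels and noise models are convenient, not
  fitted; parameter recovery is demonstrated only for `sigma_motor`.
- Mixed-model fits require an R installation with lme4/lmerTest and
  glmmTMB on PATH; the OLS layer is pure Python.
- The deposited-data adapter requires the user to supply the column
  mapping; it does not guess schemas, and it does not download anything.
- CSV logs do not carry dyad-level metadata (`meta`); the JSONL dialect
  is the canonical, lossless one.
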