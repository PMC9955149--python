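# Methods

## Model and procedure

The package classifies tabular clinical records into four classes
(1 normal, 2 type 1, 3 type 2, 4 gestational diabetes) with a sequential
cascade of three binary multilayer perceptrons.  The pipeline is

1. **Max-normalization** — each column divided by its maximum.  This
   assumes non-negative measurements; negative values and all-zero columns
   are rejected rather than silently handled.  The default pipeline
   normalizes the full table before splitting ("literal" mode); a
   leakage-safe variant (`normalize_with`) re-applies training-set maxima
   to test data and clips at 1.
2. **Discretization** — levels 1–4 at cut points 0.25/0.5/0.75.  The
   interior boundaries are assigned to the upper bin (half-open, left-closed
   bins; top bin closed at 1), the only convention that partitions [0, 1]
   exactly while keeping the stated cut points.
3. **Attribute selection** — the 16-cell (level × class) co-occurrence odds
   described in the README, smoothed by an additive constant *s* on
   numerator and denominator.  *s* = 1 by default: raw ratios are undefined
   whenever a (level, class) cell is class-pure, and additive smoothing
   removes the undefined cells while preserving the ranking of well-defined
   ones.  *s* = 0 is available for raw comparisons (+inf sorts highest).
   Ties in strength discard the later column.  The discard count defaults
   to 2.  The per-(attribute, class) weight uses the same presence/absence
   odds evaluated at the attribute's modal level within the class; this is
   the package's operationalization of a class-association weight whose
   printed source formula is not computable as stated.
4. **80/20 split** — uniform random partition, |train| = ⌊0.8·n + 0.5⌋
   (round-half-up; only the percentage is prescribed, the rounding rule is
   ours).  Stratified splitting is optional and applies the same rounding
   per class, protecting small minority classes.
5. **Cascade training** — stage *k* ∈ {1,2,3} is trained on the two-class
   subset {normal, class k+1} with one-hot `[normal, disease]` targets; all
   normal rows participate in every stage.  Prediction short-circuits at
   the first disease vote; ties go to normal (the conservative choice that
   defers to later stages).  The gestational stage runs only for eligible
   records; absent an eligibility rule all records are eligible and a
   warning is logged.
6. **Evaluation** — one-vs-rest confusion counts per class.  One-vs-rest is
   used because it is the only reduction that yields sensitivity,
   specificity *and* accuracy per class.  Undefined rates (0/0) are NaN
   with an explicit flag, never coerced to 0.  MAPE is computed on numeric
   class codes by default (codes 1–4 keep the denominator nonzero); the
   epoch curve retrains the cascade from the same seed under growing
   `max_epochs` caps.

## Networks and trainers

Hidden layers use the logistic sigmoid (tanh optional), outputs sigmoid
under MSE so they are comparable to one-hot targets; the no-prop mode
switches the output layer to linear because it is solved in closed form.
Weights initialize uniformly in [−r, r], r = 1/√fan-in, from a seeded
generator.  The default hidden stack is (50, 25, 5); a `deep` preset
(50, 25, 10, 5, 3) exposes a five-hidden-layer configuration.  Input width
equals the number of retained attributes (6 after discard-2 on the standard
bench, 8 with selection disabled); output width is always 2.

**SCG** follows Møller's algorithm: σ₀ = 1e−4 scales the finite-difference
Hessian-vector probe, λ₀ = 1e−6 seeds the Levenberg-style damping, raised
when a step is rejected and quartered when the quadratic comparison
parameter exceeds 0.75.  Accepted steps strictly reduce the batch MSE, so
the recorded error trace is non-increasing.  Stopping: goal MSE (default
1e−3, the order of the best stage errors reported for this architecture
class), max 250 epochs, a vanishing gradient, or 25 iterations without
improvement.  A λ overflow raises a diagnostic error instead of looping.

**No-prop** freezes the hidden stack at initialization and solves the
output layer by ridge regression (default ridge 1e−6) on the final hidden
representation; a singular system without ridge raises an error advising
ridge > 0.  Both trainers, and therefore the whole cascade, are
bit-reproducible under a fixed seed; the pipeline fans one global seed out
to per-stage seeds through `numpy.random.SeedSequence`.

Training a deep sigmoid stack by any batch optimizer can stall on a
plateau (near-zero gradients with outputs pinned at 0.5).  `cascade_train`
therefore allows up to 5 seeded re-initializations per stage, keeping the
first run that reaches the goal MSE or else the best final error.  The
restart seeds derive deterministically from the global seed, so the
procedure remains reproducible.

## Synthetic bench

The generator draws class-conditional Gaussians truncated at zero
(`scipy.stats.truncnorm`), matching the non-negativity the normalizer
assumes.  The standard bench (`gaussian_spec`) uses **marker-style**
informative attributes: attribute *i* is elevated by `separation`·σ
(default 4σ) in exactly one disease class — assigned round-robin over
classes 2, 3, 4 — and sits at baseline elsewhere; noise attributes share
one distribution across classes.  This structure is what the sequential
cascade implicitly assumes: each subtype shows its own characteristic
deviations while looking normal on the markers of the others.  Default
conditions: 200 rows per class (n = 800, the scale of the reference
cohorts), 6 informative + 2 noise attributes, σ = 1, baseline mean 2σ.

The `pid_like` preset instead gives all eight Pima-style attributes
overlapping clinical-scale class profiles; its means and SDs are hand-typed
plausible values for demonstration, not statistics of any real cohort.

What the generator does **not** emulate: missing-value patterns (the
zero-coded missingness of real Pima data), correlated attributes, skewed or
heavy-tailed marginals, class imbalance, or label noise.  Passing the
recovery tests therefore shows the pipeline's machinery is correct and that
the strength statistic separates informative from uninformative attributes
under its own assumptions — it does not certify clinical accuracy on real
cohorts, whose headline rates depend on data and preprocessing outside this
package's scope.

## Numerical choices and degenerate inputs

- Discretization boundary ties: interior cut points belong to the upper
  bin; 0 → level 1, 1 → level 4.
- Strength with *s* = 0: cells 0/0 are reported as 0 (no co-occurrence
  evidence), n/0 as +inf.
- Modal-level ties in the attribute weight resolve to the lowest level.
- A stage with no disease rows is left untrained, warned about, and
  skipped at prediction; a table with no normal rows is an error.
- Gradient checks hold analytic backprop to ≤ 1e−5 relative error against
  central differences; on a convex quadratic SCG reaches the closed-form
  least-squares optimum.
- Model archives are JSON with a format tag and version; JSON floats
  round-trip exactly, so save/load reproduces weights bit for bit.

## Problem sizes

The test suite and examples run the bench at 200 rows per class with
hidden stacks between (4,) and the default (50, 25, 5), and the
selection-recovery experiment over 20 seeds; all complete in seconds on a
single CPU while exercising every stage at the bench's standard conditions.

## Known limitations

- The cascade's accuracy degrades gracefully but inherently when one
  subtype mimics another's markers; no rejection or calibration option is
  provided by design.
- The eligibility rule for the gestational stage must come from the data
  owner (e.g. a pregnancy flag); the package only gates on it.
- MAPE on class codes depends on the arbitrary numeric coding; the
  code-based default is kept for comparability, and the epoch-curve harness
  records it only for the cascade itself, not for non-iterative baselines.
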