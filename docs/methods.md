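# Methods

## Fate models

Two data-driven maps from signaling-protein activities `x_1..x_n` (strictly
positive, arbitrary units) to a fate score `P` (here: the fraction of
apoptotic cells):

- linear: `P = β0 + Σ_i β_i x_i` (the intercept is fitted by default; a
  flag zeroes it, in which case predictions omit the fitted offset);
- power-law: `P = e^(β0) · Π_i x_i^(β_i) + ε`, fitted in log space as
  `ln(P − ε) = β0 + Σ_i β_i ln(x_i)`.

Both are estimated by partial least squares regression (NIPALS, through
scikit-learn), which tolerates the strong collinearity of phosphoproteomic
predictors. Predictors and responses are mean-centered and scaled to unit
variance before the fit; reported coefficients are mapped back to the
original scale and stored with the model, so a serialized model reloads
exactly. With the full component count the fit coincides with ordinary
least squares (regression-tested to 1e-8); with fewer components it
shrinks along low-covariance directions.

Assumptions worth keeping in mind: the power-law form is monotone in each
protein (exponent sign fixes direction), models interactions only through
the product structure, and requires positive signals and `ε < min P`. A
constant response short-circuits to an intercept-only model, since PLS
weights are undefined at zero response variance.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-6 | power-law offset; validated against the minimum training fate value. Small enough to be negligible against apoptotic fractions (~1e-2..1) yet keeps `ln(P − ε)` finite. |
| `n_components` | min(10, rank bound) | PLS components; rank bound is min(p, n−1). An inner 5-fold selector maximizing held-out Pearson is available (`choose_n_components`). |
| log base (Eq. fitting) | natural | any base change would be absorbed by β0 only if applied consistently; fixed to ln. |

## Evaluation

Predictions of probabilities are scored with Spearman and Pearson
correlations, RMSE, and a base-2 Kullback–Leibler loss summed over the
prediction list, `L(p, p̂) = Σ_i p_i log2(p_i / p̂_i)`, *without*
renormalizing the lists to distributions — `m` is the number of
predictions, matching how the loss totals are reported for pooled
cross-validation outputs. Consequences of that convention: the loss is
guaranteed non-negative only when both lists are proper distributions
(Gibbs' inequality); over raw prediction pairs a term with `p̂_i > p_i` can
be negative. Predicted values are clipped to [1e-12, 1] before the log
because the power-law model can predict outside (0, 1]; terms with
`p_i = 0` contribute exactly 0.

The model-comparison score is `AIC = log2(L) + 2k/m`. The base-2 logarithm
is chosen for consistency with the base-2 loss it wraps (a natural-log
variant sits behind a flag). RMSE conventions: curve fitting reports
`sqrt(SSE/(n − k))` (residual degrees of freedom, as curve-fitting tools
print); prediction contexts report `sqrt(SSE/n)`. Both are exposed.

## Curve families

Single-variable candidates: power `a·x^b`, linear `a·x + b`, exponential
`a·e^(bx)`, gaussian `a·exp(−((x−b)/c)²)`. The linear family is solved in
closed form; the others by Levenberg–Marquardt / TRF with deterministic
initialization — power and exponential from the log-linear closed form,
gaussian from (max y, argmax x, half range) — and three seeded jittered
restarts on non-convergence. The gaussian family carries generous bounds
(peak within ten data spans, width at most 100 spans): on monotone
saturating data the unconstrained peak and width diverge and the optimizer
would fail rather than fit the flank. "Best" family means smallest
residual-dof RMSE, ties broken by larger R², then family name.

## Influence matrix and virtual knock-down

Each protein is regressed (log space, PLS) on all the others:
`x_i = e^(λ_i0) · Π_{j≠i} x_j^(λ_ij) + ε_i`, giving a matrix `λ` with a
structurally zero diagonal whose entry `λ_ij` quantifies the influence of
protein j on protein i. A virtual knock-down of protein k:

1. zero column k of a working copy of `λ` (k influences nobody),
2. zero the fate coefficient `β_k`,
3. replace every remaining coefficient with its influence-mediated value
   `β'_j = Σ_i λ_ij β_i` (`rule="replace"`), or add that value to the
   direct coefficient (`rule="additive"`).

The replacement rule is the primary one; the additive variant exists
because replacement discards all direct effects (with `λ = 0` it zeroes
the whole model), which can be the wrong prior when direct contributions
are known to persist. Knock-downs are recorded on the returned model and
re-knocking the same protein is a no-op — the algebraic rule applied twice
would multiply by the influence matrix twice, which has no biological
counterpart for an already-removed protein.

Candidate knock-downs are ranked by the RMSE of the rewired model's
predictions against drugged (or stimulated) observations. Blocked mode
sorts ascending — a small RMSE means removing that protein's signaling
reproduces the treated data, i.e. the treatment already blocked its
incoming signal flow; enhanced mode is defined as the exact reversal of
the blocked ordering (an independent descending sort with the same
name tie-break could differ under RMSE ties). Ties break
lexicographically by protein name for reproducibility.

## Experiment protocols

- Repeated k-fold CV: fold assignment is a uniform random permutation cut
  into contiguous blocks, no stratification; every report records its
  seed; 5 folds × 200 repeats yield exactly 1000 evaluations. Folds with
  fewer than 3 test rows or with exactly constant actual/predicted vectors
  have undefined correlations; they are flagged, excluded from threshold
  counts, and counted in the summary.
- Joint threshold count: number of evaluations with both Spearman and
  Pearson above τ; monotonically non-increasing in τ.
- Cross-cell-line transfer: one fit on the training line, one evaluation
  on the test line.
- Signals-only (DREAM8-style) protocol: per repeat a seeded 2/3–1/3 split;
  each protein in turn is the response; leave-one-out CV on the training
  part with the arithmetic mean of the back-transformed coefficient
  vectors across folds as the final model; RMSE on the held-out third,
  aggregated over proteins and 100 repeats.
- Time staggering: measurements are paired on index positions of the
  10-point acquisition grid (0, 0.1, 0.25, 0.5, 1, 2, 4, 6, 8, 12 h);
  output index o > 0 pairs with input index o − degree, the baseline
  pairs with itself.
- Cell-line discrimination: PLS on the combined table (log-transformed for
  the power-law kind), observations projected on the first two latent
  components, each assigned to the nearest cell-line centroid (Euclidean
  in score space); the misclassification count is the number of
  observations whose nearest centroid differs from their label. The
  nearest-centroid rule is this package's choice of classifier; other
  reasonable rules (e.g. k-NN) would change the count slightly.

## Synthetic data: what it emulates and what it does not

`generate_powerlaw_dataset` draws signals lognormal(0, σ=0.5) and fates
exactly from the power-law model with multiplicative lognormal noise
(default sd 0.05, i.e. ~5% noise) — the generative mirror of the fitted
model. It tests identifiability and recovery (exponent RMSE < 0.02 at
n = 500, σ = 0.05), not model adequacy on real data: real
phosphoproteomics has heavier tails, batch structure and measurement
error in the predictors, none of which are emulated.

`generate_influence_dataset` propagates lognormal root signals through a
power-law DAG (default: two drivers → a hub → two reporters, plus a bypass
reporter; couplings 0.5–0.9, node noise sd 0.05) and generates the fate
from the hub and downstream reporters. The drugged table uses identical
random draws but abolishes the blocked node's signaling function
entirely: its measured value becomes basal lognormal noise (sd 0.3)
decoupled from its parents, its downstream targets lose its input, and
its direct fate contribution is removed — a complete functional
inhibition, the regime in which ranking rewired knock-down models is
informative. A drug that merely decoupled the node's measured value while
leaving its downstream influence intact would leave every signal
predictable from the others and the ranking uninformative — with all
signals measured, no knock-down would be singled out. Recovery of the
blocked hub (top-2 of the ranking) succeeds in ≥ 18 of 20 seeded
replicates under the default replacement rule.

`simulate_boolean` emulates stochastic Boolean-network signal-transduction
simulators on a 7-node cell-death circuit (EGFR → oncogenic survival
signature ⊣ caspase-8 → caspase-9 → caspase-3 → death; DNA damage →
caspase-8 and → death; all edge weights and input levels 0.8). States are
binary per cell and absorbing once active (non-absorbing mode available);
an inactive node fires with probability clamp01(Σ activating w·s −
Σ inhibiting w·s) · rate_scale, inputs with level · rate_scale. The
reported trajectory is the population mean (default 5000 cells) of the
per-cell running activation frequency — a saturating curve in [0, 1],
monotone for absorbing nodes. `rate_scale` (default 0.05) is the
simulator's time resolution: it makes trajectories saturate over the
100-step horizon rather than within a few steps, which is what makes the
death-vs-input relation a clean power law; with raw 0.8 per-step
probabilities everything activates almost immediately and the relation
degenerates. The update semantics of the original simulator are not
published in detail; this is an emulation that reproduces the qualitative
trajectory shapes and the power-family best-fit result, not a clone.

`simulate_cascade_ode` is a deliberately small mass-action cascade
(receptor → initiator caspase → effector caspase → cumulative death
commitment, all species fractions in [0, 1]) standing in for large
kinetic apoptosis models: it reproduces the monotone, dose-responsive,
saturating death curves the validation pipelines need, not the biology of
a 112-species network. Rate defaults (0.1–1.2 /h) were picked so the
default 20 h window spans activation to near-saturation.

## Numerical choices and degenerate inputs

- Sample SD (n−1) in the DREAM8 reversal; population SD in sigmoid
  normalization (fixed conventions, chosen once for reproducibility).
- Zero-variance predictor columns are an error when scaling is enabled;
  zero-variance responses yield intercept-only models.
- A zero-variance column under sigmoid normalization maps to 0.5.
- The high-dimensional time-course feature builder expects the full
  acquisition grid per treatment/replicate (baseline + 13 points for the
  HT-29 design): raw features use the 13 post-baseline points, derivative
  features the 13 adjacent intervals, so the default families give
  19·13 + 19·13 + 3·19 = 551 columns and the optional per-protein AUC
  family completes the 570-dimensional space. Steady state is the mean of
  the last 3 time points (robust to end noise; the quantity is otherwise
  undefined for a finite noisy series).
- All randomness flows through one `numpy` Generator per call; no global
  state is touched, and identical seeds give bit-identical outputs.

## Known limitations

- Single-protein knock-downs only; simultaneous multi-protein intervention
  is not modeled.
- The influence matrix is correlational: fitted on observational data, its
  entries conflate direct and indirect influence, and on noise-free
  collinear data only well-determined rows (children of independent roots)
  are identifiable.
- The KL loss convention (no renormalization) means loss totals depend on
  the number of pooled predictions; compare models only at equal m.
- No regularized (ridge/lasso) fits and no pathway-database lookup for
  mapping ranked proteins to upstream drug targets; that interpretive step
  is manual.
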