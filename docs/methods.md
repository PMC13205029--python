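# Methods

`hpenet` quantifies the Human Performance Envelope (HPE) — the
multidimensional region of operator states within which performance remains
acceptable — as a time-resolved scalar derived from the *directed
interaction network* of five neurophysiological human factors (HFs):
mental workload, attention, vigilance, stress and effort. This note
documents the model, the estimation choices, the synthetic-data conditions
the tests run under, and the known limitations.

## 1. From EEG to five HF series

EEG is band-pass filtered 2–30 Hz with a 5th-order Butterworth filter,
applied forward–backward (zero phase). Zero-phase filtering avoids phase
distortion of the 1 s analysis epochs at the cost of doubling the effective
filter order; the stop-band tests account for this.

Frequency bands are anchored to the Individual Alpha Frequency (IAF),
estimated as the peak of the group-averaged Welch spectrum of a ≥ 10 s
eyes-closed baseline within 7–13 Hz (ties fall back to 10 Hz with a
warning). Band offsets follow the Klimesch convention and are configurable:
Theta = [IAF−6, IAF−2), Alpha = [IAF−2, IAF+2), Beta = [IAF+2, IAF+16),
Gamma = [IAF+16, 30]. Gamma is computed and carried but feeds no
neurometric.

Band power per 1 s epoch is the Hann-tapered periodogram summed over the
band's bins (1 Hz resolution) and averaged over a channel group — a
group-mean realization of global field power, chosen because no closed GFP
formula is prescribed; the spatial-SD alternative would change scale but
not the z-scored series' shape materially. Default groups: frontal
{Fpz, F3, Fz, F4, AF3, AFz, AF4}, parietal {P3, Pz, P4, POz}.

The five neurometrics are

    mental workload = Theta_frontal / Alpha_parietal
    attention       = −Alpha_frontal
    vigilance       = −Beta_frontal
    stress          = Beta_parietal
    effort          = Theta_frontal

"Alpha (high) parietal" is read as the full alpha band over parietal sites;
the upper-alpha sub-band [IAF, IAF+2) is selectable
(`alpha_parietal_band="alpha_high"`). Artifact-flagged epochs propagate NaN
only into the metrics that use the affected band/group.

Gaps are filled independently per HF: each missing sample takes the
inverse-temporal-distance weighted average of its k = 5 nearest observed
samples (distance ties at the k-th neighbour keep both sides). Imputation
is deterministic and leaves observed samples bit-identical. Series are then
z-scored (sample SD, ddof = 1) so the L1 penalty treats all five processes
equally; intercepts are therefore omitted from all regressions.

## 2. Sparse VAR identification

The five z-scored series form X(t) ∈ R⁵ modelled as a VAR(p),
X(t) = Σ_k A_k X(t−k) + W(t), cov(W) = Σ. The order p is selected per
session over p ∈ {1..20} by AIC/BIC in their log-determinant forms,
AIC = L′ ln det Σ̂ + 2N²p and BIC = L′ ln det Σ̂ + N²p ln L′, with every
candidate fitted on the same effective sample (the last L − p_max targets)
so the criteria are comparable; BIC wins disagreements (its consistency
and conservatism suit network inference).

Each row j of the stacked coefficient matrix is identified by LASSO:

    β̂_j = argmin Σ_t (X_j(t) − Z(t−1)ᵀ β_j)² + λ_j ‖β_j‖₁

solved by coordinate descent (scikit-learn; the objective maps to sklearn's
via α = λ/(2(L−p))). Convergence is verified by explicit KKT stationarity
checks rather than the solver's dual-gap heuristic, which is unreachable in
the λ → 0 limit even when the solution equals OLS to machine precision.
Coefficients below 1e−10 are snapped to exact zero; these structural zeros
*are* the directed network.

λ_j is selected per target row by blocked 10-fold cross-validation: the
series is cut into 10 sequential, contiguous, non-overlapping folds
(144 samples each at L = 1440) in original time order — no shuffling, so
serial dependence is respected — and regressor rows whose lag window
straddles a fold boundary are dropped from both sides. The grid is 50
log-spaced values in [1e−5, 1e3]; the value minimizing mean held-out
squared prediction error is retained. A single global λ is available for
comparison.

Two consequences worth knowing. First, the prediction-optimal
(minimum-MSE) λ systematically retains a few spurious coefficients of
magnitude ~0.01–0.08; support recovery on session-length data therefore
shows perfect recall but precision around 0.7–0.8 (directed-support
F1 ≈ 0.83 at study conditions). The fixed-quantile binarization rule is
provided for applications that need higher precision at known sparsity.
Second, on sessions whose true network changes across phases the CV curve
is nearly flat below the signal threshold and the per-row argmin can land
at the bottom of the grid, yielding an essentially unpenalized (dense) fit
for that row; the per-window λ re-selection policy or the global-λ mode
mitigate this when sparse window networks are required.

## 3. Analytic conditional transfer entropy

The fitted VAR is converted to its innovations-form state space by
companion embedding: state z(t) = [X(t−1); …; X(t−p)], transition F =
companion matrix, observation C = [A₁ … A_p], Kalman gain K = [I; 0; …; 0].
Because the state is the exact past, the output process reproduces the
VAR's second-order statistics exactly (verified against a Yule–Walker
oracle to 1e−6).

For source i, target j, and conditioning set S = all remaining processes,

    cTE(i → j | S) = ½ ln(σ²_r / σ²_u)     [nats; log2 option for bits]

where σ²_u = Σ_jj is the full-model innovation variance of X_j and σ²_r is
the innovation variance of X_j in the *sub-observed* model that withholds
the past of X_i — obtained by solving the discrete algebraic Riccati
equation of the reduced observation model, with no refitting. Under the
linear-Gaussian model this equals conditional Granger causality, and
σ²_r ≥ σ²_u guarantees non-negativity (asserted to 1e−12 before the log).
scipy's `solve_discrete_are` is used first; a fixed-point Riccati iteration
covers pencil degeneracies (a sparse A_p makes the companion matrix
singular). Either solution is accepted only below a 1e−9 relative residual;
failure raises.

The same machinery gives unconditioned bivariate TE (observe {i, j} vs
{j}), used to demonstrate that conditioning removes mediated influences:
in a chain 1 → 2 → 3 the conditional cTE(1→3|2) is exactly zero while the
bivariate TE(1→3) is not.

Binarization: a directed link i → j is present iff cTE(i→j) > 1e−10 (the
"exact-zero" rule — LASSO's structural zeros need no further test); a
quantile rule is available and the rule used is recorded in the output.

## 4. Graph indexes and the HPE polygon

On the binary adjacency:

- **PageRank** (damping 0.85) by power iteration with dangling-node mass
  redistributed uniformly, so the scores form a probability distribution
  (Σ PR = 1 to 1e−8); convergence when the max-abs change < 1e−10.
- **Density** D = |E| / (N(N−1)), diagonal excluded.
- **Node entropy** H(i): Bernoulli (binary) entropy, in bits, of the node's
  empirical link-presence probability p_i = (in+out degree)/(2(N−1)) over
  its 2(N−1) possible incident links. This reading yields an i-indexed H as
  the HF* formula requires; a global-pattern mode (same construction on all
  N(N−1) indicators) and a temporal mode (pooling link states across
  windows) are provided behind a switch. H is clamped below at 0.01 bits so
  it can serve as a denominator.

Each HF's contribution is HF*(i) = PR(i)·D / H(i), clipped into [0, 1]
(clips are counted and reported; clipping rather than renormalizing means
one HF cannot silently rescale the others). The five HF* values are placed
at fixed angles 90° + 72°k in the listing order (workload, attention,
vigilance, stress, effort) and the HPE is the shoelace area of that
pentagon; the all-ones pentagon has area (5/2)·sin 72° ≈ 2.3776.

**Time resolution.** A single session-level fit cannot produce
time-varying indexes, so the HPE series comes from per-window
re-estimation: default 120-sample windows, 60-sample step. The model order
comes from the whole-session selection, and by default the whole-session
per-row λ is reused inside windows (stabilizing the small-sample fits);
per-window re-selection is available. A window whose fit degenerates is
flagged and skipped. Per-minute values average frames whose centre falls
in the minute and interpolate minutes without a frame, giving exactly one
value per session minute (24 for the standard 3×8-min session).

## 5. Behavioural index and inference

Performance Index = (SME ISA / ATCO ISA) · (1 / ATCO RT), RT in seconds.
The per-phase SME rating is broadcast to each minute of its phase — the
only alignment consistent with a per-minute index. No RT trimming is
applied. Best/worst contrasts pick each subject's argmax/argmin performance
minute (earliest on ties) and compare the HPE (and link counts) there with
a paired two-tailed t-test; Cohen's d uses the SD of the paired differences
(an averaged-SD variant is available). The HPE–performance association
across a cohort uses the repeated-measures correlation: within-subject
centering (the ANCOVA subject factor), R = S_xy/√(S_xx S_yy) on the
centred data, df = n_obs − n_subjects − 1, p from F(1, df). Subjects with
constant x are dropped with a warning.

## 6. Synthetic study conditions

The generator emits what the pipeline consumes, with known ground truth:

- **Network**: N = 5, VAR order 2, off-diagonal couplings (~±0.35, random
  sign) on a random directed support, diagonal AR terms U(0.3, 0.6);
  coefficients shrunk (lag k scaled by s^k) until the companion spectral
  radius ≤ 0.95. Base density 0.4.
- **Session**: three 8-min phases (HIGH, BASELINE, MALFUNCTION) at 1 Hz,
  L = 1440. Phase density multipliers (1.5, 0.5, 1.0) give a dense HIGH,
  sparse BASELINE and intermediate MALFUNCTION network with nested
  supports; the simulation carries the VAR state across phase boundaries.
- **Missingness**: independent per HF, geometric gap lengths (mean 3 s) at
  a 20% rate — the artefact-epoch rate reported for real recordings.
- **Behaviour**: per-minute Performance Index = 0.3 + 0.5·(current true
  density) + N(0, 0.05), mapped back onto integer ISA ratings and the
  reaction time that reproduces the index exactly. The linear-in-density
  coupling is the simplest mechanism giving the HPE–performance
  correlation a known sign; coupling 0 is the null.

What the generator does **not** emulate: real EEG waveforms (the
neurometrics stage has its own sinusoid fixtures), non-stationarity within
phases, non-linear HF interactions, heavy-tailed innovations, or
rating/RT behaviour beyond the index identity. Passing tests therefore
show the pipeline recovers what it models — linear-Gaussian sparse
dynamics — not that real operator data satisfy those assumptions.

## 7. Numerical choices and problem sizes

Tolerances: PageRank 1e−10 / 1000 iterations; DARE relative residual
1e−9; LASSO KKT check rtol 1e−4; zero-snap and link threshold 1e−10;
entropy floor 0.01 bits; z-score assertions at 1e−8. Test and validation
runs use sessions of L = 1440, 10-seed recovery batches, 10 seeded cohorts
of 17 subjects, and 50 000-sample refit oracles — sizes chosen so each
check is statistically meaningful while a full run stays in the minutes
range.

## 8. Known limitations

- **Entropy floor vs sparse graphs.** For near-empty networks the
  incident-link entropy hits the 0.01-bit floor while PR and D stay
  positive, so HF* = PR·D/H inflates (and clips); mean HPE area at truth
  density 0.1 can exceed that at 0.3. The HPE area is monotone in network
  density only away from the degenerate-sparsity regime (≥ ~0.3 in our
  conditions). Interpret HPE values from nearly empty graphs with caution.
- **Prediction-optimal λ overselects** (Section 2): support precision
  ~0.7–0.8 at session length; recall is 1.0 in all tested conditions.
- The restricted-model route assumes the full fitted VAR is the true
  model; misspecification (e.g. non-linearity) biases cTE in ways the
  linear-Gaussian theory does not cover.
- Windowed re-estimation trades variance for time resolution: 120-sample
  windows make individual frames noisy; the per-minute averages and
  cohort statistics are the intended unit of interpretation.
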