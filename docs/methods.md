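# Methods

This note documents the models and procedures `mibrainnet` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would otherwise have to reverse-engineer from the
code. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Motor-imagery EEG classification: given epoched trials
`X ∈ R^{trials × channels × samples}` with class labels in `1..C`
(C = 2–4 imagined movements), predict the label of unseen trials. The
discriminative signal is band-limited (mu/beta rhythms), spatially focal
(sensorimotor electrodes), weak relative to broadband background activity,
and training sets are small (tens of trials per class). Every stage of the
pipeline addresses one of those properties.

## Preprocessing

**Bad-channel repair.** A channel is flagged when the z-score of its
trial-pooled log-variance exceeds a threshold (default 3). Flagged
channels are replaced per trial by the mean of the unflagged channels.
Log-variance was chosen because channel outliers in EEG are
multiplicative (gain faults, electrode pops); the mean-of-clean-channels
replacement needs no electrode geometry, unlike spherical-spline
interpolation. If every channel is flagged there is no clean reference
and the operation errors out.

**R² map.** For each channel and frequency band, per-trial band power is
the Welch PSD (1-second windows, 50% overlap) integrated over the band's
frequency bins, log-transformed. The cell value is the maximum over
one-vs-rest label dichotomies of the squared Pearson correlation between
log band power and the binary label, hence in [0, 1] and zero in
expectation when labels are independent of power. Log power is used
because EEG band power is approximately log-normal; the correlation is
then invariant to per-channel positive rescaling (tested). Default bands
are contiguous 4-Hz windows from 0.5 Hz to Nyquist.

**Band suggestion.** `suggest_band` returns the shortest contiguous run
of bands whose summed R² mass reaches the coverage fraction (default
0.8), leftmost run on ties; a featureless (all-zero) map yields the full
range. This automates the visual band choice practitioners make from R²
heat maps; it is deterministic but label-dependent, so in strict
generalization studies it should be computed on training data (the
library's CV harness does not call it internally for this reason — the
band is a configuration input).

**Band-pass filter.** 4th-order Butterworth, applied forward-backward
(`sosfiltfilt`) for zero phase, so filtering cannot shift class-relevant
temporal structure between trials. Order 4 (effective 8 after the double
pass) is the common EEG choice: steep enough to isolate mu/beta, flat
passband.

**Wavelet denoising.** Per channel: multilevel DWT (default `db10`,
3 levels), soft thresholding of all detail levels at the universal
threshold `σ̂ √(2 ln N)` with `σ̂ = median(|D₁|)/0.6745` (the robust MAD
noise estimate from the finest details), then reconstruction. This is the
VisuShrink recipe; it assumes the noise is approximately white at the
finest scale and the signal is concentrated in few coefficients. On pure
noise it removes most of the energy; on a clean oscillation it is nearly
idempotent (both tested).

**The DWT itself** is implemented in-package (`_wavelets.py`): Daubechies
filters of any order are generated by spectral factorization of the
Daubechies polynomial (roots inside the unit circle + N zeros at z = −1),
and the Mallat pyramid uses periodized boundaries, so a length-n signal
yields exactly n coefficients per level pair and reconstruction is exact
to ~1e-12. db1 and db2 are verified against their closed forms, all
orders against the orthonormality identities (Σh = √2, unit norm,
orthogonal even shifts, QMF pairing) and Parseval. This avoids a
dependency on a wavelet library while keeping the standard extremal-phase
coefficients.

## mSCSP: channel scoring and spatial features

For every unordered class pair (a, b): per-trial spatial covariances are
trace-normalized (so high-power trials do not dominate the class
average), averaged per class, and the generalized symmetric eigenproblem
`C_a w = λ (C_a + C_b) w` is solved. Eigenvalues lie in (0, 1); the two
classes' Rayleigh quotients for any filter sum to one (tested). The m
leading and m trailing eigenvectors per pair are retained (default
m = 2), i.e. the projections whose variance ratio between the classes is
most extreme.

**Channel score.** Channels are scored by
`score(ch) = Σ_pairs Σ_filters (2λ−1)² |w̃_ch|` with `w̃` the unit-norm
filter. Two normalizations matter here and are deliberate:

- Generalized eigenvectors are whitening-orthonormal
  (`w'(C_a+C_b)w = 1`), not unit-norm, so a filter pointing at a
  high-variance channel has a *small* Euclidean norm. Scoring raw filter
  weights therefore systematically down-ranks exactly the channels CSP
  found discriminative. Unit-normalizing each filter first makes the
  score a well-defined function of the filter's direction.
- A filter with λ ≈ 0.5 carries no class information regardless of its
  weights; `(2λ−1)²` weights each filter by its discriminability and is
  zero at the uninformative point. With trace-normalized covariances a
  single-channel power contrast also perturbs the *relative* power of all
  other channels, creating moderately informative nuisance filters; the
  squared weighting suppresses them (the linear weighting does not,
  which is measurable on the 10:1 variance fixture).

The top `n_channels_keep` channels by score are retained for the
spectral/network stage. Per-trial CSP features are the log of the
normalized projection variance (variance floored at machine epsilon
before the log) and the projection mean, per retained filter.

## Energy-entropy brain network

**Component energies.** Each selected channel's signal is decomposed
3 levels deep into D1, D2, D3 and A3. Detail energies are l2 norms
`E_Dj = ‖D_j‖₂`; the approximation contributes `E_A = mean(|A3|)`. The
mean (rather than the norm) keeps the low-frequency approximation — which
dominates EEG energy — on a scale comparable to the details, so the
resulting distribution is not degenerate at the A3 component. Constant
factors cancel in the normalization below and are dropped.

**Relative energy and entropy.** `P_j = E_j / Σ_j' E_j'` (so Σ P_j = 1
by construction; normalizing by `Σ E_j²` instead would break the simplex
property) and `S = −Σ P_j ln P_j` with `0·ln 0 := 0`. S ranges from 0
(energy concentrated in one component) to ln 4 (spread evenly); it is the
per-channel spectral-concentration feature.

**Graph construction.** Nodes are the selected channels. Edge weight
between channels m, n is `exp(−D(P_m, P_n))` with D the symmetrized KL
divergence (components floored at 1e-12 before the logs), giving a
similarity in (0, 1] that is 1 iff the distributions match. Symmetry and
boundedness are required for an undirected thresholded graph; plain KL
has neither. The top `⌈0.30 × n(n−1)/2⌉` pairs by similarity become
edges (ties broken by lexicographic pair order for determinism); any node
left isolated gets back its single strongest incident edge, so the
density is exact up to isolation repairs. 30% keeps the graph sparse
enough for informative topology but dense enough that no node is
stranded.

**Topology features**, computed on the binary adjacency: degree counts
both edge directions (`k_i = 2 × neighbors`); clustering is
`t_i / (k_i (k_i − 1))` with `t_i` the triangles through i and
`C_i := 0` when `k_i ≤ 1` — note with the doubled degree this is ¼ of
the textbook undirected coefficient, a monotone rescaling that the [0,1]
feature normalization absorbs; distances are BFS hops with unreachable
pairs assigned `d = n`; nodal efficiency is `(n−1)/Σ_j d_ij`. The 1-norm
(max absolute column sum) and spectral norm (largest singular value) are
taken on the thresholded *weighted* matrix `similarity × adjacency`,
summarizing overall connectivity strength. All graph metrics are verified
against exhaustive triangle enumeration and Floyd–Warshall on random
graphs.

**Fusion.** Per trial: entropies, degrees, clusterings, efficiencies, the
two norms, then CSP log-variances and means, concatenated with
channel-resolving names. Each column is min-max scaled to [0, 1] with
minima/maxima from training trials only; constant columns map to 0; test
values outside the training range scale past [0, 1] without clipping
(the transform stays affine; clipping would destroy ordering
information).

## Feature selection

**mutcorLasso.** Objective
`min_w ‖y − X'w‖² + α‖w‖₁ + β w'Cw`, where `C = R ⊙ R`,
`R_kl = cos(x_k, x_l) + |MI(x_k, x_l)|` (cosine of the feature rows plus
absolute histogram mutual information, 10 equal-width bins, natural log;
zero-norm rows contribute no cosine). The quadratic term charges weight
placed on *pairs* of mutually redundant features. Multi-class labels are
handled one-vs-rest with a 0/1 target per class; a feature's score is its
largest |w| across classes.

The solver is the diagonal fixed-point iteration
`w_{t+1} = M_t [M_t B M_t + αI]⁻¹ M_t X y`, `M_t = diag(w_t)`,
`B = XX' + βC`, initialized uniform (0,1) from the pipeline seed, run to
`‖Δw‖_∞ < 1e-6` or 1000 iterations. Two properties of this update are
worth knowing:

- Its fixed point satisfies `(Bw)_i + α/w_i = (Xy)_i`, i.e. it is a
  majorize-minimize scheme for the *log-penalized* objective
  `‖y − X'w‖² + β w'Cw + 2α Σ ln|w_i|`, which it descends monotonically
  (tested to 1e-12). The l1 objective above is *not* its Lyapunov
  function and may transiently increase by ~1% on noise-only problems
  (tested to stay under 2%).
- Consequently the solver is sparser than a lasso at the same α: at
  α = 0.5 it typically keeps one representative of a group of correlated
  informative features, while at the low end of the tuning grid
  (α = 0.1) it retains the group. At small α (0.01) its solutions agree
  with coordinate-descent lasso to <1% in objective with matching
  supports (tested). α and β are meant to be tuned per dataset; 0.5/0.1
  are the standard starting values.

Features with |w| < 1e-8 count as eliminated; the survivors are ranked
and the top `n_keep_lasso` (default 20) kept, lower index winning ties.

**Relief-f.** On the lasso survivors (rows in [0, 1]): a candidate pool
of `⌈sample_rate × n⌉` trials (rate default 0.35, constrained to
[0.30, 0.40]) is drawn once per run; each of 60 rounds samples a trial R
from the pool, finds its k = 6 nearest same-class hits and, per other
class c, 6 nearest misses under the L1 distance, and updates
`w_A ← w_A − Σ_H |x_R,A − x_H,A|/(mk) + Σ_c [p(c)/(1−p(class(R)))]
Σ_{M_c} |x_R,A − x_M,A|/(mk)` with m = 60. Constant features get weight
exactly 0. The top `n_keep_relief` (default 10) features by weight are
the final set — the 120 → 20 → 10 reduction chain at the defaults.
Classes must have more than k samples. Weights are invariant to sample
reordering given the same sampled-round sequence (tested via the
`rounds` override).

## Classification and evaluation

KNN (k = 5), LDA with Ledoit-Wolf analytic covariance shrinkage
(`lsqr` solver — stable when trials ≲ features), and a 10-tree seeded
random forest. The ensemble takes the majority label; three-way ties go
to the sLDA prediction (a fixed, deterministic rule; sLDA is the most
calibrated of the three on small samples). Accuracy is the confusion
matrix trace over its total.

Evaluation schemes: stratified k-fold (default 10) and repeated
stratified 50/50 splits (default 20 repeats), both seeded. Every
data-dependent stage — CSP filters and channel choice, fusion scaling,
both selection stages, the classifiers — is refit inside each training
fold and applied unchanged to the test fold; train/test index disjointness
is asserted on every fold. Only per-trial stateless stages (band-pass,
denoising, per-trial wavelet energies) are computed once globally, which
is safe because they involve no cross-trial statistics.

## Synthetic data

The generator emulates the two properties the method exploits:
class-dependent band power on designated channels (random-phase sinusoids
with per-class band and amplitude) and class-dependent spatial variance
(per-channel variance scaling), on top of 1/f-ish broadband noise
(demeaned, variance-normalized random walk mixed 1:1 with white noise,
sd 1.0). Defaults: fs = 128 Hz, 2-s epochs, 10 channels.

Presets: `easy4` — 4 classes × 40 trials, each class plants a
3x-amplitude oscillation (vs the amplitude-1 background rhythm present on
all channels) in its own 4-Hz band on its own channel pair plus a 2x
variance scale; `null4` — same marginals, zero contrast; `twoclass` —
only a 10:1 variance contrast on one channel (the CSP fixture). Identical
seeds give bitwise-identical data, and ground truth records the planted
channels/bands by *name* so recovery tests survive reconfiguration.

What the generator does **not** emulate: event-related
desynchronization time courses (contrast is stationary within an epoch),
ocular/muscle artifacts, inter-channel correlation structure beyond the
planted scaling, non-stationarity across trials, and realistic EEG
spectra beyond the 1/f trend. A green end-to-end test therefore
establishes that the pipeline recovers planted band-power/variance
structure without leaking labels — not that it attains any particular
accuracy on real recordings.

## Numerical choices and degenerate inputs

- Zero-variance CSP projections: floored at machine epsilon before log.
- All-zero channel energies: an error ("degenerate channel") — entropy
  of an undefined distribution has no meaningful value.
- KL floors components at 1e-12; similarity hence stays in (0, 1].
- Histogram MI canonicalizes argument order bytewise, making symmetry
  exact rather than approximate.
- Network ties and selection ties resolve by lexicographic/lower-index
  order, so every ranking is deterministic.
- All randomness (lasso init, relief sampling, forests, fold shuffling)
  descends from the single pipeline seed.
- EDF export quantizes to 16 bits over each signal's observed range; the
  native `.npz` container round-trips bitwise.

## Known limitations

- The Table-style fixed-point solver inverts a p × p matrix per
  iteration (p = number of features); fine for p ≲ 300, not intended for
  thousands of features.
- `suggest_band` uses labels at the dataset level (as practitioners do
  with R² maps); for strict generalization claims, compute it on a
  held-out calibration split.
- Nodal efficiency uses `d = n` for unreachable pairs, a finite
  convention that slightly overstates the efficiency of nodes in small
  disconnected components relative to the `d = ∞` convention.
- The bad-channel rule assumes at most a minority of channels are bad;
  montage-aware interpolation is out of scope.
- GDF and EDF+ annotation parsing are out of scope; EDF reading covers
  plain EDF with uniform samples-per-record.
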