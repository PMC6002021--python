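# Methods

This note documents the models, the synthetic-data design and the numerical
choices made in `teneeg`, in the package's own words.  Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Spectral features

Each trial is transformed with a single unwindowed full-length DFT; the
periodogram is `p(f_k) = |x(f_k)|²/T` and the phase spectrum
`h(f_k) = angle x(f_k)`.  No taper and no segment averaging are applied: the
features are defined on the raw periodogram, and Parseval's identity
(`Σ_k p(f_k) = Σ_t x(t)²`) is enforced as a test invariant.  Trials may have
different lengths (the listening stimuli last 13–22 s), so each trial has
its own frequency grid; band averaging is what makes features comparable
across trials.

Band membership uses half-open intervals `[low, high)` over the positive
frequency bins `k = 1 … ⌊T/2⌋`.  This places the touching edges of the
canonical bands (4, 8, 12, 30 Hz) in the upper band exactly once and never
includes DC.  The defaults are δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–45 Hz.

Phase differences are ambiguous modulo 2π.  Each per-bin difference
`h₁(f_k) − h₂(f_k)` is wrapped to (−π, π] **before** band averaging, which
keeps PHD bounded and exactly antisymmetric in the channel pair.  The
literal unwrapped subtraction is available (`wrap=False`, CLI flag
`--no-phase-wrap`) because either convention is defensible; wrapped is the
default.

Preprocessing (`preprocess`) is a zero-phase forward–backward Butterworth
band-pass (default 0.5–50 Hz) followed by integer-factor decimation with
anti-alias filtering (default 512 → 256 Hz).  Zero-phase filtering is
non-negotiable here: a causal filter's phase distortion would corrupt the
phase-difference features.  The default order is 8, chosen so that the
squared (forward–backward) response suppresses a 60 Hz mains tone by more
than 20 dB while leaving a 10 Hz tone within 5% — a 4th-order zero-phase
band-pass only reaches about 11 dB at 60 Hz, which is not a meaningful
mains rejection.

## Feature layouts

With `M` channels and `F` bands there are exactly `I = F(M(M−1)+M) = F·M²`
features per trial: `M` PSD values, `M(M−1)/2` PWD values (ordered pairs
with `m₁ > m₂`) and `M(M−1)/2` PHD values (`m₁ < m₂`) per band.  The tensor
layout places PWD in the lower channel triangle, PHD in the upper triangle
and PSD on the diagonal of each band slice; the vector layout enumerates
band-major, then kind (PSD, PWD, PHD), then channel/pair lexicographic.  Any
fixed column order is equivalent for PLS; an explicit `index_map` makes the
order auditable and drives the attribution reports.  Both layouts contain
the same value multiset, which is an acceptance-tested invariant.

## PLS (vectorized features)

Classical NIPALS PLS2 with X- and Y-deflation: per component the inner
iteration converges to the dominant covariance direction between X and the
current Y residual; scores are stored unit-norm, the sign of each weight
vector is fixed by making its first non-negligible entry positive, and
prediction uses `B = W (PᵀW)⁻¹ Cᵀ` on centered data.  X columns are
mean-centered but not variance-scaled (only the responses are normalized);
`scale_x=True` opts into autoscaling.  Inner-loop tolerance is 1e−10 on the
score change with at most 500 iterations.  Component counts are limited to
`min(N−1, I)`; a zero-variance X or an exhausted residual stops extraction
early with a warning.  Predictions agree with scikit-learn's
`PLSRegression(scale=False)` to 1e−6 on random instances (a test-only
cross-check; scikit-learn is never used in the implementation).

Note one subtlety frozen into the oracle tests: `Y = XB` with a rank-3 `B`
is *not* fitted exactly by 3 PLS components for generic full-rank X; exact
recovery at `R1 = rank` requires the data to come from a rank-3 latent
model (X itself of rank 3).  The oracle fixtures generate that latent form.

## HOPLS (tensor features)

Per component `r`, on the current residuals:

1. the cross-covariance tensor `C[j, m₁, m₂, f] = Σ_n Y[n,j]·X[n, m₁, m₂, f]`
   is formed;
2. its best rank-(1, L1, L2, L3) orthogonal Tucker approximation is computed
   by HOOI (initialized from the truncated SVDs of the unfoldings, at most
   100 alternations, convergence when the core norm changes < 1e−9
   relative), giving the response direction, the loading matrices
   `P_r^(k)` and a core `D_r`;
3. the latent score is `t_r ∝ Z₍₁₎ · vec(D_r)/‖D_r‖`, where `Z` is X
   projected onto the loadings — the multilinear analogue of the PLS weight
   step.  This choice (rather than a dominant singular vector of the
   projected residual) is what makes HOPLS with full loading ranks
   (L1 = L2 = M, L3 = F) reduce *exactly* to PLS2 on the vectorized tensor,
   a property the test suite asserts at 1e−6;
4. `q_r = Yᵀt_r/d_r` with `d_r = ‖Yᵀt_r‖`, and both blocks are deflated by
   their rank-one reconstructions.

Prediction projects a centered test tensor onto the loadings, maps through
the stored core (division by `vec(G_r)·w_r`), accumulates `d_r t q_rᵀ` and
deflates with the training order.  The coefficient tensor `W` (M×M×F×J) is
obtained exactly by pushing the canonical basis tensors through the (linear)
prediction rule.

Signs are fixed deterministically (first non-negligible entry of every
loading column and of every score non-negative), so identical inputs give
bit-identical model files.  Tensors are centered trial-wise, mirroring PLS
column centering.  Tensor primitives (unfolding, mode-n products, HOOI) are
implemented in the package on plain numpy; leading singular vectors of wide
unfoldings are taken from the eigendecomposition of the small Gram matrix
for speed.

Greedy multi-component extraction is only exactly identifiable when the
generating components do not interfere; the recovery oracle therefore
builds latent scores that are mean-zero *and* orthonormal and gives the
components mutually orthogonal channel-1 loading subspaces.  With fully
generic random components the greedy fit leaves a small (~1%) residual,
which is expected behaviour, not an implementation defect.

## Evaluation protocol

Responses are normalized per scale to zero mean and unit sample variance
(divisor N−1).  By default normalization parameters are estimated inside
each training fold of the per-subject leave-one-out cross-validation, so no
information from the held-out trial leaks into the model;
`global_normalize=True` reproduces the literal normalize-then-split reading.
RMSE is reported on the normalized scale, where 1.0 is the no-skill
baseline.

Hyperparameters are selected by the LOOCV error itself over a grid — the
small-sample protocol; `nested_loocv` provides the honest nested variant.
The default grids are R1 ∈ 1..43 (PLS) and L1, L2 ∈ 1..7, L3, R2 ∈ 1..5
(HOPLS, 1225 points); the selection objective is the mean RMSE over the
three scales (one hyperparameter set per subject), ties broken toward the
smaller model.  With N = 44 trials a LOOCV training fold has 43 trials, so
the grid's R1 = 43 point is infeasible inside the folds; `grid_search`
skips infeasible points with a warning rather than failing the whole search.
Grid searches exploit that both models extract components sequentially: one
fit per fold at the largest component count provides the predictions of
every smaller count exactly.

Attribution ranks features by `|coefficient|` per scale (ties broken by
column order), reports the top-K list (default K = 100), counts by feature
kind and band among the top K, and the top channel pairs by the summed
magnitude over both pair kinds and all bands.

## Synthetic data

The generator emulates a per-subject speech-listening recording: default 44
trials, durations uniform in 13–22 s at 256 Hz, M = 16 channels labelled
from the standard 10/20 extension.  Each trial is a sum over bands of one
sinusoid at a random in-band frequency, with per-channel amplitudes,
channel phase offsets plus per-trial phase jitter (sd 0.3 rad), over white
Gaussian sensor noise (sd 1.0 in signal units).  Band amplitude ranges
follow the usual resting ordering (α prominent, γ weak).  Amplitudes carry a
low-rank spatial structure: a few (default 3) latent sources mix into all
channels through fixed non-negative profiles shared across bands, the way
cortical generators project smoothly across the scalp; this gives the data
the separable spatial–spectral covariance that motivates tensor features in
the first place.  `amplitude_rank=None` switches to independent channel
amplitudes.

Ratings are built from a known coefficient tensor per scale (`make_truth`:
sparse cells or a low-rank sum of outer products, antisymmetrized over the
pairwise region, optionally restricted to chosen bands or to pairwise cells
only, optionally with channel factors drawn in the span of the source
profiles).  The latent signal `s_n = ⟨Xc_n, W⟩` is standardized to unit
variance before Gaussian noise (`rating_noise_sd`) is added — so the rating
SNR is `1/rating_noise_sd²` — and the result is affinely mapped into the
printed ranges (MOS 1–5, VAL/ARL 1–9).  The truth tensor, noise draws and
scaling are returned for test assertions.  Everything is driven by one
integer seed and reproduces bit-exactly.

What the generator does **not** emulate: 1/f background spectra, artifacts
(blinks, muscle), volume-conduction forward models, non-stationarity within
a trial, or any nonlinearity in the feature–rating coupling.  Passing tests
therefore demonstrate the correctness and the statistical behaviour of the
pipeline under its assumed (linear, oscillatory) data model, not performance
on real recordings.

## Simulation studies (test suite and acceptance script)

* **Strong-signal check**: SNR ≈ 11 (rating noise 0.3), M = 8, N = 44; the
  vectorized model's LOOCV RMSE falls well below 0.7.
* **Null-skill control**: zero coefficient truth, minimal-capacity models
  (R1 = 1; L = (1,1,1), R2 = 1).  LOOCV RMSE sits at the baseline 1 ± 0.1
  seed-averaged; permuted responses never show skill.  Larger models drift
  *above* 1 on null data by overfitting noise, which is the expected
  behaviour of LOOCV, so the baseline check deliberately uses the smallest
  models.
* **Attribution**: a single planted PWD cell (noiseless coupling) must be
  the top-ranked feature on every scale.  The band-count check uses M = 12
  so that the 132 alpha pairwise cells can actually fill a top-100 list.
* **Tensor-vs-vector comparison**: per-subject grid-searched LOOCV for both
  models on recordings with low-rank spatial–spectral structure (rank-1
  pairwise truth with spatial factors in the source span, rating SNR 1),
  repeated over 20 seeds; the tensor model's mean RMSE is compared with the
  vectorized model's per seed.  The PLS grid is the full R1 ∈ 1..43; the
  HOPLS grid is a desk-scale 375-point subset (L1, L2 ∈ 1..5, L3 ∈ 1..3,
  R2 ∈ 1..5) of the loading ranks relevant at M = 16, preserving the
  protocol's characteristic asymmetry — the tensor model is searched over
  many more hyperparameter points than the vector model, and both are
  selected by their best LOOCV error.  Two ingredients drive the expected
  direction: the low-rank structure that the tensor class can represent
  with few parameters, and that grid asymmetry under best-LOOCV selection;
  with symmetric small grids the two models tie at this problem size.
  Problem sizes (M = 16, N = 44) were chosen so the whole suite runs on one
  CPU.

The grid searches run through a batched leave-one-out engine: all folds are
fitted simultaneously with batched linear algebra (identical, to numerical
equality, with fitting fold by fold — an asserted test invariant), and the
sequential nature of component extraction lets one fit per fold provide
every smaller component count on the grid.
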