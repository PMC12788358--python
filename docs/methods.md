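# Methods

`gcirnet` decodes motor-imagery (MI) EEG by converting each trial into a
small stack of connectivity topographies and classifying the stack with
a variational autoencoder (VAE) whose objective balances reconstruction,
classification and latent regularization. This note documents the model,
the numerical choices, and what the synthetic study conditions do and do
not establish.

## Signal model and preprocessing

A trial is a matrix `X ∈ R^{C×τ}` (channels × samples, microvolts) with
sampling rate `fs` and a one-hot class label over `Q` classes. Raw
recordings are standardized by (i) common-average referencing (the
channel mean subtracted at every sample), (ii) a zero-phase fifth-order
Butterworth band-pass (default 4–40 Hz, forward–backward with
second-order sections, so no group delay distorts the analysis window),
and (iii) polyphase FIR resampling to 128 Hz. The reference → filter →
resample order is fixed; referencing is idempotent and linear, so it
commutes with the later linear steps in exact arithmetic.

Volume conduction is attenuated with the spherical-spline surface
Laplacian (current-source density). Electrodes sit on a unit sphere;
with `cos θ` the cosine similarity between two electrodes
(`cos θ = 1 − ‖e−e′‖²/2`), the spline kernels are truncated Legendre
series

    g(cos θ) = (1/4π) Σ_{n=1}^{Nmax} (2n+1) P_n(cos θ) / (n(n+1))^ρ
    h(cos θ) = (1/4π) Σ_{n=1}^{Nmax} (2n+1) P_n(cos θ) / (n(n+1))^(ρ−1)

with stiffness `ρ = 4`, truncation `Nmax = 50` and ridge `λ = 10⁻⁵` on
`G` — the conventional EEG-CSD values; all three are exposed. Per time
sample the spline coefficients solve the regularized system on
`Gs = G + λI` under the mean-coefficient constraint and are mapped
through `H`. The operator is precomputed once per montage, so the
per-trial cost is one matrix product. A spatially constant potential is
annihilated by construction (the constraint projects it out); this and
agreement with an independent per-sample dense solve are tested. Output
units are arbitrary CSD units — the later min-max normalization removes
scale. The MI window (e.g. 2.5–4.5 s) is cut with the half-open
convention `[round(t_s·fs), round(t_e·fs))` used everywhere in the
package.

## Gaussian functional connectivity (GFC)

Four rhythms are analyzed: μ (8–12 Hz), low-β (12–15), mid-β (15–20)
and high-β (18–40). The upper two overlap deliberately; band edges are
half-open `[f_lo, f_hi)` on the FFT grid. Per band, each channel is
reduced to its band-limited spectral reconstruction (real FFT, bins
outside the band zeroed, inverse FFT) — an exact orthogonal projection.
Channel pairs are compared with a Gaussian kernel

    K[c,c′] = exp(−‖x_c − x_c′‖² / 2σ²),

with `σ` set per trial and band to the median of the C(C−1)/2 distinct
pairwise Euclidean distances (median heuristic; self-distances are
excluded, which would otherwise bias σ low). The matrix is compressed
to a flow vector `g_c = (1/C) Σ_{c′≠c} K[c,c′]`; the divisor `C` is kept
although the sum has C−1 terms, so flows live in `[0, (C−1)/C]` — a
fixed offset the normalization removes. Flows are min-max normalized
per channel and band over the *training* trials only (values outside
the training range clamp to [0,1]; a channel constant across training
trials maps to 0.5). The normalizer is refit for every cross-validation
training split; a whole-dataset fit would leak test statistics.

A property worth knowing: because σ is data-driven, a strong source
added to a few channels shifts the median distance and therefore moves
*all* kernel entries, not only those of the loaded channels. On very
small montages (say 8 electrodes, 3 of them loaded) the class signature
is consequently global rather than local; on a 64-channel montage a
5-electrode effect barely moves the median and stays spatially local.
This matters for interpretability tests (below).

## Topographic imaging

Electrode positions are projected to the plane by an azimuthal
equidistant projection about the vertex (radius = polar angle, azimuth
preserved, rescaled to fit [−1,1]²), Delaunay-triangulated, and each
pixel center of a 40×40 lattice (bounding box of the projected
electrodes padded by 2%) inside the convex hull receives the linear
barycentric interpolation of its enclosing triangle's electrode values.
This interpolation has linear precision (affine fields are reproduced
exactly) and obeys a maximum principle (no over/undershoot). Pixels
outside the hull are zero; the reconstruction loss uses the full image
including those zeros, and the in-hull mask is kept for plotting only.
The four band maps stack channel-last into the 40×40×4 network input.

## Network and losses

The VAE is LeNet-like. Encoder: 3×3 convolutions with 6, 16 and 120
filters (SELU, stride 1, same padding) with 2×2 average pooling after
the first two, so a 40×40×4 input flattens to 12 000 features, then a
dense SELU layer to 128 and two linear heads for the posterior mean μ
and log-variance log σ² of a 128-D diagonal Gaussian. Decoder: dense
128 → dense 12 000 (SELU) → reshape 10×10×120 → 3×3 conv to 16 → 2×
nearest-neighbor upsample → 3×3 conv to 6 → upsample → 3×3 conv to B
channels with a sigmoid. Spatial growth comes from the upsampling; the
stride-1 "transposed" convolutions are algebraically plain convolutions
and are implemented as such. Classifier: dense 128 (SELU) → dense Q
(softmax), reading the same latent vector. Training samples
`z = μ + exp(½ log σ²) ⊙ ε` once per example per step; inference uses
`z = μ` (deterministic).

The objective is a convex combination on the simplex,

    L = w_rec · NMSE + w_cla · NBCE + w_reg · NKL,

with each term normalized so a non-informative predictor scores 1:

* NMSE = Σᵢ‖Yᵢ−Ŷᵢ‖²_F / Σᵢ‖Yᵢ−Ȳ‖²_F, with Ȳ the training-set mean
  image frozen at fit time (ratio of batch sums; the two 1/N factors
  cancel). Predicting every image as Ȳ scores exactly 1.
* NBCE = meanᵢ CE(pᵢ,p̂ᵢ)/CE(u,p̂ᵢ) with u the uniform label (1/Q,…);
  predictions are clipped to [10⁻⁷, 1−10⁻⁷] in numerator and
  denominator, so the uniform predictor scores exactly 1.
* NKL = (1/(N ln N)) Σᵢ KL(N(μᵢ,σᵢ²) ‖ N(0,I)) in closed form; the
  ln N factor keeps the term from growing with batch size. N = 1 is
  guarded by max(ln N, 1) with a warning.

This common scale is what makes simplex weights meaningful. Gradients
are hand-derived and backpropagated through a small NumPy layer
framework (float64, channels-last); a finite-difference check holds the
analytic gradient to better than 10⁻⁴ relative error. Optimization is
Adam (lr 10⁻³), batch 64, at most 200 epochs with early stopping on
validation total loss (patience 10, best parameters restored). One
master seed drives initialization, shuffling and the ε draws; runs are
bit-reproducible single-threaded. Desk-scale runs in the test suite and
the acceptance script cap epochs at 60 — on the strongly separable
synthetic conditions early stopping fires well before that, and the cap
keeps a 5-split evaluation under ten minutes on one CPU.

Loss weights can be searched over the simplex (default lattice with
step 0.1): each candidate trains a freshly initialized model for a
short run and the candidate with the lowest validation total loss wins.
Comparing weighted totals across different weightings is deliberate: a
candidate that leans on a term whose validation value cannot drop below
its non-informative baseline (e.g. classification under uninformative
labels) is penalized exactly as intended.

## Evaluation and statistics

Per subject: stratified shuffle splits (5 × 80/20), the full
training-dependent state (min-max normalizer, Ȳ, network) refit per
split, accuracy on the held-out 20%. Subject cohorts are stratified by
a reference model's accuracy into Good (>80%), Mid ([60, 80]%) and Bad
(<60%); the printed group ranges overlap at the boundaries, resolved
here as stated. Model comparison: Friedman test over per-subject mean
accuracies (average ranks on ties, tie-corrected chi-square, asymptotic
p; identical columns degenerate to statistic 0, p = 1), all-pairs
paired-t or Wilcoxon signed-rank tests (exact when feasible) with Holm
step-down correction over the pair family, per-model average corrected
p against all others, and per-subject average ranks (1 = best).

## Interpretability

Grad-CAM++ relevance of a named encoder convolution for a class uses
the exponential-score reduction: with `g = ∂(logit_c)/∂A` (first-order
gradients at `z = μ`), α = g²/(2g² + Σ_spatial A·g³) with an ε = 10⁻⁸
guard, channel weights Σ α·relu(g), map = relu(Σ_k w_k A_k), bilinear
upsample to input size, max-normalized. Channel relevance is the
bilinear sample of the map at each electrode's pixel position (same
grid as rendering). Edge graphs retain connectivity-matrix edges whose
upper-triangle weight falls in a percentile band (linear-interpolated
percentiles, ties at the bounds included), on class-averaged matrices.

A stability caveat, found empirically and handled explicitly: on easily
separable data a single trained network may implement any of several
decision strategies, and a single model's relevance contrast between
regions can flip sign with the initialization seed. Relevance analyses
in the acceptance checks therefore average channel relevance over three
training restarts and read the deepest convolution (the layer that
specializes most sharply), which makes the planted-region contrast
reproducible across generator seeds.

## Synthetic study conditions

The generator emulates the statistical skeleton of sensorimotor MI
EEG at the level this pipeline is sensitive to: 1/f-shaped Gaussian
background (exponent 1.0, unit variance) plus a white floor (std 0.2),
with class-dependent narrowband sources (flat spectrum inside the band,
random phase) mixed into configured electrode sets. A *shared* source
raises within-set waveform similarity — precisely the quantity the
Gaussian kernel measures — as well as band power. Defaults: 8
sensorimotor channels (F3/F4/C3/Cz/C4/P3/Pz/P4), fs = 128 Hz, 2 s
trials (256 samples), balanced classes; the binary condition plants
μ and low-β sources (amplitude 2.0 relative to the unit background) on
{F3,C3,P3} for class 0 and {F4,C4,P4} for class 1. A 5-class variant
uses distinct set/band signatures with a background-only "rest" class.
The interpretability condition uses the full 64-channel 10-10 montage
with a single 5-electrode left-central planted set.

What the generator does *not* emulate: realistic source geometry (no
lead fields or dipoles), artifacts (blinks, EMG), non-stationarity
within trials, or inter-subject variability. Passing the end-to-end
checks therefore shows that the pipeline recovers class structure that
enters through band-limited inter-channel similarity at realistic SNR —
not that it attains any particular accuracy on real recordings.

One empirical property of the conditions is worth recording: with the
median-heuristic σ, raw flows at planted electrodes are *lower* for the
planted class (the strong shared source pushes the loaded channels away
from the remaining five more than it binds the three loaded ones);
after the surface Laplacian suppresses the globally shared component
the planted set's within-set coupling dominates and the direction
reverses. Both effects are large (rank-test p ≪ 10⁻⁹ at 100 trials per
class) and both are asserted in the tests.

## Problem sizes

Deliberate desk-scale choices, stated as the package's own protocol:
the end-to-end binary check uses 100 trials per class, 5 stratified
splits, epoch cap 60 (early stopping typically fires around epoch
20–40); the interpretability check uses 20 trials per class, 3 restarts
at 60 epochs. The loss-weight search in tests uses a 4-candidate set
and 3-epoch runs; the full 66-point lattice is the library default.

## Known limitations

* EDF import reads EDF/EDF+ only (no BDF/FIF); the GigaScience `.mat`
  layout is left to a user script.
* The trial container requires a uniform τ; mixed-length imports crop
  to the shortest trial and flag it in metadata.
* No artifact rejection or ICA; the Laplacian is the only spatial
  cleanup.
* Exact bit-reproducibility is promised only single-threaded; BLAS
  threading can reorder floating-point sums.
* The loss-weight search trains one model per candidate; with the full
  lattice this is 66 short trainings and is meant for per-subject
  offline tuning, not interactive use.
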