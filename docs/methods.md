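# Methods

This note documents the models, numerical choices and limitations of the
`thermomics` package in one place. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute themselves.

## Pennes bioheat phantom

The simulator integrates the Pennes bioheat equation

ρ_t c_t ∂T/∂t = ∇·(k_t ∇T) + ω_b c_b (T_a − T) + q_m

on a 2-D rectangular grid. The grid is interpreted as the frontal,
skin-parallel plane of the chest and the whole plane is the observed
frame: collapsing the 3-D tissue field to the observation plane keeps the
simulator desk-scale while producing the 2-D frames every downstream
stage consumes. (Treating a single grid row as "the skin" would yield 1-D
observations, which no avatar can be built from.)

**Discretization.** Forward Euler in time; the diffusion term is a
conservative flux form of the 5-point Laplacian with harmonic-mean face
conductivities, so heterogeneous (and zero) conductivity is handled and
an insulated phantom conserves Σ ρcT to round-off — the test suite checks
relative drift < 1e-8 over 1000 steps. Boundaries are zero-flux
(insulated) by default; an optional convective term h(T − T_ambient)/h_cell
along the frame border models skin-to-air loss. The explicit stability
bound dt ≤ min(ρc h²/4k) is enforced with an error naming the maximal
admissible step. First-order accuracy in dt is verified against the
closed-form perfusion-only relaxation T_a + (T0 − T_a)e^(−ω c_b t/ρc).

**Defaults and units.** ρ_t = 1050 kg/m³, c_t = 3600 J/(kg·K),
k_t = 0.48 W/(m·K), c_b = 3617 J/(kg·K), T_a = 37 °C — literature-typical
soft-tissue values. ω_b is a perfusion mass-flow density in kg/(m³·s)
(blood flow rate × blood density), default 0.5, tripled inside tumors as
a vasodilation surrogate. Grids default to 64×64 cells of 2 mm
(configurable to 480×640); sequences to 23 frames at 15 s; initial field
30 °C (a post-acclimatization surrogate). The acquisition protocol behind
a real 23-frame sequence (static vs cooling-recovery, frame spacing) is
not standardized, so the simulator exposes `frame_interval`, `dt` and
`T0` as configuration rather than asserting a protocol.

**Cohorts.** Symptomatic phantoms get one tumor disc (radius 3–6 cells)
placed uniformly inside a random breast disc, with metabolic heat
q_m ~ U[1e5, 1.2e6] W/m³ against 2e4 W/m³ for normal tissue — the
reported range for cancerous vs normal breast metabolism — plus locally
elevated perfusion. Gaussian sensor noise (σ = 0.04 °C, the camera
sensitivity class of screening hardware) is added per pixel and frame.
Covariates mimic the screening population: age ≈ N(60, 15) clipped to
[18, 100], family history (none/diabetes/hypertensive/leukemia at
0.721/0.25/0.024/0.005), hormone therapy Bernoulli(0.183). Covariates are
sampled independently of the label, so clinical-only classification on
synthetic cohorts is chance by construction — a deliberate null.

**What the phantom does not emulate.** Absolute temperatures can exceed
physiological skin values (no radiative/evaporative loss, strong tumor
sources); there is no anatomy beyond two discs, no motion, no camera
fixed-pattern noise, no bilateral asymmetry other than the tumor itself.
A green end-to-end test therefore establishes that the pipeline recovers
a strong, localized thermal-heterogeneity signal from noisy sequences —
not that it reaches any particular accuracy on clinical data.

## Heat matrix

Centering is per-pixel over time (row-wise): the decomposition should
rank patterns by *temporal* variance, which is the thermography
convention. Vectorization is row-major; ROIs are 0-based half-open
rectangles; p > n is enforced (economy shape). Un-centering reconstructs
the ROI exactly (tested).

## PCT and sparse PCT

PCT is the economy SVD via `numpy.linalg.svd` with a deterministic sign
convention (largest-magnitude entry of each basis positive); the test
oracle is an independent eigendecomposition of XᵀX. Sparse PCT is a
penalized power iteration on the implicit covariance XXᵀ: iterate
z ← XXᵀu, ridge-shrink by 1/(1+λ₂), normalize, soft-threshold at λ₁
(applied to the unit-normalized update, so λ₁ ∈ [0, 1) is meaningful),
optionally truncate to a hard cardinality cap, renormalize; converged
when the direction change drops below `tol`. Components are extracted
sequentially with projection deflation X ← (I − uuᵀ)X, and the spectrum
re-sorted non-increasing afterwards. Non-convergence warns and still
returns. With both penalties zero the iteration is exactly the power
method, so the λ→0 limit equals PCT up to sign (tested at 1e-8).

The printed sparsity constraint "‖v‖₀ ≥ k" is infeasible as written; it
is implemented as a cardinality *cap*, consistent with the elastic-net
sparse-PCA formulation it cites. A planted 2-sparse direction is checked
against exhaustive support enumeration (feasible for p ≤ 10). λ₁/λ₂ have
no canonical values; defaults (λ₁ = 0.05, λ₂ = 0) are exposed in config.

k defaults to 3: the avatar needs exactly β₁..β₃ as channels. The 80%
cumulative-variance count (`variance_fraction`) is reported as a
diagnostic, never used to change k.

## Avatar

Each basis is min-max normalized to [0, 1] independently (constant basis
→ zeros), center-cropped square and bilinearly resized to 224. Avatar
scaling is a convention of this package; backbone-specific input
standardization (pretraining-corpus channel mean/std) is applied inside
the backbone only when pretrained weights are loaded, identity for
seeded-random weights.

## Backbone

The ResNet-50 is a declarative layer table (stem 7×7/2 + 3×3/2 max pool;
bottleneck stages of 3/4/6/3 blocks, mid widths 64/128/256/512, ×4
expansion, projection shortcuts on first blocks; global average pool;
1000-way head). Parameter counting is a closed-form sum over the table
under a fixed convention — biased convolutions, trainable BN γ/β,
non-trainable BN moving statistics — which is the only convention
reproducing the canonical totals 25,583,592 / 53,120; framework variants
that omit convolution biases will not match. The head is kept for
counting and dropped for extraction (features are the 2048-d
global-average-pool output).

No deep-learning framework is available offline, so inference is NumPy:
im2col convolutions (float32 BLAS matmuls), inference-mode batch norm,
reference-counted activation cache. A forward pass takes ~0.2 s on one
CPU. Default weights are seeded He-normal (identity BN statistics):
deterministic, offline, and sufficient for the pipeline because a random
convolutional network acts as a fixed nonlinear random projection that
preserves the avatar's spatial texture differences. Pretrained weights
can be loaded from a local `.npz` (keys `<layer>/kernel` etc.); they are
never required by tests and no download is attempted.

## Sparse autoencoder

Eight dense layers — encoder 2048→1024→256→64→16 and an untied mirrored
decoder — ReLU on all hidden layers (including the bottleneck, making
codes non-negative and sparse-ish), sigmoid output. Inputs are min-max
scaled per feature to [0, 1] (constant features → 0, flagged, scaler
invertible on the rest) because the BCE output contract needs targets in
[0, 1]. Loss: mean BCE (predictions clipped to [1e-7, 1−1e-7]) plus
λ·mean|h₁| on the first encoder activation (λ default 1e-5), the sparse
distributed-representation penalty. Untied decoder weights are the
default (the parameter count of the 8-layer schedule, 4,758,160, assumes
untied); a tied variant (gradient-shared transposes) sits behind a flag.

Training: Adam (lr 1e-3, β 0.9/0.999), batch 128, 500 epochs by default,
seeded shuffling and initialization — reproducible run-to-run in NumPy
float32. Divergence (NaN loss) raises with advice to lower the learning
rate. The published epoch/iteration counts differ between 500 epochs and
3000 iterations; both are exposed in `TrainConfig` with 500 epochs as the
default. The model trains on whatever feature table is supplied (the
synthetic cohort supplies one row per subject); tests verify the
entropy-floor limit on repeated inputs, monotone 10-epoch-averaged loss,
λ-monotone code shrinkage, and cluster preservation (positive silhouette)
in the 16-d latent space.

## Classification

Random forest (scikit-learn), 1000 trees, √d features per split, fixed
`random_state`, LOOCV over subjects. The accuracy interval is a
percentile bootstrap (2000 resamples, 2.5/97.5 percentiles) over the
out-of-fold correctness vector — reproducible and assumption-light, since
no interval construction is canonical for LOOCV; the interval is clamped
to contain the point estimate. ROC is computed from pooled out-of-fold
class-1 probabilities. Because forests are sensitive to row order at a
fixed seed, subjects are canonically sorted by `subject_id` before every
fit, bootstrap and pooling step; LOOCV output is therefore invariant to
the caller's row order (tested). Family history defaults to any-vs-none
encoding (one-hot over the four levels available), hormone therapy
optional.

## Pipeline

One `RunConfig` (YAML-serializable) drives simulate → decompose →
features → autoencoder → classify; `method="both"` runs sparse PCT and
PCT side by side and writes a comparison table. Expensive stages
(simulation, deep features) are cached by a content hash of their
configuration slice. With fixed seeds and seeded-random weights a run is
end-to-end deterministic (tested byte-for-byte on the report JSON).
External data requires a per-subject ROI table up front; its absence
fails validation before any computation.

## Known limitations

- Random-weight features are a proxy; pretrained features would change
  absolute performance and can only be evaluated with a user-supplied
  checkpoint.
- The phantom's thermal contrast is strong by construction; the pipeline
  is validated for signal recovery, not for clinical effect sizes.
- The sparse-PCT solver is a local (greedy, deflation-based) method; the
  exhaustive-support oracle is only feasible at toy sizes.
- PNG sequence storage quantizes to 0.01 °C; TIFF and text dialects are
  lossless.
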