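# Methods

This note records the models implemented in `ucpwi`, the assumptions of the
synthetic-data generator, and the numerical and design choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Shelled-bubble dynamics (`ucpwi.bubble`)

The radial dynamics R(t) of a phospholipid-shelled microbubble follow a
Rayleigh–Plesset-type ODE with shell elasticity and a nonlinear
(shear-thinning) shell viscosity:

    ρ_l (R R″ + 3/2 R′²) = (P₀ + 2σ(R₀)/R₀)(R₀/R)^{3γ} − 2σ(R₀)/R
                           − 4χ(1/R₀ − 1/R) − P₀ − P_drive(t)
                           − 4η_l R′/R − 4(k₀/(1 + α_t|R′/R|) + k₁ R′/R) R′/R²

with R(0) = R₀, R′(0) = 0. Default constants (SI): ρ_l = 1000, P₀ = 101 000,
γ = 1.07, R₀ = 1.7 µm, σ(R₀) = 0.072, χ = 0.25, η_l = 0.002, k₀ = 4·10⁻⁸,
k₁ = 7·10⁻¹⁵, α_t = 4 µs — a SonoVue-like parameterisation. The far-field
scattered pressure is P(d) = ρ_l (R/d)(2R′² + RR″), exactly ∝ 1/d.

**Integration.** Adaptive RK45 with rtol 1e-8, atol 1e-12 and max_step 1 ns
(the compression phase is stiff); output is sampled on a uniform grid at the
requested rate. R″ is recovered by evaluating the ODE right-hand side on the
solution, never by finite-differencing. The right-hand side guards trial
evaluations at R ≤ 0; a terminal event at R = 0.01 R₀ detects collapse.

**Stability limit.** Implemented exactly as written, the shell-viscosity
bracket k₀/(1+α_t|R′/R|) + k₁R′/R changes sign at large compression shear
(the k₁ term dominates), making the model anti-damped: for a two-cycle 4 MHz
drive the compression phase runs away above ≈ 60 kPa peak pressure. The
solver reports this as a `BubbleCollapseError`. The default drive is
therefore 58 kPa — just under the runaway threshold, maximising harmonic
content while keeping the mechanical index at 0.029, far below the 0.1
bubble-destruction limit. The harmonic-growth property test covers the
stable 1–50 kPa range.

**Drive pulse.** `DrivePulse` models the *acoustic* pulse as an n-cycle
sinusoid with a Hann taper by default: a transducer excited by a hard-gated
two-cycle sine radiates a band-limited pulse, and the taper is the simplest
stand-in for that band-limiting. A "rect" envelope (the raw gated sine) is
available.

**Mother wavelet.** The scattered pressure is trimmed to the window holding
99.9 % of its energy (compact support for convolution), mean-subtracted
(admissibility), and normalised to unit energy (Σψ²·dt = 1). Its spectral
peak f_c is located on a zero-padded FFT. At 25 MHz sampling the default
wavelet is 17 samples long with f_c ≈ 3.9 MHz — the bubble radiates mostly
near its (shelled) resonance, slightly below the 4 MHz drive. The optimal
dilation s = f_c / (2 f_tx) places the dilated wavelet's passband at the
second harmonic; dilation is linear-interpolation resampling of ψ(t/s) with
the L2 factor 1/√s.

## Plane-wave RF simulator (`ucpwi.rf_sim`)

The generator emulates a 0° plane-wave acquisition on a 128-element linear
array (pitch 0.3 mm, 25 MHz sampling, 2100 samples per line by default;
sound speed 1540 m/s — the standard soft-tissue value, unstated by the
instrument configuration). For a scatterer at (x, z) and element i at x_i,
the echo arrives at τ_i = (z + √((x−x_i)² + z²))/c₀ with amplitude ∝
strength / return-distance; fractional delays are applied by linear
interpolation. Tissue scatterers return the transmit pulse; bubble
scatterers return the Doinikov scattered-pressure waveform (unit-peak
normalised — scatterer strengths set the scale). Per-sample truth labels
mark bubble and tissue echo supports, bubble taking precedence where echoes
overlap. Additive white Gaussian noise is seeded and reproducible; fixed
seeds give bitwise-identical frames.

**What the generator emulates and what it does not.** It reproduces the
statistical structure the method exploits — tissue echoes centred at the
transmit frequency, bubble echoes carrying a second harmonic (averaged
bubble-segment spectra sit ≥ 10 dB above tissue segments at 2 f_tx under the
default conditions; the property test pools several frames because
single-frame estimates scatter by a few dB) and a much larger covariance
eigenvalue over bubble regions. It omits element directivity, frequency-
dependent attenuation, multiple scattering, speckle from unresolved
sub-wavelength tissue microstructure, bubble motion, and transducer impulse
response beyond the Hann taper. Passing tests therefore demonstrate the
pipeline's mechanics and relative orderings under its own assumptions, not
calibrated performance on clinical data.

**Random scenes.** Training phantoms draw 40–80 tissue scatterers (dense,
speckle-like overlap), 3–5 bubble *clusters* of 4–7 bubbles each (contrast
agent fills vessels, it does not appear as isolated scatterers), bubble
strengths 1.5–6 against tissue 0.5–2 (contrast agents scatter several-fold
stronger per scatterer), noise σ = 0.2, and transmit frequencies cycled
through 3/4/5 MHz — the acquisition-parameter variation used to enrich a
real corpus.

**Segmentation and corpus.** Sliding windows of length 60 with step 5
(409 per 2100-sample line). A window's label is the majority of its
labelled samples, ties to bubble; windows > 50 % background are excluded
from corpora, as are windows whose majority class holds < 70 % of labelled
samples: real corpora are collected from acquisitions that are purely
bubble or purely tissue, so straddling windows with near-arbitrary majority
labels would only inject label noise (they are still scored at inference).
The corpus is balanced to 45 % bubble / 55 % tissue and split 80/20 at
*frame* level — windows overlap heavily within a frame, so a segment-level
split would leak.

## Segment classifiers (`ucpwi.classifier`, `ucpwi.nn`)

All models consume a (batch, 60) window of raw RF, normalised per segment to
unit peak (echo amplitude spans orders of magnitude with depth; the class
information is waveform shape), and emit two-class softmax probabilities.

**U-net.** Encoder 1→32→32 | 32→64→64 | 64→128→128 with 2×1 max pooling
(60 → 30 → 15 → 7, odd tails dropped); bottleneck 128→219→219; decoder
up-convolutions 219→128, 128→83, 83→51, each upsampling nearest-neighbour
×2 with deterministic zero-padding to the matching encoder length, fused by
concatenation with the corresponding encoder feature map and followed by one
convolution (256→128, 147→83, 83→51); dense head 3060→2. All convolutions
are kernel-3, stride-1, zero-padded; ReLU activations; dropout (rate 0.5)
after each encoder block and the bottleneck — four dropout layers, fourteen
convolutions, three fusions, one dense layer. The free widths (219; 128, 83,
51) were fixed by integer search so the trainable-parameter total is exactly
607,112, the architecture's printed checksum; the search space was every
plan consistent with the layer inventory above.

**Baselines.** CNN: two 128-filter convolutions, max-pool, two 64-filter
convolutions, max-pool, dropout, two dense layers (960→64→2). RNN: four
100-unit tanh Elman layers, dropout on the last hidden state, three dense
layers (100→64→32→2).

**Engine.** A deliberately small NumPy implementation — im2col convolution,
pooling with cached argmax, hand-written backward passes, softmax
cross-entropy, Adam — in float32. Gradients are verified against
double-precision finite differences in the test suite (weights only:
zero-initialised biases sit exactly on ReLU kinks, where one-sided finite
differences legitimately disagree).

**Training.** Defaults follow the study schedule: batch 100, 150 epochs,
Adam with step 1e-5, β₁ 0.9, β₂ 0.999, ε 1e-8, cross-entropy. The **fast
profile** (`TrainConfig.fast()`, used by CI-scale runs and the acceptance
script) trains 6 epochs at step 1e-3 with ×0.6 per-epoch decay: Adam's
step-size bound means 1e-5 cannot move 607k parameters far in a few epochs,
so the fast profile trades the long schedule for a larger, annealed step.
Training is deterministic given the seed (init, shuffling and dropout all
derive from it). Divergence (non-finite loss) aborts with a diagnostic.

**Mask aggregation.** At inference every window is scored and each sample's
bubble probability is the mean over all windows covering it (order-
invariant); the binary mask thresholds at 0.5. How per-segment decisions
become per-sample masks is not constrained by the segment design; mean
aggregation is the declared choice.

## BAWT (`ucpwi.bawt`)

Real-valued "same"-mode correlation of each RF line with the dilated,
unit-energy-renormalised wavelet (L2 convention; the wavelet is a real
measured-pressure waveform and the beamformer expects real RF). Edges are
zero-padded, so coefficients near line ends are attenuated. `apply_bawt`
replaces bubble-classified samples with the coefficient at the configured
scale and zeroes tissue-classified samples.

A band-selectivity analysis tempers expectations of the CWT alone: the
17-sample wavelet's dilated kernel has ~11 dB selectivity between 8 and
4 MHz, while the bubble echo's own energy is mostly fundamental, so pure
coefficient replacement changes bubble-to-tissue *energy* ratios by only a
few percent — the matched-filter advantage is a *peak* effect, and the
chain's tissue suppression comes from the mask and the eigenvalue
threshold. This matches the small printed increments that BAWT contributes
in the original tables.

## Beamforming (`ucpwi.beamform`)

Scan lines sit at the element lateral positions (one line per element);
depths default to the two-way sample grid z_k = c₀k/(2 f_s), optionally
decimated. Delays use linear interpolation; out-of-window times contribute
zeros and are flagged.

Per pixel: subarray covariance R = (1/(M−L+1)) Σ_p x_p x_pᴴ over sliding
length-L subarrays (L = 32); diagonal loading R̃ = R + δ·tr(R)·I with
δ = 1/(10L) by default (the constraint is δ ≤ 1/L; 1/(10L) is a
conventional light loading); eigendecomposition with eigenvalues sorted
descending; signal subspace U_S = span{v_i : λ_i ≥ α λ₁}, α = 0.4, N ≥ 1
(the alternative noise-floor rule for choosing N is not implemented — the
processing flow specifies only the α rule). DAS is the element mean; MV
applies w = R̃⁻¹d/(dᴴR̃⁻¹d) with d = 1 (delays already applied — the
standard steering for delayed data); ESBMV projects w onto U_S. One weight
is computed per pixel and shared across the subarray sum, which is how the
output equations read. A silent pixel (tr R = 0) falls back to uniform DAS
weights. The whole-image engine vectorises covariance assembly, batched
`eigh`, and batched solves per line, and is tested to agree with the
single-pixel reference functions to 1e-10.

**Detection.** λ₁ is far larger over bubble pixels than tissue pixels; a
pixel is flagged bubble when λ₁ ≥ c · (its scan line's maximum λ₁),
c = 0.15, per line (each non-silent line flags at least its own argmax; no
connectivity is enforced). Outside the detection mask the final image is
set to the display floor (−60 dB).

**Display.** Envelope by analytic-signal magnitude along each line
(standard for RF), then 20 log₁₀(env/max) clipped to [−60, 0] dB.

## Pipeline and metrics (`ucpwi.pipeline`)

The seven steps run in order with every intermediate retained for
inspection; any stage failure aborts with the stage name. Ablation switches
reduce the chain to BAWT + threshold (no classifier) or classifier + ESBMV
(no BAWT/threshold); both are exposed on the CLI.

CTR and CNR are computed on the linear envelope before log compression
(dB means on a clipped display would saturate); the CNR numerator uses
|I_UCA − I_tissue| so the logarithm is defined when tissue outshines
contrast, as it does in unprocessed frames. Improvement is
|CTR_method − CTR_DAS|. A zero-intensity tissue region yields +inf with a
warning.

## Problem sizes

Desk-scale defaults keep every run on one CPU: the training corpus is
20,000 segments from 12 frames of 32 elements (fast profile ≈ 3–4 minutes);
the evaluation fixture is a 64-element, 1100-sample frame (a contrast tube
at 18–20 mm under a strong scattering layer at ~10 mm) beamformed on a
64-line × 275-depth grid. Full 128 × 2100 frames are supported throughout.

## Known limitations

- The shell model as written is anti-damped above ≈ 60 kPa (two-cycle
  4 MHz), so high-MI regimes cannot be simulated.
- The simulator's idealisations (no directivity, attenuation, or real
  speckle) make absolute CTR/CNR values fixture-specific; only orderings
  and mechanism-level properties are meaningful, and the per-stage margins
  (e.g., how much the classifier alone improves ESBMV) vary between seeds
  and trained models.
- Accuracy targets are evaluated on synthetic corpora whose difficulty is
  set by the generator, not on clinical recordings.
- The RNN baseline trains slowly (sequential BPTT in NumPy) and is included
  for interface parity; the quantitative claims attach to the U-net.
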