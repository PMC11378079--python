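# Methods

## Tissue model

Both anatomies are planar layered media indexed by a single free parameter
vector (B, S, fm, a):

| layer | thickness | composition | μs′ |
|---|---|---|---|
| skin: epidermis | 0.1 mm | melanosomes `fm`, 50% water, background | a·(λ/500)⁻² |
| skin: dermis | 2 mm | blood `B` at saturation `S`, 70% water, background | a·(λ/500)⁻² |
| skin: subcutis | ∞ | fixed: 0.5% blood (S=0.7), 15% water | 1.2 mm⁻¹ |
| gingiva: epithelium | 0.2 mm | melanosomes `fm`, 50% water, background | a·(λ/500)⁻² |
| gingiva: lamina propria | 1.5 mm | blood `B` at `S`, 70% water, background | a·(λ/500)⁻² |
| gingiva: dentin | 2 mm | fixed: flat 0.3 mm⁻¹ | 3.0 mm⁻¹ |
| gingiva: pulp | ∞ | fixed: 5% blood (S=0.7), 80% water | 1.0 mm⁻¹ |

Refractive index 1.4 in every layer (ambient 1.0), anisotropy g = 0.9, and a
constant background absorption of 0.025 mm⁻¹ in the top two layers. The
free layers share one scattering intensity; the deep fixed layers carry
single literature-typical values — they sit under ≥1.6 mm of perfused
tissue, so Rd in 420–830 nm is only weakly sensitive to them. Blood
saturation partitions whole-blood absorption as
S·ε_HbO₂ + (1−S)·ε_Hb. Layer lists are declarative (`LayerSpec`) and
YAML-serializable, so alternate anatomies (e.g. blood-free pulp, extra
layers) need no code changes.

### Chromophore library

Packaged two-column text tables give absorption in mm⁻¹ per unit volume
fraction: oxy-/deoxygenated whole blood (molar-extinction compilation
anchors at 150 g Hb/L, 64 500 g/mol, capturing the Soret bands, the
542/577 nm oxyhemoglobin doublet, the 555 nm deoxy band, the deoxy-dominant
red window and the ~800 nm isosbestic point), melanosome interior
(6.6×10¹¹·λ⁻³·³³ cm⁻¹), and pure water (visible/NIR compilation). The
tables are smooth anchor sets (5–20 nm spacing) evaluated by piecewise
linear interpolation; out-of-range evaluation is an error, never an
extrapolation. Absolute hemoglobin band heights are accurate at the few-
percent-of-feature level, which is far below the corpus noise floor; the
sidecar `data/library.json` records units and conversions.

## Monte Carlo transport

`simulate_rd` is a standard weighted multi-layer kernel: photons launch
perpendicular to the surface just inside the top layer with unit weight
(the imaging geometry rejects specular light with crossed polarizers, so no
specular term enters Rd); dimensionless exponential steps with per-segment
boundary handling; weight deposition W·μa/μt per interaction;
Henyey–Greenstein deflection; unpolarized Fresnel reflection/refraction
with total internal reflection at index-mismatched interfaces; Russian
roulette below weight 10⁻⁴ with survival 1/10. Stacks store μs′; the kernel
converts μs = μs′/(1−g). With roulette disabled, sub-threshold photons
deposit their remainder into the absorbed tally so Rd+Td+A = 1 to floating
precision (with roulette the identity holds in expectation). A step cap
(default 10⁶) guards the recurrent zero-absorption corner case; capped
photons count as absorbed. Randomness: NumPy `SeedSequence` substreams per
wavelength / per node seed the in-kernel generator, so equal seeds give
bit-identical results.

### Path-length ("white") acceleration

Photon trajectories are independent of absorption, so for corpus and lookup
generation the engine simulates paths absorption-free on a 1-D grid of
tissue μs′ values (32 log-spaced nodes covering a∈[0.5,5] mm⁻¹ times the
(λ/500)⁻² range, 10⁴ photons per node) and records per-layer path lengths
of photons escaping the top surface. For any absorption vector the survival
estimator

    Rd = E[ exp(−Σ_l μa_l ℓ_l) ]

is then evaluated analytically over the recorded paths; off-node μs′ values
interpolate linearly in ln μs′. This reuses one photon set across every
(B, S, fm, λ) combination — the entire forward-model table costs ~1 minute
on one CPU — and is cross-checked against the direct weighted kernel in the
test suite (agreement within Monte Carlo error). Wandering photons are
terminated once a guaranteed-minimum attenuation bound (per-layer minimum
μa times recorded path) exceeds e⁻¹⁴, a relative bias below 10⁻⁶.

The lookup table spans log₁₀B×S×fm×a = 9×9×13×9 nodes per wavelength
(B log-spaced over 0.1–10%). Attenuation is exponential in melanin and
blood content, so those axes are densest; the multilinear interpolation
error is ≤ ~0.015 reflectance (mean ~0.001) over the sampled space, and
tests allow for exactly that tolerance where the lookup stands in for fresh
transport.

## Simulated corpus

Study conditions: parameters drawn independently — B log-uniform in
[0.1%, 10%], S uniform [0, 1], fm uniform [0, 20%], a uniform
[0.5, 5] mm⁻¹ — spanning light-to-dark pigmentation and the in-vivo blood
and scattering ranges. Spectra live on the camera band convention
λᵢ = 400 + i·(600/299) nm, i = 0…298, windowed to 420–830 nm (205 bands).
Additive i.i.d. Gaussian noise per spectrum with σ set from a target SNR
drawn uniformly in 10–16 dB, where SNR ≡ 10·log₁₀(mean(Rd²)/σ²) on the
clean spectrum; noise is added before the random 64/16/20 split. Labels are
stored as (log₁₀B, S, fm, a), matching the network output. Per-band input
and per-column output min–max scalers are fitted on the training split
only; transforms do not clip, and a degenerate column maps to 0.

At full scale the corpus is 30,000 spectra per tissue (splitting exactly
into 19,200/4,800/6,000); the package default working profile is 4,700
spectra (3,008 training) with the 10⁴-photon forward tables — sizes chosen
so the complete study, including network training and the least-squares
head-to-head, re-runs in minutes on a single core.

What the generator emulates: physically consistent spectra across the
parameter space with realistic measurement noise levels. What it does not:
wavelength-correlated or signal-dependent instrument noise (shot/read
noise, stray light), the camera's true spectral response, tissue curvature
and lateral heterogeneity, and motion. Passing tests therefore demonstrate
the correctness and self-consistency of the inversion pipeline, not its
in-vivo accuracy, for which no desk-scale ground truth exists.

## Inverse models

**Network.** 205 → 256 → 128 → 64 → 4, ReLU hidden activations, linear
output, Adam (lr 10⁻³, batch 64), MSE on scaled targets with equal channel
weights, ≤ 300 epochs with early stopping (patience 25) on the validation
split; weights from the best validation epoch are restored. Widths form a
pyramid between the input and output sizes; one model per tissue. Training
is an explicit `partial_fit` epoch loop so split usage and checkpointing
are exact and seeded. Prediction inverse-scales the outputs and
exponentiates the blood channel.

**Least-squares baseline.** Bound-constrained trust-region least squares
(`scipy.optimize.least_squares`) over (log₁₀B, S, fm, a) minimizing the
spectrum-domain residual against the lookup-backed forward model;
numerically differenced Jacobian; multi-start (range center plus two
random starts, best objective kept) because the objective is mildly
multimodal in (B, fm). Blood is fitted in log₁₀ for conditioning parity
with the network. Using the lookup rather than fresh transport inside the
optimizer preserves the estimator while reducing per-spectrum cost from
minutes to milliseconds; lookup-vs-direct agreement is verified separately.

## Cube pipeline

Flat-field and tile calibration are exact linear algebra: the per-band tile
statistic is the region mean (a region-size-invariant equivalent of the
summed pixel value, the scale difference being absorbed into the slope),
and the per-band line fit is closed-form least squares. Six in-frame tiles
are the default; a helper bootstraps unknown tile reflectances from the
five manufacturer standards (0.02/0.10/0.20/0.40/0.80). Reflectance cubes
feed per-pixel prediction, by default on 2×2-binned spectra; ROI statistics
are means/SDs over roi∩mask. Cube I/O is ENVI (text header + raw binary,
BSQ/BIL/BIP) with float-TIFF export for maps; rectangles are half-open
(row0, row1, col0, col1), row-major and 0-based.

## Numerical choices and degenerate inputs

- Interpolation everywhere is piecewise/multilinear; no extrapolation —
  out-of-range chromophore or lookup queries raise, except an explicit
  `clip=True` mode used when forward-modelling unconstrained network
  predictions.
- Split sizes round val/test down, remainder to train; corpora below 3 rows
  are rejected.
- Zero-μt layers are treated as transparent (ballistic flight to the
  boundary). μs′ = 0 with μa > 0 gives Rd = 0 exactly.
- All stochastic components (sampling, noise, splits, transport, training
  shuffles, multi-start) derive 32-bit substreams from one `SeedSequence`
  seed.

## Known limitations

- The MSE-trained network shrinks extreme saturations toward the corpus
  mean at the default noise level (regression to the mean): on a true-S
  sweep at B = 2% the predictions are monotone but compressed, and region
  means are reliable to ~0.1 only in the mid-physiological range. Larger
  corpora and lower noise reduce the shrinkage.
- Saturation is weakly identifiable when blood volume is near its lower
  bound (0.1%), which dominates the aggregate S error.
- Chromophore tables are smooth approximate compilations, adequate here
  because corpus noise dominates, but not a metrological reference.
- Fixed deep-layer optical properties are single literature values; the
  declarative tissue config is the intended extension point.
- The transport model is planar and unpolarized; no spatially resolved
  Rd(r), fluorescence, or polarization tracking.
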