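# Methods

## Rupture competition model

Two bonds in series — the protein–DNA sample bond and the DNA-duplex
reference bond — feel the same force F(t) = r·t under a constant-velocity
retraction. Each bond fails with a Bell off-rate k(F) = k₀·exp(F/F_β).
Serial elastic compliance of the PEG/DNA linkers is ignored: the read-out
depends only on which bond breaks, not on the precise force–extension
path, so both bonds are assumed to carry the identical instantaneous
force. Rebinding, loading-geometry heterogeneity, and sequence-level
unzipping models are out of scope.

The probability that the reference breaks first is the competing-risks
integral

    P_ref = ∫₀^F_max (k_ref(F)/r) · S(F) dF,
    S(F)  = exp(−[Λ_ref(F) + Λ_sample(F)]),
    Λ(F)  = (k₀·F_β/r)·(e^{F/F_β} − 1).

`reference_rupture_probability` evaluates this with adaptive quadrature
(absolute tolerance 1e−8), cutting the domain off where S < 1e−12 (or at
the optional force cap). Without a cap, P_ref + P_sample = 1 exactly.
`simulate_rupture` draws the same process: the total rupture force is
sampled by inverse-CDF inversion of Λ_ref+Λ_sample (vectorized bisection,
80 iterations), then the broken bond is a Bernoulli draw with probability
k_ref/(k_ref+k_sample) at that force. The quadrature and the Monte Carlo
are implemented independently and cross-checked in the tests.

### Duplex → Bell parameters

The mapping from reference length to kinetics is a simulator choice (no
kinetic parameters are measured here):

    k₀(n_bp) = k₀,₁ · exp(−ΔG_bp · n_bp),   F_β constant per geometry.

| parameter | shear | zipper | meaning |
|---|---|---|---|
| k₀,₁ (1/s) | 30 | 30 | prefactor of the per-bp rule |
| ΔG_bp (1/bp) | 0.6 | 0.12 | log-rate gain per base pair |
| F_β (pN) | 8 | 4 | force scale of the off-rate |
| loading rate r (pN/s) | 100 | 100 | default ramp |

Shear duplexes load all base pairs in parallel and gain stability quickly
with length; zipper peeling gains little per base pair and has a smaller
force scale. The numbers are chosen so that 20–40 bp shear references
rupture in the tens-of-pN to ~200 pN range at 100 pN/s and, most
importantly, so that rupture probability is strictly monotone in length —
all calibration logic depends only on that monotonicity, not on the
absolute rates. The experimental retract velocity is not part of the
available record; 100 pN/s is a configurable placeholder.

## Synthetic imaging

One field of view is a 4×4 grid (configurable) of square pads centred in
a 16-bit image. Ground truth per pad: protein density (counts), transfer
probability p, and a transfer-ratio spread σ_p. Per pixel:

    saturation = B + D·φ·(1+cv·g_s) + ε_s
    transfer   = B + D·φ·p(x)·(1+cv·g_t) + ε_t

with background B ~ N(μ_B, σ_B²), density D, shared inhomogeneity field φ
(Gaussian-filtered noise, unit mean, amplitude < 1, identical in both
channels because the same immobilized proteins are imaged twice),
independent per-channel multiplicative noise g and read noise ε, and a
per-pixel transfer ratio p(x) = clip(p + σ_p·ζ(x), 0, 1) — each pixel's
construct population has its own transferred fraction, which is what
gives a pad's NF histogram its finite width. Default scales follow the
published images: μ_B = 1500 counts (stated range 1000–2000), strong-pad
density 15 500 counts so a fully transferred pad reads 17 000 counts;
default (p, σ_p) per condition are the published NF table
(0.65±0.07, 0.32±0.01 high affinity; 0.39±0.15, 0.20±0.02 low affinity;
0 for no binding). Counts are kept as float64 clipped to [0, 65535] in
memory and quantized to uint16 on TIFF export, so noise-free ratios are
exact in memory.

Not emulated: optical PSF and defocus, chromatic/stage registration
error, photobleaching, Poisson statistics (multiplicative Gaussian noise
approximates shot noise since counts ≫ 1), autofluorescence structure,
and pad-placement error. Passing tests therefore demonstrate correctness
of the *analysis* given the stated image model, not robustness to every
optical artefact of a real microscope.

## NF pipeline

- **Background**: median and 1.4826·MAD of all pixels outside the pad
  rectangles, per channel. A smoothly varying field estimator
  (in-painting pads, Gaussian smoothing) is available for non-uniform
  illumination; the scalar estimate is the default.
- **Subtraction**: pixel-wise, clipped at zero.
- **Division**: transfer/saturation wherever the corrected saturation
  signal ≥ `min_denominator` (default 5 robust SDs of the background,
  floor 1 count); other pixels are invalid, not zero. NF > 1 values are
  retained — clipping would skew the Gaussian fits.
- **Segmentation**: pads are known by design; masks are the pad
  rectangles eroded by a 2 px margin (edge pixels mix pad and
  background). An over-eroded (empty) pad is reported as `failed`.
- Channels are assumed registered (same stage position); no alignment.

## Per-pad statistics

Valid NF pixels of a pad are histogrammed into 100 uniform bins over
[min, max] and fitted with A·exp(−(x−μ)²/2σ²) by least squares,
initialized from the sample moments; the fitted (μ, σ) are the pad's
NF mean ± SD. Pads with fewer than 500 valid pixels, or non-converging
fits, are `failed`. The **zero rule**: a pad whose median raw transfer
signal ≤ background mean + 3σ (inclusive) is `zeroed` — NF = 0, no fit.
Two fitted pads are **equal within errors** iff |μ₁−μ₂| ≤ σ₁+σ₂ — the
most permissive reading consistent with calling 0.39±0.15 and 0.32±0.01
equal; the ± here is the fitted histogram SD, not a standard error of the
mean.

## Calibration

Per motif, mean NF vs reference length is fitted by ordinary least
squares (exact interpolation for two lengths); zeroed conditions are
excluded from fits but reported with NF 0. The matched-stability length
solves NF(L) = 0.5; solutions outside the fitted length range are flagged
as extrapolation since linearity is only established within it, and
|slope| < 1e−12 NF/bp raises a degenerate-model error. Equivalent-bp
differences come from two methods: `matched_pair` (default — the length
gap of the best equal-within-errors cross-motif pair, ties broken by
smallest |ΔNF|; deterministic and assumption-free but requires a lucky
overlap) and `linear_model` (difference of matched lengths; needs ≥ 2
reference lengths per motif). On the published table they give 20.0 and
20.7 bp. When replicate pads share a condition, the report averages their
fitted means and SDs before pairing.

## Numerical and design choices

- All randomness flows through `numpy.random.SeedSequence`; a run's seed
  reproduces every array, CSV and JSON byte for byte.
- Bisection (80 iterations) rather than Newton for hazard inversion:
  unconditionally convergent for the monotone cumulative hazard.
- The quadrature cutoff (survival < 1e−12) bounds the truncation error
  of P by 1e−12, far below the 1e−8 quadrature tolerance.
- Degenerate single-valued pads (zero histogram range) return the value
  with σ = 1e−6 instead of attempting a fit.
- Acceptance-style computations use a 256×256 single-pad field
  (~24 000 valid pixels) and 10⁵ Monte-Carlo replicates; both finish in
  seconds while leaving Monte-Carlo errors (≈2·10⁻³) well below the
  tolerances of interest.

## Known limitations

- The Bell model has no force-history or catch-bond behaviour; only the
  identity of the broken bond matters here.
- Equivalent-bp statements inherit the linearity assumption; outside
  20–40 bp (or for zipper references) the flagged extrapolations should
  not be trusted, and no free-energy or K_d conversion is attempted.
- Fitted-SD error bars understate replicate-to-replicate variability of
  real experiments; multi-slide aggregation is out of scope.
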