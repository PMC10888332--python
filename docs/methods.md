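# Methods

This note documents the models, algorithms and design choices behind
`pwqus`, in the spirit of a methods appendix: what is simulated, how each
quantity is estimated, which knobs matter, and what the synthetic
experiments do and do not demonstrate.

## 1. Tissue phantoms

A phantom is a set of co-registered 2D property maps — attenuation
coefficient AC (dB/cm/MHz), speed of sound SoS (m/s), density (kg/m³),
effective scatterer diameter ESD (µm) and effective scatterer
concentration ESC (scatterers per squared wavelength) — over a square
region of interest, default 0.2 mm pitch. The background is a layered
skin (2 mm) / subcutaneous fat / gland stack; lesions are ellipses or
boundary-perturbed ellipses (low-order Fourier modulation of the polar
radius) embedded in the gland. Property values per tissue class are drawn
uniformly from configurable ranges chosen to bracket published group
statistics for benign and malignant breast lesions and the typical
soft-tissue literature values: e.g. AC 0.35–0.65 (benign) vs 0.6–1.1
dB/cm/MHz (malignant), SoS 1520–1560 vs 1545–1600 m/s, ESD 85–105 vs
70–92 µm, ESC 1.2–4.2 /λ² for both. Density defaults to ~1000 kg/m³ with
small class contrasts; it participates in scattering conceptually but the
forward model below does not use it quantitatively.

## 2. Plane-wave RF forward model

Full wave-equation simulation is out of scope; instead each phantom is
converted to discrete point scatterers and echoes are synthesized
directly. Scatterer count per pixel is Poisson with expectation
`ESC · pixel_area / λ²` (λ at the 5 MHz center frequency in 1540 m/s
tissue), positions uniform within the pixel, reflectivity zero-mean
Gaussian with standard deviation proportional to the local ESD (larger
scatterers return more low-frequency energy; the *spectral* size
signature is carried by the form factor).

The central trick: the transmit pulse has a Gaussian amplitude spectrum
(60 % FWHM fractional bandwidth), and both frequency-dependent
attenuation `exp(-β f)` and the Gaussian form factor
`F(f) = exp(-0.827 k² (ESD/2)²)` (amplitude `√F = exp(-γ f²)`) are
exponentials of polynomials in frequency. Their product is again a
Gaussian spectrum with a shifted center frequency, modified width and a
closed-form amplitude constant, so every echo is deposited in the time
domain as a Gaussian-modulated cosine with per-echo effective parameters
— no per-frequency filtering, and the spectra seen by the estimators obey
the model *exactly*. The deposit kernel advances the envelope and carrier
by multiplicative recurrences, avoiding transcendentals in the inner loop
(numba-compiled).

Geometry: plane-wave transmit with per-element delays
`T(n) = n·pitch·sin θ / c_ref` (128 elements, 0.3 mm pitch, c_ref =
1540 m/s, angles −10…10°), receive at 62.5 MHz for 3018 samples (a record
that covers ≈ 37 mm of depth at 1540 m/s; deeper scatterers truncate).
Travel times integrate the depth-averaged slowness of the column above
each scatterer along straight transmit and (oblique) receive paths;
attenuation uses the column-mean AC times the *actual two-way path
length* of each scatterer–element pair, so oblique paths are dimmer, as
in tissue. Spreading is 1/√r; electronic noise is white Gaussian at 30 dB
SNR relative to the frame RMS.

Known limitations: no multiple scattering, no refraction, no elevation
focusing, no frequency-dependent element directivity. These are the
standard omissions of point-scatterer simulators; they mainly affect
absolute image texture, not the spectral features the estimators consume.

## 3. Classical estimators

All spectral estimators operate on *beamformed* complex images, not raw
element traces: within one range gate the 128 element signals are highly
correlated (they see the same scatterers), whereas beamformed lines half
a beamwidth apart carry nearly independent speckle. Delay-and-sum uses an
F-number-1 receive aperture for spectral work (full aperture for sound
speed, where defocus sensitivity is the signal). Windows are 4 × 4 mm
with 50 % overlap (Hann along depth); periodograms average over the
window's lines and all steering angles. The white-noise floor is
estimated per window from bins far above the pulse band (the axial
beamforming step of 0.035 mm puts the axial Nyquist at ≈ 11 MHz) and
subtracted; bins within a gate of the floor are masked.

**Sound speed** — cross-angle phase coherence: each candidate speed
beamforms all angles onto a central patch; the energy-weighted coherence
factor of the per-angle complex images peaks at the true speed. Grid
search plus parabolic refinement; ties break to the lowest candidate; a
peak on the search boundary returns the boundary value with a warning.
Accuracy on uniform media is ~1–2 m/s. The *estimated* speed is then used
to beamform the target acquisition for the spectral estimators (the
reference is beamformed at its own known speed), which removes defocus
and depth-mapping bias; because the axial frequency axis scales with the
beamforming speed, reference spectra are log-interpolated onto the target
frequency grid before any ratio is formed.

**Attenuation** — spectral log difference against a simulated reference
acquisition of known properties (AC 0.5 dB/cm/MHz, SoS 1540 m/s, ESD
85 µm, ESC 2 /λ²). The log of the noise-subtracted, reference-normalized
power spectrum is linear in frequency with a slope that grows with depth
at a rate `−2 Δα_np · P` per unit depth, where `P ≈ 2.03` is the mean
two-way path per unit depth of the F#1 geometry (transmit cosine +
aperture-averaged obliquity). The per-window map uses a sliding local
regression of slope against depth; the pooled summary uses the joint fit
below.

**Scatterer size and concentration** — Gaussian form-factor fit: the
reference-normalized log power spectrum is quadratic in frequency; the
`f²` coefficient equals `−0.827 (2π/c)² ((ESD/2)² − (ESD_ref/2)²)` and
the intercept gives the concentration. Because the forward model draws
reflectivity std ∝ ESD, the intercept is corrected by `(ESD_ref/ESD̂)²`
to report ESC in scatterers/λ² — this amplitude convention (and hence the
exact meaning of the fitted concentration) is a package convention, since
no standard normalization exists. Scaling the RF by a gain g leaves AC,
SoS and ESD unchanged and scales the fitted backscatter power (hence ESC)
by g².

**Joint pooled fit.** Per-window quadratic fits at 5 MHz with 4 mm
windows are speckle-limited (the form-factor curvature across a ±3.3 MHz
band is only a few 0.01 nats). The whole-region summary therefore fits
all depths jointly: `lnr(z, f) = A_z + B f + C f² + D z f`, with
per-depth intercepts absorbing speckle power, `D` the attenuation slope
and `C` the size curvature, each bin weighted by reference power and
masked by its noise gate. The fit is performed in MHz — the same model in
Hz has a condition number around 10¹³ and silently corrupts the
curvature.

**Beamforming curvature calibration.** Delay-and-sum mixes receive paths
of different obliquity; each oblique element contributes an axially
stretched (frequency-scaled) copy of the pulse, and attenuation reweights
these components with depth. The net effect is a residual quadratic
spectral term proportional to `Δα · z`. Its constant is a property of the
acquisition geometry alone, so it is measured once per configuration from
two reference phantoms whose AC differs by a known 0.3 dB/cm/MHz (same
scatterer seed, so speckle cancels in the ratio) — exactly the
two-reference calibration a QUS lab performs on physical phantoms — and
the calibrated term `κ · Δα̂ · z · f²` is subtracted before the curvature
is read off. `Δα̂` itself comes from the uncorrected fit's `D` term.

Recovery performance (10 uniform phantoms, 38.4 mm ROI, properties drawn
across the full tissue ranges, two independent speckle realizations
averaged per phantom — the analogue of scanning two planes of one
lesion): median absolute error ≈ 0.03–0.06 dB/cm/MHz (AC), ≈ 0.5 m/s
(SoS), ≈ 4–6 µm (ESD); ESC rank correlation ≈ 0.85–0.9. Because phantoms
obey the forward model exactly, these figures demonstrate internal
consistency of simulator + estimators, not clinical accuracy.

## 4. Conditional encoder–decoder

The network reconstructs all four parameter maps with one set of weights.
Input is a stack of per-angle channel-data planes (128 elements × the
covered depth block-averaged to 128 rows, magnitudes, fixed scale — a
per-sample normalization would erase the absolute backscatter level,
which is itself a cue). A one-hot condition vector selects the objective.

*Encoder*: three stride-2 3×3 convolutions (widths 16/32/64 by default;
512-channel full-scale layout available by widening `stage_channels`),
each followed by conditional instance normalization — per-channel
`γ_cond (x − µ)/σ + β_cond` with one (γ, β) row per condition — and ReLU,
producing a 16 × 16 latent. The conditional tables are initialized with a
small seeded spread (σ = 0.1) around (1, 0): with identical tables all
conditions produce identical features, and at the reference learning rate
of 10⁻⁴ the tables would take thousands of steps to diverge; the
symmetry-breaking prior makes condition-specific behaviour trainable at
desk scale. Dropout (retention 0.5) acts on the latent during training.

*Decoder*: four parallel branches at 16/32/64/128 px. Each projects the
latent (1×1 conv), upsamples (nearest), applies one residual block whose
second convolution is zero-initialized (the block is the identity at
initialization), and emits its resolution's image through a 1×1 head. The
four outputs are upsampled to 128 px, concatenated and fused by a 3×3 +
1×1 bottleneck into the final map. The final bias starts at 0.5 — the
mid-range prior on the [0, 1] target scale.

*Objective*: summed-squared error of the final map plus the same for
every resolution branch against average-pooled targets plus
`λ Σ w²` (λ = 10⁻⁴) on convolution weights; the three parts are exposed
separately and sum exactly to the total. Optimization is Adam
(lr 10⁻⁴, β₁ = 0.9, β₂ = 0.999), batch size 8, up to 120 epochs with
early stopping (patience 10) on a validation split carved at the
train:test ratio 15.5:1; MNAE, PSNR and SSIM are logged per epoch.
Targets are scaled to [0, 1] by fixed physical ranges (AC 0–1.5 dB/cm/MHz,
SoS 1400–1700 m/s, ESD 20–150 µm, ESC 0–6 /λ²).

Everything is NumPy with hand-written backpropagation (im2col
convolutions, analytic instance-norm backward); gradients are verified
against finite differences in the test suite.

*Desk-scale training recipe.* The defaults above (lr 10⁻⁴, dropout
retention 0.5, ≤120 epochs) describe the reference full-scale recipe.
The demonstration suite trains the desk configuration on a 64-row toy
set — 32 simulated frames, each appearing once per condition with the
matching target, since identical inputs demanding different outputs is
what makes the conditional pathway necessary at all — with the learning
rate scaled up to 10⁻³ and dropout disabled. Both changes follow from the
hundred-fold smaller model and dataset: a few hundred Adam steps at 10⁻⁴
cannot move the conditional tables far enough to matter, and latent
dropout noise (unit-scale, per channel) drowns the few-percent
conditional differences a small net develops early in training. Under
this recipe the training loss drops by ~90 % within 30 epochs and
condition switching produces parameter-specific outputs; this
demonstrates that the architecture trains and that conditioning works,
not that a desk-scale net reaches the reconstruction quality of the
full-scale configuration trained on 15 500 simulated frames.

## 5. Malignancy model and statistics

The packaged logistic model carries published coefficients (intercept
−31.7558; AC +10.6396; SoS +0.0210; ESD −0.0975; ESC +0.0805) estimated
on a 55-lesion clinical cohort, with its inference table; probabilities
are `sigmoid(log odds)` and the default classification threshold is 0.5
(none was published). Refitting uses maximum likelihood (statsmodels)
with Wald z inference; perfect separation is detected and flagged rather
than silently diverging. Mann–Whitney U is two-sided with tie correction
(degenerate all-equal input returns p = 1); AUC is the trapezoidal/rank
statistic with a stratified percentile bootstrap CI (2000 resamples,
seed mandatory); binomial CIs are exact Clopper–Pearson from beta
quantiles.

## 6. Synthetic cohorts

Only group medians and IQRs are published, so cohorts are emulated with
log-normal marginals for AC, ESD, ESC (`µ = ln median`,
`σ = ln(q3/q1)/(2·0.67449)`) and a normal for SoS. Within-group
parameters are independent by default (no correlations were published);
a Gaussian-copula correlation hook exists but ships as identity. The
default cohort composition is 32 benign / 23 malignant. Consequences of
the independence assumption are stated where they matter: the fixed
published model scores such cohorts at a mean AUC ≈ 0.85 over 200 seeds —
inside the published confidence band (0.78–0.96) but not equal to the
clinical point estimate 0.90, which depended on the real joint
distribution.

## 7. Numerical and testing conventions

Every stochastic step takes an explicit seed and is reproducible
bit-for-bit; pipeline stages derive their seeds deterministically from
one global seed. Problem sizes in the test suite (25.6–38.4 mm phantoms,
64-sample training sets, 15–30 epochs) were chosen so the full suite
demonstrates each property at desk scale; the statements they support are
about correctness of the implementations, with clinical-scale fidelity
explicitly out of scope.
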