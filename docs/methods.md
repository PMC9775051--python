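# Methods

## The measurement model

A TDFS experiment observes the emission of a solvatochromic probe
(Laurdan in these conditions) through a series of emission windows.  The
package models the underlying time-resolved emission surface as

    S(ν, t) = P(t) · g(ν; ν_p(t), Δ, γ),

where `P(t) = exp(−t/τ_f)` is the excited-state population decay
(lifetime `τ_f`), `g` is the asymmetric log-normal band

    g(ν) = h · exp(−ln2 · [ln(1+α)/γ]²),   α = 2γ(ν − ν_p)/Δ,

(zero where `1+α ≤ 0`; Gaussian of FWHM `Δ` in the `γ→0` limit), and the
band maximum relaxes as

    ν_p(t) = ν(∞) + Δν · Σᵢ aᵢ exp(−t/τᵢ),   Σᵢ aᵢ = 1.

The two reported observables are the overall dynamic Stokes shift
`Δν = ν(0) − ν(∞)` (hydration/polarity proxy) and the integral
relaxation time `τᵣ = ∫₀^∞ [ν(t) − ν(∞)]/Δν dt = Σ aᵢτᵢ` (mobility
proxy).

What the instrument records per emission wavelength λ is the impulse
response `d_λ(t) = S(ν_λ, t)·|dν/dλ|` blurred by the IRF and corrupted
by Poisson counting noise.  The analysis inverts that chain in three
steps.

### 1. Reconvolution decay fitting

Each decay is modelled as `baseline + [IRF ⊛ Σⱼ αⱼ exp(−t/τⱼ)]` with the
measured IRF normalised to unit sum and shifted by a sub-channel offset
(linear interpolation).  Channel times are midpoints, `t_k = (k+½)·dt`,
which makes the discrete convolution a midpoint quadrature of the
continuous one (O(dt²) accurate).  The objective is Pearson χ² with
weights `1/max(c,1)`; channels before the IRF onset (first channel above
10⁻³ of the IRF maximum, minus two) are excluded.

The optimisation uses *variable projection*: amplitudes and baseline are
linear given the lifetimes and shift, so they are solved exactly by
weighted least squares at every step of a bounded nonlinear search over
`(log τⱼ, shift)`.  This removes the amplitude–lifetime cancellation
degeneracies that otherwise trap a full-parameter search, and it is what
makes negative amplitudes (the rising decays expected at the red edge of
a relaxing band) unproblematic.  Initialisation is deterministic: a small
set of log-spaced lifetime ladders spanning fractions of the empirical
mean decay time is probed briefly and the best start is polished, so a
rerun reproduces the same fit.  Covariances come from a
finite-difference Jacobian of the weighted residual at the optimum,
scaled by the reduced χ².

Two fitting modes exist:

- `DecayModel` — one decay at a time, 1–4 components (default 3, typical
  for Laurdan).  This is the right tool for lifetime analysis of a
  single curve.
- `GlobalDecayModel` — one shared lifetime ladder across the whole
  wavelength series with per-wavelength amplitudes (default 5
  components).  Because every emission window watches the same emitting
  state, linked lifetimes are the physically natural model, and they
  suppress the per-curve fit artifacts (±30–50 cm⁻¹, time-correlated)
  that otherwise leak into the late-time reconstruction and bias τᵣ.
  The pipeline uses this mode by default.

### 2. TRES reconstruction

With IRF-free impulse responses `d_λ(t)` in hand,

    S(λ, t) = I_ss(λ) · d_λ(t) / ∫₀^∞ d_λ(t) dt,

where `I_ss` is the steady-state emission spectrum (linear
interpolation between measured wavelengths; 10 nm spacing is too coarse
for splines) and the denominator is the analytic `Σⱼ αⱼτⱼ`.  By
construction the reconstruction time-integrates back to the steady
state.  Intensities are converted to the wavenumber axis with the λ²/10⁷
Jacobian (standard practice for broad bands; a flag disables it), and
each time slice is fitted with the log-normal band.  ν(t) is the fitted
peak `ν_p`, not the grid argmax (which is quantized to the ~400–700 cm⁻¹
wavelength spacing); the argmax series is kept as a cross-check.

The default time grid is log-spaced over 100 points from 0.1× the
channel width to 5× the longest *significant* lifetime — per fit, the
longest component carrying ≥1% of the net integrated intensity, median
across wavelengths, capped at the window length.  The median makes the
grid robust to a runaway component in one noisy curve, which would
otherwise extend the grid into signal-free tail where slice fits return
noise.

### 3. Observables

`SpectralRelaxationModel` fits `ν(t) = c + Σ Aᵢ exp(−t/τᵢ)` with
1–3 components chosen by AIC, weighted by the per-point σ(ν_p) when the
slice fits provide usable ones.  Two physically motivated bounds block a
known degeneracy (a near-constant slow exponential trading against the
offset): the offset must lie within one data span of the observed
series, and component lifetimes may not exceed 3× the window.  The fit
flags *incomplete relaxation* when more than 1% of the fitted amplitude
survives at the window end — in that case ν(∞) is an extrapolation and
should be treated with care.

τᵣ is computed two ways and both are reported: the analytic `Σ aᵢτᵢ`
(primary) and a trapezoidal integral of the observed `C(t) =
(ν(t)−ν(∞))/Δν` completed with the fit's analytic head (0 → first grid
point) and tail (last grid point → ∞).  A >5% discrepancy warns.  When a
time-zero estimate ν(0) is supplied (the reference-solvent construction
`ν(0) = ν_abs,polar − (ν_abs,ref − ν_em,ref)`, peaks taken from
log-normal fits), the total shift is reported alongside the observed
one, but τᵣ always integrates the observed series: relaxation faster
than the IRF cannot contribute to a measured relaxation time.

Uncertainties for (Δν, τᵣ) are available through a seeded parametric
bootstrap over the decay-fit covariances (default 200 resamples; the
tests use fewer).  For global fits the resampling draws per-wavelength
amplitudes from their conditional covariances at fixed shared lifetimes;
lifetime uncertainty is quantified by the global covariance but not
resampled, a deliberate approximation that keeps the bootstrap cheap.

## The synthetic generator and what it does (not) emulate

The generator draws the exact measurement model above: log-normal band
(fixed Δ, γ over time unless a width slope is enabled), multi-exponential
ν(t), Gaussian IRF, per-wavelength Poisson sampling from independent
child streams of one root seed (bit-reproducible).  The steady-state
spectrum is defined as the channel-grid quadrature of the noiseless
impulse decays, so the normalization identity the reconstruction inverts
holds exactly.

Default study conditions (chosen once, as a realistic fluid-phase
Laurdan/bilayer scenario): ν(∞) = 21000 cm⁻¹, Δν = 3000 cm⁻¹ (so
ν(0) = 24000 cm⁻¹ ≈ 417 nm, inside the 400–540 nm acquisition range),
relaxation components a = (0.5, 0.5), τ = (0.6, 2.4) ns giving
τᵣ = 1.5 ns, population lifetime 4 ns, band width Δ = 3000 cm⁻¹ with
γ = −0.2, IRF FWHM 0.1 ns centred at 1 ns, 2048 channels of 20 ps
(window ≥ 5× the slowest timescale), peak 10⁴ counts, 15 emission
wavelengths at 10 nm steps.

Not emulated: detector afterpulsing, pile-up, dark counts,
wavelength-dependent IRFs, scattered excitation light, and any
non-exponential population kinetics.  Passing tests therefore show that
the *inversion chain* is faithful under ideal counting statistics; they
do not certify robustness to those instrument artifacts.

## Bilayer post-processing

Density profiles: each frame is recentred so the reference group
(phosphates by default) sits at z = 0, using a circular mean over the
periodic z axis so groups wrapped across the boundary centre correctly.
A warning fires when the reference distribution is nearly antipodal over
the box (two leaflets exactly half a period apart make the circular mean
ill-defined — relevant for thin water slabs).  Coordinates are wrapped
into a fixed slab taken from the first frame (the z box edge must be
constant to 1%; per-frame slabs for strongly fluctuating NpT boxes are
out of scope), histogrammed per group, normalised by the bin volume
`Lx·Ly·Δz` to number densities in nm⁻³, frame-averaged, and optionally
mirror-symmetrized, `ρ(z) ← (ρ(z)+ρ(−z))/2` (idempotent, exact on
mirrored bins).  Histogram counts are conserved exactly by construction.
Peak positions get parabolic sub-bin refinement.  Area per lipid is
`Lx·Ly / n_leaflet` per frame with block-averaged standard errors
(5 blocks by default).  The toy generator places mirrored Gaussian
leaflets about the midplane of a 64×64×100 Å box; the 100 Å height keeps
leaflets at ±20 Å well away from the antipodal degeneracy.

## Numerical choices and degenerate inputs

- Lifetime bounds: `dt/10` to the window length; shift bounded to ±10
  channels; baselines non-negative (refit without the baseline column if
  the unconstrained solution goes negative).
- Log-normal slice fits: deterministic start from the empirical peak,
  half-maximum crossings (`r/l = e^γ`) and `FWHM = Δ·sinh γ/γ`; |γ| <
  10⁻⁷ switches to the Gaussian branch; a maximum on the grid edge flags
  the slice (`edge_peak`) rather than failing.
- Decays with fewer than 1000 total counts are rejected; generator peak
  counts below 100 warn.
- A non-decreasing ν(t) series (no net red shift) is an error — there is
  no relaxation to extrapolate; a constant surface yields a constant
  series by the same fits.
- Reduced χ² of Pearson-weighted fits runs below 1 when many tail
  channels are empty (weight floor 1 under-counts them); this is a
  reporting convention, not a misfit.

## Known limitations

- The multi-exponential impulse representation cannot be exact for a
  band sliding through a wavelength window (the true time course is not
  a finite exponential sum).  Five shared components keep the resulting
  ν(t) systematics below ~20 cm⁻¹ under the default conditions; the
  noiseless-oracle checks use seven, where the representation error
  drops below 5 cm⁻¹.  Very fast relaxation components (≪ IRF width)
  are not recoverable from the decays alone — use the reference-solvent
  ν(0) estimate to quantify the missed shift.
- GP band integration assumes a ±5 nm monochromator-like window; the
  true instrument bandpass should be configured when known.
- Trajectory post-processing assumes orthorhombic boxes and a z-constant
  analysis slab; no force-field or simulation setup is reproduced here.
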