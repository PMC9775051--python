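# tdfshift

Time-dependent fluorescence shift (TDFS) analysis for lipid-membrane
spectroscopy, plus the steady-state (Laurdan GP) and MD post-processing
that usually accompany it.

Solvatochromic probes such as Laurdan report on their local environment:
after excitation, the surrounding dipoles (water, lipid carbonyls)
reorganise and the emission band slides to the red.  Tracking the band
maximum ν(t) over time separates two quantities that steady-state
measurements mix together:

- **Δν = ν(0) − ν(∞)** — the overall dynamic Stokes shift, a proxy for
  *hydration* (polarity) at the probe's location;
- **τᵣ = ∫₀^∞ [ν(t) − ν(∞)]/Δν dt** — the integral relaxation time, a
  proxy for local *mobility* (larger = more rigid environment).

The package takes raw time-correlated single-photon counting (TCSPC)
histograms — one per emission wavelength — plus the instrument response
function (IRF) and the steady-state emission spectrum, and produces Δν
and τᵣ with diagnostics at every stage:

1. **Decay fitting** (`tdfshift.decay`) — iterative-reconvolution
   multi-exponential fits, `DecayModel(decay, irf).fit()`, per wavelength
   or globally with one shared lifetime ladder
   (`GlobalDecayModel`, the default in the pipeline).
2. **TRES reconstruction** (`tdfshift.tres`) — time-resolved emission
   spectra from the fitted impulse responses normalised to the
   steady-state spectrum, S(λ,t) = I_ss(λ)·d_λ(t)/∫d_λ, with every time
   slice fitted by the asymmetric log-normal band
   h·exp(−ln2·[ln(1+α)/γ]²), α = 2γ(ν−ν_p)/Δ.
3. **Observables** (`tdfshift.metrics`) —
   `SpectralRelaxationModel(t, ν).fit()` extrapolates ν(∞), and
   `relaxation_time` computes τᵣ both analytically (Σaᵢτᵢ) and by
   numerical integration.
4. **Laurdan GP** (`tdfshift.gp`) — GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀)
   from intensity pairs or band integrals, with bootstrap CIs per
   condition.
5. **Bilayer profiles** (`tdfshift.mdprofiles`) — symmetrized number
   density profiles along the membrane normal, ion-peak statistics, and
   area per lipid from GRO/XTC trajectories (via MDAnalysis).

A synthetic-data module (`tdfshift.synthetic`) generates TCSPC datasets
with known ground truth — a log-normal band relaxing as a
multi-exponential ν(t), times a population decay, convolved with a
Gaussian IRF and Poisson-sampled — so the whole chain is testable with no
measured data.

## Worked example

```python
from tdfshift import GroundTruth, generate_dataset, analyze_dataset

truth = GroundTruth(seed=1)          # delta_nu = 3000 cm^-1, tau_r = 1.5 ns
ds = generate_dataset(truth)         # 15 decays (400-540 nm), IRF, steady state
run = analyze_dataset(ds.decays, ds.irf, ds.steady_state)
print(run.summary())
```

prints

```
Spectral relaxation nu(t) fit
=============================
components            : 2
nu(0)   [fit, cm^-1]  :   24007.9
nu(inf)      [cm^-1]  :   20999.9 ± 0.6
delta_nu     [cm^-1]  :    3008.0
tau_r           [ns]  :     1.494
chi2_reduced          : 2.987
incomplete relaxation : False
  i        a_i        tau_i (ns)
  0     0.4924        0.5817
  1     0.5076         2.378

tau_r numeric path    :     1.496 ns (analytic 1.494 ns)
```

i.e. the generating Δν = 3000 cm⁻¹ and τᵣ = 1.5 ns are recovered to
0.3% and 0.4% from Poisson-noised data at 10⁴ peak counts, together with
the relaxation components (0.6 / 2.4 ns at equal weight).

The same pipeline runs from the shell on decay files:

```bash
tdfshift simulate --out data --seed 1
tdfshift run --config config.yaml      # fit -> reconstruct -> metrics
tdfshift gp --i440 600 --i490 400      # GP = 0.2000
tdfshift mdprofile --topology sys.gro --trajectory traj.xtc \
    --select "PO4=name P*" --lipids-per-leaflet 65 --out profile.tsv
```

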