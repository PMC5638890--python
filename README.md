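# smfluor

Multiparameter single-molecule fluorescence analysis for characterizing
small fluorogenic probes — such as the biarsenical dye FlAsH bound to a
tetracysteine peptide motif — as donors for single-molecule FRET.  The
package implements the four analysis layers such an experiment needs, plus
a photon-level instrument simulator so that every stage can be validated
against ground truth without access to a microscope:

* **`smfluor.tcspc`** — time-correlated single-photon counting.  Decay and
  anisotropy curves are built from polarized photon nanotimes and fitted
  under periodic pulsed excitation (period *T* = 12.5 ns at 80 MHz).  The
  decay model is the wrapped multi-exponential nanotime density

  *F*(*t*) = Σᵢ *B*ᵢ e^(−*t*/τᵢ) / (τᵢ (1 − e^(−*T*/τᵢ))),  *t* ∈ [0, *T*),

  where *B*ᵢ is the photon fraction of the component with lifetime τᵢ and
  the 1/(1 − e^(−*T*/τ)) factor accounts for emission folded past the pulse
  period.  Anisotropy decays r(*t*) = r₀ Σⱼ *A*ⱼ e^(−*t*/ρⱼ) (an infinite ρ
  encodes a residual offset) are fitted with a model that sums the
  polarized intensities over the 5 preceding pulses before re-forming
  r(*t*) = (I∥ − G·I⊥)/(I∥ + 2G·I⊥).  Uncertainties come from bootstrap
  resampling of photon records; model order is compared by AIC.

* **`smfluor.fcs`** — fluorescence correlation spectroscopy.  A software
  multi-tau correlator feeds the 3-D diffusion model with multiplicative
  triplet-blink terms,

  G(τ) = 1 + (1/⟨N⟩)(1 + τ/τ_D)⁻¹ (1 + τ/(s²τ_D))^(−1/2) Πᵢ (1 + Kᵢ/(1−Kᵢ) e^(−τ/tᵢ)),

  and converts the diffusion time to a hydrodynamic radius via
  ω₀²/(4τ_D) = k_B T/(6πη R_H), the fitted ⟨N⟩ to an effective
  concentration via V_eff = π^(3/2)ω₀³s, and the concentration ratio to a
  fluorescent-state percentage.

* **`smfluor.burst`** — ALEX smFRET burst analysis: excitation-phase
  assignment, inter-photon-delay background estimation, sliding-window
  burst search (≥ *M* = 10 photons in a centered 500 µs window, bursts with
  < *L* = 25 photons discarded), background/leakage/direct-excitation
  corrections, FRET efficiency E = I_A/(I_A + γ I_D) and stoichiometry
  S = I_DD/(I_DD + I_AA), the S ∈ [0.2, 0.8] gate, a 200 µs
  donor/acceptor mean-arrival-time photobleach filter, per-burst
  maximum-likelihood donor lifetimes, γ calibration against the static
  FRET line E = 1 − τ_DA/τ_D0, and Gaussian-mixture fitting of the FRET
  histogram.

* **`smfluor.fretorient`** — dipole-orientation post-processing of
  molecular-dynamics dye trajectories: the orientation factor
  κ² = [d̂·â − 3(d̂·r̂)(â·r̂)]² (unit vectors; range 0–4, isotropic mean 2/3),
  Förster-radius rescaling R₀(κ²) = R₀ · (κ²/(2/3))^(1/6), and transfer
  efficiency E = 1/(1 + (R/R₀)⁶) in isotropic, instantaneous, or
  time-averaged κ² modes.

* **`smfluor.photonsim`** — the synthetic instrument: TCSPC photon streams
  with rotational depolarization and period fold-back, Brownian diffusion
  of pointlike emitters through a 3-D Gaussian confocal volume with
  independent telegraph (triplet) blink processes, and two-color ALEX
  FRET bursts from molecules switching between conformations, with
  background, spectral leakage, acceptor direct excitation, and optional
  mid-transit acceptor photobleaching.  Every generator records its ground
  truth in the stream's `truth` block.

## Worked example

```python
import numpy as np
from smfluor import burst, fretorient, tcspc
from smfluor.photonsim import (DiffusionModel, EmitterModel, FretScheme,
                               simulate_alex_bursts, simulate_decay_photons)
from smfluor.stream import AcquisitionConfig

# TCSPC: peptide-bound-dye decay (0.55/4.72 ns) and hindered rotation
acq = AcquisitionConfig()                      # 12.5 ns period, 50 us ALEX
stream = simulate_decay_photons(EmitterModel(), acq, 500_000, seed=1)
hist = tcspc.build_decay(stream)
lt = tcspc.fit_lifetimes(tcspc.isotropic_decay(hist), n_components=2)
an = tcspc.fit_anisotropy(hist, lt, n_components=1, with_offset=True)

# ALEX smFRET: two-conformation molecule, full burst pipeline
donor = EmitterModel(lifetimes_ns=(4.37,), fractions=(1.0,),
                     rot_times_ns=(), rot_amplitudes=(),
                     brightness_cps=1_000_000)
acceptor = EmitterModel(lifetimes_ns=(1.0,), fractions=(1.0,),
                        rot_times_ns=(), rot_amplitudes=(),
                        brightness_cps=300_000)
dm = DiffusionModel(hydrodynamic_radius_A=15.0, beam_waist_um=0.35,
                    n_molecules=10)
s = simulate_alex_bursts(FretScheme(), (donor, acceptor), dm,
                         AcquisitionConfig(duration_s=10.0), seed=7)
crit = burst.BurstCriteria(l_min=50)
corr = burst.CorrectionSet(gamma=0.91, leakage=0.05, direct_exc=0.05)
kept = burst.filter_bursts(burst.analyze_stream(s, crit, corr), crit)
mix = burst.fit_fret_histogram(np.array([b.e_fret for b in kept]), 2)

# Orientation factor and Forster bounds
mean_k2, se = fretorient.isotropic_kappa_mc(1_000_000, seed=2)
```

Printed results:

```
lifetimes: [0.53 4.84] ns, fractions [0.14 0.86], chi2_red 1.12
anisotropy: r0=0.40, rho=[2.4 inf] ns, amplitudes [0.87 0.13]
bursts kept: 193;  E peaks: [-0.001  0.885]  weights [0.52 0.48]
donor lifetime in low-FRET bursts: 4.42 +- 0.69 ns
isotropic <kappa^2> = 0.6659 +- 0.0007
R0 = 52 A: min E over 20-50 A = 55.9%
R0 = 43 A: min E over 20-50 A = 28.8%
```

The lifetime fit recovers the simulated quenched (0.55 ns, 17%) and
unquenched (4.72 ns, 83%) components; the anisotropy fit resolves the 2.29
ns rotational time with its 14% residual offset (slow peptide tumbling);
the burst pipeline resolves the zero-FRET and E = 0.9 conformations and
the unquenched donor lifetime; and the Monte-Carlo isotropic κ² average
reproduces 2/3.  With an isotropic Förster radius of 52 Å, distances of
20–50 Å can only produce efficiencies above ~56%; with the
orientation-restricted radius of 43 Å the accessible range extends down to
~29% — the quantitative reason low-FRET populations can reflect dye
orientation rather than distance.

A `smfluor` command-line entry point wraps the same operations
(`smfluor simulate decay|fcs|bursts`, `smfluor tcspc fit-lifetime`,
`smfluor fcs correlate|fit`, `smfluor bursts`, `smfluor fretmd`); see
`smfluor --help`.

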