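# Methods

This note records the models behind `smfluor`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate about real data.

## Photon-stream representation

All stages exchange photons as three aligned arrays: macrotime (absolute
arrival, integer ticks of a configurable clock, default 12.5 ns = one
excitation period, the native TCSPC hardware convention — lossless and
compact), nanotime (TCSPC delay as an integer bin in [0, 256) spanning one
period), and detector channel (donor/acceptor × parallel/perpendicular).
On disk the layout follows the community photon-HDF5 convention
(`photon_data/{timestamps,nanotimes,detectors}`, `setup`), with a
nonstandard `truth` group carrying generator parameters; a plain-text TSV
fallback exists for small fixtures.

## TCSPC simulation and fitting

**Emission sampling.** A photon picks a lifetime component with
probability *B*ᵢ (photon fractions), draws an exponential delay, and folds
it modulo the period *T*; the number of folded photons is recorded in the
truth block.  Folding is what produces the 1/(1 − e^(−T/τ)) amplitude in
the periodic density.  An optional Gaussian instrument response (default
σ = 0, i.e. delta) can be convolved in; the default keeps the closed-form
model exact.  Polarization is assigned per photon with
p(∥) = (1 + 2r)/(2 + r) at G = 1, where r is the anisotropy evaluated at
the *unfolded* emission delay — wrapped photons therefore carry the
residual polarization of earlier pulses, exactly the effect the
pulse-history model corrects for.

**Lifetime fitting.** Weighted least squares of amplitude × bin-integrated
periodic density (the analytic per-bin integral, not the bin-center value;
this matters once the shortest lifetime approaches a few bin widths).
Weighting is Poisson in two passes: an initial pass on observed-count
variances, then variances re-derived from the fitted model (Pearson-style
reweighting).  Pure observed-count weighting over-weights bins that
fluctuate low and biased lifetimes by more than their own confidence
intervals at ~10⁴ photons; the reweighted scheme restores nominal bootstrap
coverage.  Reported χ² and AIC are always evaluated against the fixed
observed-count errors so different component counts are compared on a
common scale.  Note that an exact AIC accepts a spurious extra component
whenever it lowers χ² by more than 4, which happens with probability up to
e⁻² ≈ 13.5% on null data — a designed property of AIC, reflected in the
model-selection test's threshold.

**Anisotropy fitting.** The model r(t) is built from unnormalized
intensities F(t + kT) and anisotropies r(t + kT) summed over the current
plus 5 preceding pulses and re-formed through the polarization ratio; it
reduces to the intensity-weighted average of r over contributing pulses.
The 5-pulse history is applied to the model, not the data — the data
already contain the pulse history.  The intensity weighting uses the
separately fitted lifetimes.  Low-count bins (denominator < 10 counts by
default) are masked, not zeroed.  A fitted rotational time below one bin
width is flagged unresolvable.  The G factor is accepted as metadata
(default 1, correct for the simulator); no tail-matching estimator is
implemented.

**Bootstrap.** Parameter intervals are 2.5/97.5 percentiles over ≥100
resamples of photon records (nanotime, channel rows) with replacement;
degenerate all-identical resamples are skipped and counted.  For
histogram-only input, a multinomial resample of bin counts is
distributionally identical to resampling photon records and re-binning.
Anisotropy bootstraps refit the lifetimes per replicate so lifetime
uncertainty propagates into rotational times.

## Diffusion / FCS simulation

Pointlike emitters perform Euler–Maruyama Brownian steps (default macro
step 1 µs) in a periodic cubic box centered on a 3-D Gaussian detection
profile with 1/e² lateral waist ω₀ (default 0.3 µm) and axial waist s·ω₀
(default s = 5).  The diffusion coefficient comes from Stokes–Einstein at
298.15 K in water (η = 0.89 mPa·s) when a hydrodynamic radius is given.
Photon emission is thinned within each step at rate brightness × W(x),
giving Poisson statistics; a step with rms displacement above ω₀/5 is
refused as undersampled.  Each triplet process is an independent two-state
telegraph with stated bright→dark and dark→bright rates, initialized at
equilibrium; its blink fraction is K = k_bd/(k_bd + k_db) and relaxation
time 1/(k_bd + k_db).  (Multi-component triplet decays are represented as
independent telegraphs; a sequential dark-state ladder would produce the
same multiplicative-exponential correlation form at this level of
analysis.)

Two finite-simulation artifacts are worth knowing:

* the box must be large relative to the axial detection tail — the default
  box edge is 5× the axial waist after wrap-around re-entry at 3× was
  found to shorten apparent diffusion times by ~5%;
* particle number is conserved in the box, so the measured correlation
  carries a small negative long-lag offset relative to the open-reservoir
  model; `fit_fcs(free_baseline=True)` absorbs it with a constant.

**Correlator.** Multi-tau with 16 linear lags in the first octave and 8
per subsequent octave, bin width doubling per octave (hardware-correlator
emulation).  At every level the estimator is the symmetrically normalized
product average G(k) = ⟨I_t I_{t+k}⟩ / (⟨I⟩_left ⟨I⟩_right) on the
pairwise-rebinned trace; these exact semantics are what the brute-force
oracle in the tests reproduces independently.  Errors are standard errors
over 10 contiguous segments.  Fits use lags up to ~5 ms, well below the
box-recurrence time of the simulations.

**Model fitting.** Triplet times are parameterized as fractions of τ_D
bounded below 1/2: blinking faster than diffusion is the physical regime,
and an unbounded blink time is exactly degenerate with the diffusion
shoulder on noisy single curves.  Curves are stored as G with baseline 1;
display normalization divides the fluctuation part by its value at a
reference lag (default 10⁻⁶ s) and flags the convention so a fit never
misreads the amplitude (a normalized curve has no ⟨N⟩).  The effective
volume for concentrations is V_eff = π^(3/2)ω₀³s.

## ALEX burst simulation and analysis

**Generator.** Molecules carry a conformational state (E_true, occupancy,
exponential dwell); switching picks the next state proportional to
occupancy.  During donor excitation the detected rates are
r_DD = B_D·W·(1−E) and r_DA = γ_true·E·B_D·W + leakage·r_DD +
direct·B_A·W; during acceptor excitation r_AA = B_A·W.  Leakage and direct
excitation are additive Poisson processes, so the standard linear
correction n_DA − l·n_DD − d·n_AA is exactly unbiased.  Excitation phase
uses integer step arithmetic aligned with the 50 µs ALEX gates (a
floating-point phase computation was observed to mislabel boundary
steps).  Donor nanotimes are drawn with lifetimes quenched by the current
state (τ_DA = (1−E)τ_D); FRET-excited acceptor photons follow the acceptor
decay; acceptor-excitation nanotimes are uniform (CW red laser).
Acceptor photobleaching is a hazard ∝ illumination; a bleached molecule
regains a fresh acceptor when far from the focus, emulating reservoir
exchange.  Background photons are uniform in time and nanotime per
channel (default 0.5 kcps total).  The default acceptor brightness in the
examples is ~0.3× the donor's: with the stoichiometry defined as
S = I_DD/(I_DD + I_AA), this is the ratio that keeps both a zero-FRET and
a high-FRET population inside the 0.2–0.8 gate, as observed experimental
E–S maps require.

**Pipeline.** Burst search is the centered sliding window (photon
eligible iff ≥ M photons within ±T/2), maximal runs of eligible photons,
split where successive eligible photons are further apart than the window
(two clusters with nothing between them are index-adjacent), and a total
threshold L; the common leading-window variant is available behind a
flag.  The search runs on all photons, matching the single M/T/L
thresholds.  Background rates are per-stream wall-clock rates estimated
from the inter-photon delay tail (MLE for an exponential tail truncated
at the 90th percentile).  Corrections are background-first, then
spectral; negative corrected counts are flagged, never clipped.  S is
computed exactly as defined above; the more common ALEX convention
including the donor-excitation acceptor signal is available via
`conventional_s=True`.  The mean-arrival-time bleach filter uses the
donor-excitation-period photons of both dyes.  Per-burst donor lifetimes
are single-exponential periodic MLEs (≥ 20 photons, bounded 1-D
optimization, no IRF — adequate for delta-IRF simulation, a documented
limitation for real data).

**γ calibration.** The two-standard procedure clusters bursts by
uncorrected proximity ratio, trims each cluster to bursts near its center
(mixed or coincident bursts otherwise contaminate both centroids), pools
the core bursts' donor nanotimes, and fits a lifetime with an explicit
uniform-background component (a plain exponential MLE is pulled up
severely by ~1% nanotime-uniform background).  γ then minimizes the
summed squared distance of the two (mean E(γ), population lifetime)
centroids from the static FRET line E = 1 − τ_DA/τ_D0.  Pooling replaces
per-burst lifetimes because a high-FRET burst carries only a handful of
donor photons — per-burst MLE is undefined exactly where the line is most
informative.  Calibration works best with moderate-E standards (the
static-line position is ~10× less sensitive to γ at E ≈ 0.9 than at
E ≈ 0.35), which is also how the procedure is used in practice with
dsDNA rulers.

**Mixture fitting.** Gaussian components on the binned E histogram (bin
width 0.02 on [−0.1, 1.1]), k-means-initialized means, Poisson-weighted
least squares; weights are normalized component areas.

## Orientation factor and trajectory FRET

κ² is computed from unit vectors (dipole directions and the
donor→acceptor separation direction) — the only convention with the 0–4
range and isotropic mean 2/3.  Dipoles may be given directly or as two
atom positions per dye (differenced, then normalized); a converter
extracts named atoms and residue centroids from multi-model PDB
snapshots.  R₀ rescales as the sixth root of κ²; note that rescaling 52 Å
by κ² = 0.245 gives 44.0 Å (a rounded 43 Å is sometimes quoted from
unrounded intermediates — the package returns the computed value).
`trajectory_fret` provides three κ² conventions: isotropic (R₀ fixed),
instantaneous (per-frame rescaling; κ² = 0 frames transfer nothing), and
time-averaged (one rescale by the trajectory mean); all three are
reported because published instantaneous-efficiency traces rarely state
which was used.  Distances are center-to-center as supplied; no
accessible-volume dye-cloud averaging.

## What the simulations do and do not show

The generator reproduces the statistical structure the analyses assume:
Poisson emission, exponential nanotimes with period fold-back, Gaussian
detection profile, telegraph blinking, binomial donor/acceptor splitting,
uniform background.  It does not include detector dead time or
afterpulsing, an instrument response function (unless enabled), spectral
dependence of the detection efficiencies, dye adsorption or
photophysics beyond multi-telegraph blinking, or a true open reservoir
(see the closed-box offset above).  Passing recovery tests therefore
demonstrates the correctness of the estimators under the stated model,
not robustness to instrument artifacts.

## Problem sizes and determinism

Test and acceptance runs use sizes chosen to put statistical errors well
inside the stated tolerances on a single CPU: 10⁵–10⁶ photons for decay
and anisotropy fits (bootstrap 100–200 replicates), 5–10 s traces with
8–17 molecules at ~1 MHz peak brightness for FCS (triplet recovery
averages 8 seeded replicate curves, standard FCS practice for repeated
runs), 25 s of ALEX bursts (~400–700 bursts after filtering) for the
FRET-histogram and γ recoveries, and 10⁶ Monte-Carlo samples for the
isotropic κ² average.  Every stochastic routine takes an explicit integer
seed; a single top-level seed fans out to independent substreams via
`numpy.random.SeedSequence`.

## Known limitations

* No IRF deconvolution by iterative reconvolution; tail fitting with a
  start offset is the supported approach for real detectors.
* No global multi-curve lifetime analysis, phasor analysis, FCCS,
  PET-FCS kinetic modeling beyond multiplicative exponentials, PDA, BVA,
  or dynamic-FRET dwell-time inference.
* The burst search's eligibility rule is the centered-window
  interpretation of sliding-window search; boundary conventions differ
  between published implementations, so burst counts may differ at the
  margins from other software on identical data.
* Absolute hydrodynamic radii and concentrations require a calibrated
  beam waist; without one, only ratios between measurements under the
  same calibration are meaningful.
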