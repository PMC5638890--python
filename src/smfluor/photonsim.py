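"""Synthetic photon-stream generation.

This module emulates a pulsed-excitation confocal instrument at the level of
individual detected photons, providing ground-truth test data for every
downstream analysis stage:

* :func:`simulate_decay_photons` — TCSPC nanotimes from a multi-exponential
  emitter with rotational depolarization, including the fold-back of
  emission past the pulse period that produces the ``1/(1-exp(-T/tau))``
  amplitude factor of the periodic decay model.
* :func:`simulate_diffusion_trace` — photon arrival times from pointlike
  emitters diffusing through a 3-D Gaussian detection volume with
  independent telegraph (triplet) blink processes; the input to FCS.
* :func:`simulate_alex_bursts` — two-color alternating-laser-excitation
  bursts from molecules switching between FRET conformations, with
  background, spectral leakage, acceptor direct excitation and optional
  mid-transit acceptor photobleaching; the input to the burst pipeline.

Every generator parameter is recorded in the output stream's ``truth``
block.  Downstream tests read the truth only inside assertions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from . import _kernels
from .stream import (AcquisitionConfig, PhotonStream, CH_D_PAR, CH_D_PERP,
                     CH_A_PAR, CH_A_PERP, _merge_sorted)

__all__ = [
    "EmitterModel",
    "DiffusionModel",
    "FretScheme",
    "simulate_decay_photons",
    "simulate_diffusion_trace",
    "simulate_alex_bursts",
    "stokes_einstein_diffusion",
]

_NORM_TOL = 1e-9


def stokes_einstein_diffusion(hydrodynamic_radius_A: float,
                              temperature_K: float = 298.15,
                              viscosity_Pa_s: float = 0.89e-3) -> float:
    """Diffusion coefficient (um^2/s) of a sphere of given Stokes radius."""
    r_m = hydrodynamic_radius_A * 1e-10
    d_m2_s = constants.k * temperature_K / (6 * np.pi * viscosity_Pa_s * r_m)
    return d_m2_s * 1e12


@dataclass(frozen=True)
class EmitterModel:
    """Photophysics of a single fluorophore.

    ``fractions`` are photon fractions: the probability that a detected
    photon originates from the component with lifetime ``lifetimes_ns[i]``.
    Rotational depolarization follows r(t) = r0 * sum_j A_j exp(-t/rho_j);
    an infinite ``rot_times_ns`` entry encodes a residual (non-decaying)
    anisotropy offset.  ``triplet_rates`` lists independent two-state blink
    processes as (bright->dark rate, dark->bright rate) pairs in 1/s.
    """

    lifetimes_ns: tuple[float, ...] = (0.55, 4.72)
    fractions: tuple[float, ...] = (0.17, 0.83)
    r0: float = 0.4
    rot_times_ns: tuple[float, ...] = (2.29, np.inf)
    rot_amplitudes: tuple[float, ...] = (0.86, 0.14)
    brightness_cps: float = 50_000.0
    triplet_rates: tuple[tuple[float, float], ...] = ()
    irf_sigma_ns: float = 0.0

    def __post_init__(self) -> None:
        if any(tau <= 0 for tau in self.lifetimes_ns):
            raise ValueError("lifetimes must be positive")
        if len(self.fractions) != len(self.lifetimes_ns):
            raise ValueError("fractions and lifetimes lengths differ")
        if abs(sum(self.fractions) - 1.0) > _NORM_TOL:
            raise ValueError("fractions must sum to 1")
        if any(b <= 0 for b in self.fractions):
            raise ValueError("fractions must be in (0, 1]")
        if not 0.0 <= self.r0 <= 0.4:
            raise ValueError("r0 must be in [0, 0.4]")
        if self.rot_times_ns:
            if len(self.rot_amplitudes) != len(self.rot_times_ns):
                raise ValueError("rot amplitudes/times lengths differ")
            if abs(sum(self.rot_amplitudes) - 1.0) > _NORM_TOL:
                raise ValueError("rotational amplitudes must sum to 1")
            if any(rho <= 0 for rho in self.rot_times_ns):
                raise ValueError("rotational times must be positive")
        if self.brightness_cps <= 0:
            raise ValueError("brightness must be positive")
        for k_od, k_do in self.triplet_rates:
            if k_od <= 0 or k_do <= 0:
                raise ValueError("blink rates must be positive")

    def anisotropy(self, t_ns: np.ndarray) -> np.ndarray:
        """r(t) for time since excitation (not folded)."""
        if not self.rot_times_ns:
            return np.full_like(np.asarray(t_ns, dtype=float), self.r0)
        r = np.zeros_like(np.asarray(t_ns, dtype=float))
        for a_j, rho_j in zip(self.rot_amplitudes, self.rot_times_ns):
            if np.isinf(rho_j):
                r += a_j
            else:
                r += a_j * np.exp(-np.asarray(t_ns, dtype=float) / rho_j)
        return self.r0 * r


@dataclass(frozen=True)
class DiffusionModel:
    """Brownian motion of emitters in a periodic box around the focus.

    Exactly one of ``hydrodynamic_radius_A`` (converted via Stokes-Einstein)
    or ``diffusion_coeff_um2_s`` must be given.  The detection profile is a
    3-D Gaussian with 1/e^2 lateral waist ``beam_waist_um`` and axial waist
    ``ellipticity * beam_waist_um``.
    """

    hydrodynamic_radius_A: float | None = None
    diffusion_coeff_um2_s: float | None = None
    beam_waist_um: float = 0.3
    ellipticity: float = 5.0
    box_size_um: float = 7.5
    n_molecules: int = 5
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.89e-3

    def __post_init__(self) -> None:
        if (self.hydrodynamic_radius_A is None) == \
                (self.diffusion_coeff_um2_s is None):
            raise ValueError("give exactly one of hydrodynamic_radius_A or "
                             "diffusion_coeff_um2_s")
        if self.ellipticity < 1:
            raise ValueError("ellipticity must be >= 1")
        if self.beam_waist_um <= 0 or self.box_size_um <= 0:
            raise ValueError("geometry must be positive")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be nonnegative")
        axial = self.ellipticity * self.beam_waist_um
        if self.box_size_um < 3 * axial:
            raise ValueError("box must be much larger than the detection "
                             "volume (>= 3 x axial waist)")

    @property
    def d_um2_s(self) -> float:
        if self.diffusion_coeff_um2_s is not None:
            return self.diffusion_coeff_um2_s
        return stokes_einstein_diffusion(self.hydrodynamic_radius_A,
                                         self.temperature_K,
                                         self.viscosity_Pa_s)

    @property
    def tau_d_expected_us(self) -> float:
        """Analytic diffusion time omega^2 / (4 D) in microseconds."""
        return self.beam_waist_um ** 2 / (4 * self.d_um2_s) * 1e6


@dataclass(frozen=True)
class FretScheme:
    """Ground truth for a two-color ALEX FRET experiment.

    ``states`` lists (E_true, occupancy, mean dwell in us) conformations.
    ``background_cps`` maps channel labels (``D_par`` ...) to dark rates.
    ``acceptor_bleach_rate`` is the photobleach hazard (1/s) at the beam
    center, scaled by local illumination.
    """

    states: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.5, 10_000.0), (0.9, 0.5, 10_000.0))
    gamma_true: float = 0.91
    leakage: float = 0.05
    direct_excitation: float = 0.05
    background_cps: dict = field(default_factory=lambda: {
        "D_par": 125.0, "D_perp": 125.0, "A_par": 125.0, "A_perp": 125.0})
    acceptor_bleach_rate: float = 0.0
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("at least one FRET state required")
        occ = sum(s[1] for s in self.states)
        if abs(occ - 1.0) > _NORM_TOL:
            raise ValueError("state occupancies must sum to 1")
        for e_true, _, dwell in self.states:
            if not 0.0 <= e_true <= 1.0:
                raise ValueError("E_true must be in [0, 1]")
            if dwell <= 0:
                raise ValueError("dwell times must be positive")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must be in [0, 1)")
        if not 0.0 <= self.direct_excitation < 1.0:
            raise ValueError("direct_excitation must be in [0, 1)")
        if any(v < 0 for v in self.background_cps.values()):
            raise ValueError("background rates must be nonnegative")
        if self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rate must be nonnegative")


# ---------------------------------------------------------------------------
# nanotime / polarization sampling
# ---------------------------------------------------------------------------

def _sample_emission(emitter: EmitterModel, config: AcquisitionConfig,
                     n: int, rng: np.random.Generator,
                     lifetime_scale: np.ndarray | float = 1.0):
    """Draw nanotimes (bins) and polarization channels for n photons.

    ``lifetime_scale`` multiplies every lifetime component (used for donor
    quenching by FRET, where tau_DA = (1 - E) * tau_D0).

    Returns (nanotime_bins, parallel_mask, n_wrapped).
    """
    period = config.pulse_period_ns
    comp = rng.choice(len(emitter.lifetimes_ns), size=n,
                      p=np.asarray(emitter.fractions))
    taus = np.asarray(emitter.lifetimes_ns)[comp] * lifetime_scale
    t_true = rng.exponential(taus)
    n_wrapped = int(np.count_nonzero(t_true >= period))
    t_obs = np.mod(t_true, period)
    if emitter.irf_sigma_ns > 0:
        t_obs = np.mod(t_obs + rng.normal(0.0, emitter.irf_sigma_ns, size=n),
                       period)
    bins = np.minimum((t_obs / config.nanotime_bin_width_ns).astype(np.int32),
                      config.nanotime_bins - 1)
    # polarization split: I_par ~ (1+2r)/3, I_perp ~ (1-r)/3 at G = 1
    r = emitter.anisotropy(t_true)
    p_par = (1.0 + 2.0 * r) / (2.0 + r)
    par = rng.random(n) < p_par
    return bins, par, n_wrapped


def _truth_base(**kwargs) -> dict:
    return {k: v for k, v in kwargs.items()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_decay_photons(emitter: EmitterModel, config: AcquisitionConfig,
                           n_photons: int, seed: int) -> PhotonStream:
    """TCSPC photon stream from a stationary multi-exponential emitter.

    Emission delays exceeding the pulse period are folded modulo T into the
    following observation windows, reproducing the periodic pile-up that
    the 1/(1-exp(-T/tau)) factor of the periodic decay model describes.
    Arrival macrotimes form a homogeneous Poisson process at the emitter
    brightness.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    period = config.pulse_period_ns
    if any(tau >= 100.0 * period for tau in emitter.lifetimes_ns):
        raise ValueError("lifetime >= 100 pulse periods is unresolvable "
                         "under periodic excitation")
    rng = np.random.default_rng(seed)
    bins, par, n_wrapped = _sample_emission(emitter, config, n_photons, rng)
    channels = np.where(par, CH_D_PAR, CH_D_PERP).astype(np.int8)
    gaps = rng.exponential(1.0 / emitter.brightness_cps, size=n_photons)
    times_s = np.cumsum(gaps)
    macrotimes = (times_s / (config.macrotime_clock_ns * 1e-9)).astype(np.int64)
    truth = _truth_base(
        lifetimes_ns=list(emitter.lifetimes_ns),
        fractions=list(emitter.fractions),
        r0=emitter.r0,
        rot_times_ns=[float(x) for x in emitter.rot_times_ns],
        rot_amplitudes=list(emitter.rot_amplitudes),
        brightness_cps=emitter.brightness_cps,
        irf_sigma_ns=emitter.irf_sigma_ns,
        n_wrapped=n_wrapped,
        seed=seed,
    )
    return PhotonStream(macrotimes, bins, channels, config, truth)


def simulate_diffusion_trace(emitter: EmitterModel, diffusion: DiffusionModel,
                             config: AcquisitionConfig, seed: int,
                             dt_s: float = 1e-6) -> PhotonStream:
    """Photon stream from emitters diffusing through the detection volume.

    Brownian steps use Euler-Maruyama integration with macro-step ``dt_s``;
    photons are thinned within each step (Poisson statistics).  Each
    triplet blink process of the emitter is an independent telegraph
    gating emission off.
    """
    expected = emitter.brightness_cps * config.duration_s
    if expected > 1e8:
        raise ValueError("requested simulation would exceed ~1e8 photons")
    if diffusion.n_molecules == 0:
        warnings.warn("no molecules: returning an empty stream")
        return PhotonStream(np.empty(0, np.int64), np.empty(0, np.int32),
                            np.empty(0, np.int8), config,
                            _truth_base(n_molecules=0, seed=seed))
    d_um2_s = diffusion.d_um2_s
    step_rms_um = np.sqrt(2.0 * d_um2_s * dt_s)
    if step_rms_um > diffusion.beam_waist_um / 5.0:
        raise ValueError(
            f"per-axis rms step {step_rms_um:.3g} um exceeds beam_waist/5; "
            "reduce dt_s (undersampled dynamics)")
    n_steps = int(round(config.duration_s / dt_s))
    rates = np.asarray(emitter.triplet_rates, dtype=np.float64).reshape(-1, 2)
    ss = np.random.SeedSequence(seed)
    kernel_seed = int(ss.generate_state(1)[0] % (2 ** 32 - 1))
    rng = np.random.default_rng(ss.spawn(1)[0])

    max_photons = int(expected * diffusion.n_molecules * 0.5 + 1e5)
    out = np.empty(max_photons, dtype=np.float64)
    n_out = _kernels.diffusion_photons(
        kernel_seed, n_steps, dt_s, diffusion.n_molecules, d_um2_s,
        diffusion.box_size_um / 2.0, diffusion.beam_waist_um,
        diffusion.ellipticity, emitter.brightness_cps,
        np.ascontiguousarray(rates[:, 0]), np.ascontiguousarray(rates[:, 1]),
        out)
    if n_out < 0:
        raise RuntimeError("photon buffer overflow; lower the brightness or "
                           "concentration")
    times_s = np.sort(out[:n_out])
    bins, par, n_wrapped = _sample_emission(emitter, config, n_out, rng)
    channels = np.where(par, CH_D_PAR, CH_D_PERP).astype(np.int8)
    macrotimes = (times_s / (config.macrotime_clock_ns * 1e-9)).astype(np.int64)
    triplet_k = [float(a / (a + b)) for a, b in rates]
    triplet_t_us = [float(1e6 / (a + b)) for a, b in rates]
    truth = _truth_base(
        d_um2_s=d_um2_s,
        tau_d_expected_us=diffusion.tau_d_expected_us,
        n_molecules=diffusion.n_molecules,
        beam_waist_um=diffusion.beam_waist_um,
        ellipticity=diffusion.ellipticity,
        box_size_um=diffusion.box_size_um,
        brightness_cps=emitter.brightness_cps,
        triplet_fracs=triplet_k,
        triplet_times_us=triplet_t_us,
        n_wrapped=n_wrapped,
        seed=seed,
        dt_s=dt_s,
    )
    return PhotonStream(macrotimes, bins, channels, config, truth)


def simulate_alex_bursts(fret: FretScheme,
                         emitters: tuple[EmitterModel, EmitterModel],
                         diffusion: DiffusionModel, config: AcquisitionConfig,
                         seed: int, dt_s: float = 1e-6) -> PhotonStream:
    """ALEX two-color FRET burst stream from diffusing labeled molecules.

    ``emitters`` is the (donor, acceptor) pair; the acceptor's
    ``brightness_cps`` sets the acceptor-excitation count rate.  Donor
    nanotimes are drawn with lifetimes quenched by the current FRET state
    (tau_DA = (1-E) tau_D); acceptor-excitation nanotimes are uniform
    (continuous-wave red laser); FRET-excited acceptor photons follow the
    acceptor decay.  Background photons are uniform in time and nanotime.

    Per-photon truth arrays: ``truth_stream`` (0=DD, 1=DA, 2=AA, 255=bg),
    ``truth_mol`` (molecule index, -1 for bg), ``truth_E`` (state at
    emission) and ``truth_excitation`` (0 donor phase, 1 acceptor phase).
    """
    donor, acceptor = emitters
    period = config.pulse_period_ns
    for _, _, dwell_us in fret.states:
        if dwell_us * 1e3 < period:
            raise ValueError("state dwell time below the pulse period")
    d_um2_s = diffusion.d_um2_s
    if np.sqrt(2.0 * d_um2_s * dt_s) > diffusion.beam_waist_um / 5.0:
        raise ValueError("per-axis rms step exceeds beam_waist/5; reduce dt_s")
    n_steps = int(round(config.duration_s / dt_s))
    steps_per_half = int(round(config.alex_alternation_us * 1e-6 / dt_s))
    if abs(steps_per_half * dt_s - config.alex_alternation_us * 1e-6) \
            > 1e-12:
        raise ValueError("the ALEX half-period must be an integer multiple "
                         "of the integration step dt_s")
    e_states = np.array([s[0] for s in fret.states])
    occ = np.array([s[1] for s in fret.states])
    dwell = np.array([s[2] * 1e-6 for s in fret.states])

    ss = np.random.SeedSequence(seed)
    kernel_seed = int(ss.generate_state(1)[0] % (2 ** 32 - 1))
    rng = np.random.default_rng(ss.spawn(1)[0])

    mean_bright = max(donor.brightness_cps, acceptor.brightness_cps)
    max_photons = int(mean_bright * config.duration_s
                      * diffusion.n_molecules * 0.5 + 1e5)
    times = np.empty(max_photons, np.float64)
    code = np.empty(max_photons, np.uint8)
    e_val = np.empty(max_photons, np.float32)
    mol = np.empty(max_photons, np.int16)
    bleach = np.empty(100_000, np.float64)
    n_out, n_bleach = _kernels.alex_burst_photons(
        kernel_seed, n_steps, dt_s, diffusion.n_molecules, d_um2_s,
        diffusion.box_size_um / 2.0, diffusion.beam_waist_um,
        diffusion.ellipticity, steps_per_half,
        donor.brightness_cps, acceptor.brightness_cps,
        e_states, occ, dwell,
        fret.gamma_true, fret.leakage, fret.direct_excitation,
        fret.acceptor_bleach_rate,
        fret.donor_only_fraction, fret.acceptor_only_fraction,
        times, code, e_val, mol, bleach)
    if n_out < 0:
        raise RuntimeError("photon buffer overflow; lower brightness or "
                           "concentration")
    times, code, e_val, mol = (times[:n_out], code[:n_out], e_val[:n_out],
                               mol[:n_out])

    clock_s = config.macrotime_clock_ns * 1e-9
    blocks = []

    # DD photons: donor decay quenched by current E
    is_dd = code == _kernels.CODE_DD
    n_dd = int(is_dd.sum())
    if n_dd:
        bins, par, _ = _sample_emission(donor, config, n_dd, rng,
                                        lifetime_scale=1.0 - e_val[is_dd])
        chans = np.where(par, CH_D_PAR, CH_D_PERP).astype(np.int8)
        blocks.append(((times[is_dd] / clock_s).astype(np.int64), bins, chans,
                       {"truth_stream": code[is_dd],
                        "truth_mol": mol[is_dd],
                        "truth_E": e_val[is_dd]}))
    # DA photons: acceptor decay (FRET-excited by the pulsed donor laser)
    is_da = code == _kernels.CODE_DA
    n_da = int(is_da.sum())
    if n_da:
        bins, par, _ = _sample_emission(acceptor, config, n_da, rng)
        chans = np.where(par, CH_A_PAR, CH_A_PERP).astype(np.int8)
        blocks.append(((times[is_da] / clock_s).astype(np.int64), bins, chans,
                       {"truth_stream": code[is_da],
                        "truth_mol": mol[is_da],
                        "truth_E": e_val[is_da]}))
    # AA photons: CW acceptor excitation -> uniform nanotimes
    is_aa = code == _kernels.CODE_AA
    n_aa = int(is_aa.sum())
    if n_aa:
        bins = rng.integers(0, config.nanotime_bins, n_aa, dtype=np.int32)
        chans = np.where(rng.random(n_aa) < 0.5, CH_A_PAR,
                         CH_A_PERP).astype(np.int8)
        blocks.append(((times[is_aa] / clock_s).astype(np.int64), bins, chans,
                       {"truth_stream": code[is_aa],
                        "truth_mol": mol[is_aa],
                        "truth_E": e_val[is_aa]}))
    # background: uniform in time and nanotime, per channel
    from .stream import _LABEL_TO_CODE
    for label, rate in fret.background_cps.items():
        n_bg = rng.poisson(rate * config.duration_s)
        if n_bg == 0:
            continue
        t_bg = rng.random(n_bg) * config.duration_s
        bins = rng.integers(0, config.nanotime_bins, n_bg, dtype=np.int32)
        chans = np.full(n_bg, _LABEL_TO_CODE[label], dtype=np.int8)
        blocks.append(((t_bg / clock_s).astype(np.int64), bins, chans,
                       {"truth_stream": np.full(n_bg, 255, np.uint8),
                        "truth_mol": np.full(n_bg, -1, np.int16),
                        "truth_E": np.full(n_bg, np.nan, np.float32)}))

    truth = _truth_base(
        states=[list(s) for s in fret.states],
        gamma_true=fret.gamma_true,
        leakage=fret.leakage,
        direct_excitation=fret.direct_excitation,
        background_cps=dict(fret.background_cps),
        acceptor_bleach_rate=fret.acceptor_bleach_rate,
        donor_only_fraction=fret.donor_only_fraction,
        acceptor_only_fraction=fret.acceptor_only_fraction,
        donor_lifetimes_ns=list(donor.lifetimes_ns),
        donor_fractions=list(donor.fractions),
        donor_brightness_cps=donor.brightness_cps,
        acceptor_brightness_cps=acceptor.brightness_cps,
        tau_d_expected_us=diffusion.tau_d_expected_us,
        n_molecules=diffusion.n_molecules,
        seed=seed,
        bleach_times_s=bleach[:n_bleach].copy(),
    )
    stream = _merge_sorted(blocks, config, truth)
    # truth excitation label from the emission-time phase
    cycle_ticks = 2.0 * config.alex_alternation_us * 1e3 \
        / config.macrotime_clock_ns
    alt_ticks = cycle_ticks / 2.0
    phase = np.mod(stream.macrotimes, cycle_ticks)
    stream.truth["truth_excitation"] = (phase >= alt_ticks).astype(np.uint8)
    return stream
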