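"""Fluorescence correlation spectroscopy.

Implements a software multi-tau correlator (emulating the hardware
correlators used on confocal FCS setups), fitting of the 3-D diffusion
model with multiplicative triplet (blink) terms,

    G(tau) = 1 + (1/<N>) (1 + tau/tau_D)^-1 (1 + tau/(s^2 tau_D))^-1/2
             * prod_i (1 + K_i/(1-K_i) exp(-tau/t_i)),

and the derived quantities: hydrodynamic radius via the Stokes-Einstein
relation omega_0^2/(4 tau_D) = k_B T / (6 pi eta R_H), effective
concentration from <N> and the effective detection volume
V_eff = pi^(3/2) omega_0^3 s, and the fluorescent fraction relative to a
nominal concentration.

Correlation curves are stored as G(tau) with G(inf) -> 1 ("G" convention);
:func:`normalize_curve` rescales the fluctuation part (G - 1) to unity at a
reference lag (display convention) and records this in the curve metadata
so fits resolve the amplitude convention explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import constants

from .stream import PhotonStream

__all__ = [
    "CorrelationCurve",
    "FCSFit",
    "EnvironmentParams",
    "bin_photons",
    "correlate",
    "fit_fcs",
    "hydrodynamic_radius",
    "effective_concentration",
    "fluorescent_fraction",
    "normalize_curve",
    "write_curve_text",
    "read_curve_text",
]


@dataclass
class CorrelationCurve:
    """Quasi-log-spaced correlation curve.

    ``convention`` is ``"G"`` (amplitudes are G(tau), baseline 1) or
    ``"g-1-normalized"`` (amplitudes are (G-1)/(G(ref)-1)).
    """

    lags_s: np.ndarray
    g: np.ndarray
    errors: np.ndarray
    convention: str = "G"
    normalization_lag_s: float | None = None

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if len(self.g) != len(self.lags_s) or \
                len(self.errors) != len(self.lags_s):
            raise ValueError("lags, g, errors must have equal length")
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.lags_s <= 0):
            raise ValueError("lags must be positive")
        if np.any(self.errors < 0):
            raise ValueError("errors must be nonnegative")

    @property
    def fluctuation(self) -> np.ndarray:
        """The fitted quantity: G-1 for "G" curves, stored values otherwise."""
        return self.g - 1.0 if self.convention == "G" else self.g


@dataclass
class FCSFit:
    n_mean: float | None
    tau_d_us: float
    ellipticity: float
    triplet_fracs: np.ndarray
    triplet_times_us: np.ndarray
    amplitude: float
    chi2_reduced: float
    aic: float
    success: bool
    message: str = ""
    param_stderr: dict | None = None

    def g0_minus_1(self) -> float:
        """Algebraic zero-lag limit (1/<N>) prod (1 + K_i/(1-K_i))."""
        amp = self.amplitude
        for k in self.triplet_fracs:
            amp *= 1.0 + k / (1.0 - k)
        return amp


@dataclass(frozen=True)
class EnvironmentParams:
    """Optical and solvent parameters entering Eq-of-state conversions."""

    beam_waist_um: float
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.89e-3
    ellipticity: float = 5.0
    boltzmann: float = constants.k

    def __post_init__(self) -> None:
        if min(self.beam_waist_um, self.temperature_K, self.viscosity_Pa_s,
               self.ellipticity) <= 0:
            raise ValueError("environment parameters must be positive")

    @property
    def v_eff_um3(self) -> float:
        """Effective detection volume pi^(3/2) omega_0^3 s in um^3."""
        return np.pi ** 1.5 * self.beam_waist_um ** 3 * self.ellipticity


# ---------------------------------------------------------------------------
# correlator
# ---------------------------------------------------------------------------

def bin_photons(stream: PhotonStream, bin_width_s: float = 1e-6,
                channels=None) -> np.ndarray:
    """Intensity trace (counts per bin) from a photon stream."""
    times = stream.times_s
    if channels is not None:
        times = times[np.isin(stream.channels, channels)]
    # cover the actual time span (decay streams may outlast the nominal
    # acquisition duration since their arrival process is open-ended)
    span = max(stream.config.duration_s,
               float(times[-1]) + bin_width_s if len(times) else 0.0)
    n_bins = int(np.ceil(span / bin_width_s))
    idx = np.minimum((times / bin_width_s).astype(np.int64), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(np.float64)


def _multitau_lag_grid(n_bins: int, m: int, max_lag_bins: int):
    """(lag_in_base_bins, level) pairs of the multi-tau cascade."""
    lags, levels = [], []
    width = 1
    lag = 0
    level = 0
    first = True
    while True:
        count = m if first else m // 2
        for _ in range(count):
            lag += width
            if lag > max_lag_bins:
                return lags, levels
            lags.append(lag)
            levels.append(level)
        first = False
        width *= 2
        level += 1
        if width > n_bins // 4:
            return lags, levels


def _correlate_at(signal: np.ndarray, k: int) -> float:
    """Symmetrically normalized correlation of a binned trace at lag k bins.

    G = (1/(M-k)) sum_t I_t I_{t+k} / (mean(I_0..M-k-1) * mean(I_k..M-1)).
    """
    m_valid = len(signal) - k
    if m_valid < 2:
        return np.nan
    left = signal[:m_valid]
    right = signal[k:]
    mean_l = left.mean()
    mean_r = right.mean()
    if mean_l == 0 or mean_r == 0:
        return np.nan
    return float(np.dot(left, right) / m_valid / (mean_l * mean_r))


def _multitau_one(signal: np.ndarray, dt: float, lags, levels):
    out = np.empty(len(lags))
    sig = signal
    width = 1
    cur_level = 0
    for i, (lag, level) in enumerate(zip(lags, levels)):
        while cur_level < level:
            n_even = (len(sig) // 2) * 2
            sig = sig[:n_even:2] + sig[1:n_even:2]
            width *= 2
            cur_level += 1
        out[i] = _correlate_at(sig, lag // width)
    return out


def correlate(source, bin_width_s: float = 1e-6, m: int = 16,
              max_lag_s: float | None = None, n_segments: int = 10,
              channels=None) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon stream or binned trace.

    The cascade uses ``m`` linearly spaced lags in the first octave and
    ``m/2`` per subsequent octave with the bin width doubling each octave
    (hardware-correlator emulation).  At every level the estimator is the
    symmetrically normalized product average documented in
    :func:`_correlate_at`, applied to the pairwise-rebinned trace.
    Errors are the standard error over ``n_segments`` contiguous segments.
    """
    if isinstance(source, PhotonStream):
        if len(source) < 2:
            raise ValueError("need at least 2 photons to correlate")
        signal = bin_photons(source, bin_width_s, channels)
    else:
        signal = np.asarray(source, dtype=np.float64)
        if signal.sum() < 2:
            raise ValueError("need at least 2 counts to correlate")
    duration = len(signal) * bin_width_s
    if max_lag_s is None:
        max_lag_s = duration / 100.0
    if duration < 100.0 * max_lag_s * (1 - 1e-9):
        raise ValueError("duration must be >= 100 x the longest lag")
    max_lag_bins = int(max_lag_s / bin_width_s)
    lags, levels = _multitau_lag_grid(len(signal), m, max_lag_bins)
    g_full = _multitau_one(signal, bin_width_s, lags, levels)

    seg_len = len(signal) // n_segments
    seg_curves = []
    for s in range(n_segments):
        seg = signal[s * seg_len:(s + 1) * seg_len]
        seg_curves.append(_multitau_one(seg, bin_width_s, lags, levels))
    seg_curves = np.array(seg_curves)
    with np.errstate(invalid="ignore"):
        err = np.nanstd(seg_curves, axis=0, ddof=1) / np.sqrt(n_segments)

    lag_s = np.asarray(lags, dtype=float) * bin_width_s
    good = np.isfinite(g_full) & np.isfinite(err)
    return CorrelationCurve(lag_s[good], g_full[good], err[good])


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _fcs_shape(tau_s, tau_d_s, s_ell, k_fracs, t_trip_s):
    g = (1.0 + tau_s / tau_d_s) ** -1 * \
        (1.0 + tau_s / (s_ell ** 2 * tau_d_s)) ** -0.5
    for k_i, t_i in zip(k_fracs, t_trip_s):
        g = g * (1.0 + k_i / (1.0 - k_i) * np.exp(-tau_s / t_i))
    return g


def fit_fcs(curve: CorrelationCurve, n_triplet: int = 0,
            fixed_s: float | None = None,
            free_baseline: bool = False) -> FCSFit:
    """Weighted fit of the 3-D diffusion x multi-triplet model.

    The fitted quantity is the fluctuation part of the curve (G - 1 for
    raw curves; the stored values for display-normalized curves, where the
    amplitude loses its 1/<N> meaning and ``n_mean`` is None).  The
    ellipticity s is poorly identified unless the curve spans the full
    diffusion shoulder; pass ``fixed_s`` to pin it.  ``free_baseline``
    adds a constant offset absorbing residual long-lag correlation (e.g.
    the small negative offset a closed simulation volume with a conserved
    number of molecules produces).
    """
    if not 0 <= n_triplet <= 3:
        raise ValueError("n_triplet must be 0..3")
    span = np.log10(curve.lags_s[-1] / curve.lags_s[0])
    if span < 3:
        raise ValueError("correlation curve must span >= 3 decades of lag")
    y = curve.fluctuation
    err = np.where(curve.errors > 0, curve.errors,
                   np.min(curve.errors[curve.errors > 0], initial=1e-6))
    t = curve.lags_s

    params = lmfit.Parameters()
    amp0 = max(float(y[0]), 1e-3)
    params.add("amplitude", value=amp0, min=1e-9)
    params.add("tau_d", value=float(t[len(t) // 2]), min=t[0] / 10,
               max=t[-1] * 10)
    if fixed_s is not None:
        params.add("s", value=fixed_s, vary=False)
    else:
        params.add("s", value=5.0, min=1.0, max=20.0)
    # triplet times are parameterized as fractions of tau_D, bounded below
    # 1/2: blink kinetics faster than diffusion is the physical regime, and
    # an unbounded blink time is degenerate with the diffusion shoulder
    for i in range(1, n_triplet + 1):
        params.add(f"k{i}", value=0.15, min=0.0, max=0.95)
        params.add(f"tfrac{i}", value=min(0.02 * 10 ** (i - 1), 0.4),
                   min=1e-5, max=0.5)
    params.add("baseline", value=0.0, vary=free_baseline)

    def residual(p):
        ks = [p[f"k{i}"].value for i in range(1, n_triplet + 1)]
        ts = [p[f"tfrac{i}"].value * p["tau_d"].value
              for i in range(1, n_triplet + 1)]
        model = p["baseline"].value + p["amplitude"].value * _fcs_shape(
            t, p["tau_d"].value, p["s"].value, ks, ts)
        return (model - y) / err

    result = lmfit.minimize(residual, params, method="leastsq")
    ks = np.array([result.params[f"k{i}"].value
                   for i in range(1, n_triplet + 1)])
    ts = np.array([result.params[f"tfrac{i}"].value
                   * result.params["tau_d"].value
                   for i in range(1, n_triplet + 1)]) * 1e6
    order = np.argsort(ts)
    ks, ts = ks[order], ts[order]
    amp = result.params["amplitude"].value
    normalized = curve.convention != "G"
    n_mean = None if normalized else 1.0 / amp
    tau_d_us = result.params["tau_d"].value * 1e6
    if np.any(ts >= tau_d_us):
        import warnings
        warnings.warn("triplet time exceeds the diffusion time; check the "
                      "model order")
    stderr = {name: (float(par.stderr) if par.stderr is not None else None)
              for name, par in result.params.items() if par.vary}
    return FCSFit(
        n_mean=n_mean, tau_d_us=tau_d_us,
        ellipticity=result.params["s"].value, triplet_fracs=ks,
        triplet_times_us=ts, amplitude=amp,
        chi2_reduced=float(result.redchi), aic=float(result.aic),
        success=bool(result.success),
        message="" if result.success else str(result.message),
        param_stderr=stderr)


def select_n_triplet(curve: CorrelationCurve, max_n: int = 3,
                     fixed_s: float | None = None):
    """Fit with 0..max_n triplet terms and return (best_fit, aic_list)."""
    fits = [fit_fcs(curve, n, fixed_s) for n in range(max_n + 1)]
    aics = [f.aic for f in fits]
    return fits[int(np.argmin(aics))], aics


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def hydrodynamic_radius(tau_d_us: float, env: EnvironmentParams) -> float:
    """Stokes radius in Angstrom from the diffusion time.

    Inverts omega_0^2 / (4 tau_D) = k_B T / (6 pi eta R_H).
    """
    if tau_d_us <= 0:
        raise ValueError("tau_d must be positive")
    d_m2_s = (env.beam_waist_um * 1e-6) ** 2 / (4.0 * tau_d_us * 1e-6)
    r_m = env.boltzmann * env.temperature_K / \
        (6.0 * np.pi * env.viscosity_Pa_s * d_m2_s)
    return r_m * 1e10


def effective_concentration(n_mean: float, env: EnvironmentParams) -> float:
    """Molar concentration of fluorescent species from <N> and V_eff."""
    if n_mean <= 0:
        raise ValueError("n_mean must be positive")
    v_eff_L = env.v_eff_um3 * 1e-15
    return n_mean / (constants.Avogadro * v_eff_L)


def fluorescent_fraction(c_eff: float, c_nominal: float) -> float:
    """Percentage of nominally present species that are fluorescent."""
    if c_nominal <= 0:
        raise ValueError("c_nominal must be positive")
    return 100.0 * c_eff / c_nominal


def normalize_curve(curve: CorrelationCurve,
                    at_lag_s: float = 1e-6) -> CorrelationCurve:
    """Rescale the fluctuation part to 1 at a reference lag (display form)."""
    if not curve.lags_s[0] <= at_lag_s <= curve.lags_s[-1]:
        raise ValueError("normalization lag outside the curve's lag range")
    ref = float(np.interp(np.log(at_lag_s), np.log(curve.lags_s),
                          curve.fluctuation))
    if ref == 0:
        raise ValueError("curve value at the normalization lag is zero")
    return CorrelationCurve(curve.lags_s, curve.fluctuation / ref,
                            curve.errors / abs(ref),
                            convention="g-1-normalized",
                            normalization_lag_s=at_lag_s)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def write_curve_text(curve: CorrelationCurve, path) -> None:
    norm = curve.normalization_lag_s
    with open(path, "w") as fh:
        fh.write(f"# convention={curve.convention} "
                 f"normalization_lag_s={'' if norm is None else norm}\n"
                 "lag_s\tg\terr\n")
        for lag, g, e in zip(curve.lags_s, curve.g, curve.errors):
            fh.write(f"{lag:.9e}\t{g:.9e}\t{e:.9e}\n")


def read_curve_text(path) -> CorrelationCurve:
    with open(path) as fh:
        meta = dict(kv.split("=") for kv in fh.readline().lstrip("# ").split())
        fh.readline()
        rows = np.array([[float(x) for x in line.split()]
                         for line in fh if line.strip()])
    norm = meta.get("normalization_lag_s", "")
    return CorrelationCurve(rows[:, 0], rows[:, 1], rows[:, 2],
                            convention=meta["convention"],
                            normalization_lag_s=float(norm) if norm else None)
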