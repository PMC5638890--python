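"""Photon-stream container and on-disk formats.

The photon stream is the universal currency of the pipeline: every photon
carries a macrotime (absolute arrival time in integer clock ticks), a
nanotime (TCSPC delay after the excitation pulse, as an integer bin index)
and a detection channel (donor/acceptor crossed with parallel/perpendicular
polarization).  Streams produced by the simulator additionally carry a
``truth`` block recording every generator parameter, so that downstream
recovery tests can compare fitted values against ground truth without ever
feeding the truth into a fit.

On disk, streams follow the community photon-HDF5 convention (groups
``photon_data`` with ``timestamps``/``nanotimes``/``detectors`` and
``setup`` with the alternation and pulse periods), plus a nonstandard
``truth`` group.  A plain-text TSV fallback (macrotime_tick, nanotime_bin,
channel) is provided for small fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "PhotonStream",
    "CH_D_PAR",
    "CH_D_PERP",
    "CH_A_PAR",
    "CH_A_PERP",
    "CHANNEL_LABELS",
    "write_photon_hdf5",
    "read_photon_hdf5",
    "write_photon_tsv",
    "read_photon_tsv",
]

# Detector channel codes: donor/acceptor x parallel/perpendicular.
CH_D_PAR = 0
CH_D_PERP = 1
CH_A_PAR = 2
CH_A_PERP = 3

CHANNEL_LABELS = {CH_D_PAR: "D_par", CH_D_PERP: "D_perp",
                  CH_A_PAR: "A_par", CH_A_PERP: "A_perp"}
_LABEL_TO_CODE = {v: k for k, v in CHANNEL_LABELS.items()}

DONOR_CHANNELS = (CH_D_PAR, CH_D_PERP)
ACCEPTOR_CHANNELS = (CH_A_PAR, CH_A_PERP)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing layout of the (emulated) instrument.

    Parameters
    ----------
    pulse_period_ns:
        Excitation pulse period T.  Default 12.5 ns (80 MHz pulsed laser).
    macrotime_clock_ns:
        Tick size for absolute arrival times.  Default one pulse period,
        the native TCSPC hardware convention.
    alex_alternation_us:
        Duration of each excitation half-period of the alternating-laser
        (ALEX) cycle; donor and acceptor excitation alternate with this
        duty cycle (default 50 us), so a full cycle is twice this.
    nanotime_bins:
        Number of TCSPC bins spanning one pulse period.
    duration_s:
        Nominal acquisition length for simulations.
    """

    pulse_period_ns: float = 12.5
    macrotime_clock_ns: float = 12.5
    alex_alternation_us: float = 50.0
    nanotime_bins: int = 256
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_period_ns <= 0:
            raise ValueError("pulse_period_ns must be positive")
        if self.macrotime_clock_ns <= 0:
            raise ValueError("macrotime_clock_ns must be positive")
        if self.alex_alternation_us * 1000.0 <= 10 * self.pulse_period_ns:
            raise ValueError("ALEX half-period must be much longer than the "
                             "pulse period")
        if self.nanotime_bins < 64:
            raise ValueError("nanotime_bins must be >= 64")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def nanotime_bin_width_ns(self) -> float:
        return self.pulse_period_ns / self.nanotime_bins


@dataclass
class PhotonStream:
    """Timestamped, channel-tagged, nanotime-tagged photon records."""

    macrotimes: np.ndarray           # int64 ticks, nondecreasing
    nanotimes: np.ndarray            # int32 in [0, nanotime_bins)
    channels: np.ndarray             # int8 codes (CH_*)
    config: AcquisitionConfig
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.int64)
        self.nanotimes = np.asarray(self.nanotimes, dtype=np.int32)
        self.channels = np.asarray(self.channels, dtype=np.int8)
        n = len(self.macrotimes)
        if len(self.nanotimes) != n or len(self.channels) != n:
            raise ValueError("macrotimes, nanotimes, channels must have "
                             "equal length")
        if n and np.any(np.diff(self.macrotimes) < 0):
            raise ValueError("macrotimes must be nondecreasing")
        if n and (self.nanotimes.min() < 0
                  or self.nanotimes.max() >= self.config.nanotime_bins):
            raise ValueError("nanotimes out of [0, nanotime_bins)")

    def __len__(self) -> int:
        return len(self.macrotimes)

    @property
    def times_s(self) -> np.ndarray:
        """Macrotimes in seconds."""
        return self.macrotimes * (self.config.macrotime_clock_ns * 1e-9)

    @property
    def nanotimes_ns(self) -> np.ndarray:
        """Nanotime bin centers in nanoseconds."""
        return (self.nanotimes + 0.5) * self.config.nanotime_bin_width_ns

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Subset of the stream; per-photon truth arrays are subset too."""
        truth = dict(self.truth)
        for key, val in self.truth.items():
            if isinstance(val, np.ndarray) and len(val) == len(self):
                truth[key] = val[mask]
        return PhotonStream(self.macrotimes[mask], self.nanotimes[mask],
                            self.channels[mask], self.config, truth)


def _merge_sorted(streams: list[tuple[np.ndarray, np.ndarray, np.ndarray, dict]],
                  config: AcquisitionConfig, truth: dict) -> PhotonStream:
    """Merge (macrotime, nanotime, channel, per-photon-truth) blocks."""
    mac = np.concatenate([s[0] for s in streams])
    nano = np.concatenate([s[1] for s in streams])
    chan = np.concatenate([s[2] for s in streams])
    order = np.argsort(mac, kind="stable")
    out_truth = dict(truth)
    keys = set().union(*(s[3].keys() for s in streams)) if streams else set()
    for key in keys:
        parts = []
        for s in streams:
            if key in s[3]:
                parts.append(np.asarray(s[3][key]))
            else:
                raise KeyError(f"per-photon truth key {key!r} missing in a block")
        out_truth[key] = np.concatenate(parts)[order]
    return PhotonStream(mac[order], nano[order], chan[order], config, out_truth)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _truth_split(truth: dict) -> tuple[dict, dict]:
    """Split truth into JSON-serializable scalars and ndarray datasets."""
    scalars, arrays = {}, {}
    for key, val in truth.items():
        if isinstance(val, np.ndarray):
            arrays[key] = val
        else:
            scalars[key] = val
    return scalars, arrays


def write_photon_hdf5(stream: PhotonStream, path) -> None:
    """Write a stream in a photon-HDF5-style layout (plus a truth group)."""
    import h5py

    cfg = stream.config
    with h5py.File(path, "w") as h5:
        pd_grp = h5.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.macrotimes)
        pd_grp.create_dataset("nanotimes", data=stream.nanotimes)
        pd_grp.create_dataset("detectors", data=stream.channels)
        setup = h5.create_group("setup")
        setup.attrs["pulse_period_ns"] = cfg.pulse_period_ns
        setup.attrs["macrotime_clock_ns"] = cfg.macrotime_clock_ns
        setup.attrs["alex_alternation_us"] = cfg.alex_alternation_us
        setup.attrs["nanotime_bins"] = cfg.nanotime_bins
        setup.attrs["duration_s"] = cfg.duration_s
        scalars, arrays = _truth_split(stream.truth)
        tg = h5.create_group("truth")
        tg.attrs["json"] = json.dumps(scalars, default=float)
        for key, val in arrays.items():
            tg.create_dataset(key, data=val)


def read_photon_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as h5:
        setup = h5["setup"].attrs
        cfg = AcquisitionConfig(
            pulse_period_ns=float(setup["pulse_period_ns"]),
            macrotime_clock_ns=float(setup["macrotime_clock_ns"]),
            alex_alternation_us=float(setup["alex_alternation_us"]),
            nanotime_bins=int(setup["nanotime_bins"]),
            duration_s=float(setup["duration_s"]),
        )
        truth = {}
        if "truth" in h5:
            truth.update(json.loads(h5["truth"].attrs.get("json", "{}")))
            for key in h5["truth"]:
                truth[key] = h5["truth"][key][()]
        return PhotonStream(h5["photon_data/timestamps"][()],
                            h5["photon_data/nanotimes"][()],
                            h5["photon_data/detectors"][()], cfg, truth)


def write_photon_tsv(stream: PhotonStream, path) -> None:
    """Columnar text fallback: macrotime_tick, nanotime_bin, channel label."""
    cfg = stream.config
    header = (f"# pulse_period_ns={cfg.pulse_period_ns} "
              f"macrotime_clock_ns={cfg.macrotime_clock_ns} "
              f"alex_alternation_us={cfg.alex_alternation_us} "
              f"nanotime_bins={cfg.nanotime_bins} "
              f"duration_s={cfg.duration_s}\n"
              "macrotime_tick\tnanotime_bin\tchannel\n")
    with open(path, "w") as fh:
        fh.write(header)
        labels = np.array([CHANNEL_LABELS[c] for c in sorted(CHANNEL_LABELS)])
        for mac, nano, chan in zip(stream.macrotimes, stream.nanotimes,
                                   stream.channels):
            fh.write(f"{mac}\t{nano}\t{labels[chan]}\n")


def read_photon_tsv(path) -> PhotonStream:
    with open(path) as fh:
        first = fh.readline()
        meta: Mapping[str, float] = dict(
            kv.split("=") for kv in first.lstrip("# ").split())
        fh.readline()  # column names
        mac, nano, chan = [], [], []
        for line in fh:
            m, n, c = line.split()
            mac.append(int(m))
            nano.append(int(n))
            chan.append(_LABEL_TO_CODE[c])
    cfg = AcquisitionConfig(
        pulse_period_ns=float(meta["pulse_period_ns"]),
        macrotime_clock_ns=float(meta["macrotime_clock_ns"]),
        alex_alternation_us=float(meta["alex_alternation_us"]),
        nanotime_bins=int(meta["nanotime_bins"]),
        duration_s=float(meta["duration_s"]),
    )
    return PhotonStream(np.array(mac), np.array(nano), np.array(chan), cfg)
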