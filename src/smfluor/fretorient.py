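"""Orientation factor and FRET efficiency from dye trajectories.

Post-processing of molecular-dynamics dye coordinates: the orientation
factor between donor and acceptor transition dipoles,

    kappa^2 = [ d.a - 3 (d.r)(a.r) ]^2,

with d, a, r unit vectors (dipole directions and the donor->acceptor
separation direction; unit normalization is what bounds the factor to its
theoretical 0-4 range), the sixth-root rescaling of the Forster radius
R0(kappa^2) = R0_iso * (kappa^2 / (2/3))^(1/6), and the Forster transfer
efficiency E = 1 / (1 + (R/R0)^6) evaluated per frame in isotropic,
instantaneous or time-averaged kappa^2 modes.

Trajectory tables are delimited text with one row per frame; a converter
from multi-model PDB snapshots extracting four named dipole-defining atoms
is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DipoleFrame",
    "ForsterParams",
    "kappa_squared",
    "isotropic_kappa_mc",
    "rescale_r0",
    "fret_efficiency",
    "trajectory_fret",
    "read_trajectory_table",
    "write_trajectory_table",
    "frames_from_pdb_models",
    "ISOTROPIC_KAPPA2",
]

ISOTROPIC_KAPPA2 = 2.0 / 3.0

TRAJ_COLUMNS = (
    ["time_ns"]
    + [f"d_center_{ax}" for ax in "xyz"]
    + [f"a_center_{ax}" for ax in "xyz"]
    + [f"d_atom1_{ax}" for ax in "xyz"]
    + [f"d_atom2_{ax}" for ax in "xyz"]
    + [f"a_atom1_{ax}" for ax in "xyz"]
    + [f"a_atom2_{ax}" for ax in "xyz"]
)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"{what} vector must be nonzero")
    return v / norm


@dataclass(frozen=True)
class DipoleFrame:
    """One trajectory time-point: dye centers (A) and dipole directions.

    Dipole vectors are normalized on ingest; they may be given either as
    direct directions or as the difference of two atom positions (see
    :meth:`from_atoms`).
    """

    time_ns: float
    d_center: np.ndarray
    a_center: np.ndarray
    d_dipole: np.ndarray
    a_dipole: np.ndarray

    def __post_init__(self) -> None:
        for name in ("d_center", "a_center"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)) or v.shape != (3,):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "d_dipole", _unit(self.d_dipole, "d_dipole"))
        object.__setattr__(self, "a_dipole", _unit(self.a_dipole, "a_dipole"))
        if self.time_ns < 0:
            raise ValueError("time_ns must be nonnegative")

    @classmethod
    def from_atoms(cls, time_ns, d_center, a_center, d_atom1, d_atom2,
                   a_atom1, a_atom2) -> "DipoleFrame":
        """Build a frame from two dipole-defining atoms per dye."""
        return cls(time_ns, d_center, a_center,
                   np.asarray(d_atom2, float) - np.asarray(d_atom1, float),
                   np.asarray(a_atom2, float) - np.asarray(a_atom1, float))

    @property
    def separation_A(self) -> float:
        return float(np.linalg.norm(self.a_center - self.d_center))


@dataclass(frozen=True)
class ForsterParams:
    """Forster radius at kappa^2 = 2/3 and the kappa^2 handling mode."""

    r0_iso_A: float = 52.0
    kappa2_mode: str = "isotropic"   # isotropic | instantaneous | time_averaged

    def __post_init__(self) -> None:
        if self.r0_iso_A <= 0:
            raise ValueError("r0_iso_A must be positive")
        if self.kappa2_mode not in ("isotropic", "instantaneous",
                                    "time_averaged"):
            raise ValueError("unknown kappa2_mode")


def kappa_squared(frame: DipoleFrame) -> float:
    """Orientation factor of one frame; always in [0, 4]."""
    sep = frame.a_center - frame.d_center
    if np.linalg.norm(sep) == 0:
        raise ValueError("donor and acceptor centers coincide")
    r_hat = _unit(sep, "separation")
    d_hat, a_hat = frame.d_dipole, frame.a_dipole
    val = (d_hat @ a_hat - 3.0 * (d_hat @ r_hat) * (a_hat @ r_hat)) ** 2
    return float(val)


def isotropic_kappa_mc(n_samples: int, seed: int):
    """Monte-Carlo mean of kappa^2 under isotropic dipole orientations.

    Draws uniform random unit vectors for both dipoles with a fixed
    separation direction; returns (mean, standard_error).  The analytic
    isotropic average is 2/3.
    """
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 1e4")
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(n_samples, 3))
    a = rng.normal(size=(n_samples, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    # separation direction fixed along z
    k2 = (np.einsum("ij,ij->i", d, a) - 3.0 * d[:, 2] * a[:, 2]) ** 2
    return float(k2.mean()), float(k2.std(ddof=1) / np.sqrt(n_samples))


def rescale_r0(r0_iso_A: float, kappa2: float) -> float:
    """Forster radius under a non-isotropic kappa^2.

    R0 scales as the sixth root of kappa^2: R0 = R0_iso (kappa^2/(2/3))^(1/6).
    kappa^2 = 0 means no transfer; R0 = 0 is returned with a warning.
    """
    if kappa2 < 0:
        raise ValueError("kappa2 must be nonnegative")
    if kappa2 == 0:
        warnings.warn("kappa^2 = 0: no energy transfer (R0 = 0)")
        return 0.0
    return r0_iso_A * (kappa2 / ISOTROPIC_KAPPA2) ** (1.0 / 6.0)


def fret_efficiency(r_A: float, r0_A: float) -> float:
    """Forster equation E = 1 / (1 + (R/R0)^6)."""
    r_A = np.asarray(r_A, dtype=float)
    if np.any(r_A <= 0):
        raise ValueError("distance must be positive")
    if r0_A == 0:
        return np.zeros_like(r_A) if r_A.ndim else 0.0
    if r0_A < 0:
        raise ValueError("R0 must be nonnegative")
    out = 1.0 / (1.0 + (r_A / r0_A) ** 6)
    return out if r_A.ndim else float(out)


def trajectory_fret(frames, params: ForsterParams) -> pd.DataFrame:
    """Per-frame distance, kappa^2 and FRET efficiency for a trajectory.

    kappa^2 handling: ``isotropic`` keeps R0 at its 2/3 value for every
    frame; ``instantaneous`` rescales R0 per frame by that frame's
    kappa^2 (frames with kappa^2 = 0 transfer nothing, E = 0);
    ``time_averaged`` rescales once by the trajectory-mean kappa^2.
    The returned frame has attrs with summary statistics.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.array([f.time_ns for f in frames])
    r = np.array([f.separation_A for f in frames])
    k2 = np.array([kappa_squared(f) for f in frames])
    mode = params.kappa2_mode
    if mode == "isotropic":
        r0 = np.full_like(r, params.r0_iso_A)
    elif mode == "time_averaged":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0 = np.full_like(r, rescale_r0(params.r0_iso_A,
                                            float(k2.mean())))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0 = np.array([rescale_r0(params.r0_iso_A, v) for v in k2])
    e = np.where(r0 > 0, 1.0 / (1.0 + (r / np.where(r0 > 0, r0, 1.0)) ** 6),
                 0.0)
    out = pd.DataFrame({"time_ns": times, "r_A": r, "kappa2": k2,
                        "r0_A": r0, "efficiency": e})
    out.attrs["kappa2_mean"] = float(k2.mean())
    out.attrs["kappa2_min"] = float(k2.min())
    out.attrs["kappa2_max"] = float(k2.max())
    out.attrs["e_min"] = float(e.min())
    out.attrs["e_max"] = float(e.max())
    out.attrs["e_mean"] = float(e.mean())
    out.attrs["n_zero_kappa_frames"] = int(np.count_nonzero(k2 == 0))
    out.attrs["mode"] = mode
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trajectory_table(path) -> list[DipoleFrame]:
    """Read the 19-column delimited trajectory table (see TRAJ_COLUMNS)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    frames = []
    for _, row in df.iterrows():
        frames.append(DipoleFrame.from_atoms(
            row["time_ns"],
            [row[f"d_center_{ax}"] for ax in "xyz"],
            [row[f"a_center_{ax}"] for ax in "xyz"],
            [row[f"d_atom1_{ax}"] for ax in "xyz"],
            [row[f"d_atom2_{ax}"] for ax in "xyz"],
            [row[f"a_atom1_{ax}"] for ax in "xyz"],
            [row[f"a_atom2_{ax}"] for ax in "xyz"]))
    return frames


def write_trajectory_table(frames, path) -> None:
    """Write frames as a table; dipoles stored as center +- direction/2."""
    rows = []
    for f in frames:
        row = {"time_ns": f.time_ns}
        for ax_i, ax in enumerate("xyz"):
            row[f"d_center_{ax}"] = f.d_center[ax_i]
            row[f"a_center_{ax}"] = f.a_center[ax_i]
            row[f"d_atom1_{ax}"] = f.d_center[ax_i] - f.d_dipole[ax_i] / 2
            row[f"d_atom2_{ax}"] = f.d_center[ax_i] + f.d_dipole[ax_i] / 2
            row[f"a_atom1_{ax}"] = f.a_center[ax_i] - f.a_dipole[ax_i] / 2
            row[f"a_atom2_{ax}"] = f.a_center[ax_i] + f.a_dipole[ax_i] / 2
        rows.append(row)
    pd.DataFrame(rows, columns=TRAJ_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


def frames_from_pdb_models(path, donor_resname: str, donor_atoms: tuple,
                           acceptor_resname: str, acceptor_atoms: tuple,
                           frame_dt_ns: float = 1.0) -> list[DipoleFrame]:
    """Extract dipole frames from a multi-model PDB snapshot file.

    ``donor_atoms`` / ``acceptor_atoms`` name the two dipole-defining atoms
    of each dye residue (e.g. ("C12", "C16") for a fluorescein arsenical
    donor and ("N5", "N4") for a cyanine acceptor).  Dye centers are the
    geometric centers of all atoms of the named residue.  Model k is
    assigned time k * frame_dt_ns.
    """
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    stack = pdb.get_structure()
    frames = []
    for k in range(stack.stack_depth()):
        model = stack[k]
        frames.append(_frame_from_model(model, k * frame_dt_ns,
                                        donor_resname, donor_atoms,
                                        acceptor_resname, acceptor_atoms))
    return frames


def _frame_from_model(model, time_ns, donor_resname, donor_atoms,
                      acceptor_resname, acceptor_atoms) -> DipoleFrame:
    def dye(resname, atoms):
        sel = model[model.res_name == resname]
        if sel.array_length() == 0:
            raise ValueError(f"residue {resname} not found")
        center = sel.coord.mean(axis=0)
        pair = []
        for name in atoms:
            hit = sel[sel.atom_name == name]
            if hit.array_length() != 1:
                raise ValueError(f"atom {name} of {resname}: expected "
                                 f"exactly one, found {hit.array_length()}")
            pair.append(hit.coord[0])
        return center, pair

    d_center, (d1, d2) = dye(donor_resname, donor_atoms)
    a_center, (a1, a2) = dye(acceptor_resname, acceptor_atoms)
    return DipoleFrame.from_atoms(time_ns, d_center, a_center, d1, d2, a1, a2)
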