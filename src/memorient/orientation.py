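"""Orientation and insertion depth of a membrane-anchored protein.

A bitopic protein such as a microsomal cytochrome P450 sits in the bilayer with a
single transmembrane (TM) helix while its globular domain dips into one leaflet.
Its pose relative to the membrane is summarised by five per-frame parameters:

* ``alpha`` — angle between the I-helix axis vector (CoM of the first four
  residues' backbone atoms to CoM of the last four) and the membrane normal;
* ``beta`` — angle between the C-helix→F-helix vector (first four residues of the
  C helix to last four of the F helix) and the normal;
* ``gamma_tm`` — tilt of the TM-helix axis from the normal;
* ``heme_tilt`` — angle between the plane of the heme's four iron-coordinating
  nitrogens and the normal, folded into [0°, 90°];
* ``com_distance`` — axial (z) distance between the globular-domain centre of
  mass and the lipid-bilayer centre of mass.

The membrane normal is fixed to the box z-axis.  ``alpha`` and ``beta`` are kept
unfolded in [0°, 180°] because the two ends of a helix vector are distinguishable;
a plane's tilt is sign-ambiguous, hence the folding of the heme tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_structures import MolecularSystem, Trajectory
from .selection import select

__all__ = [
    "OrientationSpec", "OrientationSeries", "center_of_mass", "helix_vector",
    "angle_to_membrane_normal", "heme_tilt", "insertion_depth",
    "orientation_series", "representative_frame", "assess_convergence",
]

DEFAULT_BACKBONE_NAMES = ("N", "CA", "C", "O")

PARAMETER_NAMES = ("alpha", "beta", "gamma_tm", "heme_tilt", "com_distance")
ANGLE_PARAMETERS = ("alpha", "beta", "gamma_tm", "heme_tilt")


@dataclass
class OrientationSpec:
    """Residue-range definitions of the orientation vectors.

    Ranges are inclusive ``(first_resid, last_resid)`` pairs.  Each helix range
    must span at least 8 residues so the first-4/last-4 construction does not
    overlap.  ``heme_nitrogens`` selects exactly the four nitrogen atoms
    coordinating the heme iron.
    """

    i_helix: tuple[int, int]
    c_helix: tuple[int, int]
    f_helix: tuple[int, int]
    tm_helix: tuple[int, int]
    globular_domain: tuple[int, int]
    heme_nitrogens: str  # selection expression yielding exactly 4 atoms
    backbone_atom_names: tuple[str, ...] = DEFAULT_BACKBONE_NAMES
    membrane_selection: str = "moltag lipid"

    def __post_init__(self) -> None:
        for label in ("i_helix", "c_helix", "f_helix", "tm_helix"):
            lo, hi = getattr(self, label)
            if hi - lo + 1 < 8:
                raise ValueError(f"{label} range {lo}-{hi} has fewer than 8 residues")

    def validate_on(self, system: MolecularSystem) -> None:
        """Fail fast if any definition does not resolve on a topology."""
        for label in ("i_helix", "c_helix", "f_helix", "tm_helix", "globular_domain"):
            lo, hi = getattr(self, label)
            if len(select(system, f"resid {lo}-{hi}")) == 0:
                raise ValueError(f"{label} range {lo}-{hi} selects no atoms")
        n_heme = len(select(system, self.heme_nitrogens))
        if n_heme != 4:
            raise ValueError(f"heme_nitrogens selects {n_heme} atoms (need exactly 4)")
        if len(select(system, self.membrane_selection)) == 0:
            raise ValueError(f"membrane selection {self.membrane_selection!r} selects no atoms")


@dataclass
class OrientationSeries:
    """Per-frame orientation parameters (angles in degrees, distance in Å)."""

    time: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma_tm: np.ndarray
    heme_tilt: np.ndarray
    com_distance: np.ndarray
    flags: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in PARAMETER_NAMES:
            raise KeyError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.time,
            "alpha_deg": self.alpha,
            "beta_deg": self.beta,
            "gamma_tm_deg": self.gamma_tm,
            "heme_tilt_deg": self.heme_tilt,
            "com_distance_A": self.com_distance,
        })

    def summary(self, window_ns: float | None = None) -> dict[str, tuple[float, float]]:
        """Mean ± sample standard deviation over a trailing time window.

        ``window_ns=None`` uses all frames.  The window must fit inside the
        covered time span.
        """
        if window_ns is None:
            mask = np.ones(self.n_frames, dtype=bool)
        else:
            t_end = self.time[-1]
            span = t_end - self.time[0]
            if window_ns > span and self.n_frames > 1:
                raise ValueError(
                    f"window of {window_ns} ns exceeds trajectory span of {span} ns"
                )
            mask = self.time >= t_end - window_ns
        out = {}
        for p in PARAMETER_NAMES:
            v = self.values(p)[mask]
            std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            out[p] = (float(np.mean(v)), std)
        return out


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def center_of_mass(system: MolecularSystem, indices: np.ndarray,
                   coords: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted centre of mass of a set of atoms."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty selection has no centre of mass")
    pos = (coords if coords is not None else system.positions)[indices]
    m = system.masses()[indices]
    return (pos * m[:, None]).sum(axis=0) / m.sum()


def helix_vector(system: MolecularSystem, resid_range: tuple[int, int],
                 backbone_names: tuple[str, ...] = DEFAULT_BACKBONE_NAMES,
                 coords: np.ndarray | None = None) -> np.ndarray:
    """Axis vector of a helix: CoM(first 4 residues) → CoM(last 4 residues).

    Only backbone atoms enter the CoMs (mass-weighted).  Missing backbone atoms
    in the terminal residue windows are an error naming the residues.
    """
    lo, hi = resid_range
    if hi - lo + 1 < 8:
        raise ValueError(f"helix range {lo}-{hi} has fewer than 8 residues")
    name_clause = " ".join(backbone_names)
    ends = []
    for a, b in ((lo, lo + 3), (hi - 3, hi)):
        idx = select(system, f"resid {a}-{b} and name {name_clause}")
        present = set(system.resids[idx].tolist())
        missing = [r for r in range(a, b + 1) if r not in present]
        if missing:
            raise ValueError(
                f"residues {missing} in helix range {lo}-{hi} have no backbone atoms"
            )
        ends.append(center_of_mass(system, idx, coords))
    return ends[1] - ends[0]


def angle_to_membrane_normal(v: np.ndarray) -> float:
    """Angle (degrees, [0°, 180°]) between a vector and the box z-axis."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))


def heme_tilt(system: MolecularSystem, heme_nitrogens: str | np.ndarray,
              coords: np.ndarray | None = None) -> float:
    """Tilt of the heme plane from the membrane normal, in [0°, 90°].

    The plane is the least-squares plane through the four iron-coordinating
    nitrogens (normal = smallest principal direction of the centred point set,
    which is invariant under relabelling the nitrogens).  The tilt is
    90° − angle(normal, ẑ) with the normal's sign ambiguity folded out.
    """
    if isinstance(heme_nitrogens, str):
        idx = select(system, heme_nitrogens)
    else:
        idx = np.asarray(heme_nitrogens, dtype=int)
    if len(idx) != 4:
        raise ValueError(f"heme plane needs exactly 4 atoms, got {len(idx)}")
    pts = (coords if coords is not None else system.positions)[idx]
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("heme nitrogens are collinear; plane undefined")
    normal = vt[2]
    cosang = abs(np.clip(normal[2] / np.linalg.norm(normal), -1.0, 1.0))
    normal_angle = np.degrees(np.arccos(cosang))  # folded into [0, 90]
    return float(90.0 - normal_angle)


def insertion_depth(system: MolecularSystem, globular: tuple[int, int] | np.ndarray,
                    membrane: str | np.ndarray = "moltag lipid",
                    coords: np.ndarray | None = None) -> float:
    """Axial |z(CoM globular domain) − z(CoM lipid bilayer)| in Å (mass-weighted)."""
    if isinstance(globular, tuple):
        g_idx = select(system, f"resid {globular[0]}-{globular[1]}")
    else:
        g_idx = np.asarray(globular, dtype=int)
    m_idx = select(system, membrane) if isinstance(membrane, str) else np.asarray(membrane, dtype=int)
    if g_idx.size == 0 or m_idx.size == 0:
        raise ValueError("empty globular or membrane selection")
    zg = center_of_mass(system, g_idx, coords)[2]
    zm = center_of_mass(system, m_idx, coords)[2]
    return float(abs(zg - zm))


# ---------------------------------------------------------------------------
# per-trajectory analysis
# ---------------------------------------------------------------------------

def orientation_series(traj: Trajectory, spec: OrientationSpec) -> OrientationSeries:
    """Compute the five orientation parameters for every frame of a trajectory."""
    topo = traj.topology
    spec.validate_on(topo)
    heme_idx = select(topo, spec.heme_nitrogens)
    mem_idx = select(topo, spec.membrane_selection)
    lo, hi = spec.globular_domain
    glob_idx = select(topo, f"resid {lo}-{hi}")

    cols = {p: np.empty(traj.n_frames) for p in PARAMETER_NAMES}
    for k, frame in enumerate(traj.frames):
        c = frame.coordinates
        cols["alpha"][k] = angle_to_membrane_normal(
            helix_vector(topo, spec.i_helix, spec.backbone_atom_names, coords=c))
        v2 = _cross_helix_vector(topo, spec.c_helix, spec.f_helix,
                                 spec.backbone_atom_names, coords=c)
        cols["beta"][k] = angle_to_membrane_normal(v2)
        cols["gamma_tm"][k] = angle_to_membrane_normal(
            helix_vector(topo, spec.tm_helix, spec.backbone_atom_names, coords=c))
        cols["heme_tilt"][k] = heme_tilt(topo, heme_idx, coords=c)
        cols["com_distance"][k] = insertion_depth(topo, glob_idx, mem_idx, coords=c)
    return OrientationSeries(time=traj.times, **cols)


def _cross_helix_vector(system: MolecularSystem, c_helix: tuple[int, int],
                        f_helix: tuple[int, int], backbone_names: tuple[str, ...],
                        coords: np.ndarray | None = None) -> np.ndarray:
    """CoM(first 4 residues of C helix) → CoM(last 4 residues of F helix)."""
    name_clause = " ".join(backbone_names)
    c_lo, _ = c_helix
    _, f_hi = f_helix
    c_idx = select(system, f"resid {c_lo}-{c_lo + 3} and name {name_clause}")
    f_idx = select(system, f"resid {f_hi - 3}-{f_hi} and name {name_clause}")
    if c_idx.size == 0 or f_idx.size == 0:
        raise ValueError("C/F helix terminal residues have no backbone atoms")
    return center_of_mass(system, f_idx, coords) - center_of_mass(system, c_idx, coords)


def representative_frame(series: OrientationSeries,
                         parameters: tuple[str, ...] = PARAMETER_NAMES,
                         ) -> tuple[int, bool]:
    """Pick the frame whose chosen parameters all lie within 1% of their means.

    Among qualifying frames, return the one minimising the sum of squared
    normalised deviations (earliest frame on ties).  If no frame qualifies the
    global minimiser is returned with ``within_tolerance=False``.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames")
    devs = []
    for p in parameters:
        v = series.values(p)
        mean = np.mean(v)
        scale = abs(mean) if mean != 0 else 1.0
        devs.append((v - mean) / scale)
    dev = np.stack(devs)  # (n_params, n_frames)
    score = np.sum(dev**2, axis=0)
    within = np.all(np.abs(dev) <= 0.01, axis=0)
    if np.any(within):
        candidates = np.flatnonzero(within)
        return int(candidates[np.argmin(score[candidates])]), True
    return int(np.argmin(score)), False


def assess_convergence(series: OrientationSeries, window_ns: float,
                       tolerance_deg: float,
                       parameters: tuple[str, ...] = ANGLE_PARAMETERS,
                       ) -> tuple[bool, float | None]:
    """Window-mean drift test for orientation convergence.

    The time axis is cut into consecutive non-overlapping windows of
    ``window_ns``.  The series is converged from the end of window *k* onwards if
    every later pair of consecutive window means differs by less than
    ``tolerance_deg`` for all monitored angles.  Returns ``(converged,
    first_converged_time)``; the time is the end of the first such window.
    """
    t = series.time
    t0 = t[0]
    span = t[-1] - t0
    n_windows = int(np.floor(span / window_ns + 1e-9))
    if n_windows < 2:
        raise ValueError(f"fewer than 2 windows of {window_ns} ns fit in {span} ns")
    means = np.empty((len(parameters), n_windows))
    for w in range(n_windows):
        mask = (t >= t0 + w * window_ns) & (t < t0 + (w + 1) * window_ns)
        if w == n_windows - 1:  # last window keeps its right edge
            mask |= t == t[-1]
        if not np.any(mask):
            raise ValueError(f"window {w} contains no frames")
        for j, p in enumerate(parameters):
            means[j, w] = np.mean(series.values(p)[mask])
    drift_ok = np.all(np.abs(np.diff(means, axis=1)) < tolerance_deg, axis=0)  # (n_windows-1,)
    # converged at window k iff all transitions from k onwards are quiet
    for k in range(n_windows - 1):
        if np.all(drift_ok[k:]):
            return True, float(t0 + (k + 1) * window_ns)
    return False, None
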