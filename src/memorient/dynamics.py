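"""Protein dynamics: rigid-body superposition, RMSD time series, RMSF and B-factors.

Superposition uses the standard SVD solution of the orthogonal Procrustes
problem with the determinant correction that guarantees a proper rotation.
Per-residue root-mean-square fluctuations are computed about the window-average
structure after iterative alignment (two passes), and converted to
crystallographic-convention temperature factors B = 8π²·RMSF²/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_structures import MolecularSystem, Trajectory
from .selection import select

__all__ = ["BFactorSeries", "superpose", "rmsd", "rmsd_series", "bfactors",
           "B_FACTOR_PREFACTOR"]

#: conversion RMSF² (Å²) → B (Å²): 8π²/3
B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class BFactorSeries:
    """Per-atom RMSF (Å) and B-factor (Å²) for a selection, usually the Cα set."""

    atom_indices: np.ndarray
    resids: np.ndarray
    rmsf: np.ndarray

    @property
    def b(self) -> np.ndarray:
        return B_FACTOR_PREFACTOR * self.rmsf**2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "atom_index": self.atom_indices,
            "resid": self.resids,
            "rmsf_A": self.rmsf,
            "bfactor_A2": self.b,
        })


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning mobile onto reference.

    Returns (R, mobile_centroid, reference_centroid) with the transform
    x' = (x − c_mob) @ R.T + c_ref minimising the RMSD over the paired points.
    """
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need ≥3 paired points of identical shape")
    c_mob = mobile.mean(axis=0)
    c_ref = reference.mean(axis=0)
    a = mobile - c_mob
    b = reference - c_ref
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("selection is collinear; rotation underdetermined")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, c_mob, c_ref


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The fit uses the atoms in ``selection`` (defaults to all); the returned
    transformed coordinates cover *all* mobile atoms.  Returns
    ``(rotation, translation, transformed)`` such that
    ``transformed = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection, dtype=int)
    r, c_mob, c_ref = _kabsch(mobile[sel], reference[sel])
    t = c_ref - c_mob @ r.T
    return r, t, mobile @ r.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def rmsd_series(traj: Trajectory, reference: MolecularSystem,
                selection: str | np.ndarray) -> np.ndarray:
    """Per-frame RMSD to a reference structure after superposition on the selection.

    The same selection drives both the fit and the RMSD, matching the usual
    "Cα RMSD of the globular domain" convention.  The reference is typically the
    energy-minimised starting structure supplied by the caller.
    """
    if isinstance(selection, str):
        sel_t = select(traj.topology, selection)
        sel_r = select(reference, selection)
    else:
        sel_t = sel_r = np.asarray(selection, dtype=int)
    if len(sel_t) != len(sel_r):
        raise ValueError(
            f"selection resolves to {len(sel_t)} atoms on the trajectory but "
            f"{len(sel_r)} on the reference"
        )
    ref = reference.positions[sel_r]
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        mob = frame.coordinates[sel_t]
        _, _, fitted = superpose(mob, ref)
        out[k] = rmsd(fitted, ref)
    return out


def bfactors(traj: Trajectory, selection: str | np.ndarray,
             window_ns: float | None = None, n_passes: int = 2) -> BFactorSeries:
    """Per-atom RMSF and B-factors over a trailing window.

    Frames are superposed on the selection, first onto the initial frame, then
    (``n_passes − 1`` more times) onto the running mean structure — the standard
    iterative scheme that removes the alignment-reference bias.  RMSF is the
    root-mean-square deviation of each atom about its window-mean position;
    B = 8π²·RMSF²/3.
    """
    sel = select(traj.topology, selection) if isinstance(selection, str) else np.asarray(selection, dtype=int)
    frames = traj.frames
    if window_ns is not None:
        t_end = frames[-1].time
        frames = [f for f in frames if f.time >= t_end - window_ns]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    coords = np.array([f.coordinates[sel] for f in frames])  # (T, n, 3)

    ref = coords[0]
    for _ in range(max(1, n_passes)):
        aligned = np.empty_like(coords)
        for t in range(len(frames)):
            _, _, aligned[t] = superpose(coords[t], ref)
        ref = aligned.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return BFactorSeries(sel, traj.topology.resids[sel].copy(), rmsf)
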