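"""Bilayer structure analysis: leaflets, boundary lipids, area per lipid,
order parameters, electron-density profiles and thickness.

Area per lipid (APL) follows the Voronoi-tessellation + Monte-Carlo scheme: each
lipid's head-group reference atom, projected onto the membrane plane, seeds a
Voronoi cell; protein atoms lying in a z-slab around the leaflet's head-group
plane are injected as extra seeds so that the protein footprint is excluded from
the lipid areas.  The exact tessellation (with the eight periodic images, so all
polygons are bounded and areas sum exactly to the box cross-section) and the
Monte-Carlo nearest-seed estimator are both provided; the MC estimator converges
to the exact areas and serves as an internal consistency check.

Lipids with any atom within a cutoff (default 5 Å) of a protein atom are
classified as *boundary* lipids; the rest are *non-boundary* (bulk) lipids, and
APL statistics are reported separately for the two classes.

Deuterium order parameters are S_CD = ⟨(3cos²θ − 1)/2⟩ for the C–H bond vectors
of each acyl-chain carbon relative to the bilayer normal.  Electron-density
profiles assign each atom its atomic number of electrons to 0.1 Å z-slabs and
divide by the time-averaged cross-sectional area; the bilayer thickness is the
distance between the two head-group density peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial import Voronoi, cKDTree

from .io_structures import Box, LipidDialect, MolecularSystem, Trajectory
from .orientation import center_of_mass

__all__ = [
    "LeafletPartition", "APLTable", "OrderParameterProfile", "ElectronDensityProfile",
    "ThicknessResult", "assign_leaflets", "classify_boundary", "apl_voronoi",
    "apl_montecarlo", "area_per_lipid", "order_parameters", "electron_density",
    "bilayer_thickness", "thickness_map", "periodic_voronoi_areas",
]


# ---------------------------------------------------------------------------
# leaflets and boundary classification
# ---------------------------------------------------------------------------

@dataclass
class LeafletPartition:
    """Leaflet label per lipid molecule.

    ``lipid_molecules`` holds indices into ``system.molecules`` (lipid-tagged
    groups, in order); ``labels`` holds ``"upper"``/``"lower"`` per lipid and
    ``head_indices`` the atom index of each lipid's head reference atom.
    A head atom exactly at the membrane CoM z is assigned ``lower`` (documented
    tie rule).
    """

    lipid_molecules: np.ndarray
    labels: np.ndarray
    head_indices: np.ndarray

    def lipids_in(self, leaflet: str) -> np.ndarray:
        return self.lipid_molecules[self.labels == leaflet]


def _lipid_molecule_ids(system: MolecularSystem) -> np.ndarray:
    return np.array([i for i, m in enumerate(system.molecules) if m.tag == "lipid"], dtype=int)


def _head_atom_indices(system: MolecularSystem, dialect: LipidDialect,
                       mol_ids: np.ndarray) -> np.ndarray:
    heads = np.empty(len(mol_ids), dtype=int)
    for k, mi in enumerate(mol_ids):
        idx = system.molecules[mi].indices
        hits = idx[system.names[idx] == dialect.head_reference_atom]
        if len(hits) != 1:
            rid = int(system.resids[idx[0]])
            raise ValueError(
                f"lipid starting at residue {rid} has {len(hits)} head reference "
                f"atoms {dialect.head_reference_atom!r} (need exactly 1)"
            )
        heads[k] = hits[0]
    return heads


def assign_leaflets(system: MolecularSystem, dialect: LipidDialect,
                    coords: np.ndarray | None = None) -> LeafletPartition:
    """Assign each lipid to the upper or lower leaflet.

    A lipid is *upper* if its head reference atom lies above the membrane centre
    of mass (mass-weighted CoM of all lipid atoms), else *lower*.
    """
    mol_ids = _lipid_molecule_ids(system)
    if len(mol_ids) == 0:
        raise ValueError("no lipid molecules; run group_molecules first")
    heads = _head_atom_indices(system, dialect, mol_ids)
    pos = coords if coords is not None else system.positions
    all_lipid = np.concatenate([system.molecules[mi].indices for mi in mol_ids])
    z_com = center_of_mass(system, all_lipid, coords)[2]
    labels = np.where(pos[heads, 2] > z_com, "upper", "lower").astype(object)
    return LeafletPartition(mol_ids, labels, heads)


def classify_boundary(system: MolecularSystem, cutoff: float = 5.0,
                      coords: np.ndarray | None = None,
                      box: Box | None = None) -> np.ndarray:
    """Flag boundary lipids: any lipid atom within ``cutoff`` of any protein atom.

    Distances use the minimum-image convention in the orthorhombic box; the
    cutoff must be smaller than half the shortest box edge.  Returns a boolean
    array ordered like the lipid molecules.  With no protein present all lipids
    are non-boundary (a warning is emitted).
    """
    box = box or system.box
    if box is None:
        raise ValueError("system has no box; minimum-image distances undefined")
    if cutoff >= min(box.lx, box.ly, box.lz) / 2:
        raise ValueError(
            f"cutoff {cutoff} Å ≥ half the shortest box edge; minimum-image assumption violated"
        )
    mol_ids = _lipid_molecule_ids(system)
    if len(mol_ids) == 0:
        raise ValueError("no lipid molecules; run group_molecules first")
    prot_idx = system.indices_by_tag("protein")
    flags = np.zeros(len(mol_ids), dtype=bool)
    if len(prot_idx) == 0:
        warnings.warn("no protein molecule present; all lipids classified non-boundary")
        return flags
    if cutoff <= 0:
        return flags
    pos = coords if coords is not None else system.positions
    lengths = box.lengths
    prot_pos = np.mod(pos[prot_idx], lengths)
    tree = cKDTree(prot_pos, boxsize=lengths)
    for k, mi in enumerate(mol_ids):
        lp = np.mod(pos[system.molecules[mi].indices], lengths)
        d, _ = tree.query(lp, k=1)
        flags[k] = bool(np.any(d <= cutoff))
    return flags


# ---------------------------------------------------------------------------
# area per lipid (Voronoi + Monte Carlo)
# ---------------------------------------------------------------------------

def _dedupe_seeds(points: np.ndarray) -> np.ndarray:
    """Perturb coincident 2D seeds by 1e-6 Å so the tessellation is defined."""
    rounded = np.round(points, 9)
    _, first, counts = np.unique(rounded, axis=0, return_index=True, return_counts=True)
    if np.all(counts == 1):
        return points
    warnings.warn("coincident tessellation seeds perturbed by 1e-6 Å")
    points = points.copy()
    seen: dict[tuple, int] = {}
    for i in range(len(points)):
        key = tuple(rounded[i])
        n = seen.get(key, 0)
        if n:
            ang = 2 * np.pi * (n / 8.0)
            points[i] += 1e-6 * np.array([np.cos(ang), np.sin(ang)])
        seen[key] = n + 1
    return points


def periodic_voronoi_areas(points: np.ndarray, lx: float, ly: float) -> np.ndarray:
    """Exact per-seed Voronoi areas in a periodic rectangle.

    The seed set is replicated into the 8 neighbouring images so every central
    polygon is bounded; the areas of the central seeds then tile the box exactly
    (Σ areas = lx·ly to floating-point precision).
    """
    points = np.mod(np.asarray(points, dtype=float), [lx, ly])
    n = len(points)
    if n < 3:
        raise ValueError(f"need at least 3 seeds for a tessellation, got {n}")
    points = _dedupe_seeds(points)
    shifts = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    tiled = np.vstack([points] + [points + np.array([dx * lx, dy * ly]) for dx, dy in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell for a central seed (degenerate geometry)")
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def _leaflet_seeds(system: MolecularSystem, partition: LeafletPartition, leaflet: str,
                   protein_slab_halfwidth: float,
                   coords: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(seed_xy, lipid_molecule_ids, n_protein_seeds) for one leaflet."""
    pos = coords if coords is not None else system.positions
    sel = partition.labels == leaflet
    heads = partition.head_indices[sel]
    mol_ids = partition.lipid_molecules[sel]
    if len(heads) == 0:
        raise ValueError(f"leaflet {leaflet!r} contains no lipids")
    head_xy = pos[heads, :2]
    z_plane = float(np.mean(pos[heads, 2]))
    prot_idx = system.indices_by_tag("protein")
    if len(prot_idx):
        zp = pos[prot_idx, 2]
        in_slab = np.abs(zp - z_plane) <= protein_slab_halfwidth
        prot_xy = pos[prot_idx[in_slab], :2]
    else:
        prot_xy = np.empty((0, 2))
    seeds = np.vstack([head_xy, prot_xy])
    return seeds, mol_ids, np.array([len(prot_xy)])


def apl_voronoi(system: MolecularSystem, dialect: LipidDialect, leaflet: str,
                partition: LeafletPartition | None = None,
                protein_slab_halfwidth: float = 10.0,
                coords: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Exact Voronoi area per lipid for one leaflet.

    Returns ``(table, protein_seed_area)``: a DataFrame with one row per lipid
    (``molecule``, ``leaflet``, ``area_A2``) and the total area claimed by
    protein seeds.  Lipid areas plus the protein area tile the box cross-section
    exactly.
    """
    if system.box is None:
        raise ValueError("system has no box")
    if partition is None:
        partition = assign_leaflets(system, dialect, coords)
    seeds, mol_ids, n_prot = _leaflet_seeds(system, partition, leaflet,
                                            protein_slab_halfwidth, coords)
    areas = periodic_voronoi_areas(seeds, system.box.lx, system.box.ly)
    n_l = len(mol_ids)
    table = pd.DataFrame({
        "molecule": mol_ids,
        "leaflet": leaflet,
        "area_A2": areas[:n_l],
    })
    return table, float(areas[n_l:].sum())


def apl_montecarlo(system: MolecularSystem, dialect: LipidDialect, leaflet: str,
                   n_samples: int, seed: int,
                   partition: LeafletPartition | None = None,
                   protein_slab_halfwidth: float = 10.0,
                   coords: np.ndarray | None = None) -> tuple[pd.DataFrame, float]:
    """Monte-Carlo area per lipid: nearest-seed assignment of uniform points.

    Uniform random points in the box cross-section are assigned to the nearest
    seed under the minimum-image convention; a seed's area is its winning
    fraction times lx·ly.  ``n_samples`` below 10⁴ makes the estimator unusable
    and is an error.  Fully reproducible given ``seed``.
    """
    if n_samples < 10_000:
        raise ValueError(f"n_samples={n_samples} < 10^4; Monte-Carlo estimate unusable")
    if system.box is None:
        raise ValueError("system has no box")
    if partition is None:
        partition = assign_leaflets(system, dialect, coords)
    lx, ly = system.box.lx, system.box.ly
    seeds, mol_ids, _ = _leaflet_seeds(system, partition, leaflet,
                                       protein_slab_halfwidth, coords)
    seeds = np.mod(seeds, [lx, ly])
    rng = np.random.default_rng(seed)
    pts = rng.random((n_samples, 2)) * [lx, ly]
    tree = cKDTree(seeds, boxsize=[lx, ly])
    _, owner = tree.query(pts, k=1)
    counts = np.bincount(owner, minlength=len(seeds))
    areas = counts / n_samples * (lx * ly)
    n_l = len(mol_ids)
    table = pd.DataFrame({
        "molecule": mol_ids,
        "leaflet": leaflet,
        "area_A2": areas[:n_l],
    })
    return table, float(areas[n_l:].sum())


@dataclass
class APLTable:
    """Per-lipid areas with leaflet and boundary labels plus summary statistics."""

    table: pd.DataFrame  # columns: molecule, leaflet, boundary, area_A2
    protein_seed_area: dict = field(default_factory=dict)
    box_area: float = 0.0

    def summary(self) -> pd.DataFrame:
        """Mean ± sample std of APL for boundary / non-boundary / all lipids."""
        rows = []
        groups = {
            "boundary": self.table[self.table["boundary"]],
            "non-boundary": self.table[~self.table["boundary"]],
            "all": self.table,
        }
        for label, sub in groups.items():
            v = sub["area_A2"].to_numpy()
            rows.append({
                "group": label,
                "n_lipids": len(v),
                "apl_mean_A2": float(np.mean(v)) if len(v) else np.nan,
                "apl_std_A2": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            })
        return pd.DataFrame(rows)


def area_per_lipid(system: MolecularSystem, dialect: LipidDialect,
                   method: str = "voronoi",
                   boundary_cutoff: float = 5.0,
                   protein_slab_halfwidth: float = 10.0,
                   n_samples: int = 100_000, seed: int = 0,
                   coords: np.ndarray | None = None,
                   box: Box | None = None) -> APLTable:
    """Both-leaflet APL table with boundary classification for one snapshot."""
    if box is not None and box is not system.box:
        system = system.with_positions(coords if coords is not None else system.positions, box)
        coords = None
    partition = assign_leaflets(system, dialect, coords)
    flags = classify_boundary(system, boundary_cutoff, coords)
    flag_by_mol = dict(zip(partition.lipid_molecules.tolist(), flags.tolist()))
    parts = []
    prot_area = {}
    for leaflet in ("upper", "lower"):
        if not np.any(partition.labels == leaflet):
            continue
        if method == "voronoi":
            tab, pa = apl_voronoi(system, dialect, leaflet, partition,
                                  protein_slab_halfwidth, coords)
        elif method == "mc":
            tab, pa = apl_montecarlo(system, dialect, leaflet, n_samples, seed,
                                     partition, protein_slab_halfwidth, coords)
        else:
            raise ValueError(f"unknown APL method {method!r}")
        parts.append(tab)
        prot_area[leaflet] = pa
    table = pd.concat(parts, ignore_index=True)
    table["boundary"] = table["molecule"].map(flag_by_mol)
    assert system.box is not None
    return APLTable(table[["molecule", "leaflet", "boundary", "area_A2"]],
                    prot_area, system.box.area_xy)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterProfile:
    """Signed S_CD per acyl-chain carbon, averaged over H atoms, lipids and frames."""

    chains: dict[str, np.ndarray]
    carbon_labels: dict[str, list[str]]
    n_lipids: int
    n_frames: int

    def abs_values(self, chain: str) -> np.ndarray:
        return np.abs(self.chains[chain])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chain, vals in self.chains.items():
            for j, (label, s) in enumerate(zip(self.carbon_labels[chain], vals)):
                rows.append({"chain": chain, "carbon_index": j + 2,  # C2 is first acyl carbon
                             "carbon": label, "S_CD": float(s), "abs_S_CD": float(abs(s))})
        return pd.DataFrame(rows)


def order_parameters(traj: Trajectory, dialect: LipidDialect,
                     lipid_molecules: np.ndarray | None = None) -> OrderParameterProfile:
    """Deuterium order parameters per chain carbon.

    S_CD = ⟨(3cos²θ − 1)/2⟩ with θ the angle between each C–H bond vector and
    the membrane normal (z-axis), averaged over the carbon's hydrogens, the
    selected lipid molecules (default: all) and all frames.  A chain carbon
    whose mapped hydrogens are absent from a lipid is an error naming the atom.
    """
    if not dialect.chain_definitions:
        raise ValueError("dialect declares no acyl-chain definitions")
    system = traj.topology
    mol_ids = lipid_molecules if lipid_molecules is not None else _lipid_molecule_ids(system)
    mol_ids = np.asarray(mol_ids, dtype=int)
    if len(mol_ids) == 0:
        raise ValueError("no lipid molecules selected")

    # index maps: chain -> carbon slot -> (C indices per lipid, H indices per lipid)
    maps: dict[str, list[tuple[np.ndarray, list[np.ndarray]]]] = {}
    for chain, carbons in dialect.chain_definitions.items():
        slots = []
        for cname, hnames in carbons:
            c_idx = np.empty(len(mol_ids), dtype=int)
            h_idx: list[np.ndarray] = []
            for k, mi in enumerate(mol_ids):
                idx = system.molecules[mi].indices
                names = system.names[idx]
                c_hits = idx[names == cname]
                if len(c_hits) != 1:
                    rid = int(system.resids[idx[0]])
                    raise ValueError(f"carbon {cname!r} occurs {len(c_hits)} times in lipid at residue {rid}")
                hs = idx[np.isin(names, hnames)]
                if len(hs) == 0:
                    raise ValueError(f"carbon {cname!r} has no mapped hydrogen ({hnames}) in a lipid")
                c_idx[k] = c_hits[0]
                h_idx.append(hs)
            slots.append((c_idx, h_idx))
        maps[chain] = slots

    chains_out: dict[str, np.ndarray] = {}
    for chain, slots in maps.items():
        per_carbon = np.zeros(len(slots))
        for j, (c_idx, h_idx) in enumerate(slots):
            acc = 0.0
            n = 0
            for frame in traj.frames:
                pos = frame.coordinates
                for k in range(len(mol_ids)):
                    v = pos[h_idx[k]] - pos[c_idx[k]]
                    cos2 = (v[:, 2] ** 2) / np.einsum("ij,ij->i", v, v)
                    acc += float(np.sum(1.5 * cos2 - 0.5))
                    n += len(v)
            per_carbon[j] = acc / n
        chains_out[chain] = per_carbon

    labels = {chain: [c for c, _ in carbons] for chain, carbons in dialect.chain_definitions.items()}
    return OrderParameterProfile(chains_out, labels, len(mol_ids), traj.n_frames)


# ---------------------------------------------------------------------------
# electron density and thickness
# ---------------------------------------------------------------------------

@dataclass
class ElectronDensityProfile:
    """z-binned electron densities (e/Å³) per named component.

    ``z`` holds bin centres relative to the membrane centre of mass; ``area`` is
    the time-averaged box cross-section used for normalisation.
    """

    z: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    area: float
    n_frames: int

    def electron_count(self, component: str = "total") -> float:
        """∫ρ dz × area — total electrons attributed to a component."""
        return float(np.sum(self.densities[component]) * self.bin_width * self.area)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"z_A": self.z})
        for name, rho in self.densities.items():
            df[name] = rho
        return df


def electron_density(traj: Trajectory, components: dict[str, np.ndarray] | None = None,
                     bin_width: float = 0.1, window_ns: float | None = None,
                     ) -> ElectronDensityProfile:
    """Electron-density profile along the membrane normal.

    Every atom contributes its atomic number of electrons to the 0.1 Å-thick
    z-slab containing it; slab counts averaged over the analysis window are
    divided by (time-averaged cross-sectional area × slab thickness).  The z
    origin is the lipid-bilayer centre of mass of each frame.  ``components``
    maps profile names to atom index arrays; a ``total`` profile over all atoms
    is always included.
    """
    system = traj.topology
    electrons = system.atomic_numbers()
    lipid_idx = system.indices_by_tag("lipid")
    if len(lipid_idx) == 0:
        raise ValueError("no lipid molecules; cannot define the membrane z origin")
    masses = system.masses()
    frames = traj.frames
    if window_ns is not None:
        t_end = frames[-1].time
        frames = [f for f in frames if f.time >= t_end - window_ns]
    if not frames:
        raise ValueError("analysis window contains no frames")
    comps = {"total": np.arange(system.n_atoms)}
    if components:
        comps.update({k: np.asarray(v, dtype=int) for k, v in components.items()})

    m_l = masses[lipid_idx]
    z_rel_frames = []
    areas = []
    for fr in frames:
        z = fr.coordinates[:, 2]
        z0 = float(np.dot(z[lipid_idx], m_l) / m_l.sum())
        z_rel_frames.append(z - z0)
        areas.append(fr.box.area_xy)
    zcat = np.concatenate(z_rel_frames)
    # pad by a few slabs so extreme atoms never sit in an edge bin
    half = max(abs(zcat.min()), abs(zcat.max())) + 5 * bin_width
    n_half = int(np.ceil(half / bin_width))
    edges = np.arange(-n_half, n_half + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean_area = float(np.mean(areas))

    densities = {}
    for name, idx in comps.items():
        acc = np.zeros(len(centers))
        for z_rel in z_rel_frames:
            acc += np.histogram(z_rel[idx], bins=edges, weights=electrons[idx])[0]
        densities[name] = acc / len(frames) / (mean_area * bin_width)
    return ElectronDensityProfile(centers, densities, bin_width, mean_area, len(frames))


@dataclass
class ThicknessResult:
    """Global head-peak-to-peak thickness and a local thickness map."""

    global_thickness: float | None
    map: np.ndarray | None = None          # (nx, ny) local thickness, Å; NaN where unfillable
    occluded: np.ndarray | None = None     # protein-covered cells
    filled: np.ndarray | None = None       # cells filled by nearest-neighbour


def _refine_peak(z: np.ndarray, rho: np.ndarray, i: int) -> float:
    """3-point parabolic refinement of a histogram peak position."""
    if i == 0 or i == len(rho) - 1:
        return float(z[i])
    y1, y2, y3 = rho[i - 1], rho[i], rho[i + 1]
    denom = y1 - 2 * y2 + y3
    if denom == 0:
        return float(z[i])
    offset = 0.5 * (y1 - y3) / denom
    return float(z[i] + np.clip(offset, -1, 1) * (z[1] - z[0]))


def bilayer_thickness(profile: ElectronDensityProfile, component: str = "headgroup",
                      min_peak_separation: float = 10.0) -> float:
    """Head-group peak-to-peak bilayer thickness from a density profile.

    The two dominant local maxima of the head-group component, each refined by a
    three-point parabolic fit, define the thickness.  A single merged peak (or
    two peaks closer than ``min_peak_separation`` Å) indicates an interdigitated
    or degenerate profile and raises an error.
    """
    if component not in profile.densities:
        raise KeyError(f"profile has no component {component!r}")
    rho = profile.densities[component]
    z = profile.z
    dist = max(1, int(round(min_peak_separation / profile.bin_width)))
    peaks, props = find_peaks(rho, height=0.05 * rho.max(), distance=dist)
    if len(peaks) < 2:
        raise ValueError("interdigitated or degenerate profile: fewer than two separated head-group peaks")
    order = np.argsort(props["peak_heights"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    z1 = _refine_peak(z, rho, p1)
    z2 = _refine_peak(z, rho, p2)
    return float(z2 - z1)


def thickness_from_head_z(upper_z: np.ndarray, lower_z: np.ndarray,
                          bin_width: float = 0.1) -> float:
    """Peak-to-peak thickness from raw head-atom z values (histogram route)."""
    upper_z = np.asarray(upper_z, dtype=float)
    lower_z = np.asarray(lower_z, dtype=float)
    if upper_z.size == 0 or lower_z.size == 0:
        raise ValueError("both leaflets must contribute head atoms")
    zall = np.concatenate([upper_z, lower_z])
    z0 = zall.mean()
    half = max(abs(zall - z0).max(), 1.0) + 5 * bin_width
    n_half = int(np.ceil(half / bin_width))
    edges = z0 + np.arange(-n_half, n_half + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = np.histogram(zall, bins=edges)[0].astype(float)
    fake = ElectronDensityProfile(centers - z0, {"headgroup": rho}, bin_width, 1.0, 1)
    return bilayer_thickness(fake)


def thickness_map(system: MolecularSystem, dialect: LipidDialect,
                  grid: tuple[int, int] = (20, 20),
                  partition: LeafletPartition | None = None,
                  fill_radius_cells: int = 3,
                  coords: np.ndarray | None = None) -> ThicknessResult:
    """Local leaflet-to-leaflet thickness on an (nx, ny) grid over the box.

    Each cell's thickness is the mean head-atom z of the upper leaflet minus the
    lower, for the head atoms projecting into the cell.  Cells with no head atom
    in one leaflet are filled from the nearest populated cell (periodic metric)
    up to ``fill_radius_cells``; cells beyond that stay NaN.  Cells whose column
    contains protein atoms between the leaflet planes are flagged occluded, not
    silently interpolated.
    """
    if system.box is None:
        raise ValueError("system has no box")
    nx, ny = grid
    if partition is None:
        partition = assign_leaflets(system, dialect, coords)
    pos = coords if coords is not None else system.positions
    lx, ly = system.box.lx, system.box.ly

    def cell_of(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor(np.mod(xy[:, 0], lx) / lx * nx).astype(int) % nx
        iy = np.floor(np.mod(xy[:, 1], ly) / ly * ny).astype(int) % ny
        return ix, iy

    surf = {}
    for leaflet in ("upper", "lower"):
        heads = partition.head_indices[partition.labels == leaflet]
        if len(heads) == 0:
            raise ValueError(f"leaflet {leaflet!r} is empty")
        ix, iy = cell_of(pos[heads, :2])
        zsum = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        np.add.at(zsum, (ix, iy), pos[heads, 2])
        np.add.at(cnt, (ix, iy), 1)
        mean = np.full((nx, ny), np.nan)
        mask = cnt > 0
        mean[mask] = zsum[mask] / cnt[mask]
        surf[leaflet] = _fill_nearest(mean, fill_radius_cells)

    tmap = surf["upper"][0] - surf["lower"][0]
    filled = surf["upper"][1] | surf["lower"][1]

    occluded = np.zeros((nx, ny), dtype=bool)
    prot_idx = system.indices_by_tag("protein")
    if len(prot_idx):
        z_up = np.nanmean(surf["upper"][0])
        z_lo = np.nanmean(surf["lower"][0])
        zp = pos[prot_idx, 2]
        inside = (zp > z_lo) & (zp < z_up)
        if np.any(inside):
            ix, iy = cell_of(pos[prot_idx[inside], :2])
            occluded[ix, iy] = True
    return ThicknessResult(None, tmap, occluded, filled)


def _fill_nearest(grid_vals: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN cells from the nearest populated cell under periodic wrap."""
    nx, ny = grid_vals.shape
    out = grid_vals.copy()
    filled = np.zeros_like(grid_vals, dtype=bool)
    missing = np.argwhere(np.isnan(grid_vals))
    if len(missing) == 0:
        return out, filled
    pop = np.argwhere(~np.isnan(grid_vals))
    if len(pop) == 0:
        raise ValueError("thickness map has no populated cells")
    for mx, my in missing:
        dx = np.abs(pop[:, 0] - mx)
        dx = np.minimum(dx, nx - dx)
        dy = np.abs(pop[:, 1] - my)
        dy = np.minimum(dy, ny - dy)
        d2 = dx**2 + dy**2
        j = int(np.argmin(d2))
        if d2[j] <= radius**2:
            out[mx, my] = grid_vals[pop[j, 0], pop[j, 1]]
            filled[mx, my] = True
    return out, filled
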