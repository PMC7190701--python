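"""Synthetic protein–membrane fixtures with exact ground truth.

Every analysis stage in this package is validated against systems built here:
a two-leaflet phosphatidylcholine-like bilayer with prescribed area per lipid,
head-plane separation and acyl-chain order, and a toy anchored protein (ideal
poly-alanine I/C/F/TM helices, a globular atom cloud and a planar four-nitrogen
"heme") posed at prescribed orientation angles and insertion depth.  The
generators record the exact construction values in a
:class:`SyntheticGroundTruth`, so recovery tests never re-derive truth from the
fixture geometry.

Toy lipids are geometric models, not chemically valid phospholipids: only the
atom names and elements the analyses rely on are guaranteed.  The two leaflets
are exact mirror images in z (jitter included), which pins the bilayer centre of
mass to z = 0 to floating-point precision — the property that makes insertion
depth exactly recoverable.  Each acyl chain carries two hydrogens per carbon at
right angles about the chain axis, which makes the per-carbon order parameter an
exact closed form of the chain tilt t: S_CD = (3 sin²t − 2)/4.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .elements import masses_of
from .io_structures import (Box, Frame, LipidDialect, MolecularSystem,
                            Trajectory, group_molecules)
from .orientation import OrientationSpec

__all__ = [
    "SyntheticGroundTruth", "Pose", "toy_dialect", "lipid14_popc_dialect",
    "build_bilayer", "build_toy_protein", "build_membrane_protein_system",
    "generate_trajectory", "chain_tilt_for_scd", "scd_for_chain_tilt",
]

# study conditions emulated by default: a CYP 2C9-like system in a fluid
# phosphatidylcholine bilayer (APL 66.1 Å², head-plane separation 37.1 Å,
# plateau |S_CD| ≈ 0.2)
DEFAULT_APL = 66.1
DEFAULT_SEPARATION = 37.1
DEFAULT_CHAIN_TILT = 39.2  # degrees; gives |S_CD| ≈ 0.200
DEFAULT_POSE = (74.8, 119.9, 11.9, 43.2, 45.5)  # (alpha, beta, gamma, heme_tilt, depth)


@dataclass
class Pose:
    """Target orientation of the toy protein: angles in degrees, depth in Å."""

    alpha: float
    beta: float
    gamma_tm: float
    heme_tilt: float
    depth: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticGroundTruth:
    """The exact values a fixture was built with — the recovery-test contract."""

    rng_seed: int
    apl: float | None = None
    head_plane_separation: float | None = None
    chain_order_target: dict | None = None  # chain -> per-carbon S_CD (signed)
    pose: dict | None = None
    fluctuation_sigma: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        Path(path).write_text(json.dumps(_clean(dataclasses.asdict(self)), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def scd_for_chain_tilt(tilt_deg: float) -> float:
    """Exact S_CD of a generated chain tilted ``t`` from the normal: (3 sin²t − 2)/4."""
    s = np.sin(np.radians(tilt_deg))
    return float((3 * s * s - 2) / 4)


def chain_tilt_for_scd(abs_scd: float) -> float:
    """Inverse of :func:`scd_for_chain_tilt` for the usual S_CD < 0 branch."""
    if not 0 <= abs_scd <= 0.5:
        raise ValueError("attainable |S_CD| for perpendicular C–H pairs is [0, 0.5]")
    return float(np.degrees(np.arcsin(np.sqrt((2 - 4 * abs_scd) / 3))))


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

def toy_dialect(n_carbons: int = 8) -> LipidDialect:
    """Dialect of the generated single-residue toy lipid (resname LIP)."""
    chains = {}
    for c, prefix in (("sn1", "C1"), ("sn2", "C2")):
        chains[c] = [(f"{prefix}{j}", [f"H{prefix[1]}{j}A", f"H{prefix[1]}{j}B"])
                     for j in range(1, n_carbons + 1)]
    return LipidDialect(
        mode="single-residue",
        residue_templates=[("LIP",)],
        head_reference_atom="P",
        chain_definitions=chains,
    )


def lipid14_popc_dialect() -> LipidDialect:
    """AMBER LIPID14-style split-residue POPC: PC head + PA and OL tails.

    Carbon/hydrogen naming follows the LIPID14 convention (acyl carbons C1k with
    hydrogens HkR/HkS; the oleoyl double-bond carbons carry single H91/H101).
    """
    pa = [(f"C1{k}", [f"H{k}R", f"H{k}S"]) for k in range(2, 16 + 1)]
    ol = []
    for k in range(2, 18 + 1):
        if k == 9:
            ol.append((f"C1{k}", ["H91"]))
        elif k == 10:
            ol.append((f"C1{k}", ["H101"]))
        else:
            ol.append((f"C1{k}", [f"H{k}R", f"H{k}S"]))
    return LipidDialect(
        mode="split-residue",
        residue_templates=[("PC", "PA", "OL")],
        head_reference_atom="P31",
        chain_definitions={"sn1": pa, "sn2": ol},
    )


# ---------------------------------------------------------------------------
# small geometry helpers
# ---------------------------------------------------------------------------

def _rot_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def _rot_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit(a) onto unit(b)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rot_about(perp, np.pi)
    return _rot_about(v / np.linalg.norm(v), np.arccos(np.clip(c, -1, 1)))


class _Fragment:
    """Mutable atom list used while assembling fixtures."""

    def __init__(self):
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.chains: list[str] = []
        self.elements: list[str] = []
        self.positions: list[np.ndarray] = []

    def add(self, name: str, resname: str, resid: int, chain: str, element: str,
            pos: np.ndarray) -> None:
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.chains.append(chain)
        self.elements.append(element)
        self.positions.append(np.asarray(pos, dtype=float))

    def extend(self, other: "_Fragment") -> None:
        self.names += other.names
        self.resnames += other.resnames
        self.resids += other.resids
        self.chains += other.chains
        self.elements += other.elements
        self.positions += other.positions

    @property
    def coords(self) -> np.ndarray:
        return np.array(self.positions) if self.positions else np.empty((0, 3))

    def set_coords(self, coords: np.ndarray) -> None:
        self.positions = [c for c in np.asarray(coords, dtype=float)]

    def rotate(self, r: np.ndarray) -> None:
        self.set_coords(self.coords @ r.T)

    def translate(self, t: np.ndarray) -> None:
        self.set_coords(self.coords + np.asarray(t, dtype=float))

    def mass_com(self, mask: np.ndarray | None = None) -> np.ndarray:
        m = masses_of(np.array(self.elements, dtype=object))
        c = self.coords
        if mask is not None:
            m, c = m[mask], c[mask]
        return (c * m[:, None]).sum(axis=0) / m.sum()

    def to_system(self, box: Box | None) -> MolecularSystem:
        n = len(self.names)
        return MolecularSystem(
            serials=np.arange(1, n + 1),
            names=np.array(self.names, dtype=object),
            resnames=np.array(self.resnames, dtype=object),
            resids=np.array(self.resids, dtype=int),
            chains=np.array(self.chains, dtype=object),
            segids=np.array([""] * n, dtype=object),
            elements=np.array(self.elements, dtype=object),
            positions=self.coords,
            box=box,
        )


def _ideal_helix(resid_start: int, n_res: int, chain: str = "A") -> _Fragment:
    """Ideal poly-alanine backbone helix along +z (3.6 residues/turn, 1.5 Å rise)."""
    frag = _Fragment()
    twist = np.radians(100.0)
    for i in range(n_res):
        phi = i * twist
        z = 1.5 * i
        resid = resid_start + i
        frag.add("N", "ALA", resid, chain, "N",
                 [1.6 * np.cos(phi - 0.5), 1.6 * np.sin(phi - 0.5), z - 0.9])
        frag.add("CA", "ALA", resid, chain, "C",
                 [2.3 * np.cos(phi), 2.3 * np.sin(phi), z])
        frag.add("C", "ALA", resid, chain, "C",
                 [2.0 * np.cos(phi + 0.4), 2.0 * np.sin(phi + 0.4), z + 0.7])
        frag.add("O", "ALA", resid, chain, "O",
                 [2.9 * np.cos(phi + 0.5), 2.9 * np.sin(phi + 0.5), z + 1.0])
    com = frag.mass_com()
    frag.translate(-com)
    return frag


def _fragment_helix_vector(frag: _Fragment, lo: int, hi: int,
                           backbone=("N", "CA", "C", "O")) -> np.ndarray:
    resids = np.array(frag.resids)
    names = np.array(frag.names, dtype=object)
    bb = np.isin(names, backbone)
    first = bb & (resids >= lo) & (resids <= lo + 3)
    last = bb & (resids >= hi - 3) & (resids <= hi)
    return frag.mass_com(last) - frag.mass_com(first)


# ---------------------------------------------------------------------------
# bilayer builder
# ---------------------------------------------------------------------------

def build_bilayer(
    nx: int = 8, ny: int = 8,
    apl: float = DEFAULT_APL,
    separation: float = DEFAULT_SEPARATION,
    chain_tilt_deg: float | str = DEFAULT_CHAIN_TILT,
    n_carbons: int = 8,
    jitter_xy: float = 0.0,
    undulation_amplitude: float = 0.0,
    undulation_periods: int = 1,
    with_water: bool = False,
    seed: int = 0,
    lz: float | None = None,
) -> tuple[MolecularSystem, SyntheticGroundTruth]:
    """Build a mirror-symmetric two-leaflet toy bilayer.

    Lipids sit on an nx×ny jittered lattice per leaflet with cell area ``apl``;
    each lipid has a phosphorus head atom on the leaflet plane (±separation/2)
    and two model acyl chains whose carbons each carry two perpendicular
    hydrogens.  ``chain_tilt_deg`` is either a fixed tilt from the normal
    (chain azimuths drawn from the seeded RNG; the per-carbon S_CD is then the
    exact closed form (3 sin²t − 2)/4) or ``"isotropic"`` for random chain
    directions on the lower hemisphere.  The lower leaflet is the exact mirror
    image of the upper in z, so the bilayer CoM z is exactly 0.  Optional
    sinusoidal undulation (upper leaflet only, an integer number of periods
    along x) imposes a known local-thickness modulation.
    """
    if nx * ny < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    a = float(np.sqrt(apl))
    lx_box, ly_box = nx * a, ny * a
    chain_len = 1.0 + 1.27 * (n_carbons - 1) + 1.2
    if separation <= 2 * 1.0 or separation / 2 <= 0:
        raise ValueError(f"head-plane separation {separation} Å is geometrically impossible")
    if chain_tilt_deg != "isotropic" and chain_len * np.cos(np.radians(float(chain_tilt_deg))) > separation:
        raise ValueError(
            f"chains of {n_carbons} carbons at tilt {chain_tilt_deg}° would cross the opposite head plane"
        )
    if lz is None:
        lz = separation + 30.0
    rng = np.random.default_rng(seed)
    isotropic = chain_tilt_deg == "isotropic"
    tilt = None if isotropic else np.radians(float(chain_tilt_deg))

    frag = _Fragment()
    resid = 1000
    z_head = separation / 2.0
    for i in range(nx):
        for j in range(ny):
            x0 = (i + 0.5) * a
            y0 = (j + 0.5) * a
            if jitter_xy > 0:
                x0 += rng.uniform(-jitter_xy, jitter_xy)
                y0 += rng.uniform(-jitter_xy, jitter_xy)
            dz = 0.0
            if undulation_amplitude:
                dz = undulation_amplitude * np.sin(
                    2 * np.pi * undulation_periods * (i + 0.5) / nx)
            upper = _toy_lipid(rng, resid, x0, y0, z_head + dz, n_carbons,
                               tilt, isotropic, leaflet_sign=+1)
            # exact mirror of the *unperturbed* partner keeps CoM z pinned at 0
            lower = _toy_lipid(rng, resid + 1, x0, y0, z_head, n_carbons,
                               tilt, isotropic, leaflet_sign=-1,
                               mirror_of=upper if not undulation_amplitude else None)
            frag.extend(upper)
            frag.extend(lower)
            resid += 2
    n_lipids = 2 * nx * ny

    if with_water:
        _add_water_slabs(frag, lx_box, ly_box, z_head + chain_len * 0.0 + 4.0, lz / 2.0)

    box = Box(lx_box, ly_box, lz)
    system = group_molecules(frag.to_system(box), toy_dialect(n_carbons))
    scd = None if isotropic else scd_for_chain_tilt(float(chain_tilt_deg))
    truth = SyntheticGroundTruth(
        rng_seed=seed,
        apl=apl,
        head_plane_separation=separation,
        chain_order_target=None if isotropic else {
            c: [scd] * n_carbons for c in ("sn1", "sn2")},
        extras={
            "n_lipids": n_lipids,
            "box": [lx_box, ly_box, lz],
            "chain_tilt_deg": None if isotropic else float(chain_tilt_deg),
            "membrane_com_z": 0.0,
            "undulation_amplitude": undulation_amplitude,
            "undulation_periods": undulation_periods,
            "n_carbons": n_carbons,
        },
    )
    return system, truth


def _toy_lipid(rng, resid: int, x0: float, y0: float, z_head: float,
               n_carbons: int, tilt: float | None, isotropic: bool,
               leaflet_sign: int, mirror_of: _Fragment | None = None) -> _Fragment:
    frag = _Fragment()
    if mirror_of is not None:
        for name, rn, _rid, ch, el, pos in zip(
                mirror_of.names, mirror_of.resnames, mirror_of.resids,
                mirror_of.chains, mirror_of.elements, mirror_of.positions):
            frag.add(name, rn, resid, ch, el, [pos[0], pos[1], -pos[2]])
        return frag
    frag.add("P", "LIP", resid, "L", "P", [x0, y0, leaflet_sign * z_head])
    for chain_no, x_off in ((1, -0.75), (2, 0.75)):
        if isotropic:
            axis = np.array([0.0, 0.0, -leaflet_sign * 1.0])
        else:
            phi = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.sin(tilt) * np.cos(phi),
                             np.sin(tilt) * np.sin(phi),
                             -leaflet_sign * np.cos(tilt)])
        # orthonormal pair perpendicular to the chain axis; for a fixed tilt t the
        # two-H average of cos²θ is exactly sin²t/2 regardless of the pair's phase
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis[2]) > 0.999999:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(ref, axis)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        origin = np.array([x0 + x_off, y0, leaflet_sign * z_head])
        for k in range(1, n_carbons + 1):
            c = origin + axis * (1.0 + 1.27 * (k - 1))
            if isotropic:
                # per-carbon random orthonormal C–H pair: each H direction is
                # marginally uniform on the sphere
                u1 = rng.normal(size=3)
                u1 /= np.linalg.norm(u1)
                v = rng.normal(size=3)
                u2 = v - np.dot(v, u1) * u1
                u2 /= np.linalg.norm(u2)
            else:
                u1, u2 = e1, e2
            frag.add(f"C{chain_no}{k}", "LIP", resid, "L", "C", c)
            frag.add(f"H{chain_no}{k}A", "LIP", resid, "L", "H", c + 1.09 * u1)
            frag.add(f"H{chain_no}{k}B", "LIP", resid, "L", "H", c + 1.09 * u2)
    return frag


def _add_water_slabs(frag: _Fragment, lx: float, ly: float,
                     z_from: float, z_to: float) -> None:
    """Sparse mirror-symmetric O-only water slabs outside the membrane."""
    if z_to <= z_from + 1.0:
        return
    spacing = 5.0
    resid = 50_000
    xs = np.arange(spacing / 2, lx, spacing)
    ys = np.arange(spacing / 2, ly, spacing)
    zs = np.arange(z_from + 1.0, z_to - 0.5, spacing * 0.7)
    for z in zs:
        for x in xs:
            for y in ys:
                frag.add("O", "WAT", resid, "W", "O", [x, y, z])
                frag.add("O", "WAT", resid + 1, "W", "O", [x, y, -z])
                resid += 2


# ---------------------------------------------------------------------------
# toy protein builder
# ---------------------------------------------------------------------------

TOY_RESID_RANGES = {
    "tm_helix": (1, 25),  # 25 residues ≈ 36 Å rise: spans the default bilayer
    "i_helix": (101, 112),
    "c_helix": (201, 212),
    "f_helix": (301, 312),
    "globular_domain": (100, 510),
}


def toy_orientation_spec() -> OrientationSpec:
    return OrientationSpec(
        i_helix=TOY_RESID_RANGES["i_helix"],
        c_helix=TOY_RESID_RANGES["c_helix"],
        f_helix=TOY_RESID_RANGES["f_helix"],
        tm_helix=TOY_RESID_RANGES["tm_helix"],
        globular_domain=TOY_RESID_RANGES["globular_domain"],
        heme_nitrogens="resname HEM and name NA NB NC ND",
        membrane_selection="moltag lipid",
    )


def build_toy_protein(pose: Pose | tuple = DEFAULT_POSE) -> tuple[_Fragment, SyntheticGroundTruth]:
    """Assemble the toy protein fragment posed at the requested parameters.

    Each helix is an ideal poly-alanine fragment rotated so that its
    first-4→last-4 CoM axis vector points at exactly the requested angle from
    the membrane normal; the heme is a flat 4-nitrogen plaquette rotated to the
    requested plane tilt; finally the globular portion (I/C/F helices, atom-cloud
    body and heme; residues 100–510) is translated so its mass-weighted CoM sits
    at z = depth, with the membrane centre of mass assumed at z = 0.  The five
    orientation parameters of the result equal the pose exactly by construction.
    """
    if not isinstance(pose, Pose):
        pose = Pose(*pose)
    for label, ang in (("alpha", pose.alpha), ("beta", pose.beta)):
        if not 0 <= ang <= 180:
            raise ValueError(f"{label} must lie in [0, 180] degrees")
    if not 0 <= pose.gamma_tm <= 180:
        raise ValueError("gamma_tm must lie in [0, 180] degrees")
    if not 0 <= pose.heme_tilt <= 90:
        raise ValueError("heme_tilt must lie in [0, 90] degrees")
    if pose.depth < 0:
        raise ValueError("depth must be non-negative")

    def unit_polar(theta_deg: float) -> np.ndarray:
        t = np.radians(theta_deg)
        return np.array([np.sin(t), 0.0, np.cos(t)])

    # I helix → alpha
    i_helix = _ideal_helix(TOY_RESID_RANGES["i_helix"][0], 12)
    v1 = _fragment_helix_vector(i_helix, *TOY_RESID_RANGES["i_helix"])
    i_helix.rotate(_rot_from_to(v1, unit_polar(pose.alpha)))

    # C and F helices as a rigid pair → beta
    c_helix = _ideal_helix(TOY_RESID_RANGES["c_helix"][0], 12)
    f_helix = _ideal_helix(TOY_RESID_RANGES["f_helix"][0], 12)
    f_helix.translate([9.0, 0.0, 5.0])
    pair = _Fragment()
    pair.extend(c_helix)
    pair.extend(f_helix)
    resids = np.array(pair.resids)
    names = np.array(pair.names, dtype=object)
    bb = np.isin(names, ("N", "CA", "C", "O"))
    c_lo = TOY_RESID_RANGES["c_helix"][0]
    f_hi = TOY_RESID_RANGES["f_helix"][1]
    v2 = (pair.mass_com(bb & (resids >= f_hi - 3) & (resids <= f_hi))
          - pair.mass_com(bb & (resids >= c_lo) & (resids <= c_lo + 3)))
    pair.rotate(_rot_from_to(v2, unit_polar(pose.beta)))

    # TM helix → gamma
    n_tm = TOY_RESID_RANGES["tm_helix"][1] - TOY_RESID_RANGES["tm_helix"][0] + 1
    tm = _ideal_helix(TOY_RESID_RANGES["tm_helix"][0], n_tm)
    v3 = _fragment_helix_vector(tm, *TOY_RESID_RANGES["tm_helix"])
    tm.rotate(_rot_from_to(v3, unit_polar(pose.gamma_tm)))

    # heme plaquette → heme tilt (plane normal at 90° − tilt from z)
    heme = _Fragment()
    heme.add("FE", "HEM", 500, "A", "FE", [0.0, 0.0, 0.0])
    for name, (dx, dy) in (("NA", (2.0, 0.0)), ("NB", (0.0, 2.0)),
                           ("NC", (-2.0, 0.0)), ("ND", (0.0, -2.0))):
        heme.add(name, "HEM", 500, "A", "N", [dx, dy, 0.0])
    heme.rotate(_rot_from_to(np.array([0.0, 0.0, 1.0]),
                             unit_polar(90.0 - pose.heme_tilt)))

    # globular body: a small atom cloud giving the domain bulk
    body = _Fragment()
    rid = 400
    for x in (-4.5, -1.5, 1.5, 4.5):
        for y in (-4.5, -1.5, 1.5, 4.5):
            for z in (-4.5, -1.5, 1.5, 4.5):
                if x * x + y * y + z * z <= 36.0:
                    body.add("CA", "ALA", rid, "A", "C", [x, y, z])
                    rid += 1

    # anchor the globular fragments around the origin, then set the CoM depth
    i_helix.translate([10.0, 0.0, 0.0])
    pair.translate([-10.0, 2.0, 0.0])
    heme.translate([0.0, -6.0, 0.0])
    globular = _Fragment()
    for part in (i_helix, pair, body, heme):
        globular.extend(part)
    com = globular.mass_com()
    globular.translate([-com[0], -com[1], pose.depth - com[2]])

    tm.translate([0.0, 0.0, 0.0])  # TM helix spans the membrane mid-plane

    protein = _Fragment()
    protein.extend(tm)
    protein.extend(globular)
    truth = SyntheticGroundTruth(rng_seed=0, pose=pose.as_dict(),
                                 extras={"resid_ranges": dict(TOY_RESID_RANGES)})
    return protein, truth


def build_membrane_protein_system(
    pose: Pose | tuple = DEFAULT_POSE,
    nx: int = 8, ny: int = 8,
    apl: float = DEFAULT_APL,
    separation: float = DEFAULT_SEPARATION,
    chain_tilt_deg: float | str = DEFAULT_CHAIN_TILT,
    n_carbons: int = 8,
    jitter_xy: float = 0.0,
    with_water: bool = False,
    carve_radius: float = 6.0,
    seed: int = 0,
) -> tuple[MolecularSystem, OrientationSpec, LipidDialect, SyntheticGroundTruth]:
    """Toy protein embedded in a mirror-symmetric bilayer, pose exact by construction.

    The protein is centred on the box in x/y with its TM helix crossing the
    membrane mid-plane.  Lipids whose head atom lies within ``carve_radius`` of
    the TM axis are removed *pairwise* (upper lipid and its mirror partner), so
    the bilayer CoM stays at z = 0 and the recorded insertion depth remains
    exact.
    """
    bilayer, btruth = build_bilayer(nx, ny, apl, separation, chain_tilt_deg,
                                    n_carbons, jitter_xy, with_water=with_water,
                                    seed=seed)
    assert bilayer.box is not None
    lx, ly = bilayer.box.lx, bilayer.box.ly
    protein, ptruth = build_toy_protein(pose)
    protein.translate([lx / 2.0, ly / 2.0, 0.0])

    # carve lipid pairs under the TM footprint (heads within carve_radius in xy)
    keep = np.ones(bilayer.n_atoms, dtype=bool)
    n_carved = 0
    dialect = toy_dialect(n_carbons)
    lipid_mols = [m for m in bilayer.molecules if m.tag == "lipid"]
    for pair_start in range(0, len(lipid_mols), 2):
        up = lipid_mols[pair_start]
        head = up.indices[bilayer.names[up.indices] == "P"][0]
        dx = bilayer.positions[head, 0] - lx / 2.0
        dy = bilayer.positions[head, 1] - ly / 2.0
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        if dx * dx + dy * dy < carve_radius**2:
            keep[up.indices] = False
            keep[lipid_mols[pair_start + 1].indices] = False
            n_carved += 2

    merged = _Fragment()
    prot_z = protein.coords[:, 2]
    z_extent = max(abs(prot_z.min()), abs(prot_z.max())) + 12.0
    lz = max(bilayer.box.lz, 2.0 * z_extent)
    merged.extend(protein)
    kept = np.flatnonzero(keep)
    for i in kept:
        merged.add(str(bilayer.names[i]), str(bilayer.resnames[i]),
                   int(bilayer.resids[i]), str(bilayer.chains[i]),
                   str(bilayer.elements[i]), bilayer.positions[i])
    system = group_molecules(merged.to_system(Box(lx, ly, lz)), dialect)

    n_lipids = int(btruth.extras["n_lipids"]) - n_carved
    truth = SyntheticGroundTruth(
        rng_seed=seed,
        apl=apl,
        head_plane_separation=separation,
        chain_order_target=btruth.chain_order_target,
        pose=ptruth.pose,
        extras={
            **btruth.extras,
            "n_lipids": n_lipids,
            "n_carved": n_carved,
            "box": [lx, ly, lz],
        },
    )
    return system, toy_orientation_spec(), dialect, truth


# ---------------------------------------------------------------------------
# trajectory generator
# ---------------------------------------------------------------------------

def generate_trajectory(system: MolecularSystem, n_frames: int, sigma: float,
                        rigid_motion=None, seed: int = 0,
                        dt_ns: float = 1.0) -> Trajectory:
    """Frames = base coordinates + isotropic per-coordinate Gaussian noise.

    ``rigid_motion`` may be a callable ``k -> (R, t)`` composed with the base
    coordinates before the noise is added (for testing superposition
    invariance).  Bit-reproducible for a fixed seed.
    """
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    if sigma < 0:
        raise ValueError("fluctuation sigma must be non-negative")
    if system.box is None:
        raise ValueError("system needs a box to generate trajectory frames")
    rng = np.random.default_rng(seed)
    base = system.positions
    frames = []
    for k in range(n_frames):
        coords = base
        if rigid_motion is not None:
            r, t = rigid_motion(k)
            coords = coords @ np.asarray(r, dtype=float).T + np.asarray(t, dtype=float)
        if sigma > 0:
            coords = coords + rng.normal(scale=sigma, size=base.shape)
        elif rigid_motion is None:
            coords = coords.copy()
        frames.append(Frame(np.asarray(coords), system.box, k * dt_ns))
    return Trajectory(system, frames)
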