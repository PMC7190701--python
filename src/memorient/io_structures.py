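"""Coordinate I/O and molecule bookkeeping.

This module owns the on-disk interface of the package: PDB reading/writing
(ATOM/HETATM/CRYST1/MODEL/ENDMDL), the in-memory :class:`MolecularSystem` container
that every analysis stage consumes, and the molecule-grouping step that turns raw
residue records into protein / lipid / water / ion molecules.

Lipid residue layout differs between force-field dialects: some store one
phospholipid as a single residue, others (AMBER LIPID14-style) split it into
consecutive head/tail/tail residues.  :class:`LipidDialect` declares the layout and
:func:`group_molecules` merges the records accordingly.

Only orthorhombic periodic boxes are supported; a CRYST1 record with non-90° angles
is a hard error rather than a silent approximation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .elements import infer_element, masses_of, atomic_numbers_of

__all__ = [
    "Box", "AtomRecord", "Molecule", "MolecularSystem", "Frame", "Trajectory",
    "LipidDialect", "PDBFormatError", "read_pdb", "read_trajectory", "write_pdb",
    "group_molecules",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "CYX", "CYM", "GLN", "GLU", "GLY", "HIS",
    "HID", "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL", "ASH", "GLH", "LYN",
}
WATER_RESIDUES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "T3P", "TP3"}
COFACTOR_RESIDUES = {"HEM", "HEC", "HEA"}

from .elements import ION_RESIDUES  # noqa: E402  (re-exported convenience)


class PDBFormatError(ValueError):
    """Raised for unparseable or unsupported PDB content."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box, edge lengths in Å."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(f"box lengths must be positive, got {(self.lx, self.ly, self.lz)}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz], dtype=float)

    @property
    def area_xy(self) -> float:
        return self.lx * self.ly


@dataclass(frozen=True)
class AtomRecord:
    """One atom, as read from a coordinate file."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str
    position: np.ndarray
    segment_tag: str = ""


@dataclass
class Molecule:
    """A group of atom indices with a molecule-level tag."""

    tag: str  # protein | lipid | water | ion | cofactor | ungrouped
    indices: np.ndarray


class MolecularSystem:
    """Atoms + box + molecule partition; the unit every analysis stage consumes.

    Atom attributes are stored column-wise in numpy arrays so selections and
    geometric reductions vectorise.  ``molecules`` is always a partition of the
    atom indices (disjoint, covering); freshly read systems carry one singleton
    group per residue, tagged ``ungrouped``, until :func:`group_molecules` runs.
    """

    def __init__(
        self,
        serials: np.ndarray,
        names: np.ndarray,
        resnames: np.ndarray,
        resids: np.ndarray,
        chains: np.ndarray,
        segids: np.ndarray,
        elements: np.ndarray,
        positions: np.ndarray,
        box: Box | None,
        molecules: list[Molecule] | None = None,
    ):
        n = len(names)
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n, 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(positions)):
            raise ValueError("non-finite coordinates")
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.segids = np.asarray(segids, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.positions = positions
        self.box = box
        if molecules is None:
            molecules = [
                Molecule("ungrouped", idx) for idx in _residue_index_runs(self.resids, self.resnames, self.chains)
            ]
        self.molecules = molecules
        self._validate_partition()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[AtomRecord], box: Box | None) -> "MolecularSystem":
        return cls(
            serials=np.array([r.serial for r in records]),
            names=np.array([r.name for r in records], dtype=object),
            resnames=np.array([r.residue_name for r in records], dtype=object),
            resids=np.array([r.residue_id for r in records]),
            chains=np.array([r.chain for r in records], dtype=object),
            segids=np.array([r.segment_tag for r in records], dtype=object),
            elements=np.array([r.element for r in records], dtype=object),
            positions=np.array([r.position for r in records], dtype=float),
            box=box,
        )

    # -- basics ---------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]), name=str(self.names[i]),
            residue_name=str(self.resnames[i]), residue_id=int(self.resids[i]),
            chain=str(self.chains[i]), element=str(self.elements[i]),
            position=self.positions[i].copy(), segment_tag=str(self.segids[i]),
        )

    def masses(self) -> np.ndarray:
        return masses_of(self.elements)

    def atomic_numbers(self) -> np.ndarray:
        return atomic_numbers_of(self.elements)

    def moltags(self) -> np.ndarray:
        """Per-atom molecule tag array."""
        tags = np.empty(self.n_atoms, dtype=object)
        tags[:] = ""
        for mol in self.molecules:
            tags[mol.indices] = mol.tag
        return tags

    def molecules_by_tag(self, tag: str) -> list[Molecule]:
        return [m for m in self.molecules if m.tag == tag]

    def indices_by_tag(self, tag: str) -> np.ndarray:
        mols = self.molecules_by_tag(tag)
        if not mols:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([m.indices for m in mols]))

    def with_positions(self, positions: np.ndarray, box: Box | None = None) -> "MolecularSystem":
        """Shallow copy sharing topology arrays but with new coordinates."""
        new = MolecularSystem.__new__(MolecularSystem)
        new.serials = self.serials
        new.names = self.names
        new.resnames = self.resnames
        new.resids = self.resids
        new.chains = self.chains
        new.segids = self.segids
        new.elements = self.elements
        positions = np.asarray(positions, dtype=float)
        if positions.shape != self.positions.shape:
            raise ValueError("coordinate shape mismatch")
        new.positions = positions
        new.box = box if box is not None else self.box
        new.molecules = self.molecules
        return new

    def residue_runs(self) -> list[tuple[int, int, int, str, str]]:
        """Contiguous residue blocks as (start, stop, resid, resname, chain)."""
        runs = []
        for idx in _residue_index_runs(self.resids, self.resnames, self.chains):
            i = int(idx[0])
            runs.append((i, int(idx[-1]) + 1, int(self.resids[i]), str(self.resnames[i]), str(self.chains[i])))
        return runs

    def _validate_partition(self) -> None:
        seen = np.zeros(self.n_atoms, dtype=int)
        for mol in self.molecules:
            seen[mol.indices] += 1
        if self.n_atoms and not np.all(seen == 1):
            bad = np.flatnonzero(seen != 1)[:5]
            raise ValueError(f"molecule groups are not a partition (first bad atoms: {bad.tolist()})")


def _residue_index_runs(resids: np.ndarray, resnames: np.ndarray, chains: np.ndarray) -> list[np.ndarray]:
    n = len(resids)
    if n == 0:
        return []
    key_change = np.flatnonzero(
        (resids[1:] != resids[:-1])
        | (resnames[1:] != resnames[:-1])
        | (chains[1:] != chains[:-1])
    ) + 1
    starts = np.concatenate([[0], key_change])
    stops = np.concatenate([key_change, [n]])
    return [np.arange(a, b) for a, b in zip(starts, stops)]


@dataclass
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3), Å
    box: Box
    time: float  # ns


@dataclass
class Trajectory:
    """Multi-frame coordinate set over a fixed topology (frame 0's system)."""

    topology: MolecularSystem
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coordinates.shape != (n, 3):
                raise ValueError(f"frame {k} has {fr.coordinates.shape[0]} atoms, topology has {n}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def system_at(self, k: int) -> MolecularSystem:
        fr = self.frames[k]
        return self.topology.with_positions(fr.coordinates, fr.box)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class LipidDialect:
    """Declares how lipid molecules are laid out in residue records.

    ``single-residue`` dialects store one lipid per residue; ``split-residue``
    dialects (AMBER LIPID14-style) store one lipid as a fixed sequence of
    consecutive residues, e.g. ``("PC", "PA", "OL")`` for POPC.
    ``chain_definitions`` maps acyl-chain labels (sn1/sn2) to the ordered carbon
    names, each with its bonded hydrogen names, counted from the carbonyl end.
    """

    mode: str  # "single-residue" | "split-residue"
    residue_templates: list[tuple[str, ...]]
    head_reference_atom: str = "P"
    chain_definitions: dict[str, list[tuple[str, list[str]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("single-residue", "split-residue"):
            raise ValueError(f"unknown dialect mode {self.mode!r}")
        self.residue_templates = [tuple(t) for t in self.residue_templates]
        for t in self.residue_templates:
            if len(t) < 1:
                raise ValueError("residue template must name at least one residue")
        for chain, carbons in self.chain_definitions.items():
            if not carbons:
                raise ValueError(f"chain {chain!r} has an empty carbon list")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_cryst1(line: str, lineno: int) -> Box:
    try:
        a = float(line[6:15])
        b = float(line[15:24])
        c = float(line[24:33])
        alpha = float(line[33:40])
        beta = float(line[40:47])
        gamma = float(line[47:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: malformed CRYST1 record") from exc
    if not (abs(alpha - 90) < 1e-3 and abs(beta - 90) < 1e-3 and abs(gamma - 90) < 1e-3):
        raise PDBFormatError(
            f"line {lineno}: non-orthorhombic box (angles {alpha}, {beta}, {gamma}); only rectangular boxes are supported"
        )
    return Box(a, b, c)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno  # serial overflow markers like ***** — fall back
    name = line[12:16].strip()
    resname = line[17:21].strip()
    chain = line[21:22].strip()
    try:
        resid = int(line[22:26])
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: malformed residue id field {line[22:26]!r}") from exc
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: malformed coordinate field") from exc
    segid = line[72:76].strip() if len(line) > 72 else ""
    element_field = line[76:78].strip() if len(line) > 76 else ""
    element = infer_element(name, element_field, resname)
    return AtomRecord(serial, name, resname, resid, chain, element,
                      np.array([x, y, z]), segid)


def _parse_models(path: str | Path, box: Box | None):
    """Parse a PDB file into (records-of-model-0, [(coords, box, time|None), ...])."""
    records: list[AtomRecord] = []
    model_coords: list[np.ndarray] = []
    model_boxes: list[Box | None] = []
    model_times: list[float | None] = []
    header_box = box
    cur: list[AtomRecord] = []
    cur_box: Box | None = None
    cur_time: float | None = None
    in_model = False
    saw_model = False

    def flush():
        nonlocal cur, cur_box, cur_time
        if cur:
            if not records:
                records.extend(cur)
            model_coords.append(np.array([r.position for r in cur]))
            model_boxes.append(cur_box)
            model_times.append(cur_time)
        cur = []
        cur_box = None
        cur_time = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                b = _parse_cryst1(line, lineno)
                if in_model:
                    cur_box = b
                else:
                    header_box = b if box is None else box
            elif rec == "MODEL ":
                if in_model:
                    flush()
                in_model = True
                saw_model = True
            elif rec == "ENDMDL":
                flush()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                cur.append(_parse_atom_line(line, lineno))
            elif rec == "REMARK" and "TIME_NS" in line:
                try:
                    cur_time = float(line.split("TIME_NS")[1].split()[0])
                except (ValueError, IndexError):
                    pass
    flush()
    if not model_coords:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    if header_box is None and all(b is None for b in model_boxes):
        raise PDBFormatError(f"{path}: no periodic box (missing CRYST1 and no override supplied)")
    boxes = [b if b is not None else header_box for b in model_boxes]
    if any(b is None for b in boxes):
        raise PDBFormatError(f"{path}: no periodic box for some models")
    n0 = len(records)
    for k, c in enumerate(model_coords):
        if len(c) != n0:
            raise PDBFormatError(f"{path}: model {k + 1} has {len(c)} atoms, model 1 has {n0}")
    return records, model_coords, boxes, model_times, saw_model


def read_pdb(path: str | Path, box: Box | None = None) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem` (first MODEL if several).

    The box comes from the CRYST1 record unless an explicit ``box`` override is
    given; absence of both is an error.  Elements come from the element column
    with atom-name heuristics as fallback.  Molecules are left ungrouped (one
    singleton group per residue) until :func:`group_molecules` is applied.
    """
    records, coords, boxes, _times, _ = _parse_models(path, box)
    return MolecularSystem.from_records(records, boxes[0])


def read_trajectory(path: str | Path, dt_ns: float = 1.0, box: Box | None = None) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Each MODEL may carry its own CRYST1 (fluctuating box); models without one
    inherit the header box.  Frame times come from ``REMARK ... TIME_NS t``
    records when present, else ``frame_index * dt_ns``.
    """
    records, coords, boxes, times, _ = _parse_models(path, box)
    topo = MolecularSystem.from_records(records, boxes[0])
    frames = [
        Frame(c, b, t if t is not None else k * dt_ns)
        for k, (c, b, t) in enumerate(zip(coords, boxes, times))
    ]
    return Trajectory(topo, frames)


def _format_atom_name(name: str, element: str) -> str:
    # standard PDB alignment: 1-letter-element names of <4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_lines(system: MolecularSystem, coords: np.ndarray) -> Iterable[str]:
    for i in range(system.n_atoms):
        rn = str(system.resnames[i])
        rec = "HETATM" if (rn in COFACTOR_RESIDUES or rn in ION_RESIDUES or rn in WATER_RESIDUES) else "ATOM  "
        x, y, z = coords[i]
        yield (
            f"{rec}{int(system.serials[i]) % 100000:5d} "
            f"{_format_atom_name(str(system.names[i]), str(system.elements[i]))}"
            f"{'':1s}{rn:<4.4s}{str(system.chains[i])[:1] or ' ':1s}"
            f"{int(system.resids[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}      "
            f"{str(system.segids[i]):<4.4s}{str(system.elements[i]):>2.2s}\n"
        )


def write_pdb(obj: MolecularSystem | Trajectory, path: str | Path) -> None:
    """Write a system or trajectory as (multi-model) PDB with CRYST1 records."""
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(obj, MolecularSystem):
            if obj.box is not None:
                fh.write(_cryst1_line(obj.box))
            for line in _atom_lines(obj, obj.positions):
                fh.write(line)
            fh.write("END\n")
            return
        traj: Trajectory = obj
        if traj.frames and traj.frames[0].box is not None:
            fh.write(_cryst1_line(traj.frames[0].box))
        for k, fr in enumerate(traj.frames, start=1):
            fh.write(f"MODEL {k:>8d}\n")
            fh.write(f"REMARK   6 TIME_NS {fr.time:.6f}\n")
            fh.write(_cryst1_line(fr.box))
            for line in _atom_lines(traj.topology, fr.coordinates):
                fh.write(line)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _cryst1_line(box: Box) -> str:
    return (f"CRYST1{box.lx:9.3f}{box.ly:9.3f}{box.lz:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")


# ---------------------------------------------------------------------------
# Molecule grouping
# ---------------------------------------------------------------------------

def group_molecules(
    system: MolecularSystem,
    dialect: LipidDialect,
    heme_in_protein: bool = True,
) -> MolecularSystem:
    """Partition atoms into protein / lipid / water / ion / cofactor molecules.

    Consecutive residues matching a dialect template (in file order) merge into
    one lipid molecule.  Standard amino-acid residues sharing a chain id form one
    protein molecule per chain.  Heme-type cofactors join the protein molecule of
    their chain by default (``heme_in_protein=False`` keeps them as separate
    ``cofactor`` molecules).  A residue run that matches a template prefix but
    does not complete it is an error.
    """
    runs = system.residue_runs()
    templates = sorted(dialect.residue_templates, key=len, reverse=True)
    lipid_mols: list[np.ndarray] = []
    protein_parts: dict[str, list[np.ndarray]] = {}
    cofactor_parts: list[tuple[str, np.ndarray]] = []  # (chain, indices)
    water_mols: list[np.ndarray] = []
    ion_mols: list[np.ndarray] = []
    other_mols: list[np.ndarray] = []

    i = 0
    while i < len(runs):
        start, stop, resid, resname, chain = runs[i]
        matched = False
        for tpl in templates:
            if resname != tpl[0]:
                continue
            if i + len(tpl) <= len(runs) and all(runs[i + k][3] == tpl[k] for k in range(len(tpl))):
                idx = np.arange(runs[i][0], runs[i + len(tpl) - 1][1])
                lipid_mols.append(idx)
                i += len(tpl)
                matched = True
                break
            # how far does the file match this template before diverging?
            k = 0
            while i + k < len(runs) and k < len(tpl) and runs[i + k][3] == tpl[k]:
                k += 1
            if k >= 2:
                ids = [str(runs[i + j][2]) for j in range(k)]
                raise ValueError(
                    f"residues {', '.join(ids)} match lipid template {tpl} prefix but do not complete it"
                )
        if matched:
            continue
        idx = np.arange(start, stop)
        if resname in STANDARD_AMINO_ACIDS:
            protein_parts.setdefault(chain, []).append(idx)
        elif resname in WATER_RESIDUES:
            water_mols.append(idx)
        elif resname.upper() in ION_RESIDUES:
            ion_mols.append(idx)
        elif resname in COFACTOR_RESIDUES:
            cofactor_parts.append((chain, idx))
        else:
            other_mols.append(idx)
        i += 1

    molecules: list[Molecule] = []
    protein_chains: dict[str, np.ndarray] = {
        ch: np.concatenate(parts) for ch, parts in protein_parts.items()
    }
    if heme_in_protein and protein_chains:
        for ch, idx in cofactor_parts:
            target = ch if ch in protein_chains else next(iter(protein_chains))
            protein_chains[target] = np.concatenate([protein_chains[target], idx])
        cofactor_parts = []
    for ch in protein_chains:
        molecules.append(Molecule("protein", np.sort(protein_chains[ch])))
    for idx in lipid_mols:
        molecules.append(Molecule("lipid", idx))
    for _, idx in cofactor_parts:
        molecules.append(Molecule("cofactor", idx))
    for idx in water_mols:
        molecules.append(Molecule("water", idx))
    for idx in ion_mols:
        molecules.append(Molecule("ion", idx))
    for idx in other_mols:
        molecules.append(Molecule("cofactor", idx))

    # validate head-reference-atom invariant on lipids
    head = dialect.head_reference_atom
    for mol in molecules:
        if mol.tag != "lipid":
            continue
        n_head = int(np.sum(system.names[mol.indices] == head))
        if n_head != 1:
            rid = int(system.resids[mol.indices[0]])
            raise ValueError(
                f"lipid starting at residue {rid} contains head reference atom "
                f"{head!r} {n_head} times (expected exactly once)"
            )

    return MolecularSystem(
        system.serials, system.names, system.resnames, system.resids,
        system.chains, system.segids, system.elements, system.positions,
        system.box, molecules,
    )
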