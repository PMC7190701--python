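"""Analysis configuration: a YAML file naming inputs, residue ranges and parameters.

Every selection and file referenced by the configuration is resolved against the
topology before any stage runs, so a typo fails fast instead of after minutes of
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_structures import LipidDialect, MolecularSystem
from .orientation import OrientationSpec
from .selection import select

__all__ = ["AnalysisConfig", "load_config", "dialect_from_mapping"]


def dialect_from_mapping(mapping) -> LipidDialect:
    """Build a LipidDialect from a config mapping or a builtin name."""
    from . import synthetic  # local import to avoid a cycle

    if isinstance(mapping, str):
        mapping = {"builtin": mapping}
    builtin = mapping.get("builtin")
    if builtin == "toy":
        return synthetic.toy_dialect(int(mapping.get("n_carbons", 8)))
    if builtin in ("lipid14-popc", "lipid14_popc"):
        return synthetic.lipid14_popc_dialect()
    if builtin is not None:
        raise ValueError(f"unknown builtin dialect {builtin!r}")
    chains = {}
    for chain, carbons in (mapping.get("chains") or {}).items():
        chains[chain] = [(c, list(hs)) for c, hs in carbons]
    return LipidDialect(
        mode=mapping.get("mode", "single-residue"),
        residue_templates=[tuple(t) for t in mapping.get("residue_templates", [])],
        head_reference_atom=mapping.get("head_reference_atom", "P"),
        chain_definitions=chains,
    )


@dataclass
class AnalysisConfig:
    """All knobs of a pipeline run; see ``load_config`` for the YAML layout."""

    trajectory: Path
    orientation: OrientationSpec
    dialect: LipidDialect
    reference: Path | None = None
    dt_ns: float = 1.0
    window_ns: float | None = 50.0
    boundary_cutoff: float = 5.0
    density_bin: float = 0.1
    grid: tuple[int, int] = (20, 20)
    snapshot_stride: int = 1
    seed: int = 0
    out_prefix: str = "run"
    heme_in_protein: bool = True
    protein_slab_halfwidth: float = 10.0
    dynamics_selection: str = "name CA"
    scd_lipids: str = "non-boundary"  # or "all"
    extras: dict = field(default_factory=dict)

    def validate_files(self) -> None:
        if not Path(self.trajectory).exists():
            raise FileNotFoundError(f"trajectory file {self.trajectory} does not exist")
        if self.reference is not None and not Path(self.reference).exists():
            raise FileNotFoundError(f"reference file {self.reference} does not exist")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be ≥ 1")
        if self.scd_lipids not in ("non-boundary", "all"):
            raise ValueError("scd_lipids must be 'non-boundary' or 'all'")

    def validate_on_topology(self, system: MolecularSystem) -> None:
        """Resolve every selection on the (grouped) topology; fail fast."""
        self.orientation.validate_on(system)
        if len(select(system, self.dynamics_selection)) == 0:
            raise ValueError(f"dynamics selection {self.dynamics_selection!r} selects no atoms")
        if not system.molecules_by_tag("lipid"):
            raise ValueError("no lipid molecules after grouping; check the dialect")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    o = raw["orientation"]
    spec = OrientationSpec(
        i_helix=tuple(o["i_helix"]),
        c_helix=tuple(o["c_helix"]),
        f_helix=tuple(o["f_helix"]),
        tm_helix=tuple(o["tm_helix"]),
        globular_domain=tuple(o["globular_domain"]),
        heme_nitrogens=o["heme_nitrogens"],
        backbone_atom_names=tuple(o.get("backbone_atom_names", ("N", "CA", "C", "O"))),
        membrane_selection=o.get("membrane_selection", "moltag lipid"),
    )
    grid = raw.get("grid", [20, 20])
    cfg = AnalysisConfig(
        trajectory=Path(raw["trajectory"]),
        orientation=spec,
        dialect=dialect_from_mapping(raw.get("dialect", {"builtin": "toy"})),
        reference=Path(raw["reference"]) if raw.get("reference") else None,
        dt_ns=float(raw.get("dt_ns", 1.0)),
        window_ns=(None if raw.get("window_ns") in (None, "all")
                   else float(raw.get("window_ns", 50.0))),
        boundary_cutoff=float(raw.get("boundary_cutoff", 5.0)),
        density_bin=float(raw.get("density_bin", 0.1)),
        grid=(int(grid[0]), int(grid[1])),
        snapshot_stride=int(raw.get("snapshot_stride", 1)),
        seed=int(raw.get("seed", 0)),
        out_prefix=str(raw.get("out_prefix", "run")),
        heme_in_protein=bool(raw.get("heme_in_protein", True)),
        protein_slab_halfwidth=float(raw.get("protein_slab_halfwidth", 10.0)),
        dynamics_selection=str(raw.get("dynamics_selection", "name CA")),
        scd_lipids=str(raw.get("scd_lipids", "non-boundary")),
        extras=raw.get("extras", {}) or {},
    )
    cfg.validate_files()
    return cfg
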