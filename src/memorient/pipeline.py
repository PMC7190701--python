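"""One-command reproduction of the full analysis: orientation, bilayer and dynamics.

``run_all`` executes every stage from a single :class:`AnalysisConfig` and emits
diff-able CSV files plus a JSON run log recording all parameters, the package
version and input checksums.  Numeric formats are fixed (3 decimals for angles
and Ångström quantities, 4 for order parameters, 1 for B-factors), so reruns
with identical inputs and seed produce byte-identical outputs.  A failure in any
stage aborts the run with the stage name and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .dynamics import bfactors, rmsd_series
from .io_structures import Trajectory, group_molecules, read_pdb, read_trajectory
from .lipids import (APLTable, area_per_lipid, bilayer_thickness,
                     electron_density, order_parameters, thickness_map)
from .orientation import (PARAMETER_NAMES, assess_convergence,
                          orientation_series, representative_frame)
from .selection import select

__all__ = ["run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, float_format: str, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=float_format, lineterminator="\n")


def run_all(config: AnalysisConfig, out_dir: str | Path = ".") -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict with the output paths and headline numbers.  Outputs:
    ``<prefix>_orientation.csv`` (per-frame pose parameters + mean ± std row),
    ``<prefix>_apl.csv`` (summary + per-lipid areas of the final snapshot),
    ``<prefix>_scd.csv``, ``<prefix>_edp.csv``, ``<prefix>_thickness.csv``,
    ``<prefix>_thickness_map.csv``, ``<prefix>_rmsd.csv``, ``<prefix>_bfactor.csv``
    and ``<prefix>_runlog.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / config.out_prefix
    written: list[Path] = []
    stage = "setup"
    try:
        config.validate_files()
        traj = read_trajectory(config.trajectory, dt_ns=config.dt_ns)
        traj = Trajectory(
            group_molecules(traj.topology, config.dialect, config.heme_in_protein),
            traj.frames,
        )
        topo = traj.topology
        config.validate_on_topology(topo)
        span = traj.times[-1] - traj.times[0]
        if config.window_ns is not None and traj.n_frames > 1 and config.window_ns > span:
            raise ValueError(f"window of {config.window_ns} ns exceeds trajectory span of {span} ns")
        reference = read_pdb(config.reference) if config.reference else traj.system_at(0)
        window = config.window_ns
        t_end = traj.times[-1]
        in_window = (traj.times >= t_end - window) if window is not None else np.ones(traj.n_frames, bool)
        frame_ids = np.flatnonzero(in_window)[::config.snapshot_stride]
        param_header = [
            f"memorient {__version__}",
            f"window_ns={window} boundary_cutoff={config.boundary_cutoff} "
            f"density_bin={config.density_bin} stride={config.snapshot_stride} seed={config.seed}",
        ]

        stage = "orientation"
        series = orientation_series(traj, config.orientation)
        df = series.to_dataframe()
        summ = series.summary(window)
        summary_row = {"time_ns": np.nan}
        std_row = {"time_ns": np.nan}
        for p, col in zip(PARAMETER_NAMES,
                          ["alpha_deg", "beta_deg", "gamma_tm_deg", "heme_tilt_deg", "com_distance_A"]):
            summary_row[col] = summ[p][0]
            std_row[col] = summ[p][1]
        df_out = pd.concat([df, pd.DataFrame([summary_row, std_row])], ignore_index=True)
        p_orient = prefix.parent / f"{prefix.name}_orientation.csv"
        _write_csv(df_out, p_orient, "%.3f",
                   param_header + ["last two rows: windowed mean, sample std"])
        written.append(p_orient)
        rep_idx, rep_ok = representative_frame(series) if series.n_frames >= 2 else (0, True)
        try:
            conv, conv_t = assess_convergence(series, window_ns=max(span / 4, 1e-9),
                                              tolerance_deg=5.0)
        except ValueError:
            conv, conv_t = None, None

        stage = "area-per-lipid"
        tables = []
        counts = []
        for k in frame_ids:
            sysk = traj.system_at(int(k))
            apl_k = area_per_lipid(sysk, config.dialect,
                                   boundary_cutoff=config.boundary_cutoff,
                                   protein_slab_halfwidth=config.protein_slab_halfwidth)
            tables.append(apl_k.table.assign(frame=int(k)))
            counts.append({
                "frame": int(k), "time_ns": float(traj.times[k]),
                "boundary": int(apl_k.table["boundary"].sum()),
                "non_boundary": int((~apl_k.table["boundary"]).sum()),
            })
        pooled = pd.concat(tables, ignore_index=True)
        pooled_apl = APLTable(pooled[["molecule", "leaflet", "boundary", "area_A2"]])
        apl_summary = pooled_apl.summary()
        counts_df = pd.DataFrame(counts)
        p_apl = prefix.parent / f"{prefix.name}_apl.csv"
        _write_csv(apl_summary, p_apl, "%.3f",
                   param_header + [
                       f"pooled over {len(frame_ids)} snapshots",
                       "final-frame boundary count "
                       f"{counts[-1]['boundary']}, non-boundary {counts[-1]['non_boundary']}",
                   ])
        written.append(p_apl)
        p_apl_lipids = prefix.parent / f"{prefix.name}_apl_per_lipid.csv"
        _write_csv(tables[-1], p_apl_lipids, "%.3f",
                   param_header + ["per-lipid Voronoi areas of the final analysed snapshot"])
        written.append(p_apl_lipids)

        stage = "order-parameters"
        window_traj = Trajectory(topo, [traj.frames[int(k)] for k in frame_ids])
        lipid_ids = np.array([i for i, m in enumerate(topo.molecules) if m.tag == "lipid"])
        if config.scd_lipids == "non-boundary":
            final_boundary = tables[-1].set_index("molecule")["boundary"]
            subset = np.array([i for i in lipid_ids if not bool(final_boundary.get(i, False))])
        else:
            subset = lipid_ids
        scd = order_parameters(window_traj, config.dialect, subset)
        p_scd = prefix.parent / f"{prefix.name}_scd.csv"
        _write_csv(scd.to_dataframe(), p_scd, "%.4f",
                   param_header + [f"lipid subset: {config.scd_lipids} ({len(subset)} lipids)"])
        written.append(p_scd)

        stage = "electron-density"
        head = config.dialect.head_reference_atom
        lipid_idx = topo.indices_by_tag("lipid")
        comps = {
            "water": topo.indices_by_tag("water"),
            "protein": topo.indices_by_tag("protein"),
            "lipid": lipid_idx,
            "headgroup": lipid_idx[topo.names[lipid_idx] == head],
            "chains": lipid_idx[topo.names[lipid_idx] != head],
        }
        comps = {k: v for k, v in comps.items() if len(v)}
        edp = electron_density(traj, comps, bin_width=config.density_bin, window_ns=window)
        p_edp = prefix.parent / f"{prefix.name}_edp.csv"
        _write_csv(edp.to_dataframe(), p_edp, "%.5f",
                   param_header + [f"mean cross-sectional area {edp.area:.3f} A^2"])
        written.append(p_edp)

        stage = "thickness"
        thickness = bilayer_thickness(edp, "headgroup")
        tmap = thickness_map(traj.system_at(int(frame_ids[-1])), config.dialect, config.grid)
        p_thick = prefix.parent / f"{prefix.name}_thickness.csv"
        _write_csv(pd.DataFrame([{"thickness_A": thickness}]), p_thick, "%.3f", param_header)
        written.append(p_thick)
        nx, ny = config.grid
        assert tmap.map is not None and tmap.occluded is not None
        rows = [
            {"ix": ix, "iy": iy, "thickness_A": tmap.map[ix, iy],
             "occluded": bool(tmap.occluded[ix, iy]),
             "filled": bool(tmap.filled[ix, iy]) if tmap.filled is not None else False}
            for ix in range(nx) for iy in range(ny)
        ]
        p_tmap = prefix.parent / f"{prefix.name}_thickness_map.csv"
        _write_csv(pd.DataFrame(rows), p_tmap, "%.3f",
                   param_header + ["local thickness of the final analysed snapshot"])
        written.append(p_tmap)

        stage = "protein-dynamics"
        rmsd_vals = rmsd_series(traj, reference, config.dynamics_selection)
        p_rmsd = prefix.parent / f"{prefix.name}_rmsd.csv"
        _write_csv(pd.DataFrame({"time_ns": traj.times, "rmsd_A": rmsd_vals}),
                   p_rmsd, "%.3f", param_header)
        written.append(p_rmsd)
        bf = bfactors(traj, config.dynamics_selection, window_ns=window)
        bf_df = bf.to_dataframe()
        p_bf = prefix.parent / f"{prefix.name}_bfactor.csv"
        with open(p_bf, "w") as fh:
            for line in param_header:
                fh.write(f"# {line}\n")
            fh.write("atom_index,resid,rmsf_A,bfactor_A2\n")
            for _, row in bf_df.iterrows():
                fh.write(f"{int(row['atom_index'])},{int(row['resid'])},"
                         f"{row['rmsf_A']:.3f},{row['bfactor_A2']:.1f}\n")
        written.append(p_bf)

        stage = "run-log"
        log = {
            "version": __version__,
            "inputs": {
                str(config.trajectory): _sha256(Path(config.trajectory)),
                **({str(config.reference): _sha256(Path(config.reference))}
                   if config.reference else {}),
            },
            "parameters": {
                "dt_ns": config.dt_ns, "window_ns": window,
                "boundary_cutoff_A": config.boundary_cutoff,
                "density_bin_A": config.density_bin, "grid": list(config.grid),
                "snapshot_stride": config.snapshot_stride, "seed": config.seed,
                "heme_in_protein": config.heme_in_protein,
                "protein_slab_halfwidth_A": config.protein_slab_halfwidth,
                "dynamics_selection": config.dynamics_selection,
                "scd_lipids": config.scd_lipids,
            },
            "n_frames": traj.n_frames,
            "analysed_frames": [int(k) for k in frame_ids],
            "representative_frame": {"index": rep_idx, "within_1_percent": rep_ok},
            "convergence": {"converged": conv, "first_converged_time_ns": conv_t},
            "headline": {
                "orientation_mean_std": {p: list(summ[p]) for p in PARAMETER_NAMES},
                "apl_summary": apl_summary.to_dict(orient="records"),
                "boundary_counts_final": counts[-1],
                "bilayer_thickness_A": thickness,
            },
            "outputs": [str(p) for p in written],
        }
        p_log = prefix.parent / f"{prefix.name}_runlog.json"
        p_log.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written.append(p_log)
        return log
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc
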