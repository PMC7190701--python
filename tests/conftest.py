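"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from memorient.io_structures import Box, Frame, MolecularSystem, Trajectory
from memorient.synthetic import (build_bilayer, build_membrane_protein_system,
                                 toy_dialect)


@pytest.fixture(scope="session")
def small_bilayer():
    """8×8 lipids per leaflet, flat lattice, default study conditions, no jitter."""
    system, truth = build_bilayer(nx=8, ny=8, seed=11)
    return system, truth


@pytest.fixture(scope="session")
def jittered_bilayer():
    system, truth = build_bilayer(nx=8, ny=8, jitter_xy=0.8, seed=12)
    return system, truth


@pytest.fixture(scope="session")
def embedded_system():
    """Toy protein in a jittered bilayer at the default pose."""
    return build_membrane_protein_system(seed=21, jitter_xy=0.8)


@pytest.fixture(scope="session")
def dialect():
    return toy_dialect()


def single_frame_trajectory(system: MolecularSystem) -> Trajectory:
    assert system.box is not None
    return Trajectory(system, [Frame(system.positions.copy(), system.box, 0.0)])


@pytest.fixture
def make_simple_system():
    """Factory for bare systems from (name, resname, resid, element, xyz) rows."""

    def _make(rows, box=(50.0, 50.0, 50.0)):
        n = len(rows)
        return MolecularSystem(
            serials=np.arange(1, n + 1),
            names=np.array([r[0] for r in rows], dtype=object),
            resnames=np.array([r[1] for r in rows], dtype=object),
            resids=np.array([r[2] for r in rows]),
            chains=np.array(["A"] * n, dtype=object),
            segids=np.array([""] * n, dtype=object),
            elements=np.array([r[3] for r in rows], dtype=object),
            positions=np.array([r[4] for r in rows], dtype=float),
            box=Box(*box),
        )

    return _make
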