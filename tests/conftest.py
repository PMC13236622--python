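"""Shared fixtures.

The expensive objects (the full 2 mm 20-configuration sweep in both
delivery modes, and a compact lattice-only test field) are session-scoped
so every test that needs them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from latticedose.geometry import LatticeSpec, PhantomSpec
from latticedose.grids import GridSpec
from latticedose.simulate import DeliveryMode, SimParams, normalize_prescription, simulate_dose
from latticedose.workflow import SweepConfig, run_sweep

#: single fixed seed for every stochastic fixture in the suite
SUITE_SEED = 0


def compact_grid(lattice: LatticeSpec, spacing_mm: float = 2.0,
                 margin_mm: float = 20.0) -> GridSpec:
    """Small grid covering just the lattice plus a margin (fast tests).

    Symmetric about the isocenter with odd voxel counts, like the phantom
    grid.
    """
    extent = (lattice.counts[0] - 1) / 2 * lattice.pitch_mm + lattice.radius_mm
    n_half = int(np.ceil((extent + margin_mm) / spacing_mm))
    shape = (2 * n_half + 1,) * 3
    origin = (-n_half * spacing_mm,) * 3
    return GridSpec(shape=shape, spacing=(spacing_mm,) * 3, origin=origin)


def simulated_config(diameter_cm: float, separation_cm: float, mode: str,
                     seed: int = SUITE_SEED, spacing_mm: float = 2.0,
                     **overrides):
    """Lattice + normalized dose on a compact grid, for extraction tests."""
    from latticedose.geometry import build_vertex_masks

    lattice = LatticeSpec(diameter_cm, separation_cm)
    grid = compact_grid(lattice, spacing_mm)
    params = DeliveryMode.params(mode, seed=seed, **overrides)
    raw = simulate_dose(lattice, params, grid)
    vertex_masks = build_vertex_masks(lattice, grid)
    dose, _ = normalize_prescription(raw, vertex_masks)
    return lattice, grid, params, vertex_masks, dose


@pytest.fixture(scope="session")
def full_sweep():
    """The study sweep: 4 diameters x 5 separations x both modes, 2 mm grid."""
    return run_sweep(SweepConfig(seed=SUITE_SEED))


@pytest.fixture(scope="session")
def rep_field():
    """Representative configuration (d=1.5 cm, s=2.0 cm), coplanar preset."""
    return simulated_config(1.5, 2.0, "coplanar")


@pytest.fixture(scope="session")
def rep_field_noncoplanar():
    return simulated_config(1.5, 2.0, "noncoplanar")
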