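"""Shared fixtures: small analytic models and a reduced simplified phantom.

All fixtures are generated programmatically; the mini applicator uses
shortened electrodes so that full solves stay fast while exercising every
code path (two electrodes, dielectric shell, grounded boundary).
"""

import numpy as np
import pytest

from thermoplan.applicators import ApplicatorSpec
from thermoplan.grid import RectilinearGrid
from thermoplan.materials import tissue_table
from thermoplan.model import VoxelModel, build_model
from thermoplan.solver import EQSSystem, Excitation


MINI_SPEC = dict(electrode_length=5.0, electrode_gap=2.0, tip_offset=2.0)


def make_parallel_plate(n=9, lateral=5):
    """Muscle slab between two full-face plate electrodes along x (insulated sides)."""
    g = RectilinearGrid(
        x=np.linspace(0, 10, n + 1),
        y=np.linspace(0, 10, lateral + 1),
        z=np.linspace(0, 10, lateral + 1),
    )
    em = np.full(g.shape, -1, dtype=np.int16)
    em[0, :, :] = 0
    em[-1, :, :] = 1
    return VoxelModel(
        grid=g,
        material_id=np.zeros(g.shape, dtype=np.int16),
        materials=[tissue_table()["Muscle"]],
        electrode_mask=em,
        voi=((0, 10), (0, 10), (0, 10)),
        applicators=[],
        mode="detailed",
        first_applicator_material_id=99,
    )


def make_concentric_cylinders(h=0.25, r_in=2.0, r_out=8.0, halfwidth=9.0, nz=3):
    """Inner electrode cylinder at 13 V inside a grounded outer cylinder (quasi-2D)."""
    n = int(round(2 * halfwidth / h))
    g = RectilinearGrid(
        x=np.linspace(-halfwidth, halfwidth, n + 1),
        y=np.linspace(-halfwidth, halfwidth, n + 1),
        z=np.linspace(0, 3.0 * nz, nz + 1),
    )
    cx = g.centers("x")
    cy = g.centers("y")
    r = np.hypot(cx[:, None], cy[None, :])
    em2 = np.full((n, n), -1, dtype=np.int16)
    em2[r <= r_in] = 0
    em2[r >= r_out] = 1
    em = np.repeat(em2[:, :, None], nz, axis=2)
    return VoxelModel(
        grid=g,
        material_id=np.zeros(g.shape, dtype=np.int16),
        materials=[tissue_table()["Muscle"]],
        electrode_mask=em,
        voi=((-9, 9), (-9, 9), (0, 9)),
        applicators=[],
        mode="detailed",
        first_applicator_material_id=99,
    )


@pytest.fixture(scope="session")
def mini_model():
    """One short-electrode applicator in muscle, simplified cuboid geometry."""
    spec = ApplicatorSpec(tip_position=(0.0, 0.0, 0.0), **MINI_SPEC)
    voi = ((-2.0, 2.0), (-2.0, 2.0), (-14.0, 0.0))
    return build_model([spec], voi, background="Muscle", mode="simplified", fine_step=0.1)


@pytest.fixture(scope="session")
def mini_system(mini_model):
    return EQSSystem(mini_model)


@pytest.fixture(scope="session")
def mini_solution(mini_model, mini_system):
    return mini_system.solve(Excitation.uniform(mini_model.n_electrodes))
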