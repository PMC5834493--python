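"""Shared fixtures: phantoms are generated programmatically at test time.

Expensive artifacts (rasterized volumes, pipeline runs) are session-scoped.
Voxel sizes are coarser than the 15 um source-data tier; every tolerance
asserted in the tests holds at the resolution actually used.
"""

from __future__ import annotations

import numpy as np
import pytest

from canalmorph import phantom as ph
from canalmorph.pipeline import RunConfig, run_cohort, run_specimen


def small_canal_spec(voxel_size: float = 0.06, offset: float = 0.2,
                     tilt: float = 0.0) -> ph.PhantomSpec:
    """A cheap single-canal phantom for unit-level pipeline tests:
    2 mm arc radius, 200 degree span, slender radii like the defaults."""
    canal = ph.CanalSpec(
        name="posterior",
        plane_normal=np.array([1.0, 0.0, 0.0]),
        center=np.array([0.0, 0.0, -2.0]),
        major_radius=2.0,
        arc_span_deg=200.0,
        start_direction=np.array([0.0, 0.0, 1.0]),
        bony_radius_profile=ph.RadiusProfile(0.5),
        membranous_radius_profile=ph.RadiusProfile(0.16),
        membranous_offset=offset,
        membranous_tilt_deg=tilt,
        end_margin_mm=1.0)
    return ph.PhantomSpec([canal], voxel_size=voxel_size)


@pytest.fixture(scope="session")
def small_volume():
    """(spec, volume, ground truth) for the cheap single-canal phantom."""
    spec = small_canal_spec()
    vol, gt = ph.rasterize(spec)
    return spec, vol, gt


@pytest.fixture(scope="session")
def default_spec():
    return ph.default_labyrinth_spec(seed=0)


@pytest.fixture(scope="session")
def default_run(default_spec):
    """Full pipeline on the exact (unjittered) default labyrinth at 60 um."""
    cfg = RunConfig(n_specimens=1, seed=0, voxel_size_mm=0.06)
    res = run_specimen(cfg, default_spec, specimen_id=0)
    assert res.ok, res.error
    return res


@pytest.fixture(scope="session")
def cohort3():
    """Three jittered specimens through the whole pipeline at 60 um."""
    cfg = RunConfig(n_specimens=3, seed=1, voxel_size_mm=0.06)
    return run_cohort(cfg)
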