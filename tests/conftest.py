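"""Shared fixtures: small synthetic acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from visrkit.phantom import (
    AcquisitionParams,
    MechanicalGroundTruth,
    SequenceTiming,
    acquire,
    make_phantom,
    synthesize_rf,
)
from visrkit.tracking import TrackingParams, ncc_track
from visrkit.visr import visr_image

SHIFT_GRID_UM = (2.0, 5.0, 10.0, 19.25)


@pytest.fixture(scope="session")
def timing() -> SequenceTiming:
    return SequenceTiming()


@pytest.fixture(scope="session")
def acq_params() -> AcquisitionParams:
    return AcquisitionParams(snr_db=20.0)


@pytest.fixture(scope="session")
def track_params() -> TrackingParams:
    return TrackingParams(axial_band_mm=(16.8, 23.2), lateral_halfwidth_mm=3.2)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    mech = MechanicalGroundTruth(re_long=10.0, re_trans=10.0, rv_long=5.0, rv_trans=5.0)
    return make_phantom(mech, seed=1)


def rigid_shift_ensemble(phantom, params, shifts_um, seed):
    """RF ensemble whose event blocks carry known rigid axial shifts."""
    n_ev = params.timing.n_events
    u = np.zeros((phantom.n_scatterers, n_ev))
    for i, s in enumerate(shifts_um):
        u[:, 2 + i * 10 : 2 + (i + 1) * 10] = s
    return synthesize_rf(phantom, u, seed=seed, params=params)


@pytest.fixture(scope="session")
def shift_rf(homogeneous_phantom, acq_params):
    return rigid_shift_ensemble(homogeneous_phantom, acq_params, SHIFT_GRID_UM, seed=7)


@pytest.fixture(scope="session")
def shift_field(shift_rf, track_params):
    return ncc_track(shift_rf, track_params)


@pytest.fixture(scope="session")
def anis_subject(acq_params, track_params):
    """One anisotropic subject imaged at the four protocol angles.

    Returns ``(mech, {angle: maps})`` — the raw material for the
    end-to-end anisotropy and homogeneity checks.
    """
    mech = MechanicalGroundTruth(
        re_long=25.0, re_trans=10.0, rv_long=9.0, rv_trans=5.0, aos_angle_deg=20.0
    )
    phantom = make_phantom(mech, seed=3)
    maps = {}
    for angle in (0, 30, 60, 90):
        rf = acquire(phantom, angle, acq_params, seed=100 + angle)
        field = ncc_track(rf, track_params)
        maps[angle] = visr_image(field, acq_params.timing)
    return mech, maps
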