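"""Shared fixtures: a scaled-down scanner for fast mechanical tests.

The scaled geometry keeps the 56 degree fan and the reference-channel
convention but uses 228 channels and 8 rows so that simulator-backed tests
run in seconds.  Trend assertions that depend on the interplay of fan
coverage, cone width and beam hardening (kVp monotonicity in particular) are
made only at the full 64 x 912 geometry, in the acceptance tests.
"""

import numpy as np
import pytest

from ctscatter.geometry import (BlockerArray, Phantom, ScannerGeometry,
                                water_cylinder_215)
from ctscatter.physics import Spectrum, generate_spectrum
from ctscatter.raw_io import CalibrationTable
from ctscatter.simulator import AcquisitionSetup


@pytest.fixture(scope="session")
def small_geom() -> ScannerGeometry:
    return ScannerGeometry(n_rows=8, n_channels_total=228,
                           n_channels_active=204, n_channels_reference=24)


@pytest.fixture(scope="session")
def small_blocker(small_geom) -> BlockerArray:
    return BlockerArray.default_layout(small_geom, n_bars=10, bar_width=4.0)


@pytest.fixture(scope="session")
def water_phantom() -> Phantom:
    return water_cylinder_215()


@pytest.fixture(scope="session")
def coarse_spectrum() -> Spectrum:
    return generate_spectrum(120.0, bin_width=10.0)


@pytest.fixture(scope="session")
def small_setup(small_geom, small_blocker, water_phantom, coarse_spectrum):
    return AcquisitionSetup(geometry=small_geom, phantom=water_phantom,
                            blocker=small_blocker, spectrum=coarse_spectrum,
                            tube_current=100.0, seed=11)


@pytest.fixture(scope="session")
def small_identity_cal(small_geom) -> CalibrationTable:
    return CalibrationTable.identity(small_geom.n_rows, small_geom.n_channels_total)


@pytest.fixture(scope="session")
def rendered_pair(small_setup, small_identity_cal, tmp_path_factory):
    """One scaled, noise-free acquisition pair shared across pipeline tests."""
    from ctscatter.simulator import GroundTruth, render_acquisition_pair

    out = tmp_path_factory.mktemp("pair")
    entry = render_acquisition_pair(small_setup, small_identity_cal, out,
                                    tag="unit", grid_resolution=5.0)
    entry["truth_obj"] = GroundTruth.load(entry["truth"])
    return entry
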