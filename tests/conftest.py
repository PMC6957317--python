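import warnings

import numpy as np
import pytest

from nucspt import (
    AcquisitionConfig,
    NucleusGeometry,
    preset_catalog,
    simulate_cell,
)


@pytest.fixture(scope="session")
def catalog():
    return preset_catalog()


@pytest.fixture(scope="session")
def granule():
    return NucleusGeometry(radius_um=3.0)


@pytest.fixture(scope="session")
def wt_fast_recording(catalog, granule):
    """One wild-type granule-cell fast-mode recording, reused across tests."""
    acq = AcquisitionConfig.fast_tracking(n_frames=4000)
    return simulate_cell(catalog["MeCP2_GC_WT"], granule, acq,
                         n_molecules=250, seed=11)


@pytest.fixture(scope="session")
def wt_slow_recording(catalog, granule):
    """One wild-type slow-dwell recording with ground truth."""
    acq = AcquisitionConfig.slow_dwell(n_frames=1200)
    return simulate_cell(catalog["MeCP2_GC_WT"], granule, acq,
                         n_molecules=25, seed=21)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


def pure_free_preset(D_free=1.0):
    """A preset whose molecules essentially never bind (for displacement-law
    tests); binding is made astronomically slow rather than zero because the
    kinetic chain requires F_bound in (0, 1)."""
    from nucspt.presets import KineticPreset

    return KineticPreset("pure_free", F_bound=1e-9, D_free=D_free,
                         tau_short_s=1e6, tau_long_s=1e6)


def pure_bound_preset(D_bound=0.005):
    from nucspt.presets import KineticPreset

    return KineticPreset("pure_bound", F_bound=1.0 - 1e-9, D_free=1.0,
                         D_bound=D_bound, tau_short_s=1e6, tau_long_s=1e6)
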