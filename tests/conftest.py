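"""Shared fixtures.

Expensive artifacts (pre-paced cell states, the configuration sweep, the
finer-resolution scar runs) are session-scoped and computed lazily so each
is simulated exactly once per test run.
"""

import numpy as np
import pytest

from bzsim.cell import make_variant, measure_apd, pace_to_steady_state
from bzsim.geometry import GeometryConfig
from bzsim.solver import TissueParams
from bzsim.study import BZConfiguration, enumerate_configurations, run_study

# desk-scale numerics used by the 2D fixtures (identical code path to the
# full-resolution study; sizes documented in docs/methods.md)
COARSE = dict(resolution=0.30, dt=0.1, n_sub=2, n_beats=2)
FINE = dict(resolution=0.15, dt=0.1, n_sub=2, n_beats=5)


@pytest.fixture(scope="session")
def variant_traces():
    """Steady state, final-beat trace and APD90 for the three cell variants
    (100 pre-pacing beats at CL 500 ms)."""
    out = {}
    for variant in ("control", "longer_apd", "shorter_apd"):
        params = make_variant(variant)
        state, trace = pace_to_steady_state(params, 500.0, 100, record_last=1)
        out[variant] = {"params": params, "state": state, "trace": trace,
                        "apd": measure_apd(trace)}
    return out


@pytest.fixture(scope="session")
def coarse_study():
    """All 12 BZ representations on the coarse desk-scale mesh."""
    configs = enumerate_configurations(random_seed=7)
    # 13th case: the smooth conductivity-transition variant of the
    # shorter-APD decreased-transverse column
    configs.append(BZConfiguration(apd_variant="shorter",
                                   conductivity_mode="decreased_transverse",
                                   bz_fiber_mode="horizontal",
                                   smooth_transition=1.0))
    res = run_study(
        configs=configs,
        geometry_config=GeometryConfig(resolution=COARSE["resolution"],
                                       random_seed=7),
        tissue_params=TissueParams(dt=COARSE["dt"],
                                   n_ionic_substeps=COARSE["n_sub"],
                                   n_beats=COARSE["n_beats"]),
    )
    assert not res.failures, res.failures
    return res


@pytest.fixture(scope="session")
def fine_run():
    """Shorter-APD + decreased-transverse + horizontal fibers at 0.15 mm,
    five paced beats, last two beats recorded (for periodicity checks)."""
    res = run_study(
        configs=[BZConfiguration(apd_variant="shorter",
                                 conductivity_mode="decreased_transverse",
                                 bz_fiber_mode="horizontal")],
        geometry_config=GeometryConfig(resolution=FINE["resolution"]),
        tissue_params=TissueParams(dt=FINE["dt"],
                                   n_ionic_substeps=FINE["n_sub"],
                                   n_beats=FINE["n_beats"],
                                   record_last_beats=2),
        keep_records=True,
    )
    assert not res.failures, res.failures
    return res
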