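"""Shared fixtures: study designs and paper-scale threshold curves.

The expensive artifacts (the TSP design with its exact solves, the full
Monte-Carlo threshold sweeps) are session-scoped so the stratification,
recovery and threshold tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DESIGN_SEED = 11


@pytest.fixture(scope="session")
def sat3_design():
    from hardcog.design import SAT3_STUDY_DESIGN, build_instance_set

    return build_instance_set(SAT3_STUDY_DESIGN, seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def kp_design():
    from hardcog.design import KP_STUDY_DESIGN, build_instance_set

    return build_instance_set(KP_STUDY_DESIGN, seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def tsp_design():
    from hardcog.design import TSP_STUDY_DESIGN, build_instance_set

    return build_instance_set(TSP_STUDY_DESIGN, seed=DESIGN_SEED)


@pytest.fixture(scope="session")
def sat3_curve_full():
    """3SAT satisfiability curve at study scale: N=5, 1000 instances per
    0.1 grid step over the full sweep."""
    from hardcog.generators import stage_rng
    from hardcog.metrics import satisfiability_curve
    from hardcog.pipeline import sweep_grid

    rng = stage_rng(DESIGN_SEED, "threshold_sat3")
    return satisfiability_curve("sat3", 5, sweep_grid("sat3"), 1000, rng)


@pytest.fixture(scope="session")
def tsp_curve_full():
    """TSP satisfiability curve at study scale: N=20, 100 maps, grid
    [-1.25, -0.25] in steps of 0.02."""
    from hardcog.generators import stage_rng
    from hardcog.metrics import satisfiability_curve
    from hardcog.pipeline import sweep_grid

    rng = stage_rng(DESIGN_SEED, "threshold_tsp")
    return satisfiability_curve("tsp", 20, sweep_grid("tsp"), 100, rng)
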