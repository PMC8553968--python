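"""Shared fixtures.

The gravity-transition simulations are the expensive part of the suite, so
every run that more than one test consumes is computed once per session here.
"""

from __future__ import annotations

import numpy as np
import pytest

import vestadapt as va
from vestadapt.simulate import run


def _summary(name: str, seed: int = 1) -> dict:
    return run(va.SimulationConfig(scenario=name, seed=seed)).summary


@pytest.fixture(scope="session")
def fig3_result():
    """The canonical 1 -> 0.5 g roll-tilt adaptation run."""
    return run(va.SimulationConfig(scenario="fig3", seed=1))


@pytest.fixture(scope="session")
def transition_summaries():
    """Summaries for the three gravity-transition presets (same seed)."""
    return {name: _summary(name) for name in ("fig3", "fig4b", "fig4c")}


@pytest.fixture(scope="session")
def motion_summaries():
    """Summaries for the motion-dependence presets (shared transition time)."""
    names = [
        "fig5_roll_a30",
        "fig5_roll_a15",
        "fig5_roll_a45",
        "fig5_roll_f0125",
        "fig5_roll_f05",
        "fig5_none",
        "fig5_trans_a0125",
        "fig5_trans_a025_f05",
        "fig5_yaw_a30",
        "fig5_yaw_a60_f05",
    ]
    return {name: _summary(name) for name in names}


@pytest.fixture(scope="session")
def prior_width_summaries():
    """Direct vs learned adaptation to 0.5 g."""
    return {name: _summary(name) for name in ("fig6_direct", "fig6_learned")}


@pytest.fixture(scope="session")
def noise_sweep_medians():
    """Median initiation time over five seeds per configured noise power."""
    medians = {}
    for power in va.NOISE_SWEEP_POWERS:
        name = f"fig7_p{power:.0e}".replace("e-0", "e-")
        inits = [_summary(name, seed=s)["initiation_time"] for s in range(1, 6)]
        medians[power] = float(np.median(inits))
    return medians
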