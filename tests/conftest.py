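"""Shared fixtures: synthetic bundles and scenario trajectories.

Expensive scenario realizations are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from gpcrtraj.model import select
from gpcrtraj.synth import (
    BundleSpec,
    agonist_script,
    inverse_script,
    make_bundle,
    run_scenario,
    static_script,
)

AGONIST_EVENT_FRAMES = [20, 50, 80, 110, 140, 170]


@pytest.fixture(scope="session")
def bundle():
    """Default (unkinked, noiseless) 7-TM bundle and its BW map."""
    return make_bundle()


@pytest.fixture(scope="session")
def kinked_bundle():
    """Bundle with the inactive-like TM6 kink (33°) scripted, noiseless."""
    return make_bundle(BundleSpec(kinks={6: (50, 33.0, 200.0, 0.0)}))


@pytest.fixture(scope="session")
def agonist_run():
    """200-frame agonist scenario with the six events at known frames."""
    script = agonist_script(n_frames=200, seed=11, event_frames=AGONIST_EVENT_FRAMES)
    return run_scenario(script)


@pytest.fixture(scope="session")
def inverse_run():
    """Inverse-agonist scenario: lock open at start, closes at frame 60."""
    return run_scenario(inverse_script(n_frames=120, seed=3, close_frame=60))


@pytest.fixture(scope="session")
def membrane_run():
    """Static bundle in a flat 28 Å slab, noiseless (exact constructions)."""
    return run_scenario(static_script(n_frames=5, membrane_thickness=28.0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def membrane_run_noisy():
    """Static bundle in a flat 28 Å slab with the default 0.2 Å noise."""
    return run_scenario(static_script(n_frames=10, membrane_thickness=28.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def c2_selection_for(membrane_run):
    traj, _ = membrane_run
    return select(traj, "resname LIP and name C2")
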