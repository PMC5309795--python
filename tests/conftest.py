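"""Shared fixtures: small task schedules and simulated sessions.

Simulations used by the tests are deliberately smaller than a full session
(fewer blocks, shorter blocks, 500-1000 Hz sampling) so the suite stays fast;
the generator code paths are identical to the full-size defaults.
"""

import numpy as np
import pytest

import oscicoupler as oc


@pytest.fixture(scope="session")
def small_schedule():
    params = oc.TaskScheduleParams(
        n_neutral_blocks=4, n_aversive_blocks=3, block_duration_s=20.0,
        n_neutral_clips=28, n_aversive_clips=21, seed=7)
    return oc.make_task_schedule(params)


def make_session(seed, schedule=None, fs=1000.0, **truth_kw):
    """Simulate a compact two-region session; truth overrides via kwargs."""
    if schedule is None:
        params = oc.TaskScheduleParams(
            n_neutral_blocks=4, n_aversive_blocks=3, block_duration_s=20.0,
            n_neutral_clips=28, n_aversive_clips=21, seed=seed)
        schedule = oc.make_task_schedule(params)
    truth = oc.CouplingGroundTruth(**truth_kw)
    rec = oc.simulate_lfp(schedule, truth, fs=fs, seed=seed)
    return rec, schedule, truth


@pytest.fixture(scope="session")
def coupled_session():
    """One session with coupling in both conditions and no evoked response
    (isolates the tonic coupling measures)."""
    return make_session(11, evoked_hg_amp_aversive=0.0)


@pytest.fixture(scope="session")
def full_session():
    """A session with the study-scale schedule (9 + 8 blocks), sampled at
    500 Hz to keep the suite fast; coupling in both conditions, no evoked
    response."""
    schedule = oc.make_task_schedule(oc.TaskScheduleParams(seed=11))
    truth = oc.CouplingGroundTruth(evoked_hg_amp_aversive=0.0)
    rec = oc.simulate_lfp(schedule, truth, fs=500.0, seed=11)
    return rec, schedule, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
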