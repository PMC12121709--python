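import dataclasses

import numpy as np
import pytest

import stereomotion as sm


@pytest.fixture(scope="session")
def pro():
    return sm.Observer("sub-00", group="stereo_pro", lapse=0.0)


@pytest.fixture(scope="session")
def struggler():
    return sm.Observer("sub-01", group="stereo_struggler", lapse=0.0)


@pytest.fixture(scope="session")
def one_run_schedule():
    return sm.make_schedule(n_runs=1, seed=11)


@pytest.fixture(scope="session")
def quiet_roi_spec():
    """A small ROI with every bias coefficient switched off."""
    return dataclasses.replace(
        sm.ROI_PRESETS["MT"], n_vertices=60, g_ecc=0.0, g_rad=0.0, g_int=0.0,
        s_scale=0.0, s_scale_hm=None,
    )


def make_session_matrix(pop, observer, n_runs=2, seed=0, mode="zscore",
                        noise=None, rotated=False):
    """Simulate and preprocess a small session (shared helper)."""
    from stereomotion import preprocess as pre

    sched = sm.make_schedule(n_runs=n_runs, seed=seed, rotated=rotated)
    noise = noise if noise is not None else sm.NoiseParams()
    mats = []
    for rid, _ in sched.runs():
        run = sm.simulate_run(pop, sched, observer, noise, seed=seed + 100 + rid,
                              run=rid)
        mats.append(pre.single_trial_matrix(run, mode=mode))
    return pre.assemble_session(mats)
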