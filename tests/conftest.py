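import numpy as np
import pytest

from gazekit.events import DetectionConfig
from gazekit.fixtures import EventPlan, PlannedEvent, generate_trial


@pytest.fixture
def cfg():
    return DetectionConfig()


def fix_sacc_blink_plan(gaze_noise_sd=0.0, pupil_noise_sd=0.0):
    """Three fixations, one saccade, one blink; no microsaccades.

    The post-blink fixation starts 45 ms after the gap opens so its planted
    onset sits at the refined (flank-extended) blink boundary.
    """
    return EventPlan(
        duration_ms=3000.0,
        events=[
            PlannedEvent("fixation", 0, 800, centroid=(400, 300)),
            PlannedEvent("saccade", 800, 60, start=(400, 300), end=(800, 600)),
            PlannedEvent("fixation", 860, 1040, centroid=(800, 600)),
            PlannedEvent("blink", 1900, 120),
            PlannedEvent("fixation", 2045, 955, centroid=(800, 600)),
        ],
        gaze_noise_sd=gaze_noise_sd,
        pupil_noise_sd=pupil_noise_sd,
        pupil_bump=(600.0, 60.0, 150.0),
    )


def ms_plan(gaze_noise_sd=0.4, amplitude=18.0, n_ms=1):
    """A single long fixation hosting planted microsaccades only."""
    events = [PlannedEvent("fixation", 0, 3000, centroid=(640, 512))]
    for i in range(n_ms):
        events.append(
            PlannedEvent(
                "microsaccade",
                600 + 700 * i,
                12,
                amplitude_px=amplitude,
                direction_deg=40.0 * (i + 1),
            )
        )
    return EventPlan(
        duration_ms=3000.0,
        events=events,
        gaze_noise_sd=gaze_noise_sd,
        pupil_noise_sd=1.0,
    )


@pytest.fixture
def clean_trial():
    trial, truth = generate_trial(fix_sacc_blink_plan(), 1000, seed=11)
    return trial, truth


@pytest.fixture
def noisy_trial():
    trial, truth = generate_trial(
        fix_sacc_blink_plan(gaze_noise_sd=0.3, pupil_noise_sd=2.0), 1000, seed=11
    )
    return trial, truth
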