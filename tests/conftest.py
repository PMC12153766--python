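import dataclasses

import pytest
from hypothesis import settings

from pentrack import simdata
from pentrack.metrics import FrameBoxes
from pentrack.tracker import TrackerConfig, run_sequence

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def boxes_to_tuples(frames: FrameBoxes) -> dict:
    """Convert {frame: {id: BoundingBox}} to plain-tuple form for the oracles."""
    return {t: {i: (b.left, b.top, b.width, b.height) for i, b in fb.items()}
            for t, fb in frames.items()}


def track_scenario(cfg: simdata.ScenarioConfig,
                   tracker_cfg: TrackerConfig | None = None):
    """Simulate, emulate the detector and track; returns (gt_boxes, hyp_boxes)."""
    gt = simdata.simulate_ground_truth(cfg)
    stream = simdata.emulate_detector(gt)
    rows = run_sequence(stream, tracker_cfg or TrackerConfig())
    hyp: FrameBoxes = {}
    for r in rows:
        hyp.setdefault(r.frame_index, {})[r.track_id] = r.box
    return gt.boxes, hyp


@pytest.fixture
def small_noisy_scenario():
    """A short, moderately noisy 4-animal scenario for oracle cross-checks."""
    return dataclasses.replace(
        simdata.day_night_presets(7)["day"], n_identities=4, n_frames=60,
        pen_width=640.0, pen_height=480.0)
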