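import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from feedmark import segmentation as seg
from feedmark import synthetic as syn


@pytest.fixture(scope="session")
def crossing_scenario():
    """Rendered reflective assay where a leaf-colored larva crosses a
    consumed region and then parks on the background — the scenario that
    defeats plain color thresholding but not cumulative masking."""
    events = [
        syn.ScriptedEvent(5, 4, 0.8, site=(80, 110)),
        syn.ScriptedEvent(20, 6, 1.0, site=(130, 180)),
        syn.ScriptedEvent(40, 3, 0.5, site=(90, 200)),
    ]
    n = 60
    path = syn.linear_path((80, 110), (30, 280), n)
    script = syn.BehaviorScript(events=events, larva_path=path, seed=3)
    scene = syn.SceneSpec()
    frames, truth = syn.render_sequence(script, scene, n_frames=n)
    return script, scene, frames, truth


@pytest.fixture(scope="session")
def noise_free_scenario():
    """Same schedule, no larva and no sensor noise: thresholding alone
    should be exact."""
    events = [
        syn.ScriptedEvent(5, 4, 0.8, site=(80, 110)),
        syn.ScriptedEvent(20, 6, 1.0, site=(130, 180)),
        syn.ScriptedEvent(40, 3, 0.5, site=(90, 200)),
    ]
    script = syn.BehaviorScript(events=events, seed=3)
    scene = syn.SceneSpec(noise_sd=0.0)
    frames, truth = syn.render_sequence(script, scene, n_frames=60)
    return script, scene, frames, truth


@pytest.fixture(scope="session")
def noise_free_masks(noise_free_scenario):
    """mask2 of the noise-free scenario plus its detected events."""
    from feedmark import events as ev

    script, scene, frames, truth = noise_free_scenario
    mask1 = seg.color_threshold(frames, seg.ThresholdSpec.preset("reflective"))
    mask2 = seg.cumulative_mask(mask1)
    areas = seg.measure_roi_areas(
        mask2,
        [_full_roi(frames)],
        frames.mm_per_px,
        frames.frame_interval,
    )[0]
    events, _ = ev.analyze_series(areas)
    return mask2, events, areas


def _full_roi(frames):
    from feedmark.imaging_io import RectROI

    h, w = frames.frames.shape[1:3]
    return RectROI("frame", 0, 0, h, w)
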