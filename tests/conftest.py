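from datetime import datetime, timedelta

import pandas as pd
import pytest

from sentinelcam.synth import SceneConfig


@pytest.fixture
def quiet_scene():
    """A small noiseless scene: static textured background, no failures."""
    def make(n_frames=200, seed=0, **overrides):
        kwargs = dict(
            n_frames=n_frames,
            background_texture=10.0,
            illumination_drift=0.0,
            flash_failure_prob=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return SceneConfig(**kwargs)

    return make


@pytest.fixture
def timestamps():
    def make(n, start=datetime(2020, 9, 15, 16, 0, 0), step=30):
        return [start + timedelta(seconds=step * i) for i in range(n)]

    return make


def annotation_rows(session_id, rows, timestamps=None):
    """Build an annotation table from (index, species, feeding, weevils) tuples."""
    base = datetime(2020, 9, 15, 16, 0, 0)
    return pd.DataFrame(
        [
            {
                "session_id": session_id,
                "frame_index": idx,
                "timestamp": (timestamps[idx] if timestamps else base + timedelta(seconds=30 * idx)),
                "species": species,
                "feeding_on_weevil": feeding,
                "weevils_visible": weevils,
            }
            for idx, species, feeding, weevils in rows
        ]
    )


@pytest.fixture
def make_annotations():
    return annotation_rows


@pytest.fixture
def sessions_meta():
    def make(session_ids, plot_ids=None, prey=2):
        return pd.DataFrame(
            {
                "session_id": list(session_ids),
                "plot_id": plot_ids or ["P1"] * len(session_ids),
                "prey_deployed": prey,
            }
        )

    return make
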