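import numpy as np
import pytest

from eegid import synthetic
from eegid.preprocess import SegmentSet


@pytest.fixture(scope="session")
def small_cohort():
    return synthetic.make_cohort(3, seed=11, preset="strong")


@pytest.fixture(scope="session")
def short_profiles():
    """Four-task protocol with short durations to keep tests fast."""
    return [
        synthetic.TaskLoadProfile("rest", 1.5, 0.8, 0.7, 6.0),
        synthetic.TaskLoadProfile("level1", 1.0, 1.0, 1.0, 6.0),
        synthetic.TaskLoadProfile("level2", 0.8, 1.2, 1.3, 6.0),
        synthetic.TaskLoadProfile("level3", 0.6, 1.45, 1.6, 6.0, 1.0),
    ]


@pytest.fixture(scope="session")
def tiny_recordings(small_cohort, short_profiles):
    recs = []
    for sig in small_cohort:
        recs.extend(synthetic.simulate_session(sig, short_profiles, seed=3))
    return recs


def make_segment_set(
    n_per_class: int,
    n_classes: int,
    n_channels: int = 8,
    window: int = 200,
    seed: int = 0,
    class_freqs=None,
    task_id: str = "rest",
):
    """Hand-built separable segments: each class has a dominant frequency
    and a distinct amplitude, with per-channel random phase/gain so CAR does
    not cancel the signal."""
    rng = np.random.default_rng(seed)
    labels, data, record_ids, starts = [], [], [], []
    freqs = class_freqs or [3 + 7 * c for c in range(n_classes)]
    t = np.arange(window)
    for c in range(n_classes):
        amp = 2.0**c  # geometric spacing: class amplitude ranges never overlap
        for i in range(n_per_class):
            seg = np.empty((n_channels, window))
            base_phase = rng.uniform(0, 2 * np.pi)
            for ch in range(n_channels):
                # evenly spread channel phases: the channel mean stays near
                # zero, so CAR leaves the class amplitude structure intact
                phase = base_phase + 2 * np.pi * ch / n_channels
                gain = rng.uniform(0.9, 1.1)
                seg[ch] = amp * gain * np.sin(2 * np.pi * freqs[c] * t / window + phase)
            seg += 0.02 * rng.standard_normal((n_channels, window))
            data.append(seg)
            labels.append(c)
            record_ids.append(c)
            starts.append(i * window)
    n = len(labels)
    channel_labels = list(synthetic.CHANNELS[:n_channels])
    return SegmentSet(
        data=np.array(data, dtype=np.float32),
        subject_labels=np.array(labels),
        task_ids=np.full(n, task_id, dtype=object),
        record_ids=np.array(record_ids),
        start_samples=np.array(starts),
        channel_labels=channel_labels,
        fs_hz=1000.0,
        window=window,
        step=window,
    )


@pytest.fixture()
def toy_separable():
    return make_segment_set(n_per_class=30, n_classes=3, n_channels=2, window=200, seed=1)
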