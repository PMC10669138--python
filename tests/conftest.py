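import numpy as np
import pytest

from wormchrono.copas_io import EventRecord, PopulationDataset, ProfileRecord


def make_dataset(spec, condition_label="test", ext_per_length=0.5):
    """Build a dataset from {event_id: samples} or {event_id: (samples, tof, ext)}."""
    events, profiles = [], {}
    for event_id, value in spec.items():
        if isinstance(value, tuple):
            samples, tof, ext = value
        else:
            samples = value
            tof = float(len(samples))
            ext = ext_per_length * tof
        samples = np.asarray(samples, dtype=float)
        events.append(EventRecord(event_id=event_id, tof=tof, ext=ext,
                                  ph_green=float(samples.max())))
        profiles[event_id] = ProfileRecord(event_id=event_id, samples=samples)
    return PopulationDataset(condition_label=condition_label, events=events,
                             profiles=profiles)


@pytest.fixture
def tiny_dataset():
    """Three asymmetric worms of distinct lengths, artifact-free."""
    rng = np.random.default_rng(7)
    spec = {}
    for i, length in enumerate([90, 100, 120]):
        x = np.linspace(0, 1, length)
        spec[f"w{i}"] = 5 + 20 * np.exp(-0.5 * ((x - 0.15) / 0.05) ** 2) + rng.normal(0, 0.5, length)
    return make_dataset(spec)


def random_walk_profiles(n, rng, length_range=(20, 60)):
    """Asymmetric random profiles (non-negative random walks) for orientation tests."""
    from wormchrono.copas_io import ProfileRecord

    lengths = sorted(int(rng.integers(*length_range)) for _ in range(n))
    out = []
    for i, L in enumerate(lengths):
        steps = rng.normal(0.3, 1.0, size=L)  # drift makes profiles asymmetric
        samples = np.abs(np.cumsum(steps)) + 1.0
        out.append(ProfileRecord(event_id=f"p{i:03d}", samples=samples))
    return out
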