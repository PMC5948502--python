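import numpy as np
import pytest

from litenet import (
    BeatDataset,
    augment_balance,
    default_config,
    generate_record,
    make_folds,
    normalize_dataset,
    segment_beats,
)

# Pinned seeds of the bundled separable preset used by the heavier
# end-to-end fixtures.  Kept in one place so every test sees the same data.
PRESET_SEEDS = {"generator": 11, "augment": 12, "folds": 13, "train": 14}
PRESET_EPOCHS = 8


@pytest.fixture(scope="session")
def preset_record():
    """One synthetic record from the default separable preset (40 beats/class)."""
    cfg = default_config(seed=PRESET_SEEDS["generator"], n_beats_per_class=40)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def preset_dataset(preset_record):
    """Segmented (half-window 180), balanced to 60/class, Z-scored."""
    record, annotations = preset_record
    seg = segment_beats(record, annotations, half_window=180)
    dataset = BeatDataset(seg.segments, 180)
    dataset = augment_balance(
        dataset, per_class_target=60, seed=PRESET_SEEDS["augment"],
        records={record.id: record},
    )
    return normalize_dataset(dataset)


@pytest.fixture(scope="session")
def preset_folds(preset_dataset):
    return make_folds(preset_dataset, k=10, seed=PRESET_SEEDS["folds"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
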