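"""Segment a record into R-peak-centered beat windows, balance the classes by
translation + added-noise synthesis, and Z-score every segment.

Demonstrates the 1-s windows (half-window 180 at 360 Hz → 360-sample
segments) and the class-imbalance repair used before training.
"""

from litenet import (
    BeatDataset,
    GeneratorConfig,
    augment_balance,
    generate_record,
    normalize_dataset,
    segment_beats,
)

# deliberately imbalanced record: lots of N, few ectopics — like real data
config = GeneratorConfig(
    n_beats_per_class={"N": 40, "S": 5, "V": 10, "F": 8, "Q": 3}, seed=7
)
record, annotations = generate_record(config)

seg = segment_beats(record, annotations, half_window=180)
dataset = BeatDataset(seg.segments, half_window=180)
print(f"segments: {len(dataset)} of length {2 * dataset.half_window} "
      f"({seg.skipped} skipped at record edges)")
print(f"class counts before balancing: {dataset.class_counts}")

balanced = augment_balance(dataset, per_class_target=40, seed=8,
                           records={record.id: record})
print(f"class counts after balancing:  {balanced.class_counts}")
n_synth = sum(s.synthesized for s in balanced.segments)
print(f"synthesized segments: {n_synth} (originals untouched: "
      f"{len(balanced) - n_synth})")

normalized = normalize_dataset(balanced)
v = normalized.segments[0].values
print(f"after Z-score: mean {v.mean():+.2e}, sd {v.std():.6f} per segment")
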