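"""Ten-fold cross-validated evaluation on the bundled synthetic preset.

Builds the preset dataset (40 beats/class, balanced to 60/class, Z-scored),
assigns stratified folds, rotates train-on-9/test-on-1 over all ten folds and
prints the per-fold and averaged metrics.  Every segment is tested exactly
once; with fixed seeds the whole table is bit-reproducible.
"""

from litenet import (
    BeatDataset,
    TrainConfig,
    augment_balance,
    build_litenet_basic,
    crossvalidate,
    default_config,
    generate_record,
    make_folds,
    normalize_dataset,
    segment_beats,
)

record, annotations = generate_record(default_config(seed=11, n_beats_per_class=40))
seg = segment_beats(record, annotations, half_window=180)
dataset = normalize_dataset(
    augment_balance(BeatDataset(seg.segments, 180), per_class_target=60,
                    seed=12, records={record.id: record})
)
plan = make_folds(dataset, k=10, seed=13)

spec = build_litenet_basic(input_length=360)
cfg = TrainConfig(optimizer="adam", epochs=8, seed=14)
reports, summary = crossvalidate(spec, dataset, plan, cfg)

print("fold  accuracy  macro-F1  macro-AUC")
for f, r in enumerate(reports):
    print(f"  {f:>2}    {r.accuracy:.3f}    {r.macro_f1:.3f}     {r.macro_auc:.3f}")
print(f"\nmean accuracy:  {summary.accuracy:.4f}")
print(f"mean macro F1:  {summary.macro_f1:.4f}")
print(f"mean macro AUC: {summary.macro_auc:.4f} → rated {summary.auc_rating}")
print(f"pooled confusion total: {summary.confusion.total} "
      "(= every segment tested exactly once)")
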