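"""Beat segmentation, Z-score normalization, class balancing, k-fold plans.

Segmentation cuts a fixed window around each annotated R-peak: with half
window ``h`` the segment covers the half-open range ``[r-h, r+h)`` and has
exactly ``2h`` samples, the R-peak sitting at local index ``h``.  At 360 Hz
the two standard settings are ``h=180`` (1-s windows, length 360) and
``h=360`` (2-s windows, length 720).

Class balancing synthesizes additional segments for minority classes by
(i) translating the window start by a random integer shift, re-cutting from
the source record when it is available, and (ii) adding white noise scaled to
a fraction of the segment's own standard deviation.  Originals are never
modified; synthesized segments are flagged.

Fold plans are stratified: per class, fold sizes differ by at most one, folds
are pairwise disjoint, and their union covers the dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_io import AAMI_CLASSES, Annotation, Record


@dataclass
class BeatSegment:
    """A fixed-length beat window with label and provenance."""

    values: np.ndarray
    label: str
    source_record: str
    source_index: int  # R-peak sample in the source record
    synthesized: bool = False
    degenerate: bool = False  # constant segment hit by Z-score

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class BeatDataset:
    """A labelled collection of equal-length beat segments."""

    segments: list[BeatSegment]
    half_window: int

    def __post_init__(self) -> None:
        lengths = {len(s.values) for s in self.segments}
        if lengths and lengths != {2 * self.half_window}:
            raise ValueError(
                f"all segments must have length {2 * self.half_window}, got {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in AAMI_CLASSES}
        for s in self.segments:
            counts[s.label] += 1
        return counts

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)``: segment matrix and integer class labels."""
        from .signal_io import CLASS_TO_INDEX

        X = np.stack([s.values for s in self.segments])
        y = np.array([CLASS_TO_INDEX[s.label] for s in self.segments], dtype=np.int64)
        return X, y


@dataclass
class FoldPlan:
    """Assignment of each segment index to one of ``k`` disjoint folds."""

    k: int
    assignment: np.ndarray  # segment index -> fold id in [0, k)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.assignment.size and not (
            (self.assignment >= 0).all() and (self.assignment < self.k).all()
        ):
            raise ValueError("fold ids must lie in [0, k)")

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


@dataclass
class SegmentationResult:
    """Segments plus the count of annotations skipped at the record edges."""

    segments: list[BeatSegment]
    skipped: int


def segment_beats(
    record: Record, annotations: list[Annotation], half_window: int
) -> SegmentationResult:
    """Cut one ``[r-h, r+h)`` window per annotation; skip out-of-bounds beats.

    Every emitted segment has exactly ``2 * half_window`` samples.  The number
    of emitted segments plus the skip count equals the number of annotations.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    n = len(record)
    segments: list[BeatSegment] = []
    skipped = 0
    for ann in annotations:
        r = ann.sample_index
        if r - half_window < 0 or r + half_window > n:
            skipped += 1
            continue
        segments.append(
            BeatSegment(
                values=record.samples[r - half_window : r + half_window].copy(),
                label=ann.label,
                source_record=record.id,
                source_index=r,
            )
        )
    return SegmentationResult(segments, skipped)


def zscore_array(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score a series with the population standard deviation.

    Returns ``(normalized, degenerate)``; a constant input maps to all zeros
    with the degenerate flag set instead of raising.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot Z-score an empty series")
    mu = x.mean()
    sd = x.std()  # population (ddof=0)
    if sd == 0.0:
        return np.zeros_like(x), True
    return (x - mu) / sd, False


def zscore(segment: BeatSegment) -> BeatSegment:
    """Return a new segment normalized to mean 0 and (population) sd 1."""
    values, degenerate = zscore_array(segment.values)
    return BeatSegment(
        values=values,
        label=segment.label,
        source_record=segment.source_record,
        source_index=segment.source_index,
        synthesized=segment.synthesized,
        degenerate=degenerate,
    )


def normalize_dataset(dataset: BeatDataset) -> BeatDataset:
    """Z-score every segment of a dataset (new dataset, originals untouched)."""
    return BeatDataset([zscore(s) for s in dataset.segments], dataset.half_window)


def augmented_total(class_counts: dict[str, int], per_class_target: int) -> int:
    """Planned dataset size after balancing every class to ``per_class_target``.

    Pure accounting (no segments materialized): validates the target against
    the largest existing class and returns ``n_classes * per_class_target``.
    """
    if not class_counts:
        raise ValueError("class_counts is empty")
    if per_class_target < max(class_counts.values()):
        raise ValueError(
            "per_class_target must be >= the largest class count "
            "(downsampling is not supported)"
        )
    return len(class_counts) * per_class_target


def augment_balance(
    dataset: BeatDataset,
    per_class_target: int,
    shift_max: int = 18,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
    records: dict[str, Record] | None = None,
) -> BeatDataset:
    """Balance classes to ``per_class_target`` segments each by synthesis.

    Synthesized segments are copies of uniformly chosen same-class originals
    with (i) the window start translated by an integer shift drawn uniformly
    from ``[-shift_max, +shift_max]`` — re-cut from the source record when
    ``records`` provides it and the shifted window fits, else a circular
    shift — and (ii) added white noise with sd equal to ``noise_sd_fraction``
    times the segment's own sd.  Original segments appear unmodified (same
    objects) in the output.  Deterministic for a fixed seed.
    """
    counts = dataset.class_counts
    missing = [c for c in AAMI_CLASSES if counts[c] == 0]
    if missing:
        raise ValueError(f"cannot synthesize classes with zero originals: {missing}")
    if per_class_target < max(counts.values()):
        raise ValueError("per_class_target must be >= the largest class count")

    rng = np.random.default_rng(seed)
    h = dataset.half_window
    by_class: dict[str, list[BeatSegment]] = {c: [] for c in AAMI_CLASSES}
    for s in dataset.segments:
        by_class[s.label].append(s)

    out = list(dataset.segments)
    for c in AAMI_CLASSES:
        originals = by_class[c]
        need = per_class_target - len(originals)
        for _ in range(need):
            src = originals[int(rng.integers(0, len(originals)))]
            shift = int(rng.integers(-shift_max, shift_max + 1))
            rec = records.get(src.source_record) if records else None
            new_center = src.source_index + shift
            if rec is not None and 0 <= new_center - h and new_center + h <= len(rec):
                values = rec.samples[new_center - h : new_center + h].copy()
            else:
                values = np.roll(src.values, -shift)
            sd = values.std()
            values = values + rng.normal(0.0, noise_sd_fraction * sd, values.shape)
            out.append(
                BeatSegment(
                    values=values,
                    label=c,
                    source_record=src.source_record,
                    source_index=new_center,
                    synthesized=True,
                )
            )
    return BeatDataset(out, dataset.half_window)


def _canonical_order(dataset: BeatDataset) -> dict[str, list[int]]:
    """Per-class segment indices in an input-order-independent ordering."""
    keyed: dict[str, list[tuple]] = {c: [] for c in AAMI_CLASSES}
    for i, s in enumerate(dataset.segments):
        keyed[s.label].append(
            (s.source_record, s.source_index, s.synthesized, s.values.tobytes(), i)
        )
    return {c: [t[-1] for t in sorted(rows)] for c, rows in keyed.items()}


def make_folds(dataset: BeatDataset, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan: disjoint folds covering every segment.

    Per class, fold sizes differ by at most one (remainders round-robin).
    Segments are put into a canonical order before shuffling, so permuting
    the dataset's storage order does not change the multiset of segments in
    each fold for a given seed.
    """
    n = len(dataset)
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=np.int64)
    for c, indices in _canonical_order(dataset).items():
        if not indices:
            continue
        order = rng.permutation(len(indices))
        for pos, j in enumerate(order):
            assignment[indices[j]] = pos % k
    return FoldPlan(k, assignment)


# ---------------------------------------------------------------------------
# HDF5 dataset serialization (runtime artifact format used by the CLI)

def save_dataset(
    path, dataset: BeatDataset, foldplan: FoldPlan | None = None
) -> None:
    """Write a dataset (and optional fold plan) to an HDF5 file."""
    import h5py

    X, _ = dataset.to_arrays()
    with h5py.File(path, "w") as f:
        kw = dict(track_times=False)
        f.create_dataset("values", data=X, **kw)
        f.create_dataset(
            "labels",
            data=np.array([s.label for s in dataset.segments], dtype="S1"),
            **kw,
        )
        f.create_dataset(
            "source_record",
            data=np.array([s.source_record for s in dataset.segments], dtype="S64"),
            **kw,
        )
        f.create_dataset(
            "source_index",
            data=np.array([s.source_index for s in dataset.segments], dtype=np.int64),
            **kw,
        )
        f.create_dataset(
            "synthesized",
            data=np.array([s.synthesized for s in dataset.segments], dtype=bool),
            **kw,
        )
        f.attrs["half_window"] = dataset.half_window
        if foldplan is not None:
            f.create_dataset("fold", data=foldplan.assignment, **kw)
            f.attrs["k"] = foldplan.k


def load_dataset(path) -> tuple[BeatDataset, FoldPlan | None]:
    """Read a dataset (and fold plan, if present) from an HDF5 file."""
    import h5py

    with h5py.File(path, "r") as f:
        X = f["values"][...]
        labels = [b.decode() for b in f["labels"][...]]
        src = [b.decode() for b in f["source_record"][...]]
        idx = f["source_index"][...]
        syn = f["synthesized"][...]
        half_window = int(f.attrs["half_window"])
        segments = [
            BeatSegment(X[i], labels[i], src[i], int(idx[i]), bool(syn[i]))
            for i in range(X.shape[0])
        ]
        plan = None
        if "fold" in f:
            plan = FoldPlan(int(f.attrs["k"]), f["fold"][...])
    return BeatDataset(segments, half_window), plan
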