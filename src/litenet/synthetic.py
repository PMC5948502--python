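"""Seeded synthetic single-lead ECG generator with five beat morphologies.

Each beat is a sum of five Gaussian bumps standing in for the P, Q, R, S and
T waves; the R bump always has the largest absolute amplitude so that the
R-peak is the window argmax.  Class identity (N, S, V, F, Q) is encoded by
amplitude/width/centre differences and by the mean RR interval:

* ``N`` — textbook narrow-complex beat, upright P and T.
* ``S`` — supraventricular ectopic: narrow sharp R, inverted P, short RR.
* ``V`` — ventricular ectopic: wide high-amplitude R, no P, discordant
  (negative) T.
* ``F`` — fusion of N and V morphology: intermediate QRS width.
* ``Q`` — "unknown": low-amplitude irregular morphology, long variable RR.

Records are built by concatenating beats with jittered RR intervals, then
adding white noise and a sinusoidal baseline drift.  One RNG stream is
consumed per :func:`generate_record` call, in a fixed documented order
(RR jitter → noise → drift phase), so a seed pins the output bit-exactly.

No physiological realism is claimed; the purpose is a downloadable-data-free
test bed whose classes are morphologically separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import AAMI_CLASSES, Annotation, Record

_WAVE_NAMES = ("P", "Q", "R", "S", "T")
_R = 2  # index of the R wave in the 5-tuples


@dataclass(frozen=True)
class BeatTemplateParams:
    """Parameters of one beat class: five Gaussian bumps plus RR statistics.

    ``wave_centers`` are offsets in seconds relative to the R-peak;
    ``wave_widths`` are Gaussian standard deviations in seconds.
    """

    class_label: str
    wave_amplitudes: tuple[float, float, float, float, float]
    wave_centers: tuple[float, float, float, float, float]
    wave_widths: tuple[float, float, float, float, float]
    rr_interval_mean: float
    rr_interval_sd: float

    def __post_init__(self) -> None:
        if self.class_label not in AAMI_CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if any(w <= 0 for w in self.wave_widths):
            raise ValueError("wave widths must be positive")
        if not (0.4 <= self.rr_interval_mean <= 2.0):
            raise ValueError("rr_interval_mean must lie in [0.4, 2.0] s")
        amps = np.abs(self.wave_amplitudes)
        if amps[_R] < amps.max() or amps[_R] == 0:
            raise ValueError("the R bump must have the largest |amplitude|")


#: Default morphology presets, one per AAMI class.
DEFAULT_TEMPLATES: dict[str, BeatTemplateParams] = {
    "N": BeatTemplateParams(
        "N",
        wave_amplitudes=(0.15, -0.10, 1.00, -0.25, 0.35),
        wave_centers=(-0.20, -0.045, 0.0, 0.045, 0.25),
        wave_widths=(0.030, 0.012, 0.012, 0.015, 0.060),
        rr_interval_mean=0.80, rr_interval_sd=0.03,
    ),
    "S": BeatTemplateParams(
        "S",
        wave_amplitudes=(-0.12, -0.05, 0.70, -0.15, 0.20),
        wave_centers=(-0.14, -0.04, 0.0, 0.035, 0.18),
        wave_widths=(0.025, 0.010, 0.007, 0.012, 0.045),
        rr_interval_mean=0.55, rr_interval_sd=0.05,
    ),
    "V": BeatTemplateParams(
        "V",
        wave_amplitudes=(0.0, -0.30, 1.40, -0.60, -0.45),
        wave_centers=(-0.20, -0.10, 0.0, 0.12, 0.32),
        wave_widths=(0.030, 0.040, 0.055, 0.060, 0.080),
        rr_interval_mean=0.75, rr_interval_sd=0.08,
    ),
    "F": BeatTemplateParams(
        "F",
        wave_amplitudes=(0.08, -0.20, 1.10, -0.40, -0.05),
        wave_centers=(-0.20, -0.07, 0.0, 0.08, 0.28),
        wave_widths=(0.030, 0.025, 0.032, 0.040, 0.070),
        rr_interval_mean=0.78, rr_interval_sd=0.05,
    ),
    "Q": BeatTemplateParams(
        "Q",
        wave_amplitudes=(0.05, 0.15, 0.55, 0.20, -0.15),
        wave_centers=(-0.25, -0.08, 0.0, 0.06, 0.22),
        wave_widths=(0.050, 0.030, 0.020, 0.035, 0.050),
        rr_interval_mean=0.90, rr_interval_sd=0.12,
    ),
}


@dataclass
class GeneratorConfig:
    """Configuration of one synthetic record.

    ``n_beats_per_class`` maps class label → beat count (zero allowed);
    ``noise_sd`` is the white-noise standard deviation in signal units;
    baseline drift is ``A·sin(2π f t + φ)`` with a random phase φ.
    """

    fs: float = 360.0
    n_beats_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 40 for c in AAMI_CLASSES}
    )
    noise_sd: float = 0.03
    baseline_drift_amplitude: float = 0.05
    baseline_drift_freq: float = 0.33
    seed: int = 0
    templates: dict[str, BeatTemplateParams] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n < 0 for n in self.n_beats_per_class.values()):
            raise ValueError("beat counts must be >= 0")


def default_config(seed: int = 0, n_beats_per_class: int = 40) -> GeneratorConfig:
    """The bundled separable preset: 360 Hz, equal class counts, mild noise."""
    return GeneratorConfig(
        n_beats_per_class={c: n_beats_per_class for c in AAMI_CLASSES}, seed=seed
    )


def beat_waveform(params: BeatTemplateParams, fs: float, length: int) -> np.ndarray:
    """Evaluate one beat template on a sample grid of ``length`` samples.

    The R-peak sits at the window centre, index ``length // 2``.  The output
    is the sum of the five Gaussian bumps; all-zero amplitudes give an
    all-zero series.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    t = (np.arange(length) - length // 2) / fs
    y = np.zeros(length)
    for a, c, w in zip(params.wave_amplitudes, params.wave_centers, params.wave_widths):
        if w <= 0:
            raise ValueError("wave widths must be positive")
        if a != 0.0:
            y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return y


def _beat_order(config: GeneratorConfig) -> list[str]:
    """Deterministic round-robin interleave of the requested classes."""
    remaining = {c: config.n_beats_per_class.get(c, 0) for c in AAMI_CLASSES}
    order: list[str] = []
    while any(v > 0 for v in remaining.values()):
        for c in AAMI_CLASSES:
            if remaining[c] > 0:
                order.append(c)
                remaining[c] -= 1
    return order


def generate_record(
    config: GeneratorConfig, record_id: str = "synthetic"
) -> tuple[Record, list[Annotation]]:
    """Generate one annotated record; identical config+seed → identical output.

    The RNG is consumed in a fixed order — per-beat RR jitter, then the white
    noise array, then the drift phase — so seeds remain stable even when
    ``noise_sd`` or the drift amplitude is zero.
    """
    order = _beat_order(config)
    if not order:
        raise ValueError("total beat count must be >= 1")
    rng = np.random.default_rng(config.seed)
    fs = config.fs

    # 1. RR jitter (clipped to the physiological window the templates assume)
    rr = np.empty(len(order))
    for i, label in enumerate(order):
        tpl = config.templates[label]
        rr[i] = np.clip(rng.normal(tpl.rr_interval_mean, tpl.rr_interval_sd), 0.4, 2.0)

    margin = int(round(0.8 * fs))
    positions = np.empty(len(order), dtype=np.int64)
    positions[0] = margin
    positions[1:] = margin + np.cumsum(np.round(rr[:-1] * fs).astype(np.int64))
    total_len = int(positions[-1]) + margin

    clean = np.zeros(total_len)
    wlen = int(round(1.2 * fs))  # per-beat render window, covers all bumps
    for pos, label in zip(positions, order):
        wave = beat_waveform(config.templates[label], fs, wlen)
        start = int(pos) - wlen // 2
        lo, hi = max(start, 0), min(start + wlen, total_len)
        clean[lo:hi] += wave[lo - start : hi - start]

    # 2. white noise (drawn even at sd=0 to keep the stream layout stable)
    noise = rng.normal(0.0, config.noise_sd, total_len)
    # 3. drift phase
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(total_len) / fs
    drift = config.baseline_drift_amplitude * np.sin(
        2.0 * np.pi * config.baseline_drift_freq * t + phase
    )

    record = Record(id=record_id, fs=fs, samples=clean + noise + drift)
    annotations = [Annotation(int(p), lab) for p, lab in zip(positions, order)]
    return record, annotations
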