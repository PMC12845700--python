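"""Synthetic multi-channel sEMG recordings with known ground truth.

Emulates the structure of a Ninapro-DB1-style acquisition: a 10-channel
recording sampled at 100 Hz in which rest intervals alternate with gesture
executions, each gesture class carrying a distinct low-frequency (0-1 Hz)
amplitude envelope.  Stored labels can be jittered relative to the true
activity boundaries so that boundary-refinement algorithms have something
to correct, while the true boundaries are kept alongside for scoring.

Rest intervals contain zero-mean Gaussian noise only; gesture intervals
contain a rectified sum of low-frequency sinusoids (the class template)
scaled by a per-class, per-channel gain profile, plus the same noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.io import savemat


@dataclass(frozen=True)
class GestureTemplate:
    """Low-frequency spectral recipe for one gesture class."""

    freqs_hz: np.ndarray      # component frequencies, all inside the band
    amps: np.ndarray          # component amplitudes

    def envelope(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        """Sample one rectified low-frequency envelope of length ``n``.

        Phases are redrawn per call so repetitions of the same gesture are
        correlated in spectrum but not identical in waveform.
        """
        t = np.arange(n) / fs
        phases = rng.uniform(0.0, 2.0 * np.pi, size=self.freqs_hz.size)
        wave = np.zeros(n)
        for f, a, p in zip(self.freqs_hz, self.amps, phases):
            wave += a * np.sin(2.0 * np.pi * f * t + p)
        return np.abs(wave)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording generator."""

    n_channels: int = 10
    fs: float = 100.0
    n_classes: int = 8
    n_repetitions: int = 10
    motion_duration: tuple[int, int] = (900, 120)   # mean, jitter (samples)
    rest_duration: tuple[int, int] = (300, 50)      # mean, jitter (samples)
    envelope_band: tuple[float, float] = (0.1, 1.0)  # Hz
    channel_gain_spread: float = 0.3
    noise_sd: float = 0.2
    boundary_jitter: int = 30                        # samples, symmetric
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.envelope_band
        if not (0.0 < lo < hi < self.fs / 2):
            raise ValueError("envelope band must lie inside (0, fs/2)")
        if self.motion_duration[0] <= 0 or self.rest_duration[0] <= 0:
            raise ValueError("durations must be positive")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be nonnegative")


@dataclass
class SegmentTruth:
    """True boundaries of one gesture execution (inclusive samples)."""

    onset: int
    offset: int
    gesture: int
    repetition: int


@dataclass
class Recording:
    """A multi-channel sEMG time series with per-sample annotations.

    ``emg`` is channels x T; ``labels`` holds the gesture id per sample
    (0 = rest); ``repetitions`` holds the repetition id per sample (0 on
    rest).  ``truth`` is only populated for synthetic data.
    """

    emg: np.ndarray
    fs: float
    labels: np.ndarray
    repetitions: np.ndarray
    truth: list[SegmentTruth] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        self.repetitions = np.asarray(self.repetitions, dtype=int)
        t = self.emg.shape[1]
        if self.labels.shape != (t,) or self.repetitions.shape != (t,):
            raise ValueError("labels and repetitions must have length T")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]


def generate_gesture_library(
    n_classes: int,
    envelope_band: tuple[float, float] = (0.1, 1.0),
    seed: int = 0,
    n_components: tuple[int, int] = (2, 4),
) -> list[GestureTemplate]:
    """Create per-class low-frequency spectral templates.

    Each class receives a dominant frequency on a deterministic grid across
    the band (so classes are spectrally distinct by construction) plus a
    random number of secondary components drawn inside the band.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 gesture classes")
    lo, hi = envelope_band
    if not (0.0 < lo < hi):
        raise ValueError("invalid envelope band")
    rng = np.random.default_rng(seed)
    dominants = lo + (np.arange(n_classes) + 0.5) / n_classes * (hi - lo)
    templates = []
    for c in range(n_classes):
        n_extra = int(rng.integers(n_components[0], n_components[1] + 1)) - 1
        extra_f = rng.uniform(lo, hi, size=n_extra)
        extra_a = rng.uniform(0.2, 0.5, size=n_extra)
        freqs = np.concatenate([[dominants[c]], extra_f])
        amps = np.concatenate([[1.0], extra_a])
        templates.append(GestureTemplate(freqs_hz=freqs, amps=amps))
    return templates


def _jittered(mean: int, jitter: int, rng: np.random.Generator) -> int:
    lo = max(2, mean - jitter)
    hi = mean + jitter
    return int(rng.integers(lo, hi + 1))


def generate_recording(config: SynthConfig) -> Recording:
    """Synthesize one recording with alternating rest/motion runs.

    Gesture order is class 1..n_classes within each repetition block, each
    execution preceded by a rest interval.  Stored labels are shifted from
    the true activity boundaries by a symmetric uniform jitter of up to
    ``boundary_jitter`` samples; the true boundaries are returned in
    ``truth`` so refinement can be scored.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = generate_gesture_library(
        config.n_classes, config.envelope_band, seed=config.seed
    )
    # Per-class per-channel gain profile, fixed for the whole recording.
    gains = 1.0 + config.channel_gain_spread * rng.standard_normal(
        (config.n_classes, config.n_channels)
    )
    gains = np.clip(gains, 0.2, None)

    chunks: list[np.ndarray] = []
    truth: list[SegmentTruth] = []
    pos = 0
    for rep in range(1, config.n_repetitions + 1):
        for cls in range(1, config.n_classes + 1):
            rest_n = _jittered(*config.rest_duration, rng)
            chunks.append(np.zeros((config.n_channels, rest_n)))
            pos += rest_n
            motion_n = _jittered(*config.motion_duration, rng)
            env = templates[cls - 1].envelope(motion_n, config.fs, rng)
            env *= rng.uniform(0.8, 1.2)
            motion = gains[cls - 1][:, None] * env[None, :]
            chunks.append(motion)
            truth.append(
                SegmentTruth(onset=pos, offset=pos + motion_n - 1,
                             gesture=cls, repetition=rep)
            )
            pos += motion_n
    rest_n = _jittered(*config.rest_duration, rng)
    chunks.append(np.zeros((config.n_channels, rest_n)))
    pos += rest_n

    emg = np.concatenate(chunks, axis=1)
    if config.noise_sd > 0:
        emg = emg + config.noise_sd * rng.standard_normal(emg.shape)

    labels = np.zeros(pos, dtype=int)
    repetitions = np.zeros(pos, dtype=int)
    j = config.boundary_jitter
    prev_end = -1
    for k, seg in enumerate(truth):
        on = seg.onset + (int(rng.integers(-j, j + 1)) if j else 0)
        off = seg.offset + (int(rng.integers(-j, j + 1)) if j else 0)
        on = max(on, prev_end + 2)
        off = min(off, pos - 2)
        if off <= on:
            on, off = seg.onset, seg.offset
        labels[on:off + 1] = seg.gesture
        repetitions[on:off + 1] = seg.repetition
        prev_end = off
    return Recording(emg=emg, fs=config.fs, labels=labels,
                     repetitions=repetitions, truth=truth)


def _slice_recording(rec: Recording, keep_reps: set[int]) -> Recording:
    """Cut out the chunks of a recording belonging to ``keep_reps``.

    Each true motion run owns the surrounding rest up to the midpoints of
    its neighbouring rest intervals, so the kept chunks retain context for
    boundary refinement.  True boundaries are remapped to the new indices.
    """
    n = rec.n_samples
    mids = [0]
    for a, b in zip(rec.truth[:-1], rec.truth[1:]):
        mids.append((a.offset + b.onset) // 2)
    mids.append(n)

    pieces, truth, offset = [], [], 0
    lab_pieces, rep_pieces = [], []
    for k, seg in enumerate(rec.truth):
        if seg.repetition not in keep_reps:
            continue
        a, b = mids[k], mids[k + 1]
        pieces.append(rec.emg[:, a:b])
        lab_pieces.append(rec.labels[a:b])
        rep_pieces.append(rec.repetitions[a:b])
        truth.append(SegmentTruth(onset=seg.onset - a + offset,
                                  offset=seg.offset - a + offset,
                                  gesture=seg.gesture,
                                  repetition=seg.repetition))
        offset += b - a
    if not pieces:
        raise ValueError("requested repetition set selects no segments")
    return Recording(emg=np.concatenate(pieces, axis=1), fs=rec.fs,
                     labels=np.concatenate(lab_pieces),
                     repetitions=np.concatenate(rep_pieces),
                     truth=truth)


def make_benchmark(
    config: SynthConfig,
    test_repetitions: Sequence[int] = (2, 5, 10),
) -> tuple[Recording, Recording]:
    """Generate a train/test recording pair split by repetition index.

    The canonical protocol holds out repetitions {2, 5, 10} for testing and
    trains on the remaining seven.  Both partitions must contain every
    gesture class.
    """
    config.validate()
    test_set = set(int(r) for r in test_repetitions)
    all_reps = set(range(1, config.n_repetitions + 1))
    if not test_set <= all_reps:
        raise ValueError(
            f"test repetitions {sorted(test_set - all_reps)} absent from "
            f"the {config.n_repetitions}-repetition protocol"
        )
    train_set = all_reps - test_set
    if not train_set:
        raise ValueError("no repetitions left for training")
    rec = generate_recording(config)
    train = _slice_recording(rec, train_set)
    test = _slice_recording(rec, test_set)
    for name, part in (("train", train), ("test", test)):
        present = {t.gesture for t in part.truth}
        if present != set(range(1, config.n_classes + 1)):
            raise ValueError(f"class missing from {name} partition")
    return train, test


def write_mat(rec: Recording, path: str) -> None:
    """Write a recording as a MAT-file with keys emg, stimulus, repetition.

    ``emg`` is stored T x channels, matching the DB1 container layout.
    """
    savemat(path, {
        "emg": rec.emg.T,
        "stimulus": rec.labels.reshape(-1, 1).astype(float),
        "repetition": rec.repetitions.reshape(-1, 1).astype(float),
    })


def write_delimited(rec: Recording, path: str, sep: str = "\t") -> None:
    """Write a recording as delimited text: ch1..chC, stimulus, repetition."""
    header = [f"ch{i + 1}" for i in range(rec.n_channels)]
    header += ["stimulus", "repetition"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(header)
        for t in range(rec.n_samples):
            row = [f"{v:.17g}" for v in rec.emg[:, t]]
            row += [int(rec.labels[t]), int(rec.repetitions[t])]
            w.writerow(row)
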