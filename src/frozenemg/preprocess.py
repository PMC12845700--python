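"""Loading, filtering, motion segmentation and boundary refinement.

Motion segments are cut from per-sample gesture labels, then refined by a
multi-channel generalized-likelihood-ratio (GLR) change-point scan: each
channel is modelled as a zero-mean Gaussian whose variance switches
between a rest state and a motion state, the best single change point is
located inside an expanded search window around each labelled boundary,
and the per-channel detections are fused by voting — earliest onset,
latest offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import loadmat

from .synthetic import Recording

log = logging.getLogger(__name__)


@dataclass
class MotionSegment:
    """One gesture execution window (channels x time)."""

    data: np.ndarray
    gesture: int
    repetition: int
    raw_bounds: tuple[int, int]            # inclusive sample indices
    refined_bounds: tuple[int, int] | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        on, off = self.raw_bounds
        if on >= off:
            raise ValueError("segment onset must precede offset")


@dataclass(frozen=True)
class GlrConfig:
    """Configuration of the GLR boundary-refinement scan."""

    expansion_fraction: float = 0.25   # context added on each side
    min_state_len: int = 10            # samples per state
    var_floor: float = 1e-12           # relative variance floor

    def __post_init__(self) -> None:
        if self.expansion_fraction < 0:
            raise ValueError("expansion_fraction must be nonnegative")
        if self.min_state_len < 2:
            raise ValueError("min_state_len must be at least 2")


def load_recording(path: str | Path, dialect: str = "mat",
                   fs: float = 100.0) -> Recording:
    """Load a recording from a MAT-file or delimited-text container.

    The MAT dialect expects keys ``emg`` (T x channels), ``stimulus`` and
    ``repetition``; the delimited dialect expects columns ch1..chC,
    stimulus, repetition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "mat":
        raw = loadmat(str(path))
        for key in ("emg", "stimulus", "repetition"):
            if key not in raw:
                raise ValueError(f"MAT-file missing required key '{key}'")
        emg = np.asarray(raw["emg"], dtype=float).T
        labels = np.asarray(raw["stimulus"]).ravel()
        reps = np.asarray(raw["repetition"]).ravel()
    elif dialect == "delimited":
        df = pd.read_csv(path, sep=None, engine="python")
        for col in ("stimulus", "repetition"):
            if col not in df.columns:
                raise ValueError(f"delimited file missing column '{col}'")
        chan_cols = [c for c in df.columns if c.startswith("ch")]
        if not chan_cols:
            raise ValueError("delimited file missing channel columns 'ch*'")
        try:
            emg = df[chan_cols].to_numpy(dtype=float).T
            labels = df["stimulus"].to_numpy()
            reps = df["repetition"].to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric data in {path}") from exc
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    if not np.all(np.isfinite(emg)):
        raise ValueError("non-finite samples in emg matrix")
    if labels.shape[0] != emg.shape[1]:
        raise ValueError("label vector length does not match emg")
    return Recording(emg=emg, fs=fs, labels=labels.astype(int),
                     repetitions=reps.astype(int))


def lowpass_filter(x: np.ndarray, cutoff: float = 1.0, order: int = 1,
                   fs: float = 100.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Applied forward-backward (``filtfilt``) so segment boundaries are not
    shifted by filter delay; the effective magnitude response is the
    squared one-pass response.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    if order < 1:
        raise ValueError("order must be at least 1")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def extract_segments(rec: Recording) -> list[MotionSegment]:
    """Cut one segment per maximal nonzero-label run (inclusive bounds)."""
    labels = rec.labels
    segments: list[MotionSegment] = []
    boundaries = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    for a, b in zip(starts, ends):
        g = int(labels[a])
        if g == 0:
            continue
        rep = int(rec.repetitions[a])
        segments.append(MotionSegment(
            data=rec.emg[:, a:b].copy(), gesture=g, repetition=rep,
            raw_bounds=(int(a), int(b - 1)),
        ))
    return segments


def _seg_cost(cum2: np.ndarray, i: int, j: int, floor: float) -> float:
    """Gaussian (zero-mean) negative log-likelihood of samples [i, j)."""
    n = j - i
    ms = (cum2[j] - cum2[i]) / n
    return 0.5 * n * np.log(ms + floor)


def _best_change(x: np.ndarray, min_len: int, floor: float
                 ) -> tuple[int | None, float]:
    """Best single variance change point in ``x`` and its GLR gain.

    Returns the index (relative to ``x``) splitting the window into two
    homogeneous-variance states, or None when no candidate beats a
    BIC-style penalty — the no-change outcome on stationary noise.
    """
    n = x.size
    if n < 2 * min_len:
        return None, 0.0
    cum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    full = _seg_cost(cum2, 0, n, floor)
    ts = np.arange(min_len, n - min_len + 1)
    nl, nr = ts, n - ts
    msl = (cum2[ts] - cum2[0]) / nl
    msr = (cum2[n] - cum2[ts]) / nr
    split = 0.5 * nl * np.log(msl + floor) + 0.5 * nr * np.log(msr + floor)
    k = int(np.argmin(split))
    gain = full - split[k]
    if gain <= np.log(n):           # penalty: one extra change + variance
        return None, float(gain)
    return int(ts[k]), float(gain)


def _run_limits(labels: np.ndarray, on: int, off: int) -> tuple[int, int]:
    """Nearest foreign nonzero-label samples around the run [on, off]."""
    before = np.flatnonzero(labels[:on] != 0)
    after = np.flatnonzero(labels[off + 1:] != 0)
    lo = int(before[-1]) + 1 if before.size else 0
    hi = int(after[0]) + off if after.size else labels.size - 1
    return lo, hi


def refine_boundaries_glr(rec: Recording, seg: MotionSegment,
                          cfg: GlrConfig | None = None) -> MotionSegment:
    """Refine a segment's boundaries by per-channel GLR scans plus voting.

    The search window around each labelled boundary is expanded by
    ``expansion_fraction`` of the segment length per side, clipped at
    neighbouring labelled runs and at the recording edges.  Onset and
    offset are scanned independently on each channel's squared amplitude;
    the fused onset is the earliest channel detection and the fused offset
    the latest.  When no channel detects a change the raw bounds are kept.
    """
    cfg = cfg or GlrConfig()
    on, off = seg.raw_bounds
    seg_len = off - on + 1
    exp = max(int(round(cfg.expansion_fraction * seg_len)), 2 * cfg.min_state_len)
    lo_lim, hi_lim = _run_limits(rec.labels, on, off)

    on_a = max(0, on - exp, lo_lim)
    on_b = min(on + exp, off)
    off_a = max(off - exp, on)
    off_b = min(off + exp, rec.n_samples - 1, hi_lim)

    floor_scale = float(np.mean(rec.emg[:, on_a:off_b + 1] ** 2)) or 1.0
    floor = cfg.var_floor * floor_scale

    onsets, offsets = [], []
    for c in range(rec.n_channels):
        win = rec.emg[c, on_a:on_b + 1]
        t, _ = _best_change(win, cfg.min_state_len, floor)
        if t is not None:
            onsets.append(on_a + t)
        win = rec.emg[c, off_a:off_b + 1]
        t, _ = _best_change(win, cfg.min_state_len, floor)
        if t is not None:
            offsets.append(off_a + t - 1)

    if (on_b - on_a + 1) < 2 * cfg.min_state_len or \
            (off_b - off_a + 1) < 2 * cfg.min_state_len:
        log.warning("degenerate GLR window for gesture %d rep %d; "
                    "keeping raw bounds", seg.gesture, seg.repetition)
        onsets, offsets = [], []

    new_on = min(onsets) if onsets else on
    new_off = max(offsets) if offsets else off
    if not onsets and not offsets:
        log.warning("GLR found no variance change for gesture %d rep %d; "
                    "falling back to raw bounds", seg.gesture, seg.repetition)
    if new_off <= new_on:
        new_on, new_off = on, off
    refined = replace(seg)
    refined.refined_bounds = (int(new_on), int(new_off))
    refined.data = rec.emg[:, new_on:new_off + 1].copy()
    return refined


def standardize_length(seg: MotionSegment, L: int = 1100) -> MotionSegment:
    """Zero-pad (tail) or truncate (keep head) the segment to L samples."""
    if L < 1:
        raise ValueError("L must be positive")
    data = seg.data
    n = data.shape[1]
    if n == L:
        out = data.copy()
    elif n < L:
        out = np.zeros((data.shape[0], L))
        out[:, :n] = data
    else:
        out = data[:, :L].copy()
    std = replace(seg)
    std.data = out
    return std


def welch_psd(x: np.ndarray, fs: float = 100.0, nperseg: int = 512
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density: Hamming window, 50% overlap, 512 FFT."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < nperseg:
        raise ValueError(f"signal shorter than the {nperseg}-sample window")
    return sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                     noverlap=nperseg // 2, nfft=nperseg)
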