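"""Filtering, segmentation and automatic artifact rejection.

The acquisition contract fixes a 0.5–30 Hz bandpass and a 50 Hz notch; both
are applied zero-phase (forward–backward) so the alpha band suffers no
frequency-dependent delay.  Recordings are then cut into successive,
overlapping 2-s segments and segments are rejected by simple amplitude /
gradient / flatline criteria that stand in for the study's (unpublished)
rejection algorithm — the thresholds are configurable and testable against
the synthetic generator's injected-event ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import AllSegmentsRejectedError
from .io import Recording

DEFAULT_SEGMENT_S = 2.0
DEFAULT_OVERLAP = 0.5


@dataclass
class RejectionCriteria:
    """Thresholds for automatic segment rejection (all in µV).

    A segment is rejected if ANY channel violates any criterion.
    ``min_retained`` is the retained-segment count below which a recording's
    spectrum is flagged low-confidence downstream.
    """

    p2p_max_uv: float = 100.0
    flat_range_uv: float = 0.5
    jump_max_uv: float = 50.0
    min_retained: int = 30


@dataclass
class SegmentSet:
    """Windowed view of one recording: ``segments`` is (n_segments, channels, L)."""

    segments: np.ndarray
    fs_hz: float
    step: int
    channel_labels: tuple
    provenance: str = ""
    retained_mask: np.ndarray = None
    rejection_reasons: list = field(default_factory=list)

    def __post_init__(self):
        if self.retained_mask is None:
            self.retained_mask = np.ones(len(self.segments), dtype=bool)
        if not self.rejection_reasons:
            self.rejection_reasons = [None] * len(self.segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    @property
    def segment_length(self) -> int:
        return self.segments.shape[-1]

    def retained(self) -> np.ndarray:
        return self.segments[self.retained_mask]

    def segment_times(self) -> np.ndarray:
        """Onset time (s) of each segment in the source recording."""
        return np.arange(self.n_segments) * self.step / self.fs_hz


def bandpass(rec: Recording, low: float = 0.5, high: float = 30.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth bandpass.

    The effective forward–backward response keeps the passband flat within
    1 dB and attenuates by well over 20 dB one octave outside the band.
    """
    if low >= high:
        raise ValueError(f"band edges inverted: low={low} >= high={high}")
    if high >= rec.fs_hz / 2:
        raise ValueError(f"high edge {high} Hz at or above Nyquist ({rec.fs_hz / 2} Hz)")
    if low <= 0:
        raise ValueError("low edge must be positive")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs_hz, output="sos")
    return rec.copy_with(sps.sosfiltfilt(sos, rec.data, axis=1))


def notch(rec: Recording, f0: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch: ≥20 dB at ``f0``, <1 dB at ``f0`` ± 5 Hz."""
    if f0 >= rec.fs_hz / 2:
        raise ValueError(f"notch frequency {f0} Hz at or above Nyquist")
    b, a = sps.iirnotch(f0, q, fs=rec.fs_hz)
    return rec.copy_with(sps.filtfilt(b, a, rec.data, axis=1))


def segment(
    rec: Recording,
    length_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> SegmentSet:
    """Cut a recording into successive overlapping segments.

    ``n_segments = floor((N - L) / step) + 1`` with ``L = round(length_s·fs)``
    and ``step = round(L·(1 - overlap))``.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    L = int(round(length_s * rec.fs_hz))
    step = int(round(L * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: step underflows to zero samples")
    N = rec.n_samples
    if N < L:
        raise ValueError(f"recording ({N} samples) shorter than one segment ({L})")
    n_seg = (N - L) // step + 1
    idx = np.arange(n_seg)[:, None] * step + np.arange(L)[None, :]
    segments = rec.data[:, idx].transpose(1, 0, 2).copy()
    return SegmentSet(
        segments=segments,
        fs_hz=rec.fs_hz,
        step=step,
        channel_labels=rec.channel_labels,
        provenance=rec.subject_id or "recording",
    )


def _segment_reasons(seg: np.ndarray, c: RejectionCriteria) -> str | None:
    rng = seg.max(axis=1) - seg.min(axis=1)
    reasons = []
    if np.any(rng > c.p2p_max_uv):
        reasons.append("amplitude")
    if np.any(rng < c.flat_range_uv):
        reasons.append("flatline")
    if seg.shape[1] > 1 and np.any(np.abs(np.diff(seg, axis=1)) > c.jump_max_uv):
        reasons.append("gradient")
    return "+".join(reasons) if reasons else None


def reject_artifacts(segs: SegmentSet, criteria: RejectionCriteria | None = None) -> SegmentSet:
    """Flag segments violating amplitude, flatline or gradient thresholds.

    Returns a new :class:`SegmentSet`; an already-rejected segment stays
    rejected.  Raises :class:`AllSegmentsRejectedError` when nothing survives,
    since the downstream averaged spectrum would be undefined.
    """
    c = criteria or RejectionCriteria()
    mask = segs.retained_mask.copy()
    reasons = list(segs.rejection_reasons)
    for i in range(segs.n_segments):
        if not mask[i]:
            continue
        r = _segment_reasons(segs.segments[i], c)
        if r is not None:
            mask[i] = False
            reasons[i] = r
    if not mask.any():
        raise AllSegmentsRejectedError(
            f"all {segs.n_segments} segments of '{segs.provenance}' rejected"
        )
    return replace(segs, retained_mask=mask, rejection_reasons=reasons)


def rejection_report(segs: SegmentSet) -> dict:
    """Per-recording counts and reasons, serializable as JSON."""
    reasons = [r for r in segs.rejection_reasons if r]
    counts: dict = {}
    for r in reasons:
        for part in r.split("+"):
            counts[part] = counts.get(part, 0) + 1
    return {
        "recording": segs.provenance,
        "n_segments": segs.n_segments,
        "n_retained": segs.n_retained,
        "n_rejected": segs.n_segments - segs.n_retained,
        "reason_counts": counts,
    }
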