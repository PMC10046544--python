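"""Averaged power spectra from retained segments.

Each retained 2-s segment is mean-subtracted, Hann-windowed, Fourier
transformed and converted to a one-sided power spectral density normalized by
the window power; segment spectra are then averaged — a Welch-type estimate
with the artifact-rejection mask applied between segmentation and averaging.

With 2-s segments and no zero padding the frequency grid has exactly 0.5 Hz
resolution, so the 7 and 13 Hz alpha-band edges fall on bins and band sums
are unambiguous.  Units are µV²/Hz; summing ``power × df`` over all bins
recovers the time-domain variance (Parseval, within ~2% for stationary
signals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .preprocess import SegmentSet


@dataclass
class PowerSpectrum:
    """Per-channel averaged power spectral density (µV²/Hz)."""

    freqs_hz: np.ndarray
    power: np.ndarray  # channels × freqs
    channel_labels: tuple
    n_segments_used: int
    window: str = "hann"

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def band_slice(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of bins with ``low <= f <= high`` (inclusive)."""
        return (self.freqs_hz >= low - 1e-9) & (self.freqs_hz <= high + 1e-9)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"freq_hz": self.freqs_hz})
        for i, lab in enumerate(self.channel_labels):
            out[lab] = self.power[i]
        return out


def compute_spectrum(segs: SegmentSet, window: str = "hann") -> PowerSpectrum:
    """Average one-sided periodograms over the retained segments."""
    kept = segs.retained()
    if len(kept) == 0:
        raise ValueError("no retained segments: spectrum undefined")
    L = segs.segment_length
    fs = segs.fs_hz
    w = get_window(window, L, fftbins=True)
    x = kept - kept.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(x * w, axis=-1)
    scale = 2.0 / (fs * np.sum(w ** 2))
    p = (np.abs(X) ** 2) * scale
    p[..., 0] /= 2.0
    if L % 2 == 0:
        p[..., -1] /= 2.0
    return PowerSpectrum(
        freqs_hz=np.fft.rfftfreq(L, 1.0 / fs),
        power=p.mean(axis=0),
        channel_labels=segs.channel_labels,
        n_segments_used=len(kept),
        window=window,
    )
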