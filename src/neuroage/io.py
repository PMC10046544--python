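"""Multichannel EEG exchange in EDF and validation of the acquisition contract.

The study contract is a 19-channel 10–20 montage (monopolar, linked-ears
reference), 256 Hz sampling, at least 6 minutes of eyes-closed rest.  EDF is
used as the exchange format: 16-bit samples, physical unit fixed to µV.
Reading goes through :func:`mne.io.read_raw_edf`; writing is a minimal plain
EDF encoder (one-second data records), sufficient for round-tripping the
synthetic recordings this package produces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedLayoutError

#: The 19 scalp sites of the study montage, in conventional anterior→posterior
#: order.  T3/T4/T5/T6 naming is taken literally (no T7/T8 aliasing).
STANDARD_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

DEFAULT_FS_HZ = 256.0
MIN_DURATION_S = 360.0  # "at least 6 min"

_DIG_MAX = 32767  # symmetric 16-bit range so gain is exact


@dataclass
class Recording:
    """One subject-visit of multichannel EEG, in µV.

    ``data`` is channels × samples; ``annotations`` is a list of
    ``(onset_s, duration_s, label)`` triples.
    """

    data: np.ndarray
    channel_labels: tuple
    fs_hz: float
    reference: str = "linked-ears"
    subject_id: str = ""
    visit: str = ""
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(l.lower() for l in self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            channel_labels=self.channel_labels,
            fs_hz=self.fs_hz,
            reference=self.reference,
            subject_id=self.subject_id,
            visit=self.visit,
            annotations=list(self.annotations),
        )


def _fmt_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float8(v: float) -> bytes:
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot format {v} in 8 bytes")


def write_recording(rec: Recording, path) -> Path:
    """Write ``rec`` to ``path`` as plain 16-bit EDF (µV, 1-s data records).

    The sampling rate must be a positive integer (samples per one-second
    record).  A trailing partial second is truncated with a warning.
    In-memory annotations are not serialized (plain EDF has no annotation
    channel).
    """
    path = Path(path)
    fs = rec.fs_hz
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_records * fs != rec.n_samples:
        warnings.warn("truncating trailing partial second for EDF export")
    data = rec.data[:, : n_records * fs]
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    gains = phys_max / _DIG_MAX
    digital = np.round(data / gains[:, None]).astype("<i2")

    header = b"".join(
        [
            _fmt_ascii("0", 8),
            _fmt_ascii(rec.subject_id[:80], 80),
            _fmt_ascii(f"visit:{rec.visit} ref:{rec.reference}"[:80], 80),
            _fmt_ascii("01.01.00", 8),
            _fmt_ascii("00.00.00", 8),
            _fmt_ascii(str(256 * (ns + 1)), 8),
            _fmt_ascii("", 44),
            _fmt_ascii(str(n_records), 8),
            _fmt_ascii("1", 8),
            _fmt_ascii(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_fmt_ascii(l[:16], 16) for l in rec.channel_labels),
            b"".join(_fmt_ascii("AgCl electrode", 80) for _ in range(ns)),
            b"".join(_fmt_ascii("uV", 8) for _ in range(ns)),
            b"".join(_fmt_float8(-pm) for pm in phys_max),
            b"".join(_fmt_float8(pm) for pm in phys_max),
            b"".join(_fmt_ascii(str(-_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_fmt_ascii(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_fmt_ascii("", 80) for _ in range(ns)),
            b"".join(_fmt_ascii(str(fs), 8) for _ in range(ns)),
            b"".join(_fmt_ascii("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # data records: record-major, channel-major within a record
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    return path


def _edf_header_precheck(path: Path) -> dict:
    """Parse the minimal EDF header fields needed for layout validation."""
    try:
        with open(path, "rb") as fh:
            fixed = fh.read(256)
            if len(fixed) < 256:
                raise FormatError(f"{path}: truncated or empty EDF header")
            try:
                ns = int(fixed[252:256].decode("ascii").strip())
                n_records = int(fixed[236:244].decode("ascii").strip())
                record_dur = float(fixed[244:252].decode("ascii").strip())
                patient = fixed[8:88].decode("ascii").strip()
            except ValueError as exc:
                raise FormatError(f"{path}: malformed EDF header field") from exc
            var = fh.read(256 * ns)
            if len(var) < 256 * ns:
                raise FormatError(f"{path}: truncated EDF signal header")
            labels = [
                var[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
                for i in range(ns)
            ]
            off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
            n_samps = [
                int(var[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
                for i in range(ns)
            ]
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return {
        "labels": labels,
        "n_samps": n_samps,
        "n_records": n_records,
        "record_dur": record_dur,
        "patient": patient,
    }


def read_recording(path, allow_nan: bool = False) -> Recording:
    """Read an EDF file into a :class:`Recording` with samples in µV.

    Raises :class:`FormatError` for unparseable files and
    :class:`UnsupportedLayoutError` when EEG channels carry different
    sampling rates (the pipeline has no resampling stage).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    hdr = _edf_header_precheck(path)
    data_rates = {
        n for lab, n in zip(hdr["labels"], hdr["n_samps"])
        if "annotation" not in lab.lower()
    }
    if len(data_rates) > 1:
        raise UnsupportedLayoutError(
            f"{path}: mixed sampling rates across channels: {sorted(data_rates)}"
        )
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad files
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    data = raw.get_data() * 1e6  # volts → µV
    if not allow_nan and not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: non-finite samples after read")
    annotations = [
        (float(on), float(du), str(desc))
        for on, du, desc in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    return Recording(
        data=data,
        channel_labels=tuple(raw.ch_names),
        fs_hz=float(raw.info["sfreq"]),
        subject_id=hdr["patient"],
        annotations=annotations,
    )


@dataclass
class MontageReport:
    """Outcome of validating a recording against the acquisition contract."""

    missing: tuple
    extra: tuple
    fs_found: float
    fs_expected: float
    duration_s: float
    failures: tuple
    warnings: tuple

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "missing": list(self.missing),
            "extra": list(self.extra),
            "fs_found": self.fs_found,
            "fs_expected": self.fs_expected,
            "duration_s": self.duration_s,
            "failures": list(self.failures),
            "warnings": list(self.warnings),
        }


def validate_montage(
    rec: Recording,
    required_labels=STANDARD_1020,
    fs_expected: float = DEFAULT_FS_HZ,
    min_duration_s: float = MIN_DURATION_S,
    strict: bool = True,
) -> MontageReport:
    """Check channels, rate and duration against the study contract.

    Label matching is case-insensitive.  Missing channels and a sampling-rate
    mismatch are always failures; a short recording and extra channels are
    failures only under ``strict`` (warnings otherwise).
    """
    have = {l.lower(): l for l in rec.channel_labels}
    req = {l.lower(): l for l in required_labels}
    missing = tuple(req[l] for l in req if l not in have)
    extra = tuple(have[l] for l in have if l not in req)

    failures, warns = [], []
    if missing:
        failures.append(f"missing channels: {', '.join(missing)}")
    if extra:
        (failures if strict else warns).append(f"extra channels: {', '.join(extra)}")
    if not math.isclose(rec.fs_hz, fs_expected, rel_tol=1e-9):
        failures.append(f"sampling rate {rec.fs_hz} Hz, expected {fs_expected} Hz")
    if rec.duration_s < min_duration_s:
        msg = f"duration {rec.duration_s:.1f} s below required {min_duration_s:.0f} s"
        (failures if strict else warns).append(msg)
    return MontageReport(
        missing=missing,
        extra=extra,
        fs_found=rec.fs_hz,
        fs_expected=fs_expected,
        duration_s=rec.duration_s,
        failures=tuple(failures),
        warnings=tuple(warns),
    )
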