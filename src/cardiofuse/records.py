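"""Core waveform and reference-stream containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


ECG_FS = 250.0  # Hz, wearable single-lead ECG
PPG_FS = 75.0   # Hz, finger PPG
WINDOW_S = 60.0
STRIDE_S = 30.0
WINDOW_SAMPLES = 15_000  # 60 s at 250 Hz


@dataclass
class WaveformRecord:
    """One modality's uniformly sampled signal.

    Attributes
    ----------
    samples : amplitude array in device units.
    fs : sampling rate, Hz.
    t0 : UNIX time of the first sample, seconds.
    modality : "ECG" or "PPG".
    """

    samples: np.ndarray
    fs: float
    t0: float
    modality: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.modality not in ("ECG", "PPG"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, **kw) -> "WaveformRecord":
        return replace(self, **kw)


@dataclass
class PacStream:
    """Time-stamped pulmonary-artery-catheter reference values.

    Emulates a continuous-thermodilution monitor: values are refreshed on a
    1 min computational cycle but delivered on a 2 s streaming grid.
    """

    times: np.ndarray          # unix seconds, nondecreasing
    co: np.ndarray             # L/min
    ci: np.ndarray             # L/min/m^2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.co = np.asarray(self.co, dtype=np.float64)
        self.ci = np.asarray(self.ci, dtype=np.float64)
        if not (self.times.size == self.co.size == self.ci.size):
            raise ValueError("times/co/ci must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(self.co <= 0):
            raise ValueError("CO values must be positive")


@dataclass
class SegmentPair:
    """One aligned 60 s ECG+PPG analysis window with reference labels.

    Both arrays carry 15,000 samples (60 s at 250 Hz).  The reference time is
    the window midpoint ``t_mid = t_start + 30 s``; labels may be None until
    a labeling pass attaches them, and stay None when no reference is
    available within +-30 s of the midpoint.
    """

    patient_id: str
    t_start: float
    ecg: np.ndarray
    ppg: np.ndarray
    co_ref: float | None = None
    ci_ref: float | None = None
    quality: dict = field(default_factory=dict)   # modality -> QualityScore

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        if self.ecg.size != WINDOW_SAMPLES or self.ppg.size != WINDOW_SAMPLES:
            raise ValueError(
                f"segment arrays must hold {WINDOW_SAMPLES} samples, "
                f"got ({self.ecg.size}, {self.ppg.size})"
            )

    @property
    def t_mid(self) -> float:
        return self.t_start + WINDOW_S / 2.0

    @property
    def segment_id(self) -> str:
        return f"{self.patient_id}:{self.t_start:.0f}"
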