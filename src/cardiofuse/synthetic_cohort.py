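"""Synthetic hemodynamic cohort generator.

Emulates the data a wearable ECG+PPG patch and a pulmonary-artery-catheter
(PAC) monitor would produce on cardiac-surgery patients, with a *known*
ground-truth cardiac-index (CI) trajectory, so that every downstream stage —
preprocessing, segmentation, the fusion regressor, and the method-comparison
statistics — can be exercised end-to-end without clinical recordings.

The physiological couplings are the ones a fusion model is expected to
exploit:

* heart rate rises with CI (``HR = hr_base + hr_per_ci * CI``),
* pulse transit time falls with CI (``PTT = ptt_base + ptt_per_ci * CI``,
  ``ptt_per_ci < 0``),
* PPG pulse amplitude is proportional to stroke volume ``SV = CO / HR``.

The ECG is a sum-of-Gaussians beat template (P/Q/R/S/T bumps) sampled at
250 Hz; the PPG is a gamma-shaped unimodal pulse per beat sampled at 75 Hz,
delayed by the instantaneous PTT.  Ground-truth CI lives on a 1 s grid in
1.3-4.2 L/min/m^2 (the observed clinical range), giving CO in roughly
1.8-6.3 L/min for typical body surface areas.

All randomness flows from one explicit integer seed; identical seeds and
parameters give bitwise-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .anthropometrics import bsa_mosteller
from .records import ECG_FS, PPG_FS, PacStream, WaveformRecord

__all__ = [
    "PatientMeta",
    "CiTrajectory",
    "CouplingParams",
    "TrajectoryParams",
    "sample_patient",
    "simulate_ci_trajectory",
    "synthesize_waveforms",
    "emulate_pac_stream",
    "inject_artifacts",
    "simulate_cohort",
    "write_cohort_csv",
]

CI_MIN, CI_MAX = 1.3, 4.2  # L/min/m^2, observed clinical range

# ECG beat template: (offset from R in s, amplitude rel. R, gaussian width s)
_ECG_BUMPS = (
    (-0.160, 0.12, 0.022),   # P
    (-0.022, -0.12, 0.008),  # Q
    (0.000, 1.00, 0.010),    # R
    (0.026, -0.20, 0.009),   # S
    (0.220, 0.28, 0.045),    # T
)

# PPG pulse: gamma-shaped g(tau) = (tau/tp)^k exp(k(1 - tau/tp)), peak 1 at tp
_PPG_K = 3.0
_PPG_TPEAK = 0.13    # s
_PPG_SUPPORT = 0.70  # s, pulse truncated here (value < 1e-3)


@dataclass(frozen=True)
class PatientMeta:
    """Anthropometrics of one simulated patient; BSA is Mosteller-derived."""

    patient_id: str
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")

    @property
    def bsa(self) -> float:
        return bsa_mosteller(self.height_cm, self.weight_kg)


@dataclass
class CiTrajectory:
    """Ground-truth cardiac index on a uniform time grid."""

    times: np.ndarray      # unix seconds, strictly increasing uniform grid
    ci_values: np.ndarray  # L/min/m^2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.ci_values = np.asarray(self.ci_values, dtype=np.float64)
        if self.times.size != self.ci_values.size:
            raise ValueError("times and ci_values must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def ci_at(self, t) -> np.ndarray:
        """Linear interpolation of CI at arbitrary times (clamped ends)."""
        return np.interp(t, self.times, self.ci_values)

    def trailing_mean(self, t_end: float, window_s: float = 60.0) -> float:
        """Mean CI over grid points in the half-open window (t_end - w, t_end]."""
        m = (self.times > t_end - window_s) & (self.times <= t_end)
        if not m.any():
            raise ValueError("trailing window contains no grid points")
        return float(self.ci_values[m].mean())


@dataclass(frozen=True)
class TrajectoryParams:
    """Shape of the slow CI drift: baseline + sinusoids + bounded random walk."""

    baseline: float | None = None      # L/min/m^2; None -> drawn U(1.8, 3.0)
    drift_amplitude: float = 0.45      # total sinusoid amplitude, L/min/m^2
    n_sinusoids: int = 3
    period_range_s: tuple = (120.0, 600.0)
    walk_sd: float = 0.01              # random-walk increment SD per second
    dt: float = 1.0                    # grid step, s
    ci_bounds: tuple = (CI_MIN, CI_MAX)


@dataclass(frozen=True)
class CouplingParams:
    """CI -> waveform couplings.

    Defaults keep HR near the observed clinical median (~61-75 bpm) over the
    CI range and PTT physiologic (175-250 ms).  ``amp_per_sv`` converts
    stroke volume in litres to PPG pulse amplitude in device units.
    """

    hr_base: float = 55.0        # bpm at CI = 0
    hr_per_ci: float = 8.0       # bpm per (L/min/m^2)
    ptt_base: float = 280.0      # ms at CI = 0
    ptt_per_ci: float = -25.0    # ms per (L/min/m^2), negative
    amp_per_sv: float = 20.0     # PPG units per litre of stroke volume
    noise_sd: float = 0.02       # additive white noise, signal units
    seed: int = 0

    def hr(self, ci) -> np.ndarray:
        return self.hr_base + self.hr_per_ci * np.asarray(ci, dtype=float)

    def ptt_s(self, ci) -> np.ndarray:
        return (self.ptt_base + self.ptt_per_ci * np.asarray(ci, dtype=float)) / 1e3

    def validate(self, ci_bounds=(CI_MIN, CI_MAX)) -> None:
        hr = self.hr(np.asarray(ci_bounds))
        if np.any(hr < 40.0) or np.any(hr > 180.0):
            raise ValueError(f"coupling yields HR outside 40-180 bpm: {hr}")
        if np.any(self.ptt_s(np.asarray(ci_bounds)) <= 0):
            raise ValueError("coupling yields nonpositive PTT")


def sample_patient(rng_seed: int, patient_id: str | None = None,
                   spread: float = 1.0) -> PatientMeta:
    """Draw one patient's anthropometrics.

    Height and weight come from truncated normals calibrated so that cohort
    medians land near 167 cm / 63 kg (typical of an adult cardiac-surgery
    cohort), giving BSA near 1.7 m^2.  ``spread`` scales both SDs — spread
    > 1 yields a cohort with higher body-surface-area variance.
    """
    rng = np.random.default_rng(rng_seed)
    height = _trunc_normal(rng, mean=166.0, sd=7.5 * spread, lo=145.0, hi=195.0)
    weight = _trunc_normal(rng, mean=63.0, sd=8.0 * spread, lo=38.0, hi=105.0)
    pid = patient_id if patient_id is not None else f"P{rng_seed:04d}"
    return PatientMeta(patient_id=pid, height_cm=height, weight_kg=weight)


def _trunc_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pragma: no cover


def simulate_ci_trajectory(
    duration_s: float,
    params: TrajectoryParams | None = None,
    rng_seed: int = 0,
    t0: float = 0.0,
) -> CiTrajectory:
    """Simulate a smooth, bounded CI trajectory on a uniform grid.

    The trajectory is baseline + a few slow sinusoids + a bounded random
    walk, clipped to the configured CI range.  Recordings are intended to be
    at least 10 min long (the monitor's natural analysis scale).
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    p = params or TrajectoryParams()
    rng = np.random.default_rng(rng_seed)
    t = np.arange(0.0, duration_s + p.dt / 2, p.dt)

    baseline = p.baseline
    if baseline is None:
        baseline = rng.uniform(1.8, 3.0)

    ci = np.full_like(t, baseline)
    if p.drift_amplitude > 0 and p.n_sinusoids > 0:
        amps = rng.dirichlet(np.ones(p.n_sinusoids)) * p.drift_amplitude
        for a in amps:
            period = rng.uniform(*p.period_range_s)
            phase = rng.uniform(0, 2 * np.pi)
            ci = ci + a * np.sin(2 * np.pi * t / period + phase)
        walk = np.cumsum(rng.normal(0.0, p.walk_sd * np.sqrt(p.dt), size=t.size))
        ci = ci + (walk - walk.mean())
    lo, hi = p.ci_bounds
    return CiTrajectory(times=t0 + t, ci_values=np.clip(ci, lo, hi))


def _beat_times(trajectory: CiTrajectory, coupling: CouplingParams) -> np.ndarray:
    """R-wave times whose instantaneous rate follows HR(CI(t))."""
    t0, t_end = trajectory.t0, trajectory.t0 + trajectory.duration
    beats = []
    t = t0 + 0.2
    while t < t_end:
        beats.append(t)
        hr = float(coupling.hr(trajectory.ci_at(t)))
        t += 60.0 / hr
    return np.asarray(beats)


def synthesize_waveforms(
    patient: PatientMeta,
    trajectory: CiTrajectory,
    coupling: CouplingParams | None = None,
) -> tuple[WaveformRecord, WaveformRecord]:
    """Render beat-resolved ECG (250 Hz) and PPG (75 Hz) from a CI trajectory.

    ECG beats are placed at R-times from the CI-coupled instantaneous heart
    rate; each PPG pulse follows its R-wave by PTT(CI) with amplitude
    ``amp_per_sv * SV`` where ``SV = CO / HR`` (litres per beat).  White
    Gaussian noise at ``noise_sd`` is added to both channels.
    """
    coupling = coupling or CouplingParams()
    tr_ci = trajectory.ci_values
    coupling.validate((float(tr_ci.min()), float(tr_ci.max())))

    rng = np.random.default_rng(coupling.seed)
    t0, dur = trajectory.t0, trajectory.duration
    n_ecg = int(round(dur * ECG_FS))
    n_ppg = int(round(dur * PPG_FS))
    ecg = np.zeros(n_ecg)
    ppg = np.zeros(n_ppg)

    r_times = _beat_times(trajectory, coupling)
    ci_at_beat = trajectory.ci_at(r_times)
    hr_at_beat = coupling.hr(ci_at_beat)                   # bpm
    sv_at_beat = ci_at_beat * patient.bsa / hr_at_beat     # L/beat
    ptt_at_beat = coupling.ptt_s(ci_at_beat)               # s
    amp_at_beat = coupling.amp_per_sv * sv_at_beat

    for r_t, ptt, amp in zip(r_times, ptt_at_beat, amp_at_beat):
        _add_ecg_beat(ecg, t0, r_t)
        _add_ppg_pulse(ppg, t0, r_t + ptt, amp)

    if coupling.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, coupling.noise_sd, size=n_ecg)
        ppg = ppg + rng.normal(0.0, coupling.noise_sd, size=n_ppg)

    return (
        WaveformRecord(samples=ecg, fs=ECG_FS, t0=t0, modality="ECG"),
        WaveformRecord(samples=ppg, fs=PPG_FS, t0=t0, modality="PPG"),
    )


def _add_ecg_beat(out: np.ndarray, t0: float, r_time: float) -> None:
    for off, amp, width in _ECG_BUMPS:
        c = r_time + off
        i_lo = max(0, int((c - 4 * width - t0) * ECG_FS))
        i_hi = min(out.size, int((c + 4 * width - t0) * ECG_FS) + 1)
        if i_lo >= i_hi:
            continue
        tt = t0 + np.arange(i_lo, i_hi) / ECG_FS
        out[i_lo:i_hi] += amp * np.exp(-0.5 * ((tt - c) / width) ** 2)


def _add_ppg_pulse(out: np.ndarray, t0: float, onset: float, amp: float) -> None:
    i_lo = max(0, int(np.ceil((onset - t0) * PPG_FS)))
    i_hi = min(out.size, int((onset + _PPG_SUPPORT - t0) * PPG_FS) + 1)
    if i_lo >= i_hi:
        return
    tau = t0 + np.arange(i_lo, i_hi) / PPG_FS - onset
    x = tau / _PPG_TPEAK
    out[i_lo:i_hi] += amp * np.power(x, _PPG_K) * np.exp(_PPG_K * (1.0 - x))


def emulate_pac_stream(patient: PatientMeta, trajectory: CiTrajectory) -> PacStream:
    """Emulate the PAC monitor output: trailing 60 s mean CI, recomputed on a
    1 min cycle, each value repeated on a 2 s streaming grid; CO = CI * BSA.
    """
    if trajectory.duration < 60.0:
        raise ValueError("trajectory must cover at least 60 s")
    t0 = trajectory.t0
    n_cycles = int(trajectory.duration // 60.0)
    cycle_t = t0 + 60.0 * np.arange(1, n_cycles + 1)
    cycle_ci = np.array([trajectory.trailing_mean(tc, 60.0) for tc in cycle_t])

    # the monitor is assumed already running at recording onset, so the
    # stream is backfilled with the first completed cycle's value
    stream_t = t0 + np.arange(2.0, trajectory.duration + 1e-9, 2.0)
    idx = np.searchsorted(cycle_t, stream_t, side="right") - 1
    idx = np.clip(idx, 0, n_cycles - 1)
    ci = cycle_ci[idx]
    return PacStream(times=stream_t, co=ci * patient.bsa, ci=ci)


def inject_artifacts(
    record: WaveformRecord,
    kind: str,
    spans: list[tuple[float, float]],
    rng_seed: int = 0,
    magnitude: float = 10.0,
) -> WaveformRecord:
    """Return a contaminated copy of ``record``.

    kind:
      ``noise_burst``     — add white noise at ``magnitude`` x signal SD;
      ``baseline_wander`` — add a 0.25 Hz sinusoid at ``magnitude`` x SD... /3;
      ``flatline``        — replace the span by its mean (sensor detachment),
                            driving peak-to-peak amplitude to ~0.

    Spans are (start_s, end_s) relative to the record start.
    """
    if kind not in ("noise_burst", "baseline_wander", "flatline"):
        raise ValueError(f"unknown artifact kind {kind!r}")
    out = record.samples.copy()
    if not spans:
        return record.copy_with(samples=out)
    rng = np.random.default_rng(rng_seed)
    sd = float(record.samples.std()) or 1.0
    for start, end in spans:
        if start < 0 or end > record.duration + 1e-9 or end <= start:
            raise ValueError(f"span ({start}, {end}) outside record duration")
        i0, i1 = int(start * record.fs), int(end * record.fs)
        if kind == "noise_burst":
            out[i0:i1] += rng.normal(0.0, magnitude * sd, size=i1 - i0)
        elif kind == "baseline_wander":
            tt = np.arange(i0, i1) / record.fs
            out[i0:i1] += magnitude / 3.0 * sd * np.sin(2 * np.pi * 0.25 * tt)
        else:  # flatline
            out[i0:i1] = out[i0:i1].mean() if i1 > i0 else 0.0
    return record.copy_with(samples=out)


@dataclass
class PatientRecord:
    """Everything simulated for one patient."""

    meta: PatientMeta
    trajectory: CiTrajectory
    ecg: WaveformRecord
    ppg: WaveformRecord
    pac: PacStream


def simulate_cohort(
    n_patients: int,
    duration_s: float = 600.0,
    seed: int = 0,
    coupling: CouplingParams | None = None,
    trajectory_params: TrajectoryParams | None = None,
    patient_spread: float = 1.0,
) -> list[PatientRecord]:
    """Simulate a cohort; per-patient seeds are derived from the cohort seed."""
    root = np.random.default_rng(seed)
    sub = root.integers(0, 2**31 - 1, size=3 * n_patients)
    base = coupling or CouplingParams()
    cohort = []
    for i in range(n_patients):
        meta = sample_patient(int(sub[3 * i]), patient_id=f"P{i:03d}",
                              spread=patient_spread)
        traj = simulate_ci_trajectory(
            duration_s, trajectory_params, rng_seed=int(sub[3 * i + 1])
        )
        cp = CouplingParams(**{**base.__dict__, "seed": int(sub[3 * i + 2])})
        ecg, ppg = synthesize_waveforms(meta, traj, cp)
        pac = emulate_pac_stream(meta, traj)
        cohort.append(PatientRecord(meta, traj, ecg, ppg, pac))
    return cohort


def write_cohort_csv(cohort: list[PatientRecord], out_dir: str) -> None:
    """Write per-patient waveform, PAC and metadata CSVs (columnar text)."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    meta_rows = []
    for rec in cohort:
        pid = rec.meta.patient_id
        meta_rows.append(
            dict(patient_id=pid, height_cm=rec.meta.height_cm,
                 weight_kg=rec.meta.weight_kg, bsa_m2=rec.meta.bsa)
        )
        for wf, tag in ((rec.ecg, "ecg"), (rec.ppg, "ppg")):
            pd.DataFrame({"unix_time_s": wf.times, "value": wf.samples}).to_csv(
                os.path.join(out_dir, f"{pid}_{tag}.csv"), index=False
            )
        pd.DataFrame(
            {"unix_time_s": rec.pac.times, "co_lpm": rec.pac.co,
             "ci_lpm_m2": rec.pac.ci}
        ).to_csv(os.path.join(out_dir, f"{pid}_pac.csv"), index=False)
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(out_dir, "patients.csv"), index=False
    )
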