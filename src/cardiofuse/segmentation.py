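"""Windowing, reference labeling, exclusions, and patient-level splitting.

Synchronized 250 Hz ECG/PPG are cut into 60 s windows (15,000 samples) with a
30 s stride (50% overlap).  Each window is labeled from the PAC reference
stream either as the mean of all streamed values inside the window
(``window_mean``, the default — a temporally matched, averaging-consistent
target) or by nearest-neighbour matching of the window midpoint to the 1 min
reference timestamps (``nearest_minute``).  Windows whose nearest reference
is more than 30 s from the midpoint stay unlabeled and are excluded.

Dataset splits are randomized at the *patient* level so that overlapping
windows from one patient can never leak between train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import (ECG_FS, STRIDE_S, WINDOW_S, WINDOW_SAMPLES, PacStream,
                      SegmentPair, WaveformRecord)
from .preprocess import ecg_quality, ppg_quality, zscore_gate

__all__ = [
    "DatasetSplit",
    "segment_windows",
    "label_window",
    "score_segment_quality",
    "apply_exclusions",
    "split_patients",
]

LABEL_MAX_GAP_S = 30.0
AMPLITUDE_FLOOR_FRAC = 0.01  # of the patient-median window peak-to-peak
QUALITY_MIN_SD = 0.01        # raw-score SD below which the z-gate is inert


@dataclass
class DatasetSplit:
    """Patient-level train/validation/test assignment."""

    train_patients: set
    val_patients: set
    test_patients: set
    seed: int

    def __post_init__(self) -> None:
        a, b, c = (set(self.train_patients), set(self.val_patients),
                   set(self.test_patients))
        if a & b or a & c or b & c:
            raise ValueError("split sets must be pairwise disjoint")
        self.train_patients, self.val_patients, self.test_patients = a, b, c

    @property
    def all_patients(self) -> set:
        return self.train_patients | self.val_patients | self.test_patients

    def subset_of(self, segments, which: str):
        ids = getattr(self, f"{which}_patients")
        return [s for s in segments if s.patient_id in ids]


def segment_windows(
    ecg: WaveformRecord, ppg: WaveformRecord, patient_id: str = ""
) -> list[SegmentPair]:
    """Cut the overlapping time span of two 250 Hz records into 60 s windows
    with a 30 s stride; trailing partial windows are dropped."""
    for rec in (ecg, ppg):
        if rec.fs != ECG_FS:
            raise ValueError(f"expected {ECG_FS} Hz records, got {rec.fs}")
    t_lo = max(ecg.t0, ppg.t0)
    t_hi = min(ecg.t0 + ecg.duration, ppg.t0 + ppg.duration)
    if t_hi - t_lo < WINDOW_S - 1e-9:
        raise ValueError(
            f"records overlap for {t_hi - t_lo:.1f} s; need >= {WINDOW_S:.0f} s"
        )
    segments = []
    t_start = t_lo
    while t_start + WINDOW_S <= t_hi + 1e-9:
        i_ecg = int(round((t_start - ecg.t0) * ECG_FS))
        i_ppg = int(round((t_start - ppg.t0) * ECG_FS))
        if (i_ecg + WINDOW_SAMPLES > ecg.n) or (i_ppg + WINDOW_SAMPLES > ppg.n):
            break
        segments.append(
            SegmentPair(
                patient_id=patient_id,
                t_start=t_start,
                ecg=ecg.samples[i_ecg: i_ecg + WINDOW_SAMPLES],
                ppg=ppg.samples[i_ppg: i_ppg + WINDOW_SAMPLES],
            )
        )
        t_start += STRIDE_S
    return segments


def label_window(
    segment: SegmentPair, pac: PacStream, policy: str = "window_mean"
) -> SegmentPair:
    """Attach reference CO/CI labels from the PAC stream.

    ``window_mean``: mean of streamed values with t_start <= t < t_start+60.
    ``nearest_minute``: value at the reference timestamp nearest the window
    midpoint.  Either way, the label stays None when the nearest available
    reference is more than 30 s from the midpoint.
    """
    if policy not in ("window_mean", "nearest_minute"):
        raise ValueError(f"unknown labeling policy {policy!r}")
    if pac.times.size == 0:
        raise ValueError("empty PAC stream")

    if policy == "window_mean":
        m = (pac.times >= segment.t_start) & (pac.times < segment.t_start + WINDOW_S)
        if m.any():
            segment.co_ref = float(pac.co[m].mean())
            segment.ci_ref = float(pac.ci[m].mean())
            return segment
    else:
        gaps = np.abs(pac.times - segment.t_mid)
        k = int(np.argmin(gaps))
        if gaps[k] <= LABEL_MAX_GAP_S:
            segment.co_ref = float(pac.co[k])
            segment.ci_ref = float(pac.ci[k])
            return segment
    segment.co_ref = None
    segment.ci_ref = None
    return segment


def score_segment_quality(segments: list[SegmentPair]) -> None:
    """Compute per-modality raw quality scores and cohort-wide Z-scores.

    Z-score populations are all segments of the same modality in the cohort
    being processed.  Segments where beat detection fails get raw score 0
    (certainly low quality) rather than aborting the cohort.
    """
    for which, scorer in (("ECG", ecg_quality), ("PPG", ppg_quality)):
        qs = []
        for seg in segments:
            arr = seg.ecg if which == "ECG" else seg.ppg
            try:
                q = scorer(arr, segment_id=seg.segment_id)
            except ValueError:
                from .preprocess import QualityScore
                q = QualityScore(segment_id=seg.segment_id, modality=which,
                                 raw_score=0.0)
            seg.quality[which] = q
            qs.append(q)
        if len(qs) >= 2:
            zscore_gate(qs, min_sd=QUALITY_MIN_SD)  # writes z_score in place
        else:
            for q in qs:
                q.z_score = 0.0


def apply_exclusions(
    segments: list[SegmentPair],
    amplitude_floor_frac: float = AMPLITUDE_FLOOR_FRAC,
    z_limit: float = 2.0,
) -> tuple[list[SegmentPair], list[tuple[SegmentPair, str]]]:
    """Drop segments with missing labels, NaNs, near-zero amplitude
    (sensor detachment), or outlying quality Z-scores.

    The amplitude floor is relative: a window's peak-to-peak must be at least
    ``amplitude_floor_frac`` of the same patient's median window peak-to-peak
    for that modality.  Each exclusion carries a reason code
    (label / nan / amplitude / quality).
    """
    # per-patient median peak-to-peak, per modality
    p2p: dict[tuple[str, str], list[float]] = {}
    for seg in segments:
        for mod, arr in (("ECG", seg.ecg), ("PPG", seg.ppg)):
            p2p.setdefault((seg.patient_id, mod), []).append(
                float(arr.max() - arr.min())
            )
    med = {k: float(np.median(v)) for k, v in p2p.items()}

    kept, excluded = [], []
    for seg in segments:
        if seg.co_ref is None and seg.ci_ref is None:
            excluded.append((seg, "label"))
            continue
        if np.isnan(seg.ecg).any() or np.isnan(seg.ppg).any():
            excluded.append((seg, "nan"))
            continue
        small = False
        for mod, arr in (("ECG", seg.ecg), ("PPG", seg.ppg)):
            floor = amplitude_floor_frac * med[(seg.patient_id, mod)]
            if float(arr.max() - arr.min()) < floor:
                small = True
        if small:
            excluded.append((seg, "amplitude"))
            continue
        bad_quality = any(
            q.z_score is not None and abs(q.z_score) > z_limit
            for q in seg.quality.values()
        )
        if bad_quality:
            excluded.append((seg, "quality"))
            continue
        kept.append(seg)
    return kept, excluded


def split_patients(
    patients, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly assign patients to train/val/test at the given ratios.

    Set sizes use largest-remainder rounding of ``ratio * n`` so that e.g.
    27 patients at (16/27, 5/27, 6/27) give exactly (16, 5, 6).  Assignment
    is deterministic per seed and leakage-free by construction.
    """
    patients = list(patients)
    n = len(patients)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n_nonzero = sum(1 for r in ratios if r > 0)
    if n < n_nonzero:
        raise ValueError(f"{n} patients cannot fill {n_nonzero} nonempty sets")

    targets = [r * n for r in ratios]
    sizes = [int(np.floor(t)) for t in targets]
    # nonempty sets get at least one patient before remainder distribution
    for i, r in enumerate(ratios):
        if r > 0 and sizes[i] == 0:
            sizes[i] = 1
    rem = n - sum(sizes)
    if rem < 0:
        raise ValueError("ratios incompatible with patient count")
    frac_order = np.argsort([-(t - np.floor(t)) for t in targets])
    for i in range(rem):
        sizes[frac_order[i % 3]] += 1

    order = np.random.default_rng(seed).permutation(n)
    shuffled = [patients[i] for i in order]
    train = set(shuffled[: sizes[0]])
    val = set(shuffled[sizes[0]: sizes[0] + sizes[1]])
    test = set(shuffled[sizes[0] + sizes[1]:])
    return DatasetSplit(train_patients=train, val_patients=val,
                        test_patients=test, seed=seed)
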