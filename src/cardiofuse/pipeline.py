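"""End-to-end experiment orchestration on synthetic cohorts.

Runs the full study design: simulate a cohort with known ground-truth CI ->
preprocess waveforms -> cut and label 60 s windows -> apply exclusions ->
patient-level split -> train a CI model and a direct-CO model -> evaluate
three estimators on held-out patients (CI, direct CO, indirect CO =
predicted CI x BSA) -> build agreement reports and the direct-vs-indirect
comparison table (paired permutation / bootstrap / error tests).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .records import ECG_FS
from .synthetic_cohort import (CouplingParams, TrajectoryParams,
                               simulate_cohort)
from .preprocess import preprocess_ecg, preprocess_ppg
from .segmentation import (apply_exclusions, label_window,
                           score_segment_quality, segment_windows,
                           split_patients)
from .training import CardiacOutputRegressor, predict_indirect, \
    segments_to_arrays
from .stats import (PairedSeries, bootstrap_diff_test, build_report,
                    paired_error_test, paired_permutation_pcc)

__all__ = ["ExperimentConfig", "ExperimentResult", "prepare_datasets",
           "run_experiment", "render_figures"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one synthetic experiment."""

    n_patients: int = 20
    duration_s: float = 600.0
    cohort_seed: int = 0
    patient_spread: float = 1.0   # anthropometric SD multiplier (BSA variance)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    labeling_policy: str = "window_mean"
    split_ratios: tuple = (0.6, 0.2, 0.2)
    split_seed: int = 0
    window_subsample: int = 1     # keep every k-th window (1 = all)
    estimator_kwargs: dict = field(default_factory=dict)
    boot_iters: int = 500
    stat_seed: int = 0
    out_dir: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class ExperimentResult:
    reports: dict            # label -> AgreementReport
    comparison: dict         # direct-vs-indirect test panel
    series: dict             # label -> PairedSeries
    split: object
    n_segments: dict
    histories: dict


def prepare_datasets(config: ExperimentConfig):
    """Simulate, preprocess, segment, label, exclude, and split.

    Returns (split, arrays) where arrays maps 'train'/'val'/'test' to
    (X, y_ci, y_co, patient_ids, bsa) tuples, plus segment bookkeeping.
    """
    cohort = simulate_cohort(
        config.n_patients, config.duration_s, seed=config.cohort_seed,
        coupling=config.coupling, trajectory_params=config.trajectory,
        patient_spread=config.patient_spread,
    )
    segments = []
    for rec in cohort:
        ecg = preprocess_ecg(rec.ecg)
        ppg = preprocess_ppg(rec.ppg)
        wins = segment_windows(ecg, ppg, patient_id=rec.meta.patient_id)
        wins = wins[:: config.window_subsample]
        for w in wins:
            label_window(w, rec.pac, policy=config.labeling_policy)
        segments.extend(wins)
    score_segment_quality(segments)
    kept, excluded = apply_exclusions(segments)

    split = split_patients(
        sorted({s.patient_id for s in segments}),
        ratios=config.split_ratios, seed=config.split_seed,
    )
    arrays = {}
    for which in ("train", "val", "test"):
        subset = split.subset_of(kept, which)
        if not subset:
            raise RuntimeError(f"{which} set is empty after exclusions")
        X, y_ci, pids, bsa = segments_to_arrays(subset, target="CI")
        _, y_co, _, _ = segments_to_arrays(subset, target="CO")
        arrays[which] = dict(X=X, y_ci=y_ci, y_co=y_co, pids=pids, bsa=bsa,
                             segments=subset)
    bookkeeping = {
        "n_total": len(segments),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "exclusion_reasons": sorted({r for _, r in excluded}),
    }
    return split, arrays, bookkeeping, cohort


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """The direct-vs-indirect CO experiment on one synthetic cohort."""
    split, arrays, bookkeeping, _ = prepare_datasets(config)
    tr, va, te = arrays["train"], arrays["val"], arrays["test"]

    ci_model = CardiacOutputRegressor(**config.estimator_kwargs)
    ci_model.fit(tr["X"], tr["y_ci"], va["X"], va["y_ci"])
    co_model = CardiacOutputRegressor(**config.estimator_kwargs)
    co_model.fit(tr["X"], tr["y_co"], va["X"], va["y_co"])

    ci_hat = ci_model.predict(te["X"])
    co_direct = co_model.predict(te["X"])
    co_ind = predict_indirect(ci_model, te["X"], te["bsa"])
    # the indirect pathway must be exactly CI predictions times BSA
    assert np.allclose(co_ind, ci_hat * te["bsa"])

    series = {
        "ci": PairedSeries(te["y_ci"], ci_hat),
        "co_direct": PairedSeries(te["y_co"], co_direct),
        "co_indirect": PairedSeries(te["y_co"], co_ind),
    }
    reports = {
        k: build_report(s, label=k, boot_iters=config.boot_iters,
                        seed=config.stat_seed)
        for k, s in series.items()
    }
    a, b = series["co_direct"], series["co_indirect"]
    comparison = {
        "pcc_perm_p": paired_permutation_pcc(
            a, b, perms=min(5000, 20 * config.boot_iters),
            seed=config.stat_seed),
        "ccc_boot": bootstrap_diff_test(
            a, b, "ccc", iters=max(config.boot_iters, 100),
            seed=config.stat_seed),
        "r2_boot": bootstrap_diff_test(
            a, b, "r2", iters=max(config.boot_iters, 100),
            seed=config.stat_seed),
        "mae_test": paired_error_test(a, b, "mae"),
        "rmse_test": paired_error_test(a, b, "rmse"),
        "bias_test": paired_error_test(a, b, "bias"),
    }
    result = ExperimentResult(
        reports=reports, comparison=comparison, series=series, split=split,
        n_segments=bookkeeping,
        histories={"ci": ci_model.history_, "co": co_model.history_},
    )
    if config.out_dir:
        _write_artifacts(config, result)
    return result


def _write_artifacts(config: ExperimentConfig, result: ExperimentResult):
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "experiment.json"), "w") as fh:
        fh.write(config.to_json())
    for k, rep in result.reports.items():
        with open(os.path.join(config.out_dir, f"report_{k}.json"), "w") as fh:
            fh.write(rep.to_json())
    with open(os.path.join(config.out_dir, "comparison.json"), "w") as fh:
        json.dump(result.comparison, fh, indent=2, default=float)
    with open(os.path.join(config.out_dir, "split.json"), "w") as fh:
        json.dump(
            {"train": sorted(result.split.train_patients),
             "val": sorted(result.split.val_patients),
             "test": sorted(result.split.test_patients),
             "seed": result.split.seed}, fh, indent=2)
    render_figures(result.series, result.reports, config.out_dir)
    manifest = sorted(os.listdir(config.out_dir))
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def render_figures(series: dict, reports: dict, out_dir: str) -> list[str]:
    """Scatter (with identity line) and Bland-Altman plot per estimator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for k, s in series.items():
        rep = reports[k]
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        lo = min(s.y_ref.min(), s.y_hat.min())
        hi = max(s.y_ref.max(), s.y_hat.max())
        ax1.scatter(s.y_ref, s.y_hat, s=12, alpha=0.7)
        ax1.plot([lo, hi], [lo, hi], "k-", lw=1)  # perfect agreement y = x
        ax1.set_xlabel("reference")
        ax1.set_ylabel("predicted")
        ax1.set_title(f"{k}: PCC={rep.pcc:.3f}")

        mean_ = (s.y_ref + s.y_hat) / 2
        ax2.scatter(mean_, s.d, s=12, alpha=0.7)
        ax2.axhline(rep.bias, color="b", lw=1)
        for loa in (rep.loa_lower, rep.loa_upper):
            ax2.axhline(loa, color="r", ls="--", lw=1)
        for key in ("loa_lower", "loa_upper", "bias"):
            for v in rep.ci_95[key]:
                ax2.axhline(v, color="gray", ls=":", lw=0.6)
        ax2.set_xlabel("mean of methods")
        ax2.set_ylabel("difference (pred - ref)")
        ax2.set_title(f"bias={rep.bias:.2f}, LoA=({rep.loa_lower:.2f}, "
                      f"{rep.loa_upper:.2f})")
        fig.tight_layout()
        path = os.path.join(out_dir, f"agreement_{k}.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
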