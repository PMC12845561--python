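"""Method-comparison statistics for cardiac-output estimators.

Implements the full agreement panel used to compare a noninvasive estimator
against an invasive reference: Pearson correlation (PCC), concordance
correlation (CCC), R^2, MAE, RMSE, percentage error (PE), and Bland-Altman
bias / 95% limits of agreement — each with a 95% confidence interval
(Fisher z for PCC, segment-level bootstrap for the rest) — plus the paired
hypothesis tests for comparing two estimators on the same reference series
(paired permutation for PCC; bootstrap difference tests for CCC and R^2;
Shapiro-Wilk-gated paired t / Wilcoxon for MAE, RMSE and bias).

Conventions: evaluation-side SDs use the sample (n-1) form, standard in
Bland-Altman practice; CCC uses population moments (its closed form).  PE is
100 * SD(prediction errors) / mean(reference); PE < 30% is the conventional
clinical acceptability benchmark for CO method comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "agreement_metrics",
    "bland_altman",
    "percent_ba",
    "pcc_ci_fisher",
    "bootstrap_ci",
    "paired_permutation_pcc",
    "bootstrap_diff_test",
    "paired_error_test",
    "build_report",
]

PE_ACCEPTABLE = 30.0  # %
Z975 = 1.959963984540054


@dataclass
class PairedSeries:
    """Reference values and predictions, paired per segment."""

    y_ref: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.y_ref = np.asarray(self.y_ref, float)
        self.y_hat = np.asarray(self.y_hat, float)
        if self.y_ref.shape != self.y_hat.shape or self.y_ref.ndim != 1:
            raise ValueError("y_ref and y_hat must be equal-length 1-D arrays")
        if self.y_ref.size < 2:
            raise ValueError("need at least 2 paired values")

    @property
    def d(self) -> np.ndarray:
        """Differences, prediction minus reference."""
        return self.y_hat - self.y_ref

    @property
    def n(self) -> int:
        return int(self.y_ref.size)


def _pcc(y, yh) -> float:
    if np.std(y) == 0 or np.std(yh) == 0:
        return np.nan
    return float(np.corrcoef(y, yh)[0, 1])


def _ccc(y, yh) -> float:
    # population moments, no eps (evaluation side)
    mx, my = y.mean(), yh.mean()
    vx = ((y - mx) ** 2).mean()
    vy = ((yh - my) ** 2).mean()
    sxy = ((y - mx) * (yh - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    return float(2.0 * sxy / denom) if denom > 0 else np.nan


def _r2(y, yh) -> float:
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return np.nan
    return float(1.0 - ((y - yh) ** 2).sum() / sst)


def _pe(y, yh) -> float:
    # sample-SD of errors over mean reference, in percent
    return float(100.0 * np.std(yh - y, ddof=1) / y.mean())


_METRICS = {
    "pcc": _pcc,
    "ccc": _ccc,
    "r2": _r2,
    "mae": lambda y, yh: float(np.abs(yh - y).mean()),
    "rmse": lambda y, yh: float(np.sqrt(((yh - y) ** 2).mean())),
    "pe": _pe,
    "bias": lambda y, yh: float((yh - y).mean()),
}


def agreement_metrics(series: PairedSeries) -> dict:
    """Point estimates of PCC, CCC, R^2, MAE, RMSE and PE.

    A zero-variance reference leaves PCC/CCC/R^2 as NaN (flagged, not
    fabricated); R^2 may legitimately be negative — worse than predicting
    the reference mean.
    """
    y, yh = series.y_ref, series.y_hat
    out = {k: f(y, yh) for k, f in _METRICS.items() if k != "bias"}
    if np.std(y, ddof=0) == 0:
        warnings.warn("zero-variance reference: PCC/CCC/R2 undefined")
    return out


def bland_altman(series: PairedSeries, exact_t: bool = False) -> dict:
    """Bias, 95% limits of agreement, and their confidence intervals.

    bias = mean(d); LoA = bias +- 1.96 * SD(d) with sample SD.  The bias CI
    uses the exact t distribution; LoA CIs use the standard variance formula
    Var(LoA) ~= (1/n + 1.96^2 / (2(n-1))) * SD^2 with a normal quantile by
    default (``exact_t=True`` switches to the t quantile).
    """
    d = series.d
    n = series.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    t975 = sps.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    q = t975 if exact_t else Z975
    return {
        "bias": bias,
        "sd_d": sd,
        "loa_lower": loa_lo,
        "loa_upper": loa_hi,
        "bias_ci": (bias - t975 * se_bias, bias + t975 * se_bias),
        "loa_lower_ci": (loa_lo - q * se_loa, loa_lo + q * se_loa),
        "loa_upper_ci": (loa_hi - q * se_loa, loa_hi + q * se_loa),
    }


def percent_ba(series: PairedSeries) -> dict:
    """Bland-Altman bias and LoA normalized to the mean reference, percent."""
    ref = series.y_ref.mean()
    if ref <= 0:
        raise ValueError("mean reference must be positive for percent scaling")
    ba = bland_altman(series)
    return {
        "percent_bias": 100.0 * ba["bias"] / ref,
        "percent_loa": (100.0 * ba["loa_lower"] / ref,
                        100.0 * ba["loa_upper"] / ref),
    }


def pcc_ci_fisher(series: PairedSeries, level: float = 0.95) -> tuple:
    """Fisher z-transform confidence interval for the Pearson correlation."""
    n = series.n
    if n < 4:
        raise ValueError("Fisher interval needs n >= 4")
    r = _pcc(series.y_ref, series.y_hat)
    if not np.isfinite(r):
        raise ValueError("correlation undefined (zero variance)")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: Fisher interval degenerate")
        return (r, r)
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bootstrap_ci(
    series: PairedSeries, metric: str, iters: int = 2000, seed: int = 0,
    level: float = 0.95,
) -> tuple:
    """Percentile bootstrap CI of a metric, resampling segments with
    replacement.  Resamples on which the metric is undefined (e.g. a
    zero-variance reference draw) are redrawn."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    f = _METRICS[metric]
    y, yh, n = series.y_ref, series.y_hat, series.n
    rng = np.random.default_rng(seed)
    vals = np.empty(iters)
    redraws = 0
    for i in range(iters):
        while True:
            idx = rng.integers(0, n, size=n)
            v = f(y[idx], yh[idx])
            if np.isfinite(v):
                vals[i] = v
                break
            redraws += 1
            if redraws > 100 * iters:
                raise RuntimeError("metric undefined on almost all resamples")
    a = (1.0 - level) / 2.0
    return (float(np.quantile(vals, a)), float(np.quantile(vals, 1 - a)))


def paired_permutation_pcc(
    series_a: PairedSeries, series_b: PairedSeries,
    perms: int = 5000, seed: int = 0,
) -> float:
    """Paired permutation test on the PCC difference of two estimators.

    Both series must share the same reference.  Per permutation, each
    segment's A/B prediction labels are swapped with probability 1/2; the
    two-sided p-value is the add-one-smoothed fraction of permuted |dPCC|
    at least as large as observed.
    """
    _check_paired(series_a, series_b)
    y = series_a.y_ref
    a, b = series_a.y_hat, series_b.y_hat
    obs = abs(_pcc(y, a) - _pcc(y, b))
    rng = np.random.default_rng(seed)
    count = 0
    n = y.size
    for _ in range(perms):
        swap = rng.random(n) < 0.5
        ap = np.where(swap, b, a)
        bp = np.where(swap, a, b)
        if abs(_pcc(y, ap) - _pcc(y, bp)) >= obs - 1e-15:
            count += 1
    return (count + 1) / (perms + 1)


def bootstrap_diff_test(
    series_a: PairedSeries, series_b: PairedSeries,
    metric: str = "ccc", iters: int = 3000, seed: int = 0,
) -> dict:
    """Bootstrap test of metric(A) - metric(B) on paired resamples.

    Returns the two-sided p-value (doubled smoothed tail proportion of the
    bootstrap difference distribution crossing zero, capped at 1) and the
    95% percentile CI of the difference.
    """
    if metric not in ("ccc", "r2", "mae", "rmse", "pcc"):
        raise ValueError(f"unsupported metric {metric!r}")
    _check_paired(series_a, series_b)
    f = _METRICS[metric]
    y, a, b, n = series_a.y_ref, series_a.y_hat, series_b.y_hat, series_a.n
    rng = np.random.default_rng(seed)
    diffs = np.empty(iters)
    for i in range(iters):
        while True:
            idx = rng.integers(0, n, size=n)
            va, vb = f(y[idx], a[idx]), f(y[idx], b[idx])
            if np.isfinite(va) and np.isfinite(vb):
                diffs[i] = va - vb
                break
    p_neg = (np.sum(diffs <= 0) + 1) / (iters + 1)
    p_pos = (np.sum(diffs >= 0) + 1) / (iters + 1)
    return {
        "p_value": float(min(1.0, 2.0 * min(p_neg, p_pos))),
        "diff": float(f(y, a) - f(y, b)),
        "diff_ci": (float(np.quantile(diffs, 0.025)),
                    float(np.quantile(diffs, 0.975))),
    }


def paired_error_test(
    series_a: PairedSeries, series_b: PairedSeries, metric: str = "mae",
    alpha_normality: float = 0.05,
) -> dict:
    """Compare per-segment errors of two estimators.

    Error definition follows the metric: absolute errors for MAE, squared
    errors for RMSE, signed errors for bias.  The paired differences are
    Shapiro-Wilk tested; if consistent with normality a paired t-test is
    used, otherwise the Wilcoxon signed-rank test.  Two-sided.
    """
    _check_paired(series_a, series_b)
    ea, eb = series_a.d, series_b.d
    if metric == "mae":
        ea, eb = np.abs(ea), np.abs(eb)
    elif metric == "rmse":
        ea, eb = ea**2, eb**2
    elif metric != "bias":
        raise ValueError("metric must be mae, rmse or bias")
    diff = ea - eb
    if np.allclose(diff, 0.0):
        return {"p_value": 1.0, "test": "degenerate", "shapiro_p": np.nan}
    sw_p = float(sps.shapiro(diff).pvalue)
    if sw_p >= alpha_normality:
        res = sps.ttest_rel(ea, eb)
        used = "paired_t"
    else:
        res = sps.wilcoxon(ea, eb)
        used = "wilcoxon"
    return {"p_value": float(res.pvalue), "test": used, "shapiro_p": sw_p}


def _check_paired(a: PairedSeries, b: PairedSeries) -> None:
    if a.n != b.n:
        raise ValueError("series must have equal length")
    if not np.allclose(a.y_ref, b.y_ref):
        raise ValueError("paired comparison requires a shared reference")


# ----------------------------------------------------------------- report

@dataclass
class AgreementReport:
    """The full agreement panel with confidence intervals for one estimator."""

    label: str
    n: int
    pcc: float
    ccc: float
    r2: float
    mae: float
    rmse: float
    pe: float
    bias: float
    loa_lower: float
    loa_upper: float
    ci_95: dict = field(default_factory=dict)   # metric -> (lo, hi)
    pe_pass: bool = False
    notes: tuple = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["ci_95"] = {k: list(v) for k, v in d["ci_95"].items()}
        d["notes"] = list(d["notes"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "AgreementReport":
        d = json.loads(s)
        d["ci_95"] = {k: tuple(v) for k, v in d["ci_95"].items()}
        d["notes"] = tuple(d["notes"])
        return cls(**d)

    def to_markdown(self) -> str:
        rows = [
            "| Metric | Value | 95% CI |",
            "|---|---|---|",
        ]
        for k in ("pcc", "ccc", "r2", "mae", "rmse", "pe", "bias",
                  "loa_lower", "loa_upper"):
            lo, hi = self.ci_95.get(k, (np.nan, np.nan))
            rows.append(f"| {k.upper()} | {getattr(self, k):.3f} "
                        f"| ({lo:.3f}, {hi:.3f}) |")
        rows.append(f"| PE < {PE_ACCEPTABLE:.0f}% | "
                    f"{'yes' if self.pe_pass else 'no'} | |")
        return "\n".join(rows)


def build_report(
    series: PairedSeries, label: str = "", boot_iters: int = 2000,
    seed: int = 0,
) -> AgreementReport:
    """Assemble the full metric panel with CIs and the PE acceptability flag.

    PCC gets a Fisher-z interval; CCC/R^2/MAE/RMSE/PE get segment-level
    bootstrap percentile intervals; bias and LoA get the standard
    Bland-Altman interval formulas.  Segment-level bootstrapping does not
    account for within-patient clustering of overlapping windows, which is
    surfaced as a note on the report.
    """
    m = agreement_metrics(series)
    ba = bland_altman(series)
    ci = {}
    if series.n >= 4 and np.isfinite(m["pcc"]) and abs(m["pcc"]) < 1:
        ci["pcc"] = pcc_ci_fisher(series)
    for i, k in enumerate(("ccc", "r2", "mae", "rmse", "pe")):
        if np.isfinite(m[k]):
            ci[k] = bootstrap_ci(series, k, iters=boot_iters, seed=seed + i)
    ci["bias"] = ba["bias_ci"]
    ci["loa_lower"] = ba["loa_lower_ci"]
    ci["loa_upper"] = ba["loa_upper_ci"]
    return AgreementReport(
        label=label,
        n=series.n,
        pcc=m["pcc"], ccc=m["ccc"], r2=m["r2"],
        mae=m["mae"], rmse=m["rmse"], pe=m["pe"],
        bias=ba["bias"], loa_lower=ba["loa_lower"], loa_upper=ba["loa_upper"],
        ci_95=ci,
        pe_pass=bool(m["pe"] < PE_ACCEPTABLE),
        notes=(
            "segment-level bootstrap; within-patient clustering of "
            "overlapping windows is not accounted for",
        ),
    )
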