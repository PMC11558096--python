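"""Evaluation and decision layer: confusion matrix, R-squared,
Bland-Altman agreement, linear calibration with blank+3SD detection
limit, single-feature baseline fits, specificity t-test, clinical
interval calls, and the end-to-end report.

Conventions documented once here:

* "Colorimetric intensity" of a strip = normalized green-channel
  depletion ``(base_G - mean_G) / gain_G``, since a red label band
  modulates green the most.
* R-squared for predicted-vs-true is the squared Pearson correlation;
  baseline regressions report the coefficient of determination
  (1 - SSres/SStot).  Both appear in the report under those names.
* Limits of agreement use the conventional 1.96 multiplier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from . import models, synthetic

__all__ = [
    "ConfusionMatrix",
    "BlandAltman",
    "CalibrationCurve",
    "LodResult",
    "confusion_and_accuracy",
    "r_squared",
    "bland_altman",
    "lod",
    "linear_fit_ldr",
    "colorimetric_intensity",
    "baseline_euclidean_fit",
    "baseline_channel_fit",
    "improvement_percent",
    "welch_ttest",
    "classify_clinical",
    "run_pipeline",
]

LOA_MULTIPLIER = 1.96
DEFAULT_LDR = (0.0, 0.4)  # ng/mL


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), true x predicted
    classes: np.ndarray
    overall_accuracy: float
    macro_recall: float


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    fraction_within: float


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    ldr: tuple[float, float]
    n_points: int


@dataclass
class LodResult:
    blank_mean: float  # ng/mL
    blank_sd: float  # ng/mL
    lod: float  # ng/mL

    @property
    def lod_pg_ml(self) -> float:
        return self.lod * 1000.0


def confusion_and_accuracy(true_labels, pred_labels) -> ConfusionMatrix:
    """Tally a true-by-predicted count matrix and accuracy summaries.

    ``overall_accuracy`` is trace/total; ``macro_recall`` the unweighted
    mean of per-class recalls (diagonal over row sum).
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label arrays must be non-empty and equal length")
    classes = np.unique(np.concatenate([t, p]))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, classes.size), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    overall = float(np.trace(counts) / counts.sum())
    row_sums = counts.sum(axis=1)
    present = row_sums > 0
    recalls = np.diag(counts)[present] / row_sums[present]
    return ConfusionMatrix(
        counts=counts,
        classes=classes,
        overall_accuracy=overall,
        macro_recall=float(recalls.mean()),
    )


def r_squared(pred, true) -> float:
    """Squared Pearson correlation of predictions against truth."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size != true.size or pred.size < 2:
        raise ValueError("need >= 2 paired values")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("constant input; correlation undefined")
    r = np.corrcoef(pred, true)[0, 1]
    return float(r * r)


def bland_altman(pred, true) -> BlandAltman:
    """Agreement of two measurements via the distribution of differences."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size != true.size or pred.size < 3:
        raise ValueError("need >= 3 paired values")
    diff = pred - true
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    within = float(np.mean((diff >= lo) & (diff <= hi)))
    return BlandAltman(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi, fraction_within=within)


def lod(blank_mean: float, blank_sd: float) -> LodResult:
    """Detection limit as blank mean plus three blank SDs (ng/mL in, ng/mL out)."""
    if blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    return LodResult(blank_mean=blank_mean, blank_sd=blank_sd, lod=blank_mean + 3.0 * blank_sd)


def colorimetric_intensity(rgb: np.ndarray, params: synthetic.AssayParams) -> np.ndarray:
    """Normalized green-channel depletion of each RGB triple."""
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))
    return (params.channel_base[1] - rgb[:, 1]) / params.channel_gain[1]


def linear_fit_ldr(
    conc, intensity, ldr: tuple[float, float] = DEFAULT_LDR
) -> CalibrationCurve:
    """OLS of intensity on concentration, restricted to the linear range."""
    conc = np.asarray(conc, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    mask = (conc >= ldr[0]) & (conc <= ldr[1])
    x, y = conc[mask], intensity[mask]
    if x.size < 3:
        raise ValueError(f"need >= 3 points inside the linear range {ldr}")
    if np.all(x == x[0]):
        raise ValueError("all concentrations identical inside the linear range")
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r * r),
        ldr=ldr,
        n_points=int(x.size),
    )


def _simple_ols_r2(feature: np.ndarray, conc: np.ndarray) -> float:
    """Coefficient of determination of a 1-feature OLS fit."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(conc, dtype=float)
    a = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant target; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def baseline_euclidean_fit(records: list[synthetic.SampleRecord]) -> float:
    """R^2 of the classical distance-feature calibration.

    Feature: Euclidean distance of each RGB triple from the mean blank
    RGB; model: simple linear regression against true concentration.
    """
    blanks = [r for r in records if r.true_conc == 0.0]
    if not blanks:
        raise ValueError("no blank samples to anchor the distance feature")
    blank_rgb = np.mean([r.rgb for r in blanks], axis=0)
    rgb = np.array([r.rgb for r in records], dtype=float)
    conc = np.array([r.true_conc for r in records], dtype=float)
    dist = np.sqrt(((rgb - blank_rgb) ** 2).sum(axis=1))
    return _simple_ols_r2(dist, conc)


def baseline_channel_fit(records: list[synthetic.SampleRecord], channel: str) -> float:
    """R^2 of a single-channel linear calibration (channel in R, G, B)."""
    idx = {"R": 0, "G": 1, "B": 2}
    if channel not in idx:
        raise ValueError("channel must be one of R, G, B")
    rgb = np.array([r.rgb for r in records], dtype=float)
    conc = np.array([r.true_conc for r in records], dtype=float)
    return _simple_ols_r2(rgb[:, idx[channel]], conc)


def improvement_percent(model_r2: float, baseline_r2: float) -> float:
    """Relative correlation gain of the model over a baseline, in percent."""
    if baseline_r2 == 0:
        raise ValueError("baseline R^2 is zero; relative improvement undefined")
    return (model_r2 - baseline_r2) / baseline_r2 * 100.0


def welch_ttest(group_a, group_b) -> tuple[float, float]:
    """Two-tailed unequal-variance t-test (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def classify_clinical(pred_conc: float, threshold: float | None) -> str:
    """Dichotomize a predicted concentration at the clinical cut-off.

    The cut-off is not a property of the assay and must be configured;
    boundary equality counts as positive.
    """
    if threshold is None:
        raise ValueError(
            "clinical threshold not configured; set clinical.threshold_ng_ml"
        )
    return "positive" if pred_conc >= threshold else "negative"


# ---------------------------------------------------------------------------
# End-to-end report


def run_pipeline(config: dict) -> dict:
    """Run generate -> QC -> CV models -> statistics and return the report.

    ``config`` keys (all optional): ``matrix`` (PBS|serum), ``levels``,
    ``n_per_level``, ``enriched``, ``seed``, ``knn.k``, ``folds``,
    ``gpr.restarts``, ``clinical.threshold_ng_ml``,
    ``clinical.sample_concs`` (list of blinded predictions to call).
    The report echoes every parameter so reruns are reproducible; the
    same config and seed give a bit-identical report.
    """
    matrix = str(config.get("matrix", "PBS"))
    levels = list(config.get("levels", synthetic.LADDER_NG_ML))
    n_per_level = int(config.get("n_per_level", 15))
    enriched = bool(config.get("enriched", False))
    seed = int(config.get("seed", 0))
    n_folds = int(config.get("folds", 5))
    k = int(config.get("knn.k", 5))
    restarts = int(config.get("gpr.restarts", 2))

    params = synthetic.serum_params() if matrix.lower() == "serum" else synthetic.pbs_params()
    records = synthetic.generate_dataset(
        levels, n_per_level, matrix=matrix, enriched=enriched, params=params, seed=seed
    )
    records = [r for r in records if r.qc_pass]

    rgb = np.array([r.rgb for r in records], dtype=float)
    labels = np.array([r.class_label for r in records])
    conc = np.array([r.true_conc for r in records], dtype=float)

    knn_cv = models.cross_validate(rgb, labels, "knn", n_folds=n_folds, seed=seed, k=k)
    cm = confusion_and_accuracy(knn_cv.truths, knn_cv.predictions)

    gpr_cv = models.cross_validate(
        rgb, conc, "gpr", n_folds=n_folds, seed=seed, gpr_restarts=restarts
    )
    gpr_r2 = r_squared(gpr_cv.predictions, gpr_cv.truths)
    ba = bland_altman(gpr_cv.predictions, gpr_cv.truths)

    blank_mean, blank_sd = synthetic.blank_statistics(records, params)
    lod_result = lod(blank_mean, blank_sd)

    intensity = colorimetric_intensity(rgb, params)
    curve = linear_fit_ldr(conc, intensity)

    base_euclid = baseline_euclidean_fit(records)
    base_channels = {c: baseline_channel_fit(records, c) for c in ("R", "G", "B")}

    report = {
        "config": {
            "matrix": matrix,
            "levels": levels,
            "n_per_level": n_per_level,
            "enriched": enriched,
            "seed": seed,
            "folds": n_folds,
            "knn.k": k,
            "gpr.restarts": restarts,
        },
        "n_samples": len(records),
        "knn": {
            "confusion_counts": cm.counts.tolist(),
            "classes": cm.classes.tolist(),
            "overall_accuracy": cm.overall_accuracy,
            "macro_recall": cm.macro_recall,
        },
        "gpr": {
            "r_squared": gpr_r2,
            "bland_altman": asdict(ba),
        },
        "lod": {
            matrix: {
                "blank_mean_ng_ml": lod_result.blank_mean,
                "blank_sd_ng_ml": lod_result.blank_sd,
                "lod_ng_ml": lod_result.lod,
                "lod_pg_ml": lod_result.lod_pg_ml,
            }
        },
        "linear_fit": asdict(curve),
        "baselines": {
            "euclidean_r2": base_euclid,
            "channel_r2": base_channels,
            "gpr_improvement_vs_euclidean_pct": improvement_percent(gpr_r2, base_euclid),
            "gpr_improvement_vs_channels_pct": {
                c: improvement_percent(gpr_r2, v) for c, v in base_channels.items()
            },
        },
    }

    threshold = config.get("clinical.threshold_ng_ml")
    sample_concs = config.get("clinical.sample_concs")
    if sample_concs is not None:
        calls = [classify_clinical(float(c), threshold) for c in sample_concs]
        report["clinical"] = {
            "threshold_ng_ml": threshold,
            "predicted_conc_ng_ml": [float(c) for c in sample_concs],
            "calls": calls,
            "n_positive": sum(c == "positive" for c in calls),
        }
    return report


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, sort_keys=True)
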