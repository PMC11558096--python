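"""Synthetic strip datasets and rendered strip images.

Generates RGB records whose statistical structure matches what the
downstream calibration pipeline assumes: a 9-level concentration ladder,
monotone-decreasing RGB with concentration, concentration-domain blank
noise, and an optional pre-enrichment signal gain.

Noise is injected in the *concentration* domain so that back-calculated
blank statistics reproduce the configured blank mean/SD by construction;
pixel-level noise in rendered images is secondary and averages out over
region-of-interest means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LADDER_NG_ML",
    "AssayParams",
    "SampleRecord",
    "StripGeometry",
    "StripImage",
    "pbs_params",
    "serum_params",
    "dose_response",
    "inverse_dose_response",
    "generate_dataset",
    "generate_nontarget",
    "render_strip",
    "blank_statistics",
    "detectability_threshold",
    "records_to_frame",
    "records_from_frame",
]

#: Default concentration ladder in ng/mL (blank + 8 graded levels).
LADDER_NG_ML: tuple[float, ...] = (0.0, 0.02, 0.04, 0.1, 0.2, 0.4, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class AssayParams:
    """Dose-response and camera parameters of the synthetic assay.

    ``channel_gain`` orders G > B > R because a red colloidal-gold band
    absorbs green light most strongly; absolute gains are free parameters.
    ``lowend_noise_inflation`` widens the concentration noise of low
    nonzero levels (serum-like matrices) without touching the blanks.
    """

    linear_slope: float = 0.96041  # normalized intensity per ng/mL at c -> 0
    response_scale: float = 2.0  # ng/mL, saturation scale of the response
    blank_mean_conc: float = 0.0022  # ng/mL
    blank_sd_conc: float = 0.0021  # ng/mL
    enrichment_gain: float = 10.0
    channel_base: tuple[float, float, float] = (235.0, 235.0, 235.0)
    channel_gain: tuple[float, float, float] = (40.0, 150.0, 90.0)  # R, G, B
    lowend_noise_inflation: float = 1.0
    lowend_cutoff: float = 0.05  # ng/mL; inflation applies to 0 < c <= cutoff

    def __post_init__(self) -> None:
        if self.linear_slope <= 0 or self.response_scale <= 0:
            raise ValueError("linear_slope and response_scale must be > 0")
        if self.blank_sd_conc < 0:
            raise ValueError("blank_sd_conc must be >= 0")
        if self.enrichment_gain <= 0:
            raise ValueError("enrichment_gain must be > 0")
        if any(g <= 0 for g in self.channel_gain):
            raise ValueError("channel gains must be > 0")
        if any(not (0.0 <= b <= 255.0) for b in self.channel_base):
            raise ValueError("channel_base must lie in [0, 255]")
        if self.lowend_noise_inflation < 1.0:
            raise ValueError("lowend_noise_inflation must be >= 1")

    @property
    def max_intensity(self) -> float:
        """Largest signal intensity that keeps every channel >= 0."""
        return min(b / g for b, g in zip(self.channel_base, self.channel_gain))


def pbs_params(**overrides) -> AssayParams:
    """Buffer-matrix defaults (blank 0.0022 +/- 0.0021 ng/mL)."""
    return replace(AssayParams(), **overrides) if overrides else AssayParams()


def serum_params(**overrides) -> AssayParams:
    """Serum-matrix defaults: wider blank noise, inflated low-end noise."""
    base = AssayParams(
        blank_mean_conc=0.0025,
        blank_sd_conc=0.0026,
        lowend_noise_inflation=1.25,
    )
    return replace(base, **overrides) if overrides else base


@dataclass
class SampleRecord:
    """One strip's ground truth and measured color."""

    sample_id: str
    matrix: str  # PBS | serum | plasma
    analyte: str  # tau | Abeta40 | Abeta42 | blank
    true_conc: float  # ng/mL
    enriched: bool
    rgb: tuple[float, float, float]
    class_label: int
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.true_conc < 0:
            raise ValueError("true_conc must be >= 0")
        if any(not (0.0 <= v <= 255.0) for v in self.rgb):
            raise ValueError("rgb components must lie in [0, 255]")


@dataclass(frozen=True)
class StripGeometry:
    """Physical layout of a strip and its imaging scale."""

    strip_width_mm: float = 4.0
    strip_length_mm: float = 20.0
    line_separation_mm: float = 7.0
    control_pos_mm: float = 15.0  # control line center, from the upstream end
    band_width_mm: float = 1.0  # full width of the flat band core
    band_edge_sigma_mm: float = 0.12  # Gaussian shoulder scale
    mm_per_px: float = 0.05

    def __post_init__(self) -> None:
        if min(self.strip_width_mm, self.strip_length_mm, self.mm_per_px) <= 0:
            raise ValueError("geometry lengths must be > 0")
        if self.line_separation_mm <= 0:
            raise ValueError("line_separation_mm must be > 0")

    @property
    def test_pos_mm(self) -> float:
        return self.control_pos_mm - self.line_separation_mm

    def to_px(self, mm: float) -> float:
        return mm / self.mm_per_px


@dataclass
class StripImage:
    """A strip photograph (synthetic or real) with geometry metadata.

    ``pixels`` is (rows, cols, 3) float in [0, 255]; columns run along
    the flow axis.  ``ground_truth_rois`` maps band name to
    ``(col_start, col_stop)`` pixel bounds when known.
    """

    pixels: np.ndarray
    geometry: StripGeometry
    control_line_present: bool = True
    ground_truth_rois: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (rows, cols, 3)")
        n_rows = int(round(self.geometry.strip_width_mm / self.geometry.mm_per_px))
        n_cols = int(round(self.geometry.strip_length_mm / self.geometry.mm_per_px))
        if self.pixels.shape[:2] != (n_rows, n_cols):
            raise ValueError(
                f"pixel shape {self.pixels.shape[:2]} inconsistent with geometry "
                f"({n_rows}, {n_cols})"
            )

    def sidecar_json(self) -> str:
        meta = {
            "mm_per_px": self.geometry.mm_per_px,
            "strip_width_mm": self.geometry.strip_width_mm,
            "strip_length_mm": self.geometry.strip_length_mm,
            "line_separation_mm": self.geometry.line_separation_mm,
            "control_pos_mm": self.geometry.control_pos_mm,
            "control_line_present": self.control_line_present,
            "ground_truth_rois": {k: [int(a), int(b)] for k, (a, b) in self.ground_truth_rois.items()},
        }
        return json.dumps(meta, indent=2)


def dose_response(c: float | np.ndarray, params: AssayParams) -> float | np.ndarray:
    """Normalized colorimetric intensity at concentration ``c`` (ng/mL).

    Saturating exponential ``I(c) = s*K*(1 - exp(-c/K))`` with initial
    slope ``s`` and scale ``K``; within 10% of linear over the 0-0.4
    ng/mL range at the defaults.  Negative inputs (sub-background noise
    excursions) continue linearly so the map stays invertible.
    """
    c = np.asarray(c, dtype=float)
    s, k = params.linear_slope, params.response_scale
    out = np.where(c >= 0, s * k * (1.0 - np.exp(-np.clip(c, 0, None) / k)), s * c)
    return float(out) if out.ndim == 0 else out


def inverse_dose_response(intensity: float | np.ndarray, params: AssayParams) -> float | np.ndarray:
    """Concentration recovering ``dose_response``; the exact inverse map."""
    i = np.asarray(intensity, dtype=float)
    s, k = params.linear_slope, params.response_scale
    i_sat = s * k
    if np.any(i >= i_sat):
        raise ValueError("intensity at or beyond saturation; inverse undefined")
    out = np.where(i >= 0, -k * np.log(1.0 - np.clip(i, None, i_sat * (1 - 1e-15)) / i_sat), i / s)
    return float(out) if out.ndim == 0 else out


def _signal_intensity(c_eff: np.ndarray, enriched: bool, params: AssayParams) -> np.ndarray:
    """Gained intensity, capped so no channel leaves [0, 255]."""
    gain = params.enrichment_gain if enriched else 1.0
    return np.minimum(dose_response(c_eff, params) * gain, params.max_intensity)


def _rgb_from_intensity(intensity: np.ndarray, params: AssayParams) -> np.ndarray:
    base = np.asarray(params.channel_base)
    gains = np.asarray(params.channel_gain)
    rgb = base[None, :] - gains[None, :] * np.asarray(intensity)[:, None]
    return np.clip(rgb, 0.0, 255.0)


def _noise_sd(c: float, params: AssayParams) -> float:
    if 0.0 < c <= params.lowend_cutoff:
        return params.blank_sd_conc * params.lowend_noise_inflation
    return params.blank_sd_conc


def generate_dataset(
    levels: Sequence[float],
    n_per_level: int,
    matrix: str = "PBS",
    enriched: bool = False,
    params: AssayParams | None = None,
    seed: int = 0,
    on_underflow: str = "cap",
) -> list[SampleRecord]:
    """Simulate ``n_per_level`` strips at each ladder level.

    Each replicate's effective concentration is ``c + eps`` with
    ``eps ~ Normal(mu, sd(c))``; blanks get ``mu = blank_mean_conc``
    (nonspecific background binding), nonzero levels ``mu = 0``.  The
    effective concentration maps through the dose response (times the
    enrichment gain when ``enriched``) to a real-valued RGB triple.
    Deterministic given ``seed``.

    ``on_underflow`` controls what happens when a level's gained signal
    would push a channel below zero: ``"cap"`` (default) saturates the
    intensity at the representable maximum, ``"raise"`` reports the
    offending level instead.
    """
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    if on_underflow not in ("cap", "raise"):
        raise ValueError("on_underflow must be 'cap' or 'raise'")
    params = params or AssayParams()
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for label, c in enumerate(levels):
        if c < 0:
            raise ValueError(f"negative concentration level {c}")
        gain = params.enrichment_gain if enriched else 1.0
        if on_underflow == "raise" and dose_response(c, params) * gain > params.max_intensity:
            raise ValueError(
                f"channel underflow at level {c} ng/mL: gained intensity "
                f"{dose_response(c, params) * gain:.4g} exceeds the representable "
                f"maximum {params.max_intensity:.4g}"
            )
        mu = params.blank_mean_conc if c == 0.0 else 0.0
        eps = rng.normal(mu, _noise_sd(c, params), size=n_per_level)
        c_eff = c + eps
        intensity = _signal_intensity(c_eff, enriched, params)
        rgb = _rgb_from_intensity(intensity, params)
        for i in range(n_per_level):
            records.append(
                SampleRecord(
                    sample_id=f"{matrix}-L{label}-{i:03d}",
                    matrix=matrix,
                    analyte="blank" if c == 0.0 else "tau",
                    true_conc=float(c),
                    enriched=enriched,
                    rgb=tuple(float(v) for v in rgb[i]),
                    class_label=label,
                )
            )
    return records


def generate_nontarget(
    analyte: str,
    n: int,
    params: AssayParams | None = None,
    seed: int = 0,
    matrix: str = "PBS",
) -> list[SampleRecord]:
    """Strips exposed to a non-target analyte: blank-level signal only."""
    if analyte not in ("Abeta40", "Abeta42"):
        raise ValueError("non-target analyte must be Abeta40 or Abeta42")
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or AssayParams()
    rng = np.random.default_rng(seed)
    c_eff = rng.normal(params.blank_mean_conc, params.blank_sd_conc, size=n)
    rgb = _rgb_from_intensity(_signal_intensity(c_eff, False, params), params)
    return [
        SampleRecord(
            sample_id=f"{matrix}-{analyte}-{i:03d}",
            matrix=matrix,
            analyte=analyte,
            true_conc=0.0,
            enriched=False,
            rgb=tuple(float(v) for v in rgb[i]),
            class_label=0,
        )
        for i in range(n)
    ]


def _band_weight(col_mm: np.ndarray, center_mm: float, geometry: StripGeometry) -> np.ndarray:
    """Flat-core band profile with Gaussian shoulders, peak weight 1."""
    half = geometry.band_width_mm / 2.0
    d = np.abs(col_mm - center_mm)
    excess = np.clip(d - half, 0.0, None)
    return np.exp(-0.5 * (excess / geometry.band_edge_sigma_mm) ** 2)


def render_strip(
    record: SampleRecord,
    geometry: StripGeometry | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
    control_line_present: bool = True,
    params: AssayParams | None = None,
) -> StripImage:
    """Rasterize a strip photograph for one sample.

    The background sits at the assay's unstained base color; the test
    band's core color equals ``record.rgb``; the control band is drawn at
    a fixed strong intensity whenever ``control_line_present``.  Per-pixel
    Gaussian noise (SD ``pixel_noise_sd``) is added and the image clipped
    to [0, 255].
    """
    geometry = geometry or StripGeometry()
    params = params or AssayParams()
    n_rows = int(round(geometry.strip_width_mm / geometry.mm_per_px))
    n_cols = int(round(geometry.strip_length_mm / geometry.mm_per_px))
    margin = geometry.band_width_mm / 2.0 + 3.0 * geometry.band_edge_sigma_mm
    for name, pos in (("control", geometry.control_pos_mm), ("test", geometry.test_pos_mm)):
        if pos - margin < 0 or pos + margin > geometry.strip_length_mm:
            raise ValueError(f"{name} band at {pos} mm falls outside the strip")

    col_mm = (np.arange(n_cols) + 0.5) * geometry.mm_per_px
    base = np.asarray(params.channel_base)
    profile = np.tile(base, (n_cols, 1))  # (cols, 3)

    test_rgb = np.asarray(record.rgb, dtype=float)
    w_test = _band_weight(col_mm, geometry.test_pos_mm, geometry)
    profile += w_test[:, None] * (test_rgb - base)[None, :]

    if control_line_present:
        control_rgb = _rgb_from_intensity(
            np.array([0.9 * params.max_intensity]), params
        )[0]
        w_ctrl = _band_weight(col_mm, geometry.control_pos_mm, geometry)
        profile += w_ctrl[:, None] * (control_rgb - base)[None, :]

    pixels = np.broadcast_to(profile[None, :, :], (n_rows, n_cols, 3)).copy()
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels += rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 255.0)

    half_core_px = geometry.band_width_mm / 2.0 / geometry.mm_per_px

    def roi(center_mm: float) -> tuple[int, int]:
        c_px = geometry.to_px(center_mm)
        return (int(math.ceil(c_px - half_core_px)), int(math.floor(c_px + half_core_px)))

    rois = {"test": roi(geometry.test_pos_mm)}
    if control_line_present:
        rois["control"] = roi(geometry.control_pos_mm)
    return StripImage(
        pixels=pixels,
        geometry=geometry,
        control_line_present=control_line_present,
        ground_truth_rois=rois,
    )


def blank_statistics(
    records: Iterable[SampleRecord],
    params: AssayParams | None = None,
) -> tuple[float, float]:
    """Back-calculated (mean, SD) of blank records in ng/mL.

    Each blank's green-channel depletion is converted to an intensity and
    pushed through the inverse dose response; sample statistics of the
    resulting concentration-equivalents are returned (SD with ddof=1).
    """
    params = params or AssayParams()
    blanks = [r for r in records if r.true_conc == 0.0]
    if len(blanks) < 2:
        raise ValueError("need at least 2 blank records")
    g_base, g_gain = params.channel_base[1], params.channel_gain[1]
    intensities = np.array([(g_base - r.rgb[1]) / g_gain for r in blanks])
    conc = inverse_dose_response(intensities, params)
    return float(np.mean(conc)), float(np.std(conc, ddof=1))


def detectability_threshold(
    params: AssayParams,
    levels: Sequence[float] = LADDER_NG_ML,
    enriched: bool = False,
    min_green_depletion: float = 20.0,
) -> float:
    """Lowest noise-free ladder level whose green depletion is 'visible'.

    A proxy for naked-eye detectability: the smallest level whose
    noise-free green-channel depletion reaches ``min_green_depletion``
    (out of 255).  Enrichment shifts this threshold down the ladder.
    """
    g_gain = params.channel_gain[1]
    for c in sorted(levels):
        if c == 0:
            continue
        depletion = g_gain * _signal_intensity(np.array([c]), enriched, params)[0]
        if depletion >= min_green_depletion:
            return float(c)
    raise ValueError("no ladder level reaches the depletion threshold")


_CSV_COLUMNS = [
    "sample_id", "matrix", "analyte", "true_conc_ng_ml",
    "enriched", "R", "G", "B", "class_label", "qc_pass",
]


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "matrix": r.matrix,
            "analyte": r.analyte,
            "true_conc_ng_ml": r.true_conc,
            "enriched": r.enriched,
            "R": r.rgb[0],
            "G": r.rgb[1],
            "B": r.rgb[2],
            "class_label": r.class_label,
            "qc_pass": r.qc_pass,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[SampleRecord]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")
    return [
        SampleRecord(
            sample_id=str(row.sample_id),
            matrix=str(row.matrix),
            analyte=str(row.analyte),
            true_conc=float(row.true_conc_ng_ml),
            enriched=bool(row.enriched),
            rgb=(float(row.R), float(row.G), float(row.B)),
            class_label=int(row.class_label),
            qc_pass=bool(row.qc_pass),
        )
        for row in df.itertuples(index=False)
    ]
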