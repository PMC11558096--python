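"""Locate control/test bands on strip images and extract test-line RGB.

Detection works on the green channel of the width-averaged longitudinal
profile (a red label band modulates green most strongly).  The adaptive
background is the profile median; a band is a contiguous run of columns
dipping more than a robust threshold below it.  Run validity is defined
by the control line: a strip without one fails QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import StripGeometry, StripImage

__all__ = [
    "LineProfile",
    "ExtractionResult",
    "longitudinal_profile",
    "detect_lines",
    "extract_rgb",
    "extract_strip",
    "qc_filter",
]


@dataclass
class LineProfile:
    """Width-averaged RGB as a function of position along the flow axis."""

    positions_mm: np.ndarray  # (n_cols,)
    mean_rgb: np.ndarray  # (n_cols, 3)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.mean_rgb = np.asarray(self.mean_rgb, dtype=float)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.mean_rgb.shape != (self.positions_mm.size, 3):
            raise ValueError("mean_rgb must be (n_positions, 3)")


@dataclass
class ExtractionResult:
    """Outcome of band detection and RGB extraction for one strip."""

    control_found: bool
    test_found: bool
    control_pos_mm: float | None
    test_pos_mm: float | None
    test_roi: tuple[int, int] | None  # column bounds [start, stop)
    mean_rgb: tuple[float, float, float] | None

    @property
    def qc_pass(self) -> bool:
        """Validity is defined by the control line alone."""
        return self.control_found


def longitudinal_profile(image: StripImage) -> LineProfile:
    """Per-column mean across the strip width, one value per channel."""
    px = image.pixels
    if px.shape[0] == 0 or px.shape[1] == 0:
        raise ValueError("empty image")
    mm = (np.arange(px.shape[1]) + 0.5) * image.geometry.mm_per_px
    return LineProfile(positions_mm=mm, mean_rgb=px.mean(axis=0))


def _band_runs(depth: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Contiguous index runs where ``depth > threshold`` ([start, stop))."""
    mask = depth > threshold
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def detect_lines(
    profile: LineProfile,
    geometry: StripGeometry,
    position_tol_mm: float = 1.5,
    min_depth: float = 1.0,
) -> ExtractionResult:
    """Find control and test bands on a longitudinal profile.

    Candidate bands are runs where the green channel drops below the
    median background by more than ``max(3 * robust SD, min_depth)``.
    The control band is the candidate nearest the expected control
    position; the test band must sit one line separation upstream of the
    detected control, within ``position_tol_mm``.  Absence is reported
    through the flags, never as an exception.  When the test band is too
    faint to detect (a blank strip), its ROI falls back to the expected
    window so a background-level RGB can still be read.
    """
    green = profile.mean_rgb[:, 1]
    background = float(np.median(green))
    robust_sd = 1.4826 * float(np.median(np.abs(green - background)))
    threshold = max(3.0 * robust_sd, min_depth)
    depth = background - green
    runs = _band_runs(depth, threshold)

    mm_per_px = geometry.mm_per_px
    half_core_px = geometry.band_width_mm / 2.0 / mm_per_px

    def run_center_mm(run: tuple[int, int]) -> float:
        lo, hi = run
        seg = depth[lo:hi]
        return float(np.average(profile.positions_mm[lo:hi], weights=seg))

    control_found = False
    control_pos = None
    control_run = None
    if runs:
        centers = [run_center_mm(r) for r in runs]
        idx = int(np.argmin([abs(c - geometry.control_pos_mm) for c in centers]))
        if abs(centers[idx] - geometry.control_pos_mm) <= position_tol_mm:
            control_found = True
            control_pos = centers[idx]
            control_run = runs[idx]

    expected_test_mm = (
        control_pos - geometry.line_separation_mm
        if control_pos is not None
        else geometry.test_pos_mm
    )
    test_found = False
    test_pos = None
    test_run = None
    for run, center in zip(runs, [run_center_mm(r) for r in runs]):
        if run is control_run:
            continue
        if abs(center - expected_test_mm) <= position_tol_mm:
            test_found = True
            test_pos = center
            test_run = run
            break

    if test_run is not None:
        # erode each side by the band-shoulder extent so only the flat
        # core contributes to the ROI mean; keep >= 3 central columns
        lo, hi = test_run
        erode = int(np.ceil(3.5 * geometry.band_edge_sigma_mm / mm_per_px))
        erode = max(1, min(erode, (hi - lo - 3) // 2))
        roi = (lo + erode, hi - erode) if hi - lo > 2 * erode + 2 else (lo, hi)
    else:
        center_px = expected_test_mm / mm_per_px
        roi = (
            int(np.ceil(center_px - half_core_px)),
            int(np.floor(center_px + half_core_px)),
        )
        roi = (max(roi[0], 0), min(roi[1], profile.positions_mm.size))

    return ExtractionResult(
        control_found=control_found,
        test_found=test_found,
        control_pos_mm=control_pos,
        test_pos_mm=test_pos,
        test_roi=roi,
        mean_rgb=None,
    )


def extract_rgb(image: StripImage, roi: tuple[int, int]) -> tuple[float, float, float]:
    """Arithmetic per-channel mean over the ROI columns (full width)."""
    lo, hi = roi
    if not (0 <= lo < hi <= image.pixels.shape[1]):
        raise ValueError(f"ROI {roi} outside image with {image.pixels.shape[1]} columns")
    block = image.pixels[:, lo:hi, :]
    if block.size == 0:
        raise ValueError("empty ROI")
    mean = block.reshape(-1, 3).mean(axis=0)
    return (float(mean[0]), float(mean[1]), float(mean[2]))


def extract_strip(image: StripImage, **detect_kwargs) -> ExtractionResult:
    """Full per-strip pass: profile, band detection, test-line RGB."""
    profile = longitudinal_profile(image)
    result = detect_lines(profile, image.geometry, **detect_kwargs)
    if result.test_roi is not None and result.test_roi[0] < result.test_roi[1]:
        result.mean_rgb = extract_rgb(image, result.test_roi)
    return result


def qc_filter(results: list[ExtractionResult]) -> list[ExtractionResult]:
    """Keep exactly the strips whose control line was found."""
    return [r for r in results if r.qc_pass]
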