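"""Reader-independent metrics and threshold classification.

Implements the elliptical ROI model, contrast and contrast difference,
lag-one coherence (LOC), the generalized contrast-to-noise ratio (gCNR)
with Wand's plug-in histogram bin selection, fixed-threshold fluid/solid
classification, sensitivity/specificity, and the harmonic-to-fundamental
amplitude-ratio contour analysis.

All metrics consume linear-scale (pre-normalization, pre-log) image
values; log-compressed images transparently expose their retained linear
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .beamform import BeamformedImage, coherence_stack
from .rf_data import AcquisitionGeometry, ChannelDataFrame

ROI_ROLES = ("mass", "tissue")

#: Fixed classification thresholds (mean LOC / contrast difference dB / gCNR).
DEFAULT_THRESHOLDS = {"loc": 0.28, "contrast_difference": 0.0, "gcnr": 0.73}

#: Lateral nearest-edge separation allowed between mass and tissue ROIs (mm).
LATERAL_SEPARATION_RANGE_MM = (0.9, 8.2)
#: Fallback nearest-edge depth offset limit when the mass spans the view (mm).
DEPTH_OFFSET_LIMIT_MM = 5.0


@dataclass(frozen=True)
class EllipseROI:
    """Elliptical region of interest in physical (mm) coordinates."""

    center_mm: tuple[float, float]  # (depth, lateral)
    semi_axes_mm: tuple[float, float]  # (depth, lateral)
    role: str = "mass"

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"role must be one of {ROI_ROLES}, got {self.role!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("ROI semi-axes must be positive")


def validate_roi_pair(mass: EllipseROI, tissue: EllipseROI) -> None:
    """Check the geometric pairing constraints between mass and tissue ROIs.

    The tissue ROI must match the mass ROI size and either sit at the
    same depth with a lateral nearest-edge separation of 0.9-8.2 mm, or
    (fallback, for masses spanning the lateral field of view) sit within
    5 mm nearest-edge depth offset.
    """
    if mass.role != "mass" or tissue.role != "tissue":
        raise ValueError("expected a (mass, tissue) ROI pair")
    if mass.semi_axes_mm != tissue.semi_axes_mm:
        raise ValueError("tissue ROI must have the same semi-axes as the mass ROI")
    same_depth = math.isclose(mass.center_mm[0], tissue.center_mm[0], abs_tol=1e-9)
    lat_gap = abs(mass.center_mm[1] - tissue.center_mm[1]) - 2.0 * mass.semi_axes_mm[1]
    lo, hi = LATERAL_SEPARATION_RANGE_MM
    if same_depth and lo <= lat_gap <= hi:
        return
    depth_gap = abs(mass.center_mm[0] - tissue.center_mm[0]) - 2.0 * mass.semi_axes_mm[0]
    if depth_gap < DEPTH_OFFSET_LIMIT_MM and not same_depth:
        return
    raise ValueError(
        "tissue ROI violates pairing constraints: need same-depth lateral "
        f"nearest-edge separation in [{lo}, {hi}] mm (got {lat_gap:.2f} mm) or a "
        f"depth offset < {DEPTH_OFFSET_LIMIT_MM} mm"
    )


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FN: int = 0
    TN: int = 0
    FP: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "TN", "FP"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass
class MassEvaluation:
    """Per-mass metric values and classification for one imaging mode."""

    mass_id: int
    band: str
    mode: str
    contrast_db: float
    contrast_difference_db: float
    mean_loc: float
    gcnr: float
    predicted: dict[str, str]  # metric name -> "fluid" | "solid"
    truth: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.gcnr <= 1.0):
            raise ValueError(f"gCNR must be in [0, 1], got {self.gcnr}")
        if not (-1.0 - 1e-9 <= self.mean_loc <= 1.0 + 1e-9):
            raise ValueError(f"mean LOC must be in [-1, 1], got {self.mean_loc}")


# ---------------------------------------------------------------------------
# ROI masking and basic metrics
# ---------------------------------------------------------------------------

def roi_mask(
    roi: EllipseROI,
    geometry: AcquisitionGeometry,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ellipse."""
    n_ax, n_lat = image_shape
    depth = geometry.sample_depth_mm(np.arange(n_ax))[:, None]
    if n_lat != geometry.n_scan_lines:
        raise ValueError("image lateral size does not match geometry scan lines")
    lateral = geometry.line_positions_mm()[None, :]
    cz, cx = roi.center_mm
    az, ax = roi.semi_axes_mm
    mask = ((depth - cz) / az) ** 2 + ((lateral - cx) / ax) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("ROI contains no pixels inside the image bounds")
    return mask


def _metric_values(image: BeamformedImage) -> np.ndarray:
    values = image.metric_values
    if image.mode == "DAS" and image.display_state == "linear":
        raise ValueError("B-mode metrics require envelope-detected values; run envelope_detect first")
    return values


def contrast(image: BeamformedImage, mass: EllipseROI, tissue: EllipseROI) -> float:
    """Contrast = 20 log10(mean_mass / mean_tissue), in dB."""
    values = _metric_values(image)
    mmask = roi_mask(mass, image.geometry, values.shape)
    tmask = roi_mask(tissue, image.geometry, values.shape)
    mu_mass = float(values[mmask].mean())
    mu_tissue = float(values[tmask].mean())
    if mu_tissue == 0.0:
        raise ValueError("tissue ROI mean is zero: contrast undefined")
    if mu_mass == 0.0:
        return -np.inf  # below-floor sentinel
    return 20.0 * math.log10(mu_mass / mu_tissue)


def contrast_difference(
    bmode: BeamformedImage,
    coherence: BeamformedImage,
    mass: EllipseROI,
    tissue: EllipseROI,
) -> float:
    """B-mode contrast minus coherence contrast (positive suggests fluid)."""
    if bmode.band != coherence.band:
        raise ValueError(f"band mismatch: {bmode.band!r} vs {coherence.band!r}")
    return contrast(bmode, mass, tissue) - contrast(coherence, mass, tissue)


def lag_one_coherence_map(frame: ChannelDataFrame, kernel_length: int = 5) -> BeamformedImage:
    """Lag-one coherence image (no zeroing; negative values retained)."""
    stack = coherence_stack(frame, M=1, kernel_length=kernel_length)
    return BeamformedImage(stack.lag_images[:, :, 0], "LOC", stack.band, "linear", stack.geometry)


def mean_loc(loc_map: BeamformedImage, mass: EllipseROI) -> float:
    """Arithmetic mean of the LOC map inside the mass ROI."""
    mask = roi_mask(mass, loc_map.geometry, loc_map.values.shape)
    return float(loc_map.metric_values[mask].mean())


# ---------------------------------------------------------------------------
# gCNR with Wand's plug-in bin selection
# ---------------------------------------------------------------------------

def _wand_psi2(x: np.ndarray, g: float) -> float:
    """Kernel estimate of psi_2 = int f''(x) f(x) dx (Gaussian kernel)."""
    n = len(x)
    total = 0.0
    chunk = 512
    inv_sqrt_2pi = 1.0 / math.sqrt(2.0 * math.pi)
    for start in range(0, n, chunk):
        u = (x[start : start + chunk, None] - x[None, :]) / g
        phi2 = (u * u - 1.0) * inv_sqrt_2pi * np.exp(-0.5 * u * u)
        total += phi2.sum()
    return total / (n * n * g**3)


def select_bin_count(values_mass, values_tissue) -> int:
    """Histogram bin count via Wand's one-stage plug-in rule on the pool.

    The bin width is h = (6 / (-psi2_hat * n))^(1/3) with psi2 estimated
    using a normal-scale bandwidth for psi4; the count is the pooled
    range divided by h, rounded up and clamped to >= 2.
    """
    x = np.concatenate([np.ravel(values_mass), np.ravel(values_tissue)]).astype(float)
    if len(np.ravel(values_mass)) < 2 or len(np.ravel(values_tissue)) < 2:
        raise ValueError("need at least 2 samples per ROI")
    n = len(x)
    rng_x = float(x.max() - x.min())
    sd = float(x.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0 or rng_x == 0.0:
        return 2
    # normal-scale psi4, then AMSE-optimal bandwidth for estimating psi2
    psi4_ns = 3.0 / (8.0 * math.sqrt(math.pi) * scale**5)
    g = (2.0 / math.sqrt(2.0 * math.pi) / (psi4_ns * n)) ** 0.2
    psi2 = _wand_psi2(x, g)
    if psi2 >= 0.0:  # degenerate estimate; fall back to the normal-reference rule
        h = 3.49 * scale * n ** (-1.0 / 3.0)
    else:
        h = (6.0 / (-psi2 * n)) ** (1.0 / 3.0)
    return max(2, int(math.ceil(rng_x / h)))


def gcnr(
    image: BeamformedImage,
    mass: EllipseROI,
    tissue: EllipseROI,
    n_bins: int | None = None,
) -> float:
    """gCNR = 1 - sum_j min(h_mass, h_tissue) over shared histogram bins."""
    values = _metric_values(image)
    mmask = roi_mask(mass, image.geometry, values.shape)
    tmask = roi_mask(tissue, image.geometry, values.shape)
    vm = values[mmask]
    vt = values[tmask]
    if n_bins is None:
        n_bins = select_bin_count(vm, vt)
    lo = float(min(vm.min(), vt.min()))
    hi = float(max(vm.max(), vt.max()))
    if lo == hi:
        return 0.0  # identical constant ROIs: full overlap
    edges = np.linspace(lo, hi, n_bins + 1)
    hm, _ = np.histogram(vm, bins=edges)
    ht, _ = np.histogram(vt, bins=edges)
    overlap = np.minimum(hm / hm.sum(), ht / ht.sum()).sum()
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


# ---------------------------------------------------------------------------
# classification and summary statistics
# ---------------------------------------------------------------------------

def classify_mass(
    mean_loc_value: float | None = None,
    contrast_difference_db: float | None = None,
    gcnr_value: float | None = None,
    thresholds: dict = DEFAULT_THRESHOLDS,
) -> dict[str, str]:
    """Per-metric fluid/solid label from the fixed thresholds.

    Fluid iff mean LOC < threshold, contrast difference > threshold, or
    gCNR > threshold.  Values exactly at a threshold classify as solid.
    """
    labels: dict[str, str] = {}
    if mean_loc_value is not None:
        labels["loc"] = "fluid" if mean_loc_value < thresholds["loc"] else "solid"
    if contrast_difference_db is not None:
        labels["contrast_difference"] = (
            "fluid" if contrast_difference_db > thresholds["contrast_difference"] else "solid"
        )
    if gcnr_value is not None:
        labels["gcnr"] = "fluid" if gcnr_value > thresholds["gcnr"] else "solid"
    return labels


@dataclass(frozen=True)
class ClassifierPerformance:
    sensitivity: float | None
    specificity: float | None

    @property
    def defined(self) -> bool:
        return self.sensitivity is not None and self.specificity is not None


def sensitivity_specificity(counts: ConfusionCounts) -> ClassifierPerformance:
    """Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); None if undefined."""
    sens = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) > 0 else None
    spec = counts.TN / (counts.TN + counts.FP) if (counts.TN + counts.FP) > 0 else None
    return ClassifierPerformance(sens, spec)


def confusion_from_labels(pairs: list[tuple[str, str]]) -> ConfusionCounts:
    """Counts from (truth, predicted) label pairs; 'mixed' truths skipped."""
    tp = fn = tn = fp = 0
    for truth, predicted in pairs:
        if truth == "mixed":
            continue
        if truth == "fluid":
            tp += predicted == "fluid"
            fn += predicted == "solid"
        else:
            tn += predicted == "solid"
            fp += predicted == "fluid"
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


# ---------------------------------------------------------------------------
# harmonic vs fundamental amplitude analysis
# ---------------------------------------------------------------------------

def harmonic_ratio_map(
    fund_env: BeamformedImage,
    harm_env: BeamformedImage,
    kernel: tuple[int, int] = (78, 15),
    level_range_db: tuple[float, float] = (-6.0, 21.0),
    level_step_db: float = 3.0,
) -> tuple[np.ndarray, float]:
    """Smoothed fundamental-over-harmonic amplitude ratio, in dB.

    Both envelope images are moving-average filtered with the given
    (axial samples x scan lines) kernel; the pixel-wise ratio
    20 log10(fund / harm) is quantized to ``level_step_db`` intervals
    within ``level_range_db`` for the contour map.  The returned mean is
    of the unquantized map; pixels with a zero harmonic value after
    filtering are excluded.
    """
    if fund_env.display_state != "envelope" or harm_env.display_state != "envelope":
        raise ValueError("harmonic_ratio_map expects envelope-detected images")
    if fund_env.values.shape != harm_env.values.shape:
        raise ValueError("image shape mismatch")
    ff = uniform_filter(fund_env.values, size=kernel, mode="nearest")
    fh = uniform_filter(harm_env.values, size=kernel, mode="nearest")
    ratio = np.full(ff.shape, np.nan)
    ok = (fh > 0) & (ff > 0)
    ratio[ok] = 20.0 * np.log10(ff[ok] / fh[ok])
    lo, hi = level_range_db
    quantized = np.clip(np.floor((ratio - lo) / level_step_db) * level_step_db + lo, lo, hi)
    if not ok.any():
        raise ValueError("no valid pixels for the amplitude ratio")
    mean_reduction = float(np.nanmean(ratio))
    return quantized, mean_reduction
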