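"""Amplitude and spatial-coherence image formation.

Implements delay-and-sum (DAS) beamforming, the normalized spatial
coherence function across receive-element lags, short-lag spatial
coherence (SLSC) imaging, its linearly lag-weighted variant (M-SLSC),
and display post-processing (envelope detection, normalization, log
compression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert

from .rf_data import AcquisitionGeometry, ChannelDataFrame

MODES = ("DAS", "SLSC", "M-SLSC", "r-SLSC", "R-SLSC", "LOC")
BANDS = ("fundamental", "harmonic")
DISPLAY_STATES = ("linear", "envelope", "log_compressed")

#: Kernel length (samples) used throughout unless overridden.
DEFAULT_KERNEL_LENGTH = 5
#: Default dynamic range (dB) for display.
DEFAULT_DYNAMIC_RANGE_DB = 60.0


def band_of_tag(polarity_tag: str) -> str:
    """Map a frame polarity tag to its display band."""
    return "harmonic" if polarity_tag == "harmonic" else "fundamental"


@dataclass
class BeamformedImage:
    """2-D beamformed image (axial pixel, lateral pixel).

    ``values`` are on the scale implied by ``display_state``.  After
    :func:`display_process` the pre-compression values are retained in
    ``linear`` so that metrics always read linear-scale data.
    """

    values: np.ndarray
    mode: str
    band: str
    display_state: str
    geometry: AcquisitionGeometry
    linear: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"image values must be 2-D, got shape {self.values.shape}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}, got {self.band!r}")
        if self.display_state not in DISPLAY_STATES:
            raise ValueError(f"display_state must be one of {DISPLAY_STATES}, got {self.display_state!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def metric_values(self) -> np.ndarray:
        """Linear-scale values, regardless of display processing."""
        if self.display_state == "log_compressed":
            if self.linear is None:
                raise ValueError("log-compressed image without retained linear values")
            return self.linear
        return self.values


@dataclass
class CoherenceStack:
    """Per-lag coherence images R_hat(m), m = 1..M, for one frame."""

    lag_images: np.ndarray  # (axial, lateral, lag)
    M: int
    kernel_length: int
    geometry: AcquisitionGeometry
    band: str = "fundamental"

    def __post_init__(self) -> None:
        self.lag_images = np.asarray(self.lag_images, dtype=np.float64)
        if self.lag_images.ndim != 3:
            raise ValueError("lag_images must be 3-D (axial, lateral, lag)")
        if self.M < 1 or self.lag_images.shape[2] != self.M:
            raise ValueError("lag axis must have length M >= 1")
        if self.kernel_length < 1 or self.kernel_length % 2 == 0:
            raise ValueError("kernel_length must be odd and >= 1")
        lo, hi = self.lag_images.min(), self.lag_images.max()
        if lo < -1.0 - 1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(f"coherence values outside [-1, 1]: [{lo}, {hi}]")


def _require_beamformable(frame: ChannelDataFrame) -> None:
    if not frame.delays_applied:
        raise ValueError("frame must have delays_applied=True before beamforming")
    if frame.n_elements < 2:
        raise ValueError("beamforming requires at least 2 receive elements")


def das_beamform(frame: ChannelDataFrame) -> BeamformedImage:
    """Delay-and-sum: per (depth, line) pixel, sum of s_i[n] over elements."""
    _require_beamformable(frame)
    values = frame.samples.sum(axis=1)
    return BeamformedImage(values, "DAS", band_of_tag(frame.polarity_tag), "linear", frame.geometry)


def envelope_detect(image: BeamformedImage) -> BeamformedImage:
    """Magnitude of the axial analytic signal of a linear DAS image."""
    if image.mode != "DAS":
        raise ValueError(f"envelope detection applies to DAS images only, got mode {image.mode!r}")
    if image.display_state != "linear":
        raise ValueError("envelope detection requires a linear-state image")
    if image.values.shape[0] < 2:
        raise ValueError("need at least 2 axial samples for envelope detection")
    env = np.abs(hilbert(image.values, axis=0))
    return BeamformedImage(env, "DAS", image.band, "envelope", image.geometry)


def _moving_sum(x: np.ndarray, size: int, axis: int = 0) -> np.ndarray:
    # zero-padded centered window == symmetric truncation at the edges
    return uniform_filter1d(x, size=size, axis=axis, mode="constant", cval=0.0) * size


def coherence_stack(
    frame: ChannelDataFrame,
    M: int,
    kernel_length: int = DEFAULT_KERNEL_LENGTH,
) -> CoherenceStack:
    """Normalized spatial coherence R_hat(m) for m = 1..M at every pixel.

    For each pixel (depth n, line) and lag m,

        R_hat(m) = 1/(N-m) * sum_i  sum_k s_i s_{i+m} / sqrt(sum_k s_i^2 * sum_k s_{i+m}^2)

    with the axial sums taken over the odd-length correlation kernel
    centered on the pixel depth (symmetrically truncated at the image
    edges).  Element pairs with zero energy inside the kernel contribute
    0 to the lag average.
    """
    _require_beamformable(frame)
    if kernel_length < 1 or kernel_length % 2 == 0:
        raise ValueError("kernel_length must be odd and >= 1")
    if kernel_length > frame.n_samples:
        raise ValueError("kernel_length exceeds the number of axial samples")
    N = frame.n_elements
    if not (1 <= M <= N - 1):
        raise ValueError(f"M must satisfy 1 <= M <= N-1 = {N - 1}, got {M}")

    s = frame.samples
    energy = _moving_sum(s * s, kernel_length, axis=0)  # (n, N, L)
    np.maximum(energy, 0.0, out=energy)  # filter round-off can dip below zero
    lag_images = np.empty((frame.n_samples, frame.n_lines, M))
    for m in range(1, M + 1):
        num = _moving_sum(s[:, : N - m, :] * s[:, m:, :], kernel_length, axis=0)
        denom = np.sqrt(energy[:, : N - m, :] * energy[:, m:, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0.0, num / denom, 0.0)
        np.clip(corr, -1.0, 1.0, out=corr)  # guard float round-off
        lag_images[:, :, m - 1] = corr.mean(axis=1)
    return CoherenceStack(lag_images, M, kernel_length, frame.geometry, band_of_tag(frame.polarity_tag))


def slsc_image(stack: CoherenceStack, M: int | None = None) -> BeamformedImage:
    """SLSC: sum R_hat(m) over m = 1..M; negative sums zeroed afterwards."""
    if M is None:
        M = stack.M
    if not (1 <= M <= stack.M):
        raise ValueError(f"M must satisfy 1 <= M <= stack.M = {stack.M}, got {M}")
    values = stack.lag_images[:, :, :M].sum(axis=2)
    np.maximum(values, 0.0, out=values)
    return BeamformedImage(values, "SLSC", stack.band, "linear", stack.geometry)


def m_slsc_weights(M: int) -> np.ndarray:
    """Linearly decreasing lag weights: 1 at lag 1 down to 1/M at lag M."""
    m = np.arange(1, M + 1, dtype=float)
    return 1.0 - (m - 1.0) / M


def m_slsc_image(stack: CoherenceStack, M: int | None = None) -> BeamformedImage:
    """M-weighted SLSC.

    Negative per-lag values are zeroed before the weighting, then the
    weighted per-lag images are summed.
    """
    if M is None:
        M = stack.M
    if not (1 <= M <= stack.M):
        raise ValueError(f"M must satisfy 1 <= M <= stack.M = {stack.M}, got {M}")
    positive = np.maximum(stack.lag_images[:, :, :M], 0.0)
    values = np.tensordot(positive, m_slsc_weights(M), axes=([2], [0]))
    return BeamformedImage(values, "M-SLSC", stack.band, "linear", stack.geometry)


def select_M(geometry: AcquisitionGeometry, fraction: float) -> int:
    """Lag cutoff covering a fraction of the receive aperture (ceiling)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    # tiny epsilon keeps exact integer products from rounding up
    return int(math.ceil(fraction * geometry.n_receive_elements - 1e-12))


def display_process(
    image: BeamformedImage,
    dynamic_range_db: float = DEFAULT_DYNAMIC_RANGE_DB,
) -> BeamformedImage:
    """Normalize to the image maximum, log compress, clip to -DR dB.

    The input linear values are retained on the result for metric use.
    """
    if image.display_state not in ("linear", "envelope"):
        raise ValueError("display_process expects a linear or envelope image")
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    mag = np.abs(image.values)
    peak = mag.max()
    if peak == 0.0:
        raise ValueError("all-zero image: normalization undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag / peak)
    db = np.maximum(db, -dynamic_range_db)
    return BeamformedImage(
        db, image.mode, image.band, "log_compressed", image.geometry, linear=image.values.copy()
    )
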