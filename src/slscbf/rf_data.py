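"""Data model and I/O for time-delayed RF channel data.

A :class:`ChannelDataFrame` holds per-element echo signals indexed
``(axial sample, receive element, scan line)`` together with the
acquisition geometry.  Pulse-inversion acquisitions come in
:class:`PulsePair` objects from which fundamental and harmonic channel
data are derived.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

POLARITY_TAGS = ("normal", "inverted", "fundamental", "harmonic")

#: HDF5 attributes required to reconstruct an AcquisitionGeometry.
_GEOMETRY_FIELDS = (
    "sampling_frequency",
    "transmit_center_frequency",
    "probe_center_frequency",
    "n_receive_elements",
    "n_scan_lines",
    "element_pitch_mm",
    "scan_line_spacing_mm",
    "sound_speed",
    "focal_depth_mm",
)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Receive geometry and sampling parameters of one acquisition.

    Defaults correspond to a 64-receive-element linear probe sampled at
    40 MHz with a 12.5 MHz probe center frequency, a 6 MHz transmit
    center frequency and 256 scan lines spaced 0.1 mm apart.
    """

    sampling_frequency: float = 40e6
    transmit_center_frequency: float = 6e6
    probe_center_frequency: float = 12.5e6
    n_receive_elements: int = 64
    n_scan_lines: int = 256
    element_pitch_mm: float = 0.2
    scan_line_spacing_mm: float = 0.1
    sound_speed: float = 1540.0
    focal_depth_mm: float = 15.0

    def __post_init__(self) -> None:
        for name in _GEOMETRY_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"geometry field {name!r} must be positive and finite, got {value!r}")
        if self.n_receive_elements < 2:
            raise ValueError("n_receive_elements must be >= 2")
        if int(self.n_receive_elements) != self.n_receive_elements:
            raise ValueError("n_receive_elements must be an integer")
        if int(self.n_scan_lines) != self.n_scan_lines:
            raise ValueError("n_scan_lines must be an integer")

    # ---- depth/sample bookkeeping (round-trip convention) -------------
    @property
    def mm_per_sample(self) -> float:
        """Axial extent of one sample: c / (2 fs), in mm."""
        return self.sound_speed / (2.0 * self.sampling_frequency) * 1e3

    def sample_depth_mm(self, n) -> np.ndarray:
        """Depth (mm) of 0-based axial sample ``n``."""
        return np.asarray(n, dtype=float) * self.mm_per_sample

    def depth_to_sample(self, depth_mm) -> np.ndarray:
        """Fractional axial sample index of a depth in mm."""
        return np.asarray(depth_mm, dtype=float) / self.mm_per_sample

    @property
    def samples_per_period(self) -> float:
        """Samples per period of the probe center frequency, fs / fc."""
        return self.sampling_frequency / self.probe_center_frequency

    def kernel_length_wavelengths(self, kernel_length: int) -> float:
        """Express an axial kernel length (samples) in probe wavelengths."""
        return kernel_length / self.samples_per_period

    def axial_extent_mm(self, n_samples: int) -> float:
        """Physical axial extent (mm) spanned by ``n_samples`` samples."""
        return n_samples * self.mm_per_sample

    # ---- lateral bookkeeping ------------------------------------------
    def element_offsets_mm(self) -> np.ndarray:
        """Element lateral offsets (mm) relative to the scan-line axis."""
        i = np.arange(self.n_receive_elements, dtype=float)
        return (i - (self.n_receive_elements - 1) / 2.0) * self.element_pitch_mm

    def line_positions_mm(self) -> np.ndarray:
        """Scan line lateral positions (mm), centered on 0."""
        l = np.arange(self.n_scan_lines, dtype=float)
        return (l - (self.n_scan_lines - 1) / 2.0) * self.scan_line_spacing_mm

    def to_attrs(self) -> dict:
        return {name: getattr(self, name) for name in _GEOMETRY_FIELDS}

    @classmethod
    def from_attrs(cls, attrs) -> "AcquisitionGeometry":
        missing = [name for name in _GEOMETRY_FIELDS if name not in attrs]
        if missing:
            raise ValueError(f"container missing geometry attributes: {missing}")
        kwargs = {name: attrs[name] for name in _GEOMETRY_FIELDS}
        for name in ("n_receive_elements", "n_scan_lines"):
            kwargs[name] = int(kwargs[name])
        for name in set(_GEOMETRY_FIELDS) - {"n_receive_elements", "n_scan_lines"}:
            kwargs[name] = float(kwargs[name])
        return cls(**kwargs)


@dataclass
class ChannelDataFrame:
    """Time-delayed RF channel data, indexed (axial, element, line)."""

    samples: np.ndarray
    geometry: AcquisitionGeometry
    polarity_tag: str
    delays_applied: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise ValueError(f"samples must be 3-D (axial, element, line), got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.polarity_tag not in POLARITY_TAGS:
            raise ValueError(f"polarity_tag must be one of {POLARITY_TAGS}, got {self.polarity_tag!r}")
        if self.samples.shape[1] != self.geometry.n_receive_elements:
            raise ValueError(
                f"element axis ({self.samples.shape[1]}) does not match geometry "
                f"n_receive_elements ({self.geometry.n_receive_elements})"
            )
        if self.samples.shape[2] != self.geometry.n_scan_lines:
            raise ValueError(
                f"line axis ({self.samples.shape[2]}) does not match geometry "
                f"n_scan_lines ({self.geometry.n_scan_lines})"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_elements(self) -> int:
        return self.samples.shape[1]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[2]

    def retagged(self, polarity_tag: str) -> "ChannelDataFrame":
        return dataclasses.replace(self, polarity_tag=polarity_tag)


@dataclass
class PulsePair:
    """Matched normal / inverted pulse acquisitions of the same scene."""

    normal: ChannelDataFrame
    inverted: ChannelDataFrame

    def __post_init__(self) -> None:
        if self.normal.polarity_tag != "normal":
            raise ValueError(f"first frame must be tagged 'normal', got {self.normal.polarity_tag!r}")
        if self.inverted.polarity_tag != "inverted":
            raise ValueError(f"second frame must be tagged 'inverted', got {self.inverted.polarity_tag!r}")
        if self.normal.samples.shape != self.inverted.samples.shape:
            raise ValueError(
                f"shape mismatch between pulses: {self.normal.samples.shape} vs {self.inverted.samples.shape}"
            )
        if self.normal.geometry != self.inverted.geometry:
            raise ValueError("geometry mismatch between the two pulses")


def make_fundamental(pair: PulsePair) -> ChannelDataFrame:
    """Fundamental channel data: the normal-pulse echoes, retagged."""
    if pair.normal.n_lines == 0 or pair.normal.n_samples == 0:
        raise ValueError("empty frame: cannot form fundamental channel data")
    return pair.normal.retagged("fundamental")


def make_harmonic(pair: PulsePair) -> ChannelDataFrame:
    """Harmonic channel data: element-wise sum of normal and inverted echoes.

    Pulse-inversion summation cancels the linear (odd-order) echo
    components and retains the even-order components.
    """
    if pair.normal.n_lines == 0 or pair.normal.n_samples == 0:
        raise ValueError("empty frame: cannot form harmonic channel data")
    summed = pair.normal.samples + pair.inverted.samples
    return ChannelDataFrame(
        samples=summed,
        geometry=pair.normal.geometry,
        polarity_tag="harmonic",
        delays_applied=pair.normal.delays_applied and pair.inverted.delays_applied,
    )


def apply_focal_delays(
    raw: np.ndarray,
    geometry: AcquisitionGeometry,
    polarity_tag: str = "normal",
    element_offsets_mm: np.ndarray | None = None,
) -> ChannelDataFrame:
    """Apply per-element receive delays for each line's focal point.

    The geometric receive-path excess of element ``i`` relative to the
    scan-line axis at the focal depth,

        tau_i = (sqrt(z_f^2 + d_i^2) - z_f) / c,

    is removed from channel ``i`` by linear-interpolation resampling
    along the axial axis (sub-sample shifts allowed).  Simulated data
    already aligned (zero element offsets) pass through unchanged.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ValueError(f"raw channel data must be 3-D (axial, element, line), got shape {raw.shape}")
    if raw.shape[1] != geometry.n_receive_elements:
        raise ValueError(
            f"element axis ({raw.shape[1]}) does not match geometry ({geometry.n_receive_elements})"
        )
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw channel data contains non-finite values")

    if element_offsets_mm is None:
        element_offsets_mm = geometry.element_offsets_mm()
    element_offsets_mm = np.asarray(element_offsets_mm, dtype=float)
    if element_offsets_mm.shape != (geometry.n_receive_elements,):
        raise ValueError("element_offsets_mm must have one entry per receive element")

    z_f = geometry.focal_depth_mm * 1e-3
    d = element_offsets_mm * 1e-3
    tau = (np.hypot(z_f, d) - z_f) / geometry.sound_speed  # seconds
    shift = tau * geometry.sampling_frequency  # samples; echoes arrive later on off-axis elements

    n_samples = raw.shape[0]
    grid = np.arange(n_samples, dtype=float)
    aligned = np.empty_like(raw)
    for i in range(geometry.n_receive_elements):
        pos = grid + shift[i]
        i0 = np.floor(pos).astype(int)
        frac = pos - i0
        i0c = np.clip(i0, 0, n_samples - 1)
        i1c = np.clip(i0 + 1, 0, n_samples - 1)
        valid = (pos >= 0) & (pos <= n_samples - 1)
        ch = raw[:, i, :]
        out = ch[i0c, :] * (1.0 - frac)[:, None] + ch[i1c, :] * frac[:, None]
        out[~valid, :] = 0.0
        aligned[:, i, :] = out
    return ChannelDataFrame(aligned, geometry, polarity_tag, delays_applied=True)


def write_frame(frame: ChannelDataFrame, path) -> None:
    """Write a frame to a single-file HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=frame.samples)
        for name, value in frame.geometry.to_attrs().items():
            f.attrs[name] = value
        f.attrs["polarity_tag"] = frame.polarity_tag
        f.attrs["delays_applied"] = bool(frame.delays_applied)


def read_frame(path) -> ChannelDataFrame:
    """Read a frame written by :func:`write_frame`."""
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise ValueError("container missing 'samples' dataset")
        samples = f["samples"][...]
        geometry = AcquisitionGeometry.from_attrs(f.attrs)
        for name in ("polarity_tag", "delays_applied"):
            if name not in f.attrs:
                raise ValueError(f"container missing attribute {name!r}")
        tag = str(f.attrs["polarity_tag"])
        delays = bool(f.attrs["delays_applied"])
    return ChannelDataFrame(samples, geometry, tag, delays_applied=delays)
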