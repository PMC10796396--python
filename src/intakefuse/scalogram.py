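"""Time-frequency transformation of accelerometer segments into scalogram images.

A 15-s tri-axial accelerometer segment (1920 samples per axis at 128 Hz) is
transformed, axis by axis, into the absolute magnitude of its continuous
wavelet transform (CWT) on a bank of generalized Morse wavelets, quantized to
8-bit, concatenated vertically (x, y, z) and bilinearly downsampled along the
time axis to a fixed 192 x 192 x 1 grayscale image suitable for a small CNN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 15.0
DEFAULT_SAMPLE_RATE_HZ = 128.0


@dataclass(frozen=True)
class Segment:
    """One fixed window of a tri-axial recording.

    samples has shape (n_samples, 3) in g-units; at the defaults
    (15 s @ 128 Hz) that is 1920 samples per axis.
    """

    samples: np.ndarray
    start_time_s: float
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError(f"segment samples must have shape (n, 3), got {s.shape}")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class CWTConfig:
    """Morse-wavelet filter-bank configuration.

    The frequency axis holds ``n_freq_bins`` center frequencies spanning
    [freq_min_hz, freq_max_hz]; geometric spacing is the natural CWT scale
    discretization and the default. The generalized Morse wavelet is
    parameterized by its symmetry ``gamma`` and time-bandwidth product
    ``P^2 = beta * gamma``.
    """

    n_freq_bins: int = 64
    freq_min_hz: float = 1.0
    freq_max_hz: float = 64.0
    morse_gamma: float = 3.0
    morse_time_bandwidth: float = 60.0
    freq_spacing: Literal["geometric", "linear"] = "geometric"
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.n_freq_bins < 2:
            raise ValueError("n_freq_bins must be >= 2")
        if not (0 < self.freq_min_hz < self.freq_max_hz):
            raise ValueError("need 0 < freq_min_hz < freq_max_hz")
        if self.freq_max_hz > self.sample_rate_hz / 2 + 1e-9:
            raise ValueError("freq_max_hz exceeds the Nyquist frequency")
        if self.freq_spacing not in ("geometric", "linear"):
            raise ValueError(f"unknown freq_spacing {self.freq_spacing!r}")

    @property
    def morse_beta(self) -> float:
        return self.morse_time_bandwidth / self.morse_gamma

    def frequencies_hz(self) -> np.ndarray:
        if self.freq_spacing == "geometric":
            return np.geomspace(self.freq_min_hz, self.freq_max_hz, self.n_freq_bins)
        return np.linspace(self.freq_min_hz, self.freq_max_hz, self.n_freq_bins)


@dataclass(frozen=True)
class RawScalogram:
    """Un-quantized CWT magnitude |C(a, b)| on the (frequency, time) grid."""

    magnitude: np.ndarray  # (n_freq_bins, n_samples), >= 0
    freq_axis_hz: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=float)
        if m.ndim != 2:
            raise ValueError("magnitude must be 2-D")
        if np.any(m < 0):
            raise ValueError("scalogram magnitudes must be non-negative")
        object.__setattr__(self, "magnitude", m)


@dataclass(frozen=True)
class ScalogramImage:
    """Final quantized 192 x 192 x 1 scalogram image of one segment."""

    pixels: np.ndarray  # uint8, (192, 192, 1)
    segment_id: str = ""
    start_time_s: float = 0.0
    label: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim == 2:
            p = p[:, :, None]
        if p.ndim != 3 or p.shape[2] != 1:
            raise ValueError(f"pixels must have shape (h, w, 1), got {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit unsigned integers")
        object.__setattr__(self, "pixels", p)


def morse_peak_radian_freq(gamma: float, beta: float) -> float:
    """Peak (modal) frequency of the Morse wavelet in radian units."""
    return (beta / gamma) ** (1.0 / gamma)


def morse_wavelet_freq(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain generalized Morse wavelet, peak-normalized to 2.

    Psi(w) = 2 exp(beta ln w - w^gamma - (beta ln w_p - w_p^gamma)) for w > 0,
    and 0 for w <= 0, where w_p = (beta/gamma)^(1/gamma) is the peak frequency.
    The analytic (one-sided) form means the CWT magnitude of a real sinusoid
    of amplitude A is approximately A at the matching frequency row.
    """
    omega = np.asarray(omega, dtype=float)
    wp = morse_peak_radian_freq(gamma, beta)
    log_peak = beta * np.log(wp) - wp**gamma
    out = np.zeros_like(omega)
    pos = omega > 0
    with np.errstate(divide="ignore"):
        out[pos] = 2.0 * np.exp(
            beta * np.log(omega[pos]) - omega[pos] ** gamma - log_peak
        )
    return out


def morse_filter_bank(n_samples: int, config: CWTConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build the bank of scaled Morse filters on the FFT frequency grid.

    Returns (freqs_hz, filters) with filters of shape (n_freq_bins, n_samples).
    Scales are chosen so each filter's peak lands on its center frequency;
    the bank uses L1 scale normalization (constant peak height across scales),
    so magnitudes directly read as oscillation amplitude.
    """
    gamma, beta = config.morse_gamma, config.morse_beta
    wp = morse_peak_radian_freq(gamma, beta)
    freqs = config.frequencies_hz()
    omega = 2.0 * np.pi * np.fft.fftfreq(n_samples)  # rad/sample
    scales = wp / (2.0 * np.pi * freqs / config.sample_rate_hz)
    filters = morse_wavelet_freq(scales[:, None] * omega[None, :], gamma, beta)
    return freqs, filters


def segment_signal(
    signal: np.ndarray,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    window_s: float = DEFAULT_WINDOW_S,
) -> list[Segment]:
    """Cut a tri-axial recording into consecutive non-overlapping windows.

    The trailing partial window is discarded; a recording shorter than one
    window yields an empty list.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 2 or sig.shape[1] != 3:
        raise ValueError(f"signal must have shape (n, 3), got {sig.shape}")
    win = int(round(window_s * sample_rate_hz))
    n_seg = sig.shape[0] // win
    return [
        Segment(sig[i * win : (i + 1) * win], start_time_s=i * window_s,
                sample_rate_hz=sample_rate_hz)
        for i in range(n_seg)
    ]


def cwt_scalogram(axis_signal: np.ndarray, config: CWTConfig | None = None) -> RawScalogram:
    """CWT magnitude of one axis on the configured frequency grid.

    FFT-based implementation: the signal spectrum is multiplied by each scaled
    analytic Morse filter and transformed back; the scalogram is the absolute
    magnitude. Linear in amplitude: cwt(k * s) = k * cwt(s).
    """
    config = config or CWTConfig()
    x = np.asarray(axis_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("axis_signal must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("axis_signal contains NaN or Inf")
    freqs, filters = morse_filter_bank(x.size, config)
    coeffs = np.fft.ifft(np.fft.fft(x)[None, :] * filters, axis=1)
    return RawScalogram(magnitude=np.abs(coeffs), freq_axis_hz=freqs)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (ties at .5 go up for non-negative input)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_scalogram(raw: RawScalogram | np.ndarray) -> np.ndarray:
    """Map a scalogram onto 8-bit pixels: min -> 0, max -> 255.

    I(x, y) = round(255 * (S - S_min) / (S_max - S_min)), rounding half away
    from zero and clipping to [0, 255]. A constant (degenerate) scalogram maps
    to all zeros with a logged warning rather than raising, so flat gaps in
    free-living recordings do not abort batch runs.
    """
    s = raw.magnitude if isinstance(raw, RawScalogram) else np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scalogram contains NaN or Inf")
    smin, smax = float(s.min()), float(s.max())
    if smax == smin:
        logger.warning("constant scalogram: quantizing to all zeros")
        return np.zeros(s.shape, dtype=np.uint8)
    scaled = 255.0 * (s - smin) / (smax - smin)
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


def bilinear_resize_width(image: np.ndarray, new_width: int) -> np.ndarray:
    """Bilinear resize along the time (column) axis with half-pixel centers.

    Each output column j samples source coordinate (j + 0.5) * w/new_w - 0.5
    and averages the two nearest columns with linear weights (the closest
    2-by-2 neighborhood degenerates to 2 columns because rows are untouched).
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    x = (np.arange(new_width) + 0.5) * (w / new_width) - 0.5
    x0 = np.clip(np.floor(x).astype(int), 0, w - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    frac = np.clip(x - x0, 0.0, 1.0)
    return img[:, x0] * (1.0 - frac) + img[:, x1] * frac


def assemble_scalogram(
    axis_scalograms: Sequence[np.ndarray],
    *,
    out_width: int = 192,
    segment_id: str = "",
    start_time_s: float = 0.0,
    label: int | None = None,
) -> ScalogramImage:
    """Concatenate the three per-axis quantized scalograms and downsample.

    The axis order is fixed (x, y, z): vertical concatenation gives a
    192 x 1920 image at defaults, then bilinear downsampling of the time axis
    yields the final 192 x 192 x 1 8-bit image (re-quantized by rounding).
    """
    if len(axis_scalograms) != 3:
        raise ValueError("exactly 3 per-axis scalograms are required (x, y, z)")
    shapes = {np.asarray(a).shape for a in axis_scalograms}
    if len(shapes) != 1:
        raise ValueError(f"per-axis scalogram shapes differ: {shapes}")
    stacked = np.vstack([np.asarray(a, dtype=float) for a in axis_scalograms])
    resized = bilinear_resize_width(stacked, out_width)
    pixels = np.clip(_round_half_away(resized), 0, 255).astype(np.uint8)
    return ScalogramImage(
        pixels=pixels[:, :, None],
        segment_id=segment_id,
        start_time_s=start_time_s,
        label=label,
    )


def segment_to_image(
    segment: Segment,
    config: CWTConfig | None = None,
    *,
    segment_id: str = "",
    label: int | None = None,
) -> ScalogramImage:
    """Full per-segment pipeline: per-axis CWT, 8-bit quantization, assembly.

    Quantization is applied per axis before concatenation so that one
    high-variance axis cannot blank the others.
    """
    config = config or CWTConfig(sample_rate_hz=segment.sample_rate_hz)
    quantized = [
        quantize_scalogram(cwt_scalogram(segment.samples[:, ax], config))
        for ax in range(3)
    ]
    return assemble_scalogram(
        quantized,
        segment_id=segment_id,
        start_time_s=segment.start_time_s,
        label=label,
    )
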