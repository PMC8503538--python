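"""HSV colour spectra from per-individual pixel sets.

A "colour spectrum" here is an individual's normalized frequency
distribution of one HSV channel over the pixels of its dorsal region of
interest.  The module converts calibrated 8-bit RGB pixels to HSV, strips
specular highlights (bright, desaturated pixels from reflected light), bins
each channel into a spectrum, and aggregates spectra across individuals
with highest-density bands for group-level plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv

from .summaries import hdi

__all__ = [
    "CHANNELS",
    "DEFAULT_BINS",
    "PixelSet",
    "HSVPixelSet",
    "ColourSpectrum",
    "GroupSpectrum",
    "rgb_to_hsv",
    "remove_specular",
    "build_spectrum",
    "aggregate_spectra",
]

CHANNELS = ("H", "S", "V")

# H: 1-degree bins; S, V: 256 bins mirroring 8-bit quantization
DEFAULT_BINS = {"H": 360, "S": 256, "V": 256}
_CHANNEL_RANGE = {"H": (0.0, 360.0), "S": (0.0, 1.0), "V": (0.0, 1.0)}
_CHANNEL_COL = {"H": 0, "S": 1, "V": 2}


@dataclass
class PixelSet:
    """Raw 8-bit RGB pixels of one individual's region of interest."""

    individual_id: str
    pixels: np.ndarray  # (n, 3) integers in [0, 255]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 3:
            raise ValueError("pixels must be an (n, 3) array of RGB triples")
        if self.pixels.shape[0] == 0:
            raise ValueError("no pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("RGB channel values must lie in [0, 255]")


@dataclass
class HSVPixelSet:
    """Pixels in cylindrical HSV coordinates: hue in degrees, S and V in [0, 1]."""

    individual_id: str
    pixels: np.ndarray  # (n, 3): hue deg [0, 360), saturation [0, 1], value [0, 1]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 3:
            raise ValueError("pixels must be an (n, 3) array of HSV triples")
        if self.pixels.shape[0] == 0:
            raise ValueError("no pixels")


@dataclass
class ColourSpectrum:
    """Normalized frequency distribution of one HSV channel for one individual."""

    individual_id: str
    channel: str
    bin_edges: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size != self.bin_edges.size - 1:
            raise ValueError("bin count must equal len(bin_edges) - 1")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GroupSpectrum:
    """Mean spectrum across individuals with per-bin highest-density bands."""

    channel: str
    bin_edges: np.ndarray
    mean_frequencies: np.ndarray
    lower_band: np.ndarray
    upper_band: np.ndarray
    mass: float = 0.95
    n_individuals: int = field(default=0)


def rgb_to_hsv(pixel_set: PixelSet) -> HSVPixelSet:
    """Convert 8-bit RGB pixels to HSV: hue in degrees, S and V in [0, 1].

    Achromatic pixels (R = G = B) get hue 0 and saturation 0 by convention.
    """
    rgb = np.asarray(pixel_set.pixels, dtype=float) / 255.0
    hsv = _mpl_rgb_to_hsv(rgb)
    hsv[:, 0] = (hsv[:, 0] * 360.0) % 360.0
    return HSVPixelSet(pixel_set.individual_id, hsv)


def remove_specular(hsv: HSVPixelSet, v_min: float = 0.95, s_max: float = 0.10) -> HSVPixelSet:
    """Drop specular-highlight pixels: bright (V >= v_min) AND desaturated (S <= s_max).

    Survivor order is preserved; removing every pixel is an error.
    """
    if not (0.0 <= v_min <= 1.0 and 0.0 <= s_max <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    px = hsv.pixels
    keep = ~((px[:, 2] >= v_min) & (px[:, 1] <= s_max))
    if not keep.any():
        raise ValueError("empty after highlight filter")
    return HSVPixelSet(hsv.individual_id, px[keep])


def build_spectrum(hsv: HSVPixelSet, channel: str, n_bins: int | None = None) -> ColourSpectrum:
    """Bin one HSV channel into a normalized spectrum.

    Bins are uniform over the channel's full range (H: [0, 360); S, V:
    [0, 1]) with the right edge of the last bin inclusive.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if n_bins is None:
        n_bins = DEFAULT_BINS[channel]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = hsv.pixels[:, _CHANNEL_COL[channel]]
    if values.size == 0:
        raise ValueError("no pixels")
    lo, hi = _CHANNEL_RANGE[channel]
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return ColourSpectrum(hsv.individual_id, channel, edges, counts / values.size)


def aggregate_spectra(spectra: list[ColourSpectrum], mass: float = 0.95) -> GroupSpectrum:
    """Mean spectrum over individuals with per-bin HDI bands at ``mass``.

    All spectra must share channel and bin edges.  With a single spectrum
    the bands coincide with it.
    """
    if not spectra:
        raise ValueError("no spectra to aggregate")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.channel != ref.channel or not np.array_equal(s.bin_edges, ref.bin_edges):
            raise ValueError("spectra mix channels or bin edges")
    mat = np.vstack([s.frequencies for s in spectra])
    mean = mat.mean(axis=0)
    if mat.shape[0] == 1:
        lower = upper = mat[0].copy()
    else:
        bands = np.array([hdi(mat[:, j], mass) for j in range(mat.shape[1])])
        lower, upper = bands[:, 0], bands[:, 1]
    return GroupSpectrum(
        channel=ref.channel,
        bin_edges=ref.bin_edges.copy(),
        mean_frequencies=mean,
        lower_band=lower,
        upper_band=upper,
        mass=mass,
        n_individuals=mat.shape[0],
    )
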