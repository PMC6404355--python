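"""Channel image quantification: axial profiles and membrane-damage readout.

The wet-lab readout images the extracted hydrogel strip on a flat-bed imager
with three dyes: the morphogen itself under UV transillumination (``chir_uv``),
CellTracker Deep Red for the cell distribution (``celltracker``) and EthD-1
for membrane-damaged cells (``ethd1``).  Quantification is areal intensity,
not cell counting:

* the axial profile is the per-column mean of in-mask pixel intensities,
* relative concentration is ``(I - background) / (I_sat - background)`` where
  the saturation anchor ``I_sat`` is the 99.5th-percentile intensity of the
  5% of the channel adjacent to the morphogen source (Inlet 2),
* per-section damage is the ratio of summed background-subtracted EthD-1 to
  summed background-subtracted CellTracker intensity, clipped to [0, 1].

Images are 16-bit grayscale rasters; columns run axially with the origin at
Inlet 1, so position = column index * pixel_size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diffusion import ConcentrationProfile
from .errors import InvalidParameterError
from .zonal import ZonalSection

DYES = ("chir_uv", "celltracker", "ethd1")

__all__ = [
    "DYES",
    "ChannelImage",
    "IntensityProfile",
    "extract_axial_profile",
    "estimate_background",
    "normalize_to_saturation",
    "damage_fraction_by_section",
    "as_concentration_profile",
    "read_channel_image",
    "write_channel_image",
    "write_mask",
    "read_mask",
]


@dataclass
class ChannelImage:
    """Per-dye 2D intensity raster with channel mask and pixel size."""

    pixels: np.ndarray  # (rows, cols), non-negative intensities
    dye: str
    pixel_size: float  # cm / px
    mask: "np.ndarray | None" = None  # boolean, True inside the channel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidParameterError("pixels must be a 2D raster")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("pixel intensities must be non-negative")
        if self.dye not in DYES:
            raise InvalidParameterError(f"dye must be one of {DYES}")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel_size must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise InvalidParameterError("mask shape must match pixels")


@dataclass
class IntensityProfile:
    """Mean in-channel intensity versus axial position."""

    positions: np.ndarray  # cm
    intensity: np.ndarray  # a.u., or [0, 1] once normalized
    normalized: bool = False
    dropped_columns: "tuple[int, ...]" = field(default=(), repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise InvalidParameterError("positions and intensity differ in length")
        if self.normalized and (
            self.intensity.min() < -1e-9 or self.intensity.max() > 1 + 1e-9
        ):
            raise InvalidParameterError("normalized profiles must lie in [0, 1]")


def extract_axial_profile(img: ChannelImage) -> IntensityProfile:
    """Per-axial-position mean of masked pixel intensities.

    Columns with an empty mask are dropped and reported on the profile.
    """
    counts = img.mask.sum(axis=0)
    if counts.sum() == 0:
        raise InvalidParameterError("mask is empty; no in-channel pixels")
    keep = counts > 0
    sums = np.where(img.mask, img.pixels, 0.0).sum(axis=0)
    means = sums[keep] / counts[keep]
    positions = np.arange(img.pixels.shape[1], dtype=float)[keep] * img.pixel_size
    dropped = tuple(int(i) for i in np.flatnonzero(~keep))
    return IntensityProfile(positions, means, False, dropped)


def estimate_background(img: ChannelImage) -> float:
    """Background as the median intensity outside the channel mask.

    Falls back to the image minimum when the mask covers the whole frame.
    """
    outside = img.pixels[~img.mask]
    if outside.size == 0:
        return float(img.pixels.min())
    return float(np.median(outside))


def normalize_to_saturation(
    profile: IntensityProfile,
    background: float,
    anchor_frac: float = 0.05,
    percentile: float = 99.5,
) -> IntensityProfile:
    """Rescale a profile to relative concentration in [0, 1].

    The saturation anchor is the ``percentile`` intensity of the
    Inlet-2-adjacent ``anchor_frac`` of the channel (the high-position end,
    where the source reservoir keeps the gel saturated).
    """
    x = profile.positions
    i = profile.intensity
    if i.max() <= background:
        raise InvalidParameterError("max intensity does not exceed background")
    span = x[-1] - x[0]
    anchor = i[x >= x[0] + (1.0 - anchor_frac) * span]
    if anchor.size == 0:
        raise InvalidParameterError("anchor region is empty")
    i_sat = float(np.percentile(anchor, percentile))
    if i_sat <= background:
        raise InvalidParameterError("saturation anchor does not exceed background")
    rel = np.clip((i - background) / (i_sat - background), 0.0, 1.0)
    return IntensityProfile(x.copy(), rel, True, profile.dropped_columns)


def as_concentration_profile(
    profile: IntensityProfile, time: float = 0.0, scale: float = 1.0
) -> ConcentrationProfile:
    """View an intensity profile as a concentration profile (relative units)."""
    return ConcentrationProfile(profile.positions, profile.intensity * scale, time)


def damage_fraction_by_section(
    ethd1: ChannelImage,
    celltracker: ChannelImage,
    sections: "list[ZonalSection]",
    background_ethd1: "float | None" = None,
    background_celltracker: "float | None" = None,
) -> np.ndarray:
    """Per-section membrane-damage fraction in [0, 1].

    fraction = sum(EthD-1 - bg) / sum(CellTracker - bg) over in-mask pixels of
    each section, clipped to [0, 1].  Sections without CellTracker signal are
    flagged with a warning and reported as NaN.
    """
    if ethd1.pixels.shape != celltracker.pixels.shape:
        raise InvalidParameterError("dye images must share geometry")
    if not np.array_equal(ethd1.mask, celltracker.mask):
        raise InvalidParameterError("dye images must share the channel mask")
    bg_e = estimate_background(ethd1) if background_ethd1 is None else background_ethd1
    bg_c = (
        estimate_background(celltracker)
        if background_celltracker is None
        else background_celltracker
    )
    cols = np.arange(ethd1.pixels.shape[1], dtype=float) * ethd1.pixel_size
    sig_e = np.where(ethd1.mask, np.clip(ethd1.pixels - bg_e, 0.0, None), 0.0)
    sig_c = np.where(
        celltracker.mask, np.clip(celltracker.pixels - bg_c, 0.0, None), 0.0
    )
    out = np.empty(len(sections))
    for i, sec in enumerate(sections):
        in_sec = (cols >= sec.x_lo) & (cols < sec.x_hi)
        if sec is sections[-1]:
            in_sec |= cols == sec.x_hi
        denom = sig_c[:, in_sec].sum()
        if denom <= 0:
            warnings.warn(
                f"section {sec.index}: no CellTracker signal, damage undefined",
                stacklevel=2,
            )
            out[i] = np.nan
            continue
        out[i] = np.clip(sig_e[:, in_sec].sum() / denom, 0.0, 1.0)
    return out


def _load_raster(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def read_channel_image(
    path, dye: str, pixel_size: float, mask: "np.ndarray | None" = None
) -> ChannelImage:
    """Read a 16-bit grayscale TIFF/PNG as a :class:`ChannelImage`."""
    return ChannelImage(_load_raster(path).astype(float), dye, pixel_size, mask)


def write_channel_image(img: ChannelImage, path) -> None:
    """Write pixels as 16-bit grayscale TIFF/PNG (values clipped to uint16)."""
    data = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def write_mask(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return _load_raster(path) > 0
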