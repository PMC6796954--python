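"""Specimen traits from three-view images or direct linear measurements.

Two traits are computed per specimen:

* **ellipsoid body volume** ``V = pi/6 * L * W * H`` with body length and
  width taken from the dorsal view and height from the lateral view (full
  axis lengths, head excluded by mask construction), and
* **body darkness**, the median of an inverted-intensity channel rescaled
  linearly onto ``[0, 222]`` (0 = pure white, 222 = pure black) over the
  body region (face/thorax/abdomen; wings and legs excluded by the mask).

The 0-222 ceiling mirrors the darkness scale conventionally reported for
these specimens; the median is taken from the integer-binned histogram with
the lower-median convention for even counts, matching histogram-based image
tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, MeasurementError

#: Ceiling of the darkness channel: 0 = all-white body, 222 = all-black.
DARKNESS_MAX = 222


# ----------------------------------------------------------------------
# containers

@dataclass
class ViewImage:
    """A single grayscale view plus its body-region mask."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.shape != self.mask.shape:
            raise InputError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class SpecimenImageSet:
    """Dorsal, lateral and anterior views of one pinned specimen.

    ``darkness_mask`` optionally overrides the dorsal body mask for the
    darkness measurement (the darkness region may include the face while
    the volume measurement excludes the head).
    """

    dorsal: ViewImage
    lateral: ViewImage
    anterior: ViewImage
    pixel_scale: float  # mm per pixel
    darkness_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise InputError(f"pixel_scale must be > 0, got {self.pixel_scale}")


@dataclass
class MorphMeasurement:
    """Linear dimensions (mm), ellipsoid volume (mm^3) and darkness."""

    length: float
    width: float
    height: float
    volume: float
    darkness: float


# ----------------------------------------------------------------------
# operations

def ellipsoid_volume(length: float, width: float, height: float) -> float:
    """Volume of an ellipsoid whose full axis lengths are L, W, H (mm)."""
    for name, v in (("length", length), ("width", width), ("height", height)):
        if not v > 0:
            raise InputError(f"{name} must be > 0, got {v}")
    return math.pi / 6.0 * length * width * height


def darkness_channel(image: np.ndarray) -> np.ndarray:
    """Map pixel intensities to integer darkness values on ``[0, 222]``.

    Intensity is inverted (dark pixels get high values) and rescaled
    linearly so that the minimum representable intensity maps to 222 and
    the maximum to 0.  Integer dtypes use their full range (255 for uint8,
    65535 for uint16); float images are interpreted on ``[0, 1]``.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        imax = float(np.iinfo(image.dtype).max)
    else:
        imax = 1.0
    dark = (imax - image.astype(np.float64)) * (DARKNESS_MAX / imax)
    return np.rint(dark).astype(np.int64)


def measure_darkness(image: np.ndarray, mask: np.ndarray) -> float:
    """Median darkness over the masked body region.

    The median is taken over the integer-binned darkness histogram with the
    lower-median convention for even pixel counts.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MeasurementError("darkness mask is empty")
    values = np.sort(darkness_channel(np.asarray(image)[mask]))
    med = float(values[(values.size - 1) // 2])
    return min(max(med, 0.0), float(DARKNESS_MAX))


def _mask_extent(mask: np.ndarray, axis: int) -> int:
    """Pixel extent of a mask along an axis (bounding-box width)."""
    proj = mask.any(axis=1 - axis)
    idx = np.flatnonzero(proj)
    return int(idx[-1] - idx[0] + 1)


def extract_dimensions(images: SpecimenImageSet) -> tuple[float, float, float]:
    """(length, width, height) in mm from the dorsal and lateral masks.

    Length is the horizontal (column) extent and width the vertical (row)
    extent of the dorsal body mask; height is the vertical extent of the
    lateral mask.  Extents are bounding-box pixel counts times
    ``pixel_scale``, so a single-pixel mask measures one pixel in each
    direction.
    """
    for name, view in (("dorsal", images.dorsal), ("lateral", images.lateral)):
        if not view.mask.any():
            raise MeasurementError(f"{name} body mask is empty")
    s = images.pixel_scale
    length = _mask_extent(images.dorsal.mask, axis=1) * s
    width = _mask_extent(images.dorsal.mask, axis=0) * s
    height = _mask_extent(images.lateral.mask, axis=0) * s
    return length, width, height


def measure_specimen(images: SpecimenImageSet) -> MorphMeasurement:
    """Full trait measurement: dimensions, ellipsoid volume and darkness.

    Darkness is measured on the dorsal view, using ``darkness_mask`` when
    provided (the darkness region may differ from the volume region).
    """
    length, width, height = extract_dimensions(images)
    volume = ellipsoid_volume(length, width, height)
    dmask = images.darkness_mask
    if dmask is None:
        dmask = images.dorsal.mask
    try:
        darkness = measure_darkness(images.dorsal.image, dmask)
    except MeasurementError as exc:
        raise MeasurementError(f"dorsal view: {exc}") from exc
    return MorphMeasurement(length, width, height, volume, darkness)
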