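"""Calibrated multi-channel image container and TIFF input/output.

Images are stored as ``(z, channel, y, x)`` arrays with a physical pixel
size in micrometres.  Channel semantics follow the staining convention of
the midgut assay: green = GFP clones, red = phalloidin gut outline,
blue = DAPI nuclei.  TIFFs are written in ImageJ layout with the pixel
size carried in the resolution tags, so files round-trip through Fiji.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "UncalibratedImageError",
    "DEFAULT_CHANNELS",
    "write_tiff",
    "read_tiff",
]

DEFAULT_CHANNELS = ("green", "red", "blue")


class UncalibratedImageError(ValueError):
    """Raised when an image has no pixel size and none was supplied."""


@dataclass
class CalibratedImage:
    """Pixel data of shape ``(n_z, n_channels, height, width)`` plus calibration."""

    data: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    image_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single plane, single channel
            self.data = self.data[None, None]
        elif self.data.ndim == 3:  # (c, y, x) single z
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (z, c, y, x) data, got shape {self.data.shape}")
        if self.pixel_size_um is None or self.pixel_size_um <= 0:
            raise UncalibratedImageError(
                f"pixel_size_um must be > 0, got {self.pixel_size_um}"
            )
        self.channel_names = tuple(self.channel_names)[: self.data.shape[1]]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("need one channel name per channel plane")

    @property
    def n_zplanes(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def channel(self, name: str, z: int | None = None) -> np.ndarray:
        """One channel plane: z-plane ``z``, or the max-projection if ``z`` is None."""
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present (have {self.channel_names})"
            ) from None
        if z is None:
            return self.data[:, c].max(axis=0)
        return self.data[z, c]

    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


def write_tiff(image: CalibratedImage, path) -> Path:
    """Write as an ImageJ-layout TIFF with pixel size in the resolution tags."""
    path = Path(path)
    per_px = Fraction(image.pixel_size_um).limit_denominator(10**6)
    resolution = (per_px.denominator, per_px.numerator)  # pixels per unit
    tifffile.imwrite(
        path,
        image.data,
        imagej=True,
        resolution=(resolution, resolution),
        metadata={"axes": "ZCYX", "unit": "um", "Labels": list(image.channel_names)},
    )
    return path


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, denom = tag.value
    if num == 0:
        return None
    # Only trust the resolution tags when the file declares micron units
    # (as our ImageJ-layout writer does); a bare default (1, 1) rational
    # in an unitless file is not a calibration.
    unit = (tif.imagej_metadata or {}).get("unit")
    if unit not in ("um", "micron", "µm"):
        return None
    return float(denom) / float(num)


def read_tiff(
    path,
    pixel_size_um: float | None = None,
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS,
) -> CalibratedImage:
    """Read a TIFF into a :class:`CalibratedImage`.

    The pixel size is taken from the file's resolution tags (micron units);
    an uncalibrated file is rejected unless ``pixel_size_um`` is passed
    explicitly.  Accepted layouts: ``(y, x)``, ``(c, y, x)``,
    ``(z, c, y, x)``; a 3-D stack whose leading axis is not declared as
    channels is treated as ``(c, y, x)``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        axes = tif.series[0].axes if tif.series else ""
        embedded = _pixel_size_from_tags(tif)
    if pixel_size_um is None:
        pixel_size_um = embedded
    if pixel_size_um is None:
        raise UncalibratedImageError(
            f"{path.name}: no pixel size in file; pass pixel_size_um explicitly"
        )
    if data.ndim == 3 and axes.startswith("Z") and "C" not in axes:
        data = data[:, None]  # (z, y, x) -> (z, 1, y, x)
    return CalibratedImage(
        data=data,
        pixel_size_um=pixel_size_um,
        channel_names=channel_names,
        image_id=path.stem,
    )
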