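"""In-memory containers for fluorescence images, z-stacks and label maps.

The containers are thin dataclasses around numpy arrays; TIFF round-tripping
goes through :mod:`tifffile` (one file per channel, one page per z-plane),
which is how confocal exports are commonly stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .errors import GeometryError, InvalidStackError

#: Recognised fluorescence channel tags.
CHANNELS = ("hoechst", "gfp", "pi")

#: Intensity ceiling used when images are written as 16-bit TIFF.
INTENSITY_MAX = 65535


@dataclass
class ChannelImage:
    """A single 2D fluorescence plane.

    Parameters
    ----------
    pixels : ndarray
        2D array of nonnegative intensities (any float/integer dtype).
    channel : str
        One of ``hoechst``, ``gfp``, ``pi``.
    pixel_size : float, optional
        Lateral pixel size in micrometres per pixel.
    """

    pixels: np.ndarray
    channel: str
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise GeometryError(f"expected a 2D image, got shape {self.pixels.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if np.min(self.pixels) < 0:
            raise ValueError("image intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ZStack:
    """An ordered stack of same-shape, same-channel planes.

    ``step`` is the axial spacing between consecutive planes in micrometres
    (confocal spheroid stacks here use 30 µm).
    """

    planes: Sequence[ChannelImage]
    step: float = 30.0

    def __post_init__(self) -> None:
        self.planes = list(self.planes)
        if len(self.planes) < 1:
            raise InvalidStackError("a z-stack needs at least one plane")
        shape = self.planes[0].shape
        channel = self.planes[0].channel
        for p in self.planes:
            if p.shape != shape:
                raise InvalidStackError("all planes in a stack must share one shape")
            if p.channel != channel:
                raise InvalidStackError("all planes in a stack must share one channel")

    @property
    def channel(self) -> str:
        return self.planes[0].channel

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    def as_array(self) -> np.ndarray:
        """Planes stacked along axis 0, shape (z, y, x)."""
        return np.stack([p.pixels for p in self.planes], axis=0)


@dataclass
class LabelMap:
    """Integer-labelled segmentation mask; 0 is background.

    ``kind`` records what the objects are (``nuclei``, ``cytoplasm`` or
    ``spheroid``).  Construction checks shape and dtype only; the stricter
    consecutive-label invariant is available via :meth:`validate` because
    cytoplasm rings can legitimately come out empty for a fully enclosed
    nucleus.
    """

    labels: np.ndarray
    kind: str = "nuclei"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise GeometryError(f"expected a 2D label map, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.kind not in ("nuclei", "cytoplasm", "spheroid"):
            raise ValueError(f"unknown label-map kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def label_set(self) -> set[int]:
        vals = np.unique(self.labels)
        return set(int(v) for v in vals if v > 0)

    def validate(self) -> None:
        """Assert labels are exactly {1..K} with no gaps."""
        present = sorted(self.label_set())
        if present and present != list(range(1, present[-1] + 1)):
            raise ValueError(f"label set has gaps: {present}")


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map the positive labels of ``labels`` onto 1..K preserving order."""
    labels = np.asarray(labels)
    vals = np.unique(labels)
    vals = vals[vals > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# TIFF I/O


def write_channel_tiff(path: str | Path, image: ChannelImage | ZStack) -> None:
    """Write one channel to a (multi-page) 16-bit TIFF, one page per plane."""
    data = image.as_array() if isinstance(image, ZStack) else image.pixels
    data = np.clip(np.rint(data), 0, INTENSITY_MAX).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_channel_tiff(
    path: str | Path, channel: str, step: float = 30.0, pixel_size: Optional[float] = None
) -> ChannelImage | ZStack:
    """Read a channel TIFF; returns a ChannelImage for single-page files,
    a ZStack otherwise."""
    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim == 2:
        return ChannelImage(data, channel, pixel_size)
    planes = [ChannelImage(p, channel, pixel_size) for p in data]
    return ZStack(planes, step=step)


def write_label_tiff(path: str | Path, labels: LabelMap) -> None:
    tifffile.imwrite(str(path), labels.labels.astype(np.int32))


def read_label_tiff(path: str | Path, kind: str = "nuclei") -> LabelMap:
    return LabelMap(tifffile.imread(str(path)), kind=kind)
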