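"""Core in-memory containers: multi-channel images and label masks.

A :class:`MultiChannelImage` is an (H, W, C) non-negative intensity grid with
named channels; a :class:`LabelMask` is an (H, W) integer grid aligned to an
image where 0 is background and k > 0 labels object k. Child masks (nucleoli
inside nuclei, cells around nuclei) carry an optional ``parent_map`` from the
child label to its parent label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChannelNotFound, MaskMismatch


@dataclass
class MultiChannelImage:
    pixels: np.ndarray                      # (H, W, C) float, >= 0
    channel_names: list[str]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be an (H, W, C) array")
        if len(self.channel_names) != self.pixels.shape[2]:
            raise ValueError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return the (H, W) intensity grid of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelNotFound(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.pixels[:, :, idx]


@dataclass
class LabelMask:
    labels: np.ndarray                      # (H, W) int, 0 = background
    parent_map: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def check_aligned(self, image: MultiChannelImage) -> None:
        if self.shape != image.shape:
            raise MaskMismatch(
                f"mask shape {self.shape} != image shape {image.shape}"
            )


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..N in raster order of each object's first pixel."""
    vals, first = np.unique(labels.ravel(), return_index=True)
    keep = vals > 0
    vals, first = vals[keep], first[keep]
    if vals.size == 0:
        return np.zeros_like(labels)
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    lut[vals[np.argsort(first)]] = np.arange(1, vals.size + 1, dtype=labels.dtype)
    return lut[labels]
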