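"""File I/O: multi-page TIFF images, channel configs, traces, truth sidecars.

Images travel as one TIFF page per channel plus a JSON sidecar recording
channel names (and pixel size); traces as two-column TSV with an optional
JSON ground-truth sidecar. Channel maps are JSON objects {name: page index}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import MultiChannelImage
from .polysome import PolysomeTrace


def write_image_tiff(path, image: MultiChannelImage) -> None:
    """Write channels as TIFF pages (C, H, W) plus a .json sidecar."""
    path = Path(path)
    pages = np.moveaxis(image.pixels, -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {"channel_names": image.channel_names,
               "pixel_size_um": image.pixel_size_um}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_image_tiff(path, channel_map: dict[str, int] | None = None
                    ) -> MultiChannelImage:
    """Read a single- or multi-page TIFF into a MultiChannelImage.

    ``channel_map`` maps channel names to page indices; without it the
    sidecar written by :func:`write_image_tiff` is used, falling back to
    generic names ``ch0..chN``.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    pixel_size = None
    if channel_map is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            names = list(meta["channel_names"])
            pixel_size = meta.get("pixel_size_um")
            pixels = np.moveaxis(arr, 0, -1)
            return MultiChannelImage(pixels.astype(float), names, pixel_size)
        channel_map = {f"ch{i}": i for i in range(arr.shape[0])}
    names = sorted(channel_map, key=channel_map.get)
    pixels = np.stack([arr[channel_map[n]] for n in names], axis=-1)
    return MultiChannelImage(pixels.astype(float), names, pixel_size)


def load_channel_config(path) -> dict[str, int]:
    """Load a JSON channel map, e.g. {"dna": 0, "marker": 1, "furd": 2}."""
    cfg = json.loads(Path(path).read_text())
    if not all(isinstance(v, int) for v in cfg.values()):
        raise ValueError("channel config values must be page indices")
    return cfg


def write_trace_tsv(path, trace: PolysomeTrace) -> None:
    pd.DataFrame({"x": trace.x, "od260": trace.y}).to_csv(
        path, sep="\t", index=False)


def write_truth_json(path, truth) -> None:
    """Write a ground-truth table (DataFrame or dict) as JSON."""
    path = Path(path)
    if isinstance(truth, pd.DataFrame):
        payload = truth.to_dict(orient="records")
    else:
        payload = truth
    path.write_text(json.dumps(payload, indent=1))
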