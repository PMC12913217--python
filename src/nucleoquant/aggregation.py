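"""Per-cell polyQ-EGFP aggregation quantification.

Aggregated polyQ-EGFP concentrates into bright foci next to darker
cytoplasm, giving the cell a "rough" intensity texture, while diffuse
protein gives a "smooth" one. This module quantifies that along two
complementary routes and combines them into a per-cell S0/S1/S2 score:

* **GLCM contrast** — Haralick contrast sum((i-j)^2 * P(i, j)) over a
  symmetric gray-level co-occurrence matrix accumulated from in-cell pixel
  pairs, with per-object min–max quantization; zero for a uniform cell,
  large for punctate signal.
* **Focus counting** — multi-scale Laplacian-of-Gaussian blob detection
  within each cell, thresholded at a prominence relative to the in-cell
  intensity range.
* **Scoring** — S0: no foci; S1: 1–5 foci; S2: more than 5 foci.

Cells are grown from nuclear seeds over the above-threshold EGFP region by
seeded watershed on the inverted intensity (each cell contains its seed
nucleus; when nothing exceeds the threshold a cell falls back to its
nucleus footprint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import mannwhitneyu
from skimage import measure, segmentation
from skimage.feature import blob_log, graycomatrix
from skimage.filters import threshold_otsu

from .datatypes import LabelMask, MultiChannelImage
from .errors import DegenerateObject, NoSeeds, TooFewCells

_ANGLE = {0: 0.0, 45: math.pi / 4, 90: math.pi / 2, 135: 3 * math.pi / 4}


@dataclass(frozen=True)
class TextureParams:
    """Gray-level co-occurrence settings (per-object min–max quantization)."""

    gray_levels: int = 64
    offset_distance_px: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.offset_distance_px < 1:
            raise ValueError("offset_distance_px must be >= 1")
        if not self.directions or any(d not in _ANGLE for d in self.directions):
            raise ValueError("directions must be a non-empty subset of "
                             "{0, 45, 90, 135}")


@dataclass
class CellAggregationMeasure:
    """Per-cell aggregation record; ``score`` in {S0, S1, S2}."""

    cell_id: int
    nucleus_id: int
    cell_area_px: int
    egfp_integrated: float
    glcm_contrast: float
    foci_count: int
    score: str


def score_from_count(foci_count: int) -> str:
    """S0 for 0 aggregates, S1 for 1–5, S2 for more than 5."""
    if foci_count == 0:
        return "S0"
    return "S1" if foci_count <= 5 else "S2"


def segment_cells(image: MultiChannelImage, signal_channel: str,
                  nuclei: LabelMask,
                  threshold: float | None = None) -> LabelMask:
    """Grow each nucleus into a cell over the above-threshold signal region.

    Seeded watershed on the inverted signal intensity, masked to the
    above-threshold region plus the seed nuclei; on intensity plateaus
    (e.g. two nuclei in one uniform blob) the flood advances at equal rate
    from every seed, so the boundary approximates the nearest-seed
    partition. Above-threshold pixels not connected to any nucleus stay
    unassigned; if nothing exceeds the threshold, each cell is exactly its
    nucleus footprint.
    """
    nuclei.check_aligned(image)
    if nuclei.ids.size == 0:
        raise NoSeeds("nuclei mask is empty")
    sig = image.channel(signal_channel)
    if threshold is None:
        threshold = float(threshold_otsu(sig)) if sig.max() > sig.min() \
            else float(sig.max())
    fg = sig > threshold
    seeds = nuclei.labels > 0
    if not fg.any():
        labels = nuclei.labels.copy()
    else:
        labels = segmentation.watershed(sig.max() - sig, markers=nuclei.labels,
                                        mask=fg | seeds)
    parent = {int(i): int(i) for i in np.unique(labels) if i > 0}
    return LabelMask(labels.astype(np.int32), parent_map=parent)


def _quantize(vals: np.ndarray, levels: int) -> np.ndarray:
    """Per-object min–max quantization to integer bins 0..levels-1."""
    lo, hi = vals.min(), vals.max()
    q = np.floor((vals - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint16)


def glcm_contrast(image: MultiChannelImage, signal_channel: str,
                  cells: LabelMask,
                  params: TextureParams = TextureParams()) -> dict[int, float]:
    """Haralick contrast of the signal texture inside each cell.

    Intensities are min–max quantized per object; pixels outside the cell
    are encoded as a sentinel gray level whose co-occurrence rows/columns
    are discarded, so only in-cell pixel pairs contribute. The contrast is
    averaged over the requested directions. Cells with zero intensity
    range score 0; a cell without a single valid pixel pair in some
    direction raises :class:`DegenerateObject`.
    """
    cells.check_aligned(image)
    sig = image.channel(signal_channel)
    L = params.gray_levels
    d = params.offset_distance_px
    angles = [_ANGLE[a] for a in params.directions]
    out: dict[int, float] = {}
    for region in measure.regionprops(cells.labels):
        cid = region.label
        sl = region.slice
        mask = cells.labels[sl] == cid
        vals = sig[sl][mask]
        if vals.size < 2:
            raise DegenerateObject(f"cell {cid} has fewer than 2 pixels")
        if vals.max() == vals.min():
            out[cid] = 0.0
            continue
        q = np.full(mask.shape, L, dtype=np.uint16)      # sentinel level
        q[mask] = _quantize(vals, L)
        glcm = graycomatrix(q, distances=[d], angles=angles, levels=L + 1,
                            symmetric=True, normed=False)
        i = np.arange(L, dtype=float)
        weights = (i[:, None] - i[None, :]) ** 2
        contrasts = []
        for k in range(len(angles)):
            p = glcm[:L, :L, 0, k].astype(float)
            tot = p.sum()
            if tot == 0:
                raise DegenerateObject(
                    f"cell {cid} has no pixel pair at distance {d} in "
                    f"direction {params.directions[k]}")
            contrasts.append(float((weights * p).sum() / tot))
        out[cid] = float(np.mean(contrasts))
    return out


def detect_foci(image: MultiChannelImage, signal_channel: str,
                cells: LabelMask, min_prominence: float = 0.05,
                focus_scale_px: tuple[float, float] = (1.0, 4.0),
                min_snr: float = 5.0) -> dict[int, int]:
    """Count bright foci per cell by multi-scale LoG blob detection.

    ``focus_scale_px`` bounds the focus radius. A blob is kept when its
    scale-normalized LoG response exceeds ``0.5 * min_prominence`` times
    the in-cell intensity range (the LoG response of a Gaussian spot at
    its matched scale is half the spot amplitude) *and* ``min_snr`` times
    the background fluctuation of the response field itself (a robust MAD
    estimate of the in-cell LoG response at the smallest scale); the
    second gate keeps signal-free cells, whose intensity range is pure
    noise, from producing spurious counts. Pixels outside the cell are
    padded with the in-cell median so the cell border itself does not
    respond. Empty or uniform cells count 0.
    """
    lo_r, hi_r = focus_scale_px
    if not 0 < lo_r < hi_r:
        raise ValueError("focus_scale_px must satisfy 0 < min < max")
    cells.check_aligned(image)
    sig = image.channel(signal_channel)
    pad = int(math.ceil(2 * hi_r)) + 2
    out: dict[int, int] = {}
    for region in measure.regionprops(cells.labels):
        cid = region.label
        y0 = max(0, region.slice[0].start - pad)
        y1 = min(sig.shape[0], region.slice[0].stop + pad)
        x0 = max(0, region.slice[1].start - pad)
        x1 = min(sig.shape[1], region.slice[1].stop + pad)
        mask = cells.labels[y0:y1, x0:x1] == cid
        vals = sig[y0:y1, x0:x1][mask]
        rng = float(vals.max() - vals.min()) if vals.size else 0.0
        if rng == 0.0:
            out[cid] = 0
            continue
        med = float(np.median(vals))
        crop = np.where(mask, sig[y0:y1, x0:x1], med)
        # background fluctuation of the detector response, not the raw
        # intensity: LoG filtering rescales the noise
        min_sigma = lo_r / math.sqrt(2)
        resp = -(min_sigma ** 2) * ndi.gaussian_laplace(crop, min_sigma)
        resp_in = resp[mask]
        noise = 1.4826 * float(np.median(np.abs(resp_in - np.median(resp_in))))
        thr = max(0.5 * min_prominence * rng, min_snr * noise)
        blobs = blob_log(crop, min_sigma=lo_r / math.sqrt(2),
                         max_sigma=hi_r / math.sqrt(2), num_sigma=8,
                         threshold=thr, overlap=0.3)
        count = 0
        for by, bx, _ in blobs:
            iy, ix = int(round(by)), int(round(bx))
            if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] \
                    and mask[iy, ix]:
                count += 1
        out[cid] = count
    return out


def measure_aggregation(image: MultiChannelImage, signal_channel: str,
                        nuclei: LabelMask,
                        cells: LabelMask | None = None,
                        params: TextureParams = TextureParams(),
                        min_prominence: float = 0.05,
                        focus_scale_px: tuple[float, float] = (1.0, 4.0),
                        min_egfp_integrated: float = 0.0
                        ) -> list[CellAggregationMeasure]:
    """Full per-cell pipeline: cells -> contrast -> foci -> S0/S1/S2 score.

    Cells whose integrated signal falls below ``min_egfp_integrated``
    (EGFP-negative, e.g. untransfected) are excluded from scoring.
    """
    if cells is None:
        cells = segment_cells(image, signal_channel, nuclei)
    contrast = glcm_contrast(image, signal_channel, cells, params)
    foci = detect_foci(image, signal_channel, cells, min_prominence,
                       focus_scale_px)
    sig = image.channel(signal_channel)
    out: list[CellAggregationMeasure] = []
    for region in measure.regionprops(cells.labels):
        cid = region.label
        mask = cells.labels[region.slice] == cid
        integrated = float(sig[region.slice][mask].sum())
        if integrated < min_egfp_integrated:
            continue
        parent = (cells.parent_map or {}).get(cid, cid)
        out.append(CellAggregationMeasure(
            cell_id=cid, nucleus_id=parent, cell_area_px=int(region.area),
            egfp_integrated=integrated, glcm_contrast=contrast[cid],
            foci_count=foci[cid], score=score_from_count(foci[cid])))
    return out


def score_cells(measures: list[CellAggregationMeasure]
                ) -> list[CellAggregationMeasure]:
    """(Re)assign S0/S1/S2 from each measure's ``foci_count``."""
    for m in measures:
        m.score = score_from_count(m.foci_count)
    return measures


def measures_to_frame(measures: list[CellAggregationMeasure]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in measures])


def texture_distribution(df: pd.DataFrame, value_col: str = "glcm_contrast",
                         condition_col: str = "condition"
                         ) -> tuple[pd.DataFrame, float]:
    """Per-condition contrast summaries and a two-sample rank-test p-value.

    Expects a tidy frame with one row per cell. Exactly two conditions are
    compared with a two-sided Mann–Whitney U test; each condition needs at
    least two cells.
    """
    groups = [(c, g[value_col].to_numpy())
              for c, g in df.groupby(condition_col, sort=False)]
    if len(groups) != 2:
        raise TooFewCells("texture_distribution compares exactly 2 conditions")
    if any(len(v) < 2 for _, v in groups):
        raise TooFewCells("need >= 2 cells per condition")
    summary = pd.DataFrame(
        [{"condition": c, "n": len(v), "median": float(np.median(v)),
          "q1": float(np.percentile(v, 25)), "q3": float(np.percentile(v, 75))}
         for c, v in groups])
    p = float(mannwhitneyu(groups[0][1], groups[1][1],
                           alternative="two-sided").pvalue)
    return summary, p
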