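"""Nucleolar segmentation and per-nucleus morphometry.

Nuclei are segmented from the DNA (Hoechst) channel by global Otsu
thresholding; nucleoli are segmented inside each nucleus by per-nucleus
Otsu thresholding of the nucleolar-marker channel (NCL/FBL, or FUrd for
the nascent-RNA variant), adjacent fragments merged, and each nucleolus
related to the nucleus containing its centroid. Per nucleus the module
reports:

* ``nucleolus_count`` — number of nucleoli;
* ``size_fold`` — total nucleolar area / nuclear area;
* ``presence_ratio`` — mean marker intensity over nucleolar pixels divided
  by the mean over nucleoplasmic pixels (nucleus minus nucleoli);
* integrated (sum), mean and median marker intensity over nucleolar pixels.

Areas are in pixels; square micrometres are reported additionally when the
image carries a pixel size. Coordinates are 0-based, row-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.exposure import rescale_intensity
from skimage.filters import threshold_otsu

from .datatypes import LabelMask, MultiChannelImage, relabel_raster_order
from .errors import MaskMismatch

#: a per-nucleus Otsu split is accepted as "nucleoli present" only when the
#: above-threshold mean exceeds the below-threshold mean by this factor;
#: guards against splitting unimodal noise in nucleoli-free nuclei
MIN_SPLIT_ENRICHMENT = 1.3


@dataclass
class NucleusMeasure:
    """Morphometry record for one nucleus.

    ``presence_ratio`` is NaN when the nucleus has no nucleoli or no
    nucleoplasmic pixels. ``qc_pass`` flags nuclei with plausible shape
    (solidity >= 0.8) and size (area <= 2x the 99th percentile).
    """

    nucleus_id: int
    nuclear_area_px: int
    nucleolus_count: int
    nucleolar_area_px: int
    size_fold: float
    marker_nucleolar_mean: float
    marker_nucleolar_median: float
    marker_nucleolar_integrated: float
    marker_nucleoplasm_mean: float
    presence_ratio: float
    qc_pass: bool


def segment_nuclei(image: MultiChannelImage, dna_channel: str = "dna",
                   min_area_px: int = 80,
                   exclude_border: bool = True) -> LabelMask:
    """Segment nuclei from the DNA channel by global Otsu thresholding.

    Holes are filled, objects below ``min_area_px`` removed, and (by
    default) objects touching any image edge discarded. Labels are numbered
    1..N in raster order of each object's first pixel. A constant image
    yields an empty mask.
    """
    ch = image.channel(dna_channel)
    if ch.max() == ch.min():
        return LabelMask(np.zeros(image.shape, dtype=np.int32))
    mask = ch > threshold_otsu(ch)
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    if exclude_border:
        mask = segmentation.clear_border(mask)
    labels = measure.label(mask, connectivity=2).astype(np.int32)
    return LabelMask(relabel_raster_order(labels))


def segment_nucleoli(image: MultiChannelImage, marker_channel: str,
                     nuclei: LabelMask, merge_distance_px: int = 2,
                     min_area_px: int = 12,
                     min_split_enrichment: float = MIN_SPLIT_ENRICHMENT
                     ) -> LabelMask:
    """Segment nucleoli inside each nucleus from the marker channel.

    Candidates come from per-nucleus Otsu thresholding (accepted only when
    the above/below-threshold mean-intensity ratio reaches
    ``min_split_enrichment``); pixels outside every nucleus are discarded.
    Adjacent fragments are merged by dilation-union-relabel with radius
    ceil(merge_distance_px / 2), which joins objects whose boundary gap is
    at most 2*ceil(merge_distance_px / 2) pixels. Each final object is
    assigned the parent nucleus containing its centroid; objects whose
    centroid falls outside every nucleus are dropped.
    """
    nuclei.check_aligned(image)
    marker = image.channel(marker_channel)
    h, w = image.shape
    out = np.zeros((h, w), dtype=np.int32)
    parent_map: dict[int, int] = {}
    next_label = 1
    radius = max(1, math.ceil(merge_distance_px / 2))
    footprint = morphology.disk(radius)

    for region in measure.regionprops(nuclei.labels):
        nid = region.label
        sl = region.slice
        nuc_mask = nuclei.labels[sl] == nid
        vals = marker[sl][nuc_mask]
        if vals.max() == vals.min():
            continue
        th = threshold_otsu(vals)
        above = vals > th
        if not above.any() or above.all():
            continue
        mean_below = vals[~above].mean()
        if mean_below <= 0 or vals[above].mean() / mean_below < min_split_enrichment:
            continue
        cand = np.zeros(nuc_mask.shape, dtype=bool)
        cand[nuc_mask] = above
        merged = measure.label(morphology.dilation(cand, footprint),
                               connectivity=2)
        merged[~cand] = 0
        for obj in measure.regionprops(merged):
            if obj.area < min_area_px:
                continue
            cy, cx = obj.centroid
            py, px = int(round(cy)) + sl[0].start, int(round(cx)) + sl[1].start
            parent = int(nuclei.labels[py, px])
            if parent == 0:
                continue
            oy, ox = sl[0].start, sl[1].start
            coords = obj.coords
            out[coords[:, 0] + oy, coords[:, 1] + ox] = next_label
            parent_map[next_label] = parent
            next_label += 1

    out = relabel_raster_order(out)
    # remap parent ids after raster relabelling
    remapped: dict[int, int] = {}
    for region in measure.regionprops(out):
        y, x = region.coords[0]
        remapped[region.label] = int(nuclei.labels[y, x])
    # centroid-based parents computed above are authoritative; coords give
    # the same nucleus because candidates never cross nucleus boundaries
    return LabelMask(out, parent_map=remapped)


def _qc_flags(nuclei: LabelMask) -> dict[int, bool]:
    regions = measure.regionprops(nuclei.labels)
    if not regions:
        return {}
    areas = np.array([r.area for r in regions], dtype=float)
    max_area = 2.0 * np.percentile(areas, 99)
    return {r.label: bool(r.solidity >= 0.8 and r.area <= max_area)
            for r in regions}


def measure_nuclei(image: MultiChannelImage, marker_channel: str,
                   nuclei: LabelMask, nucleoli: LabelMask
                   ) -> list[NucleusMeasure]:
    """Per-nucleus morphometry over the marker channel.

    For each nucleus: the nucleolar region is the union of its child
    nucleoli, the nucleoplasm the remaining nuclear pixels (an exact
    disjoint partition of the nucleus), and ``presence_ratio`` the ratio
    of the two regions' mean marker intensities.
    """
    nuclei.check_aligned(image)
    nucleoli.check_aligned(image)
    if nucleoli.parent_map is None:
        raise MaskMismatch("nucleoli mask must carry a parent_map into nuclei")
    marker = image.channel(marker_channel)
    qc = _qc_flags(nuclei)
    children: dict[int, list[int]] = {}
    for child, parent in nucleoli.parent_map.items():
        children.setdefault(parent, []).append(child)

    out: list[NucleusMeasure] = []
    for region in measure.regionprops(nuclei.labels):
        nid = region.label
        sl = region.slice
        nuc_mask = nuclei.labels[sl] == nid
        kids = children.get(nid, [])
        child_lab = nucleoli.labels[sl]
        nucl_mask = np.isin(child_lab, kids) & nuc_mask if kids else \
            np.zeros_like(nuc_mask)
        plasm_mask = nuc_mask & ~nucl_mask
        m = marker[sl]
        nucl_vals = m[nucl_mask]
        plasm_vals = m[plasm_mask]
        n_area = int(nuc_mask.sum())
        c_area = int(nucl_mask.sum())
        if nucl_vals.size and plasm_vals.size and plasm_vals.mean() > 0:
            presence = float(nucl_vals.mean() / plasm_vals.mean())
        else:
            presence = float("nan")
        out.append(NucleusMeasure(
            nucleus_id=nid,
            nuclear_area_px=n_area,
            nucleolus_count=len(kids),
            nucleolar_area_px=c_area,
            size_fold=c_area / n_area,
            marker_nucleolar_mean=float(nucl_vals.mean()) if nucl_vals.size else 0.0,
            marker_nucleolar_median=float(np.median(nucl_vals)) if nucl_vals.size else 0.0,
            marker_nucleolar_integrated=float(nucl_vals.sum()),
            marker_nucleoplasm_mean=float(plasm_vals.mean()) if plasm_vals.size else 0.0,
            presence_ratio=presence,
            qc_pass=qc.get(nid, False),
        ))
    return out


def measures_to_frame(measures: list[NucleusMeasure],
                      pixel_size_um: float | None = None) -> pd.DataFrame:
    """Tabulate measures; adds area columns in µm² when pixel size is known."""
    df = pd.DataFrame([vars(m) for m in measures])
    if pixel_size_um is not None and not df.empty:
        df["nuclear_area_um2"] = df["nuclear_area_px"] * pixel_size_um ** 2
        df["nucleolar_area_um2"] = df["nucleolar_area_px"] * pixel_size_um ** 2
    return df


def measure_nascent_rna(image: MultiChannelImage, furd_channel: str,
                        nuclei: LabelMask, nucleoli: LabelMask) -> pd.DataFrame:
    """Nascent-RNA (FUrd) signal inside the nucleolus, per nucleus.

    Same pixel bookkeeping as :func:`measure_nuclei`, read over the FUrd
    channel; reports both the integrated (summed) and median nucleolar
    FUrd intensity.
    """
    rows = [{"nucleus_id": m.nucleus_id,
             "furd_nucleolar_integrated": m.marker_nucleolar_integrated,
             "furd_nucleolar_median": m.marker_nucleolar_median}
            for m in measure_nuclei(image, furd_channel, nuclei, nucleoli)]
    return pd.DataFrame(rows, columns=["nucleus_id",
                                       "furd_nucleolar_integrated",
                                       "furd_nucleolar_median"])


def qc_overlay(image: MultiChannelImage, nuclei: LabelMask,
               nucleoli: LabelMask | None = None) -> np.ndarray:
    """RGB quality-control composite with object outlines.

    The composite is a contrast-stretched (1st–99th percentile) mean of all
    channels; nucleus outlines are drawn in cyan, nucleolus outlines in
    red. Empty masks leave the composite unmodified.
    """
    nuclei.check_aligned(image)
    base = image.pixels.mean(axis=2)
    lo, hi = np.percentile(base, [1, 99])
    if hi <= lo:
        gray = np.zeros_like(base)
    else:
        gray = rescale_intensity(base, in_range=(lo, hi), out_range=(0.0, 1.0))
    rgb = np.stack([gray, gray, gray], axis=-1)
    if nuclei.ids.size:
        edge = segmentation.find_boundaries(nuclei.labels, mode="inner")
        rgb[edge] = (0.0, 1.0, 1.0)
    if nucleoli is not None and nucleoli.ids.size:
        nucleoli.check_aligned(image)
        edge = segmentation.find_boundaries(nucleoli.labels, mode="inner")
        rgb[edge] = (1.0, 0.0, 0.0)
    return rgb
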