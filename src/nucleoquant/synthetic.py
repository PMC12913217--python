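"""Ground-truthed synthetic micrographs and sucrose-gradient traces.

Three generators emulate the statistical structure the quantification
pipelines assume, each returning the rendered data *and* an exact truth
table derived from the internal noiseless label rendering:

* :func:`gen_nucleolar_scene` — nuclei (DNA channel) containing 0–6 bright
  nucleoli with a controllable marker enrichment over the nucleoplasm;
* :func:`gen_aggregation_scene` — cells whose polyQ-EGFP signal is either
  diffuse or concentrated into foci, with the per-cell total signal
  conserved across focus counts;
* :func:`gen_polysome_trace` — OD260 absorbance traces built as a baseline
  plus Gaussian (optionally exponentially-modified Gaussian) ribosomal
  peaks (40S, 60S, 80S monosome, disome, ...), with analytically known
  monosome and polysome areas.

All randomness flows through ``numpy.random.default_rng(spec.seed)``, so a
fixed spec reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import score_from_count
from .datatypes import LabelMask, MultiChannelImage
from .errors import InvalidSpec, PlacementInfeasible
from .polysome import PolysomeTrace

_MAX_TRIES = 5000


# ---------------------------------------------------------------------------
# disk placement / rendering helpers
# ---------------------------------------------------------------------------

def _paint_disk(canvas: np.ndarray, cy: float, cx: float, r: float,
                value: int) -> int:
    """Set pixels with center distance <= r to ``value``; return pixel count."""
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    canvas[y0:y1, x0:x1][inside] = value
    return int(inside.sum())


def _coverage_disk(h: int, w: int, cy: float, cx: float, r: float,
                   antialias: bool) -> tuple[slice, slice, np.ndarray]:
    """Per-pixel disk coverage in [0, 1] over the disk's bounding box."""
    y0, y1 = max(0, int(cy - r) - 2), min(h, int(cy + r) + 3)
    x0, x1 = max(0, int(cx - r) - 2), min(w, int(cx + r) + 3)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    if antialias:
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    else:
        cov = (dist <= r).astype(float)
    return slice(y0, y1), slice(x0, x1), cov


def _sample_radius(rng: np.random.Generator, mean: float, sd: float) -> float:
    r = rng.normal(mean, sd)
    return max(r, 0.5)


def _place_disks(rng: np.random.Generator, n: int, radius: tuple[float, float],
                 h: int, w: int, gap: float,
                 what: str) -> list[tuple[float, float, float]]:
    """Place n non-overlapping disks away from the image border."""
    placed: list[tuple[float, float, float]] = []
    for _ in range(n):
        r = _sample_radius(rng, *radius)
        lo_y, hi_y = r + 2.0, h - r - 3.0
        lo_x, hi_x = r + 2.0, w - r - 3.0
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementInfeasible(f"{what} radius {r:.1f} exceeds image")
        for _ in range(_MAX_TRIES):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + gap) ** 2
                     for py, px, pr in placed)
            if ok:
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementInfeasible(
                f"could not place {what} {len(placed) + 1}/{n} "
                f"after {_MAX_TRIES} tries")
    return placed


def _place_inside(rng: np.random.Generator, n: int, radius: tuple[float, float],
                  center: tuple[float, float], outer_r: float, margin: float,
                  gap: float, what: str,
                  fixed_radius: bool = False) -> list[tuple[float, float, float]]:
    """Place n disks fully inside a parent disk, pairwise edge gap >= gap.

    Sequential rejection sampling can wedge itself (an early central disk
    blocks the rest), so the whole constellation is restarted on failure.
    """
    for _ in range(200):                     # constellation restarts
        placed: list[tuple[float, float, float]] = []
        for _ in range(n):
            r = radius[0] if fixed_radius else _sample_radius(rng, *radius)
            max_d = outer_r - r - margin
            if max_d <= 0:
                raise PlacementInfeasible(f"{what} radius {r:.1f} exceeds parent")
            for _ in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                d = max_d * math.sqrt(rng.uniform(0, 1))
                cy = center[0] + d * math.sin(ang)
                cx = center[1] + d * math.cos(ang)
                ok = all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + gap) ** 2
                         for py, px, pr in placed)
                if ok:
                    placed.append((cy, cx, r))
                    break
            else:
                break                        # restart the constellation
        if len(placed) == n:
            return placed
    raise PlacementInfeasible(f"could not place {n} {what} disks in parent")


def _add_noise(pixels: np.ndarray, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return pixels
    return np.clip(pixels + rng.normal(0.0, sd, pixels.shape), 0.0, None)


# ---------------------------------------------------------------------------
# nucleolar scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleolarSceneSpec:
    """Layout and photometry of a two-channel (DNA, marker) nucleolar scene.

    ``nucleoli_per_nucleus`` is a probability table over counts 0..6;
    ``nucleolar_enrichment`` is the ratio of nucleolar to nucleoplasmic
    marker intensity (>= 1). ``min_nucleolus_gap_px`` keeps sibling
    nucleoli separable by the merge rule downstream.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_nuclei: int = 12
    nucleus_radius_px: tuple[float, float] = (20.0, 1.5)
    nucleoli_per_nucleus: dict[int, float] = field(
        default_factory=lambda: {0: 0.2, 1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2})
    nucleolus_radius_px: tuple[float, float] = (3.5, 0.4)
    nucleoplasm_intensity: float = 100.0
    nucleolar_enrichment: float = 2.0
    dna_intensity: float = 150.0
    background_intensity: float = 5.0
    noise_sd: float = 5.0
    min_nucleolus_gap_px: float = 3.0
    antialias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleolar_enrichment < 1:
            raise InvalidSpec("nucleolar_enrichment must be >= 1")
        if self.n_nuclei < 0:
            raise InvalidSpec("n_nuclei must be >= 0")
        keys = set(self.nucleoli_per_nucleus)
        if not keys <= set(range(7)):
            raise InvalidSpec("nucleoli counts must lie in 0..6")
        tot = sum(self.nucleoli_per_nucleus.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise InvalidSpec("nucleoli_per_nucleus probabilities must sum to 1")
        if self.noise_sd < 0 or self.background_intensity < 0 \
                or self.nucleoplasm_intensity < 0 or self.dna_intensity < 0:
            raise InvalidSpec("intensities and noise_sd must be >= 0")


@dataclass
class NucleolarScene:
    """Rendered scene plus exact per-nucleus ground truth."""

    image: MultiChannelImage                 # channels: dna, marker
    truth: pd.DataFrame                      # one row per nucleus
    nuclei: LabelMask
    nucleoli: LabelMask                      # parent_map -> nuclei
    noiseless: MultiChannelImage


def gen_nucleolar_scene(spec: NucleolarSceneSpec) -> NucleolarScene:
    """Render a nucleolar scene and its ground-truth morphometry table.

    Truth areas are pixel counts on the noiseless label rendering, so they
    are exactly recomputable by brute-force counting of the returned masks.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px

    nuclei_lab = np.zeros((h, w), dtype=np.int32)
    nucleoli_lab = np.zeros((h, w), dtype=np.int32)
    parent_map: dict[int, int] = {}

    centers = _place_disks(rng, spec.n_nuclei, spec.nucleus_radius_px,
                           h, w, gap=2.0, what="nucleus")
    counts = list(spec.nucleoli_per_nucleus)
    probs = [spec.nucleoli_per_nucleus[k] for k in counts]

    rows = []
    next_child = 1
    for nid, (cy, cx, r) in enumerate(centers, start=1):
        nuc_area = _paint_disk(nuclei_lab, cy, cx, r, nid)
        k = int(rng.choice(counts, p=probs))
        child_area = 0
        for ccy, ccx, cr in _place_inside(
                rng, k, spec.nucleolus_radius_px, (cy, cx), r,
                margin=2.0, gap=spec.min_nucleolus_gap_px, what="nucleolus"):
            child_area += _paint_disk(nucleoli_lab, ccy, ccx, cr, next_child)
            parent_map[next_child] = nid
            next_child += 1
        rows.append({"nucleus_id": nid, "nucleolus_count": k,
                     "nuclear_area_px": nuc_area,
                     "nucleolar_area_px": child_area,
                     "enrichment": spec.nucleolar_enrichment})
    # recount areas on the final label rendering (authoritative truth)
    for row in rows:
        row["nuclear_area_px"] = int((nuclei_lab == row["nucleus_id"]).sum())
    child_parent = np.zeros(next_child, dtype=np.int32)
    for c, p in parent_map.items():
        child_parent[c] = p
    child_area_of = np.bincount(child_parent[nucleoli_lab].ravel(),
                                minlength=spec.n_nuclei + 1)
    for row in rows:
        row["nucleolar_area_px"] = int(child_area_of[row["nucleus_id"]])

    dna = np.full((h, w), spec.background_intensity, dtype=float)
    marker = np.full((h, w), spec.background_intensity, dtype=float)
    if spec.antialias:
        for nid, (cy, cx, r) in enumerate(centers, start=1):
            sy, sx, cov = _coverage_disk(h, w, cy, cx, r, True)
            dna[sy, sx] += (spec.dna_intensity - spec.background_intensity) * cov
            marker[sy, sx] += (spec.nucleoplasm_intensity
                               - spec.background_intensity) * cov
        # nucleolar enrichment stays hard-edged so truth pixels are exact
    else:
        dna[nuclei_lab > 0] = spec.dna_intensity
        marker[nuclei_lab > 0] = spec.nucleoplasm_intensity
    marker[nucleoli_lab > 0] = (spec.nucleolar_enrichment
                                * spec.nucleoplasm_intensity)

    clean = np.stack([dna, marker], axis=-1)
    noisy = _add_noise(clean, spec.noise_sd, rng)
    names = ["dna", "marker"]
    truth = pd.DataFrame(rows, columns=["nucleus_id", "nucleolus_count",
                                        "nuclear_area_px", "nucleolar_area_px",
                                        "enrichment"])
    return NucleolarScene(
        image=MultiChannelImage(noisy, names),
        truth=truth,
        nuclei=LabelMask(nuclei_lab),
        nucleoli=LabelMask(nucleoli_lab, parent_map=parent_map),
        noiseless=MultiChannelImage(clean, names),
    )


# ---------------------------------------------------------------------------
# aggregation scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregationSceneSpec:
    """Cells with conserved total polyQ-EGFP signal, diffuse or in foci.

    For a cell with f > 0 foci, a ``focus_intensity_share`` fraction of
    ``total_signal_per_cell`` is split equally among f Gaussian foci
    (sigma = focus_radius_px / 2) and the remainder spread uniformly over
    the cell; with f = 0 the whole signal is uniform. Foci are renormalized
    on the pixel grid so the per-cell noiseless sum is conserved exactly.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    foci_count_per_cell: tuple[int, ...] = (0, 3, 7)
    n_cells: int | None = None
    cell_radius_px: tuple[float, float] = (25.0, 2.0)
    nucleus_radius_px: tuple[float, float] = (9.0, 1.0)
    total_signal_per_cell: float = 1.0e5
    focus_radius_px: float = 2.5
    focus_intensity_share: float = 0.6
    dna_intensity: float = 150.0
    background_intensity: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.focus_intensity_share <= 1.0:
            raise InvalidSpec("focus_intensity_share must lie in [0, 1]")
        if self.n_cells is not None \
                and self.n_cells != len(self.foci_count_per_cell):
            raise InvalidSpec("n_cells must equal len(foci_count_per_cell)")
        if any(f < 0 for f in self.foci_count_per_cell):
            raise InvalidSpec("foci counts must be >= 0")
        if self.total_signal_per_cell <= 0:
            raise InvalidSpec("total_signal_per_cell must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpec("noise_sd must be >= 0")


@dataclass
class AggregationScene:
    image: MultiChannelImage                 # channels: dna, egfp
    truth: pd.DataFrame                      # one row per cell
    cells: LabelMask
    nuclei: LabelMask
    noiseless: MultiChannelImage


def gen_aggregation_scene(spec: AggregationSceneSpec) -> AggregationScene:
    """Render a polyQ-EGFP scene with per-cell focus-count ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    n = len(spec.foci_count_per_cell)

    cells_lab = np.zeros((h, w), dtype=np.int32)
    nuclei_lab = np.zeros((h, w), dtype=np.int32)
    egfp = np.full((h, w), spec.background_intensity, dtype=float)
    dna = np.full((h, w), spec.background_intensity, dtype=float)

    centers = _place_disks(rng, n, spec.cell_radius_px, h, w,
                           gap=3.0, what="cell")
    sigma = spec.focus_radius_px / 2.0
    rows = []
    for cid, ((cy, cx, r), f) in enumerate(
            zip(centers, spec.foci_count_per_cell), start=1):
        cell_area = _paint_disk(cells_lab, cy, cx, r, cid)
        nr = min(_sample_radius(rng, *spec.nucleus_radius_px), r - 2.0)
        _paint_disk(nuclei_lab, cy, cx, nr, cid)
        dna[nuclei_lab == cid] = spec.dna_intensity

        mask = cells_lab == cid
        share = spec.focus_intensity_share if f > 0 else 0.0
        diffuse = spec.total_signal_per_cell * (1.0 - share) / cell_area
        egfp[mask] = diffuse
        if f > 0:
            alloc = spec.total_signal_per_cell * share / f
            foci = _place_inside(rng, f, (spec.focus_radius_px, 0.0),
                                 (cy, cx), r, margin=2 * spec.focus_radius_px,
                                 gap=spec.focus_radius_px, what="focus",
                                 fixed_radius=True)
            for fy, fx, _ in foci:
                y0, y1 = max(0, int(fy - 5 * sigma)), min(h, int(fy + 5 * sigma) + 2)
                x0, x1 = max(0, int(fx - 5 * sigma)), min(w, int(fx + 5 * sigma) + 2)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                bump = np.exp(-((yy - fy) ** 2 + (xx - fx) ** 2)
                              / (2 * sigma * sigma))
                bump *= mask[y0:y1, x0:x1]
                egfp[y0:y1, x0:x1] += bump * (alloc / bump.sum())
        rows.append({"cell_id": cid, "foci_count": f,
                     "expected_score": score_from_count(f),
                     "cell_area_px": cell_area,
                     "egfp_total_noiseless": float(egfp[mask].sum())})

    clean = np.stack([dna, egfp], axis=-1)
    noisy = _add_noise(clean, spec.noise_sd, rng)
    names = ["dna", "egfp"]
    truth = pd.DataFrame(rows)
    parent = {cid: cid for cid in range(1, n + 1)}
    return AggregationScene(
        image=MultiChannelImage(noisy, names),
        truth=truth,
        cells=LabelMask(cells_lab, parent_map=parent),
        nuclei=LabelMask(nuclei_lab),
        noiseless=MultiChannelImage(clean, names),
    )


# ---------------------------------------------------------------------------
# polysome traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    """Sum-of-peaks model of a sucrose-gradient OD260 absorbance trace.

    ``peaks`` lists (label, center, width, area) with strictly increasing
    centers in sedimentation order 40S < 60S < 80S < disome < heavier.
    The 80S component is the monosome; every component after it counts as
    polysome. Peak shape is Gaussian (area = amplitude * width * sqrt(2*pi))
    or exponentially-modified Gaussian when ``shape='emg'``.
    """

    peaks: tuple[tuple[str, float, float, float], ...]
    baseline: float = 0.005
    x_range: tuple[float, float] = (0.0, 100.0)
    n_samples: int = 1000
    noise_sd: float = 0.0
    shape: str = "gaussian"
    emg_tau: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 50:
            raise InvalidSpec("n_samples must be >= 50")
        centers = [p[1] for p in self.peaks]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise InvalidSpec("peak centers must be strictly increasing")
        labels = [p[0] for p in self.peaks]
        if "80S" not in labels:
            raise InvalidSpec("an 80S (monosome) component is required")
        if any(p[2] <= 0 for p in self.peaks):
            raise InvalidSpec("peak widths must be > 0")
        if any(p[3] < 0 for p in self.peaks):
            raise InvalidSpec("peak areas must be >= 0")
        if self.baseline < 0 or self.noise_sd < 0:
            raise InvalidSpec("baseline and noise_sd must be >= 0")
        if self.shape not in ("gaussian", "emg"):
            raise InvalidSpec("shape must be 'gaussian' or 'emg'")


def _component(spec: TraceSpec, x: np.ndarray, center: float, width: float,
               area: float) -> np.ndarray:
    if spec.shape == "gaussian":
        return area * np.exp(-((x - center) ** 2) / (2 * width * width)) \
            / (width * math.sqrt(2 * math.pi))
    from scipy.stats import exponnorm
    k = spec.emg_tau / width
    return area * exponnorm.pdf(x, k, loc=center, scale=width)


def gen_polysome_trace(spec: TraceSpec) -> tuple[PolysomeTrace, dict]:
    """Render a trace; truth holds analytic monosome/polysome areas.

    ``true_ratio`` is A_polysome / A_monosome (0 when there is monosome
    area but no polysome components).
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.x_range[0], spec.x_range[1], spec.n_samples)
    y = np.full_like(x, spec.baseline)
    mono_idx = [p[0] for p in spec.peaks].index("80S")
    a_mono = spec.peaks[mono_idx][3]
    a_poly = float(sum(p[3] for p in spec.peaks[mono_idx + 1:]))
    for _, center, width, area in spec.peaks:
        y += _component(spec, x, center, width, area)
    if spec.noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, spec.noise_sd, y.shape), 0.0, None)
    truth = {"A_monosome": float(a_mono), "A_polysome": a_poly,
             "true_ratio": (a_poly / a_mono) if a_mono > 0 else float("nan")}
    return PolysomeTrace(x=x, y=y, meta={"seed": spec.seed}), truth


def standard_polysome_spec(true_ratio: float, seed: int = 0,
                           n_samples: int = 1000, baseline: float = 0.005,
                           noise_sd: float = 0.002) -> TraceSpec:
    """Canonical HeLa-like profile with the requested polysome/monosome ratio.

    The 80S monosome dominates the profile (area 2.0); polysome area
    2.0 * true_ratio is split over disome..5-some with decreasing weight
    and increasing width, as in typical gradient traces.
    """
    a80 = 2.0
    weights = (0.35, 0.28, 0.22, 0.15)
    poly_labels = ("disome", "3-some", "4-some", "5-some")
    poly_centers = (45.0, 57.0, 70.0, 83.0)
    poly_widths = (3.5, 4.5, 5.5, 6.5)
    peaks = [("40S", 10.0, 1.5, 0.3), ("60S", 20.0, 1.8, 0.5),
             ("80S", 32.0, 2.2, a80)]
    for lab, c, wdt, wt in zip(poly_labels, poly_centers, poly_widths, weights):
        peaks.append((lab, c, wdt, wt * a80 * true_ratio))
    return TraceSpec(peaks=tuple(peaks), baseline=baseline,
                     n_samples=n_samples, noise_sd=noise_sd, seed=seed)
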