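"""Polysome-profile quantification from sucrose-gradient OD260 traces.

The algorithm anchors each trace at two valleys of the absorbance profile:

1. the local minimum between the large ribosomal subunit (60S) and the
   80S monosome — this becomes X = 0;
2. the local minimum between the monosome and the disome (the first peak
   after the monosome) — the boundary between the monosome and polysome
   integration windows.

Y is min–max normalized per sample (Y = 0 at the minimal OD260, Y = 1 at
the maximal), X is rescaled affinely so the first anchor maps to 0 and the
last datapoint to 100. The monosome fraction is the sum of normalized Y
from X = 0 to the monosome/disome valley, the polysome fraction the sum
from that valley to X = 100, and the reported statistic is their ratio
(polysome/monosome, "P/M"). Sample points before X = 0 (the 40S/60S
region) are excluded from both fractions.

The monosome is identified as the tallest peak of the smoothed profile,
which in these gradients is the dominant 80S peak. Valleys are located on
a centered moving-average smoothed copy and then refined to the raw-trace
argmin within half a smoothing window, so anchors are exact on noiseless
traces; plateau ties resolve to the leftmost index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (DegenerateTrace, DivisionByZero, EmptyWindow, NonMonotonicX,
                     NoValley, ParseError, TooFewPeaks)

#: minimum trace length; shorter series cannot resolve three peaks reliably
MIN_TRACE_LEN = 50

#: default smoothing window as a fraction of the trace length
DEFAULT_SMOOTH_FRAC = 0.02

#: peak prominence threshold as a fraction of the smoothed dynamic range
PEAK_PROMINENCE_FRAC = 0.02


@dataclass
class PolysomeTrace:
    """Raw (x, OD260) series with uniform x spacing."""

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ParseError("x and y must be 1-D arrays of equal length")
        if len(self.x) < MIN_TRACE_LEN:
            raise ParseError(f"trace needs >= {MIN_TRACE_LEN} samples")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            raise NonMonotonicX("x values must be strictly increasing")

    @property
    def uniform_spacing(self) -> bool:
        dx = np.diff(self.x)
        mean = dx.mean()
        return bool(np.max(np.abs(dx - mean)) <= 0.01 * mean)


@dataclass
class NormalizedTrace:
    """Min–max normalized trace with valley anchors.

    ``x_norm`` maps the 60S/80S valley to 0 and the last datapoint to 100;
    points before the valley carry negative x_norm and are excluded from
    the fraction sums.
    """

    x_norm: np.ndarray
    y_norm: np.ndarray
    anchor_start_idx: int
    anchor_mono_di_idx: int
    smoothing_window: int


@dataclass
class PolysomeQuant:
    """Monosome/polysome fraction sums and their ratio."""

    monosome_fraction: float
    polysome_fraction: float
    pm_ratio: float


def load_trace(path, dialect: str | None = None, resample: bool = False,
               meta: dict | None = None) -> PolysomeTrace:
    """Read a two-column (position, OD260) delimited text file.

    ``dialect`` is a column separator (e.g. ``'\\t'`` or ``','``); by
    default it is sniffed. A header row is detected and skipped. Traces
    with non-uniform x spacing (> 1% deviation) require ``resample=True``
    and are linearly interpolated onto a uniform grid of the same length.
    """
    try:
        df = pd.read_csv(path, sep=dialect, engine="python", header=None,
                         comment="#", skip_blank_lines=True)
    except Exception as exc:                     # noqa: BLE001 - wrap parser errors
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ParseError("expected two columns (position, OD260)")
    try:
        x = df.iloc[:, 0].astype(float).to_numpy()
        y = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric values in {path}") from exc
    trace = PolysomeTrace(x=x, y=y, meta=meta or {"path": str(path)})
    if not trace.uniform_spacing:
        warnings.warn("non-uniform x spacing; sum-based integration assumes "
                      "uniform sampling", stacklevel=2)
        if not resample:
            raise ParseError("non-uniform x spacing: pass resample=True to "
                             "interpolate onto a uniform grid")
        xu = np.linspace(x[0], x[-1], len(x))
        trace = PolysomeTrace(x=xu, y=np.interp(xu, x, y), meta=trace.meta)
    return trace


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    yp = np.pad(y, pad, mode="reflect")
    return np.convolve(yp, np.full(window, 1.0 / window), mode="valid")


def default_smoothing_window(n: int, frac: float = DEFAULT_SMOOTH_FRAC) -> int:
    """Odd centered-moving-average window, ``frac`` of the trace length."""
    w = max(1, int(round(frac * n)))
    return w + 1 if w % 2 == 0 else w


def _valley(y_s: np.ndarray, y_raw: np.ndarray, lo: int, hi: int,
            half: int) -> int:
    """Argmin between two peak indices, refined on the raw trace."""
    seg = y_s[lo:hi + 1]
    rel = int(np.argmin(seg))
    if rel == 0 or rel == len(seg) - 1:
        raise NoValley("monotone segment between detected peaks")
    idx = lo + rel
    a = max(lo + 1, idx - half)
    b = min(hi - 1, idx + half)
    return a + int(np.argmin(y_raw[a:b + 1]))


def find_anchor_valleys(trace: PolysomeTrace,
                        smoothing_window: int | None = None) -> tuple[int, int]:
    """Locate the 60S/80S valley and the monosome/disome valley.

    Returns raw-trace indices ``(anchor_start_idx, anchor_mono_di_idx)``.
    Requires at least three detectable peaks (60S, 80S, >= 1 polysome)
    with the tallest peak (the monosome) neither first nor last.
    """
    y = trace.y
    n = len(y)
    if smoothing_window is None:
        smoothing_window = default_smoothing_window(n)
    y_s = _smooth(y, smoothing_window)
    rng = float(y_s.max() - y_s.min())
    if rng <= 0:
        raise DegenerateTrace("flat trace")
    peaks, _ = find_peaks(y_s, prominence=PEAK_PROMINENCE_FRAC * rng)
    if len(peaks) < 3:
        raise TooFewPeaks(f"found {len(peaks)} peaks; need >= 3 "
                          "(60S, monosome, >= 1 polysome)")
    mono_pos = int(np.argmax(y_s[peaks]))
    if mono_pos == 0:
        raise TooFewPeaks("no peak precedes the monosome (60S not resolved)")
    if mono_pos == len(peaks) - 1:
        raise TooFewPeaks("no peak follows the monosome (no polysome peak)")
    half = smoothing_window // 2
    start = _valley(y_s, y, int(peaks[mono_pos - 1]), int(peaks[mono_pos]), half)
    mono_di = _valley(y_s, y, int(peaks[mono_pos]), int(peaks[mono_pos + 1]), half)
    return start, mono_di


def normalize_trace(trace: PolysomeTrace,
                    anchors: tuple[int, int],
                    smoothing_window: int = 1) -> NormalizedTrace:
    """Min–max normalize Y and rescale X so anchors[0] -> 0, last -> 100."""
    a0, a1 = anchors
    if not 0 <= a0 < a1 < len(trace.y):
        raise EmptyWindow("anchors must be ordered within the trace")
    ymin, ymax = float(trace.y.min()), float(trace.y.max())
    if ymax == ymin:
        raise DegenerateTrace("max(y) == min(y); cannot normalize")
    y_norm = (trace.y - ymin) / (ymax - ymin)
    span = trace.x[-1] - trace.x[a0]
    x_norm = 100.0 * (trace.x - trace.x[a0]) / span
    return NormalizedTrace(x_norm=x_norm, y_norm=y_norm,
                           anchor_start_idx=a0, anchor_mono_di_idx=a1,
                           smoothing_window=smoothing_window)


def integrate_fractions(norm: NormalizedTrace, method: str = "sum",
                        boundary: str = "monosome") -> PolysomeQuant:
    """Sum normalized Y over the monosome and polysome windows.

    The monosome window runs from the start anchor to the monosome/disome
    valley inclusive; the polysome window from the next sample to the last
    datapoint, so the boundary sample is counted once (``boundary``
    switches it to the polysome window). ``method='trapezoid'`` integrates
    in sample-index units instead of summing, for non-uniform input.
    """
    a0, a1 = norm.anchor_start_idx, norm.anchor_mono_di_idx
    if boundary == "monosome":
        mono_sl, poly_sl = slice(a0, a1 + 1), slice(a1 + 1, len(norm.y_norm))
    elif boundary == "polysome":
        mono_sl, poly_sl = slice(a0, a1), slice(a1, len(norm.y_norm))
    else:
        raise ValueError("boundary must be 'monosome' or 'polysome'")
    y_m, y_p = norm.y_norm[mono_sl], norm.y_norm[poly_sl]
    if len(y_m) < 2 or len(y_p) < 2:
        raise EmptyWindow("each fraction window needs >= 2 samples")
    if method == "sum":
        mono, poly = float(y_m.sum()), float(y_p.sum())
    elif method == "trapezoid":
        mono, poly = float(np.trapezoid(y_m)), float(np.trapezoid(y_p))
    else:
        raise ValueError("method must be 'sum' or 'trapezoid'")
    if mono <= 0:
        raise DivisionByZero("monosome fraction is zero")
    return PolysomeQuant(monosome_fraction=mono, polysome_fraction=poly,
                         pm_ratio=poly / mono)


def quantify_trace(trace: PolysomeTrace,
                   smoothing_window: int | None = None,
                   method: str = "sum") -> tuple[PolysomeQuant, NormalizedTrace]:
    """Full pipeline: anchors -> normalization -> fraction sums."""
    anchors = find_anchor_valleys(trace, smoothing_window)
    w = smoothing_window or default_smoothing_window(len(trace.y))
    norm = normalize_trace(trace, anchors, smoothing_window=w)
    return integrate_fractions(norm, method=method), norm


def compare_profiles(quants: list[tuple[str, str, PolysomeQuant]]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate P/M ratios per sample and mean ± sd per condition.

    ``quants`` holds (sample_id, condition, PolysomeQuant) tuples;
    conditions are reported in first-appearance order.
    """
    table = pd.DataFrame(
        [{"sample_id": s, "condition": c,
          "monosome_fraction": q.monosome_fraction,
          "polysome_fraction": q.polysome_fraction,
          "pm_ratio": q.pm_ratio} for s, c, q in quants])
    summary = (table.groupby("condition", sort=False)["pm_ratio"]
               .agg(n="size", mean="mean", sd="std")
               .reset_index())
    summary["sd"] = summary["sd"].fillna(0.0)
    return table, summary
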