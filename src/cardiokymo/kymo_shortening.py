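"""Cell-length trace extraction and contraction-parameter analysis.

The pipeline follows standard line-scan contractility analysis: the
kymograph is binarized with a global threshold to separate intracellular
from extracellular space, the cell edges on every line are the outermost
pixels of the largest intracellular run (so interior holes do not shrink
the length), and the per-line length trace yields per-beat contraction
descriptors:

* cell shortening — maximal decrease of length below the diastolic level,
  in µm and as % of the diastolic length;
* maximal shortening velocity — peak of ``-dL/dt`` during contraction;
* TTPS — time from contraction onset (10% amplitude crossing by default)
  to peak shortening;
* TTHR — time from peak shortening to 50% length recovery.

Parameters from the selected beats (third and fourth by default, so the
cell is in a quasi-steady state) are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import (DegenerateInputError, NoResponseError, ParameterError,
                     SegmentationError)
from .records import AcquisitionMeta, Kymograph

__all__ = ["LengthTrace", "ContractionParams", "binarize", "extract_length_trace",
           "contraction_params", "contraction_params_from_length"]


@dataclass
class LengthTrace:
    """Per-line cell length and edge positions.

    Edge positions are in continuous pixel coordinates where pixel ``i``
    covers ``[i, i+1)``; ``length_um = (right - left) * pixel_size_um``.
    """

    t: np.ndarray             # line timestamps, s
    length_um: np.ndarray     # cell length per line, µm
    left_edge_px: np.ndarray
    right_edge_px: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.length_um) == len(self.left_edge_px)
                == len(self.right_edge_px) == n):
            raise ParameterError("length trace arrays must have equal length")
        if np.any(self.left_edge_px >= self.right_edge_px):
            raise ParameterError("left edge must lie left of right edge on every line")


@dataclass
class ContractionParams:
    """Per-record contraction descriptors (means over the selected beats)."""

    shortening_um: float
    shortening_pct: float
    max_velocity_um_s: float
    ttps_s: float
    tthr_s: float
    n_beats_used: int


def binarize(
    kymo: Kymograph | np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    polarity: str = "bright",
    min_size: int = 64,
) -> np.ndarray:
    """Global-threshold binarization of a kymograph.

    Parameters
    ----------
    method
        ``"otsu"`` (default, minimizes intra-class intensity variance),
        ``"fixed"`` (absolute threshold ``value``) or ``"fraction"``
        (``value`` as a fraction of the intensity range above the minimum).
    polarity
        ``"bright"`` if the cell is brighter than the background (the usual
        fluorescence case), ``"dark"`` for inverted contrast.
    min_size
        Connected components smaller than this many pixels are removed.

    Returns a boolean mask that is True for intracellular pixels.
    """
    image = kymo.image if isinstance(kymo, Kymograph) else np.asarray(kymo)
    if image.size == 0 or np.ptp(image) == 0:
        raise DegenerateInputError("cannot threshold a constant image")
    if method == "otsu":
        thr = threshold_otsu(image)
    elif method == "fixed":
        if value is None:
            raise ParameterError("method='fixed' requires a threshold value")
        thr = float(value)
    elif method == "fraction":
        if value is None or not 0 <= value <= 1:
            raise ParameterError("method='fraction' requires a value in [0, 1]")
        thr = image.min() + value * np.ptp(image)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    if polarity == "bright":
        mask = image > thr
    elif polarity == "dark":
        mask = image < thr
    else:
        raise ParameterError("polarity must be 'bright' or 'dark'")
    if min_size > 0:
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return mask


def _largest_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-line first/last column of the largest True run.

    Raises :class:`SegmentationError` (with the line index) for any line
    without a True pixel.
    """
    n_lines, n_px = mask.shape
    padded = np.zeros((n_lines, n_px + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    rows_s, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)          # exclusive end, row-major like starts
    if len(rows_s) == 0:
        raise SegmentationError("no intracellular pixels in any line", 0)
    covered = np.zeros(n_lines, dtype=bool)
    covered[rows_s] = True
    if not covered.all():
        bad = int(np.flatnonzero(~covered)[0])
        raise SegmentationError(f"no intracellular pixels in line {bad}", bad)
    lengths = ends - starts
    # runs are emitted row-major; pick the longest run per row (ties: rightmost)
    order = np.lexsort((lengths, rows_s))
    _, counts = np.unique(rows_s, return_counts=True)
    best = order[np.cumsum(counts) - 1]
    return starts[best], ends[best] - 1    # inclusive right edge


def extract_length_trace(
    mask: np.ndarray,
    meta: AcquisitionMeta,
    kymo: Kymograph | np.ndarray | None = None,
    subpixel: bool = True,
    median_width: int = 3,
    border_px: int = 8,
    max_gap_px: int = 2,
) -> LengthTrace:
    """Extract the per-line cell-length trace from a binary mask.

    On each line the cell spans the largest run of intracellular pixels.
    With ``subpixel=True`` (default) the two boundary pixels are refined by
    coverage-fraction interpolation against the original image ``kymo``:
    the partial intensity of an edge pixel, relative to the per-line
    interior and background levels, locates the true edge to a fraction of
    a pixel.  With ``subpixel=False`` the integer outermost-pixel rule is
    used (``length = (right - left + 1) * pixel_size_um``).

    Interior gaps up to ``max_gap_px`` pixels wide (dark sarcomeric bands,
    single-pixel dropouts) are bridged by a morphological closing along the
    spatial axis before the largest run is selected, so small holes do not
    shrink the measured length.  A running median of width ``median_width``
    lines (default 3) over the edge positions suppresses single-line
    segmentation dropouts.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (meta.n_lines, meta.n_pixels):
        raise ParameterError("mask shape does not match acquisition metadata")
    run_mask = mask
    if max_gap_px > 0:
        run_mask = ndimage.binary_closing(
            mask, structure=np.ones((1, max_gap_px + 1), dtype=bool))
        run_mask |= mask      # closing must never delete true pixels
    left_i, right_i = _largest_runs(run_mask)

    if subpixel:
        if kymo is None:
            raise ParameterError("subpixel edge refinement requires the original image")
        img = (kymo.image if isinstance(kymo, Kymograph) else np.asarray(kymo))
        img = img.astype(float)
        rows = np.arange(meta.n_lines)
        bg = 0.5 * (img[:, :border_px].mean(axis=1) + img[:, -border_px:].mean(axis=1))
        # interior level per line from a central band well inside the cell
        half = max(4, int(0.25 * (right_i - left_i).min()))
        mid = (left_i + right_i) // 2
        cols = np.clip(mid[:, None] + np.arange(-half, half + 1)[None, :],
                       0, meta.n_pixels - 1)
        interior = img[rows[:, None], cols].mean(axis=1)
        contrast = interior - bg
        ok = contrast > 0

        def _coverage(col_idx: np.ndarray) -> np.ndarray:
            vals = img[rows, np.clip(col_idx, 0, meta.n_pixels - 1)]
            with np.errstate(divide="ignore", invalid="ignore"):
                c = (vals - bg) / contrast
            return np.clip(np.where(ok, c, 0.0), 0.0, 1.0)

        # pixel i covers [i, i+1): a = left+1 - cov(left) - cov(left-1), and
        # symmetrically b = right + cov(right) + cov(right+1)
        left = np.where(ok, left_i + 1.0 - _coverage(left_i) - _coverage(left_i - 1),
                        left_i.astype(float))
        right = np.where(ok, right_i + _coverage(right_i) + _coverage(right_i + 1),
                         right_i + 1.0)
    else:
        left = left_i.astype(float)
        right = right_i + 1.0

    if median_width and median_width > 1:
        left = ndimage.median_filter(left, size=median_width, mode="nearest")
        right = ndimage.median_filter(right, size=median_width, mode="nearest")

    length_um = (right - left) * meta.pixel_size_um
    return LengthTrace(t=meta.line_times_s, length_um=length_um,
                       left_edge_px=left, right_edge_px=right)


def _cross_time(t: np.ndarray, y: np.ndarray, k: int, thr: float) -> float:
    """Sub-sample crossing time: linear interpolation between sample ``k``
    (the first sample past the threshold) and its predecessor, falling back
    to ``t[k]`` when the predecessor does not bracket the threshold."""
    if k > 0 and (y[k - 1] - thr) * (y[k] - thr) < 0:
        frac = (y[k - 1] - thr) / (y[k - 1] - y[k])
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))
    return float(t[k])


def _refine_peak(t: np.ndarray, y: np.ndarray, k: int,
                 kind: str) -> tuple[float, float]:
    """Parabolic sub-sample refinement of a strict local extremum at ``k``.

    Returns ``(time, value)``; falls back to the sample when the extremum
    is not strict (plateaus, square edges) or lies at the array boundary.
    """
    if not 0 < k < len(y) - 1:
        return float(t[k]), float(y[k])
    a, b, c = y[k - 1], y[k], y[k + 1]
    strict = (a > b and c > b) if kind == "min" else (a < b and c < b)
    denom = a - 2 * b + c
    if not strict or denom == 0:
        return float(t[k]), float(y[k])
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = t[k] - t[k - 1]
    value = b - 0.25 * (a - c) * delta
    return float(t[k] + delta * dt), float(value)


def _beat_windows(
    t: np.ndarray, onsets: np.ndarray, beats: tuple[int, ...]
) -> list[tuple[float, float, float]]:
    if len(onsets) < max(beats) + 1:
        raise ParameterError(
            f"need at least {max(beats) + 1} stimulus onsets, got {len(onsets)}")
    windows = []
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    for b in beats:
        w0 = onsets[b]
        w1 = onsets[b + 1] if b + 1 < len(onsets) else t[-1] + dt
        windows.append((float(onsets[b]), float(w0), float(w1)))
    return windows


def contraction_params_from_length(
    t: np.ndarray,
    length_um: np.ndarray,
    stimulus_onsets,
    beats_to_average: tuple[int, ...] = (2, 3),
    smooth_window: int | None = 7,
    smooth_order: int = 2,
    diastolic_window_s: float = 0.05,
    onset_fraction: float = 0.10,
    min_shortening_um: float = 0.5,
) -> ContractionParams:
    """Compute contraction parameters from a sampled length trace.

    This is the core routine shared by the image pipeline and the
    synthetic-data ground truth (which evaluates it on a dense noiseless
    grid).  Event conventions: the first sample satisfying each condition
    locates an event, then the crossing time is refined by linear
    interpolation against the preceding sample, and extrema are refined by
    a parabolic fit when they are strict (plateaus and square edges keep
    the sample value).

    Per selected beat (window ``[onset_i, onset_{i+1})``, last window
    extended to the trace end): the diastolic length is the mean over the
    ``diastolic_window_s`` before the stimulus onset; shortening is
    diastolic minus the window minimum; the contraction onset is the first
    crossing of ``onset_fraction`` of the beat amplitude below the diastolic
    length; max velocity is the peak of ``-dL/dt`` (central differences on
    the optionally Savitzky-Golay-smoothed trace) between stimulus onset and
    peak shortening; TTHR is the first 50% length recovery after the peak.
    Beats with amplitude below ``min_shortening_um`` are rejected with a
    warning; if all beats are rejected a :class:`NoResponseError` is raised.
    """
    t = np.asarray(t, dtype=float)
    L = np.asarray(length_um, dtype=float)
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if smooth_window is not None and smooth_window > 2:
        win = min(smooth_window, len(L) if len(L) % 2 else len(L) - 1)
        Ls = savgol_filter(L, win, min(smooth_order, win - 1))
    else:
        Ls = L
    velocity = -np.gradient(Ls, t)

    per_beat: list[tuple[float, float, float, float, float]] = []
    for b_idx, (stim_on, w0, w1) in enumerate(
            _beat_windows(t, onsets, tuple(beats_to_average))):
        sel = (t >= w0) & (t < w1)
        dia = (t >= stim_on - diastolic_window_s) & (t < stim_on)
        if not sel.any() or not dia.any():
            warnings.warn(f"beat {beats_to_average[b_idx]}: empty window, rejected")
            continue
        idx = np.flatnonzero(sel)
        diastolic = float(Ls[dia].mean())
        k_min = idx[int(np.argmin(Ls[idx]))]       # first minimum sample
        t_min, l_min = _refine_peak(t, Ls, int(k_min), "min")
        shortening = diastolic - l_min
        if shortening <= min_shortening_um:
            warnings.warn(
                f"beat {beats_to_average[b_idx]}: shortening {shortening:.3g} µm "
                f"below threshold, rejected")
            continue
        thr = diastolic - onset_fraction * shortening
        below = idx[(Ls[idx] <= thr) & (idx <= k_min)]
        k_on = int(below[0]) if len(below) else int(k_min)
        ttps = t_min - _cross_time(t, Ls, k_on, thr)
        vmax = float(velocity[idx[0]:k_min + 1].max())
        half = l_min + 0.5 * shortening
        after = idx[idx > k_min]
        rec = after[Ls[after] >= half]
        tthr = _cross_time(t, Ls, int(rec[0]), half) - t_min if len(rec) else np.nan
        per_beat.append((shortening, 100.0 * shortening / diastolic, vmax,
                         float(ttps), tthr))

    if not per_beat:
        raise NoResponseError("no beat produced a measurable contraction")
    arr = np.array(per_beat, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN TTHR column
        means = np.nanmean(arr, axis=0)
    return ContractionParams(
        shortening_um=float(means[0]),
        shortening_pct=float(means[1]),
        max_velocity_um_s=float(means[2]),
        ttps_s=float(means[3]),
        tthr_s=float(means[4]),
        n_beats_used=len(per_beat),
    )


def contraction_params(
    trace: LengthTrace,
    stimulus_onsets,
    beats_to_average: tuple[int, ...] = (2, 3),
    **kwargs,
) -> ContractionParams:
    """Contraction parameters of a :class:`LengthTrace` (see
    :func:`contraction_params_from_length` for conventions and options)."""
    return contraction_params_from_length(
        trace.t, trace.length_um, stimulus_onsets,
        beats_to_average=beats_to_average, **kwargs)
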