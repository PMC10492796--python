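"""Fluo-4 F/F0 Ca2+-transient traces and transient parameters.

The fluorescence trace is the mean intracellular intensity per scan line,
restricted to the binarization mask so the moving cell boundary is
respected (the mask is eroded by a couple of pixels per side so partially
covered edge pixels do not dilute the mean).  F0 is the average of the
trace before the first stimulus (minus a short guard), and the transient
parameters follow the field's literal conventions: amplitude is the
maximal F/F0 value (the peak ratio, not peak minus baseline), raise rate
is amplitude divided by the onset-to-peak time, and T50 is the time for
the transient to decay by half of its peak-minus-baseline excursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BaselineError, NoTransientError, ParameterError, SegmentationError
from .kymo_shortening import _cross_time, _refine_peak
from .records import Kymograph

__all__ = ["FluoTrace", "TransientParams", "extract_fluo_trace",
           "transient_params", "transient_params_from_ratio"]


@dataclass
class FluoTrace:
    """Per-line mean intracellular fluorescence and its F/F0 ratio."""

    t: np.ndarray        # line timestamps, s
    f: np.ndarray        # mean intracellular intensity per line, counts
    f0: float            # pre-stimulus baseline intensity, counts
    ratio: np.ndarray    # F/F0, unitless

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ParameterError("f0 must be > 0")
        if len(self.t) != len(self.f) or len(self.f) != len(self.ratio):
            raise ParameterError("fluo trace arrays must have equal length")


@dataclass
class TransientParams:
    """Per-record Ca2+ transient descriptors (means over selected beats)."""

    amplitude: float          # max F/F0
    time_to_peak_s: float     # onset -> peak
    raise_rate_per_s: float   # amplitude / time_to_peak
    t50_s: float              # peak -> 50% decay of the excursion
    n_beats_used: int


def extract_fluo_trace(
    kymo: Kymograph,
    mask: np.ndarray,
    stimulus_onsets=None,
    guard_s: float = 0.02,
    erode_px: int = 2,
) -> FluoTrace:
    """Mask-restricted F/F0 trace of a kymograph.

    ``mask`` must come from :func:`cardiokymo.kymo_shortening.binarize` on
    the same record.  F0 is the mean of the per-line fluorescence over all
    lines earlier than ``first onset - guard_s``.
    """
    if stimulus_onsets is None:
        stimulus_onsets = kymo.meta.stimulus_onsets
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        raise BaselineError("no stimulus onsets: cannot locate the F0 window")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != kymo.image.shape:
        raise ParameterError("mask shape does not match the kymograph")
    if erode_px > 0:
        structure = np.ones((1, 2 * erode_px + 1), dtype=bool)
        core = ndimage.binary_erosion(mask, structure=structure)
    else:
        core = mask
    counts = core.sum(axis=1)
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0])
        raise SegmentationError(f"no intracellular pixels in line {bad} "
                                "after mask erosion", bad)
    img = kymo.image.astype(float)
    f = (img * core).sum(axis=1) / counts
    t = kymo.meta.line_times_s
    pre = t < onsets[0] - guard_s
    if not pre.any():
        raise BaselineError("empty pre-stimulus window: cannot estimate F0")
    f0 = float(f[pre].mean())
    if not f0 > 0:
        raise BaselineError("non-positive F0 baseline")
    return FluoTrace(t=t, f=f, f0=f0, ratio=f / f0)


def transient_params_from_ratio(
    t: np.ndarray,
    ratio: np.ndarray,
    stimulus_onsets,
    beats_to_average: tuple[int, ...] = (2, 3),
    baseline_window_s: float = 0.05,
    onset_fraction: float = 0.10,
    noise_floor_k: float = 3.0,
) -> TransientParams:
    """Transient parameters from a sampled F/F0 trace.

    Shared by the image pipeline and the synthetic ground truth.  Events
    are located at the first sample satisfying each condition and refined
    to sub-sample precision (linear interpolation for crossings, guarded
    parabolic fits for strict extrema).  Per
    selected beat: the beat baseline is the mean ratio over
    ``baseline_window_s`` before the stimulus onset; amplitude is the
    maximal ratio in the beat window; the transient onset is the first
    crossing of ``onset_fraction`` of the excursion above baseline; T50 is
    the first sample after the peak at or below baseline plus half the
    excursion.  A beat whose excursion does not exceed ``noise_floor_k``
    times the baseline standard deviation is rejected; if every beat is
    rejected a :class:`NoTransientError` is raised.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(ratio, dtype=float)
    onsets = np.asarray(stimulus_onsets, dtype=float)
    beats = tuple(beats_to_average)
    if len(onsets) < max(beats) + 1:
        raise ParameterError(
            f"need at least {max(beats) + 1} stimulus onsets, got {len(onsets)}")
    dt = t[1] - t[0] if len(t) > 1 else 0.0

    per_beat: list[tuple[float, float, float, float]] = []
    for b in beats:
        w0 = onsets[b]
        w1 = onsets[b + 1] if b + 1 < len(onsets) else t[-1] + dt
        sel = (t >= w0) & (t < w1)
        base_sel = (t >= w0 - baseline_window_s) & (t < w0)
        if not sel.any() or not base_sel.any():
            warnings.warn(f"beat {b}: empty window, rejected")
            continue
        idx = np.flatnonzero(sel)
        base = float(r[base_sel].mean())
        base_sd = float(r[base_sel].std())
        k_peak = idx[int(np.argmax(r[idx]))]       # first maximum sample
        t_peak, amplitude = _refine_peak(t, r, int(k_peak), "max")
        delta = amplitude - base
        if delta <= 0 or delta <= noise_floor_k * base_sd:
            warnings.warn(f"beat {b}: excursion below the noise floor, rejected")
            continue
        above = idx[(r[idx] >= base + onset_fraction * delta) & (idx <= k_peak)]
        k_on = int(above[0]) if len(above) else int(k_peak)
        ttp = t_peak - _cross_time(t, r, k_on, base + onset_fraction * delta)
        rate = amplitude / ttp if ttp > 0 else np.nan
        after = idx[idx > k_peak]
        dec = after[r[after] <= base + 0.5 * delta]
        t50 = (_cross_time(t, r, int(dec[0]), base + 0.5 * delta) - t_peak
               if len(dec) else np.nan)
        per_beat.append((amplitude, ttp, rate, t50))

    if not per_beat:
        raise NoTransientError("no beat produced a measurable Ca2+ transient")
    arr = np.array(per_beat, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
    return TransientParams(
        amplitude=float(means[0]),
        time_to_peak_s=float(means[1]),
        raise_rate_per_s=float(means[2]),
        t50_s=float(means[3]),
        n_beats_used=len(per_beat),
    )


def transient_params(
    trace: FluoTrace,
    stimulus_onsets,
    beats_to_average: tuple[int, ...] = (2, 3),
    **kwargs,
) -> TransientParams:
    """Transient parameters of a :class:`FluoTrace` (see
    :func:`transient_params_from_ratio` for conventions and options)."""
    return transient_params_from_ratio(
        trace.t, trace.ratio, stimulus_onsets,
        beats_to_average=beats_to_average, **kwargs)
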