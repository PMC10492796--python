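"""End-to-end helpers tying the modules together in memory.

``analyze_kymograph`` runs the full per-cell analysis (binarize -> length
trace -> contraction parameters; fluorescence trace -> transient
parameters) and returns one flat result row.  ``run_condition`` streams a
synthetic population for one (preset, frequency, noise) condition through
that analysis and returns a tidy per-cell DataFrame with the matching
ground-truth columns, which is what the group statistics and the
reproduction script consume.
"""

from __future__ import annotations

import warnings
from typing import Any

import numpy as np
import pandas as pd

from .ca_transient import extract_fluo_trace, transient_params
from .errors import CardioKymoError
from .kymo_shortening import binarize, contraction_params, extract_length_trace
from .records import Kymograph
from .synthetic_data import CellRecord, GroupPreset, generate_population

__all__ = ["analyze_kymograph", "run_condition", "ENDPOINTS"]

ENDPOINTS = ["shortening_um", "shortening_pct", "max_velocity_um_s", "ttps_s",
             "tthr_s", "amplitude", "time_to_peak_s", "raise_rate_per_s", "t50_s"]


def analyze_kymograph(
    kymo: Kymograph,
    stimulus_onsets=None,
    beats_to_average: tuple[int, ...] = (2, 3),
    threshold_method: str = "otsu",
    subpixel: bool = True,
    smooth_window: int | None = 7,
) -> dict[str, Any]:
    """Full per-cell analysis of one kymograph.

    Returns a flat dict with the nine contraction/transient endpoints; an
    endpoint family that fails (e.g. no measurable response) is reported as
    NaNs with the error class name in ``error``.
    """
    if stimulus_onsets is None:
        stimulus_onsets = kymo.meta.stimulus_onsets
    row: dict[str, Any] = {ep: np.nan for ep in ENDPOINTS}
    row["error"] = ""
    errors = []
    try:
        mask = binarize(kymo, method=threshold_method)
        trace = extract_length_trace(mask, kymo.meta, kymo=kymo, subpixel=subpixel)
    except CardioKymoError as exc:
        row["error"] = type(exc).__name__
        return row
    try:
        cp = contraction_params(trace, stimulus_onsets,
                                beats_to_average=beats_to_average,
                                smooth_window=smooth_window)
        row.update(shortening_um=cp.shortening_um, shortening_pct=cp.shortening_pct,
                   max_velocity_um_s=cp.max_velocity_um_s, ttps_s=cp.ttps_s,
                   tthr_s=cp.tthr_s)
    except CardioKymoError as exc:
        errors.append(type(exc).__name__)
    try:
        fluo = extract_fluo_trace(kymo, mask, stimulus_onsets)
        tp = transient_params(fluo, stimulus_onsets,
                              beats_to_average=beats_to_average)
        row.update(amplitude=tp.amplitude, time_to_peak_s=tp.time_to_peak_s,
                   raise_rate_per_s=tp.raise_rate_per_s, t50_s=tp.t50_s)
    except CardioKymoError as exc:
        errors.append(type(exc).__name__)
    row["error"] = ";".join(errors)
    return row


def _truth_row(record: CellRecord) -> dict[str, float]:
    out = {}
    if record.contraction_truth is not None:
        for f in ("shortening_um", "shortening_pct", "max_velocity_um_s",
                  "ttps_s", "tthr_s"):
            out[f"true_{f}"] = getattr(record.contraction_truth, f)
    if record.transient_truth is not None:
        for f in ("amplitude", "time_to_peak_s", "raise_rate_per_s", "t50_s"):
            out[f"true_{f}"] = getattr(record.transient_truth, f)
    return out


def run_condition(
    preset: GroupPreset,
    frequency_hz: float,
    noise_fraction: float,
    base_seed: int = 0,
    n_animals: int | None = None,
    cells_per_animal: int | None = None,
    analyze_kwargs: dict[str, Any] | None = None,
    **generate_kwargs,
) -> pd.DataFrame:
    """Generate and analyze one condition; one row per cell.

    Rows carry the condition labels, the measured endpoints, the analytic
    ground-truth endpoints (``true_*`` columns) and any analysis error
    code.  Cells are processed one at a time (bounded memory).
    """
    analyze_kwargs = analyze_kwargs or {}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for record in generate_population(
                preset, frequency_hz, noise_fraction, base_seed=base_seed,
                n_animals=n_animals, cells_per_animal=cells_per_animal,
                **generate_kwargs):
            row = {"group": preset.group_id, "animal_id": record.animal_id,
                   "cell_id": record.cell_id, "frequency_hz": frequency_hz,
                   "noise_fraction": noise_fraction}
            row.update(analyze_kymograph(record.kymo, **analyze_kwargs))
            row.update(_truth_row(record))
            rows.append(row)
    return pd.DataFrame(rows)
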