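"""Auxiliary assay computations: calcein cell volume, fibrotic index,
myocyte cross-sectional area, qPCR 2^-ddCt fold change, and respirometry
state analysis.

Respirometry states follow the standard succinate-driven protocol in
permeabilized cells: state 3 (phosphorylating) after ADP, state 4 after
oligomycin, uncoupled after FCCP, non-mitochondrial after antimycin A;
cytochrome c oxidase (Cox) activity is the TMPD/ascorbate-driven flux minus
the KCN-resistant autoxidation component.  The respiratory control ratio
(RCR) is state-3 over state-4 flux; the inverse (state4/state3) and the
uncoupled/state4 ratio are also reported, since both conventions appear in
practice.  Fluxes can be normalized to citrate-synthase activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, MissingEventError, ParameterError

__all__ = ["MorphometryResult", "RespirometryResult", "cell_volume",
           "fibrotic_index", "myocyte_area", "fold_change_ddct",
           "respirometry_analyze"]


@dataclass
class MorphometryResult:
    """Bundle of the morphometric endpoints (all non-negative)."""

    volume_um3: float | None = None
    fibrotic_index: float | None = None
    area_um2: float | None = None


def cell_volume(
    stack: np.ndarray,
    voxel: tuple[float, float, float],
    method: str = "otsu",
    value: float | None = None,
) -> float:
    """Cell volume from a calcein z-stack by suprathreshold voxel counting.

    ``volume = (count of suprathreshold voxels) * pixel_area * z_step``.
    ``voxel`` is (dx, dy, dz) in µm; ``method`` is ``"otsu"`` (default) or
    ``"fixed"`` with an absolute threshold ``value``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ParameterError("z-stack must be 3D with at least 2 planes")
    dx, dy, dz = voxel
    if not (dx > 0 and dy > 0 and dz > 0):
        raise ParameterError("voxel dimensions must be > 0")
    if method == "otsu":
        if np.ptp(stack) == 0:
            # a constant stack is either all cell or all background; treat as
            # fully suprathreshold only if it is strictly positive
            if stack.flat[0] <= 0:
                raise DegenerateInputError("no suprathreshold voxels in the stack")
            count = stack.size
            return float(count) * dx * dy * dz
        thr = threshold_otsu(stack)
    elif method == "fixed":
        if value is None:
            raise ParameterError("method='fixed' requires a threshold value")
        thr = float(value)
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    count = int((stack > thr).sum())
    if count == 0:
        raise DegenerateInputError("no suprathreshold voxels in the stack")
    return float(count) * dx * dy * dz


def fibrotic_index(
    label_image: np.ndarray,
    blue_label: int = 2,
    red_label: int = 1,
) -> float:
    """%blue / %red pixel ratio of a pre-classified two-color image.

    Pixels carrying neither label are excluded from both counts, so the
    ratio of percentages reduces to the ratio of counts.
    """
    labels = np.asarray(label_image)
    n_blue = int((labels == blue_label).sum())
    n_red = int((labels == red_label).sum())
    if n_red == 0:
        raise DegenerateInputError("no red pixels: fibrotic index undefined")
    return n_blue / n_red


def myocyte_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Cross-sectional area of a labeled mask: pixel count x pixel area."""
    if not pixel_size_um > 0:
        raise ParameterError("pixel_size_um must be > 0")
    return float(np.asarray(mask, dtype=bool).sum()) * pixel_size_um ** 2


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    the fold change is 2 ** -ddCt.
    """
    for ct in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(ct):
            raise ParameterError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


@dataclass
class RespirometryResult:
    """Per-state mean O2 fluxes and the derived ratios.

    Fluxes are per-state means over ``[event + settle, next event)`` in the
    input units (divided by the citrate-synthase activity if one was
    provided).  ``rcr`` is state3/state4; ``state4_over_state3`` and
    ``uncoupled_over_state4`` are the alternative panel conventions.
    """

    fluxes: dict[str, float] = field(default_factory=dict)
    rcr: float | None = None
    state4_over_state3: float | None = None
    uncoupled_over_state4: float | None = None
    cox_activity: float | None = None
    cs_normalized: bool = False


_STATE_EVENTS = {
    "basal": "succinate", "state3": "adp", "state4": "oligomycin",
    "uncoupled": "fccp", "non_mito": "antimycin_a",
    "tmpd_asc": "tmpd_asc", "kcn_resistant": "kcn",
}
_REQUIRED_EVENTS = ("adp", "oligomycin", "fccp")


def respirometry_analyze(
    trace: pd.DataFrame,
    settle_s: float = 60.0,
    cs_activity: float | None = None,
    subtract_non_mito: bool = False,
    required_events: tuple[str, ...] = _REQUIRED_EVENTS,
) -> RespirometryResult:
    """Segment an event-annotated O2-flux trace into respiratory states.

    ``trace`` needs columns ``time_s``, ``flux`` and ``event`` (sparse
    labels; expected labels: digitonin, succinate, adp, oligomycin, fccp,
    antimycin_a, tmpd_asc, kcn).  Each state flux is the mean over
    ``[event_time + settle_s, next_event_time)``.  Missing required events
    raise :class:`MissingEventError`.  With ``subtract_non_mito`` the
    post-antimycin-A flux is subtracted from the basal/state/uncoupled
    fluxes before ratios are formed.
    """
    for col in ("time_s", "flux", "event"):
        if col not in trace.columns:
            raise ParameterError(f"trace is missing column {col!r}")
    t = trace["time_s"].to_numpy(dtype=float)
    flux = trace["flux"].to_numpy(dtype=float)
    ev = trace["event"].fillna("").astype(str).to_numpy()
    marks = [(ev[i], t[i]) for i in np.flatnonzero(ev != "")]
    if any(b[1] <= a[1] for a, b in zip(marks, marks[1:])):
        raise ParameterError("events must be strictly increasing in time")
    by_name = dict(marks)
    for name in required_events:
        if name not in by_name:
            raise MissingEventError(name)

    boundary_times = [at for _, at in marks] + [t[-1] + (t[1] - t[0] if len(t) > 1 else 1.0)]
    fluxes: dict[str, float] = {}
    for state, event in _STATE_EVENTS.items():
        if event not in by_name:
            continue
        t0 = by_name[event]
        t1 = min(bt for bt in boundary_times if bt > t0)
        sel = (t >= t0 + settle_s) & (t < t1)
        if not sel.any():
            raise ParameterError(
                f"settle time {settle_s} s leaves no samples for state {state!r}")
        fluxes[state] = float(flux[sel].mean())

    if cs_activity is not None:
        if not cs_activity > 0:
            raise ParameterError("cs_activity must be > 0")
        fluxes = {k: v / cs_activity for k, v in fluxes.items()}

    adjusted = dict(fluxes)
    if subtract_non_mito and "non_mito" in fluxes:
        for k in ("basal", "state3", "state4", "uncoupled"):
            if k in adjusted:
                adjusted[k] = adjusted[k] - fluxes["non_mito"]

    result = RespirometryResult(fluxes=fluxes, cs_normalized=cs_activity is not None)
    s3, s4 = adjusted.get("state3"), adjusted.get("state4")
    unc = adjusted.get("uncoupled")
    if s3 is not None and s4 is not None:
        if s4 <= 0:
            raise DegenerateInputError("state-4 flux <= 0: RCR undefined")
        result.rcr = s3 / s4
        result.state4_over_state3 = s4 / s3 if s3 > 0 else None
        if unc is not None:
            result.uncoupled_over_state4 = unc / s4
    if "tmpd_asc" in adjusted and "kcn_resistant" in adjusted:
        result.cox_activity = adjusted["tmpd_asc"] - adjusted["kcn_resistant"]
    return result
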