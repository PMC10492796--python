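"""Synthetic study data: line-scan kymographs, calcein z-stacks, histology
fields, respirometry traces and Ct tables with known ground truth.

No experimental data is deposited for this study design, so every analysis
stage is exercised against a generator that emulates the study's cells.  A
contracting cardiomyocyte (resting length ~120 µm) is imaged on a scan line
longer than the cell; four stimulus-locked twitches modulate both the cell
length and the intracellular Fluo-4 F/F0 ratio.  The twitch time course is a
peak-normalized double-exponential kernel

    k(t) = N * (1 - exp(-t/tau_c)) * exp(-t/tau_r),   k(t<0) = 0,

whose rise and decay constants map directly onto the measured kinetic
parameters (peak time = tau_c * ln(1 + tau_r/tau_c)).  Named group presets
(CTRL vs DOX) carry per-endpoint multipliers and a (frequency, noise-level)
gain table calibrated to the study's printed relative effects; amplitude
multipliers act on the *measured* endpoints (e.g. peak F/F0), and kinetic
multipliers are realized by uniform time-scaling of the kernel, so the full
analysis pipeline should recover each multiplier from the rendered images.

Populations drawn for different groups are *yoked*: the per-animal and
per-cell latent variability comes from a group-independent random stream,
so group contrasts are driven by the preset multipliers rather than
finite-sample noise, while within-group variability (and hence SEMs) stays
realistic.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .ca_transient import TransientParams, transient_params_from_ratio
from .errors import GeometryError, NoResponseError, NoTransientError, ParameterError
from .kymo_shortening import ContractionParams, contraction_params_from_length
from .records import AcquisitionMeta, Kymograph
from .stimulus import StimulusProtocol

__all__ = [
    "CellTruth", "EndpointGains", "GroupPreset", "CellRecord",
    "twitch_kernel", "twitch_kernel_peak_time", "apply_endpoint_gains",
    "default_meta", "simulate_cell_record", "generate_population",
    "ctrl_preset", "dox_preset", "generate_zstack", "generate_cross_section",
    "sample_volumes", "sample_cross_sections", "generate_two_color_field",
    "generate_respirometry_trace", "generate_ct_table",
]

TRUTH_GRID_DT_S = 1e-4   # dense-grid step for analytic ground-truth parameters


# --------------------------------------------------------------------------
# twitch kernel
# --------------------------------------------------------------------------

def twitch_kernel_peak_time(contract_tau_s: float, relax_tau_s: float) -> float:
    """Closed-form peak time of the twitch kernel."""
    return contract_tau_s * np.log1p(relax_tau_s / contract_tau_s)


def _kernel_norm(contract_tau_s: float, relax_tau_s: float) -> float:
    tp = twitch_kernel_peak_time(contract_tau_s, relax_tau_s)
    peak = (1.0 - np.exp(-tp / contract_tau_s)) * np.exp(-tp / relax_tau_s)
    return 1.0 / peak


def twitch_kernel(t_since_onset, contract_tau_s: float, relax_tau_s: float):
    """Peak-normalized double-exponential activation, zero before onset.

    Requires ``relax_tau_s > contract_tau_s > 0`` (otherwise the peak
    normalization is ill-conditioned).
    """
    if not contract_tau_s > 0 or not relax_tau_s > 0:
        raise ParameterError("twitch kernel taus must be > 0")
    if relax_tau_s <= contract_tau_s:
        raise ParameterError("relax_tau_s must exceed contract_tau_s")
    t = np.asarray(t_since_onset, dtype=float)
    n = _kernel_norm(contract_tau_s, relax_tau_s)
    with np.errstate(over="ignore"):
        k = n * (1.0 - np.exp(-t / contract_tau_s)) * np.exp(-t / relax_tau_s)
    return np.where(t >= 0, k, 0.0)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTruth:
    """Generative truth for one cell.

    ``ca_amplitude`` is the peak F/F0 excess above 1 (so a value of 1.0
    means the transient peaks at F/F0 = 2).
    """

    rest_length_um: float = 120.0
    shortening_frac: float = 0.08
    contract_tau_s: float = 0.02
    relax_tau_s: float = 0.12
    ca_amplitude: float = 1.0
    ca_rise_tau_s: float = 0.01
    ca_decay_tau_s: float = 0.08
    baseline_intensity: float = 150.0
    background_intensity: float = 10.0
    cell_center_px: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.shortening_frac < 0.5:
            raise ParameterError("shortening_frac must be in [0, 0.5)")
        if self.ca_amplitude < 0:
            raise ParameterError("ca_amplitude must be >= 0")
        if not self.baseline_intensity > self.background_intensity >= 0:
            raise ParameterError(
                "need baseline_intensity > background_intensity >= 0")
        for name in ("contract_tau_s", "relax_tau_s", "ca_rise_tau_s",
                     "ca_decay_tau_s", "rest_length_um"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class EndpointGains:
    """Multiplicative per-endpoint response factors.

    ``shortening`` and ``max_velocity`` multiply the measured cell
    shortening (µm) and maximal shortening velocity; ``ca_amplitude`` and
    ``raise_rate`` multiply the measured peak F/F0 and raise rate.
    """

    shortening: float = 1.0
    max_velocity: float = 1.0
    ca_amplitude: float = 1.0
    raise_rate: float = 1.0

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if not getattr(self, f_.name) > 0:
                raise ParameterError(f"gain {f_.name} must be > 0")

    def combine(self, other: "EndpointGains") -> "EndpointGains":
        return EndpointGains(
            shortening=self.shortening * other.shortening,
            max_velocity=self.max_velocity * other.max_velocity,
            ca_amplitude=self.ca_amplitude * other.ca_amplitude,
            raise_rate=self.raise_rate * other.raise_rate,
        )

    @property
    def is_identity(self) -> bool:
        return all(getattr(self, f_.name) == 1.0 for f_ in dataclasses.fields(self))


_IDENTITY = EndpointGains()


def _key(frequency_hz: float, noise_fraction: float) -> tuple[float, float]:
    return (round(float(frequency_hz), 6), round(float(noise_fraction), 6))


@dataclass(frozen=True)
class GroupPreset:
    """Generative truth for a synthetic population (one treatment group).

    ``baseline`` multiplies every endpoint relative to the CTRL group at 0%
    noise; ``gain_table`` maps (frequency_hz, noise_fraction) to the extra
    noise-induced response gain (absent entries mean no response, i.e. gain
    1; 0%-noise gain is 1 by construction).  ``cell_cv`` / ``animal_cv``
    are lognormal coefficients of variation of the between-cell and
    between-animal endpoint variability; ``tau_cv`` the (smaller) kinetic
    variability.  Scalar presets for the auxiliary assays (cell volume,
    cross-sectional area, respirometry state rates, BNP ddCt) ride along so
    one preset object describes the whole group.
    """

    group_id: str
    baseline: EndpointGains = _IDENTITY
    gain_table: dict[tuple[float, float], EndpointGains] = field(default_factory=dict)
    truth_means: CellTruth = CellTruth()
    cell_cv: float = 0.15
    animal_cv: float = 0.05
    tau_cv: float = 0.10
    n_animals: int = 6
    cells_per_animal: int = 40
    volume_um3: float = 20_000.0
    area_um2: float = 280.0
    respirometry_rates: tuple[tuple[str, float], ...] = (
        ("basal", 8.0), ("state3", 40.0), ("state4", 8.0), ("uncoupled", 45.0),
        ("non_mito", 2.0), ("tmpd_asc", 80.0), ("kcn_resistant", 30.0))
    cs_activity: float = 1.0
    bnp_ddct: float = 0.0

    def __post_init__(self) -> None:
        for key, g in self.gain_table.items():
            if round(key[1], 6) == 0.0 and not g.is_identity:
                raise ParameterError("gain at noise_fraction 0 must be 1")
        if self.n_animals < 1 or self.cells_per_animal < 1:
            raise ParameterError("n_animals and cells_per_animal must be >= 1")

    def gains_for(self, frequency_hz: float, noise_fraction: float) -> EndpointGains:
        """Total endpoint multipliers (baseline x noise gain) for a condition."""
        gain = self.gain_table.get(_key(frequency_hz, noise_fraction), _IDENTITY)
        return self.baseline.combine(gain)


def ctrl_preset(**overrides) -> GroupPreset:
    """Control-group preset.

    The noise-gain table carries the study's printed control responses to a
    10% noisy stimulus: +20% shortening at 0.5 Hz (+17% max velocity) and
    +16% shortening at 1 Hz.  Velocity gains without a printed value track
    the shortening gain so that twitch timing is noise-invariant; all other
    entries default to 1.
    """
    table = {
        _key(0.5, 0.10): EndpointGains(shortening=1.20, max_velocity=1.17),
        _key(1.0, 0.10): EndpointGains(shortening=1.16, max_velocity=1.16),
    }
    kwargs = dict(group_id="CTRL", gain_table=table, n_animals=6)
    kwargs.update(overrides)
    return GroupPreset(**kwargs)


def dox_preset(**overrides) -> GroupPreset:
    """DOX (doxorubicin-treated) group preset.

    Baseline endpoints relative to CTRL at 0% noise: shortening x0.83, max
    velocity x0.88, Ca2+ amplitude x0.85, raise rate x0.85.  At 20% noise
    the shortening, amplitude and raise-rate gains are set so the group
    returns exactly to the CTRL 0%-noise baseline, while max velocity does
    not respond.  Auxiliary presets: cell volume x0.70, cross-sectional
    area x0.80, phosphorylating (state-3) and uncoupled respiration x0.5,
    Cox activity reduced, lower citrate-synthase activity, BNP ~2-fold up
    (ddCt = -1).
    """
    baseline = EndpointGains(shortening=0.83, max_velocity=0.88,
                             ca_amplitude=0.85, raise_rate=0.85)
    rescue = EndpointGains(shortening=1 / 0.83, max_velocity=1.0,
                           ca_amplitude=1 / 0.85, raise_rate=1 / 0.85)
    table = {_key(f, 0.20): rescue for f in (0.5, 1.0)}
    kwargs = dict(
        group_id="DOX", baseline=baseline, gain_table=table, n_animals=8,
        volume_um3=0.70 * 20_000.0, area_um2=0.80 * 280.0,
        respirometry_rates=(
            ("basal", 8.0), ("state3", 20.0), ("state4", 8.0),
            ("uncoupled", 22.5), ("non_mito", 2.0), ("tmpd_asc", 55.0),
            ("kcn_resistant", 30.0)),
        cs_activity=0.7, bnp_ddct=-1.0)
    kwargs.update(overrides)
    return GroupPreset(**kwargs)


def apply_endpoint_gains(truth: CellTruth, gains: EndpointGains) -> CellTruth:
    """Map endpoint multipliers onto generative parameters.

    * shortening: scales ``shortening_frac`` directly (the measured
      shortening is linear in it);
    * max velocity: a gain differing from the shortening gain is realized
      by uniform time-scaling of the mechanical kernel (both taus scaled by
      ``shortening/max_velocity``), which changes the peak velocity by the
      inverse factor while leaving the peak shortening untouched;
    * Ca2+ amplitude: acts on the measured endpoint (peak F/F0), so the
      excess above 1 becomes ``g * (1 + ca) - 1``;
    * raise rate: realized by uniform time-scaling of the Ca2+ kernel by
      ``ca_amplitude/raise_rate`` (rate = amplitude / time-to-peak).
    """
    mech_scale = gains.shortening / gains.max_velocity
    ca_scale = gains.ca_amplitude / gains.raise_rate
    if truth.ca_amplitude > 0:
        ca_eff = gains.ca_amplitude * (1.0 + truth.ca_amplitude) - 1.0
        if ca_eff <= 0:
            raise ParameterError(
                "ca_amplitude endpoint gain drives the peak F/F0 below 1")
    else:
        ca_eff = 0.0
    return replace(
        truth,
        shortening_frac=truth.shortening_frac * gains.shortening,
        contract_tau_s=truth.contract_tau_s * mech_scale,
        relax_tau_s=truth.relax_tau_s * mech_scale,
        ca_amplitude=ca_eff,
        ca_rise_tau_s=truth.ca_rise_tau_s * ca_scale,
        ca_decay_tau_s=truth.ca_decay_tau_s * ca_scale,
    )


# --------------------------------------------------------------------------
# line-scan record simulation
# --------------------------------------------------------------------------

def default_meta(
    protocol: StimulusProtocol,
    pre_s: float = 0.5,
    line_period_s: float = 0.002,
    pixel_size_um: float = 0.2,
    n_pixels: int = 768,
) -> AcquisitionMeta:
    """Acquisition metadata sized to hold a full stimulation run.

    The record starts ``pre_s`` before the first pulse (for the F0 and
    diastolic baselines) and ends ``protocol.tail_s`` after the last pulse.
    """
    duration = pre_s + (protocol.n_pulses - 1) / protocol.frequency_hz \
        + protocol.tail_s
    n_lines = int(np.ceil(duration / line_period_s))
    onsets = tuple(pre_s + o for o in protocol.onsets_s)
    return AcquisitionMeta(line_period_s=line_period_s, pixel_size_um=pixel_size_um,
                           n_lines=n_lines, n_pixels=n_pixels,
                           stimulus_onsets=onsets)


def _activation(t: np.ndarray, onsets: np.ndarray, tau_c: float,
                tau_r: float) -> np.ndarray:
    act = np.zeros_like(t)
    for onset in onsets:
        act += twitch_kernel(t - onset, tau_c, tau_r)
    return act


def _noiseless_traces(truth: CellTruth, onsets: np.ndarray,
                      t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form length (µm) and F/F0 traces at times ``t``."""
    if truth.shortening_frac > 0:
        length = truth.rest_length_um * (
            1.0 - truth.shortening_frac
            * _activation(t, onsets, truth.contract_tau_s, truth.relax_tau_s))
    else:
        length = np.full_like(t, truth.rest_length_um)
    if truth.ca_amplitude > 0:
        ratio = 1.0 + truth.ca_amplitude * _activation(
            t, onsets, truth.ca_rise_tau_s, truth.ca_decay_tau_s)
    else:
        ratio = np.ones_like(t)
    return length, ratio


@dataclass
class CellRecord:
    """One simulated cell: image, provenance and analytic ground truth."""

    animal_id: str
    cell_id: str
    kymo: Kymograph
    cell_truth: CellTruth          # latent truth before endpoint gains
    effective_truth: CellTruth     # truth after endpoint gains
    gains: EndpointGains
    contraction_truth: ContractionParams | None
    transient_truth: TransientParams | None


def ground_truth_params(
    effective_truth: CellTruth,
    meta: AcquisitionMeta,
    beats_to_average: tuple[int, ...] = (2, 3),
    dt: float = TRUTH_GRID_DT_S,
) -> tuple[ContractionParams | None, TransientParams | None]:
    """Analytic per-beat parameters implied by the twitch kernels.

    Evaluated by brute force on a dense grid (default 0.1 ms) of the
    closed-form noiseless traces, using the same parameter definitions as
    the image pipeline.  Returns ``None`` for an endpoint the cell does not
    express (zero shortening fraction / zero Ca2+ amplitude).
    """
    onsets = np.asarray(meta.stimulus_onsets, dtype=float)
    t = np.arange(0.0, meta.duration_s, dt)
    length, ratio = _noiseless_traces(effective_truth, onsets, t)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            contraction = contraction_params_from_length(
                t, length, onsets, beats_to_average=beats_to_average,
                smooth_window=None)
    except NoResponseError:
        contraction = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            transient = transient_params_from_ratio(
                t, ratio, onsets, beats_to_average=beats_to_average)
    except NoTransientError:
        transient = None
    return contraction, transient


def simulate_cell_record(
    truth: CellTruth,
    gains: EndpointGains,
    protocol: StimulusProtocol,
    meta: AcquisitionMeta | None = None,
    seed=None,
    pre_s: float = 0.5,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
    quantize: bool = True,
    beats_to_average: tuple[int, ...] = (2, 3),
    animal_id: str = "a01",
    cell_id: str = "c001",
) -> CellRecord:
    """Render one line-scan kymograph and its analytic ground truth.

    The per-line expected intensity is ``background`` outside the cell and
    ``baseline * F/F0(t)`` inside ``[center - L(t)/2, center + L(t)/2]``
    (edge pixels get their geometric coverage fraction, i.e. both edges
    move symmetrically).  Poisson shot noise is applied to the expected
    image, then additive Gaussian read noise, then quantization to uint16
    (``quantize=False`` keeps the float image, for strictly noise-free
    validation records).
    """
    if meta is None:
        meta = default_meta(protocol, pre_s=pre_s)
    onsets = np.asarray(meta.stimulus_onsets, dtype=float)
    if onsets.size == 0 or onsets[-1] >= meta.duration_s:
        raise ParameterError("stimulus onsets must fall inside the record")
    eff = apply_endpoint_gains(truth, gains)
    center_px = eff.cell_center_px
    if center_px is None:
        center_px = meta.n_pixels / 2.0
    half_rest_px = 0.5 * eff.rest_length_um / meta.pixel_size_um
    if center_px - half_rest_px < 0 or center_px + half_rest_px > meta.n_pixels:
        raise GeometryError(
            f"cell of resting length {eff.rest_length_um:.1f} µm does not fit "
            f"on the {meta.scan_width_um:.1f} µm scan line at center "
            f"{center_px:.0f} px")

    t = meta.line_times_s
    length, ratio = _noiseless_traces(eff, onsets, t)
    # per-line fractional pixel coverage of the cell interval [a, b] (pixel
    # units; pixel i covers [i, i+1)), computed in float32 to keep the
    # renderer's memory traffic low
    half_px = 0.5 * length / meta.pixel_size_um
    a = (center_px - half_px).astype(np.float32)[:, None]
    b = (center_px + half_px).astype(np.float32)[:, None]
    left_edges = np.arange(meta.n_pixels, dtype=np.float32)[None, :]
    cov = np.minimum(b, left_edges + 1.0)
    np.subtract(cov, np.maximum(a, left_edges), out=cov)
    np.clip(cov, 0.0, 1.0, out=cov)
    excess = (eff.baseline_intensity * ratio
              - eff.background_intensity).astype(np.float32)
    expected = cov
    expected *= excess[:, None]
    expected += np.float32(eff.background_intensity)

    rng = np.random.default_rng(seed)
    img = rng.poisson(expected).astype(np.float32) if shot_noise else expected
    if read_noise_sd > 0:
        noise = rng.standard_normal(img.shape, dtype=np.float32)
        noise *= np.float32(read_noise_sd)
        img += noise
    if quantize:
        np.rint(img, out=img)
        img = np.clip(img, 0, 65535).astype(np.uint16)
    else:
        np.clip(img, 0, None, out=img)

    contraction, transient = ground_truth_params(
        eff, meta, beats_to_average=beats_to_average)
    return CellRecord(animal_id=animal_id, cell_id=cell_id,
                      kymo=Kymograph(image=img, meta=meta),
                      cell_truth=truth, effective_truth=eff, gains=gains,
                      contraction_truth=contraction, transient_truth=transient)


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size=None):
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv <= 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _draw_cell_truth(preset: GroupPreset, rng: np.random.Generator,
                     animal_effects: dict[str, float],
                     meta: AcquisitionMeta) -> CellTruth:
    m = preset.truth_means
    rest = float(_lognormal(rng, m.rest_length_um, 0.05))
    frac = float(_lognormal(rng, m.shortening_frac * animal_effects["shortening"],
                            preset.cell_cv))
    ca = float(_lognormal(rng, m.ca_amplitude * animal_effects["ca_amplitude"],
                          preset.cell_cv))
    tau_c = float(_lognormal(rng, m.contract_tau_s, preset.tau_cv))
    tau_r = float(_lognormal(rng, m.relax_tau_s, preset.tau_cv))
    tau_r = max(tau_r, 2.0 * tau_c)          # keep the kernel well-conditioned
    ca_rise = float(_lognormal(rng, m.ca_rise_tau_s, preset.tau_cv))
    ca_decay = float(_lognormal(rng, m.ca_decay_tau_s, preset.tau_cv))
    ca_decay = max(ca_decay, 2.0 * ca_rise)
    baseline = float(_lognormal(rng, m.baseline_intensity, 0.10))
    # keep the (possibly rescaled) cell comfortably on the scan line
    margin_px = 0.5 * rest * 1.3 / meta.pixel_size_um + 8
    lo, hi = margin_px, meta.n_pixels - margin_px
    center = meta.n_pixels / 2.0 + rng.normal(0.0, 10.0)
    center = float(np.clip(center, lo, hi)) if lo < hi else meta.n_pixels / 2.0
    return CellTruth(
        rest_length_um=rest, shortening_frac=min(frac, 0.49),
        contract_tau_s=tau_c, relax_tau_s=tau_r,
        ca_amplitude=ca, ca_rise_tau_s=ca_rise, ca_decay_tau_s=ca_decay,
        baseline_intensity=baseline,
        background_intensity=m.background_intensity,
        cell_center_px=center)


def generate_population(
    preset: GroupPreset,
    frequency_hz: float,
    noise_fraction: float,
    meta: AcquisitionMeta | None = None,
    base_seed: int = 0,
    n_animals: int | None = None,
    cells_per_animal: int | None = None,
    **simulate_kwargs,
) -> Iterator[CellRecord]:
    """Stream a synthetic population for one (group, frequency, noise) condition.

    Per-cell truths are drawn lognormally around the preset means with the
    preset's between-cell CV, with a multiplicative per-animal random effect
    (lognormal, mean 1, the preset's between-animal CV).  The latent draws
    depend only on ``base_seed`` and the animal/cell indices — not on the
    group, frequency or noise level — so conditions and groups generated
    from the same ``base_seed`` are yoked (same underlying cells, different
    preset gains).  Records are yielded one at a time; nothing requires the
    full population in memory.
    """
    protocol = StimulusProtocol(frequency_hz=frequency_hz,
                                noise_fraction=noise_fraction)
    if meta is None:
        meta = default_meta(protocol)
    gains = preset.gains_for(frequency_hz, noise_fraction)
    n_animals = preset.n_animals if n_animals is None else n_animals
    cells = preset.cells_per_animal if cells_per_animal is None else cells_per_animal
    for a in range(n_animals):
        rng_a = np.random.default_rng([int(base_seed), a])
        animal_effects = {
            "shortening": float(_lognormal(rng_a, 1.0, preset.animal_cv)),
            "ca_amplitude": float(_lognormal(rng_a, 1.0, preset.animal_cv)),
        }
        for c in range(cells):
            rng_c = np.random.default_rng([int(base_seed), a, c])
            truth = _draw_cell_truth(preset, rng_c, animal_effects, meta)
            yield simulate_cell_record(
                truth, gains, protocol, meta=meta, seed=rng_c,
                animal_id=f"{preset.group_id}-a{a + 1:02d}",
                cell_id=f"c{c + 1:03d}", **simulate_kwargs)


# --------------------------------------------------------------------------
# auxiliary-assay generators
# --------------------------------------------------------------------------

def generate_zstack(
    volume_um3: float,
    voxel: tuple[float, float, float] = (0.5, 0.5, 1.0),
    seed=None,
    aspect: tuple[float, float, float] = (5.0, 1.4, 1.0),
    foreground: float = 100.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    margin_voxels: int = 4,
) -> tuple[np.ndarray, float]:
    """Calcein-like z-stack of an ellipsoidal cell with a known volume.

    ``aspect`` is the (x, y, z) semi-axis ratio of the elongated cell.
    Returns ``(stack, true_volume_um3)`` where the true volume is the count
    of interior voxels times the voxel volume (so it matches the target up
    to one voxel-shell discretization error).  The stack is float counts,
    planes along axis 0.
    """
    dx, dy, dz = voxel
    if not (dx > 0 and dy > 0 and dz > 0):
        raise ParameterError("voxel dimensions must be > 0")
    if volume_um3 < dx * dy * dz:
        raise ParameterError("target volume is smaller than one voxel")
    abc = 3.0 * volume_um3 / (4.0 * np.pi)
    unit = (abc / (aspect[0] * aspect[1] * aspect[2])) ** (1.0 / 3.0)
    ax, ay, az = (unit * a for a in aspect)
    nx = 2 * int(np.ceil(ax / dx)) + 2 * margin_voxels
    ny = 2 * int(np.ceil(ay / dy)) + 2 * margin_voxels
    nz = 2 * int(np.ceil(az / dz)) + 2 * margin_voxels
    x = (np.arange(nx) + 0.5 - nx / 2) * dx
    y = (np.arange(ny) + 0.5 - ny / 2) * dy
    z = (np.arange(nz) + 0.5 - nz / 2) * dz
    r2 = ((z[:, None, None] / az) ** 2 + (y[None, :, None] / ay) ** 2
          + (x[None, None, :] / ax) ** 2)
    inside = r2 <= 1.0
    true_volume = float(inside.sum()) * dx * dy * dz
    stack = np.where(inside, foreground, background).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = np.clip(stack + rng.normal(0.0, noise_sd, stack.shape), 0, None)
    return stack, true_volume


def generate_cross_section(
    area_um2: float,
    pixel_size_um: float = 0.25,
    seed=None,
    aspect: float = 1.6,
    margin_px: int = 4,
) -> tuple[np.ndarray, float]:
    """Elliptical myocyte cross-section mask with a known area.

    Returns ``(mask, true_area_um2)`` with the true area equal to the pixel
    count times the pixel area.
    """
    if area_um2 <= 0 or pixel_size_um <= 0:
        raise ParameterError("area and pixel size must be > 0")
    rng = np.random.default_rng(seed)
    aspect = aspect * float(_lognormal(rng, 1.0, 0.10))
    a = np.sqrt(area_um2 * aspect / np.pi)
    b = a / aspect
    nx = 2 * int(np.ceil(a / pixel_size_um)) + 2 * margin_px
    ny = 2 * int(np.ceil(b / pixel_size_um)) + 2 * margin_px
    x = (np.arange(nx) + 0.5 - nx / 2) * pixel_size_um
    y = (np.arange(ny) + 0.5 - ny / 2) * pixel_size_um
    mask = ((y[:, None] / b) ** 2 + (x[None, :] / a) ** 2) <= 1.0
    return mask, float(mask.sum()) * pixel_size_um ** 2


def sample_volumes(preset: GroupPreset, n: int, base_seed: int = 0,
                   voxel=(0.5, 0.5, 1.0), **kwargs) -> Iterator[tuple[np.ndarray, float]]:
    """Stream ``n`` z-stacks whose target volumes are lognormal around the
    preset's mean volume (yoked across groups via group-independent seeds)."""
    for i in range(n):
        rng = np.random.default_rng([int(base_seed), 7001, i])
        target = preset.volume_um3 * float(_lognormal(rng, 1.0, preset.cell_cv))
        yield generate_zstack(target, voxel=voxel, seed=rng, **kwargs)


def sample_cross_sections(preset: GroupPreset, n: int, base_seed: int = 0,
                          pixel_size_um: float = 0.25,
                          **kwargs) -> Iterator[tuple[np.ndarray, float]]:
    """Stream ``n`` cross-section masks with lognormal target areas around
    the preset's mean area (yoked across groups)."""
    for i in range(n):
        rng = np.random.default_rng([int(base_seed), 7002, i])
        target = preset.area_um2 * float(_lognormal(rng, 1.0, preset.cell_cv))
        yield generate_cross_section(target, pixel_size_um=pixel_size_um,
                                     seed=rng, **kwargs)


def generate_two_color_field(
    blue_frac: float,
    size: tuple[int, int] = (256, 256),
    seed=None,
    unclassified_frac: float = 0.0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Histology-like pre-classified field: labels 0 = unclassified,
    1 = red (muscle), 2 = blue (collagen), drawn i.i.d. per pixel.

    Returns the label image and the true class fractions.
    """
    if not 0 <= blue_frac <= 1:
        raise ParameterError("blue_frac must be in [0, 1]")
    if not 0 <= unclassified_frac < 1 or blue_frac > 1 - unclassified_frac:
        raise ParameterError("class fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    p_blue = blue_frac
    p_red = 1.0 - unclassified_frac - blue_frac
    labels = rng.choice([0, 1, 2], size=size,
                        p=[unclassified_frac, p_red, p_blue]).astype(np.uint8)
    n = labels.size
    return labels, {"blue": float((labels == 2).sum()) / n,
                    "red": float((labels == 1).sum()) / n}


DEFAULT_RESPIROMETRY_EVENTS: tuple[tuple[str, float], ...] = (
    ("digitonin", 60.0), ("succinate", 120.0), ("adp", 240.0),
    ("oligomycin", 360.0), ("fccp", 480.0), ("antimycin_a", 600.0),
    ("tmpd_asc", 720.0), ("kcn", 840.0))

# which flux applies after each titration event
_EVENT_TO_RATE = {
    "digitonin": "basal", "succinate": "basal", "adp": "state3",
    "oligomycin": "state4", "fccp": "uncoupled", "antimycin_a": "non_mito",
    "tmpd_asc": "tmpd_asc", "kcn": "kcn_resistant",
}


def generate_respirometry_trace(
    state_rates: dict[str, float] | None = None,
    event_times: tuple[tuple[str, float], ...] | None = None,
    noise_sd: float = 0.5,
    seed=None,
    dt_s: float = 1.0,
    duration_s: float = 960.0,
    pre_rate: float = 2.0,
) -> pd.DataFrame:
    """Event-annotated O2-flux trace (columns ``time_s, flux, event``).

    The flux is piecewise constant — ``pre_rate`` before the first event,
    then the state rate keyed by each titration — plus Gaussian noise.
    Event labels appear on the sample nearest each event time.
    """
    if state_rates is None:
        state_rates = dict(GroupPreset(group_id="CTRL").respirometry_rates)
    if event_times is None:
        event_times = DEFAULT_RESPIROMETRY_EVENTS
    times = [t for _, t in event_times]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ParameterError("event times must be strictly increasing")
    t = np.arange(0.0, duration_s, dt_s)
    flux = np.full_like(t, pre_rate)
    for name, at in event_times:
        rate_key = _EVENT_TO_RATE.get(name, name)
        if rate_key not in state_rates:
            raise ParameterError(f"no rate configured for event {name!r}")
        flux[t >= at] = state_rates[rate_key]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flux = flux + rng.normal(0.0, noise_sd, flux.shape)
    event_col = np.full(len(t), "", dtype=object)
    for name, at in event_times:
        event_col[int(np.argmin(np.abs(t - at)))] = name
    return pd.DataFrame({"time_s": t, "flux": flux, "event": event_col})


def generate_ct_table(
    preset: GroupPreset,
    ctrl_preset_: GroupPreset | None = None,
    n_per_group: int = 6,
    seed=None,
    ct_target_ctrl: float = 24.0,
    ct_ref: float = 20.0,
    sd: float = 0.15,
) -> pd.DataFrame:
    """qPCR Ct table (columns ``sample_id, group, gene, ct``) for the BNP
    target against the HPRT reference, with the case group's ddCt taken
    from its preset (e.g. -1 for a two-fold up-regulation)."""
    rng = np.random.default_rng(seed)
    rows = []
    presets = [ctrl_preset_ or ctrl_preset(), preset]
    for p in presets:
        for i in range(n_per_group):
            sid = f"{p.group_id}-s{i + 1:02d}"
            rows.append((sid, p.group_id, "BNP",
                         ct_target_ctrl + p.bnp_ddct + rng.normal(0, sd)))
            rows.append((sid, p.group_id, "HPRT", ct_ref + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
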