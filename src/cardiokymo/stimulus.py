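"""Field-stimulation waveform synthesis.

A stimulation run is a train of rectangular pulses (default four pulses of
20 V/cm, 5 ms wide) delivered at a pacing frequency of 0.5, 1 or 3 Hz, with
optional zero-mean Gaussian white noise added over the stimulation window
(from the first pulse onset to the last pulse offset).  The noise scale is
expressed as a fraction of the pulse amplitude and is interpreted as the
standard deviation of the Gaussian process (an RMS convention); the noise is
white at the waveform sampling rate and is not band-limited or clipped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError

__all__ = ["StimulusProtocol", "Waveform", "build_pulse_train", "add_stimulus_noise",
           "write_waveform"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Parameters of one pulse-train stimulation run.

    Parameters
    ----------
    frequency_hz
        Pacing frequency in Hz (0.5, 1 and 3 Hz are the study values).
    n_pulses
        Number of pulses in the train (default 4).
    pulse_amplitude
        Field strength of each rectangular pulse, V/cm (default 20).
    pulse_width_s
        Pulse duration in seconds (default 5 ms).
    noise_fraction
        Gaussian noise sigma as a fraction of ``pulse_amplitude``
        (0, 0.10, 0.20 or 0.30 in the study design).
    sample_rate_hz
        Waveform sampling rate; each pulse must span >= 2 samples.
    seed
        RNG seed used by :func:`add_stimulus_noise` when none is given there.
    tail_s
        Noise-free recording time after the last pulse offset, seconds.
    """

    frequency_hz: float = 1.0
    n_pulses: int = 4
    pulse_amplitude: float = 20.0
    pulse_width_s: float = 0.005
    noise_fraction: float = 0.0
    sample_rate_hz: float = 10_000.0
    seed: int | None = None
    tail_s: float = 0.5

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ParameterError("frequency_hz must be > 0")
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if not self.pulse_width_s > 0:
            raise ParameterError("pulse_width_s must be > 0")
        if not self.pulse_width_s < 1.0 / self.frequency_hz:
            raise ParameterError(
                "pulse_width_s must be < 1/frequency_hz (pulses must not overlap)")
        if self.noise_fraction < 0:
            raise ParameterError("noise_fraction must be >= 0")
        if self.sample_rate_hz < 2.0 / self.pulse_width_s:
            raise ParameterError(
                "sample_rate_hz must be >= 2/pulse_width_s "
                "(each pulse must be representable by at least 2 samples)")
        if self.tail_s < 0:
            raise ParameterError("tail_s must be >= 0")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def onsets_s(self) -> np.ndarray:
        """Pulse onset times, seconds from the start of the train."""
        return np.arange(self.n_pulses) / self.frequency_hz

    @property
    def duration_s(self) -> float:
        """Total waveform duration: train span + pulse width + tail."""
        return (self.n_pulses - 1) / self.frequency_hz + self.pulse_width_s + self.tail_s


@dataclass
class Waveform:
    """Uniformly sampled stimulation waveform."""

    t: np.ndarray                 # time, s; uniform step 1/sample_rate_hz
    v: np.ndarray                 # field, V/cm
    stimulus_onsets: np.ndarray   # pulse onset times, s

    def copy(self) -> "Waveform":
        return Waveform(self.t.copy(), self.v.copy(), self.stimulus_onsets.copy())


def build_pulse_train(protocol: StimulusProtocol) -> Waveform:
    """Synthesize the clean (noise-free) pulse-train waveform.

    The field equals ``pulse_amplitude`` on each half-open interval
    ``[onset_i, onset_i + pulse_width_s)`` with onsets at ``i / frequency_hz``,
    and zero elsewhere.  Pulses are aligned to the nearest sample, so every
    pulse spans exactly ``round(pulse_width_s * sample_rate_hz)`` samples and
    the onset sample index of pulse ``i`` is ``round(i * fs / frequency_hz)``.
    """
    fs = protocol.sample_rate_hz
    n_samples = int(round(protocol.duration_s * fs)) + 1
    t = np.arange(n_samples) / fs
    v = np.zeros(n_samples)
    width_n = max(1, int(round(protocol.pulse_width_s * fs)))
    for onset in protocol.onsets_s:
        i0 = int(round(onset * fs))
        v[i0:i0 + width_n] = protocol.pulse_amplitude
    return Waveform(t=t, v=v, stimulus_onsets=protocol.onsets_s)


def add_stimulus_noise(
    w: Waveform,
    noise_fraction: float | None = None,
    *,
    protocol: StimulusProtocol,
    seed: int | None = None,
) -> Waveform:
    """Add Gaussian white noise over the stimulation window.

    i.i.d. samples with mean 0 and standard deviation
    ``noise_fraction * pulse_amplitude`` are added to ``v`` on the closed
    window [first onset, last onset + pulse_width_s]; samples outside the
    window are bit-identical to the input.  With ``noise_fraction == 0`` the
    input is returned unchanged (as a copy).  Output is deterministic given
    the seed (falling back to ``protocol.seed``).
    """
    if noise_fraction is None:
        noise_fraction = protocol.noise_fraction
    if noise_fraction < 0:
        raise ParameterError("noise_fraction must be >= 0")
    out = w.copy()
    if noise_fraction == 0:
        return out
    sigma = noise_fraction * protocol.pulse_amplitude
    onsets = np.asarray(w.stimulus_onsets)
    fs = protocol.sample_rate_hz
    # the window is sample-aligned the same way the pulses are
    i0 = int(round(onsets[0] * fs))
    i1 = int(round((onsets[-1] + protocol.pulse_width_s) * fs))
    window = np.zeros(len(w.t), dtype=bool)
    window[i0:min(i1 + 1, len(w.t))] = True
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    out.v[window] += rng.normal(0.0, sigma, int(window.sum()))
    return out


def write_waveform(w: Waveform, path: str | Path, protocol: StimulusProtocol) -> Path:
    """Export a waveform as two-column CSV plus a JSON parameter sidecar."""
    path = Path(path)
    arr = np.column_stack([w.t, w.v])
    header = "time_s,field_V_per_cm"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"protocol": dataclasses.asdict(protocol),
         "stimulus_onsets_s": list(map(float, w.stimulus_onsets))},
        indent=2))
    return sidecar
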