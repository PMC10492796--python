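"""Shared data containers for line-scan records.

A kymograph is a 2D image whose rows are repeated acquisitions of a single
confocal scan line placed along the long axis of a cardiomyocyte: rows are
time (one line period apart), columns are space (one pixel size apart).  The
scan line is longer than the cell, so contraction shows up as the bright
intracellular band narrowing symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["AcquisitionMeta", "Kymograph"]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata for one line-scan record.

    line_period_s   time between successive scan lines, s
    pixel_size_um   spatial sampling along the scan line, µm/pixel
    n_lines         number of scan lines (image rows)
    n_pixels        number of pixels per line (image columns)
    stimulus_onsets pulse onset times, s from the start of the record
    """

    line_period_s: float
    pixel_size_um: float
    n_lines: int
    n_pixels: int
    stimulus_onsets: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.line_period_s > 0:
            raise ParameterError("line_period_s must be > 0")
        if not self.pixel_size_um > 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.n_lines < 1 or self.n_pixels < 1:
            raise ParameterError("n_lines and n_pixels must be >= 1")
        object.__setattr__(self, "stimulus_onsets",
                           tuple(float(x) for x in self.stimulus_onsets))

    @property
    def scan_width_um(self) -> float:
        return self.n_pixels * self.pixel_size_um

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_period_s

    @property
    def line_times_s(self) -> np.ndarray:
        """Timestamp of each line (line start), s."""
        return np.arange(self.n_lines) * self.line_period_s


@dataclass
class Kymograph:
    """A line-scan image plus its acquisition metadata.

    ``image`` has shape ``(meta.n_lines, meta.n_pixels)`` with non-negative
    intensities in detector counts.
    """

    image: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ParameterError("kymograph image must be 2D (lines x pixels)")
        if self.image.shape != (self.meta.n_lines, self.meta.n_pixels):
            raise ParameterError(
                f"image shape {self.image.shape} does not match metadata "
                f"({self.meta.n_lines}, {self.meta.n_pixels})")
        if np.any(self.image < 0):
            raise ParameterError("kymograph intensities must be >= 0")
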