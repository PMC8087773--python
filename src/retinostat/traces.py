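"""Containers for uniformly sampled physiological recordings.

A :class:`Trace` holds one flash response — an ERG trace in microvolts or a
rod photocurrent in picoamps — together with the sample interval, the flash
time, the flash intensity and identifying tags (mouse, genotype, eye/rod).
A :class:`FlashSession` groups the traces recorded from one eye under one
adaptation condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "Trace",
    "FlashMeasurement",
    "FlashSession",
    "measure_bwave_amplitude",
]

#: polarity conventions for stored traces
POLARITIES = ("corneal-positive", "photocurrent")


@dataclass
class Trace:
    """One uniformly sampled flash response.

    Parameters
    ----------
    values : ndarray
        Sampled amplitudes.  ERG traces are stored corneal-positive (the
        B-wave is an upward deflection, the A-wave a downward one);
        photocurrents are stored response-positive.
    dt : float
        Sample interval in seconds.
    t_flash : float
        Flash time in seconds relative to the first sample.
    flash_intensity : float
        Flash strength (scotopic/photopic cd*s/m^2 for ERG, R*/rod for
        photocurrents); the unit travels in ``intensity_unit``.
    """

    values: np.ndarray
    dt: float
    t_flash: float = 0.0
    flash_intensity: float = np.nan
    intensity_unit: str = ""
    polarity: str = "corneal-positive"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.dt

    def with_values(self, values: np.ndarray) -> "Trace":
        """Copy of this trace with ``values`` replaced (same metadata)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the record)."""
        return int(np.clip(round(t / self.dt), 0, self.values.size - 1))


@dataclass(frozen=True)
class FlashMeasurement:
    """A (flash intensity, response amplitude) pair feeding the saturation fit."""

    intensity: float
    amplitude: float
    intensity_unit: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("flash intensity must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 after the polarity convention")


@dataclass
class FlashSession:
    """All traces recorded from one eye (or one rod) under one condition."""

    mouse: str
    genotype: str
    eye: str
    condition: str
    traces: list[Trace] = field(default_factory=list)
    pair: int = -1

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def trace_for(self, intensity: float) -> Trace:
        for tr in self.traces:
            if np.isclose(tr.flash_intensity, intensity):
                return tr
        raise KeyError(f"no trace with flash intensity {intensity}")

    @property
    def intensities(self) -> np.ndarray:
        return np.array([tr.flash_intensity for tr in self.traces])


def measure_bwave_amplitude(
    trace: Trace,
    window: tuple[float, float] | None = None,
    baseline_span: float = 0.050,
    mode: str = "baseline-to-peak",
) -> FlashMeasurement:
    """B-wave amplitude of a low-pass-filtered ERG trace.

    The amplitude is the post-flash maximum minus the pre-flash baseline
    (mean of the ``baseline_span`` seconds preceding the flash, or of all
    pre-flash samples if the record is shorter).  ``mode='trough-to-peak'``
    instead references the post-flash minimum preceding the maximum.

    Parameters
    ----------
    window : (t0, t1), optional
        Search window for the peak, in seconds; defaults to flash-to-end.
    """
    t0, t1 = window if window is not None else (trace.t_flash, trace.duration)
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 <= i0:
        raise ValueError(f"empty amplitude window [{t0}, {t1}] s")
    seg = trace.values[i0 : i1 + 1]

    if mode == "trough-to-peak":
        ipk = int(np.argmax(seg))
        ref = float(np.min(seg[: ipk + 1]))
    else:
        ib = trace.index_at(trace.t_flash)
        nb = min(ib, max(1, round(baseline_span / trace.dt)))
        ref = float(np.mean(trace.values[ib - nb : ib])) if nb > 0 and ib > 0 else 0.0
    amp = max(float(np.max(seg)) - ref, 0.0)
    return FlashMeasurement(
        intensity=float(trace.flash_intensity),
        amplitude=amp,
        intensity_unit=trace.intensity_unit,
    )
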