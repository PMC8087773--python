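"""Butterworth filtering of physiological traces.

ERG B-waves and rod photocurrents are low-pass filtered at 22.5 Hz, ERG
A-waves at 1 kHz, and oscillatory potentials are extracted with a
75–300 Hz band-pass — all 6th-order Butterworth designs.  By default the
filter is applied forward-backward (zero phase) so peak times, which feed
the rising-window selection, are not shifted; a single-pass causal mode is
available.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .traces import Trace

__all__ = ["apply_butterworth", "LOWPASS_BWAVE_HZ", "LOWPASS_AWAVE_HZ", "OP_BAND_HZ"]

LOWPASS_BWAVE_HZ = 22.5   # B-wave and rod photocurrent low-pass cutoff
LOWPASS_AWAVE_HZ = 1000.0  # ERG A-wave low-pass cutoff
OP_BAND_HZ = (75.0, 300.0)  # oscillatory-potential band


def apply_butterworth(
    trace: Trace,
    kind: str,
    cutoffs: float | tuple[float, float],
    order: int = 6,
    zero_phase: bool = True,
) -> Trace:
    """Return a filtered copy of ``trace``.

    Parameters
    ----------
    kind : {'lowpass', 'bandpass'}
    cutoffs : float or (low, high) in Hz
        Must lie strictly below the Nyquist frequency.
    order : int
        Order of the underlying Butterworth design (default 6).  With
        ``zero_phase`` the design is applied forward and backward, which
        squares the magnitude response but leaves the design order as
        stated.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if kind not in ("lowpass", "bandpass"):
        raise ValueError(f"kind must be 'lowpass' or 'bandpass', got {kind!r}")
    fs = 1.0 / trace.dt
    nyq = fs / 2.0
    wn = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if kind == "lowpass" and wn.size != 1:
        raise ValueError("lowpass takes a single cutoff")
    if kind == "bandpass" and wn.size != 2:
        raise ValueError("bandpass takes (low, high) cutoffs")
    if np.any(wn <= 0) or np.any(wn >= nyq):
        raise ValueError(f"cutoffs {cutoffs} Hz must lie in (0, Nyquist={nyq} Hz)")

    sos = signal.butter(order, wn if wn.size > 1 else wn[0], btype=kind, fs=fs, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, trace.values)
    else:
        filtered = signal.sosfilt(sos, trace.values)
    return trace.with_values(filtered)
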