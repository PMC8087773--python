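"""Response-sensitivity models for ERG and rod-photocurrent data.

Two models, in the statsmodels idiom (construct from data, ``fit()``
returns a results object):

* :class:`SaturationModel` — the hyperbolic saturation of B-wave peak
  amplitudes, ``B/B_max = S_B I / (1 + S_B I)``, where ``S_B`` is the
  inverse of the half-saturating flash intensity.  Fitted from as few as
  two flash intensities (exact algebraic inversion) or by least squares
  for more.

* :class:`RisingPhaseModel` — the delayed-Gaussian activation model of
  the photoresponse rising phase, ``A(I,t)/A_max = 1 - exp(-S_A I
  (t - t_d)^2)``, fitted jointly over the rising windows of a family of
  flash responses with the delay ``t_d`` shared across flashes and
  constrained to a physiological range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .traces import FlashMeasurement, Trace

__all__ = [
    "SaturationModel",
    "SaturationFit",
    "RisingPhaseModel",
    "RisingPhaseFit",
    "select_rising_window",
    "rising_phase_model",
    "photons_to_isomerizations",
    "summarize_cohort",
    "FitError",
    "ERG_TD_BOUNDS",
    "ROD_TD_BOUNDS",
    "ROD_WINDOW_S",
    "ROD_COLLECTING_AREA_UM2",
]

# Observed delay ranges: ERG A-wave 3.4–4.4 ms, rod photocurrent 14–17 ms.
ERG_TD_BOUNDS = (0.0034, 0.0044)
ROD_TD_BOUNDS = (0.014, 0.017)
#: fixed rising-window length for dim-flash rod photocurrents
ROD_WINDOW_S = 0.060
#: effective collecting area per rod, µm², for photon → R* conversion
ROD_COLLECTING_AREA_UM2 = 0.5


class FitError(RuntimeError):
    """Raised when a sensitivity fit has no admissible solution."""


def photons_to_isomerizations(
    photon_density: float | np.ndarray,
    collecting_area: float = ROD_COLLECTING_AREA_UM2,
) -> float | np.ndarray:
    """Convert flash photon density (photons/µm²) to photoisomerizations per rod."""
    pd = np.asarray(photon_density, dtype=float)
    if np.any(pd < 0) or collecting_area < 0:
        raise ValueError("photon density and collecting area must be >= 0")
    out = pd * collecting_area
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Saturation (B-wave) model
# ---------------------------------------------------------------------------

@dataclass
class SaturationFit:
    """Fitted saturation parameters.

    ``s_b`` is the sensitivity (inverse half-saturating intensity) and
    ``b_max`` the saturated amplitude.  ``exact`` is True when the fit is
    the closed-form two-point inversion.
    """

    s_b: float
    b_max: float
    exact: bool
    n_points: int
    residual: float = 0.0
    intensity_unit: str = ""
    model: object = field(default=None, repr=False, compare=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.s_b, self.b_max])

    def predict(self, intensity: np.ndarray | float) -> np.ndarray | float:
        i = np.asarray(intensity, dtype=float)
        out = self.b_max * self.s_b * i / (1.0 + self.s_b * i)
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        unit = f" [{self.intensity_unit}]^-1" if self.intensity_unit else ""
        lines = [
            "Saturation fit  B = B_max * S_B I / (1 + S_B I)",
            "-" * 48,
            f"S_B    {self.s_b:#.6g}{unit}",
            f"B_max  {self.b_max:#.6g}",
            f"n points        {self.n_points}",
            f"method          {'two-point exact' if self.exact else 'least squares'}",
            f"residual (RSS)  {self.residual:.3g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Amplitude-vs-intensity data with the fitted saturation curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.semilogx(self.model.intensity, self.model.amplitude, "o",
                        label="measured")
            grid = np.geomspace(self.model.intensity.min() / 3,
                                self.model.intensity.max() * 3, 200)
        else:
            grid = np.geomspace(0.01 / self.s_b, 100 / self.s_b, 200)
        ax.semilogx(grid, self.predict(grid), "-", label="fit")
        ax.axhline(self.b_max, ls=":", color="grey")
        ax.set_xlabel(f"flash intensity [{self.intensity_unit or 'a.u.'}]")
        ax.set_ylabel("amplitude")
        ax.legend()
        return ax


class SaturationModel:
    """Hyperbolic saturation of response amplitude vs flash intensity.

    Parameters
    ----------
    points : sequence of FlashMeasurement, or (intensities, amplitudes)
        At least two measurements at distinct positive intensities with
        positive amplitudes.
    """

    def __init__(self, points, amplitudes=None):
        if amplitudes is not None:
            intens = np.asarray(points, dtype=float)
            amps = np.asarray(amplitudes, dtype=float)
            self.intensity_unit = ""
        else:
            pts = list(points)
            intens = np.array([p.intensity for p in pts])
            amps = np.array([p.amplitude for p in pts])
            self.intensity_unit = pts[0].intensity_unit if pts else ""
        if intens.size < 2 or intens.size != amps.size:
            raise ValueError("need >= 2 (intensity, amplitude) points")
        if np.unique(intens).size < 2:
            raise ValueError("need >= 2 distinct intensities")
        if np.any(intens <= 0) or np.any(amps <= 0):
            raise ValueError("intensities and amplitudes must be positive")
        self.intensity = intens
        self.amplitude = amps

    def fit(self) -> SaturationFit:
        if self.intensity.size == 2:
            s_b, b_max = self._two_point()
            return SaturationFit(s_b, b_max, exact=True, n_points=2,
                                 intensity_unit=self.intensity_unit,
                                 model=self)
        fit = self._least_squares()
        fit.model = self
        return fit

    def _two_point(self) -> tuple[float, float]:
        # 1/B is linear in 1/I:  1/B = 1/B_max + (1/(B_max S_B)) * (1/I)
        (i1, i2), (b1, b2) = self.intensity, self.amplitude
        slope = (1.0 / b1 - 1.0 / b2) / (1.0 / i1 - 1.0 / i2)
        intercept = 1.0 / b1 - slope / i1
        if intercept <= 0 or slope <= 0:
            raise FitError(
                "two-point amplitudes are inconsistent with saturating kinetics "
                f"(no positive S_B, B_max): I={self.intensity}, B={self.amplitude}"
            )
        return intercept / slope, 1.0 / intercept

    def _least_squares(self) -> SaturationFit:
        i, b = self.intensity, self.amplitude

        def resid(p):
            s_b, b_max = np.exp(p)  # positivity via log parametrisation
            return b_max * s_b * i / (1.0 + s_b * i) - b

        b_max0 = float(np.max(b)) * 1.05
        half = 0.5 * b_max0
        k = int(np.argmin(np.abs(b - half)))
        s_b0 = 1.0 / i[k] if b[k] > 0 else 1.0 / np.median(i)
        best = None
        for scale in (0.1, 1.0, 10.0):
            sol = least_squares(resid, x0=np.log([s_b0 * scale, b_max0]),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or sol.cost < best.cost:
                best = sol
        s_b, b_max = np.exp(best.x)
        return SaturationFit(float(s_b), float(b_max), exact=False,
                             n_points=i.size, residual=2 * float(best.cost),
                             intensity_unit=self.intensity_unit)


# ---------------------------------------------------------------------------
# Rising-phase (activation) model
# ---------------------------------------------------------------------------

def rising_phase_model(t: np.ndarray, intensity: float,
                       s_a: float, a_max: float, t_d: float,
                       t_flash: float = 0.0) -> np.ndarray:
    """Evaluate ``A(I,t) = A_max (1 - exp(-S_A I (t - t_flash - t_d)^2))``.

    Zero for ``t <= t_flash + t_d``.
    """
    tt = np.asarray(t, dtype=float) - t_flash - t_d
    tt = np.where(tt > 0, tt, 0.0)
    return a_max * (1.0 - np.exp(-s_a * intensity * tt**2))


def select_rising_window(
    trace: Trace,
    t_d: float,
    mode: str,
    long_period_rule: str = "end-before-peak",
) -> tuple[float, float]:
    """Rising-phase window of a flash response, in seconds.

    ``mode='erg_awave'``: from ``t_flash + t_d`` to the response peak; if
    that span exceeds 5 ms, the window ends 5 ms before the peak
    (``long_period_rule='end-before-peak'``, the literal reading) or is
    capped at 5 ms length (``'cap-length'``).

    ``mode='rod_photocurrent'``: fixed 60 ms starting at ``t_flash + t_d``.
    """
    t0 = trace.t_flash + t_d
    if not 0 <= t0 <= trace.duration:
        raise ValueError(f"t_d={t_d} s places the window start outside the trace")
    if mode == "rod_photocurrent":
        t1 = min(t0 + ROD_WINDOW_S, trace.duration)
    elif mode == "erg_awave":
        vals = trace.values if trace.polarity == "photocurrent" else -trace.values
        i0 = trace.index_at(t0)
        t_peak = (i0 + int(np.argmax(vals[i0:]))) * trace.dt
        if t_peak - t0 <= 0.005:
            t1 = t_peak
        elif long_period_rule == "end-before-peak":
            t1 = t_peak - 0.005
        elif long_period_rule == "cap-length":
            t1 = t0 + 0.005
        else:
            raise ValueError(f"unknown long_period_rule {long_period_rule!r}")
    else:
        raise ValueError(f"mode must be 'erg_awave' or 'rod_photocurrent', got {mode!r}")
    if (t1 - t0) / trace.dt < 1:
        raise ValueError(f"rising window [{t0}, {t1}] s holds fewer than 2 samples")
    return (t0, t1)


@dataclass
class RisingPhaseFit:
    """Jointly fitted activation parameters for one eye/rod."""

    s_a: float
    a_max: float
    t_d: float
    n_traces: int
    n_samples: int
    residual: float
    converged: bool
    mode: str
    intensity_unit: str = ""
    diagnostics: dict = field(default_factory=dict)
    model: object = field(default=None, repr=False, compare=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.s_a, self.a_max, self.t_d])

    def predict(self, t: np.ndarray, intensity: float, t_flash: float = 0.0) -> np.ndarray:
        return rising_phase_model(t, intensity, self.s_a, self.a_max, self.t_d, t_flash)

    def summary(self) -> str:
        unit = f" [{self.intensity_unit}]^-1 s^-2" if self.intensity_unit else " s^-2 (per intensity unit)"
        return "\n".join([
            "Rising-phase fit  A(I,t) = A_max (1 - exp(-S_A I (t-t_d)^2))",
            "-" * 60,
            f"S_A    {self.s_a:#.6g}{unit}",
            f"A_max  {self.a_max:#.6g}",
            f"t_d    {self.t_d * 1e3:#.4g} ms",
            f"mode            {self.mode}",
            f"traces/samples  {self.n_traces}/{self.n_samples}",
            f"residual (RSS)  {self.residual:.3g}",
            f"converged       {self.converged}",
        ])

    def plot(self, ax=None):
        """Rising-phase traces overlaid with the fitted activation curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            for tr in self.model.traces:
                y = self.model._response_values(tr)
                ax.plot(tr.times * 1e3, y, lw=0.8, alpha=0.6)
                ax.plot(tr.times * 1e3,
                        self.predict(tr.times, tr.flash_intensity, tr.t_flash),
                        "k--", lw=0.8)
        ax.set_xlabel("time [ms]")
        ax.set_ylabel("response amplitude")
        ax.set_title(f"S_A = {self.s_a:#.4g}, A_max = {self.a_max:#.4g}, "
                     f"t_d = {self.t_d * 1e3:.2f} ms")
        return ax


class RisingPhaseModel:
    """Joint activation-model fit over a family of flash responses.

    Parameters
    ----------
    traces : sequence of Trace
        Flash responses from one eye (ERG A-wave, corneal-positive; the
        fit negates them) or one rod (photocurrent, response-positive),
        already low-pass filtered per convention (1 kHz for A-waves,
        22.5 Hz for rod currents).  Flash intensities are taken from the
        traces.
    mode : {'erg_awave', 'rod_photocurrent'}
    t_d_bounds : (lo, hi) seconds, optional
        Delay constraint; defaults to the observed physiological ranges.
    """

    N_STARTS = 5  # deterministic multistart count

    def __init__(self, traces, mode: str,
                 t_d_bounds: tuple[float, float] | None = None,
                 long_period_rule: str = "end-before-peak"):
        self.traces = list(traces)
        if not self.traces:
            raise ValueError("need at least one trace")
        if mode not in ("erg_awave", "rod_photocurrent"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.t_d_bounds = t_d_bounds or (
            ERG_TD_BOUNDS if mode == "erg_awave" else ROD_TD_BOUNDS
        )
        self.long_period_rule = long_period_rule
        self.intensity_unit = self.traces[0].intensity_unit
        self._assemble()

    def _response_values(self, trace: Trace) -> np.ndarray:
        # A-wave fitting operates on the negated corneal-positive ERG.
        if self.mode == "erg_awave" and trace.polarity == "corneal-positive":
            return -trace.values
        return trace.values

    def _assemble(self) -> None:
        t_d_mid = 0.5 * (self.t_d_bounds[0] + self.t_d_bounds[1])
        ts, ys, intens, flashes = [], [], [], []
        for tr in self.traces:
            t0, t1 = select_rising_window(tr, t_d_mid, self.mode, self.long_period_rule)
            i0, i1 = tr.index_at(t0), tr.index_at(t1)
            tt = np.arange(i0, i1 + 1) * tr.dt
            vals = self._response_values(tr)[i0 : i1 + 1]
            ts.append(tt)
            ys.append(vals)
            intens.append(np.full(tt.size, tr.flash_intensity))
            flashes.append(np.full(tt.size, tr.t_flash))
        self._t = np.concatenate(ts)
        self._y = np.concatenate(ys)
        self._i = np.concatenate(intens)
        self._flash = np.concatenate(flashes)

    def fit(self) -> RisingPhaseFit:
        lo_td, hi_td = self.t_d_bounds
        t_d0 = 0.5 * (lo_td + hi_td)
        a_max0 = float(np.max(np.abs(self._y)))
        if a_max0 <= 0:
            raise FitError("all rising-phase samples are zero; nothing to fit")
        # crude S_A guess from the brightest flash reaching half-max
        i_ref = float(np.max(self._i))
        tt = self._t - self._flash - t_d0
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.clip(self._y / a_max0, 1e-6, 1 - 1e-9)
            cand = -np.log(1 - frac) / np.where(tt > 0, self._i * tt**2, np.nan)
        s_a0 = float(np.nanmedian(cand))
        if not np.isfinite(s_a0) or s_a0 <= 0:
            s_a0 = 1.0 / (i_ref * (0.01) ** 2)

        def resid(p):
            s_a, a_max = np.exp(p[0]), np.exp(p[1])
            return (
                rising_phase_model(self._t, self._i, s_a, a_max, p[2], self._flash)
                - self._y
            )

        best = None
        for scale in (0.05, 0.3, 1.0, 3.0, 20.0):  # 5 deterministic starts
            x0 = np.array([np.log(s_a0 * scale), np.log(a_max0), t_d0])
            sol = least_squares(
                resid, x0=x0,
                bounds=([-np.inf, -np.inf, lo_td], [np.inf, np.inf, hi_td]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and best.cost > 1e-6:
            raise FitError(f"rising-phase fit did not converge: {best.message if best else 'no solution'}")
        s_a, a_max = np.exp(best.x[0]), np.exp(best.x[1])
        return RisingPhaseFit(
            s_a=float(s_a), a_max=float(a_max), t_d=float(best.x[2]),
            n_traces=len(self.traces), n_samples=self._y.size,
            residual=2 * float(best.cost), converged=bool(best.success),
            mode=self.mode, intensity_unit=self.intensity_unit,
            diagnostics={"status": best.status, "nfev": best.nfev},
            model=self,
        )


# ---------------------------------------------------------------------------
# Per-mouse summaries
# ---------------------------------------------------------------------------

def summarize_cohort(rows) -> "pd.DataFrame":
    """Average per-eye (or per-rod) fit parameters to one row per mouse.

    ``rows`` is a tidy table (DataFrame or list of dicts) with columns
    ``mouse``, ``genotype``, ``pair``, a ``unit`` column naming the
    intensity unit, plus numeric parameter columns.  Parameters are
    arithmetically averaged over the eyes/rods of each mouse; genotype and
    pair labels are propagated for the downstream paired statistics.  A
    mouse contributing a single unit is kept and flagged ``n=1``.
    """
    import pandas as pd

    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no rows to summarize")
    keys = [k for k in ("mouse", "genotype", "pair") if k in df.columns]
    if "mouse" not in keys:
        raise ValueError("rows must carry a 'mouse' column")
    if "unit" in df.columns:
        for _, grp in df.groupby("mouse"):
            if grp["unit"].nunique() > 1:
                raise ValueError(f"mixed units for mouse {grp['mouse'].iloc[0]!r}")
    num_cols = [c for c in df.columns if c not in keys + ["unit", "eye", "rod"]
                and np.issubdtype(df[c].dtype, np.number)]
    out = df.groupby(keys, as_index=False)[num_cols].mean()
    out["n_units"] = df.groupby(keys).size().values
    if "unit" in df.columns:
        out["unit"] = df.groupby(keys)["unit"].first().values
    return out
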