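"""Synthetic cohorts with known ground truth.

Everything the analysis modules consume can be generated here: rising-phase
photoresponse families (the delayed-Gaussian activation model), B-wave
flash series whose peak amplitudes follow the hyperbolic saturation law
(with optional 75–300 Hz oscillatory potentials riding the rising phase),
full WT/KO ERG littermate cohorts, two-channel confocal stacks with rod
puncta and elongated cone patches over an ONL-like background, and paired
WT/KO intensity tables for the ratio estimators.

Every generated object is mirrored by exactly one ground-truth record, and
identical configurations (including the seed) give bit-identical output:
a single root seed is spawned into independent per-object streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .puncta import ImageStack, VoxelSize
from .ratiostats import PairedSample
from .traces import FlashSession, Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "OPSpec",
    "gen_rising_phase_trace",
    "gen_bwave_trace",
    "gen_erg_cohort",
    "gen_confocal_stack",
    "gen_confocal_pair",
    "gen_imaging_cohort",
    "gen_paired_samples",
    "SCOTOPIC_DIM", "SCOTOPIC_SAT", "PHOTOPIC_DIM", "PHOTOPIC_SAT",
]

# Flash intensities of the study protocol (cd*s/m^2)
SCOTOPIC_DIM = 0.00022
SCOTOPIC_SAT = 0.011
PHOTOPIC_DIM = 1.0
PHOTOPIC_SAT = 1000.0

#: oscillatory-potential band (Hz); frequencies outside trigger a warning
OP_FREQ_RANGE = (75.0, 300.0)


@dataclass(frozen=True)
class SimConfig:
    """Root configuration of a synthetic study.

    ``sample_dt`` defaults to the 0.2 ms ERG sampling interval;
    ``voxel_size`` to 0.1 µm lateral pixels and the 0.3 µm slice spacing
    of the imaging protocol; ``n_pairs`` to the 7 WT/KO littermate pairs
    of the ERG design (the imaging arm of the study used 14 section
    pairs, set per call).  ``effect_ratio`` is the true KO/WT staining
    ratio (≈1.4 regime); ``noise_sd`` the additive trace noise in signal
    units (0 = noise-free closure mode).
    """

    seed: int = 0
    n_pairs: int = 7
    effect_ratio: float = 1.4
    noise_sd: float = 0.0
    sample_dt: float = 0.0002
    voxel_size: VoxelSize = VoxelSize(0.1, 0.1, 0.3)

    def __post_init__(self) -> None:
        if self.effect_ratio <= 0:
            raise ValueError("effect_ratio must be > 0")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    def rng_streams(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class GroundTruth:
    """True parameters behind a synthetic data set, one record per object."""

    traces: list = field(default_factory=list)
    puncta: list = field(default_factory=list)
    pairs: list = field(default_factory=list)


@dataclass(frozen=True)
class OPSpec:
    """Damped sinusoid injected on the B-wave rising phase."""

    freq_hz: float = 120.0
    amplitude: float = 10.0
    decay_s: float = 0.05


# ---------------------------------------------------------------------------
# Trace generators
# ---------------------------------------------------------------------------

def gen_rising_phase_trace(
    s_a: float,
    a_max: float,
    t_d: float,
    intensity: float,
    dt: float,
    duration: float,
    noise_sd: float = 0.0,
    rise_duration: float | None = None,
    t_flash: float = 0.0,
    polarity: str = "photocurrent",
    intensity_unit: str = "",
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> tuple[Trace, dict]:
    """Photoresponse rising phase: 0 until ``t_flash + t_d``, then
    ``A_max (1 - exp(-S_A I (t - t_flash - t_d)^2))``.

    ``rise_duration`` (s after t_d) optionally freezes the response at the
    value reached — only the rising phase is modeled, the recovery is not.
    Additive Gaussian noise of SD ``noise_sd``.  Returns the trace and its
    ground-truth record.
    """
    if min(s_a, a_max, intensity, dt, duration) <= 0 or t_d <= 0:
        raise ValueError("all rising-phase parameters must be positive")
    if duration <= t_flash + t_d:
        raise ValueError("duration must exceed t_flash + t_d")
    t = np.arange(0, round(duration / dt) + 1) * dt
    tt = np.clip(t - t_flash - t_d, 0.0, None)
    if rise_duration is not None:
        tt = np.minimum(tt, rise_duration)
    values = a_max * (1.0 - np.exp(-s_a * intensity * tt**2))
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        values = values + rng.normal(0.0, noise_sd, values.size)
    if polarity == "corneal-positive":
        values = -values  # A-wave is corneal-negative
    trace = Trace(values, dt, t_flash=t_flash, flash_intensity=intensity,
                  intensity_unit=intensity_unit, polarity=polarity,
                  meta=dict(meta or {}))
    gt = {"kind": "rising_phase", "s_a": s_a, "a_max": a_max, "t_d": t_d,
          "intensity": intensity, "noise_sd": noise_sd}
    return trace, gt


def _gamma_rise(t: np.ndarray, t_flash: float, tau: float) -> np.ndarray:
    """Smooth unit-peak rise: (t/tau)^2 exp(2(1 - t/tau)), peak 1 at tau."""
    tt = np.clip(t - t_flash, 0.0, None) / tau
    return tt**2 * np.exp(2.0 * (1.0 - tt))


def gen_bwave_trace(
    s_b: float,
    b_max: float,
    intensity: float,
    dt: float,
    op_spec: OPSpec | None = None,
    duration: float = 0.5,
    t_flash: float = 0.1,
    tau_peak: float = 0.06,
    noise_sd: float = 0.0,
    intensity_unit: str = "",
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> tuple[Trace, dict]:
    """Smooth positive B-wave whose peak follows the saturation law.

    The kinetic waveform (not constrained by the saturation model, which
    only fixes the peak) is a gamma-function rise peaking ``tau_peak``
    seconds after the flash, scaled so the peak amplitude equals
    ``B_max S_B I / (1 + S_B I)``.  ``tau_peak`` is snapped to the sample
    grid so the sampled maximum equals the analytic peak exactly.  An
    optional damped 75–300 Hz sinusoid (``op_spec``) is added on the
    rising phase.
    """
    if s_b < 0 or b_max < 0 or intensity < 0:
        raise ValueError("S_B, B_max and intensity must be >= 0")
    if dt <= 0 or duration <= t_flash:
        raise ValueError("invalid dt/duration")
    tau = max(dt, round(tau_peak / dt) * dt)
    t = np.arange(0, round(duration / dt) + 1) * dt
    peak = b_max * s_b * intensity / (1.0 + s_b * intensity)
    values = peak * _gamma_rise(t, t_flash, tau)

    op_true = 0.0
    if op_spec is not None:
        lo, hi = OP_FREQ_RANGE
        if not lo <= op_spec.freq_hz <= hi:
            warnings.warn(
                f"OP frequency {op_spec.freq_hz} Hz outside the {lo}-{hi} Hz band",
                UserWarning, stacklevel=2,
            )
        t_on = t_flash + 0.25 * tau  # early rising phase
        rel = t - t_on
        osc = np.where(
            rel >= 0,
            op_spec.amplitude * np.sin(2 * np.pi * op_spec.freq_hz * rel)
            * np.exp(-np.clip(rel, 0, None) / op_spec.decay_s),
            0.0,
        )
        # confine to the rising phase (fade out at the peak)
        osc[t > t_flash + tau] = 0.0
        values = values + osc
        op_true = op_spec.amplitude
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        values = values + rng.normal(0.0, noise_sd, values.size)
    trace = Trace(values, dt, t_flash=t_flash, flash_intensity=intensity,
                  intensity_unit=intensity_unit, polarity="corneal-positive",
                  meta=dict(meta or {}))
    gt = {"kind": "bwave", "s_b": s_b, "b_max": b_max, "peak": peak,
          "intensity": intensity, "op_amplitude": op_true, "noise_sd": noise_sd}
    return trace, gt


# ---------------------------------------------------------------------------
# ERG cohort
# ---------------------------------------------------------------------------

#: per-condition baseline parameters (S_B in (cd*s/m^2)^-1, B_max in uV)
COHORT_BASELINES = {
    "scotopic": {"s_b": 1000.0, "b_max": 400.0,
                 "dim": SCOTOPIC_DIM, "sat": SCOTOPIC_SAT},
    "photopic": {"s_b": 0.2, "b_max": 150.0,
                 "dim": PHOTOPIC_DIM, "sat": PHOTOPIC_SAT},
}


def gen_erg_cohort(
    config: SimConfig,
    s_b_factor: float = 1.5,
    op_coupling: bool = False,
    op_gain: float = 0.05,
    between_pair_cv: float = 0.15,
    between_eye_cv: float = 0.03,
) -> tuple[list[FlashSession], GroundTruth]:
    """WT/KO littermate ERG cohort, two eyes per mouse.

    Each eye gets a dim and a saturating flash per condition (scotopic
    and photopic).  KO sensitivity is the littermate WT value scaled by
    ``s_b_factor``; ``B_max`` is drawn from the same distribution for
    both genotypes (the saturated amplitude does not depend on the RGS
    level).  With ``op_coupling`` the oscillatory-potential amplitude on
    the photopic saturating flash is proportional to that eye's photopic
    sensitivity, emulating the downstream inner-retinal coupling.
    """
    rngs = config.rng_streams(config.n_pairs)
    sessions: list[FlashSession] = []
    gt = GroundTruth()
    for p in range(config.n_pairs):
        rng = rngs[p]
        pair_scale = {c: np.exp(rng.normal(0.0, between_pair_cv))
                      for c in COHORT_BASELINES}
        bmax_scale = {c: np.exp(rng.normal(0.0, between_pair_cv))
                      for c in COHORT_BASELINES}
        # per-eye jitters are drawn once per littermate pair and shared by
        # both genotypes, so factor 1 + zero noise gives identical sessions
        eye_jit = {(e, c): np.exp(rng.normal(0.0, between_eye_cv))
                   for e in ("OD", "OS") for c in COHORT_BASELINES}
        eye_jit_b = {(e, c): np.exp(rng.normal(0.0, between_eye_cv))
                     for e in ("OD", "OS") for c in COHORT_BASELINES}
        for genotype in ("WT", "KO"):
            mouse = f"pair{p:02d}_{genotype}"
            for eye in ("OD", "OS"):
                for cond, base in COHORT_BASELINES.items():
                    s_b = base["s_b"] * pair_scale[cond] * eye_jit[(eye, cond)]
                    if genotype == "KO":
                        s_b *= s_b_factor
                    b_max = base["b_max"] * bmax_scale[cond] * eye_jit_b[(eye, cond)]
                    session = FlashSession(mouse=mouse, genotype=genotype,
                                           eye=eye, condition=cond, pair=p)
                    for which in ("dim", "sat"):
                        op = None
                        if cond == "photopic" and which == "sat":
                            # OP amplitude tracks sensitivity when coupled
                            rel = s_b / COHORT_BASELINES[cond]["s_b"]
                            amp = op_gain * b_max * (rel if op_coupling else 1.0)
                            op = OPSpec(freq_hz=120.0, amplitude=amp)
                        tr, tr_gt = gen_bwave_trace(
                            s_b, b_max, base[which], config.sample_dt,
                            op_spec=op, noise_sd=config.noise_sd,
                            intensity_unit="cd.s/m^2", rng=rng,
                            meta={"mouse": mouse, "genotype": genotype,
                                  "eye": eye, "condition": cond,
                                  "flash": which, "pair": p},
                        )
                        tr_gt.update(mouse=mouse, genotype=genotype, eye=eye,
                                     condition=cond, flash=which, pair=p)
                        session.traces.append(tr)
                        gt.traces.append(tr_gt)
                    sessions.append(session)
    return sessions, gt


# ---------------------------------------------------------------------------
# Confocal stacks
# ---------------------------------------------------------------------------

#: default stack geometry (µm): OPL ROI of the imaging protocol
DEFAULT_ROI_UM = (105.0, 7.5)


def _truncated_gaussian_patch(shape_px: tuple[int, int, int],
                              sigmas_px: tuple[float, float, float]) -> np.ndarray:
    """Unit-amplitude separable Gaussian on a hard (2h+1)^3 support."""
    hz, hy, hx = shape_px
    sz, sy, sx = sigmas_px
    z = np.arange(-hz, hz + 1)[:, None, None]
    y = np.arange(-hy, hy + 1)[None, :, None]
    x = np.arange(-hx, hx + 1)[None, None, :]
    return np.exp(-(z**2) / (2 * sz**2) - (y**2) / (2 * sy**2)
                  - (x**2) / (2 * sx**2))


class GenerationError(RuntimeError):
    """Puncta cannot be placed under the separation constraint."""


def gen_confocal_stack(
    config: SimConfig,
    n_rod: int = 20,
    n_cone: int = 4,
    channel_intensities: dict | None = None,
    genotype: str = "WT",
    roi_um: tuple[float, float] = DEFAULT_ROI_UM,
    min_separation_um: float = 3.0,
    background: float = 2.0,
    noise: bool = False,
    gaussian_noise_sd: float = 0.05,
    poisson: bool = False,
    rng: np.random.Generator | None = None,
    _geometry: dict | None = None,
) -> tuple[ImageStack, list[dict]]:
    """Two-channel confocal stack with rod puncta and cone patches.

    Channel 0 is the reference (mGluR6 proxy), the remaining channels the
    target proteins; all channels share punctum centres.  For KO stacks
    the injected target amplitudes are scaled by ``config.effect_ratio``.
    Rod puncta are isotropic truncated-Gaussian blobs whose
    above-background footprint extends 0.3 µm each side of the centre
    (within the ≤0.5 µm rod criterion); cone patches are horizontally
    elongated with a 1.3 µm half-extent, safely beyond the >1.1 µm
    cone criterion.  Puncta sit inside the OPL ROI with at
    least ``min_separation_um`` between centres so ground truth is
    unambiguous; an ONL band of pure background is included for
    normalization.
    """
    if channel_intensities is None:
        channel_intensities = {"mGluR6": 5.0, "RGS7": 4.0}
    channels = list(channel_intensities)
    rng = rng or np.random.default_rng(config.seed)
    vx = config.voxel_size

    roi_w_px = round(roi_um[0] / vx.x)
    roi_h_px = round(roi_um[1] / vx.y)
    nz = 7
    margin = 8
    onl_h = 30
    gap = 10
    ny = onl_h + gap + roi_h_px + 2 * margin
    nx = roi_w_px + 2 * margin
    onl_region = (0, onl_h, 0, nx)
    y0 = onl_h + gap + margin
    opl_roi = (y0, y0 + roi_h_px, margin, margin + roi_w_px)

    n_puncta = n_rod + n_cone
    sep_px = round(min_separation_um / vx.x)
    if _geometry is not None:
        centers, classes = _geometry["centers"], _geometry["classes"]
    else:
        centers, classes = [], []
        if n_puncta > 0:
            # one slot per punctum along the ROI, margin for the cone support
            edge = round(1.6 / vx.x)
            usable = roi_w_px - 2 * edge
            if n_puncta * sep_px > usable:
                raise GenerationError(
                    f"{n_puncta} puncta at {min_separation_um} µm separation "
                    f"do not fit in a {roi_um[0]} µm ROI"
                )
            slot = usable // n_puncta
            jitter_max = max(0, (slot - sep_px) // 2)
            order = rng.permutation(np.array(["rod"] * n_rod + ["cone"] * n_cone))
            zc = nz // 2
            yc = y0 + roi_h_px // 2
            for k, klass in enumerate(order):
                jx = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
                jy = int(rng.integers(-2, 3))
                x = opl_roi[2] + edge + slot * k + slot // 2 + jx
                centers.append((zc, yc + jy, x))
                classes.append(str(klass))

    data = np.full((len(channels), nz, ny, nx), background, dtype=float)
    rod_patch = _truncated_gaussian_patch((1, 3, 3), (1.0, 1.2, 1.2))
    cone_patch = _truncated_gaussian_patch((1, 3, 13), (1.0, 1.2, 6.0))
    gt: list[dict] = []
    for (z, y, x), klass in zip(centers, classes):
        patch = rod_patch if klass == "rod" else cone_patch
        hz, hy, hx = (s // 2 for s in patch.shape)
        amps = {}
        for ci, ch in enumerate(channels):
            amp = channel_intensities[ch]
            if ci > 0 and genotype == "KO":
                amp *= config.effect_ratio
            data[ci, z - hz : z + hz + 1, y - hy : y + hy + 1,
                 x - hx : x + hx + 1] += amp * patch
            amps[ch] = amp
        gt.append({"center": (z, y, x), "class": klass, "amplitudes": amps,
                   "genotype": genotype})

    if noise:
        if poisson:
            data = rng.poisson(np.clip(data, 0, None) * 20.0) / 20.0
        data = data + rng.normal(0.0, gaussian_noise_sd * background, data.shape)

    stack = ImageStack(data, vx, opl_roi, onl_region, channels=channels,
                       reference=channels[0],
                       meta={"genotype": genotype, "seed": config.seed})
    return stack, gt


def gen_confocal_pair(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    pair_effect: float | None = None,
    **kwargs,
) -> tuple[ImageStack, ImageStack, dict]:
    """Matched WT/KO stacks sharing punctum geometry.

    The KO target channels are scaled by ``pair_effect`` (default the
    config's ``effect_ratio``), so with noise off the KO/WT window-sum
    ratio equals it exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    geom_rng = np.random.default_rng(rng.integers(2**31))
    wt, gt_wt = gen_confocal_stack(config, genotype="WT",
                                   rng=np.random.default_rng(geom_rng.integers(2**31)),
                                   **kwargs)
    geometry = {"centers": [g["center"] for g in gt_wt],
                "classes": [g["class"] for g in gt_wt]}
    eff = config.effect_ratio if pair_effect is None else pair_effect
    ko_cfg = replace(config, effect_ratio=eff)
    ko, gt_ko = gen_confocal_stack(ko_cfg, genotype="KO",
                                   rng=np.random.default_rng(geom_rng.integers(2**31)),
                                   _geometry=geometry, **kwargs)
    return wt, ko, {"wt": gt_wt, "ko": gt_ko, "true_ratio": eff}


def gen_imaging_cohort(
    config: SimConfig,
    proteins: tuple[str, ...] = ("RGS7", "Gb5"),
    effect_ratios: dict | None = None,
    pair_cv: float = 0.0,
    shared_pair_latent: bool = True,
    **kwargs,
) -> tuple[list[dict], GroundTruth]:
    """Per-pair WT/KO stacks for each target protein.

    Each littermate pair contributes one two-channel stack per protein
    (mGluR6 reference + target).  ``pair_cv`` adds lognormal spread to
    the per-pair true ratio; with ``shared_pair_latent`` the same latent
    multiplier applies to every protein of a pair, inducing the positive
    cross-protein correlation of the paired ratios.
    """
    effect_ratios = effect_ratios or {p: config.effect_ratio for p in proteins}
    rngs = config.rng_streams(config.n_pairs + 1)
    gt = GroundTruth()
    cohort: list[dict] = []
    for p in range(config.n_pairs):
        rng = rngs[p]
        latent = np.exp(rng.normal(0.0, pair_cv)) if pair_cv > 0 else 1.0
        entry: dict = {"pair": p, "stacks": {}, "true_ratios": {}, "gt": {}}
        for prot in proteins:
            own = latent if shared_pair_latent else (
                np.exp(rng.normal(0.0, pair_cv)) if pair_cv > 0 else 1.0)
            eff = effect_ratios[prot] * own
            ci = {"mGluR6": 5.0, prot: 4.0}
            wt, ko, pair_gt = gen_confocal_pair(
                config, rng=rng, pair_effect=eff,
                channel_intensities=ci, **kwargs)
            entry["stacks"][prot] = (wt, ko)
            entry["true_ratios"][prot] = eff
            entry["gt"][prot] = pair_gt
            gt.puncta.extend(pair_gt["wt"] + pair_gt["ko"])
        gt.pairs.append(entry["true_ratios"] | {"pair": p})
        cohort.append(entry)
    return cohort, gt


# ---------------------------------------------------------------------------
# Paired intensity tables
# ---------------------------------------------------------------------------

def gen_paired_samples(
    n: int,
    true_ratio: float,
    cv: float,
    seed: int | np.random.Generator = 0,
    independent_noise: bool = False,
) -> tuple[PairedSample, dict]:
    """Paired WT/KO intensities: x lognormal about 1 with the stated CV,
    y = true_ratio · x · (multiplicative lognormal noise of the same CV).

    With ``independent_noise`` the shared factor x drops out of y
    (``y = true_ratio · noise``), so numerator and denominator noise are
    independent.  In that regime the ratio-of-sums estimator carries the
    classic O(1/n) denominator bias that the jackknife correction
    targets; in the default shared-factor regime the common noise
    cancels and the estimator is already unbiased."""
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    x = np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    noise = np.exp(rng.normal(-sigma**2 / 2, sigma, n)) if cv > 0 else np.ones(n)
    y = true_ratio * (noise if independent_noise else x * noise)
    return PairedSample(x, y), {"true_ratio": true_ratio, "cv": cv, "n": n,
                                "independent_noise": independent_noise}
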