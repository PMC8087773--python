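"""End-to-end analyses: ERG cohort and imaging cohort.

Two orchestrated runs mirror the study design.  The ERG run fits
per-eye sensitivities (two-point saturation fit on dim + saturating
flashes), extracts oscillatory potentials from the photopic saturating
flash, averages eyes per mouse and applies paired KO-vs-WT statistics
plus the OP-vs-sensitivity correlation.  The imaging run quantifies each
section pair, forms jackknife bias-corrected KO/WT ratios for OPL, rod-
and cone-tip levels, and correlates paired ratios across proteins.  Both
are fully deterministic under a fixed :class:`RunConfig` and write their
configuration snapshot next to their reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .filters import LOWPASS_BWAVE_HZ, apply_butterworth
from .oscillations import extract_op_amplitude
from .puncta import VoxelSize, quantify_section
from .ratiostats import (PairedSample, correlations, jackknife_ratio, paired_t,
                         DegenerateSampleError)
from .sensitivity import SaturationModel, summarize_cohort
from .traces import measure_bwave_amplitude

logger = logging.getLogger("retinostat")

__all__ = ["RunConfig", "run_erg_pipeline", "run_imaging_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    All protocol constants are surfaced here rather than hard-coded:
    filter cutoffs, delay bounds, classification windows, thresholds and
    cohort parameters.  ``snapshot()`` serializes the exact configuration
    alongside every report for provenance.
    """

    seed: int = 0
    n_pairs: int = 7
    noise_sd: float = 0.0
    s_b_factor: float = 1.5
    op_coupling: bool = True
    lowpass_hz: float = LOWPASS_BWAVE_HZ
    apply_lowpass: bool = True
    op_band_hz: tuple = (75.0, 300.0)
    alpha: float = 0.05
    # imaging arm
    effect_ratios: dict = field(default_factory=lambda: {"RGS7": 1.4, "Gb5": 1.3})
    proteins: tuple = ("RGS7", "Gb5")
    n_rod: int = 20
    n_cone: int = 4
    pair_cv: float = 0.0
    imaging_noise: bool = False
    roi_um: tuple = (105.0, 7.5)
    voxel_um: tuple = (0.1, 0.1, 0.3)
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.noise_sd < 0 or self.pair_cv < 0:
            raise ValueError("noise levels must be >= 0")

    def sim_config(self, effect_ratio: float = 1.4) -> synth.SimConfig:
        return synth.SimConfig(seed=self.seed, n_pairs=self.n_pairs,
                               effect_ratio=effect_ratio,
                               noise_sd=self.noise_sd,
                               voxel_size=VoxelSize(*self.voxel_um))

    def snapshot(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("op_band_hz", "proteins", "roi_um", "voxel_um"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# ERG pipeline
# ---------------------------------------------------------------------------

def run_erg_pipeline(config: RunConfig, sessions=None) -> dict:
    """Simulate (or take) an ERG cohort and run the full analysis.

    Returns a dict with ``per_eye`` and ``per_mouse`` DataFrames, the
    paired-test table ``tests`` and the OP-vs-sensitivity
    ``correlation``.  When ``config.out_dir`` is set, tidy CSVs and a
    config snapshot are written there.
    """
    if sessions is None:
        sessions, _ = synth.gen_erg_cohort(
            config.sim_config(), s_b_factor=config.s_b_factor,
            op_coupling=config.op_coupling)
    rows = []
    for sess in sessions:
        if len(sess.traces) < 2:
            logger.warning("session %s/%s/%s has <2 flashes; skipped",
                           sess.mouse, sess.eye, sess.condition)
            continue
        points = []
        for tr in sess.traces:
            work = (apply_butterworth(tr, "lowpass", config.lowpass_hz)
                    if config.apply_lowpass else tr)
            points.append(measure_bwave_amplitude(work))
        fit = SaturationModel(points).fit()
        row = {"mouse": sess.mouse, "genotype": sess.genotype,
               "pair": sess.pair, "eye": sess.eye,
               "condition": sess.condition, "unit": "cd.s/m^2",
               "s_b": fit.s_b, "b_max": fit.b_max}
        if sess.condition == "photopic":
            sat = max(sess.traces, key=lambda t: t.flash_intensity)
            op = extract_op_amplitude(sat, b_max=fit.b_max,
                                      band=config.op_band_hz)
            row["op_amplitude"] = op.amplitude
            row["op_normalized"] = op.normalized
        rows.append(row)
    per_eye = pd.DataFrame(rows)
    per_mouse = pd.concat([
        summarize_cohort(grp).assign(condition=cond)
        for cond, grp in per_eye.groupby("condition")
    ], ignore_index=True)

    tests = []
    for cond, grp in per_mouse.groupby("condition"):
        wide = grp.pivot_table(index="pair", columns="genotype",
                               values=["s_b", "b_max"])
        for param in ("s_b", "b_max"):
            cols = wide[param].dropna()
            if not {"WT", "KO"}.issubset(cols.columns):
                logger.warning("condition %s lacks complete pairs; dropped", cond)
                continue
            sample = PairedSample(cols["WT"].to_numpy(), cols["KO"].to_numpy())
            tests.append({
                "condition": cond, "parameter": param,
                "p": paired_t(sample),
                "mean_wt": cols["WT"].mean(), "mean_ko": cols["KO"].mean(),
                "n": sample.n,
            })
    tests = pd.DataFrame(tests)

    corr = None
    phot = per_mouse[per_mouse["condition"] == "photopic"]
    if len(phot) >= 3 and "op_normalized" in phot:
        try:
            corr = correlations(phot["s_b"].to_numpy(),
                                phot["op_normalized"].to_numpy())
        except DegenerateSampleError:
            logger.warning("OP-vs-sensitivity correlation degenerate; skipped")

    report = {"per_eye": per_eye, "per_mouse": per_mouse, "tests": tests,
              "correlation": corr}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_eye.to_csv(out / "erg_per_eye.csv", index=False, float_format="%.10g")
        per_mouse.to_csv(out / "erg_per_mouse.csv", index=False, float_format="%.10g")
        tests.to_csv(out / "erg_tests.csv", index=False, float_format="%.10g")
        if corr is not None:
            (out / "erg_correlation.json").write_text(json.dumps(
                dataclasses.asdict(corr), indent=1))
        config.snapshot(out / "run_config.yaml")
    return report


# ---------------------------------------------------------------------------
# Imaging pipeline
# ---------------------------------------------------------------------------

def run_imaging_pipeline(config: RunConfig, cohort=None) -> dict:
    """Quantify a WT/KO imaging cohort and estimate KO/WT ratios.

    Returns per-section quantifications, per-pair paired measurements,
    jackknife bias-corrected ratios for OPL / rod-tip / cone-tip levels
    of every target protein, and cross-protein correlations of the
    paired ratios.
    """
    if cohort is None:
        cohort, _ = synth.gen_imaging_cohort(
            config.sim_config(), proteins=config.proteins,
            effect_ratios=config.effect_ratios, pair_cv=config.pair_cv,
            n_rod=config.n_rod, n_cone=config.n_cone, roi_um=config.roi_um,
            noise=config.imaging_noise)

    section_rows, pair_rows = [], []
    for entry in cohort:
        for prot, (wt, ko) in entry["stacks"].items():
            quants = {}
            for genotype, stack in (("WT", wt), ("KO", ko)):
                sq = quantify_section(stack, sample_id=f"pair{entry['pair']}_{genotype}_{prot}")
                quants[genotype] = sq
                section_rows.append({
                    "pair": entry["pair"], "protein": prot, "genotype": genotype,
                    "opl_mean": sq.opl_means.get(prot, np.nan),
                    "n_rod": sq.n_rod,
                    "n_cone": sq.n_cone, "n_excluded": sq.n_excluded,
                    **{f"{k}_{c}": v for (k, c), v in sq.class_means.items()},
                })
            row = {"pair": entry["pair"], "protein": prot}
            for measure in ("opl", "rod", "cone"):
                for genotype, sq in quants.items():
                    if measure == "opl":
                        val = sq.opl_means.get(prot, np.nan)
                    else:
                        val = sq.class_means.get((measure, prot), np.nan)
                    row[f"{measure}_{genotype}"] = val
            pair_rows.append(row)
    sections = pd.DataFrame(section_rows)
    pairs = pd.DataFrame(pair_rows)

    ratio_rows = []
    for prot, grp in pairs.groupby("protein"):
        for measure in ("opl", "rod", "cone"):
            wt = grp[f"{measure}_WT"].to_numpy()
            ko = grp[f"{measure}_KO"].to_numpy()
            ok = np.isfinite(wt) & np.isfinite(ko)
            if ok.sum() < 2:
                logger.warning("%s/%s: fewer than 2 complete pairs; ratio undefined",
                               prot, measure)
                ratio_rows.append({"protein": prot, "measure": measure,
                                   "n": int(ok.sum()), "r": np.nan,
                                   "r_c": np.nan, "s_c": np.nan,
                                   "flag": "undefined"})
                continue
            est = jackknife_ratio(PairedSample(wt[ok], ko[ok]))
            ratio_rows.append({"protein": prot, "measure": measure, "n": est.n,
                               "r": est.r, "r_c": est.r_c, "s": est.s,
                               "s_c": est.s_c, "flag": ""})
    ratios = pd.DataFrame(ratio_rows)

    cross = {}
    prots = list(config.proteins)
    if len(prots) >= 2:
        for measure in ("opl", "rod", "cone"):
            a = pairs[pairs["protein"] == prots[0]].set_index("pair")
            b = pairs[pairs["protein"] == prots[1]].set_index("pair")
            ra = (a[f"{measure}_KO"] / a[f"{measure}_WT"]).dropna()
            rb = (b[f"{measure}_KO"] / b[f"{measure}_WT"]).dropna()
            common = ra.index.intersection(rb.index)
            if len(common) >= 3:
                try:
                    cross[measure] = correlations(ra.loc[common].to_numpy(),
                                                  rb.loc[common].to_numpy())
                except DegenerateSampleError:
                    logger.info("cross-protein correlation for %s degenerate "
                                "(noise-free ratios have zero variance)", measure)

    report = {"sections": sections, "pairs": pairs, "ratios": ratios,
              "cross_correlations": cross}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sections.to_csv(out / "imaging_sections.csv", index=False, float_format="%.10g")
        pairs.to_csv(out / "imaging_pairs.csv", index=False, float_format="%.10g")
        ratios.to_csv(out / "imaging_ratios.csv", index=False, float_format="%.10g")
        config.snapshot(out / "run_config.yaml")
    return report
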