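"""Orchestration of the two study workflows.

* **Phantom accuracy**: per-site parametric maps of the calibration vials
  (simulated or supplied), vial-mean measurements, percent differences
  against reference values, and cross-site CVs.
* **Volunteer reproducibility**: per-scan morphometry + ROI means assembled
  into a measure table, then average CVs, Friedman and pairwise rank tests,
  variance components, and the sample-size grid.

Both accept either image-level inputs (full pipeline) or a pre-computed
measure table ("table-only" mode), so tabulated study data can drive the
statistics without images.  All randomness flows from one master seed;
reports are plain dicts serialized as sorted-key JSON, so identical
configurations produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry as morpho
from . import repro
from .imaging import ContourStack, GridSpec
from .mapping import B1Map, ParametricMap, compute_mtr, fit_adc, fit_t1_vfa
from .phantom import (
    PhantomSpec,
    SiteEffect,
    StudyDesign,
    make_vial_phantom_truth,
    make_pancreas_truth,
    simulate_acquisition,
    simulate_multisite_study,
)
from .power import power_table

__all__ = [
    "RunConfig",
    "compute_subject_measures",
    "measure_phantom_site",
    "run_phantom_workflow",
    "run_volunteer_workflow",
]

_VARIANTS = ("standardized", "non_standardized")


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    workflow: str  # "phantom" | "volunteer" | "simulate"
    table: str | Path | None = None        # table-only mode input CSV
    references: dict | None = None         # measure -> reference value
    variant: str = "standardized"
    out_dir: str | Path | None = None
    seed: int = 0
    n_sites: int = 5
    noise_sigma: float = 0.0
    site_effects: list[SiteEffect] | None = None
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        if self.workflow not in ("phantom", "volunteer", "simulate"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        # "fixture" selects the packaged study table
        if (
            self.table is not None
            and str(self.table) != "fixture"
            and not Path(self.table).exists()
        ):
            raise FileNotFoundError(self.table)


def compute_subject_measures(
    subject_id: str,
    site_id: str,
    contours: ContourStack,
    maps: dict[str, ParametricMap],
    weight_kg: float | None = None,
    hepatic_roi: tuple[tuple[float, float], int] | None = None,
) -> morpho.SubjectMeasures:
    """All per-scan measures for one subject at one site.

    ``maps`` may hold any of adc / t1 / mtr / fat_fraction parametric maps;
    absent maps leave the corresponding measures missing.  ``hepatic_roi``
    is ((x_mm, y_mm), slice_index) for the 4 cm² circular liver ROI on the
    fat-fraction map.
    """
    values: dict[str, float] = {}
    volume = morpho.pancreas_volume(contours)
    values["volume"] = volume
    values["surface_to_volume"] = morpho.surface_area_to_volume(contours)
    if weight_kg is not None:
        values["pvi"] = morpho.pancreas_volume_index(volume, weight_kg)
    for key, measure in (("adc", "adc"), ("t1", "t1"), ("mtr", "mtr")):
        if key in maps:
            values[measure] = morpho.roi_mean_on_map(maps[key], contours).mean
    if "fat_fraction" in maps:
        values["panc_fat_fraction"] = morpho.roi_mean_on_map(maps["fat_fraction"], contours).mean
        if hepatic_roi is not None:
            center, k = hepatic_roi
            values["hep_fat_fraction"] = morpho.circular_roi_mean(
                maps["fat_fraction"], center, k
            ).mean
    return morpho.SubjectMeasures(subject_id, site_id, weight_kg, values)


def measure_phantom_site(
    spec: PhantomSpec,
    site: SiteEffect = SiteEffect(),
    seed: int = 0,
    variant: str = "standardized",
) -> dict[str, float]:
    """Simulate one site's phantom session and measure every vial.

    Forward-simulates VFA/DWI/MT acquisitions under the site's gain and
    B1 miscalibration, fits the maps (standardized: B1-corrected T1 and the
    200/800 b-pair; non-standardized: f = 1 and the 0/800 pair), and returns
    the mean of each map over its vial region.
    """
    params = {"gain": site.gain_factor}
    vfa = simulate_acquisition(spec, "vfa", {**params, "b1_scale": site.b1_scale}, seed=seed)
    dwi = simulate_acquisition(spec, "dwi", dict(params), seed=seed + 1)
    mt = simulate_acquisition(spec, "mt", dict(params), seed=seed + 2)
    if variant == "standardized":
        # the fit is handed the nominal transmit field; the site's b1_scale
        # miscalibration is what the correction does not know about
        t1_map = fit_t1_vfa(vfa, B1Map(spec.b1_field))
        adc_map = fit_adc(dwi, 200.0, 800.0)
    else:
        t1_map = fit_t1_vfa(vfa, None)
        adc_map = fit_adc(dwi, 0.0, 800.0)
    mtr_map = compute_mtr(mt)

    out: dict[str, float] = {}
    for i in range(4):
        region = spec.regions[f"t1_vial_{i + 1}"]
        out[f"t1_vial_{i + 1}"] = _region_mean(t1_map, region)
    out["adc"] = _region_mean(adc_map, spec.regions["ice_water"])
    out["mtr"] = _region_mean(mtr_map, spec.regions["mt_vial"])
    out["fat_fraction"] = float(
        spec.truth_maps["fat_fraction"].data[spec.regions["fat_vial"]].mean()
    )
    return out


def _region_mean(pmap: ParametricMap, region: np.ndarray) -> float:
    vals = pmap.data[region]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def run_phantom_workflow(config: RunConfig) -> dict:
    """Phantom accuracy report: percent differences vs reference values and
    cross-site CVs for every measure.

    Table-only mode (``config.table`` or the packaged phantom fixture when
    the path is the string ``"fixture"``) skips simulation.  Otherwise the
    vial phantom and the pancreas shape phantom are simulated at
    ``config.n_sites`` sites and measured through the full fitting chain.
    """
    warnings: list[str] = []
    if config.table is not None or config.references is not None:
        if config.table is None or str(config.table) == "fixture":
            table, references = repro.load_phantom_table()
        else:
            table = repro.load_measure_table(config.table)
            references = dict(config.references or {})
        pivot = table.pivot(index="site", columns="measure", values="value")
    else:
        grid = config.grid or GridSpec((128, 104, 24), (3.0, 3.0), 4.0)
        spec = make_vial_phantom_truth(grid, noise_sigma=config.noise_sigma, seed=config.seed)
        _, contours = make_pancreas_truth(
            GridSpec((256, 208, 24), (1.5, 1.5), 4.0), volume_ml=89.0, seed=config.seed
        )
        sites = config.site_effects or [SiteEffect() for _ in range(config.n_sites)]
        rows = {}
        for j, site in enumerate(sites):
            meas = measure_phantom_site(spec, site, seed=config.seed + 17 * j + 1,
                                        variant=config.variant)
            meas["volume"] = morpho.pancreas_volume(contours)
            rows[f"site{j + 1}"] = meas
        pivot = pd.DataFrame(rows).T
        pivot.index.name = "site"
        pivot.columns.name = "measure"
        references = {"volume": 89.0, "t1_vial_1": 500.0, "t1_vial_2": 1000.0,
                      "t1_vial_3": 1250.0, "t1_vial_4": 1500.0}

    percent_diffs: dict[str, dict[str, float]] = {}
    for measure, ref in references.items():
        if measure not in pivot.columns:
            warnings.append(f"no measurements for referenced measure {measure!r}")
            continue
        percent_diffs[measure] = {
            str(site): repro.percent_difference(val, ref)
            for site, val in pivot[measure].dropna().items()
        }
    t1_diffs = [d for m, per_site in percent_diffs.items() if m.startswith("t1_vial")
                for d in per_site.values()]
    vol_diffs = list(percent_diffs.get("volume", {}).values())
    cvs: dict[str, float] = {}
    for measure in pivot.columns:
        vals = pivot[measure].dropna()
        if len(vals) >= 2:
            try:
                cvs[measure] = repro.coefficient_of_variation(vals)
            except repro.InsufficientDataError as exc:
                warnings.append(f"{measure}: {exc}")
        else:
            warnings.append(f"{measure}: skipped ({len(vals)} site(s) reported)")

    report = {
        "workflow": "phantom",
        "variant": config.variant,
        "n_sites": int(pivot.shape[0]),
        "percent_difference": percent_diffs,
        "t1_mean_abs_percent_difference": float(np.mean(t1_diffs)) if t1_diffs else None,
        "t1_max_abs_percent_difference": float(np.max(t1_diffs)) if t1_diffs else None,
        "volume_mean_abs_percent_difference": float(np.mean(vol_diffs)) if vol_diffs else None,
        "volume_max_abs_percent_difference": float(np.max(vol_diffs)) if vol_diffs else None,
        "cross_site_cv_percent": cvs,
        "warnings": warnings,
    }
    _emit(report, pivot.reset_index(), config.out_dir, "phantom")
    return report


def run_volunteer_workflow(config: RunConfig) -> dict:
    """Volunteer reproducibility report over a measure table.

    Table-only mode uses ``config.table`` (or the packaged volunteer fixture
    when the path is ``"fixture"``); ``workflow="simulate"`` generates a
    measure-level multisite study instead.  The report contains per-measure
    average CVs, Friedman and pairwise rank-test p-values, variance
    components, and the sample-size grid.
    """
    if config.workflow == "simulate":
        design = StudyDesign(
            n_subjects=5, n_sites=4,
            measure_means={"volume": 85.0, "t1": 950.0, "adc": 1.2e-3},
            subject_sd={"volume": 20.0, "t1": 150.0, "adc": 1.5e-4},
            site_sd={"volume": 5.0, "t1": 50.0, "adc": 0.5e-4},
            seed=config.seed,
        )
        table, _ = simulate_multisite_study(design, config.site_effects)
    elif config.table is None or str(config.table) == "fixture":
        table = repro.load_volunteer_table()
    else:
        table = repro.load_measure_table(config.table)

    warnings: list[str] = []
    measures = sorted(table["measure"].unique())
    # subjects observed at < 2 sites contribute nothing; drop with a warning
    site_counts = (
        table.dropna(subset=["value"]).groupby("subject")["site"].nunique()
    )
    thin = site_counts[site_counts < 2].index.tolist()
    if thin:
        warnings.append(f"subjects excluded (<2 sites): {thin}")
        table = table[~table["subject"].isin(thin)]

    avg_cvs, friedman, pairwise, components = {}, {}, {}, {}
    for measure in measures:
        try:
            avg_cvs[measure] = repro.average_cv(table, measure, warnings)
        except repro.InsufficientDataError as exc:
            warnings.append(str(exc))
        try:
            fr = repro.friedman_across_sites(table, measure)
            friedman[measure] = {
                "statistic": fr.statistic, "p_value": fr.p_value,
                "n_complete_blocks": fr.n_complete_blocks, "n_sites": fr.n_sites,
            }
        except repro.InsufficientDataError as exc:
            warnings.append(str(exc))
        pw = repro.pairwise_rank_tests(table, measure)
        pairwise[measure] = pw.to_dict(orient="records")
        try:
            vc = repro.variance_components(table, measure)
            components[measure] = {
                "grand_mean": vc.grand_mean,
                "inter_individual_sd": vc.inter_individual_sd,
                "inter_assay_sd": vc.inter_assay_sd,
                "n_subjects": vc.n_subjects,
            }
        except repro.InsufficientDataError as exc:
            warnings.append(str(exc))

    sizes = power_table(table)
    report = {
        "workflow": "volunteer",
        "variant": config.variant,
        "n_subjects": int(table["subject"].nunique()),
        "n_sites": int(table["site"].nunique()),
        "average_cv_percent": avg_cvs,
        "friedman": friedman,
        "pairwise_rank_tests": pairwise,
        "variance_components": components,
        "sample_sizes": sizes.to_dict(orient="records"),
        "warnings": warnings,
    }
    _emit(report, table, config.out_dir, "volunteer", extra_csvs={"power_table": sizes})
    return report


def _emit(report: dict, table: pd.DataFrame, out_dir, stem: str,
          extra_csvs: dict[str, pd.DataFrame] | None = None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{stem}_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    table.to_csv(out / f"{stem}_table.csv", index=False)
    for name, df in (extra_csvs or {}).items():
        df.to_csv(out / f"{stem}_{name}.csv", index=False)
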