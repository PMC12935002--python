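"""End-to-end orchestration of the two study designs.

``run_timelapse_study`` ties the modules into the imaging experiment:
simulate a multichannel timelapse -> segment cells from brightfield ->
curate -> segment puncta from GFP -> quantify background-subtracted
R395/470 per object -> aggregate per compartment and condition ->
bimodality / hysteresis decisions and group comparisons.

``run_bulk_study`` mirrors the spectrofluorometer experiment: generate
replicate excitation spectra per strain/condition/treatment, compute bulk
ratios against WT blanks, and compare groups.

Both are deterministic given the config seed, embed a config hash in every
summary, and log a QC funnel (objects segmented, removed, undefined
ratios) so filtering is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import bulk as bulk_mod
from .optics import OpticalModel, SpectralEndmembers, default_optical_model
from .population import (
    aggregate_timeseries,
    assess_hysteresis,
    compare_groups,
    detect_bimodality,
)
from .ratiometrics import BackgroundScope, add_ratios, estimate_background, measure_objects
from .segmentation import (
    CurationRules,
    LabelMap,
    SegmentationParams,
    curate_cells,
    segment_cells,
    segment_puncta,
)
from .synthetic.scene import (
    Compartment,
    Condition,
    SceneResult,
    SceneSpec,
    StrainSpec,
    generate_scene,
)
from .synthetic.spectra import generate_spectrum

logger = logging.getLogger(__name__)


class StudyConfig(BaseModel):
    """Timelapse study configuration (scene + analysis settings)."""

    model_config = ConfigDict(frozen=True)

    scene: SceneSpec
    optics: OpticalModel
    segmentation: SegmentationParams = SegmentationParams()
    curation: CurationRules = CurationRules()
    background_scope: BackgroundScope = BackgroundScope.global_
    burn_in_hours: float = 3.0
    settle_hours: float = 3.0  # discarded after each condition switch
    size_filter_compartments: tuple[str, ...] = ("procarboxysome",)
    bimodality_min_n: int = 50
    bimodality_delta_bic: float = 10.0
    bimodality_min_d: float = 2.0
    # "terminal_frame": one value per object (the last frame of each
    # condition window) so the mixture model sees independent objects;
    # "pooled" repeats every object once per frame in the window.
    bimodality_sample: str = "terminal_frame"
    histogram_bins: int = 30
    histogram_range: tuple[float, float] = (0.0, 3.5)
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def default_study_strains(n_cells: int = 100) -> list[StrainSpec]:
    """The default synthetic population.

    Absolute oxidation fractions are a modeling choice (only orderings and
    shifts are constrained by the biology): carboxysomes are the most
    oxidized compartment, the cytosol and procarboxysomes sit lower and
    close together, everything reduces under 3% CO2, and a 40% subpopulation
    of carboxysomes drops to a procarboxysome-like reduced mode there.
    """
    return [
        StrainSpec(
            name="WT", compartment=Compartment.wt, n_cells=n_cells, division_rate=0.03
        ),
        StrainSpec(
            name="cytosol-Grx1-roGFP2",
            compartment=Compartment.cytosol,
            n_cells=n_cells,
            oxd_air=0.35,
            oxd_high=0.20,
            oxd_sd=0.04,
            division_rate=0.03,
        ),
        StrainSpec(
            name="RbcL-Grx1-roGFP2",
            compartment=Compartment.carboxysome,
            n_cells=n_cells,
            oxd_air=0.80,
            oxd_high=0.60,
            oxd_sd=0.04,
            bimodal_fraction_high=0.40,
            oxd_high_alt=0.25,
            puncta_per_cell=2,
            puncta_area_px=75,
            division_rate=0.03,
        ),
        StrainSpec(
            name="dCcmO-RbcL-Grx1-roGFP2",
            compartment=Compartment.procarboxysome,
            n_cells=n_cells,
            oxd_air=0.40,
            oxd_high=0.25,
            oxd_sd=0.04,
            puncta_per_cell=1,
            puncta_area_px=140,
            division_rate=0.0,  # HCR mutant does not grow in air
        ),
    ]


def default_study_config(
    seed: int = 0,
    n_cells: int = 100,
    n_frames: int = 30,
    image_shape: tuple[int, int] = (1024, 1024),
    shift_frame: int = 15,
    **scene_overrides,
) -> StudyConfig:
    """Air -> 3% CO2 modulation study at the default population sizes."""
    scene = SceneSpec(
        image_shape=image_shape,
        n_frames=n_frames,
        strains=default_study_strains(n_cells),
        co2_schedule=[(0, Condition.air), (shift_frame, Condition.high)],
        rng_seed=seed,
        **scene_overrides,
    )
    return StudyConfig(scene=scene, optics=default_optical_model(), seed=seed)


@dataclass
class QCFunnel:
    cells_segmented: int = 0
    cells_removed_curation: int = 0
    cells_unmatched_strain: int = 0
    puncta_found: int = 0
    puncta_removed_small: int = 0
    ratios_undefined: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TimelapseReport:
    config: StudyConfig
    scene: SceneResult
    measurements: pd.DataFrame
    series: pd.DataFrame
    comparisons: pd.DataFrame
    bimodality: dict[tuple[str, str], object]
    hysteresis: Optional[object]
    qc: QCFunnel
    summary: dict


def _strain_lookup(truth: pd.DataFrame) -> dict[int, tuple[str, str]]:
    """oracle cell label -> (strain, compartment), per frame handled upstream."""
    sub = truth[truth.kind == "cell"]
    return {
        int(r.object_id): (r.strain, r.compartment)
        for r in sub.itertuples()
    }


def _match_strains(
    seg: LabelMap, oracle: np.ndarray, lookup: dict[int, tuple[str, str]]
) -> dict[int, tuple[str, str]]:
    """Assign each segmented cell the strain of the oracle cell it mostly
    overlaps (simulation-mode replacement for visual strain identification)."""
    out: dict[int, tuple[str, str]] = {}
    labels = seg.labels
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        ids, counts = np.unique(oracle[mask], return_counts=True)
        order = np.argsort(counts)[::-1]
        for idx in order:
            oid = int(ids[idx])
            if oid != 0 and oid in lookup:
                out[int(lab)] = lookup[oid]
                break
    return out


def _analysis_windows(
    spec: SceneSpec, burn_in_hours: float, settle_hours: float
) -> list[tuple[str, int, int]]:
    """(condition, frame_lo, frame_hi) windows after burn-in and settling."""
    settle = int(np.ceil(settle_hours * 60.0 / spec.frame_interval_min))
    burn_in = int(np.ceil(burn_in_hours * 60.0 / spec.frame_interval_min))
    sched = list(spec.co2_schedule) + [(spec.n_frames, None)]
    out = []
    for (start, cond), (end, _) in zip(sched, sched[1:]):
        lo = max(start + (settle if start > 0 else 0), burn_in)
        if lo < end:
            out.append((cond.value, lo, end))
    return out


def run_timelapse_study(config: StudyConfig, out_dir: str | Path | None = None) -> TimelapseReport:
    """Execute the full simulate -> segment -> quantify -> aggregate chain.

    Deterministic at the table level for a fixed config (the config hash and
    seed are embedded in the summary).
    """
    qc = QCFunnel()
    scene = generate_scene(config.scene, config.optics)
    truth = scene.truth
    n_frames = config.scene.n_frames
    conditions = config.scene.condition_per_frame()

    # --- segmentation + curation ---------------------------------------
    cell_maps = [
        segment_cells(scene.stack.channel("brightfield", f), config.segmentation, f)
        for f in range(n_frames)
    ]
    qc.cells_segmented = sum(m.n_objects for m in cell_maps)
    chl = [scene.stack.channel("chlorophyll", f) for f in range(n_frames)]
    cell_maps, cur_log = curate_cells(cell_maps, chl, config.curation)
    qc.cells_removed_curation = len(cur_log.removed)

    # --- strain identity from ground truth (simulation mode) -----------
    frame_meas: list[pd.DataFrame] = []
    for f in range(n_frames):
        lookup = _strain_lookup(truth[truth.frame == f])
        strains = _match_strains(cell_maps[f], scene.cell_labels[f], lookup)
        ch395 = scene.stack.channel("ex395", f)
        ch470 = scene.stack.channel("ex470", f)

        cells_df = measure_objects(ch395, ch470, cell_maps[f])
        cells_df["kind"] = "cell"
        cells_df["strain"] = cells_df.object_id.map(lambda i: strains.get(i, ("", ""))[0])
        cells_df["compartment"] = cells_df.object_id.map(lambda i: strains.get(i, ("", ""))[1])
        qc.cells_unmatched_strain += int((cells_df.strain == "").sum())
        cells_df = cells_df[cells_df.strain != ""]

        # puncta only inside cells of puncta-bearing strains
        puncta_compartments = {"carboxysome", "procarboxysome"}
        keep = {
            lab for lab, (_, comp) in strains.items() if comp in puncta_compartments
        }
        host = cell_maps[f].labels * np.isin(cell_maps[f].labels, list(keep))
        host_map = LabelMap(host.astype(np.int32), "cell", f)
        puncta_rows = []
        if keep:
            for comp in puncta_compartments:
                comp_labels = [
                    lab for lab, (_, c) in strains.items() if c == comp
                ]
                if not comp_labels:
                    continue
                sub = host_map.labels * np.isin(host_map.labels, comp_labels)
                pres = segment_puncta(
                    ch470 + ch395,
                    LabelMap(sub.astype(np.int32), "cell", f),
                    config.segmentation,
                    size_filter=comp in config.size_filter_compartments,
                )
                qc.puncta_found += pres.labels.n_objects
                qc.puncta_removed_small += pres.n_removed_small
                pdf = measure_objects(ch395, ch470, pres.labels)
                if pdf.empty:
                    continue
                pdf["kind"] = "punctum"
                pdf["compartment"] = comp
                pdf["strain"] = pdf.object_id.map(
                    lambda i: strains.get(pres.parent_cell.get(int(i), -1), ("", ""))[0]
                )
                # puncta ids are per-frame/per-class; make them unique-ish
                pdf["object_id"] = pdf["object_id"] + 10_000 * (f + 1)
                puncta_rows.append(pdf)
        parts = [cells_df] + puncta_rows
        fdf = pd.concat(parts, ignore_index=True)
        fdf["condition"] = conditions[f].value
        fdf["time_min"] = f * config.scene.frame_interval_min
        frame_meas.append(fdf)

    meas = pd.concat(frame_meas, ignore_index=True)

    # --- background from WT cells, ratios ------------------------------
    wt = meas[(meas.compartment == "wt") & (meas.kind == "cell")]
    bg = estimate_background(wt, config.background_scope)
    # probe measurements: cytosol cells + puncta of the puncta strains
    probe = meas[
        ((meas.compartment == "cytosol") & (meas.kind == "cell"))
        | (meas.kind == "punctum")
    ].copy()
    probe = add_ratios(probe, bg)
    qc.ratios_undefined = int(probe.ratio.isna().sum())

    # --- aggregation -----------------------------------------------------
    series = aggregate_timeseries(
        probe, grouping=("compartment",), burn_in_hours=config.burn_in_hours
    )

    windows = _analysis_windows(config.scene, config.burn_in_hours, config.settle_hours)

    def _pool(compartment: str, condition: str) -> np.ndarray:
        vals = []
        for cond, lo, hi in windows:
            if cond != condition:
                continue
            sel = probe[
                (probe.compartment == compartment)
                & (probe.frame >= lo)
                & (probe.frame < hi)
                & probe.ratio.notna()
            ]
            vals.append(sel.ratio.to_numpy())
        return np.concatenate(vals) if vals else np.array([])

    compartments = sorted(set(probe.compartment) - {""})
    conds = sorted({c for c, _, _ in windows})

    comp_rows = []
    # air vs high within each compartment
    for comp in compartments:
        pools = {c: _pool(comp, c) for c in conds}
        if all(len(v) >= 2 for v in pools.values()) and len(conds) == 2:
            res = compare_groups(pools["air"], pools["high"])
            comp_rows.append(
                dict(
                    comparison="air_vs_high",
                    compartment=comp,
                    mean_a=float(pools["air"].mean()),
                    mean_b=float(pools["high"].mean()),
                    t=res.t_statistic,
                    p_value=res.p_value,
                    stars=res.stars,
                    n_a=res.n_a,
                    n_b=res.n_b,
                )
            )
    # carboxysome vs cytosol within each condition
    for cond in conds:
        a, b = _pool("carboxysome", cond), _pool("cytosol", cond)
        if len(a) >= 2 and len(b) >= 2:
            res = compare_groups(a, b)
            comp_rows.append(
                dict(
                    comparison="carboxysome_vs_cytosol",
                    compartment=cond,
                    mean_a=float(a.mean()),
                    mean_b=float(b.mean()),
                    t=res.t_statistic,
                    p_value=res.p_value,
                    stars=res.stars,
                    n_a=res.n_a,
                    n_b=res.n_b,
                )
            )
    comparisons = pd.DataFrame(comp_rows)

    def _terminal_sample(compartment: str, condition: str) -> np.ndarray:
        vals = []
        for cond, lo, hi in windows:
            if cond != condition:
                continue
            sel = probe[
                (probe.compartment == compartment)
                & (probe.frame == hi - 1)
                & probe.ratio.notna()
            ]
            vals.append(sel.ratio.to_numpy())
        return np.concatenate(vals) if vals else np.array([])

    # --- bimodality per compartment x condition -------------------------
    bimodality = {}
    for comp in compartments:
        for cond in conds:
            if config.bimodality_sample == "terminal_frame":
                sample = _terminal_sample(comp, cond)
            else:
                sample = _pool(comp, cond)
            bimodality[(comp, cond)] = detect_bimodality(
                sample,
                min_n=config.bimodality_min_n,
                delta_bic_threshold=config.bimodality_delta_bic,
                min_separation_d=config.bimodality_min_d,
                seed=config.seed,
            )

    # --- hysteresis when the schedule returns to air --------------------
    hysteresis = None
    sched = config.scene.co2_schedule
    if len(sched) >= 3 and sched[-1][1] is Condition.air:
        shift_frame = sched[1][0]
        return_frame = sched[-1][0]
        carb = series[(series.compartment == "carboxysome") & (~series.burn_in)]
        window = max(2, min(shift_frame - int(np.ceil(
            config.burn_in_hours * 60 / config.scene.frame_interval_min)),
            config.scene.n_frames - return_frame - 1))
        try:
            hysteresis = assess_hysteresis(carb, shift_frame, window, return_frame)
        except ValueError as err:
            logger.warning("hysteresis not assessable: %s", err)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "qc": qc.as_dict(),
        "n_measurements": int(len(probe)),
        "mean_ratio_by_compartment_condition": {
            f"{comp}/{cond}": float(np.mean(_pool(comp, cond)))
            for comp in compartments
            for cond in conds
            if len(_pool(comp, cond)) > 0
        },
        "bimodality_components": {
            f"{comp}/{cond}": res.n_components for (comp, cond), res in bimodality.items()
        },
        "comparisons": comparisons.to_dict(orient="records"),
        "hysteresis": (
            None
            if hysteresis is None
            else {
                "pre_mean": hysteresis.pre_mean,
                "post_mean": hysteresis.post_mean,
                "difference": hysteresis.difference,
                "p_value": hysteresis.p_value,
            }
        ),
    }

    report = TimelapseReport(
        config, scene, probe, series, comparisons, bimodality, hysteresis, qc, summary
    )
    if out_dir is not None:
        _write_timelapse(report, Path(out_dir))
    return report


def _write_timelapse(report: TimelapseReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.measurements.to_csv(out / "measurements.csv", index=False)
    report.series.to_csv(out / "series.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.summary, indent=2))
    (out / "config.json").write_text(report.config.model_dump_json(indent=2))
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for comp, g in report.series.groupby("compartment"):
            ax.errorbar(g.time_min / 60.0, g.mean_ratio, yerr=g["sem"], label=comp, capsize=2)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("R395/470")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "timeseries.png", dpi=120)
        plt.close(fig)
    except Exception as err:  # figures are conveniences, not acceptance surfaces
        logger.warning("figure rendering failed: %s", err)


# --------------------------------------------------------------------------
# bulk study
# --------------------------------------------------------------------------


class BulkStrainSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    compartment: str
    oxd_air: float = Field(ge=0, le=1)
    oxd_high: float = Field(ge=0, le=1)
    oxd_dtt: float = Field(default=0.05, ge=0, le=1)
    oxd_h2o2: float = Field(default=0.90, ge=0, le=1)
    treatment_condition: str = "air"


class BulkStudyConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    strains: list[BulkStrainSpec]
    n_replicates: int = 4
    noise_sd: float = 4.0
    amplitude: float = 1000.0
    blank_level: float = 5.0
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def default_bulk_config(seed: int = 0) -> BulkStudyConfig:
    """Bulk comparison mirroring the redox-agent panel and the air vs 3% CO2
    comparison: the cytosol responds to both agents, carboxysomes do not
    respond to H2O2 (already fully oxidized / shielded), procarboxysomes
    respond to neither from their pre-reduced state."""
    return BulkStudyConfig(
        strains=[
            BulkStrainSpec(
                name="cytosol-Grx1-roGFP2", compartment="cytosol",
                oxd_air=0.35, oxd_high=0.20, oxd_dtt=0.05, oxd_h2o2=0.90,
            ),
            BulkStrainSpec(
                name="RbcL-Grx1-roGFP2", compartment="carboxysome",
                oxd_air=0.80, oxd_high=0.60, oxd_dtt=0.45, oxd_h2o2=0.80,
            ),
            BulkStrainSpec(
                name="dCcmO-RbcL-Grx1-roGFP2", compartment="procarboxysome",
                oxd_air=0.40, oxd_high=0.25, oxd_dtt=0.25, oxd_h2o2=0.25,
                treatment_condition="high",
            ),
        ],
        seed=seed,
    )


@dataclass
class BulkReport:
    config: BulkStudyConfig
    condition_table: pd.DataFrame
    treatment_tables: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    summary: dict


def run_bulk_study(config: BulkStudyConfig, out_dir: str | Path | None = None) -> BulkReport:
    """Generate spectra and compute the bulk-ratio comparison tables."""
    em = SpectralEndmembers()
    seed = config.seed
    ratios: dict[tuple[str, str], bulk_mod.BulkRatioResult] = {}
    cond_rows = []
    for si, strain in enumerate(config.strains):
        for ci, cond in enumerate(("air", "high")):
            oxd = strain.oxd_air if cond == "air" else strain.oxd_high
            traces, blanks = generate_spectrum(
                oxd, em, config.amplitude, config.blank_level,
                config.n_replicates, config.noise_sd,
                seed=seed + 101 * si + 13 * ci,
                strain=strain.name, condition=cond,
            )
            res = bulk_mod.bulk_ratio(traces, blanks)
            ratios[(strain.name, cond)] = res
            cond_rows.append(
                dict(
                    strain=strain.name, compartment=strain.compartment, condition=cond,
                    mean_ratio=res.mean_ratio, sd_ratio=res.sd_ratio, n=res.n_used,
                )
            )
    condition_table = pd.DataFrame(cond_rows)

    comp_rows = []
    for strain in config.strains:
        a = ratios[(strain.name, "air")].per_replicate
        b = ratios[(strain.name, "high")].per_replicate
        if len(a) >= 2 and len(b) >= 2:
            res = compare_groups(a, b)
            comp_rows.append(
                dict(comparison="air_vs_high", key=strain.compartment,
                     mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                     t=res.t_statistic, p_value=res.p_value, stars=res.stars)
            )
        else:
            comp_rows.append(
                dict(comparison="air_vs_high", key=strain.compartment,
                     mean_a=np.nan, mean_b=np.nan, t=np.nan, p_value=np.nan,
                     stars="insufficient-n")
            )
    by_comp = {s.compartment: s.name for s in config.strains}
    for cond in ("air", "high"):
        if "carboxysome" in by_comp and "cytosol" in by_comp:
            a = ratios[(by_comp["carboxysome"], cond)].per_replicate
            b = ratios[(by_comp["cytosol"], cond)].per_replicate
            if len(a) >= 2 and len(b) >= 2:
                res = compare_groups(a, b)
                comp_rows.append(
                    dict(comparison="carboxysome_vs_cytosol", key=cond,
                         mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                         t=res.t_statistic, p_value=res.p_value, stars=res.stars)
                )
    comparisons = pd.DataFrame(comp_rows)

    treatment_tables: dict[str, pd.DataFrame] = {}
    for si, strain in enumerate(config.strains):
        cond = strain.treatment_condition
        base_oxd = strain.oxd_air if cond == "air" else strain.oxd_high
        groups, blanks_all = {}, []
        for ti, (treat, oxd) in enumerate(
            (("none", base_oxd), ("DTT", strain.oxd_dtt), ("H2O2", strain.oxd_h2o2))
        ):
            traces, blanks = generate_spectrum(
                oxd, em, config.amplitude, config.blank_level,
                config.n_replicates, config.noise_sd,
                seed=seed + 1009 * si + 31 * ti + 7,
                strain=strain.name, treatment=treat, condition=cond,
            )
            groups[treat] = traces
            blanks_all.extend(blanks)
        treatment_tables[strain.name] = bulk_mod.treatment_response(groups, blanks_all)

    summary = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "mean_ratio": {
            f"{s}/{c}": r.mean_ratio for (s, c), r in ratios.items()
        },
        "comparisons": comparisons.to_dict(orient="records"),
        "treatments": {k: v.to_dict(orient="records") for k, v in treatment_tables.items()},
    }
    report = BulkReport(config, condition_table, treatment_tables, comparisons, summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        condition_table.to_csv(out / "bulk_ratios.csv", index=False)
        comparisons.to_csv(out / "bulk_comparisons.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report
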