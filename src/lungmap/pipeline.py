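"""End-to-end cohort pipeline: phantom simulation -> per-subject image
analysis -> cohort summary -> statistics report.

A run is fully specified by a :class:`PipelineConfig` plus a master seed;
per-subject seeds are split from the master seed by row index, so results
are bit-identical across reruns and invariant to execution order.  A
failing subject is recorded and skipped rather than aborting the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import asl as asl_mod
from . import cohort as cohort_mod
from . import density as density_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import phantom as phantom_mod
from . import stats as stats_mod
from . import svmap as svmap_mod

__all__ = [
    "PhantomConfig",
    "AnalysisConfig",
    "StatsConfig",
    "PipelineConfig",
    "SubjectAnalysis",
    "PipelineResult",
    "analyze_subject",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("lungmap")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    shape: int = 64                 # grid side; acquisitions are shape x shape
    snr: float = 40.0
    enhancement: float = 0.12
    n_vessels: int = 3
    vessel_boost: float = 5.0
    density_mean: float = 0.25


class AnalysisConfig(_Strict):
    sv_grid_min: float = 0.01
    sv_grid_max: float = 10.0
    sv_grid_n: int = 50
    min_corr: float = 0.5
    vessel_threshold: float = 0.35
    coil_smoothing: float = 5.0
    register_frames: bool = False   # phantom frames are emitted aligned


class StatsConfig(_Strict):
    alpha: float = 0.05
    nicotine_split: float = 20.0    # mg/mL
    bmi_split: float = 25.0         # kg/m^2


_COHORT_DEFAULTS = cohort_mod.CohortParams()


class CohortConfig(_Strict):
    """Serialisable mirror of :class:`lungmap.cohort.CohortParams`."""

    n_controls: int = _COHORT_DEFAULTS.n_controls
    n_vapers: int = _COHORT_DEFAULTS.n_vapers
    sv_mean_control: float = _COHORT_DEFAULTS.sv_mean_control
    sv_sd_control: float = _COHORT_DEFAULTS.sv_sd_control
    sv_mean_vaper: float = _COHORT_DEFAULTS.sv_mean_vaper
    sv_sd_vaper: float = _COHORT_DEFAULTS.sv_sd_vaper
    sv_post_shift: float = _COHORT_DEFAULTS.sv_post_shift
    sv_post_noise_sd: float = _COHORT_DEFAULTS.sv_post_noise_sd
    sv_rd_mean: float = _COHORT_DEFAULTS.sv_rd_mean
    sv_rd_sd: float = _COHORT_DEFAULTS.sv_rd_sd
    q_mean_control: float = _COHORT_DEFAULTS.q_mean_control
    q_sd_control: float = _COHORT_DEFAULTS.q_sd_control
    q_mean_vaper: float = _COHORT_DEFAULTS.q_mean_vaper
    q_sd_vaper: float = _COHORT_DEFAULTS.q_sd_vaper
    q_rd_mean: float = _COHORT_DEFAULTS.q_rd_mean
    q_rd_sd: float = _COHORT_DEFAULTS.q_rd_sd
    bmi_dq_slope: float = _COHORT_DEFAULTS.bmi_dq_slope
    dq_noise_sd: float = _COHORT_DEFAULTS.dq_noise_sd
    hr_mean: float = _COHORT_DEFAULTS.hr_mean
    hr_sd: float = _COHORT_DEFAULTS.hr_sd
    hr_post_increase: float = _COHORT_DEFAULTS.hr_post_increase
    hr_post_noise_sd: float = _COHORT_DEFAULTS.hr_post_noise_sd
    bmi_mean: float = _COHORT_DEFAULTS.bmi_mean
    bmi_sd: float = _COHORT_DEFAULTS.bmi_sd
    age_mean: float = _COHORT_DEFAULTS.age_mean
    age_sd: float = _COHORT_DEFAULTS.age_sd
    frc_mean: float = _COHORT_DEFAULTS.frc_mean
    frc_sd: float = _COHORT_DEFAULTS.frc_sd
    vt_mean_vaper: float = _COHORT_DEFAULTS.vt_mean_vaper
    vt_sd_vaper: float = _COHORT_DEFAULTS.vt_sd_vaper
    vt_mean_control: float = _COHORT_DEFAULTS.vt_mean_control
    vt_sd_control: float = _COHORT_DEFAULTS.vt_sd_control

    def to_params(self) -> cohort_mod.CohortParams:
        return cohort_mod.CohortParams(**self.model_dump())


class PipelineConfig(_Strict):
    seed: int = 0
    cohort: CohortConfig = CohortConfig()
    phantom: PhantomConfig = PhantomConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    stats: StatsConfig = StatsConfig()
    write_images: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys raise a validation error
    naming the offending key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as err:
        raise ValueError(f"invalid pipeline config {path}: {err}") from err


@dataclass
class SubjectAnalysis:
    """All per-subject-timepoint outputs of the analysis stage."""

    summary: dict
    sv_map: svmap_mod.SVMap
    q_map: asl_mod.QMap
    density_map: density_mod.DensityMap
    coil_field: density_mod.CoilField
    lci: metrics_mod.LCIResult
    qc: dict = field(default_factory=dict)


def analyze_subject(
    bundle: phantom_mod.AcquisitionBundle,
    lung_mask: np.ndarray,
    phantom_roi: np.ndarray,
    voxel_volume: float,
    heart_rate: float,
    frc: float,
    tidal_volume: float | None,
    config: AnalysisConfig | None = None,
    phantom_known_density: float = 1.0,
) -> SubjectAnalysis:
    """Run the full per-subject analysis chain on one acquisition bundle.

    The lung mask and reference-phantom ROI play the role of the manual
    segmentations available with real acquisitions; no ground-truth
    functional map is consulted.
    """
    cfg = config or AnalysisConfig()
    support = lung_mask | phantom_roi

    # density + coil sensitivity from the dual-echo pairs
    s0_body, t2_body = density_mod.extrapolate_s0(
        bundle.echo1_body, bundle.echo2_body, bundle.te1, bundle.te2
    )
    s0_torso, _ = density_mod.extrapolate_s0(
        bundle.echo1_torso, bundle.echo2_torso, bundle.te1, bundle.te2
    )
    coil = density_mod.estimate_coil_field(
        s0_torso, s0_body, support, smoothing_scale=cfg.coil_smoothing
    )
    density_map = density_mod.calibrate_density(
        s0_body, t2_body, phantom_roi, phantom_known_density
    )

    # perfusion from the ASL pair
    sub = asl_mod.subtract_pair(bundle.asl_selective, bundle.asl_nonselective)
    qmap = asl_mod.correct_and_calibrate(
        sub, coil, phantom_roi, bundle.asl_nonselective,
        voxel_volume, heart_rate, lung_mask, phantom_known_density,
    )
    qmap = asl_mod.filter_vessels(qmap, cfg.vessel_threshold)
    q_stats = asl_mod.q_summary(qmap)

    # specific ventilation from the O2-enhanced series
    series = bundle.sv_series
    shifts = None
    if cfg.register_frames:
        series, shifts, _ = svmap_mod.register_series(series)
    grid = np.geomspace(cfg.sv_grid_min, cfg.sv_grid_max, cfg.sv_grid_n)
    sv_map = svmap_mod.estimate_sv_map(
        series, bundle.schedule, lung_mask, grid=grid, min_corr=cfg.min_corr
    )
    sv_stats = svmap_mod.sv_summary(sv_map)

    # image-based LCI from the SV histogram; the headline value uses the
    # volume-weighted mean-SV turnover (aggregate dV/V0 per breath), which
    # keeps the index driven by the SV distribution itself; the VT/FRC
    # conversion is reported alongside when tidal volume is available
    bins, weights = metrics_mod.sv_histogram(sv_map)
    lci = metrics_mod.image_lci(bins, weights, frc=frc, tidal_volume=None)
    lci_vt = (
        metrics_mod.image_lci(bins, weights, frc=frc, tidal_volume=tidal_volume)
        if tidal_volume is not None and tidal_volume > 0
        else None
    )

    lung_density = float(np.nanmean(density_map.density[lung_mask]))
    summary = {
        "mean_sv": sv_stats["mean_sv"],
        "rd_sv": sv_stats["rd_sv"],
        "lci": lci.lci,
        "lci_vt": np.nan if lci_vt is None else lci_vt.lci,
        "mean_q": q_stats["mean_q"],
        "rd_q": q_stats["rd_q"],
        "mean_density": lung_density,
        "n_vessel_removed": q_stats["n_vessel_removed"],
        "heart_rate": heart_rate,
    }
    qc = {
        "sv": sv_map.qc,
        "asl": qmap.qc,
        "registration_shifts": None if shifts is None else shifts.tolist(),
        "lci_turnover_source": lci.turnover_source,
    }
    return SubjectAnalysis(
        summary=summary, sv_map=sv_map, q_map=qmap,
        density_map=density_map, coil_field=coil, lci=lci, qc=qc,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort_truth: pd.DataFrame
    summary: pd.DataFrame
    report: pd.DataFrame
    correlations: pd.DataFrame
    qc: dict
    errors: list
    out_dir: Path | None = None


def _subject_seed(master_seed: int, row_index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(row_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _phantom_for_row(row: pd.Series, cfg: PipelineConfig, seed: int):
    return phantom_mod.make_phantom(
        shape=(cfg.phantom.shape, cfg.phantom.shape),
        sv_mean=row["mean_sv_true"],
        sv_rd=row["rd_sv_true"],
        q_mean=row["mean_q_true"],
        q_rd=row["rd_q_true"],
        density_mean=cfg.phantom.density_mean,
        n_vessels=cfg.phantom.n_vessels,
        vessel_boost=cfg.phantom.vessel_boost,
        heart_rate=row["heart_rate"],
        frc=row["frc"],
        tidal_volume=row["tidal_volume"],
        seed=seed,
    )


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> PipelineResult:
    """Simulate a synthetic cohort, analyse every subject-timepoint, and
    compute the cohort statistics report.

    Returns the in-memory result; with ``out_dir`` also writes the cohort
    truth, per-subject summary, statistics report, QC JSON, the resolved
    config, and a plain-text log (plus NIfTI maps when
    ``config.write_images`` is set).
    """
    cfg = config or PipelineConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    handler = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_path / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        return _run(cfg, out_path)
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()


def _run(cfg: PipelineConfig, out_path: Path | None) -> PipelineResult:
    log.info("pipeline start: config hash %s, seed %d", cfg.config_hash(), cfg.seed)
    truth = cohort_mod.sample_cohort_truth(cfg.cohort.to_params(), seed=cfg.seed)
    schedule = phantom_mod.default_schedule()

    rows, errors = [], []
    for idx, row in truth.iterrows():
        seed = _subject_seed(cfg.seed, int(idx))
        label = f"{row['subject']}/{row['timepoint']}"
        try:
            ph = _phantom_for_row(row, cfg, seed)
            bundle = phantom_mod.simulate_acquisitions(
                ph, schedule, enhancement=cfg.phantom.enhancement,
                snr=cfg.phantom.snr, seed=seed,
            )
            result = analyze_subject(
                bundle, ph.lung_mask, ph.phantom_roi, ph.voxel_volume,
                row["heart_rate"], row["frc"], row["tidal_volume"],
                cfg.analysis, ph.phantom_density,
            )
            out_row = {
                "subject": row["subject"],
                "group": row["group"],
                "timepoint": row["timepoint"],
                "sex": row["sex"],
                "age": row["age"],
                "bmi": row["bmi"],
                "nicotine": row["nicotine"],
                "nicotine_type": row["nicotine_type"],
                "pack_years": row["pack_years"],
                "frc": row["frc"],
                "tidal_volume": row["tidal_volume"],
            }
            out_row.update(result.summary)
            rows.append(out_row)
            log.info("analysed %s: mean SV %.3f, mean Q %.2f, LCI %.2f",
                     label, result.summary["mean_sv"],
                     result.summary["mean_q"], result.summary["lci"])
            if out_path is not None and cfg.write_images:
                sub_dir = out_path / "subjects" / f"{row['subject']}_{row['timepoint']}"
                io_mod.save_nifti(result.sv_map.sv, sub_dir / "sv_map.nii")
                io_mod.save_nifti(result.sv_map.correlation, sub_dir / "sv_correlation.nii")
                io_mod.save_nifti(result.q_map.q, sub_dir / "q_map.nii")
                io_mod.save_nifti(result.q_map.vessel_removed_mask.astype(float),
                                  sub_dir / "vessel_removed.nii")
                io_mod.save_nifti(result.density_map.density, sub_dir / "density.nii")
                io_mod.save_nifti(result.coil_field.sensitivity, sub_dir / "coil_field.nii")
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            errors.append({"subject": row["subject"], "timepoint": row["timepoint"],
                           "error": str(exc)})
            log.error("subject %s failed: %s", label, exc)

    summary = pd.DataFrame(rows)
    if summary.empty:
        raise RuntimeError("every subject failed; see error records")

    report, correlations = stats_report(summary)

    qc = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_analysed": len(rows),
        "n_failed": len(errors),
        "errors": errors,
    }
    result = PipelineResult(cfg, truth, summary, report, correlations, qc, errors,
                            out_dir=out_path)
    if out_path is not None:
        truth.to_csv(out_path / "cohort_truth.csv", index=False)
        summary.to_csv(out_path / "summary.csv", index=False)
        report.to_csv(out_path / "report.csv", index=False)
        correlations.to_csv(out_path / "correlations.csv", index=False)
        (out_path / "qc.json").write_text(json.dumps(qc, indent=2))
        (out_path / "config.yaml").write_text(
            yaml.safe_dump(cfg.model_dump(), sort_keys=True)
        )
        log.info("wrote outputs to %s", out_path)
    return result


def simulate_to_dir(config: PipelineConfig, out_dir) -> Path:
    """Generate the synthetic cohort and write every acquisition to disk:
    per-subject NIfTI volumes plus the cohort-truth CSV.  The directory can
    then be analysed with :func:`analyze_dir` (or the CLI ``analyze``)."""
    cfg = config or PipelineConfig()
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    truth = cohort_mod.sample_cohort_truth(cfg.cohort.to_params(), seed=cfg.seed)
    schedule = phantom_mod.default_schedule()
    for idx, row in truth.iterrows():
        seed = _subject_seed(cfg.seed, int(idx))
        ph = _phantom_for_row(row, cfg, seed)
        bundle = phantom_mod.simulate_acquisitions(
            ph, schedule, enhancement=cfg.phantom.enhancement,
            snr=cfg.phantom.snr, seed=seed,
        )
        sub_dir = out_path / "subjects" / f"{row['subject']}_{row['timepoint']}"
        io_mod.save_nifti(bundle.sv_series, sub_dir / "sv_series.nii")
        io_mod.save_nifti(bundle.asl_selective, sub_dir / "asl_selective.nii")
        io_mod.save_nifti(bundle.asl_nonselective, sub_dir / "asl_nonselective.nii")
        for name in ("echo1_body", "echo2_body", "echo1_torso", "echo2_torso"):
            io_mod.save_nifti(getattr(bundle, name), sub_dir / f"{name}.nii")
        io_mod.save_nifti(ph.lung_mask.astype(float), sub_dir / "lung_mask.nii")
        io_mod.save_nifti(ph.phantom_roi.astype(float), sub_dir / "phantom_roi.nii")
        scalars = {
            "te1": bundle.te1, "te2": bundle.te2, "ti": bundle.ti,
            "voxel_volume": ph.voxel_volume,
            "phantom_density": ph.phantom_density,
            "heart_rate": row["heart_rate"], "frc": row["frc"],
            "tidal_volume": row["tidal_volume"],
        }
        (sub_dir / "scalars.json").write_text(json.dumps(scalars, indent=2))
    truth.to_csv(out_path / "cohort_truth.csv", index=False)
    (out_path / "config.yaml").write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return out_path


def analyze_dir(in_dir, out_dir=None, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Analyse a directory written by :func:`simulate_to_dir` and return
    (and optionally write) the per-subject summary table."""
    in_path = Path(in_dir)
    truth = pd.read_csv(in_path / "cohort_truth.csv")
    schedule = phantom_mod.default_schedule()
    rows = []
    for _, row in truth.iterrows():
        sub_dir = in_path / "subjects" / f"{row['subject']}_{row['timepoint']}"
        scalars = json.loads((sub_dir / "scalars.json").read_text())
        bundle = phantom_mod.AcquisitionBundle(
            sv_series=io_mod.load_nifti(sub_dir / "sv_series.nii", series=True),
            asl_selective=io_mod.load_nifti(sub_dir / "asl_selective.nii"),
            asl_nonselective=io_mod.load_nifti(sub_dir / "asl_nonselective.nii"),
            echo1_body=io_mod.load_nifti(sub_dir / "echo1_body.nii"),
            echo2_body=io_mod.load_nifti(sub_dir / "echo2_body.nii"),
            echo1_torso=io_mod.load_nifti(sub_dir / "echo1_torso.nii"),
            echo2_torso=io_mod.load_nifti(sub_dir / "echo2_torso.nii"),
            te1=scalars["te1"], te2=scalars["te2"], ti=scalars["ti"],
            schedule=schedule,
        )
        lung_mask = io_mod.load_nifti(sub_dir / "lung_mask.nii") > 0.5
        phantom_roi = io_mod.load_nifti(sub_dir / "phantom_roi.nii") > 0.5
        result = analyze_subject(
            bundle, lung_mask, phantom_roi, scalars["voxel_volume"],
            scalars["heart_rate"], scalars["frc"], scalars["tidal_volume"],
            config, scalars["phantom_density"],
        )
        out_row = {k: row[k] for k in
                   ("subject", "group", "timepoint", "sex", "age", "bmi",
                    "nicotine", "nicotine_type", "pack_years", "frc",
                    "tidal_volume")}
        out_row.update(result.summary)
        rows.append(out_row)
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_path / "summary.csv", index=False)
    return summary


def stats_report(summary: pd.DataFrame, out_dir=None):
    """Cohort statistics from a per-subject summary table: the group
    comparison report plus the exposure-response correlation screen."""
    report = stats_mod.build_summary_tables(
        summary, metrics=["mean_sv", "rd_sv", "lci", "mean_q", "rd_q",
                          "mean_density", "heart_rate"],
    )
    correlations = _exposure_correlations(summary)
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_path / "report.csv", index=False)
        correlations.to_csv(out_path / "correlations.csv", index=False)
    return report, correlations


def _exposure_correlations(summary: pd.DataFrame) -> pd.DataFrame:
    """Exposure-response screen on the vaping cohort: BMI against the
    change in mean perfusion, and pre-exposure SV heterogeneity against the
    change in perfusion heterogeneity."""
    pre = summary[summary.timepoint == "pre"].set_index("subject")
    post = summary[summary.timepoint == "post"].set_index("subject")
    common = pre.index.intersection(post.index)
    if len(common) < 4:
        return pd.DataFrame()
    paired = pd.DataFrame({
        "bmi": pre.loc[common, "bmi"],
        "delta_mean_q": post.loc[common, "mean_q"] - pre.loc[common, "mean_q"],
        "rd_sv_pre": pre.loc[common, "rd_sv"],
        "delta_rd_q": post.loc[common, "rd_q"] - pre.loc[common, "rd_q"],
    })
    pairs = [("bmi", "delta_mean_q"), ("rd_sv_pre", "delta_rd_q")]
    rows = []
    for method in ("spearman", "pearson"):
        for res in stats_mod.correlation_screen(paired, pairs, method=method):
            rows.append({
                "x": res.extra["x"], "y": res.extra["y"], "method": method,
                "coefficient": res.estimate, "p_value": res.p_value,
                "n": res.n[0],
            })
    return pd.DataFrame(rows)
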