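"""End-to-end orchestration: simulate → QC → preprocess → gFCD → GLM →
cluster extraction → mediation, with config round-tripping, structured
logging, and a run manifest.

Subject-level quality control follows the cohort's stated exclusion rule:
a subject fails if any frame's translation exceeds 3 mm on any axis or any
rotation exceeds 2° (both relative to the first frame). The manifest records
subject counts into and out of every filtering step (in = out + excluded),
per-stage seeds, and SHA-256 hashes of written outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcd, mediation, preprocess, scalarstats, synth, voxelstats

__all__ = ["RunConfig", "qc_motion", "apply_exclusions", "run_pipeline"]

logger = logging.getLogger("gfcdmap")


def _log(stage: str, **fields) -> None:
    logger.info(json.dumps({"stage": stage, "time": time.time(), **fields}))


@dataclass
class RunConfig:
    """All pipeline stage parameters; round-trips through YAML unchanged."""

    seed: int = 0
    out_dir: str = "gfcdmap_run"
    # cohort
    n_per_cell: int = 6
    n_volumes: int = 140
    tr_seconds: float = 3.0
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    hub_strengths: dict[str, float] = field(
        default_factory=lambda: {
            "CN/e2+": 1.25, "CN/e3e3": 1.25, "CN/e4+": 1.25,
            "MCI/e2+": 1.5, "MCI/e3e3": 1.25, "MCI/e4+": 1.0,
        }
    )
    motion_amplitude_mm: float = 0.05
    spatial_noise_fwhm_mm: float = 6.0
    # preprocessing
    n_discard: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    filter_nuisance_regressors: bool = False
    # QC (subject-level exclusion)
    max_translation_mm: float = 3.0
    max_rotation_deg: float = 2.0
    # gFCD
    r_threshold: float = 0.6
    snr_fraction: float = 0.5
    smooth_fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    # voxel-wise stats
    voxel_p: float = 0.005
    cluster_alpha: float = 0.001
    mc_iterations: int = 1000
    connectivity: int = 26
    # mediation
    mediation_group: str = "MCI"
    mediation_outcomes: tuple[str, ...] = ("mmse", "adas13", "ravlt_forgetting")
    n_boot: int = 2000
    ci_level: float = 0.95

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("grid_shape", "voxel_mm", "smooth_fwhm_mm", "mediation_outcomes"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def cohort_spec(self) -> synth.CohortSpec:
        return synth.CohortSpec(
            n_per_cell=self.n_per_cell,
            n_volumes=self.n_volumes,
            tr_seconds=self.tr_seconds,
            grid_shape=tuple(self.grid_shape),
            voxel_mm=tuple(self.voxel_mm),
        )

    def effect_spec(self) -> synth.EffectSpec:
        strengths = {
            tuple(k.split("/")): float(v) for k, v in self.hub_strengths.items()
        }
        spec = synth.default_effect_spec(
            hub_strengths=strengths, grid_shape=tuple(self.grid_shape)
        )
        spec.motion_amplitude_mm = self.motion_amplitude_mm
        spec.spatial_noise_fwhm_mm = self.spatial_noise_fwhm_mm
        return spec


def qc_motion(
    motion: preprocess.MotionTrace,
    max_translation_mm: float = 3.0,
    max_rotation_deg: float = 2.0,
) -> tuple[bool, list[str]]:
    """Subject-level motion QC. Translations and rotations are taken relative
    to the first frame; rotations are compared in degrees. Returns
    (passed, reasons)."""
    rel = motion.params - motion.params[0]
    reasons = []
    if np.any(np.abs(rel[:, :3]) > max_translation_mm):
        reasons.append("translation")
    if np.any(np.abs(np.degrees(rel[:, 3:])) > max_rotation_deg):
        reasons.append("rotation")
    return (not reasons), reasons


def apply_exclusions(
    manifest: pd.DataFrame, excluded_ids: dict[str, list]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged subjects and return in/out/excluded bookkeeping.

    ``excluded_ids`` maps a reason (e.g. 'poor_signal', 'motion') to subject
    ids; a subject flagged for several reasons is counted under the first."""
    counts: dict[str, int] = {"in": len(manifest)}
    dropped: set = set()
    for reason, ids in excluded_ids.items():
        new = [i for i in ids if i not in dropped]
        counts[f"excluded_{reason}"] = len(new)
        dropped.update(new)
    kept = manifest[~manifest["subject_id"].isin(dropped)].reset_index(drop=True)
    counts["out"] = len(kept)
    return kept, counts


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _preprocess_subject(
    series: preprocess.BoldSeries,
    motion: preprocess.MotionTrace,
    masks: dict[str, np.ndarray],
    cfg: RunConfig,
) -> tuple[preprocess.BoldSeries, float]:
    series = preprocess.discard_initial(series, cfg.n_discard)
    motion_post = preprocess.MotionTrace(motion.params[cfg.n_discard :])
    fd = preprocess.compute_fd(motion_post)
    series = preprocess.detrend_and_bandpass(series, cfg.low_hz, cfg.high_hz)
    wm = preprocess.extract_tissue_signal(series, masks["wm"])
    csf = preprocess.extract_tissue_signal(series, masks["csf"])
    regressors = np.column_stack([motion_post.params, wm, csf])
    series = preprocess.nuisance_regress(series, regressors)
    return series, fd.mean_fd


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain on a synthetic cohort; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    rng_registry = {"simulate": config.seed, "monte_carlo": config.seed + 1,
                    "mediation": config.seed + 2}
    manifest["seeds"] = rng_registry

    # --- simulate -----------------------------------------------------------
    cohort = config.cohort_spec()
    effects = config.effect_spec()
    table, series_list, motion_list = synth.generate_cohort(
        cohort, effects, rng_registry["simulate"]
    )
    masks = synth.cohort_masks(tuple(config.grid_shape))
    _log("simulate", n_subjects=len(table), seed=rng_registry["simulate"])
    manifest["stages"]["simulate"] = {"n_subjects": len(table)}

    # --- motion QC ----------------------------------------------------------
    qc_fail: list[str] = []
    qc_reasons: dict[str, list[str]] = {}
    for sid, motion in zip(table["subject_id"], motion_list):
        ok, reasons = qc_motion(motion, config.max_translation_mm, config.max_rotation_deg)
        if not ok:
            qc_fail.append(sid)
            qc_reasons[sid] = reasons
    table_qc, qc_counts = apply_exclusions(table, {"motion": qc_fail})
    keep = table["subject_id"].isin(table_qc["subject_id"]).to_numpy()
    series_list = [s for s, k in zip(series_list, keep) if k]
    motion_list = [m for m, k in zip(motion_list, keep) if k]
    _log("qc", **qc_counts)
    manifest["stages"]["qc"] = {**qc_counts, "reasons": qc_reasons}

    # --- preprocess + gFCD --------------------------------------------------
    gfcd_maps = []
    mean_fds = []
    for series, motion in zip(series_list, motion_list):
        clean, mean_fd = _preprocess_subject(series, motion, masks, config)
        mean_fds.append(mean_fd)
        qmask = fcd.build_qualified_mask(series, masks["gm"], config.snr_fraction)
        raw = fcd.compute_gfcd(clean, qmask, config.r_threshold)
        smoothed = fcd.smooth_map(fcd.grand_mean_scale(raw), config.smooth_fwhm_mm)
        gfcd_maps.append(smoothed)
    table_qc = table_qc.assign(mean_fd=mean_fds)
    _log("gfcd", n_maps=len(gfcd_maps))
    manifest["stages"]["preprocess"] = {
        "in": len(series_list), "out": len(gfcd_maps), "excluded": 0,
        "n_frames_after_discard": config.n_volumes - config.n_discard,
    }

    # --- voxel-wise GLM -----------------------------------------------------
    design = voxelstats.build_design(table_qc)
    qmask_ref = gfcd_maps[0].mask
    fmaps = voxelstats.fit_voxelwise_ancova(gfcd_maps, design, qmask_ref)
    fwhm_est = voxelstats.estimate_smoothness(fmaps, tuple(config.voxel_mm))
    k_min = voxelstats.monte_carlo_extent_threshold(
        fmaps.analysis_mask,
        tuple(fwhm_est),
        config.voxel_p,
        config.cluster_alpha,
        config.mc_iterations,
        config.connectivity,
        seed=rng_registry["monte_carlo"],
        voxel_mm=tuple(config.voxel_mm),
    )
    reports = {
        effect: voxelstats.form_clusters(
            fmaps.p_maps[effect],
            config.voxel_p,
            k_min,
            config.connectivity,
            affine=cohort.affine,
            stat_map=fmaps.f_maps[effect],
            mask=fmaps.analysis_mask,
            alpha=config.cluster_alpha,
        )
        for effect in voxelstats.EFFECTS
    }
    _log("glm", k_min=k_min, fwhm_mm=list(map(float, fwhm_est)),
         clusters={e: r.n_clusters for e, r in reports.items()})
    manifest["stages"]["glm"] = {
        "in": len(gfcd_maps),
        "k_min_voxels": int(k_min),
        "k_min_mm3": float(k_min * np.prod(config.voxel_mm)),
        "estimated_fwhm_mm": [float(v) for v in fwhm_est],
        "excluded_voxels": fmaps.excluded_voxels,
        "clusters": {
            e: r.to_dataframe().to_dict("records") for e, r in reports.items()
        },
    }

    # --- cluster-mean extraction -------------------------------------------
    mediator_cols = ["hippocampus"]
    extract_effect = next(
        (e for e in ("interaction", "genotype", "diagnosis") if reports[e].n_clusters),
        None,
    )
    if extract_effect is not None:
        means = voxelstats.extract_cluster_means(gfcd_maps, reports[extract_effect])
        means.columns = [f"gfcd_{extract_effect}_{c}" for c in means.columns]
        table_qc = pd.concat([table_qc.reset_index(drop=True), means], axis=1)
        mediator_cols += list(means.columns)
    manifest["stages"]["extract"] = {
        "effect": extract_effect,
        "n_clusters": 0 if extract_effect is None else reports[extract_effect].n_clusters,
        "mediators": mediator_cols,
    }

    # --- scalar statistics --------------------------------------------------
    report_df = scalarstats.table1_report(table_qc)
    report_path = out / "table1.tsv"
    report_df.to_csv(report_path, sep="\t", index=False)

    # --- mediation ----------------------------------------------------------
    fits = mediation.run_mediation_battery(
        table_qc,
        tuple(mediator_cols),
        tuple(config.mediation_outcomes),
        group=config.mediation_group,
        n_boot=config.n_boot,
        ci_level=config.ci_level,
        seed=rng_registry["mediation"],
    )
    med_df = pd.DataFrame([asdict(f) for f in fits])
    med_path = out / "mediation.tsv"
    med_df.to_csv(med_path, sep="\t", index=False)
    _log("mediate", n_fits=len(fits),
         n_significant=int(sum(f.significant for f in fits)))
    manifest["stages"]["mediate"] = {
        "group": config.mediation_group,
        "n_fits": len(fits),
        "n_significant": int(sum(f.significant for f in fits)),
    }

    # --- write outputs + hashes --------------------------------------------
    pheno_path = out / "phenotypes_analyzed.tsv"
    table_qc.to_csv(pheno_path, sep="\t", index=False, float_format="%.6f")
    manifest["hashes"] = {
        p.name: _sha256(p) for p in (pheno_path, report_path, med_path)
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
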