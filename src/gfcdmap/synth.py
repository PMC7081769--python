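"""Seeded synthetic cohorts for the gene–brain–cognition pipeline.

Generates everything the downstream analysis consumes — a phenotype table
with a 2 (diagnosis: CN/MCI) × 3 (APOE genotype: e2+/e3e3/e4+) factorial
structure, 4D BOLD series with planted connectivity hubs, rigid-body motion
traces, and tissue masks — with bit-reproducible outputs for a given seed.

Hub construction: each hub region shares one latent unit-variance signal;
a member voxel's time course is baseline + σ·(s·latent + ε) with ε ~ N(0,1),
so the correlation between two members is s²/(s²+1) for hub strength s.
Strength may differ per (diagnosis, genotype) cell, which is how group and
group×genotype effects on connectivity density are planted.

Phenotype outcomes are cell mean + covariate slopes · (covariate − its
generative mean) + Gaussian noise; planted mediation triples (a, b, c′)
additionally generate mediator/outcome column pairs from the ordinal
genotype code. A map-level generator (`generate_gfcd_maps`) produces
smoothed Gaussian connectivity-density-like maps directly, for calibrating
the cluster-level statistics without the O(V²) connectivity pass.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

from .fcd import _FWHM_TO_SIGMA
from .preprocess import BoldSeries, MotionTrace, compute_fd
from .voxelstats import DIAGNOSIS_LEVELS, GENOTYPE_LEVELS

__all__ = [
    "HubSpec",
    "EffectSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_motion",
    "generate_gfcd_maps",
    "default_effect_spec",
    "cohort_masks",
    "write_cohort",
]

CELLS = [(dx, gt) for dx in DIAGNOSIS_LEVELS for gt in GENOTYPE_LEVELS]

# Cohort-scale generative means/SDs (plausibility dressing on the cognitive
# and structural outcomes; the factorial structure, not these numbers, is
# what the tests exercise).
_TABLE_MEANS = {
    "adas13": {("CN", "e2+"): 11.89, ("CN", "e3e3"): 9.21, ("CN", "e4+"): 9.25,
               ("MCI", "e2+"): 13.33, ("MCI", "e3e3"): 13.81, ("MCI", "e4+"): 15.68},
    "mmse": {("CN", "e2+"): 28.63, ("CN", "e3e3"): 28.79, ("CN", "e4+"): 28.78,
             ("MCI", "e2+"): 28.92, ("MCI", "e3e3"): 28.10, ("MCI", "e4+"): 27.69},
    "ravlt_immediate": {("CN", "e2+"): 45.47, ("CN", "e3e3"): 43.76, ("CN", "e4+"): 42.44,
                        ("MCI", "e2+"): 42.91, ("MCI", "e3e3"): 35.37, ("MCI", "e4+"): 37.52},
    "ravlt_learning": {("CN", "e2+"): 5.26, ("CN", "e3e3"): 5.69, ("CN", "e4+"): 5.88,
                       ("MCI", "e2+"): 4.91, ("MCI", "e3e3"): 4.95, ("MCI", "e4+"): 4.40},
    "ravlt_forgetting": {("CN", "e2+"): 35.31, ("CN", "e3e3"): 39.40, ("CN", "e4+"): 36.53,
                         ("MCI", "e2+"): 42.09, ("MCI", "e3e3"): 52.71, ("MCI", "e4+"): 64.77},
    "logical_memory": {("CN", "e2+"): 13.79, ("CN", "e3e3"): 13.76, ("CN", "e4+"): 13.94,
                       ("MCI", "e2+"): 6.61, ("MCI", "e3e3"): 6.91, ("MCI", "e4+"): 6.71},
    "trails_b": {("CN", "e2+"): 84.52, ("CN", "e3e3"): 72.84, ("CN", "e4+"): 90.11,
                 ("MCI", "e2+"): 81.07, ("MCI", "e3e3"): 109.93, ("MCI", "e4+"): 105.90},
    "icv": {cell: 1.52 for cell in CELLS},
    "hippocampus": {("CN", "e2+"): 7.32, ("CN", "e3e3"): 7.44, ("CN", "e4+"): 7.74,
                    ("MCI", "e2+"): 7.64, ("MCI", "e3e3"): 7.43, ("MCI", "e4+"): 7.29},
    "entorhinal": {cell: 3.75 for cell in CELLS},
    "fusiform": {cell: 17.9 for cell in CELLS},
}
_TABLE_SDS = {
    "adas13": 6.0, "mmse": 1.6, "ravlt_immediate": 10.0, "ravlt_learning": 2.5,
    "ravlt_forgetting": 27.0, "logical_memory": 3.0, "trails_b": 47.0,
    "icv": 0.16, "hippocampus": 0.9, "entorhinal": 0.7, "fusiform": 2.1,
}
_AGE_MEAN, _AGE_SD = 73.0, 6.0
_EDU_MEAN, _EDU_SD = 16.0, 2.5
_GENOTYPE_CODE = {"e2+": 1.0, "e3e3": 2.0, "e4+": 3.0}


@dataclass
class HubSpec:
    """A spherical connectivity hub: center (voxel indices), radius (voxels),
    and connection strength, either one scalar or one per (dx, gt) cell."""

    center: tuple[int, int, int]
    radius: float
    strength: float | dict[tuple[str, str], float]

    def strength_for(self, cell: tuple[str, str]) -> float:
        if isinstance(self.strength, dict):
            return float(self.strength[cell])
        return float(self.strength)

    def member_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.indices(shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return d2 <= self.radius**2


@dataclass
class EffectSpec:
    """Planted statistical structure for a synthetic cohort."""

    cell_means: dict[str, dict[tuple[str, str], float]] = dataclass_field(
        default_factory=dict
    )
    hub_regions: list[HubSpec] = dataclass_field(default_factory=list)
    noise_sd: dict[str, float] = dataclass_field(default_factory=dict)
    covariate_slopes: dict[str, dict[str, float]] = dataclass_field(default_factory=dict)
    mediation_paths: dict[tuple[str, str], tuple[float, float, float]] = dataclass_field(
        default_factory=dict
    )
    motion_amplitude_mm: float = 0.05
    bold_baseline: float = 800.0
    bold_noise_sd: float = 10.0
    drift_amplitude: float = 0.0
    # spatial correlation of the background noise; 0 keeps voxels independent
    # so hub–hub correlations follow the closed form s²/(s²+1) exactly
    spatial_noise_fwhm_mm: float = 0.0

    def validate(self, cohort: "CohortSpec") -> None:
        for var, means in self.cell_means.items():
            for cell, mu in means.items():
                if not np.isfinite(mu):
                    raise ValueError(f"cell_means[{var!r}][{cell}] is not finite")
            sd = self.noise_sd.get(var, 1.0)
            if not sd > 0:
                raise ValueError(f"noise_sd[{var!r}] must be > 0, got {sd}")
        brain = cohort_masks(cohort.grid_shape)["brain"]
        for i, hub in enumerate(self.hub_regions):
            if hub.radius < 1:
                raise ValueError(f"hub_regions[{i}].radius must be >= 1 voxel")
            if not brain[tuple(hub.center)]:
                raise ValueError(f"hub_regions[{i}].center {hub.center} lies outside the brain mask")
        if self.motion_amplitude_mm < 0:
            raise ValueError("motion_amplitude_mm must be >= 0")


@dataclass
class CohortSpec:
    """Cohort geometry and acquisition parameters."""

    n_per_cell: int | dict[tuple[str, str], int] = 3
    n_volumes: int = 140
    tr_seconds: float = 3.0
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    max_grid_voxels: int = 32768  # guard: keeps the O(V²) gFCD pass desk-scale

    def validate(self) -> None:
        counts = self.cell_counts()
        if min(counts.values()) < 2:
            raise ValueError("n_per_cell must be >= 2 in every cell")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed 10 (initial-volume discard)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if int(np.prod(self.grid_shape)) > self.max_grid_voxels:
            raise ValueError(
                f"grid_shape {self.grid_shape} exceeds max_grid_voxels="
                f"{self.max_grid_voxels}; raise the guard explicitly for larger grids"
            )

    def cell_counts(self) -> dict[tuple[str, str], int]:
        if isinstance(self.n_per_cell, dict):
            return {cell: int(self.n_per_cell[cell]) for cell in CELLS}
        return {cell: int(self.n_per_cell) for cell in CELLS}

    @property
    def affine(self) -> np.ndarray:
        # diagonal RAS affine with an MNI-like origin at the grid center
        aff = np.diag([*self.voxel_mm, 1.0])
        aff[:3, 3] = -np.asarray(self.grid_shape) / 2.0 * np.asarray(self.voxel_mm)
        return aff


def default_effect_spec(
    hub_strengths: dict[tuple[str, str], float] | float = 1.25,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
) -> EffectSpec:
    """Cohort-scale default effects: cognitive/structural outcome means on
    the published scale and one planted hub in the right-hemisphere deep
    gray, with configurable per-cell strength."""
    # offset the hub from the grid center by ~30% of the brain radius so it
    # sits inside the brain at any grid size
    r_brain = min(grid_shape) / 2.0 - 0.5
    center = tuple(int(round((s - 1) / 2.0 + 0.3 * r_brain)) for s in grid_shape)
    return EffectSpec(
        cell_means={k: dict(v) for k, v in _TABLE_MEANS.items()},
        noise_sd=dict(_TABLE_SDS),
        covariate_slopes={"adas13": {"age": 0.1, "education": -0.3}},
        hub_regions=[HubSpec(center=center, radius=2.0, strength=hub_strengths)],
        mediation_paths={},
    )


def cohort_masks(grid_shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Simple concentric head geometry: a spherical brain, a small central
    CSF core, a white-matter shell around it, gray matter elsewhere."""
    grids = np.indices(grid_shape).astype(np.float64)
    center = (np.asarray(grid_shape) - 1) / 2.0
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    r_brain = min(grid_shape) / 2.0 - 0.5
    brain = d <= r_brain
    csf = d <= max(r_brain * 0.15, 1.0)
    wm = (d > max(r_brain * 0.15, 1.0)) & (d <= max(r_brain * 0.35, 2.0))
    gm = brain & ~csf & ~wm
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def generate_motion(n_volumes: int, amplitude_mm: float, seed: int) -> MotionTrace:
    """Random-walk motion trace: 3 translations (mm) and 3 rotations (rad),
    increments scaled by ``amplitude_mm`` (rotations by amplitude/50 so their
    arc-length contribution on a 50 mm sphere is commensurate)."""
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    steps[:, :3] *= amplitude_mm
    steps[:, 3:] *= amplitude_mm / 50.0
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(params)


def _subject_bold(
    cohort: CohortSpec,
    effects: EffectSpec,
    cell: tuple[str, str],
    masks: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> BoldSeries:
    shape = (*cohort.grid_shape, cohort.n_volumes)
    data = np.zeros(shape)
    brain = masks["brain"]
    nt = cohort.n_volumes
    if effects.spatial_noise_fwhm_mm > 0:
        # spatially correlated background: smooth each frame, then restore
        # unit temporal variance per voxel so only the correlation changes
        sigma_vox = (
            effects.spatial_noise_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(cohort.voxel_mm)
        )
        field = rng.standard_normal(shape)
        field = ndimage.gaussian_filter(field, sigma=(*sigma_vox, 0.0), mode="reflect")
        field /= field.std(axis=3, keepdims=True)
        noise = field[brain]
    else:
        noise = rng.standard_normal((int(brain.sum()), nt))
    data[brain] = effects.bold_baseline + effects.bold_noise_sd * noise
    for hub in effects.hub_regions:
        s = hub.strength_for(cell)
        if s == 0:
            continue
        latent = rng.standard_normal(nt)
        members = hub.member_mask(cohort.grid_shape) & brain
        data[members] += effects.bold_noise_sd * s * latent
    if effects.drift_amplitude:
        ramp = np.linspace(-0.5, 0.5, nt) * effects.drift_amplitude
        data[brain] += ramp
    return BoldSeries(data, cohort.affine, cohort.tr_seconds)


def generate_cohort(
    cohort: CohortSpec, effects: EffectSpec, seed: int, imaging: bool = True
) -> tuple[pd.DataFrame, list[BoldSeries], list[MotionTrace]]:
    """Generate one synthetic cohort: phenotype table, one 4D BOLD series and
    one motion trace per subject. Identical (specs, seed) yields identical
    outputs. ``imaging=False`` skips the BOLD/motion stage (phenotype-only
    cohorts for large-n statistical simulations); the table then carries a
    zero mean FD."""
    cohort.validate()
    effects.validate(cohort)
    root = np.random.SeedSequence(seed)
    pheno_rng = np.random.default_rng(root.spawn(1)[0])
    masks = cohort_masks(cohort.grid_shape)

    counts = cohort.cell_counts()
    rows = []
    for dx, gt in CELLS:
        for _ in range(counts[(dx, gt)]):
            rows.append({"diagnosis": dx, "genotype": gt})
    n = len(rows)
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n)])
    table["age"] = pheno_rng.normal(_AGE_MEAN, _AGE_SD, n)
    table["sex"] = pheno_rng.integers(0, 2, n).astype(float)
    table["education"] = pheno_rng.normal(_EDU_MEAN, _EDU_SD, n)

    centered = {
        "age": table["age"] - _AGE_MEAN,
        "sex": table["sex"] - 0.5,
        "education": table["education"] - _EDU_MEAN,
    }
    for var, means in effects.cell_means.items():
        mu = np.array([means[(r.diagnosis, r.genotype)] for r in table.itertuples()])
        sd = effects.noise_sd.get(var, 1.0)
        y = mu + pheno_rng.normal(0.0, sd, n)
        for cov, slope in effects.covariate_slopes.get(var, {}).items():
            y = y + slope * centered[cov].to_numpy()
        table[var] = y
    x_code = table["genotype"].map(_GENOTYPE_CODE).to_numpy()
    for (m_col, y_col), (a, b, c_prime) in effects.mediation_paths.items():
        m = a * x_code + pheno_rng.standard_normal(n)
        y = b * m + c_prime * x_code + pheno_rng.standard_normal(n)
        table[m_col] = m
        table[y_col] = y

    series_list: list[BoldSeries] = []
    motion_list: list[MotionTrace] = []
    if not imaging:
        table["mean_fd"] = 0.0
        return table, series_list, motion_list
    subject_seeds = root.spawn(1 + n)[1:]
    for i, row in enumerate(table.itertuples()):
        sub_rng = np.random.default_rng(subject_seeds[i])
        series_list.append(
            _subject_bold(cohort, effects, (row.diagnosis, row.genotype), masks, sub_rng)
        )
        motion_seed = int(sub_rng.integers(0, 2**31 - 1))
        motion_list.append(
            generate_motion(cohort.n_volumes, effects.motion_amplitude_mm, motion_seed)
        )
    table["mean_fd"] = [compute_fd(mt).mean_fd for mt in motion_list]
    return table, series_list, motion_list


def generate_gfcd_maps(
    n_per_cell: int,
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    fwhm_mm: tuple[float, float, float] = (6.0, 6.0, 6.0),
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    effect_region: HubSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Map-level simulator for cluster-statistics calibration.

    Each subject's map is smoothed standard-normal noise (unit variance after
    smoothing) plus, optionally, a per-cell mean shift inside a spherical
    region (``effect_region.strength`` keyed by cell). Returns (phenotype
    table, maps (n, *grid_shape), brain mask).
    """
    rng = np.random.default_rng(seed)
    sigma_vox = np.asarray(fwhm_mm) * _FWHM_TO_SIGMA / np.asarray(voxel_mm)
    mask = np.ones(grid_shape, dtype=bool)
    rows = []
    for dx, gt in CELLS:
        rows.extend({"diagnosis": dx, "genotype": gt} for _ in range(n_per_cell))
    table = pd.DataFrame(rows)
    n = len(table)
    table.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n)])
    table["age"] = rng.normal(_AGE_MEAN, _AGE_SD, n)
    table["sex"] = rng.integers(0, 2, n).astype(float)
    table["education"] = rng.normal(_EDU_MEAN, _EDU_SD, n)
    table["mean_fd"] = np.abs(rng.normal(0.15, 0.05, n))
    maps = np.empty((n, *grid_shape))
    region = effect_region.member_mask(grid_shape) if effect_region is not None else None
    for i, row in enumerate(table.itertuples()):
        field = rng.standard_normal(grid_shape)
        if np.any(sigma_vox > 0):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="reflect")
            field /= field.std()
        if region is not None:
            field[region] += effect_region.strength_for((row.diagnosis, row.genotype))
        maps[i] = field
    return table, maps, mask


def _save_nifti_deterministic(img: nib.Nifti1Image, path: Path) -> None:
    """Write NIfTI with gzip mtime pinned to 0 so outputs are byte-identical
    across runs."""
    raw = img.to_bytes()
    if str(path).endswith(".gz"):
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        path.write_bytes(raw)


def write_cohort(
    table: pd.DataFrame,
    series_list: list[BoldSeries],
    motion_list: list[MotionTrace],
    out_dir: str | Path,
    grid_shape: tuple[int, int, int] | None = None,
) -> dict[str, str]:
    """Write phenotypes.tsv, per-subject BOLD (.nii.gz) and motion (.txt),
    and the tissue masks. Returns a name → path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    pheno = out / "phenotypes.tsv"
    table.to_csv(pheno, sep="\t", index=False, float_format="%.6f")
    paths["phenotypes"] = str(pheno)
    affine = series_list[0].affine
    shape = grid_shape or series_list[0].shape
    for name, m in cohort_masks(shape).items():
        p = out / f"mask_{name}.nii.gz"
        _save_nifti_deterministic(nib.Nifti1Image(m.astype(np.uint8), affine), p)
        paths[f"mask_{name}"] = str(p)
    for sid, series, motion in zip(table["subject_id"], series_list, motion_list):
        bp = out / f"{sid}_bold.nii.gz"
        img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
        img.header.set_zooms((*series.voxel_sizes_mm, series.tr_seconds))
        _save_nifti_deterministic(img, bp)
        mp = out / f"{sid}_motion.txt"
        motion.to_text(mp)
        paths[sid] = str(bp)
    return paths
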