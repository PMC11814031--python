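"""Seeded phantom cohorts with known ground truth.

The generator emulates, on a small common grid, the features of the study
data that the downstream measurement and inference chain depends on:

* bilateral hyperintense LC "tubes" on a uniform pontine background, with
  group-dependent sub-regional contrast (rostral / middle / caudal thirds);
* multiplicative per-slice intensity drift (the artifact the slice
  normalization step must undo) and additive Gaussian noise;
* a covariate table (age, sex, education, raw MoCA) tied to a latent
  cognition score;
* PET uptake volumes for the patient group carrying a planted cortical
  cluster whose amplitude co-varies with that latent score, plus a
  score-independent reference region.

Averaging of repeated acquisitions is represented by a noise-variance
argument: generated volumes carry additive noise with standard deviation
``noise_sd / sqrt(n_acquisitions)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AXIAL_AXIS, ImageVolume, ROISet, save_mask
from .lc_quantification import SIDES, SUBREGIONS, split_axial_thirds

GROUPS = ("HC", "MSA", "PD")


class ConfigError(ValueError):
    """Invalid phantom configuration; the message names the offending field."""


class GeometryError(ValueError):
    """Requested structure does not fit inside the phantom grid."""


@dataclass
class CognitionModel:
    """Linear links between the latent cognition score and observables.

    A standard-normal latent score ``z`` per subject drives (i) the raw MoCA
    score, ``round(moca_center[group] + moca_scale * z)`` clipped to 0-30;
    (ii) the subject's rostral LC contrast via ``rostral_coef * z``; and
    (iii) the planted PET cluster amplitude via ``suvr_coef * z``
    (fractional uptake change per unit score).
    """

    rostral_coef: float = 0.06
    suvr_coef: float = 0.02
    moca_center: dict[str, float] = field(
        default_factory=lambda: {"HC": 27.5, "MSA": 25.0, "PD": 27.0}
    )
    moca_scale: float = 2.0


def _default_contrasts() -> dict[str, dict[str, float]]:
    # Healthy-control contrasts ~0.2-0.3 with patient reductions concentrated
    # in the middle (MSA, PD) and caudal (MSA) thirds; rostral spared.
    return {
        "HC": {"rostral": 0.30, "middle": 0.250, "caudal": 0.200},
        "MSA": {"rostral": 0.30, "middle": 0.175, "caudal": 0.140},
        "PD": {"rostral": 0.30, "middle": 0.200, "caudal": 0.160},
    }


@dataclass
class PhantomConfig:
    """Parameters of a synthetic cohort; defaults define the study conditions."""

    grid_shape: tuple[int, int, int] = (48, 48, 18)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_mean: float = 100.0
    noise_sd: float = 2.0                       # per-acquisition, intensity units
    n_acquisitions: int = 3                     # averaged acquisitions -> sd/sqrt(n)
    slice_gain_range: tuple[float, float] = (0.9, 1.1)
    lc_tube_radius_vox: int = 1
    lc_length_slices: int = 9
    contrast_by_group: dict[str, dict] = field(default_factory=_default_contrasts)
    contrast_subject_sd: float = 0.05           # between-subject biological spread
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 18, "MSA": 11, "PD": 18}
    )
    cognition_model: CognitionModel = field(default_factory=CognitionModel)
    # PET phantom (generated for `pet_group` subjects only)
    pet_group: str = "MSA"
    pet_baseline: float = 100.0
    pet_noise_sd: float = 1.0
    cluster_radius_vox: float = 3.0
    cluster_center_vox: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 16 for g in self.grid_shape):
            raise ConfigError(f"grid_shape: all axes must be >= 16, got {self.grid_shape}")
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigError(f"voxel_size_mm: spacings must be positive, got {self.voxel_size_mm}")
        if self.background_mean <= 0:
            raise ConfigError(f"background_mean: must be positive, got {self.background_mean}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        if self.n_acquisitions < 1:
            raise ConfigError(f"n_acquisitions: must be >= 1, got {self.n_acquisitions}")
        lo, hi = self.slice_gain_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ConfigError(f"slice_gain_range: bounds must be positive and ordered, got {self.slice_gain_range}")
        if self.lc_tube_radius_vox < 1:
            raise ConfigError(f"lc_tube_radius_vox: must be >= 1, got {self.lc_tube_radius_vox}")
        if self.lc_length_slices < 3:
            raise ConfigError(f"lc_length_slices: must be >= 3, got {self.lc_length_slices}")
        for group, subs in self.contrast_by_group.items():
            for sub, val in subs.items():
                for side_val in _as_side_dict(val).values():
                    if side_val <= -1:
                        raise ConfigError(
                            f"contrast_by_group: contrast for {group}/{sub} must be > -1, got {side_val}"
                        )
        for group, n in self.n_per_group.items():
            if group not in self.contrast_by_group:
                raise ConfigError(f"n_per_group: group '{group}' has no contrast_by_group entry")
            if int(n) < 2:
                raise ConfigError(f"n_per_group: need >= 2 subjects per group, got {n} for '{group}'")
        if self.contrast_subject_sd < 0:
            raise ConfigError(f"contrast_subject_sd: must be >= 0, got {self.contrast_subject_sd}")
        if self.pet_noise_sd < 0:
            raise ConfigError(f"pet_noise_sd: must be >= 0, got {self.pet_noise_sd}")
        if self.pet_baseline <= 0:
            raise ConfigError(f"pet_baseline: must be positive, got {self.pet_baseline}")
        if self.cluster_radius_vox <= 0:
            raise ConfigError(f"cluster_radius_vox: must be positive, got {self.cluster_radius_vox}")
        self.seed = int(self.seed)


def _as_side_dict(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in SIDES}
    return {s: float(value) for s in SIDES}


@dataclass
class SubjectRecord:
    """Covariate row for one phantom subject."""

    subject_id: str
    group: str
    age: int
    sex: str
    education_years: int
    moca_raw: int
    moca_adjusted: int | None = None
    contrasts: dict[str, float] | None = None   # filled by the analysis stage


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    contrasts: dict[str, dict[str, dict[str, float]]]   # subject -> side -> subregion
    latent_score: dict[str, float]
    lc_masks: dict[str, np.ndarray]                     # side -> bool mask
    subregion_masks: dict[str, np.ndarray]              # "side_subregion" -> bool mask
    cluster_mask: np.ndarray
    cluster_center_vox: tuple[int, int, int]
    cluster_amplitude: dict[str, float]                 # subject -> fractional amplitude

    def scalars(self) -> dict:
        return {
            "contrasts": self.contrasts,
            "latent_score": self.latent_score,
            "cluster_amplitude": self.cluster_amplitude,
            "cluster_center_vox": list(self.cluster_center_vox),
        }


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class _Geometry:
    tube_centers: dict[str, tuple[int, int]]    # side -> in-plane (i, j) center
    tube_slices: np.ndarray                     # axial slice indices of the tubes
    thirds: dict[str, np.ndarray]               # subregion -> slice indices


def _geometry(config: PhantomConfig) -> _Geometry:
    nx, ny, nz = config.grid_shape
    cx, cy = nx // 2, ny // 2
    r = config.lc_tube_radius_vox
    offset = max(2 * r + 2, 4)                  # keep search ROIs clear of the midline background ROI
    tube_y = cy + ny // 8                       # dorsal pons
    z0 = (nz - config.lc_length_slices) // 2
    slices = np.arange(z0, z0 + config.lc_length_slices)
    if z0 < 0 or slices[-1] >= nz:
        raise GeometryError(
            f"lc_length_slices: {config.lc_length_slices} tube slices do not fit in {nz} axial slices"
        )
    for side_x in (cx - offset, cx + offset):
        if side_x - r - 1 < 0 or side_x + r + 1 >= nx:
            raise GeometryError("lc_tube_radius_vox: tube (with search margin) falls outside the grid")
    return _Geometry(
        tube_centers={"left": (cx - offset, tube_y), "right": (cx + offset, tube_y)},
        tube_slices=slices,
        thirds=split_axial_thirds(slices),
    )


def _disk(shape_xy: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    ii, jj = np.ogrid[: shape_xy[0], : shape_xy[1]]
    return (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2


def build_rois(config: PhantomConfig) -> tuple[ROISet, dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Construct the shared ROISet plus true LC / subregion / cluster masks."""
    nx, ny, nz = config.grid_shape
    geom = _geometry(config)
    r = config.lc_tube_radius_vox

    in_slices = np.zeros(nz, dtype=bool)
    in_slices[geom.tube_slices] = True

    lc_masks: dict[str, np.ndarray] = {}
    search: dict[str, np.ndarray] = {}
    for side, center in geom.tube_centers.items():
        tube2d = _disk((nx, ny), center, r)
        search2d = _disk((nx, ny), center, r + 1.5)
        lc_masks[side] = tube2d[:, :, None] & in_slices[None, None, :]
        search[side] = search2d[:, :, None] & in_slices[None, None, :]

    subregion_masks: dict[str, np.ndarray] = {}
    for side in SIDES:
        for sub, slc in geom.thirds.items():
            block = np.zeros(nz, dtype=bool)
            block[slc] = True
            subregion_masks[f"{side}_{sub}"] = lc_masks[side] & block[None, None, :]

    # Midline pontine background ROI: same cross-section as the tubes and the
    # same axial extent as the search ROIs, so the background extraction pool
    # matches the LC extraction pool geometry.
    cx, cy = nx // 2, geom.tube_centers["left"][1]
    background = _disk((nx, ny), (cx, cy), r)[:, :, None] & in_slices[None, None, :]

    # Slice-scaling mask: everything outside a dorsal-pons box that encloses
    # the tubes, search ROIs and background ROI, so that every axial slice has
    # identical in-mask composition and per-slice gains cancel exactly.
    half_w = (geom.tube_centers["right"][0] - cx) + r + 3
    brain = np.ones(config.grid_shape, dtype=bool)
    brain[cx - half_w : cx + half_w + 1, cy - r - 3 : cy + r + 4, :] = False

    # PET side: planted "frontal" cluster and a score-independent "occipital"
    # reference region at opposite ends of the j (anterior-posterior) axis.
    if config.cluster_center_vox is None:
        ccenter = (cx, (3 * ny) // 4 + ny // 16, nz // 2)
    else:
        ccenter = tuple(int(c) for c in config.cluster_center_vox)
    ii, jj, kk = np.ogrid[:nx, :ny, :nz]
    cluster = (
        (ii - ccenter[0]) ** 2 + (jj - ccenter[1]) ** 2 + (kk - ccenter[2]) ** 2
    ) <= config.cluster_radius_vox**2
    if not cluster.any():
        raise GeometryError("cluster_radius_vox: planted cluster is empty on this grid")

    reference = np.zeros(config.grid_shape, dtype=bool)
    reference[cx - 6 : cx + 7, 2 : 6, max(0, nz // 2 - 3) : nz // 2 + 4] = True

    analysis = np.zeros(config.grid_shape, dtype=bool)
    analysis[2 : nx - 2, 2 : ny - 2, 2 : nz - 2] = True
    analysis &= ~reference

    rois = ROISet(
        search_roi_left=search["left"],
        search_roi_right=search["right"],
        background_roi=background,
        brain_mask=brain,
        reference_mask=reference,
        analysis_mask=analysis,
    )
    problems = rois.validate(config.grid_shape)
    if problems:
        raise GeometryError("; ".join(problems))
    if (cluster & reference).any():
        raise GeometryError("cluster_center_vox: planted cluster overlaps the reference region")
    return rois, lc_masks, subregion_masks, cluster


# ---------------------------------------------------------------------------
# image construction
# ---------------------------------------------------------------------------

def make_lc_tubes(config: PhantomConfig, subject_contrasts: dict[str, dict[str, float]]) -> ImageVolume:
    """Noiseless neuromelanin phantom for one subject.

    ``subject_contrasts[side][subregion]`` sets each tube third's intensity to
    ``background_mean * (1 + contrast)`` on a uniform background.
    """
    _, _, subregion_masks, _ = build_rois(config)
    data = np.full(config.grid_shape, config.background_mean, dtype=float)
    for side in SIDES:
        for sub in SUBREGIONS:
            c = float(subject_contrasts[side][sub])
            data[subregion_masks[f"{side}_{sub}"]] = config.background_mean * (1.0 + c)
    return ImageVolume(data=data, voxel_size_mm=config.voxel_size_mm)


def apply_slice_gain(volume: ImageVolume, gains: np.ndarray, axis: int = AXIAL_AXIS) -> ImageVolume:
    """Multiply every axial slice ``k`` by ``gains[k]`` (all gains > 0)."""
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (volume.shape[axis],):
        raise ValueError(f"need one gain per axial slice ({volume.shape[axis]}), got shape {gains.shape}")
    if np.any(gains <= 0):
        raise ValueError("slice gains must all be positive")
    shape = [1, 1, 1]
    shape[axis] = len(gains)
    return volume.with_data(volume.data * gains.reshape(shape))


def make_suvr_phantom(config: PhantomConfig, score: float) -> ImageVolume:
    """Noiseless PET uptake phantom for one subject.

    Uniform baseline uptake everywhere; inside the planted cluster the uptake
    is ``baseline * (1 + suvr_coef * score)``.  The reference region stays at
    baseline regardless of the score.
    """
    _, _, _, cluster = build_rois(config)
    a = config.cognition_model.suvr_coef
    data = np.full(config.grid_shape, config.pet_baseline, dtype=float)
    data[cluster] = config.pet_baseline * (1.0 + a * float(score))
    return ImageVolume(data=data, voxel_size_mm=config.voxel_size_mm)


# ---------------------------------------------------------------------------
# covariates and cohorts
# ---------------------------------------------------------------------------

def _draw_covariates(config: PhantomConfig, rng: np.random.Generator) -> tuple[list[SubjectRecord], dict[str, float]]:
    cm = config.cognition_model
    records: list[SubjectRecord] = []
    scores: dict[str, float] = {}
    for group in sorted(config.n_per_group):
        for i in range(int(config.n_per_group[group])):
            sid = f"{group}{i + 1:03d}"
            z = float(rng.normal())
            age = int(rng.integers(45, 81))
            sex = "M" if rng.random() < 0.5 else "F"
            education = int(rng.integers(8, 21))
            center = cm.moca_center.get(group, 27.0)
            moca = int(np.clip(round(center + cm.moca_scale * z), 0, 30))
            records.append(SubjectRecord(sid, group, age, sex, education, moca))
            scores[sid] = z
    return records, scores


def generate_covariates(config: PhantomConfig, rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Covariate table only (ages 45-80, integer MoCA 0-30); seed-deterministic."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records, _ = _draw_covariates(config, rng)
    return records


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[SubjectRecord], dict[str, dict[str, ImageVolume | None]], ROISet, GroundTruth]:
    """Generate a full phantom cohort.

    Returns the covariate records, per-subject volumes
    (``volumes[sid]["nm"]`` always, ``volumes[sid]["pet"]`` for the PET
    group), the shared ROISet, and the ground truth.  Bit-identical for a
    fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    rois, lc_masks, subregion_masks, cluster = build_rois(config)
    records, scores = _draw_covariates(config, rng)
    cm = config.cognition_model
    nm_noise_sd = config.noise_sd / np.sqrt(config.n_acquisitions)
    nz = config.grid_shape[AXIAL_AXIS]

    truth_contrasts: dict[str, dict[str, dict[str, float]]] = {}
    amplitudes: dict[str, float] = {}
    volumes: dict[str, dict[str, ImageVolume | None]] = {}

    for rec in records:
        z = scores[rec.subject_id]
        group_c = config.contrast_by_group[rec.group]
        subj: dict[str, dict[str, float]] = {s: {} for s in SIDES}
        for sub in SUBREGIONS:
            sides = _as_side_dict(group_c[sub])
            dev = float(rng.normal(0.0, config.contrast_subject_sd)) if config.contrast_subject_sd else 0.0
            for side in SIDES:
                c = sides[side] + dev
                if sub == "rostral":
                    c += cm.rostral_coef * z
                subj[side][sub] = max(c, -0.95)
        truth_contrasts[rec.subject_id] = subj

        vol = make_lc_tubes(config, subj)
        noisy = vol.data + rng.normal(0.0, nm_noise_sd, size=vol.shape)
        gains = rng.uniform(config.slice_gain_range[0], config.slice_gain_range[1], size=nz)
        nm = apply_slice_gain(vol.with_data(noisy), gains)

        pet: ImageVolume | None = None
        if rec.group == config.pet_group:
            base = make_suvr_phantom(config, z)
            pet = base.with_data(base.data + rng.normal(0.0, config.pet_noise_sd, size=base.shape))
            amplitudes[rec.subject_id] = cm.suvr_coef * z
        volumes[rec.subject_id] = {"nm": nm, "pet": pet}

    center = np.argwhere(cluster).mean(axis=0)
    truth = GroundTruth(
        contrasts=truth_contrasts,
        latent_score=scores,
        lc_masks=lc_masks,
        subregion_masks=subregion_masks,
        cluster_mask=cluster,
        cluster_center_vox=tuple(int(round(c)) for c in center),
        cluster_amplitude=amplitudes,
    )
    return records, volumes, rois, truth


def simulate_contrast_cohort(
    n_per_group: dict[str, int],
    means: dict[str, float],
    subject_sd: float,
    seed: int,
    measurement_sd: float = 0.0,
    age_range: tuple[int, int] = (45, 80),
    age_effect: float = 0.0,
) -> pd.DataFrame:
    """Scalar-level cohort from the phantom measurement model.

    Draws per-subject measured contrasts ``mean[group] + age_effect*(age-62.5)
    + N(0, subject_sd) + N(0, measurement_sd)`` without rendering images;
    used for statistical calibration and power studies where the quantity
    under test is the inference procedure, not the image pipeline.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(n_per_group):
        for _ in range(int(n_per_group[group])):
            age = int(rng.integers(age_range[0], age_range[1] + 1))
            y = (
                means[group]
                + age_effect * (age - np.mean(age_range))
                + rng.normal(0.0, subject_sd)
                + (rng.normal(0.0, measurement_sd) if measurement_sd else 0.0)
            )
            rows.append({"group": group, "age": age, "y": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    cols = ["subject_id", "group", "age", "sex", "education_years", "moca_raw"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def write_cohort(
    outdir: str | Path,
    config: PhantomConfig,
    records: list[SubjectRecord],
    volumes: dict[str, dict[str, ImageVolume | None]],
    rois: ROISet,
    truth: GroundTruth,
) -> dict:
    """Write a cohort to disk (NIfTI volumes/masks, covariate TSV, truth JSON).

    Returns a manifest dict with the seed and a SHA-256 digest per file.
    """
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for sid, vols in volumes.items():
        written.append(vols["nm"].save(outdir / f"nm_{sid}.nii.gz"))
        if vols.get("pet") is not None:
            written.append(vols["pet"].save(outdir / f"pet_{sid}.nii.gz"))

    affine = next(iter(volumes.values()))["nm"].affine if volumes else None
    for name, mask in rois.masks().items():
        written.append(save_mask(mask, outdir / "masks" / f"{name}.nii.gz", affine))
    for key, mask in truth.subregion_masks.items():
        written.append(save_mask(mask, outdir / "masks" / f"true_lc_{key}.nii.gz", affine))
    written.append(save_mask(truth.cluster_mask, outdir / "masks" / "true_cluster.nii.gz", affine))

    cov_path = outdir / "covariates.tsv"
    records_to_frame(records).to_csv(cov_path, sep="\t", index=False)
    written.append(cov_path)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth.scalars(), indent=2, sort_keys=True))
    written.append(truth_path)

    manifest = {
        "seed": config.seed,
        "n_subjects": len(records),
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "files": {
            str(p.relative_to(outdir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(written)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
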