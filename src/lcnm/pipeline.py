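"""End-to-end orchestration: simulate -> quantify -> SUVR -> stats -> voxel-wise.

Every stage is deterministic given the run configuration and its seed, logs
the seed it used, and writes machine-readable outputs (TSV/JSON/NIfTI) plus
a plain-text report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_stats, lc_quantification, pet_suvr, voxelwise_stats
from .core import ImageVolume, ROISet, load_mask
from .synthetic_data import (
    CognitionModel,
    GroundTruth,
    PhantomConfig,
    SubjectRecord,
    generate_cohort,
    records_to_frame,
    write_cohort,
)

logger = logging.getLogger(__name__)


class ConfigFieldError(ValueError):
    """A run-configuration field is missing or invalid; message names it."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "lcnm_run"
    seed: int = 0
    n_perm: int = 10_000
    alpha: float = 0.05
    posthoc_n_tests: int = 6
    cluster_forming_p: float = 0.001
    exploratory_cluster_p: float = 0.01
    fwhm_mm: float = 8.0
    extract_connectivity: int = 26
    cluster_connectivity: int = 18
    extraction_method: str = "exact"
    background_method: str = "brightest"
    background_extent: str = "per-subregion"
    force_posthoc: bool = False
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        for name in ("alpha", "cluster_forming_p", "exploratory_cluster_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigFieldError(f"{name}: must be in (0, 1), got {v}")
        if self.n_perm < 1:
            raise ConfigFieldError(f"n_perm: must be >= 1, got {self.n_perm}")
        if self.fwhm_mm < 0:
            raise ConfigFieldError(f"fwhm_mm: must be >= 0, got {self.fwhm_mm}")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        phantom_raw = raw.pop("phantom", {})
        known = {f for f in cls.__dataclass_fields__ if f != "phantom"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigFieldError(f"unknown run-config field(s): {sorted(unknown)}")
        try:
            cm = phantom_raw.pop("cognition_model", None)
            if isinstance(cm, dict):
                phantom_raw["cognition_model"] = CognitionModel(**cm)
            if "seed" not in phantom_raw:
                phantom_raw["seed"] = raw.get("seed", 0)
            phantom = PhantomConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in phantom_raw.items()})
        except TypeError as exc:
            raise ConfigFieldError(f"phantom: {exc}") from exc
        return cls(phantom=phantom, **raw)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, phantom=replace(self.phantom, seed=seed))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulation(config: RunConfig) -> Path:
    """Generate and write a phantom cohort; returns the data directory."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir) / "data"
    records, volumes, rois, truth = generate_cohort(config.phantom)
    manifest = write_cohort(outdir, config.phantom, records, volumes, rois, truth)
    logger.info("simulate: %d subjects, seed=%d, %.1fs -> %s",
                len(records), config.phantom.seed, time.perf_counter() - t0, outdir)
    logger.info("simulate: manifest sha256 count=%d", len(manifest["files"]))
    return outdir


def load_cohort(data_dir: str | Path) -> tuple[pd.DataFrame, dict[str, dict[str, ImageVolume | None]], ROISet]:
    """Read a cohort directory written by :func:`run_simulation`."""
    data_dir = Path(data_dir)
    cov = pd.read_csv(data_dir / "covariates.tsv", sep="\t")
    volumes: dict[str, dict[str, ImageVolume | None]] = {}
    for sid in cov["subject_id"]:
        nm_path = data_dir / f"nm_{sid}.nii.gz"
        pet_path = data_dir / f"pet_{sid}.nii.gz"
        volumes[sid] = {
            "nm": ImageVolume.load(nm_path),
            "pet": ImageVolume.load(pet_path) if pet_path.exists() else None,
        }
    masks = data_dir / "masks"
    rois = ROISet(
        search_roi_left=load_mask(masks / "search_roi_left.nii.gz"),
        search_roi_right=load_mask(masks / "search_roi_right.nii.gz"),
        background_roi=load_mask(masks / "background_roi.nii.gz"),
        brain_mask=load_mask(masks / "brain_mask.nii.gz"),
        reference_mask=load_mask(masks / "reference_mask.nii.gz") if (masks / "reference_mask.nii.gz").exists() else None,
        analysis_mask=load_mask(masks / "analysis_mask.nii.gz") if (masks / "analysis_mask.nii.gz").exists() else None,
    )
    return cov, volumes, rois


def validate_inputs(data_dir: str | Path) -> dict:
    """Check grid compatibility, mask disjointness and covariate schema.

    Problems are reported (not raised); ``report["ok"]`` is the verdict.
    """
    problems: list[str] = []
    try:
        cov, volumes, rois = load_cohort(data_dir)
    except (OSError, KeyError, ValueError) as exc:
        return {"ok": False, "problems": [f"cohort unreadable: {exc}"]}
    required = {"subject_id", "group", "age", "sex", "education_years", "moca_raw"}
    missing = required - set(cov.columns)
    if missing:
        problems.append(f"covariates.tsv missing columns: {sorted(missing)}")
    shapes = {v["nm"].shape for v in volumes.values()}
    if len(shapes) > 1:
        problems.append(f"neuromelanin volumes on mixed grids: {sorted(shapes)}")
    grid = next(iter(shapes)) if shapes else None
    if grid is not None:
        problems.extend(rois.validate(grid))
        for sid, v in volumes.items():
            if v["pet"] is not None and v["pet"].shape != grid:
                problems.append(f"PET volume for {sid} has shape {v['pet'].shape}, expected {grid}")
    return {"ok": not problems, "problems": problems, "n_subjects": len(cov)}


def run_quantification(config: RunConfig, cov: pd.DataFrame,
                       volumes: dict, rois: ROISet, outdir: Path) -> pd.DataFrame:
    """Per-subject LC contrast extraction; writes TSV + voxel audit JSON."""
    t0 = time.perf_counter()
    rows, audit = [], {}
    for sid in cov["subject_id"]:
        res = lc_quantification.quantify_subject(
            volumes[sid]["nm"], rois,
            connectivity=config.extract_connectivity,
            method=config.extraction_method,
            background_method=config.background_method,
            background_extent=config.background_extent,
        )
        rows.extend(res.to_records(subject_id=sid))
        for sub, val in res.averaged.items():
            rows.append({"subject_id": sid, "side": "avg", "subregion": sub,
                         "roi_mean": np.nan, "background_mean": np.nan,
                         "contrast": val, "flag": ""})
        audit[sid] = res.audit()
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "lc_contrasts.tsv", sep="\t", index=False)
    (outdir / "lc_contrast_audit.json").write_text(json.dumps(audit, indent=2, sort_keys=True))
    logger.info("quantify: %d subjects in %.1fs", cov.shape[0], time.perf_counter() - t0)
    return table


def contrast_matrix(contrasts: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table of averaged sub-regional contrasts + covariates."""
    avg = contrasts[contrasts["side"] == "avg"].pivot(
        index="subject_id", columns="subregion", values="contrast")
    merged = cov.set_index("subject_id").join(avg).reset_index()
    merged["moca_adjusted"] = [
        group_stats.adjust_moca(int(r), int(e))
        for r, e in zip(merged["moca_raw"], merged["education_years"])
    ]
    return merged


def run_group_stats(config: RunConfig, table: pd.DataFrame, outdir: Path) -> dict:
    """Omnibus + gated post hoc permutation tests, correlations, descriptives."""
    t0 = time.perf_counter()
    results: dict = {"seed": config.seed, "n_perm": config.n_perm, "regions": {}}
    groups = table["group"].to_numpy()
    age = table["age"].to_numpy(float)

    for sub in lc_quantification.SUBREGIONS:
        y = table[sub].to_numpy(float)
        omnibus = group_stats.permutation_ancova(
            y, groups, covariates=age, n_perm=config.n_perm, seed=config.seed)
        W, p_lev = group_stats.levene_test(y, groups)
        entry = {"omnibus": omnibus.to_dict(), "levene": {"W": W, "p": p_lev}}
        if omnibus.p_value < config.alpha or config.force_posthoc:
            posthocs = group_stats.posthoc_pairwise(
                y, groups, covariates=age, n_perm=config.n_perm,
                seed=config.seed, n_tests=config.posthoc_n_tests)
            entry["posthoc"] = [p.to_dict() for p in posthocs]
        else:
            entry["posthoc"] = None
            entry["posthoc_note"] = "omnibus not significant; post hocs skipped"
        results["regions"][sub] = entry

    results["descriptives"] = descriptives = group_stats.descriptive_tests(table)
    results["correlations"] = {}
    patients = table[table["group"] != "HC"]
    cohorts = {"patients": patients}
    for g in sorted(set(groups) - {"HC"}):
        cohorts[g] = table[table["group"] == g]
    for name, sub_table in cohorts.items():
        for region in lc_quantification.SUBREGIONS:
            r = group_stats.spearman_corr(
                sub_table[region].to_numpy(float),
                sub_table["moca_adjusted"].to_numpy(float))
            results["correlations"][f"{name}_{region}_vs_moca"] = {
                "rho": r.rho, "p": r.p_value, "n": r.n, "method": r.method}

    (outdir / "group_stats.json").write_text(json.dumps(results, indent=2, sort_keys=True, default=float))
    _write_report(results, descriptives, outdir / "report.txt")
    logger.info("group stats: seed=%d, %.1fs", config.seed, time.perf_counter() - t0)
    return results


def _write_report(results: dict, descriptives: dict, path: Path) -> None:
    lines = ["LC neuromelanin phantom analysis", "=" * 34, ""]
    lines.append("Sub-regional LC neuromelanin signal")
    for sub, entry in results["regions"].items():
        om = entry["omnibus"]
        lines.append(f"  {sub}: F({om['df'][0]:.0f},{om['df'][1]:.0f}) = {om['observed']:.2f}, "
                     f"p = {om['p_value']:.4f} ({om['n_perm']} permutations)")
        if entry["posthoc"]:
            for ph in entry["posthoc"]:
                lines.append(f"    {ph['contrast']}: t({ph['df']:.0f}) = {ph['observed']:.2f}, "
                             f"p = {ph['p_value']:.4f}, p_FWER = {ph['p_fwer']:.4f}")
        else:
            lines.append(f"    {entry['posthoc_note']}")
    lines.append("")
    lines.append("Spearman correlations with adjusted MoCA")
    for name, c in results["correlations"].items():
        lines.append(f"  {name}: rho = {c['rho']:.3f}, p = {c['p']:.4f} (n = {c['n']})")
    lines.append("")
    lines.append("Descriptives")
    for test, vals in descriptives["tests"].items():
        stat = {k: v for k, v in vals.items() if k != "p"}
        lines.append(f"  {test}: {stat}, p = {vals['p']:.3f}")
    path.write_text("\n".join(lines) + "\n")


def run_voxelwise(config: RunConfig, table: pd.DataFrame, volumes: dict,
                  rois: ROISet, outdir: Path) -> dict:
    """SUVR conversion, smoothing and cluster-FWE association maps."""
    t0 = time.perf_counter()
    if rois.reference_mask is None or rois.analysis_mask is None:
        raise ValueError("reference_mask and analysis_mask are required for voxel-wise analysis")
    pet_rows = table[[volumes[s]["pet"] is not None for s in table["subject_id"]]]
    if len(pet_rows) < 3:
        logger.warning("voxelwise: fewer than 3 PET subjects; skipping")
        return {}
    suvrs, affine = [], None
    for sid in pet_rows["subject_id"]:
        s = pet_suvr.compute_suvr(volumes[sid]["pet"], rois.reference_mask)
        s = pet_suvr.smooth_suvr(s, config.fwhm_mm)
        affine = s.volume.affine
        suvrs.append(s)

    out: dict = {}
    analyses = {
        "moca": (pet_rows["moca_adjusted"].to_numpy(float), config.cluster_forming_p),
        "rostral_lc": (pet_rows["rostral"].to_numpy(float), config.exploratory_cluster_p),
    }
    for name, (regressor, forming_p) in analyses.items():
        res = voxelwise_stats.cluster_fwe(
            suvrs, regressor, rois.analysis_mask,
            cluster_forming_p=forming_p, n_perm=config.n_perm,
            seed=config.seed, connectivity=config.cluster_connectivity,
            affine=affine, regressor_name=name,
        )
        res.table.to_csv(outdir / f"clusters_{name}.tsv", sep="\t", index=False)
        tvol = ImageVolume(np.nan_to_num(res.t_map.t), affine=affine)
        tvol.save(outdir / f"tmap_{name}.nii.gz")
        ImageVolume(res.labels.astype(float), affine=affine).save(outdir / f"clusterlabels_{name}.nii.gz")
        out[name] = {
            "n_clusters": int(len(res.table)),
            "t_crit": res.t_crit, "df": res.t_map.df,
            "n_perm": res.n_perm, "exhaustive": res.exhaustive,
            "table": res.table.to_dict(orient="records"),
        }
    (outdir / "voxelwise.json").write_text(json.dumps(out, indent=2, sort_keys=True, default=float))
    logger.info("voxelwise: %d PET subjects, %.1fs", len(pet_rows), time.perf_counter() - t0)
    return out


def run_analysis(config: RunConfig, data_dir: str | Path | None = None) -> Path:
    """Quantification + statistics (+ voxel-wise when PET data exist)."""
    outdir = Path(config.outdir) / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.outdir) / "data" if data_dir is None else Path(data_dir)
    report = validate_inputs(data_dir)
    if not report["ok"]:
        raise ValueError("input validation failed: " + "; ".join(report["problems"]))
    cov, volumes, rois = load_cohort(data_dir)
    contrasts = run_quantification(config, cov, volumes, rois, outdir)
    table = contrast_matrix(contrasts, cov)
    table.to_csv(outdir / "subject_table.tsv", sep="\t", index=False)
    run_group_stats(config, table, outdir)
    if any(v["pet"] is not None for v in volumes.values()):
        run_voxelwise(config, table, volumes, rois, outdir)
    return outdir


def run_all(config: RunConfig) -> Path:
    """Simulate a cohort and analyze it end-to-end."""
    data_dir = run_simulation(config)
    return run_analysis(config, data_dir)
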