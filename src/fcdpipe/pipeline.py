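"""End-to-end orchestration of the FCD group analysis.

Ties the stages together in the study's order: motion QC -> per-subject
preprocessing (nuisance regression, band-pass) -> FCD mapping (global /
short / long, rescaled, smoothed) -> covariate-adjusted voxel-wise group
GLM with Monte-Carlo cluster-extent correction -> seed-based connectivity
follow-up for every surviving cluster -> clinical partial correlations.
Two optional arms: mFD as an extra covariate, and global signal regression.

Every run writes a provenance record (config, seeds, package and library
versions) next to its outputs so results are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import associate_clusters, cluster_mean_fcd
from .core import BoldSeries, VolumeMask, save_volume
from .fcd import AdjacencySpec, FCDConfig, compute_subject_fcd
from .inference import (
    ClusterTable,
    adjacency_from_radius,
    build_design_matrix,
    cluster_extent_threshold,
    extract_clusters,
    fit_voxelwise_glm,
    simulate_null_cluster_distribution,
)
from .preprocess import compute_mfd, exclude_high_motion, make_gm_mask, preprocess_subject
from .seedfc import (
    AtlasVolume,
    SeedSpec,
    group_fc_comparison,
    label_clusters_with_atlas,
    subject_seed_zmap,
)
from .synthetic import SubjectRecord, cohort_table, generate_clinical_table

log = logging.getLogger("fcdpipe")

__all__ = ["RunConfig", "ConfigError", "StageError", "validate_config", "run_group_analysis"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        where = f"stage={stage}" + (f", subject={subject}" if subject else "")
        super().__init__(f"pipeline failed at {where}: {cause}")


@dataclass
class RunConfig:
    """All tunable parameters of a run, with the study's defaults."""

    out_dir: str = "fcd_run"
    r_threshold: float = 0.6
    mask_prob: float = 0.2
    band: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 6.0
    voxel_p: float = 0.01
    n_iterations: int = 5000
    radius_mm: float = 5.0
    alpha: float = 0.05
    n_discard: int = 10
    growing_adjacency: int = 26  # 6 | 18 | 26
    use_mfd_covariate: bool = False
    use_gsr: bool = False
    write_subject_maps: bool = False  # per-subject _gfcd/_sfcd/_lfcd NIfTI + sidecar
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Every violated invariant, as human-readable strings (empty = valid)."""
    v: list[str] = []
    if not (0 < config.mask_prob < 1):
        v.append(f"mask_prob={config.mask_prob} outside (0, 1)")
    lo, hi = config.band
    if not (0 <= lo < hi):
        v.append(f"band={config.band}: need 0 <= low < high")
    if hi > 0.25:  # Nyquist at TR = 2 s
        v.append(f"band upper {hi} Hz exceeds the 0.25 Hz Nyquist frequency at TR = 2 s")
    if not (0 < config.voxel_p < 1):
        v.append(f"voxel_p={config.voxel_p} outside (0, 1)")
    if not (0 < config.alpha < 1):
        v.append(f"alpha={config.alpha} outside (0, 1)")
    if config.n_iterations < 1:
        v.append("n_iterations must be >= 1")
    if config.fwhm_mm < 0:
        v.append("fwhm_mm must be non-negative")
    if not (0 < config.r_threshold < 1):
        v.append(f"r_threshold={config.r_threshold} outside (0, 1)")
    if config.n_discard < 0:
        v.append("n_discard must be non-negative")
    if config.growing_adjacency not in (6, 18, 26):
        v.append(f"growing_adjacency={config.growing_adjacency} not in (6, 18, 26)")
    if config.radius_mm <= 0:
        v.append("radius_mm must be positive")
    if config.seed is None:
        v.append("an explicit seed is required")
    return v


@dataclass
class RunResult:
    """Everything a run produced, in memory."""

    mask: VolumeMask
    qc: pd.DataFrame
    design_table: pd.DataFrame
    stat_maps: dict  # kind -> StatMap
    cluster_tables: dict  # kind -> ClusterTable
    extent_threshold: int
    seed_fc_tables: dict  # seed label -> ClusterTable
    associations: pd.DataFrame | None
    provenance: dict


def _provenance(config: RunConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "fcdpipe_version": __version__,
        "numpy_version": np.__version__,
    }


def run_group_analysis(
    config: RunConfig,
    records: list[SubjectRecord],
    gm_prob: np.ndarray,
    atlas: AtlasVolume | None = None,
    write: bool = True,
) -> RunResult:
    """Run the full analysis on an in-memory cohort.

    ``gm_prob`` is the gray-matter probability map on the cohort grid.
    Outputs (NIfTI maps, CSV tables, provenance JSON) land in
    ``config.out_dir`` unless ``write`` is False.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    vs = records[0].bold.voxel_size_mm

    # --- motion QC ------------------------------------------------------
    try:
        mfds = [
            (r.subject_id, compute_mfd(r.motion.discard_initial(config.n_discard)))
            for r in records
        ]
        kept_ids, excluded_ids, thr = exclude_high_motion(mfds)
    except Exception as e:  # noqa: BLE001
        raise StageError("motion_qc", None, e) from e
    qc = pd.DataFrame(mfds, columns=["subject_id", "mfd"])
    qc["excluded"] = qc["subject_id"].isin(excluded_ids)
    qc["threshold"] = thr
    kept = [r for r in records if r.subject_id in kept_ids]
    log.info("motion QC: kept %d / %d subjects (threshold %.4f)", len(kept), len(records), thr)

    # --- preprocessing + analysis mask ---------------------------------
    try:
        mask = make_gm_mask(gm_prob, config.mask_prob, vs)
    except Exception as e:  # noqa: BLE001
        raise StageError("gm_mask", None, e) from e
    cleaned: list[BoldSeries] = []
    for r in kept:
        try:
            cleaned.append(
                preprocess_subject(
                    r.bold,
                    r.motion,
                    n_discard=config.n_discard,
                    wm_mean=r.wm_series,
                    csf_mean=r.csf_series,
                    band=config.band,
                    use_gsr=config.use_gsr,
                    brain_mask=mask.mask,
                )
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("preprocess", r.subject_id, e) from e

    # --- per-subject FCD ------------------------------------------------
    fcd_cfg = FCDConfig(
        r_threshold=config.r_threshold,
        adjacency=AdjacencySpec.connectivity(config.growing_adjacency),
        fwhm_mm=config.fwhm_mm,
    )
    fcd_maps = []
    for r, bold in zip(kept, cleaned):
        try:
            maps = compute_subject_fcd(bold, mask, fcd_cfg)
            fcd_maps.append(maps)
            if write and config.write_subject_maps:
                maps.save(out / "subject_maps", r.subject_id, vs)
        except Exception as e:  # noqa: BLE001
            raise StageError("fcd_mapping", r.subject_id, e) from e

    # --- group inference -------------------------------------------------
    table = cohort_table(kept)
    table["mfd"] = [dict(mfds)[s] for s in table["subject_id"]]
    covs = ("age", "gender", "tiv") + (("mfd",) if config.use_mfd_covariate else ())
    try:
        design = build_design_matrix(table, covariates=covs)
        cluster_adj = adjacency_from_radius(vs, config.radius_mm)
        null = None
        cache = out / "null_distribution.json"
        if write and cache.exists():
            from .inference import NullClusterDistribution

            cached = NullClusterDistribution.from_json(cache)
            want = {
                "voxel_p": config.voxel_p,
                "n_iterations": config.n_iterations,
                "fwhm_mm": config.fwhm_mm,
                "adjacency": cluster_adj.derivation,
                "mask_hash": int(zlib.crc32(mask.mask.tobytes())),
                "seed": config.seed,
            }
            if cached.params == want:
                null = cached
                log.info("reusing cached null cluster distribution")
        if null is None:
            null = simulate_null_cluster_distribution(
                mask, config.fwhm_mm, config.voxel_p, config.n_iterations, cluster_adj,
                seed=config.seed,
            )
            if write:
                null.to_json(cache)
        k_min = cluster_extent_threshold(null, config.alpha)
    except Exception as e:  # noqa: BLE001
        raise StageError("group_inference", None, e) from e
    log.info("cluster extent threshold: %d voxels", k_min)

    stat_maps, cluster_tables = {}, {}
    for kind in ("sfcd", "lfcd"):
        maps = np.stack([m.named()[kind] for m in fcd_maps])
        stat = fit_voxelwise_glm(maps, design, mask)
        stat_maps[kind] = stat
        ctab = extract_clusters(stat, config.voxel_p, k_min, cluster_adj, mask)
        if atlas is not None:
            ctab = label_clusters_with_atlas(ctab, atlas)
        cluster_tables[kind] = ctab

    # --- seed-based follow-up --------------------------------------------
    seed_fc_tables: dict[str, ClusterTable] = {}
    for kind, ctab in cluster_tables.items():
        for c in ctab.clusters:
            label = f"{kind}_cluster{c.index}"
            try:
                seed = SeedSpec(c.mask, label)
                zmaps = [
                    subject_seed_zmap(b, seed, mask, config.fwhm_mm, r.subject_id)
                    for r, b in zip(kept, cleaned)
                ]
                tab = group_fc_comparison(
                    zmaps, design, mask, null, config.voxel_p, config.alpha, cluster_adj
                )
                if atlas is not None:
                    tab = label_clusters_with_atlas(tab, atlas)
                seed_fc_tables[label] = tab
            except Exception as e:  # noqa: BLE001
                raise StageError("seed_connectivity", label, e) from e

    # --- clinical association --------------------------------------------
    associations = None
    patients = [(r, m) for r, m in zip(kept, fcd_maps) if r.group == "patient"]
    sig = [
        (f"{kind}_cluster{c.index}", kind, c.mask)
        for kind, ctab in cluster_tables.items()
        for c in ctab.clusters
    ]
    n_controls = len(("age", "gender", "tiv")) + (1 if config.use_mfd_covariate else 0)
    if len(patients) <= n_controls + 2:
        if patients and sig:
            log.warning(
                "clinical association skipped: %d patients cannot support %d control variables",
                len(patients), n_controls,
            )
        sig = []
    if patients and sig:
        try:
            clin = generate_clinical_table([r for r, _ in patients])
            means = pd.DataFrame(
                {
                    name: [cluster_mean_fcd(m.named()[kind], cm) for _, m in patients]
                    for name, kind, cm in sig
                }
            )
            ctrl = ("age", "gender", "tiv") + (("mfd",) if config.use_mfd_covariate else ())
            if config.use_mfd_covariate:
                clin = clin.merge(qc[["subject_id", "mfd"]], on="subject_id")
            associations = associate_clusters(means, clin, controls=ctrl, alpha=config.alpha)
        except Exception as e:  # noqa: BLE001
            raise StageError("clinical_association", None, e) from e

    prov = _provenance(config)
    prov["extent_threshold_voxels"] = k_min
    prov["n_subjects_kept"] = len(kept)

    if write:
        qc.to_csv(out / "qc.csv", index=False)
        save_volume(mask.mask, vs, out / "gm_mask.nii.gz")
        for kind, stat in stat_maps.items():
            save_volume(stat.t_values, vs, out / f"tmap_{kind}.nii.gz")
            cluster_tables[kind].to_frame().to_csv(out / f"clusters_{kind}.csv", index=False)
        for label, tab in seed_fc_tables.items():
            tab.to_frame().to_csv(out / f"seedfc_{label}.csv", index=False)
        if associations is not None:
            associations.to_csv(out / "clinical_associations.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))

    return RunResult(
        mask=mask,
        qc=qc,
        design_table=table,
        stat_maps=stat_maps,
        cluster_tables=cluster_tables,
        extent_threshold=k_min,
        seed_fc_tables=seed_fc_tables,
        associations=associations,
        provenance=prov,
    )
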