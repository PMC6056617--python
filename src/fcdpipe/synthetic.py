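"""Synthetic resting-state cohorts with planted connectivity structure.

Every downstream stage is testable without external data: the generator
emulates the study conditions — two groups of ~35 subjects, 3 mm isotropic
grids, 230 retained volumes at TR = 2 s, spatially autocorrelated noise
(~6 mm FWHM) — and plants known connectivity: contiguous locally-coupled
blocks (short-range structure), remote coupled block pairs (long-range
structure), and group differences expressed as coupling multipliers.

Signal model per subject: every block b has a private shared signal
s_b(t) ~ N(0,1); a member voxel v of b gets

    y_v = w * s_b + sqrt(1 - w^2) * eps_v,      w = sqrt(rho_effective)

where eps_v is unit-variance (spatially smoothed, renormalized) Gaussian
noise and rho_effective = coupling * multiplier for the subject's group
(clipped to [0, 1]).  Two members of the same block then correlate at
w^2 = rho_effective in expectation.  Optional nuisance components (linear
drift, global signal, motion-linked artifact, WM/CSF physiological series)
are added on top and are what the preprocessing stage removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .clinical import progression_rate
from .core import BoldSeries, save_bold
from .fcd import FWHM_TO_SIGMA, AdjacencySpec
from .preprocess import MotionTrace

__all__ = [
    "BlockSpec",
    "CohortSpec",
    "SubjectRecord",
    "cube_block",
    "remote_pair_block",
    "generate_cohort",
    "generate_motion_trace",
    "generate_clinical_table",
    "cohort_table",
    "synthetic_gm_prob",
    "write_cohort",
]

# covariate distributions (plausible ranges for an ALS cohort; recorded in
# the manifest so tests read them from here instead of hard-coding)
COVARIATE_MODEL = {
    "age": {"dist": "truncnorm", "mean": 49.0, "sd": 10.0, "lo": 20.0, "hi": 80.0},
    "tiv": {"dist": "normal", "mean": 1.6, "sd": 0.16},
    "gender": {"dist": "balanced", "levels": ["M", "F"]},
    "alsfrs_r": {"dist": "truncnorm", "mean": 30.44, "sd": 6.77, "lo": 0, "hi": 48},
    "duration_months": {"dist": "lognormal", "mean": 22.89, "sd": 18.06},
}


@dataclass
class BlockSpec:
    """A planted coupled voxel set.

    ``contiguous_local`` blocks form one connected component (short-range
    structure); ``remote_pair`` blocks are two components separated beyond
    the adjacency radius (long-range structure).  ``coupling`` is the target
    pairwise correlation between members under the shared-signal model.
    """

    id: str
    member_voxels: np.ndarray  # (n, 3) integer voxel indices
    kind: str = "contiguous_local"
    coupling: float = 0.9

    def __post_init__(self) -> None:
        self.member_voxels = np.atleast_2d(np.asarray(self.member_voxels, dtype=int))
        if self.member_voxels.shape[1] != 3:
            raise ValueError("member_voxels must be (n, 3) indices")
        if self.kind not in ("contiguous_local", "remote_pair"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must lie in [0, 1]")

    def n_components(self, adjacency: AdjacencySpec | None = None) -> int:
        adjacency = adjacency or AdjacencySpec.connectivity(26)
        lo = self.member_voxels.min(axis=0)
        shape = self.member_voxels.max(axis=0) - lo + 1
        sub = np.zeros(shape, dtype=bool)
        sub[tuple((self.member_voxels - lo).T)] = True
        _, n = ndimage.label(sub, structure=adjacency.structure())
        return int(n)


def cube_block(block_id: str, corner, size: int, coupling: float) -> BlockSpec:
    """Contiguous cubic block of ``size``^3 voxels with its low corner at
    ``corner``."""
    c = np.asarray(corner, dtype=int)
    pts = np.array(
        [c + (i, j, k) for i in range(size) for j in range(size) for k in range(size)]
    )
    return BlockSpec(block_id, pts, "contiguous_local", coupling)


def remote_pair_block(
    block_id: str, corner_a, corner_b, size: int, coupling: float
) -> BlockSpec:
    """Two coupled cubic halves at distant corners (long-range structure)."""
    a = cube_block("a", corner_a, size, coupling).member_voxels
    b = cube_block("b", corner_b, size, coupling).member_voxels
    return BlockSpec(block_id, np.vstack([a, b]), "remote_pair", coupling)


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    n_per_group: int = 35
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_volumes: int = 230
    tr_s: float = 2.0
    noise_fwhm_mm: float = 6.0
    blocks: list[BlockSpec] = field(default_factory=list)
    group_effects: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    drift_amplitude: float = 0.0
    global_amplitude: float = 0.0
    motion_artifact_amplitude: float = 0.0
    physio_amplitude: float = 0.0
    motion_step_sd_mm: float = 0.02

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes < 20:
            raise ValueError("need at least 20 volumes")
        if self.noise_fwhm_mm < 0:
            raise ValueError("noise FWHM must be non-negative")
        grid = np.asarray(self.grid_shape, dtype=int)
        seen: dict[tuple[int, int, int], str] = {}
        for blk in self.blocks:
            if (blk.member_voxels < 0).any() or (blk.member_voxels >= grid).any():
                raise ValueError(f"block {blk.id!r} extends outside the grid")
            want = 1 if blk.kind == "contiguous_local" else 2
            if blk.n_components() != want:
                raise ValueError(
                    f"block {blk.id!r} ({blk.kind}) must have {want} connected component(s)"
                )
            for p in map(tuple, blk.member_voxels):
                if p in seen:
                    raise ValueError(
                        f"blocks {seen[p]!r} and {blk.id!r} overlap at voxel {p}: "
                        "contradictory couplings"
                    )
                seen[p] = blk.id
        ids = {b.id for b in self.blocks}
        for bid, grp, mult in self.group_effects:
            if bid not in ids:
                raise ValueError(f"group effect references unknown block {bid!r}")
            if grp not in ("patient", "control"):
                raise ValueError(f"unknown group {grp!r}")
            if mult < 0:
                raise ValueError("coupling multipliers must be >= 0")

    def effective_coupling(self, block: BlockSpec, group: str) -> float:
        rho = block.coupling
        for bid, grp, mult in self.group_effects:
            if bid == block.id and grp == group:
                rho = rho * mult
        return min(rho, 1.0)


@dataclass
class SubjectRecord:
    """One synthetic subject: BOLD data, motion, covariates, clinical scores."""

    subject_id: str
    group: str  # "patient" | "control"
    bold: BoldSeries
    motion: MotionTrace
    age: float
    gender: str
    tiv: float
    alsfrs_r: int | None = None
    duration_months: float | None = None
    wm_series: np.ndarray | None = None
    csf_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group == "patient":
            if self.alsfrs_r is None or self.duration_months is None:
                raise ValueError("patients must carry ALSFRS-R and disease duration")
        elif self.group == "control":
            if self.alsfrs_r is not None or self.duration_months is not None:
                raise ValueError("controls carry no clinical fields")
        else:
            raise ValueError(f"unknown group {self.group!r}")


def _noise_norm(sigma_vox: np.ndarray, shape) -> float:
    """L2 norm of the Gaussian smoothing kernel: the factor by which white
    noise variance shrinks under smoothing (computed from an impulse)."""
    imp = np.zeros(shape)
    imp[tuple(np.asarray(shape) // 2)] = 1.0
    k = ndimage.gaussian_filter(imp, sigma=sigma_vox, mode="constant")
    return float(np.sqrt((k**2).sum()))


def _smoothed_noise(rng, shape, n_volumes: int, sigma_vox: np.ndarray) -> np.ndarray:
    noise = rng.standard_normal((*shape, n_volumes))
    if np.all(sigma_vox == 0):
        return noise
    noise = ndimage.gaussian_filter(noise, sigma=(*sigma_vox, 0.0), mode="wrap")
    return noise / _noise_norm(sigma_vox, shape)


def _truncnorm(rng, mean, sd, lo, hi) -> float:
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def generate_motion_trace(n_volumes: int, step_sd_mm: float, seed: int) -> MotionTrace:
    """Random-walk rigid-body motion: translation increments N(0, step_sd_mm)
    in mm, rotation increments N(0, step_sd_mm / 50) in radians (so both
    contribute comparably to frame-wise displacement on a 50 mm sphere)."""
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if step_sd_mm < 0:
        raise ValueError("step sd must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes - 1, 6))
    steps[:, :3] *= step_sd_mm
    steps[:, 3:] *= step_sd_mm / 50.0
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(params)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Deterministically generate the cohort described by ``spec``.

    Controls are generated first, then patients; all randomness flows from
    a single generator seeded with ``spec.seed`` (two calls with the same
    spec are bit-identical).
    """
    rng = np.random.default_rng(spec.seed)
    sigma_vox = (
        spec.noise_fwhm_mm * FWHM_TO_SIGMA / np.asarray(spec.voxel_size_mm, dtype=float)
    )
    T = spec.n_volumes
    trend = np.linspace(-1.0, 1.0, T)
    records: list[SubjectRecord] = []
    for group in ("control", "patient"):
        for i in range(spec.n_per_group):
            sid = f"{group[:3]}{i:03d}"
            data = _smoothed_noise(rng, spec.grid_shape, T, sigma_vox)
            for blk in spec.blocks:
                w = np.sqrt(spec.effective_coupling(blk, group))
                s = rng.standard_normal(T)
                vox = tuple(blk.member_voxels.T)
                data[vox] = w * s + np.sqrt(1.0 - w * w) * data[vox]
            wm = rng.standard_normal(T)
            csf = rng.standard_normal(T)
            motion = generate_motion_trace(
                T, spec.motion_step_sd_mm, int(rng.integers(2**31))
            )
            if spec.drift_amplitude > 0:
                coef = rng.standard_normal(spec.grid_shape)
                data += spec.drift_amplitude * coef[..., None] * trend
            if spec.global_amplitude > 0:
                data += spec.global_amplitude * rng.standard_normal(T)
            if spec.motion_artifact_amplitude > 0:
                mix = motion.params @ rng.standard_normal(6)
                coef = rng.standard_normal(spec.grid_shape)
                data += spec.motion_artifact_amplitude * coef[..., None] * mix
            if spec.physio_amplitude > 0:
                cw = rng.standard_normal(spec.grid_shape)
                cc = rng.standard_normal(spec.grid_shape)
                data += spec.physio_amplitude * (cw[..., None] * wm + cc[..., None] * csf)
            age = _truncnorm(rng, **{k: COVARIATE_MODEL["age"][k] for k in ("mean", "sd", "lo", "hi")})
            gender = COVARIATE_MODEL["gender"]["levels"][i % 2]
            tiv = float(rng.normal(COVARIATE_MODEL["tiv"]["mean"], COVARIATE_MODEL["tiv"]["sd"]))
            alsfrs = duration = None
            if group == "patient":
                alsfrs = int(round(_truncnorm(rng, 30.44, 6.77, 0, 48)))
                mu, sd = COVARIATE_MODEL["duration_months"]["mean"], COVARIATE_MODEL["duration_months"]["sd"]
                s2 = np.log(1.0 + (sd / mu) ** 2)
                duration = float(rng.lognormal(np.log(mu) - s2 / 2.0, np.sqrt(s2)))
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    bold=BoldSeries(data, spec.voxel_size_mm, spec.tr_s, "synthetic"),
                    motion=motion,
                    age=age,
                    gender=gender,
                    tiv=tiv,
                    alsfrs_r=alsfrs,
                    duration_months=duration,
                    wm_series=wm,
                    csf_series=csf,
                )
            )
    return records


def generate_clinical_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Per-patient clinical table with the computed progression rate."""
    pats = [r for r in records if r.group == "patient"]
    if not pats:
        raise ValueError("no patients in cohort")
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in pats],
            "alsfrs_r": [r.alsfrs_r for r in pats],
            "duration_months": [r.duration_months for r in pats],
            "age": [r.age for r in pats],
            "gender": [r.gender for r in pats],
            "tiv": [r.tiv for r in pats],
        }
    )
    df["progression_rate"] = progression_rate(
        df["alsfrs_r"].to_numpy(), df["duration_months"].to_numpy()
    )
    return df


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Covariate table for all subjects (design-matrix input); clinical
    columns are NaN for controls."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "tiv": [r.tiv for r in records],
            "alsfrs_r": [r.alsfrs_r for r in records],
            "duration_months": [r.duration_months for r in records],
        }
    )


def synthetic_gm_prob(
    grid_shape, semiaxes_vox=None, inside: float = 0.9, outside: float = 0.05
) -> np.ndarray:
    """Ellipsoidal gray-matter probability map on the grid (probability
    ``inside`` within the ellipsoid, ``outside`` beyond); with the 20%
    threshold this yields an ellipsoidal analysis mask."""
    shape = np.asarray(grid_shape, dtype=int)
    if semiaxes_vox is None:
        semiaxes_vox = (shape - 1) / 2.4
    center = (shape - 1) / 2.0
    ax = np.asarray(semiaxes_vox, dtype=float)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, ax))
    return np.where(d2 <= 1.0, inside, outside)


def write_cohort(records: list[SubjectRecord], spec: CohortSpec, outdir) -> Path:
    """Write per-subject 4D NIfTI + SPM-dialect rp_*.txt motion files plus a
    cohort manifest (CSV + JSON documenting generator parameters and the
    coupling mapping rho = coupling * multiplier, w = sqrt(rho))."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for r in records:
        save_bold(r.bold, out / f"{r.subject_id}_bold.nii.gz")
        r.motion.to_file(out / f"rp_{r.subject_id}.txt")
    cohort_table(records).to_csv(out / "cohort.csv", index=False)
    manifest = {
        "n_per_group": spec.n_per_group,
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "n_volumes": spec.n_volumes,
        "tr_s": spec.tr_s,
        "noise_fwhm_mm": spec.noise_fwhm_mm,
        "seed": spec.seed,
        "coupling_model": "y = w*s + sqrt(1-w^2)*eps, w = sqrt(coupling*multiplier)",
        "blocks": [
            {"id": b.id, "kind": b.kind, "coupling": b.coupling, "n_voxels": len(b.member_voxels)}
            for b in spec.blocks
        ],
        "group_effects": [list(g) for g in spec.group_effects],
        "covariate_model": COVARIATE_MODEL,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
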