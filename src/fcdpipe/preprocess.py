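"""Per-subject temporal cleanup and motion quality control.

The pipeline assumes spatially aligned, normalized 4D data and performs, in
fixed order: discarding of initial volumes, motion QC via mean frame-wise
displacement (mFD), nuisance regression (white matter, CSF, six rigid-body
motion parameters, linear drift, optionally the global mean signal), and
0.01-0.08 Hz band-pass filtering.

mFD follows the Power convention: per volume-to-volume transition, the sum
of absolute backward differences of the six parameters, with the three
rotations converted to arc length on a 50 mm sphere; mFD is the mean over
transitions.  The band-pass is an ideal (boxcar) frequency-domain filter,
which is exactly idempotent and has assertable pass/stop gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoldSeries, VolumeMask

__all__ = [
    "MotionTrace",
    "NuisanceSet",
    "discard_initial_volumes",
    "compute_mfd",
    "exclude_high_motion",
    "build_nuisance_set",
    "regress_nuisance",
    "bandpass",
    "make_gm_mask",
    "preprocess_subject",
]

MFD_SPHERE_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """t x 6 rigid-body motion parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(f"motion trace must have 6 columns, got {self.params.shape[1]}")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def discard_initial(self, n: int) -> "MotionTrace":
        return MotionTrace(self.params[n:])

    @classmethod
    def from_file(cls, path) -> "MotionTrace":
        """Read a 6-column whitespace-delimited SPM rp_*.txt file."""
        return cls(np.loadtxt(str(path)))

    def to_file(self, path) -> None:
        np.savetxt(str(path), self.params, fmt="%.8e")


@dataclass
class NuisanceSet:
    """Design of nuisance regressors: t x k matrix plus column labels."""

    regressors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("one label per regressor column required")
        if self.regressors.shape[1] >= self.regressors.shape[0]:
            raise ValueError("more regressors than time points")
        norms = np.abs(self.regressors).max(axis=0)
        zero = [lbl for lbl, nz in zip(self.labels, norms == 0) if nz]
        if zero:
            raise ValueError(f"all-zero nuisance columns: {zero}")


def discard_initial_volumes(bold: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (signal-equilibration period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= bold.n_volumes:
        raise ValueError(f"cannot discard {n} of {bold.n_volumes} volumes")
    if n == 0:
        return bold
    return bold.with_data(bold.data[..., n:])


def compute_mfd(motion: MotionTrace, sphere_radius_mm: float = MFD_SPHERE_RADIUS_MM) -> float:
    """Mean frame-wise displacement of a motion trace.

    FD at transition i is sum_j |d_ij - d_(i-1)j| over the six parameters,
    with rotations mapped to arc length on a sphere of ``sphere_radius_mm``.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("mFD needs at least 2 volumes")
    d = np.abs(np.diff(p, axis=0))
    d[:, 3:] *= sphere_radius_mm
    return float(d.sum(axis=1).mean())


def exclude_high_motion(
    mfds: list[tuple[str, float]],
) -> tuple[list[str], list[str], float]:
    """Flag subjects whose mFD is strictly above group mean + 2 * sample SD.

    Returns ``(kept_ids, excluded_ids, threshold)``.
    """
    if len(mfds) < 2:
        raise ValueError("motion exclusion needs at least 2 subjects")
    ids = [s for s, _ in mfds]
    vals = np.array([v for _, v in mfds], dtype=float)
    threshold = float(vals.mean() + 2.0 * vals.std(ddof=1))
    excluded = [s for s, v in zip(ids, vals) if v > threshold]
    kept = [s for s in ids if s not in excluded]
    return kept, excluded, threshold


def build_nuisance_set(
    n_volumes: int,
    motion: MotionTrace | None = None,
    wm_mean: np.ndarray | None = None,
    csf_mean: np.ndarray | None = None,
    global_mean: np.ndarray | None = None,
) -> NuisanceSet:
    """Assemble the standard nuisance design: WM, CSF, motion 1-6, linear
    drift, intercept, and (with global signal regression) the global mean."""
    cols, labels = [], []
    if wm_mean is not None:
        cols.append(np.asarray(wm_mean, float))
        labels.append("wm_mean")
    if csf_mean is not None:
        cols.append(np.asarray(csf_mean, float))
        labels.append("csf_mean")
    if motion is not None:
        if motion.n_volumes != n_volumes:
            raise ValueError("motion trace length does not match volume count")
        for j in range(6):
            cols.append(motion.params[:, j])
            labels.append(f"motion{j + 1}")
    cols.append(np.linspace(-1.0, 1.0, n_volumes))
    labels.append("linear_drift")
    cols.append(np.ones(n_volumes))
    labels.append("intercept")
    if global_mean is not None:
        cols.append(np.asarray(global_mean, float))
        labels.append("global_mean")
    for c in cols:
        if c.shape != (n_volumes,):
            raise ValueError("nuisance column length does not match volume count")
    return NuisanceSet(np.column_stack(cols), labels)


def regress_nuisance(bold: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Replace every voxel series by its least-squares residual against the
    nuisance design.  Residuals are orthogonal to each regressor column."""
    X = nuisance.regressors
    t = bold.n_volumes
    if X.shape[0] != t:
        raise ValueError(f"nuisance rows ({X.shape[0]}) != volumes ({t})")
    labels = list(nuisance.labels)
    if "intercept" not in labels:
        X = np.column_stack([X, np.ones(t)])
        labels.append("intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pinpoint offending columns via incremental rank
        bad, r_prev = [], 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == r_prev:
                bad.append(labels[j])
            r_prev = r
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    Y = bold.data.reshape(-1, t).T  # t x nvox
    beta = np.linalg.solve(X.T @ X, X.T @ Y)  # full rank guaranteed above
    resid = Y - X @ beta
    return bold.with_data(resid.T.reshape(bold.data.shape))


def bandpass(bold: BoldSeries, f_lo: float = 0.01, f_hi: float = 0.08) -> BoldSeries:
    """Ideal frequency-domain band-pass: discrete frequencies f with
    f_lo <= f <= f_hi are retained, all others zeroed (DC drops whenever
    f_lo > 0).  Exactly idempotent."""
    if not (0 <= f_lo < f_hi):
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > bold.nyquist_hz + 1e-12:
        raise ValueError(f"f_hi={f_hi} Hz exceeds Nyquist {bold.nyquist_hz} Hz (TR={bold.tr_s}s)")
    t = bold.n_volumes
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    return bold.with_data(np.fft.irfft(spec, n=t, axis=-1))


def make_gm_mask(
    prob_map: np.ndarray,
    threshold: float = 0.2,
    voxel_size_mm=(3.0, 3.0, 3.0),
) -> VolumeMask:
    """Gray-matter analysis mask: voxels with tissue probability strictly
    greater than ``threshold`` (default 20%)."""
    prob = np.asarray(prob_map, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("gray-matter probabilities must lie in [0, 1]")
    return VolumeMask(prob > threshold, voxel_size_mm)


def preprocess_subject(
    bold: BoldSeries,
    motion: MotionTrace,
    n_discard: int = 10,
    wm_mean: np.ndarray | None = None,
    csf_mean: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    use_gsr: bool = False,
    brain_mask: np.ndarray | None = None,
) -> BoldSeries:
    """Fixed-order driver: discard -> nuisance regression -> band-pass.

    With ``use_gsr`` the mean series over ``brain_mask`` (whole grid if None)
    after discarding is appended to the nuisance design.
    """
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace and BOLD series must cover the same volumes")
    t_full = bold.n_volumes
    bold = discard_initial_volumes(bold, n_discard)
    motion = motion.discard_initial(n_discard)

    def _trim(series):
        if series is None:
            return None
        series = np.asarray(series, float)
        return series[n_discard:] if series.shape[0] == t_full else series

    wm_mean, csf_mean = _trim(wm_mean), _trim(csf_mean)
    gmean = None
    if use_gsr:
        if brain_mask is None:
            gmean = bold.data.reshape(-1, bold.n_volumes).mean(axis=0)
        else:
            gmean = bold.data[np.asarray(brain_mask, bool)].mean(axis=0)
    nuis = build_nuisance_set(bold.n_volumes, motion, wm_mean, csf_mean, gmean)
    bold = regress_nuisance(bold, nuis)
    return bandpass(bold, *band)
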