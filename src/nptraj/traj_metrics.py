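"""Conformational-state metrics over trajectories.

Superposition (Kabsch), RMSD/RMSF, Shrake-Rupley SASA, centre-of-mass
distances, inter-selection contact counts, PCA of pooled coordinates,
moving-average smoothing and phase statistics. Distances are nm, areas nm²,
times ns throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigError,
    DegenerateFitError,
    InsufficientFramesError,
    SelectionError,
)
from .md_io import Selection, Trajectory

__all__ = [
    "MetricSeries",
    "PhaseSummary",
    "DEFAULT_VDW_RADII_NM",
    "kabsch_align",
    "rmsd_series",
    "rmsf_profile",
    "com_distance_series",
    "contact_count_series",
    "sasa_series",
    "residue_sasa",
    "shrake_rupley_sasa",
    "pca_project",
    "moving_average",
    "phase_statistics",
]

#: Bondi-style van der Waals radii in nm, including gold for nanoparticle
#: surfaces. Override per analysis through the ``radii`` argument.
DEFAULT_VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
    "AU": 0.166,
    "NA": 0.227,
    "CL": 0.175,
}


@dataclass
class MetricSeries:
    """A per-frame scalar metric with optional smoothing provenance."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    smoothing_window_ns: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ConfigError("MetricSeries times and values must align")


@dataclass
class PhaseSummary:
    """Pooled mean/SD of metrics inside consecutive time phases."""

    boundaries_ns: list[tuple[float, float]]
    stats: dict[str, list[tuple[float, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _check_fit_atoms(x: np.ndarray):
    if x.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def kabsch_transform(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping mobile onto reference.

    Rotation is computed by SVD of the cross-covariance with reflection
    correction, so ``det(R) = +1`` always.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    _check_fit_atoms(mobile)
    _check_fit_atoms(reference)
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    h = (mobile - mu_m).T @ (reference - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_r - rot @ mu_m
    return rot, t


def kabsch_align(mobile_frame: np.ndarray, reference_frame: np.ndarray,
                 fit_selection_idx: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align a full frame to a reference using the fit atoms only.

    Returns (aligned_frame, rotation, translation); the transform is applied
    to every atom of ``mobile_frame``.
    """
    idx = np.asarray(fit_selection_idx, dtype=int)
    rot, t = kabsch_transform(mobile_frame[idx], reference_frame[idx])
    return mobile_frame @ rot.T + t, rot, t


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference_frame: np.ndarray,
                fit_selection: Selection, measure_selection: Selection,
                label: str = "rmsd") -> MetricSeries:
    """Per-frame RMSD of the measure atoms after fitting on the fit atoms."""
    fit_idx = fit_selection.resolve_nonempty(traj.topology)
    meas_idx = measure_selection.resolve_nonempty(traj.topology)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        aligned, _, _ = kabsch_align(traj.coords[f], reference_frame, fit_idx)
        out[f] = _rmsd(aligned[meas_idx], reference_frame[meas_idx])
    return MetricSeries(traj.times.copy(), out, label=label)


def _aligned_coords(traj: Trajectory, fit_idx: np.ndarray) -> np.ndarray:
    """Align every frame to the mean structure (one iterative-fit pass):
    fit to frame 0, average, then re-fit all frames to that average."""
    coords = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        coords[f], _, _ = kabsch_align(traj.coords[f], traj.coords[0], fit_idx)
    mean = coords.mean(axis=0)
    for f in range(traj.n_frames):
        coords[f], _, _ = kabsch_align(traj.coords[f], mean, fit_idx)
    return coords


def rmsf_profile(traj: Trajectory, fit_selection: Selection,
                 measure_selection: Selection
                 ) -> dict[tuple[str, int], float]:
    """Per-residue RMSF (nm) about the time-mean position after alignment.

    Atom RMSF is sqrt(<|x - <x>|²>) over frames; the residue value is the
    mean over that residue's atoms within the measure selection.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF requires at least 2 frames")
    fit_idx = fit_selection.resolve_nonempty(traj.topology)
    meas_idx = measure_selection.resolve_nonempty(traj.topology)
    coords = _aligned_coords(traj, fit_idx)
    mean = coords.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    per_res: dict[tuple[str, int], list[float]] = {}
    for i in meas_idx:
        rec = traj.topology[i]
        per_res.setdefault((rec.chain_id, rec.residue_id), []).append(atom_rmsf[i])
    return {k: float(np.mean(v)) for k, v in per_res.items()}


# ---------------------------------------------------------------------------
# Distances and contacts
# ---------------------------------------------------------------------------

def _centroid(coords: np.ndarray, idx: np.ndarray,
              weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return coords[idx].mean(axis=0)
    w = weights[idx]
    return (coords[idx] * w[:, None]).sum(axis=0) / w.sum()


def com_distance_series(traj: Trajectory, selection_a: Selection,
                        selection_b: Selection, mass_weighted: bool = False,
                        label: str = "com_distance") -> MetricSeries:
    """Per-frame distance between the (optionally mass-weighted) centroids."""
    ia = selection_a.resolve_nonempty(traj.topology)
    ib = selection_b.resolve_nonempty(traj.topology)
    w = traj.masses() if mass_weighted else None
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = np.linalg.norm(_centroid(traj.coords[f], ia, w)
                                - _centroid(traj.coords[f], ib, w))
    return MetricSeries(traj.times.copy(), out, label=label)


def contact_count_series(traj: Trajectory, selection_a: Selection,
                         selection_b: Selection, cutoff_nm: float,
                         label: str = "contacts") -> MetricSeries:
    """Number of inter-residue atom pairs (a in A, b in B) closer than the
    cutoff per frame. Pairs of identical atoms and pairs within one residue
    are excluded, which matters only for overlapping selections."""
    if cutoff_nm <= 0:
        raise ConfigError("cutoff must be positive")
    ia = selection_a.resolve(traj.topology)
    ib = selection_b.resolve(traj.topology)
    res_key = np.array([hash((r.chain_id, r.residue_id))
                        for r in traj.topology])
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if ia.size == 0 or ib.size == 0:
            out[f] = 0
            continue
        tree = cKDTree(traj.coords[f][ib])
        pairs = tree.query_ball_point(traj.coords[f][ia], cutoff_nm)
        n = 0
        for k, hits in enumerate(pairs):
            a = ia[k]
            for h in hits:
                b = ib[h]
                if a == b or res_key[a] == res_key[b]:
                    continue
                # strict inequality at the cutoff
                if np.linalg.norm(traj.coords[f][a] - traj.coords[f][b]) < cutoff_nm:
                    n += 1
        out[f] = n
    return MetricSeries(traj.times.copy(), out, label=label)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe_radius_nm: float = 0.14,
                       n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (nm²).

    Rolls a probe sphere over each atom's van der Waals sphere: test points
    on the expanded sphere (r + probe) count as accessible when inside no
    neighbouring expanded sphere. Exact additivity over atoms holds by
    construction, so per-residue sums equal the total.
    """
    if n_sphere_points < 100:
        raise ConfigError("n_sphere_points must be >= 100")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius_nm
    sphere = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                 if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def _atom_radii(traj: Trajectory, idx: np.ndarray,
                radii: dict[str, float]) -> np.ndarray:
    out = np.empty(idx.size)
    for k, i in enumerate(idx):
        el = traj.topology[i].element.upper()
        if el not in radii:
            raise ConfigError(f"no van der Waals radius configured for {el!r}")
        out[k] = radii[el]
    return out


def sasa_series(traj: Trajectory, selection: Selection,
                probe_radius_nm: float = 0.14, n_sphere_points: int = 960,
                radii: dict[str, float] | None = None,
                label: str = "sasa") -> MetricSeries:
    """Total SASA (nm²) of the selection per frame."""
    idx = selection.resolve_nonempty(traj.topology)
    r = _atom_radii(traj, idx, radii or DEFAULT_VDW_RADII_NM)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = shrake_rupley_sasa(traj.coords[f][idx], r, probe_radius_nm,
                                    n_sphere_points).sum()
    return MetricSeries(traj.times.copy(), out, label=label)


def residue_sasa(traj: Trajectory, selection: Selection, frame: int,
                 probe_radius_nm: float = 0.14, n_sphere_points: int = 960,
                 radii: dict[str, float] | None = None
                 ) -> dict[tuple[str, int], float]:
    """Per-residue SASA (nm²) of one frame; values sum to the frame total."""
    idx = selection.resolve_nonempty(traj.topology)
    r = _atom_radii(traj, idx, radii or DEFAULT_VDW_RADII_NM)
    atom_areas = shrake_rupley_sasa(traj.coords[frame][idx], r,
                                    probe_radius_nm, n_sphere_points)
    per_res: dict[tuple[str, int], float] = {}
    for k, i in enumerate(idx):
        rec = traj.topology[i]
        key = (rec.chain_id, rec.residue_id)
        per_res[key] = per_res.get(key, 0.0) + float(atom_areas[k])
    return per_res


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_project(trajs: list[Trajectory], fit_selection: Selection,
                heavy_atoms_only: bool = True
                ) -> tuple[list[np.ndarray], np.ndarray]:
    """Project pooled frames onto the top-2 principal components of the
    coordinate covariance.

    Frames from all replicates are aligned (one iterative-fit pass to the
    pooled mean) before the covariance is formed. Returns per-trajectory
    projection arrays of shape (n_frames, 2) and the explained-variance
    fractions of the two components.
    """
    if not trajs:
        raise ConfigError("at least one trajectory required")
    topo = trajs[0].topology
    for t in trajs[1:]:
        if [(r.chain_id, r.residue_id, r.atom_name) for r in t.topology] != \
           [(r.chain_id, r.residue_id, r.atom_name) for r in topo]:
            raise ConfigError("all trajectories must share a topology")
    fit_idx = fit_selection.resolve_nonempty(topo)
    if heavy_atoms_only:
        fit_idx = np.array([i for i in fit_idx
                            if topo[i].element.upper() != "H"], dtype=int)
        if fit_idx.size == 0:
            raise SelectionError("no heavy atoms in fit selection")
    pooled = np.concatenate([t.coords for t in trajs], axis=0)
    if pooled.shape[0] < 2:
        raise InsufficientFramesError("PCA requires at least 2 frames")
    aligned = np.empty((pooled.shape[0], fit_idx.size, 3))
    for f in range(pooled.shape[0]):
        fr, _, _ = kabsch_align(pooled[f], pooled[0], fit_idx)
        aligned[f] = fr[fit_idx]
    mean = aligned.mean(axis=0)
    for f in range(aligned.shape[0]):
        rot, tr = kabsch_transform(aligned[f], mean)
        aligned[f] = aligned[f] @ rot.T + tr
    flat = aligned.reshape(aligned.shape[0], -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    explained = (evals[:2] / total) if total > 0 else np.zeros(2)
    proj = centered @ evecs[:, :2]
    out, k = [], 0
    for t in trajs:
        out.append(proj[k:k + t.n_frames])
        k += t.n_frames
    return out, explained


# ---------------------------------------------------------------------------
# Smoothing and phase statistics
# ---------------------------------------------------------------------------

def moving_average(series: MetricSeries, window_ns: float) -> MetricSeries:
    """Centered running mean over all samples within ±window/2 in time.

    Length-preserving; edge samples average over the truncated window. A
    window narrower than the sampling interval returns the series unchanged.
    """
    if window_ns <= 0:
        raise ConfigError("window must be positive")
    t, v = series.times, series.values
    half = window_ns / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return MetricSeries(t.copy(), out, label=series.label,
                        smoothing_window_ns=window_ns)


def phase_statistics(series_per_replicate: dict[str, list[MetricSeries]] |
                     list[list[MetricSeries]],
                     boundaries_ns: list[tuple[float, float]] | None = None
                     ) -> PhaseSummary:
    """Pooled mean and population SD per phase, across replicates.

    ``series_per_replicate`` maps metric label -> list of per-replicate
    series (or a list of such lists). Default phases are 0-750 ns and
    750-2000 ns, the extended and compact intervals.
    """
    if boundaries_ns is None:
        boundaries_ns = [(0.0, 750.0), (750.0, 2000.0)]
    if isinstance(series_per_replicate, list):
        series_per_replicate = {
            (reps[0].label or f"metric_{k}"): reps
            for k, reps in enumerate(series_per_replicate)
        }
    summary = PhaseSummary(boundaries_ns=list(boundaries_ns))
    for label, reps in series_per_replicate.items():
        if not reps:
            raise ConfigError("each metric needs at least one replicate")
        stats = []
        for k, (lo, hi) in enumerate(boundaries_ns):
            last = k == len(boundaries_ns) - 1
            pooled = np.concatenate([
                s.values[(s.times >= lo) &
                         ((s.times <= hi) if last else (s.times < hi))]
                for s in reps])
            if pooled.size == 0:
                raise ConfigError(f"phase [{lo}, {hi}) ns contains no samples")
            stats.append((float(pooled.mean()), float(pooled.std())))
        summary.stats[label] = stats
    return summary
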