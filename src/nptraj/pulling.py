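"""Constant-velocity steered-pulling force analysis.

Replicate force traces are aligned on pull distance (rate x time) so runs
with a common pulling rate share a distance grid, then binned and averaged
into a mean ± SD force profile. Detachment is located by a
threshold-after-last-peak rule on the smoothed mean force, since rupture in
these profiles shows up as the force dropping off after its final peak and
staying low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SelectionError, UndefinedDetachmentError
from .md_io import Selection, Trajectory
from .traj_metrics import MetricSeries

__all__ = [
    "PullTrace",
    "ForceProfile",
    "profile_over_distance",
    "detachment_distance",
    "work_integral",
    "motif_surface_distance_series",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184


@dataclass
class PullTrace:
    """One constant-velocity pulling run.

    times in ps, force in kJ·mol⁻¹·nm⁻¹, pull_rate in nm/ps, spring constant
    in kJ·mol⁻¹·nm⁻². ``pull_distance`` (nm) is the reaction-coordinate
    displacement rate × time unless supplied explicitly.
    """

    times: np.ndarray
    force: np.ndarray
    pull_rate: float = 0.0008
    spring_k: float = 1000.0
    pull_distance: np.ndarray | None = None
    start_distance_nm: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.times.size != self.force.size:
            raise ConfigError("times and force must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigError("times must be strictly increasing")
        if self.pull_rate <= 0:
            raise ConfigError("pull rate must be positive")
        if self.pull_distance is None:
            self.pull_distance = self.start_distance_nm + self.pull_rate * self.times
        else:
            self.pull_distance = np.asarray(self.pull_distance, dtype=float)


@dataclass
class ForceProfile:
    """Mean ± population-SD force vs pull distance across replicates."""

    distance_nm: np.ndarray
    mean_force: np.ndarray
    sd_force: np.ndarray
    n_replicates: int
    coverage: np.ndarray = field(default=None)  # replicates contributing per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_nm": self.distance_nm,
            "mean_force": self.mean_force,
            "sd": self.sd_force,
            "n": self.coverage,
        })


def profile_over_distance(traces: list[PullTrace],
                          grid_step_nm: float = 0.05) -> ForceProfile:
    """Bin each trace by pull distance on a common grid and average.

    Per bin: each trace contributes its within-bin mean force; the profile
    is the mean and population SD across contributing traces. Bins covered
    by fewer than all replicates are flagged via ``coverage``.
    """
    if not traces:
        raise ConfigError("at least one trace required")
    if grid_step_nm <= 0:
        raise ConfigError("grid step must be positive")
    lo = min(t.pull_distance.min() for t in traces)
    hi = max(t.pull_distance.max() for t in traces)
    edges = np.arange(lo, hi + grid_step_nm, grid_step_nm)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + grid_step_nm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_trace = np.full((len(traces), centers.size), np.nan)
    for k, tr in enumerate(traces):
        which = np.digitize(tr.pull_distance, edges) - 1
        for b in range(centers.size):
            m = which == b
            if m.any():
                per_trace[k, b] = tr.force[m].mean()
    coverage = np.sum(~np.isnan(per_trace), axis=0)
    keep = coverage > 0
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_trace, axis=0)
        sd = np.nanstd(per_trace, axis=0)
    return ForceProfile(centers[keep], mean[keep], sd[keep],
                        len(traces), coverage[keep])


def _smooth_over_distance(profile: ForceProfile, window_nm: float) -> np.ndarray:
    s = MetricSeries(profile.distance_nm, profile.mean_force)
    from .traj_metrics import moving_average
    return moving_average(s, window_nm).values


def detachment_distance(profile: ForceProfile, drop_fraction: float = 0.1,
                        smooth_window_nm: float = 0.0
                        ) -> tuple[float, bool]:
    """Largest grid distance where the smoothed mean force still reaches
    ``drop_fraction`` × its global maximum; beyond it the force stays below
    threshold. Negative (compressive) samples are ignored by this logic.

    Returns (distance_nm, unruptured): ``unruptured`` is True when the force
    never falls below threshold before the end of the profile.
    """
    if not (0 < drop_fraction < 1):
        raise ConfigError("drop_fraction must be in (0, 1)")
    force = (profile.mean_force if smooth_window_nm <= 0
             else _smooth_over_distance(profile, smooth_window_nm))
    force = np.clip(force, 0.0, None)
    fmax = force.max()
    if fmax <= 0:
        raise UndefinedDetachmentError("force profile carries no positive signal")
    thresh = drop_fraction * fmax
    above = np.nonzero(force >= thresh)[0]
    last = above[-1]
    unruptured = last == force.size - 1
    return float(profile.distance_nm[last]), bool(unruptured)


def work_integral(trace: PullTrace) -> float:
    """Nonequilibrium pulling work: trapezoidal integral of force over pull
    distance, in kJ/mol."""
    if trace.times.size < 2:
        raise ConfigError("work integral requires at least 2 samples")
    return float(np.trapezoid(trace.force, trace.pull_distance))


def work_integral_kcal(trace: PullTrace) -> float:
    return work_integral(trace) / KJ_PER_KCAL


def motif_surface_distance_series(traj: Trajectory,
                                  motif_residues: list[tuple[str, int]],
                                  reference: Selection | tuple[str, int, str],
                                  ca_only: bool = True,
                                  label: str = "motif_distance") -> MetricSeries:
    """Distance between the motif's Cα centroid and a reference Au atom.

    ``reference`` is either a (chain, residue_id, atom_name) triple for one
    representative atom, or a Selection whose nearest member is used per
    frame.
    """
    idx = []
    for chain, resid in motif_residues:
        found = [i for i, r in enumerate(traj.topology)
                 if r.chain_id == chain and r.residue_id == resid
                 and (not ca_only or r.atom_name == "CA")]
        if not found:
            what = "CA atom" if ca_only else "atoms"
            raise SelectionError(f"motif residue {chain}:{resid} has no {what}")
        idx.extend(found)
    idx = np.asarray(idx, dtype=int)
    out = np.empty(traj.n_frames)
    if isinstance(reference, Selection):
        ref_idx = reference.resolve_nonempty(traj.topology)
        for f in range(traj.n_frames):
            cen = traj.coords[f][idx].mean(axis=0)
            out[f] = np.min(np.linalg.norm(traj.coords[f][ref_idx] - cen, axis=1))
    else:
        chain, resid, name = reference
        ref = [i for i, r in enumerate(traj.topology)
               if (r.chain_id, r.residue_id, r.atom_name) == (chain, resid, name)]
        if not ref:
            raise SelectionError(f"reference atom {reference} not found")
        for f in range(traj.n_frames):
            cen = traj.coords[f][idx].mean(axis=0)
            out[f] = np.linalg.norm(traj.coords[f][ref[0]] - cen)
    return MetricSeries(traj.times.copy(), out, label=label)
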