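"""Geometric hydrogen-bond detection and occupancy statistics.

A bond D-H···A is counted when the donor-acceptor distance is strictly below
the cutoff (default 0.30 nm) and the deviation-from-linearity angle is
strictly below the angle cutoff (default 20°). The default angle convention
measures the angle between the D->H and D->A vectors at the donor, which is
the only reading under which a "D-H-A angle less than 20 degrees" criterion
is satisfiable by near-linear bonds; the literal 180°-∠(D-H-A) alternative
is available as a config switch and gives identical results for ideal
geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, SelectionError, TopologyError
from .md_io import Selection, Trajectory
from .traj_metrics import MetricSeries

__all__ = [
    "HBondConfig",
    "assign_hydrogens",
    "find_polar_atoms",
    "detect_hbonds",
    "pair_occupancy",
    "occupancy_table",
    "hbond_count_series",
    "count_distribution_bootstrap",
    "pair_distance_series",
    "rank_pairs_by_occupancy",
    "round_half_away",
]

POLAR_ELEMENTS = {"N", "O", "S"}
COVALENT_H_CUTOFF_NM = 0.12


@dataclass(frozen=True)
class HBondConfig:
    """Distance/angle gates and the angle convention.

    ``angle_convention``: "donor" = angle(D->H, D->A) at the donor;
    "linearity" = 180° − ∠(D-H-A) at the hydrogen.
    """

    da_cutoff_nm: float = 0.30
    angle_cutoff_deg: float = 20.0
    angle_convention: str = "donor"

    def __post_init__(self):
        if self.da_cutoff_nm <= 0 or self.angle_cutoff_deg <= 0:
            raise ConfigError("cutoffs must be positive")
        if self.angle_cutoff_deg >= 90:
            raise ConfigError("angle cutoff must be below 90 degrees")
        if self.angle_convention not in ("donor", "linearity"):
            raise ConfigError("angle_convention must be 'donor' or 'linearity'")


def assign_hydrogens(traj: Trajectory, frame: int = 0) -> dict[int, int]:
    """Map hydrogen atom index -> covalently bound polar donor index.

    With no bond table available, a hydrogen belongs to the nearest N/O/S
    atom within 0.12 nm in the given frame. Hydrogens bound to carbon (or
    anything non-polar) are simply not donor hydrogens and are omitted.
    """
    coords = traj.coords[frame]
    h_idx = [i for i, r in enumerate(traj.topology) if r.element.upper() == "H"]
    polar = np.array([i for i, r in enumerate(traj.topology)
                      if r.element.upper() in POLAR_ELEMENTS], dtype=int)
    out: dict[int, int] = {}
    if polar.size == 0:
        return out
    for h in h_idx:
        d = np.linalg.norm(coords[polar] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] < COVALENT_H_CUTOFF_NM:
            out[h] = int(polar[j])
    return out


def find_polar_atoms(traj: Trajectory, selection: Selection | None = None
                     ) -> tuple[dict[int, int], list[int]]:
    """Donor-hydrogen map and acceptor list (all N/O/S) for a selection."""
    sel_idx = set((selection or Selection.protein()).resolve(traj.topology))
    h_to_d = {h: d for h, d in assign_hydrogens(traj).items() if d in sel_idx}
    acceptors = [i for i in sorted(sel_idx)
                 if traj.topology[i].element.upper() in POLAR_ELEMENTS]
    return h_to_d, acceptors


def _deviation_angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray,
                         convention: str) -> float:
    if convention == "donor":
        v1, v2 = h - d, a - d
    else:  # linearity: 180 deg minus the angle at the hydrogen
        v1, v2 = d - h, a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 180.0
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    return ang if convention == "donor" else 180.0 - ang


def detect_hbonds(coords: np.ndarray, traj: Trajectory,
                  h_to_d: dict[int, int], acceptors: list[int],
                  cfg: HBondConfig | None = None) -> list[tuple[int, int, int]]:
    """All (D, H, A) triplets passing the geometric gates in one frame.

    Donor and acceptor must sit in different residues. Every hydrogen passed
    must carry a donor assignment; an unassigned hydrogen is a topology
    error.
    """
    cfg = cfg or HBondConfig()
    for h, d in h_to_d.items():
        if d is None:
            raise TopologyError(f"hydrogen atom index {h} has no assigned donor")
    res_of = [(r.chain_id, r.residue_id) for r in traj.topology]
    out = []
    acc = np.asarray(acceptors, dtype=int)
    for h, d in h_to_d.items():
        if acc.size == 0:
            break
        da = np.linalg.norm(coords[acc] - coords[d], axis=1)
        for a in acc[da < cfg.da_cutoff_nm]:
            a = int(a)
            if a == d or res_of[a] == res_of[d]:
                continue
            ang = _deviation_angle_deg(coords[d], coords[h], coords[a],
                                       cfg.angle_convention)
            if ang < cfg.angle_cutoff_deg:
                out.append((d, h, a))
    return out


def _pair_bonded_frames(traj: Trajectory, donor_res: tuple[str, int],
                        acceptor_res: tuple[str, int],
                        cfg: HBondConfig) -> int:
    h_to_d, acceptors = find_polar_atoms(traj)
    res_of = [(r.chain_id, r.residue_id) for r in traj.topology]
    h_to_d = {h: d for h, d in h_to_d.items() if res_of[d] == tuple(donor_res)}
    acceptors = [a for a in acceptors if res_of[a] == tuple(acceptor_res)]
    n = 0
    for f in range(traj.n_frames):
        if detect_hbonds(traj.coords[f], traj, h_to_d, acceptors, cfg):
            n += 1
    return n


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _two_sig_figs(x: float) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.2g}")


def pair_occupancy(trajs: list[Trajectory], donor_res: tuple[str, int],
                   acceptor_res: tuple[str, int],
                   cfg: HBondConfig | None = None) -> dict:
    """Occupancy of one donor/acceptor residue pair across replicates.

    Per replicate: 100 × (frames with at least one D-H···A triplet between
    the pair) / (total frames). The cross-replicate average is the
    arithmetic mean. ``average_rounded`` is reported at table precision
    (nearest integer, halves away from zero; replicate values at 2
    significant figures).
    """
    cfg = cfg or HBondConfig()
    occ = []
    for traj in trajs:
        k = _pair_bonded_frames(traj, donor_res, acceptor_res, cfg)
        occ.append(100.0 * k / traj.n_frames)
    avg = float(np.mean(occ))
    return {
        "donor": tuple(donor_res),
        "acceptor": tuple(acceptor_res),
        "replicate_occupancy": occ,
        "replicate_rounded": [_two_sig_figs(o) for o in occ],
        "average": avg,
        "average_rounded": round_half_away(avg),
    }


def occupancy_table(trajs: list[Trajectory],
                    pairs: list[tuple[tuple[str, int], tuple[str, int]]],
                    cfg: HBondConfig | None = None) -> pd.DataFrame:
    rows = [pair_occupancy(trajs, d, a, cfg) for d, a in pairs]
    df = pd.DataFrame([{
        "donor_chain": r["donor"][0], "donor_resid": r["donor"][1],
        "acceptor_chain": r["acceptor"][0], "acceptor_resid": r["acceptor"][1],
        "average_pct": r["average_rounded"],
        **{f"rep{i + 1}_pct": v for i, v in enumerate(r["replicate_rounded"])},
    } for r in rows])
    return df


def hbond_count_series(traj: Trajectory, selection_a: Selection,
                       selection_b: Selection, cfg: HBondConfig | None = None,
                       label: str = "hbonds") -> MetricSeries:
    """Per-frame count of distinct bonded (D, A) atom pairs between two
    disjoint selections (either direction). Multiple hydrogens bridging the
    same D-A atom pair count once."""
    cfg = cfg or HBondConfig()
    ia = set(selection_a.resolve(traj.topology))
    ib = set(selection_b.resolve(traj.topology))
    if ia & ib:
        raise SelectionError("hbond_count_series requires disjoint selections")
    h_to_d, acceptors = find_polar_atoms(traj, Selection.all())
    h_to_d = {h: d for h, d in h_to_d.items() if d in ia or d in ib}
    acceptors = [a for a in acceptors if a in ia or a in ib]
    counts = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        triplets = detect_hbonds(traj.coords[f], traj, h_to_d, acceptors, cfg)
        pairs = {(d, a) for d, _, a in triplets
                 if (d in ia and a in ib) or (d in ib and a in ia)}
        counts[f] = len(pairs)
    return MetricSeries(traj.times.copy(), counts, label=label)


def count_distribution_bootstrap(series_per_replicate: list[MetricSeries],
                                 state_windows: list[tuple[float, float]] | None = None,
                                 n_boot: int = 1000, seed: int = 0
                                 ) -> dict[tuple[float, float], pd.DataFrame]:
    """Percentage distribution of integer H-bond counts per state window,
    pooled across replicates, with bootstrap standard deviations.

    Error bars follow the standard deviation over ``n_boot`` resamples of
    the pooled per-frame counts (frames resampled with replacement).
    Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    if state_windows is None:
        state_windows = [(0.0, 750.0), (750.0, 2000.0)]
    rng = np.random.default_rng(seed)
    out = {}
    for k, (lo, hi) in enumerate(state_windows):
        last = k == len(state_windows) - 1
        pooled = np.concatenate([
            s.values[(s.times >= lo) &
                     ((s.times <= hi) if last else (s.times < hi))]
            for s in series_per_replicate]).astype(int)
        if pooled.size == 0:
            raise ConfigError(f"state window [{lo}, {hi}) ns has no frames")
        values = np.arange(pooled.min(), pooled.max() + 1)
        pct = np.array([(pooled == v).mean() * 100.0 for v in values])
        boot = np.empty((n_boot, values.size))
        for b in range(n_boot):
            res = rng.choice(pooled, size=pooled.size, replace=True)
            boot[b] = [(res == v).mean() * 100.0 for v in values]
        out[(lo, hi)] = pd.DataFrame({
            "count": values,
            "percentage": pct,
            "bootstrap_sd": boot.std(axis=0),
        })
    return out


def pair_distance_series(traj: Trajectory, atom_a: tuple[str, int, str],
                         atom_b: tuple[str, int, str],
                         label: str = "distance") -> MetricSeries:
    """Per-frame distance (nm) between two named atoms
    ((chain, residue_id, atom_name) each)."""
    def locate(spec):
        for i, r in enumerate(traj.topology):
            if (r.chain_id, r.residue_id, r.atom_name) == tuple(spec):
                return i
        raise SelectionError(f"atom {spec} not found in topology")
    ia, ib = locate(atom_a), locate(atom_b)
    d = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return MetricSeries(traj.times.copy(), d, label=label)


def rank_pairs_by_occupancy(rows: list[dict], top: int = 3) -> list[dict]:
    """Top pairs by average occupancy; ties broken by ascending donor
    residue id."""
    return sorted(rows, key=lambda r: (-r["average"], r["donor"][1]))[:top]
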