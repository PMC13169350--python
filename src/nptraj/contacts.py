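"""Per-residue nanoparticle contact analysis.

A residue is "in contact" in a frame when any of its atoms lies strictly
within the cutoff (default 0.45 nm) of any nanoparticle (Au) atom. The
headline statistic is the conditional contact ratio: the fraction of frames
in which the residue touches the surface, counted only over frames where the
protein touches the surface at all. This conditioning makes the ratio
insensitive to how long a replicate spends diffusing before adsorption, so
ratios can be averaged across replicates of very different approach times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigError, SelectionError
from .md_io import Selection, Trajectory

__all__ = [
    "ContactConfig",
    "ReplicateContacts",
    "ContactRatioTable",
    "residue_contact_mask",
    "contact_ratio",
    "average_contact_ratios",
    "pooled_contact_ratio",
    "rank_binding_motifs",
]


@dataclass(frozen=True)
class ContactConfig:
    """Contact definition: cutoff (nm) and the two atom selections."""

    cutoff_nm: float = 0.45
    nanoparticle_selection: Selection = field(default_factory=Selection.gold)
    protein_selection: Selection = field(default_factory=Selection.protein)

    def __post_init__(self):
        if self.cutoff_nm <= 0:
            raise ConfigError("contact cutoff must be positive")


@dataclass
class ReplicateContacts:
    """Conditional contact ratios of one replicate."""

    residues: list[tuple[str, int]]
    residue_names: list[str]
    ratios: np.ndarray          # in [0, 1]
    n_contact_frames: np.ndarray
    n_frames_with_any_contact: int
    n_frames_total: int
    no_contact: bool            # True when no frame had any residue in contact

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.residues],
            "residue_id": [r for _, r in self.residues],
            "residue_name": self.residue_names,
            "ratio": self.ratios,
            "n_contact_frames": self.n_contact_frames,
            "n_frames": self.n_frames_with_any_contact,
        })


@dataclass
class ContactRatioTable:
    """Cross-replicate averaged conditional contact ratios."""

    residues: list[tuple[str, int]]
    residue_names: list[str]
    mean_ratios: np.ndarray
    n_replicates_used: int
    replicates: list[ReplicateContacts]
    averaging: str = "per_replicate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.residues],
            "residue_id": [r for _, r in self.residues],
            "residue_name": self.residue_names,
            "ratio": self.mean_ratios,
        })

    def as_dict(self) -> dict[tuple[str, int], float]:
        return dict(zip(self.residues, self.mean_ratios.tolist()))


def _protein_residues(traj: Trajectory, cfg: ContactConfig
                      ) -> tuple[list[tuple[str, int]], list[str], list[np.ndarray]]:
    idx = cfg.protein_selection.resolve_nonempty(traj.topology)
    keys, names, groups = [], [], {}
    for i in idx:
        rec = traj.topology[i]
        key = (rec.chain_id, rec.residue_id)
        if key not in groups:
            groups[key] = []
            keys.append(key)
            names.append(rec.residue_name)
    for i in idx:
        rec = traj.topology[i]
        groups[(rec.chain_id, rec.residue_id)].append(i)
    return keys, names, [np.asarray(groups[k], dtype=int) for k in keys]


def residue_contact_mask(traj: Trajectory, cfg: ContactConfig
                         ) -> tuple[np.ndarray, list[tuple[str, int]], list[str]]:
    """Boolean table of shape (n_frames, n_residues): True when the residue's
    minimum atom distance to any nanoparticle atom is strictly below the
    cutoff. A KD-tree accelerates the query; results are identical to the
    exhaustive pairwise minimum."""
    np_idx = cfg.nanoparticle_selection.resolve(traj.topology)
    if np_idx.size == 0:
        raise SelectionError("nanoparticle selection resolved to zero atoms")
    keys, names, groups = _protein_residues(traj, cfg)
    mask = np.zeros((traj.n_frames, len(keys)), dtype=bool)
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f][np_idx])
        for r, atom_idx in enumerate(groups):
            d, _ = tree.query(traj.coords[f][atom_idx], k=1)
            mask[f, r] = bool(np.min(d) < cfg.cutoff_nm)
    return mask, keys, names


def contact_ratio(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Conditional contact ratios from a per-frame per-residue mask.

    Denominator: frames with at least one residue in contact. Numerator per
    residue: its contact frames (necessarily among those). When no frame has
    any contact, all ratios are 0 and the no-contact flag is set.

    Returns (ratios, n_contact_frames, n_frames_with_any_contact, no_contact).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] < 1:
        raise ConfigError("mask needs at least one frame")
    any_contact = mask.any(axis=1)
    denom = int(any_contact.sum())
    counts = mask.sum(axis=0)
    if denom == 0:
        return np.zeros(mask.shape[1]), counts, 0, True
    return counts / denom, counts, denom, False


def replicate_contacts(traj: Trajectory, cfg: ContactConfig) -> ReplicateContacts:
    """Full per-replicate pipeline: mask then conditional ratios."""
    mask, keys, names = residue_contact_mask(traj, cfg)
    ratios, counts, denom, flag = contact_ratio(mask)
    return ReplicateContacts(keys, names, ratios, counts, denom,
                             mask.shape[0], flag)


def average_contact_ratios(tables: list[ReplicateContacts]) -> ContactRatioTable:
    """Unweighted mean of per-replicate conditional ratios per residue.

    Replicates in which the protein never touched the nanoparticle carry no
    contact frames and are excluded from the mean rather than averaged in as
    zeros."""
    usable = [t for t in tables if not t.no_contact]
    if not usable:
        raise ConfigError("no replicate has any nanoparticle contact")
    residues = usable[0].residues
    for t in usable[1:]:
        if t.residues != residues:
            raise ConfigError("replicates must share a residue set")
    mean = np.mean([t.ratios for t in usable], axis=0)
    return ContactRatioTable(residues, usable[0].residue_names, mean,
                             len(usable), tables, averaging="per_replicate")


def pooled_contact_ratio(trajs: list[Trajectory], cfg: ContactConfig
                         ) -> ContactRatioTable:
    """Alternative averaging: pool the contact frames of all replicates and
    compute a single conditional ratio over the pooled set."""
    masks, keys, names = [], None, None
    reps = []
    for traj in trajs:
        m, k, n = residue_contact_mask(traj, cfg)
        if keys is None:
            keys, names = k, n
        elif k != keys:
            raise ConfigError("replicates must share a residue set")
        masks.append(m)
        ratios, counts, denom, flag = contact_ratio(m)
        reps.append(ReplicateContacts(k, n, ratios, counts, denom,
                                      m.shape[0], flag))
    pooled = np.concatenate(masks, axis=0)
    ratios, _, denom, flag = contact_ratio(pooled)
    if flag:
        raise ConfigError("no replicate has any nanoparticle contact")
    return ContactRatioTable(keys, names, ratios, len(trajs), reps,
                             averaging="pooled_frames")


@dataclass
class BindingMotif:
    chain: str
    residue_ids: list[int]
    residue_names: list[str]
    mean_ratio: float

    @property
    def sequence(self) -> str:
        return "-".join(self.residue_names)


def rank_binding_motifs(table: ContactRatioTable, min_len: int = 3,
                        threshold: float = 0.5
                        ) -> tuple[list[BindingMotif], list[BindingMotif]]:
    """Contiguous runs of consecutive residue ids with ratio >= threshold.

    Runs never span chains or numbering gaps. Runs of at least ``min_len``
    are motifs; shorter ones are reported separately as single-residue-scale
    sites. Both lists are sorted by descending mean ratio.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    # a threshold above 1 is allowed and simply yields an empty report
    runs: list[BindingMotif] = []
    cur: list[int] = []

    def flush(run_idx: list[int]):
        if not run_idx:
            return
        chain = table.residues[run_idx[0]][0]
        runs.append(BindingMotif(
            chain=chain,
            residue_ids=[table.residues[i][1] for i in run_idx],
            residue_names=[table.residue_names[i] for i in run_idx],
            mean_ratio=float(np.mean(table.mean_ratios[run_idx])),
        ))

    for i in range(len(table.residues)):
        ok = table.mean_ratios[i] >= threshold
        if ok and cur:
            pc, pr = table.residues[cur[-1]]
            c, r = table.residues[i]
            if c != pc or r != pr + 1:
                flush(cur)
                cur = []
        if ok:
            cur.append(i)
        elif cur:
            flush(cur)
            cur = []
    flush(cur)
    motifs = sorted([m for m in runs if len(m.residue_ids) >= min_len],
                    key=lambda m: -m.mean_ratio)
    sites = sorted([m for m in runs if len(m.residue_ids) < min_len],
                   key=lambda m: -m.mean_ratio)
    return motifs, sites
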