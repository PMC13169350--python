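"""Synthetic trajectory and free-energy fixtures with exported ground truth.

Every generator emulates the statistical structure one analysis stage
assumes — programmed residue-surface contact episodes, donor-H-acceptor
geometries at target occupancies, a two-arm extended-to-compact transition,
overdamped Langevin samples in harmonic umbrella windows over an analytic
PMF, and constant-velocity pulling traces with prescribed bond ruptures.
Ground truth is always computed by construction or enumeration, never by
calling the analysis modules, so fixture comparisons are genuine oracles.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, StabilityError
from .md_io import AtomRecord, Trajectory
from .pulling import PullTrace
from .wham import KB_KJ_PER_MOL_K, KJ_PER_KCAL, UmbrellaWindow

__all__ = [
    "GENERATOR_VERSION",
    "ContactSchedule",
    "gen_interface_trajectory",
    "HBondPairSpec",
    "gen_hbond_trajectory",
    "gen_two_state_trajectory",
    "PmfSpec",
    "LangevinParams",
    "langevin_umbrella_samples",
    "gen_pull_trace",
]

GENERATOR_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# Interface-contact fixture
# ---------------------------------------------------------------------------

@dataclass
class ContactSchedule:
    """Ground-truth contact plan: which residues touch the surface in which
    frames."""

    n_frames: int
    contacts: dict[int, set[int]]      # residue_id -> frame indices
    n_residues: int
    motif_residues: list[int] = field(default_factory=list)

    def __post_init__(self):
        for rid, frames in self.contacts.items():
            if not (1 <= rid <= self.n_residues):
                raise ConfigError(f"scheduled residue {rid} outside 1..{self.n_residues}")
            if any(f < 0 or f >= self.n_frames for f in frames):
                raise ConfigError("scheduled frame index out of range")

    @staticmethod
    def random(n_residues: int, n_frames: int, seed: int,
               motif: tuple[list[int], float] | None = None,
               background_rate: float = 0.1) -> "ContactSchedule":
        """Random schedule: background residues contact independently at
        ``background_rate`` per frame; motif residues at the motif rate."""
        rng = np.random.default_rng(seed)
        motif_ids, motif_rate = motif if motif else ([], 0.0)
        contacts: dict[int, set[int]] = {}
        for rid in range(1, n_residues + 1):
            rate = motif_rate if rid in motif_ids else background_rate
            hits = set(np.nonzero(rng.random(n_frames) < rate)[0].tolist())
            if hits:
                contacts[rid] = hits
        return ContactSchedule(n_frames, contacts, n_residues,
                               motif_residues=list(motif_ids))

    def conditional_ratios(self) -> tuple[dict[int, float], int, bool]:
        """Enumerated ground truth: per-residue conditional contact ratio,
        the number of frames with any contact, and the no-contact flag."""
        frames_with_contact = set()
        for frames in self.contacts.values():
            frames_with_contact |= frames
        denom = len(frames_with_contact)
        if denom == 0:
            return ({rid: 0.0 for rid in range(1, self.n_residues + 1)}, 0, True)
        ratios = {rid: len(self.contacts.get(rid, set())) / denom
                  for rid in range(1, self.n_residues + 1)}
        return ratios, denom, False


def _gold_cap(shell_radius_nm: float, cap_angle_deg: float,
              spacing_nm: float) -> np.ndarray:
    """Au positions on a spherical cap of the given radius; the cap apex sits
    at the origin with outward normal +z (sphere centre at (0,0,-R))."""
    centre = np.array([0.0, 0.0, -shell_radius_nm])
    pts = []
    theta_max = math.radians(cap_angle_deg)
    n_theta = max(int(shell_radius_nm * theta_max / spacing_nm), 1)
    for it in range(n_theta + 1):
        theta = theta_max * it / n_theta
        ring_r = shell_radius_nm * math.sin(theta)
        n_phi = max(int(2 * math.pi * ring_r / spacing_nm), 1)
        for ip in range(n_phi):
            phi = 2 * math.pi * ip / n_phi
            pts.append(centre + shell_radius_nm * np.array([
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta)]))
    return np.asarray(pts)


def gen_interface_trajectory(schedule: ContactSchedule, seed: int = 0,
                             shell_radius_nm: float = 3.0,
                             cap_angle_deg: float = 25.0,
                             spacing_nm: float = 0.15,
                             contact_distance_nm: float = 0.35,
                             rest_distance_nm: float = 0.9,
                             residue_names: list[str] | None = None
                             ) -> tuple[Trajectory, dict]:
    """Bead-model trajectory realizing a contact schedule against a gold cap.

    One CA pseudo-atom per residue. In a scheduled frame the residue bead
    sits ``contact_distance_nm`` outside its assigned surface atom (within
    the 0.45 nm cutoff); otherwise at ``rest_distance_nm`` (outside it).
    Returns the trajectory and a ground-truth dict with the enumerated
    conditional ratios.
    """
    if rest_distance_nm <= contact_distance_nm:
        raise ConfigError("rest distance must exceed contact distance")
    gold = _gold_cap(shell_radius_nm, cap_angle_deg, spacing_nm)
    if schedule.n_residues > len(gold):
        raise ConfigError(
            f"{schedule.n_residues} residues need {schedule.n_residues} surface "
            f"slots but the cap provides {len(gold)}; enlarge the cap")
    rng = np.random.default_rng(seed)
    slots = rng.choice(len(gold), size=schedule.n_residues, replace=False)
    centre = np.array([0.0, 0.0, -shell_radius_nm])
    normals = gold[slots] - centre
    normals /= np.linalg.norm(normals, axis=1)[:, None]

    topology = [AtomRecord("CA", "C",
                           (residue_names[r] if residue_names else "GLY"),
                           r + 1, "A")
                for r in range(schedule.n_residues)]
    topology += [AtomRecord("AU", "AU", "AUN", 1000 + i, "Z",
                            is_nanoparticle=True)
                 for i in range(len(gold))]

    coords = np.empty((schedule.n_frames, len(topology), 3))
    for f in range(schedule.n_frames):
        for r in range(schedule.n_residues):
            d = (contact_distance_nm
                 if f in schedule.contacts.get(r + 1, set())
                 else rest_distance_nm)
            coords[f, r] = gold[slots[r]] + d * normals[r]
        coords[f, schedule.n_residues:] = gold
    times = np.arange(schedule.n_frames, dtype=float)
    ratios, denom, flag = schedule.conditional_ratios()
    truth = {
        "conditional_ratios": ratios,
        "n_frames_with_any_contact": denom,
        "no_contact": flag,
        "motif_residues": schedule.motif_residues,
        "generator_version": GENERATOR_VERSION,
    }
    return Trajectory(topology, coords, times), truth


# ---------------------------------------------------------------------------
# Hydrogen-bond fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondPairSpec:
    """Target occupancy for one donor/acceptor residue pair."""

    donor_resid: int
    acceptor_resid: int
    occupancy_pct: float
    donor_name: str = "ARG"
    acceptor_name: str = "ASP"

    def __post_init__(self):
        if not (0 <= self.occupancy_pct <= 100):
            raise ConfigError("occupancy must be in [0, 100]")
        if self.donor_resid == self.acceptor_resid:
            raise ConfigError("donor and acceptor must be different residues")


def gen_hbond_trajectory(pairs: list[HBondPairSpec], n_frames: int,
                         seed: int = 0,
                         bond_distance_nm: float = 0.28,
                         bond_deviation_deg: float = 5.0,
                         broken_distance_nm: float = 0.45
                         ) -> tuple[Trajectory, dict]:
    """Trajectory in which each D-H···A pair is in bonding geometry in a
    random subset of exactly floor(occupancy × n_frames / 100) frames.

    Bonding geometry: D-A distance 0.28 nm with the acceptor 5° off the D-H
    axis; broken geometry: D-A at 0.45 nm (outside the 0.30 nm gate). Pairs
    live 5 nm apart so they cannot cross-talk. Ground truth is the realized
    occupancy of the chosen frame subsets.
    """
    rng = np.random.default_rng(seed)
    dev = math.radians(bond_deviation_deg)
    topology, truth_occ = [], {}
    bonded_frames: list[set[int]] = []
    for j, spec in enumerate(pairs):
        topology.append(AtomRecord("N", "N", spec.donor_name,
                                   spec.donor_resid, "A"))
        topology.append(AtomRecord("H", "H", spec.donor_name,
                                   spec.donor_resid, "A"))
        topology.append(AtomRecord("O", "O", spec.acceptor_name,
                                   spec.acceptor_resid, "A"))
        k = int(math.floor(spec.occupancy_pct * n_frames / 100.0))
        chosen = set(rng.choice(n_frames, size=k, replace=False).tolist())
        bonded_frames.append(chosen)
        truth_occ[(spec.donor_resid, spec.acceptor_resid)] = 100.0 * k / n_frames

    coords = np.empty((n_frames, len(topology), 3))
    for j, spec in enumerate(pairs):
        base = np.array([0.0, 5.0 * j, 0.0])      # spatial isolation per pair
        d_pos = base
        h_pos = base + np.array([0.10, 0.0, 0.0])
        a_bond = base + bond_distance_nm * np.array(
            [math.cos(dev), math.sin(dev), 0.0])
        a_free = base + np.array([broken_distance_nm, 0.0, 0.0])
        for f in range(n_frames):
            coords[f, 3 * j] = d_pos
            coords[f, 3 * j + 1] = h_pos
            coords[f, 3 * j + 2] = a_bond if f in bonded_frames[j] else a_free
    times = np.arange(n_frames, dtype=float)
    truth = {
        "occupancy_pct": truth_occ,
        "bonded_frames": [sorted(s) for s in bonded_frames],
        "generator_version": GENERATOR_VERSION,
    }
    return Trajectory(topology, coords, times), truth


# ---------------------------------------------------------------------------
# Two-state (extended -> compact) fixture
# ---------------------------------------------------------------------------

def gen_two_state_trajectory(n_frames: int, transition_frame: int,
                             n_arm_residues: int = 8,
                             extended_distance_nm: float = 4.0,
                             compact_distance_nm: float = 1.0,
                             ramp_frames: int | None = None,
                             n_hbond_pairs: int = 2,
                             seed: int = 0) -> tuple[Trajectory, dict]:
    """Two bead arms (chains A and B) that converge linearly after the
    transition frame, emulating an extended-to-compact conformational change.

    Before ``transition_frame`` the arm centroids sit ``extended_distance``
    apart; afterwards the separation ramps linearly to ``compact_distance``
    over ``ramp_frames`` (default 10% of the trajectory) and holds. Each
    inter-arm H-bond pair is built with inward offsets such that its D-A
    distance is exactly 0.28 nm at the compact separation, so bonds exist
    only in the compact state. Ground truth (separation series, contact
    onset frame, compact-state H-bond count) is computed from the placement
    geometry by construction.
    """
    if not (0 <= transition_frame <= n_frames):
        raise ConfigError("transition_frame must lie within the trajectory")
    if compact_distance_nm >= extended_distance_nm:
        raise ConfigError("compact distance must be below extended distance")
    if ramp_frames is None:
        ramp_frames = max(n_frames // 10, 1)

    sep = np.empty(n_frames)
    for f in range(n_frames):
        if f < transition_frame:
            sep[f] = extended_distance_nm
        else:
            frac = min((f - transition_frame) / ramp_frames, 1.0)
            sep[f] = extended_distance_nm + frac * (
                compact_distance_nm - extended_distance_nm)

    spacing = 0.4
    topology = []
    for chain in ("A", "B"):
        for r in range(n_arm_residues):
            topology.append(AtomRecord("CA", "C", "GLY", r + 1, chain))
    bond_offset = (compact_distance_nm - 0.28) / 2.0
    for j in range(n_hbond_pairs):
        y = (n_arm_residues + 1 + j) * spacing
        topology.append(AtomRecord("N", "N", "ARG", 100 + j, "A"))
        topology.append(AtomRecord("H", "H", "ARG", 100 + j, "A"))
        topology.append(AtomRecord("O", "O", "ASP", 100 + j, "B"))

    n_atoms = len(topology)
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        d = sep[f]
        i = 0
        for sign in (-1.0, +1.0):
            for r in range(n_arm_residues):
                coords[f, i] = [sign * d / 2.0, r * spacing, 0.0]
                i += 1
        for j in range(n_hbond_pairs):
            y = (n_arm_residues + 1 + j) * spacing
            xn = -d / 2.0 + bond_offset
            xo = +d / 2.0 - bond_offset
            coords[f, i] = [xn, y, 0.0]
            coords[f, i + 1] = [xn + 0.10, y, 0.0]
            coords[f, i + 2] = [xo, y, 0.0]
            i += 3

    times = np.arange(n_frames, dtype=float)
    da_dist = sep - 2.0 * bond_offset          # D-A distance per frame
    hbond_counts = np.where(da_dist < 0.30, n_hbond_pairs, 0)
    contact_frames = np.nonzero(sep - 2.0 * bond_offset - 0.10 < 0.45)[0]
    truth = {
        "separation_nm": sep,
        "hbond_count": hbond_counts,
        "contact_onset_frame": (int(contact_frames[0])
                                if contact_frames.size else None),
        "transition_frame": transition_frame,
        "generator_version": GENERATOR_VERSION,
    }
    return Trajectory(topology, coords, times), truth


# ---------------------------------------------------------------------------
# Analytic PMFs and Langevin umbrella sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PmfSpec:
    """Analytic reaction-coordinate potential (energies in kJ/mol).

    kinds: "harmonic" (curvature a about centre c), "well_plateau" (bound
    well of the given depth at ``minimum_nm`` rising smoothly to a flat zero
    plateau at ``plateau_onset_nm``; harmonic wall on the near side) and
    "double_well" (quartic, barrier ``depth`` between minima at c ± b).
    """

    kind: str = "well_plateau"
    depth_kcal: float = 5.0
    minimum_nm: float = 0.5
    plateau_onset_nm: float = 1.5
    curvature: float = 2000.0          # kJ/mol/nm^2 (harmonic kind and wall)
    half_separation_nm: float = 0.5    # double-well b

    def __post_init__(self):
        if self.kind not in ("harmonic", "well_plateau", "double_well"):
            raise ConfigError(f"unknown PMF kind {self.kind!r}")
        if self.kind == "well_plateau" and \
           self.plateau_onset_nm <= self.minimum_nm:
            raise ConfigError("plateau onset must lie beyond the minimum")

    @property
    def depth_kj(self) -> float:
        return self.depth_kcal * KJ_PER_KCAL

    def value(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if self.kind == "harmonic":
            return self.curvature * (xi - self.minimum_nm) ** 2
        if self.kind == "double_well":
            b = self.half_separation_nm
            return self.depth_kj * ((xi - self.minimum_nm) ** 2 - b ** 2) ** 2 / b ** 4
        d, x0, x1 = self.depth_kj, self.minimum_nm, self.plateau_onset_nm
        w = x1 - x0
        v = np.where(
            xi < x0,
            -d + self.curvature * (xi - x0) ** 2,
            np.where(xi > x1, 0.0,
                     -d / 2.0 * (1.0 + np.cos(np.pi * (xi - x0) / w))))
        return v

    def grad(self, xi) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if self.kind == "harmonic":
            return 2.0 * self.curvature * (xi - self.minimum_nm)
        if self.kind == "double_well":
            b = self.half_separation_nm
            u = (xi - self.minimum_nm) ** 2 - b ** 2
            return 4.0 * self.depth_kj * u * (xi - self.minimum_nm) / b ** 4
        d, x0, x1 = self.depth_kj, self.minimum_nm, self.plateau_onset_nm
        w = x1 - x0
        return np.where(
            xi < x0,
            2.0 * self.curvature * (xi - x0),
            np.where(xi > x1, 0.0,
                     d * np.pi / (2.0 * w) * np.sin(np.pi * (xi - x0) / w)))

    def delta_g_kcal(self) -> float:
        """Binding depth: plateau level minus minimum, in kcal/mol."""
        if self.kind == "well_plateau":
            return self.depth_kcal
        if self.kind == "harmonic":
            return 0.0
        return self.depth_kcal  # double well: barrier height


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped-Langevin integrator settings for 1-D umbrella sampling."""

    diffusion_nm2_per_ps: float = 1e-3
    timestep_ps: float = 0.05
    temperature_k: float = 310.0
    n_steps: int = 60000
    stride: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.diffusion_nm2_per_ps, self.timestep_ps,
               self.temperature_k) <= 0:
            raise ConfigError("diffusion, timestep and temperature must be positive")
        if self.n_steps < 10 or self.stride < 1:
            raise ConfigError("need n_steps >= 10 and stride >= 1")


def langevin_umbrella_samples(pmf: PmfSpec,
                              windows: list[tuple[float, float]],
                              params: LangevinParams,
                              convention: str = "full",
                              domain: tuple[float, float] | None = None
                              ) -> list[UmbrellaWindow]:
    """Sample each harmonic window by overdamped Langevin dynamics on
    V(ξ) + u_i(ξ).

    Update: ξ' = ξ − βD ∇(V+u) dt + sqrt(2 D dt) η. The first 10% of steps
    are discarded as equilibration and the rest recorded every ``stride``
    steps. The drift-step bound βD dt max|∇(V+u)| < 0.1 is checked on a
    domain grid before integration; trajectories leaving the domain by more
    than 10% of its span raise a stability error advising a smaller
    timestep.
    """
    if not windows:
        raise ConfigError("at least one window required")
    if domain is None:
        rs = [r for r, _ in windows]
        lo = min(min(rs), pmf.minimum_nm) - 0.3
        hi = max(max(rs), pmf.plateau_onset_nm
                 if pmf.kind == "well_plateau" else max(rs)) + 0.3
        domain = (lo, hi)
    lo, hi = domain
    span = hi - lo
    kt = KB_KJ_PER_MOL_K * params.temperature_k
    beta = 1.0 / kt
    dt, diff = params.timestep_ps, params.diffusion_nm2_per_ps
    bias_factor = 2.0 if convention == "full" else 1.0

    grid = np.linspace(lo, hi, 512)
    for r_i, k_i in windows:
        g = np.abs(pmf.grad(grid) + bias_factor * k_i * (grid - r_i))
        if beta * diff * dt * g.max() >= 0.1:
            raise StabilityError(
                f"drift step too large in window r={r_i}: reduce the "
                "timestep or the force constant")

    rng = np.random.default_rng(params.seed)
    n_win = len(windows)
    r = np.array([w[0] for w in windows])
    k = np.array([w[1] for w in windows])
    xi = np.clip(r.copy(), lo, hi)
    n_equil = params.n_steps // 10
    sqrt_step = math.sqrt(2.0 * diff * dt)
    records: list[list[float]] = [[] for _ in range(n_win)]
    rec_times: list[list[float]] = [[] for _ in range(n_win)]
    for step in range(params.n_steps):
        grad = pmf.grad(xi) + bias_factor * k * (xi - r)
        xi = xi - beta * diff * dt * grad + sqrt_step * rng.standard_normal(n_win)
        if np.any(xi < lo - 0.1 * span) or np.any(xi > hi + 0.1 * span):
            raise StabilityError(
                "Langevin trajectory left the domain; reduce the timestep")
        if step >= n_equil and (step - n_equil) % params.stride == 0:
            t = step * dt
            for j in range(n_win):
                records[j].append(xi[j])
                rec_times[j].append(t)
    return [UmbrellaWindow(float(r[j]), float(k[j]),
                           np.asarray(records[j]), np.asarray(rec_times[j]),
                           window_id=f"w{j:03d}")
            for j in range(n_win)]


# ---------------------------------------------------------------------------
# Pulling-trace fixture
# ---------------------------------------------------------------------------

def gen_pull_trace(ruptures: list[tuple[float, float]],
                   pull_rate: float = 0.0008, spring_k: float = 1000.0,
                   noise_sd: float = 20.0, seed: int = 0,
                   dt_ps: float = 5.0, max_distance_nm: float | None = None,
                   decay_width_nm: float = 0.1
                   ) -> tuple[PullTrace, dict]:
    """Constant-velocity pulling trace over a piecewise bond potential.

    ``ruptures`` is a list of (rupture_distance_nm, bond_stiffness) with
    strictly increasing rupture distances. While bond j holds, the measured
    force is the series spring response k·κ_j/(k+κ_j) × (d − e_j), where
    e_j is the distance at which the bond engaged (the previous rupture
    point); at its rupture distance the force peaks and the next bond takes
    over. After the final rupture the force decays exponentially with the
    given width. Gaussian noise of ``noise_sd`` (kJ·mol⁻¹·nm⁻¹) is added.
    Exported ground truth: analytic peak forces and rupture distances.
    """
    pos = [p for p, _ in ruptures]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ConfigError("rupture positions must be strictly increasing")
    if max_distance_nm is None:
        max_distance_nm = (pos[-1] + 10 * decay_width_nm) if pos else 2.0
    t_max = max_distance_nm / pull_rate
    times = np.arange(0.0, t_max, dt_ps)
    dist = pull_rate * times
    force = np.zeros_like(dist)
    peaks = []
    engage = 0.0
    for r_pos, kappa in ruptures:
        k_eff = spring_k * kappa / (spring_k + kappa)
        m = (dist > engage) & (dist <= r_pos)
        force[m] = k_eff * (dist[m] - engage)
        peaks.append(k_eff * (r_pos - engage))
        engage = r_pos
    if ruptures:
        tail = dist > engage
        force[tail] = peaks[-1] * np.exp(-(dist[tail] - engage) / decay_width_nm)
    rng = np.random.default_rng(seed)
    noisy = force + rng.normal(0.0, noise_sd, size=force.size)
    trace = PullTrace(times, noisy, pull_rate=pull_rate, spring_k=spring_k)
    truth = {
        "peak_forces": peaks,
        "rupture_distances_nm": pos,
        "decay_width_nm": decay_width_nm,
        "generator_version": GENERATOR_VERSION,
    }
    return trace, truth
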