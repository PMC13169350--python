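"""Umbrella-sampling datasets and WHAM free-energy reconstruction.

The weighted histogram analysis method combines biased reaction-coordinate
histograms from a ladder of harmonically restrained windows into one
unbiased potential of mean force. The self-consistent equations solved here
are the standard ones:

    P(b) = sum_i n_i(b) / sum_j N_j exp(-beta (u_j(b) - f_j))
    f_j  = -kT ln sum_b P(b) exp(-beta u_j(b))

iterated until the window free energies f_j stop moving. G(b) = -kT ln P(b),
anchored so the minimum is zero. All internal energies are kJ/mol; profiles
are reported in kcal/mol by default.

Two bias conventions are supported because the literature is split: the
"full" convention u = k (r - r0)^2 and the "half" convention u = k/2 (r -
r0)^2 used by most MD engines. The convention is stamped into every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (
    ConfigError,
    ConvergenceError,
    DisconnectedDatasetError,
    NoPlateauError,
)
from .md_io import read_xvg_series

__all__ = [
    "KB_KJ_PER_MOL_K",
    "KJ_PER_KCAL",
    "UmbrellaWindow",
    "WhamConfig",
    "PmfProfile",
    "BindingEnergyEstimate",
    "bias_energy",
    "wham_solve",
    "overlap_histograms",
    "block_convergence",
    "bootstrap_pmf",
    "extract_binding_energy",
    "read_window_manifest",
    "write_window_manifest",
]

KB_KJ_PER_MOL_K = 0.0083144621
KJ_PER_KCAL = 4.184


@dataclass
class UmbrellaWindow:
    """One harmonic window: reference position, force constant, samples."""

    r_nm: float
    k: float                       # kJ/mol/nm^2, in the dataset's convention
    samples: np.ndarray            # reaction-coordinate values, nm
    times_ps: np.ndarray | None = None
    window_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.k <= 0:
            raise ConfigError("window force constant must be positive")
        if self.samples.size == 0:
            raise ConfigError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("window samples must be finite")
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if self.times_ps.size != self.samples.size:
                raise ConfigError("times and samples must align")

    def truncated(self, t_max_ps: float) -> "UmbrellaWindow | None":
        if self.times_ps is None:
            raise ConfigError("window carries no times; cannot truncate")
        m = self.times_ps <= t_max_ps
        if not m.any():
            return None
        return UmbrellaWindow(self.r_nm, self.k, self.samples[m],
                              self.times_ps[m], self.window_id)


@dataclass
class WhamConfig:
    """Solver settings. ``bias_convention``: "full" for u = k(r-r0)^2 (as in
    the umbrella-sampling write-ups that print the bias without the half) or
    "half" for the engine convention u = k/2 (r-r0)^2."""

    temperature_k: float = 310.0
    bin_edges: np.ndarray | None = None
    n_bins: int = 200
    tolerance_kj: float = 1e-6
    max_iterations: int = 100000
    bias_convention: str = "full"
    output_unit: str = "kcal/mol"

    def __post_init__(self):
        if self.temperature_k <= 0:
            raise ConfigError("temperature must be positive")
        if self.tolerance_kj <= 0:
            raise ConfigError("tolerance must be positive")
        if self.bias_convention not in ("full", "half"):
            raise ConfigError("bias_convention must be 'full' or 'half'")
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.size < 3:
                raise ConfigError("need at least 2 bins")
        elif self.n_bins < 2:
            raise ConfigError("need at least 2 bins")

    @property
    def kt_kj(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature_k

    def energy_scale(self) -> float:
        """Factor converting kJ/mol to the configured output unit."""
        return 1.0 / KJ_PER_KCAL if self.output_unit == "kcal/mol" else 1.0


@dataclass
class PmfProfile:
    """Reconstructed free-energy profile, min-anchored at zero."""

    bin_centers_nm: np.ndarray
    free_energy: np.ndarray        # output unit; NaN where the bin is empty
    unit: str
    window_free_energies_kj: np.ndarray
    iterations: int
    bias_convention: str
    temperature_k: float
    bootstrap_sd: np.ndarray | None = None
    residual_history: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "bin_center_nm": self.bin_centers_nm,
            f"G_{'kcal_mol' if self.unit == 'kcal/mol' else 'kj_mol'}":
                self.free_energy,
        })
        if self.bootstrap_sd is not None:
            df["sd"] = self.bootstrap_sd
        return df


@dataclass
class BindingEnergyEstimate:
    """Binding free energy read off a PMF as plateau minus bound minimum."""

    delta_g: float
    unit: str
    minimum_nm: float
    plateau_interval_nm: tuple[float, float]
    criterion: str


def bias_energy(xi, window: UmbrellaWindow, convention: str = "full"):
    """Harmonic bias energy (kJ/mol) at reaction-coordinate value(s) xi."""
    xi = np.asarray(xi, dtype=float)
    d2 = (xi - window.r_nm) ** 2
    if convention == "full":
        return window.k * d2
    if convention == "half":
        return 0.5 * window.k * d2
    raise ConfigError("convention must be 'full' or 'half'")


def _bin_edges(windows: list[UmbrellaWindow], cfg: WhamConfig) -> np.ndarray:
    if cfg.bin_edges is not None:
        return cfg.bin_edges
    pooled_min = min(w.samples.min() for w in windows)
    pooled_max = max(w.samples.max() for w in windows)
    span = pooled_max - pooled_min
    pad = 0.01 * span if span > 0 else 0.01
    return np.linspace(pooled_min - pad, pooled_max + pad, cfg.n_bins + 1)


def _check_connected(counts: np.ndarray):
    """Windows whose histogram supports share no bin cannot be stitched."""
    n_win = counts.shape[0]
    if n_win == 1:
        return
    adj = [[] for _ in range(n_win)]
    for i in range(n_win):
        for j in range(i + 1, n_win):
            if np.any((counts[i] > 0) & (counts[j] > 0)):
                adj[i].append(j)
                adj[j].append(i)
    seen, stack = {0}, [0]
    while stack:
        for j in adj[stack.pop()]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if len(seen) < n_win:
        raise DisconnectedDatasetError(
            f"umbrella windows form {n_win - len(seen) + 1}+ clusters with no "
            "histogram overlap; add intermediate windows")


def wham_solve(windows: list[UmbrellaWindow], cfg: WhamConfig | None = None
               ) -> PmfProfile:
    """Self-consistent WHAM solution over the supplied windows.

    Deterministic for fixed inputs. Bins never visited by any window are
    masked (NaN) in the output; interpolation across them is refused
    downstream. Raises :class:`ConvergenceError` when the window free
    energies have not settled within the iteration budget.
    """
    cfg = cfg or WhamConfig()
    if not windows:
        raise ConfigError("at least one window required")
    edges = _bin_edges(windows, cfg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win, n_bin = len(windows), centers.size

    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows]).astype(float)
    _check_connected(counts)
    n_b = counts.sum(axis=0)
    covered = n_b > 0
    if not covered.any():
        raise ConfigError("no samples fall inside the requested bins")

    beta = 1.0 / cfg.kt_kj
    bias = np.stack([bias_energy(centers, w, cfg.bias_convention)
                     for w in windows])            # (W, B), kJ/mol
    log_n_samples = np.log(np.array([w.samples.size for w in windows],
                                    dtype=float))
    log_counts = np.where(covered, np.log(np.where(covered, n_b, 1.0)), -np.inf)

    f = np.zeros(n_win)
    residuals = []
    neg_beta_bias = -beta * bias
    for it in range(1, cfg.max_iterations + 1):
        # log denominator per bin: logsumexp_j [ln N_j + beta f_j - beta u_j(b)]
        log_denom = logsumexp(neg_beta_bias
                              + (log_n_samples + beta * f)[:, None], axis=0)
        log_p = log_counts - log_denom
        log_p -= logsumexp(log_p[covered])
        f_new = -cfg.kt_kj * logsumexp(log_p[None, covered]
                                       + neg_beta_bias[:, covered], axis=1)
        f_new -= f_new[0]                          # gauge: f_1 = 0
        resid = float(np.max(np.abs(f_new - f)))
        residuals.append(resid)
        f = f_new
        if resid < cfg.tolerance_kj:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {cfg.max_iterations} iterations "
            f"(last max |df| = {residuals[-1]:.3e} kJ/mol)",
            residual=residuals[-1])

    res_arr = np.asarray(residuals)
    burn = min(20, res_arr.size // 2)
    if res_arr.size > burn + 1:
        tail = res_arr[burn:]
        if np.any(tail[1:] > 1.5 * tail[:-1]):
            warnings.warn(
                "WHAM residual increased after burn-in; inspect "
                "residual_history on the returned profile", RuntimeWarning)

    g_kj = np.full(n_bin, np.nan)
    g_kj[covered] = -cfg.kt_kj * log_p[covered]
    g_kj -= np.nanmin(g_kj)
    scale = cfg.energy_scale()
    return PmfProfile(
        bin_centers_nm=centers,
        free_energy=g_kj * scale,
        unit=cfg.output_unit,
        window_free_energies_kj=f,
        iterations=it,
        bias_convention=cfg.bias_convention,
        temperature_k=cfg.temperature_k,
        residual_history=res_arr,
    )


def overlap_histograms(windows: list[UmbrellaWindow],
                       bin_edges: np.ndarray,
                       warn_threshold: float = 0.03
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Normalized per-window histograms and adjacent-pair overlap.

    Windows are ordered by reference position; the overlap coefficient of an
    adjacent pair is sum_b min(p_b, q_b) of the probability-mass histograms,
    1 for identical sampling and 0 for disjoint supports. Pairs below
    ``warn_threshold`` are flagged.
    """
    if len(windows) < 2:
        raise ConfigError("overlap diagnostics need at least 2 windows")
    order = np.argsort([w.r_nm for w in windows])
    ordered = [windows[i] for i in order]
    hists = np.stack([
        np.histogram(w.samples, bins=bin_edges)[0] / w.samples.size
        for w in ordered])
    rows = []
    for i in range(len(ordered) - 1):
        ov = float(np.minimum(hists[i], hists[i + 1]).sum())
        rows.append({
            "window_a": ordered[i].window_id or str(i),
            "window_b": ordered[i + 1].window_id or str(i + 1),
            "r_a_nm": ordered[i].r_nm,
            "r_b_nm": ordered[i + 1].r_nm,
            "overlap": ov,
            "flagged": ov < warn_threshold,
        })
    return hists, pd.DataFrame(rows)


def block_convergence(windows: list[UmbrellaWindow],
                      block_ends_ps: list[float],
                      cfg: WhamConfig | None = None
                      ) -> tuple[list[PmfProfile], list[float], list[list[str]]]:
    """WHAM re-solved on nested time blocks (0..t for each t).

    Returns (profiles, successive max |dG| over shared valid bins, dropped
    window ids per block). Overlaying successive profiles is the usual
    visual convergence check for umbrella sampling.
    """
    if any(b2 <= b1 for b1, b2 in zip(block_ends_ps, block_ends_ps[1:])):
        raise ConfigError("block ends must be strictly increasing")
    cfg = cfg or WhamConfig()
    profiles, dropped_all = [], []
    for t_end in block_ends_ps:
        kept, dropped = [], []
        for w in windows:
            tw = w.truncated(t_end)
            if tw is None:
                dropped.append(w.window_id)
            else:
                kept.append(tw)
        if not kept:
            raise ConfigError(f"no window has samples before {t_end} ps")
        profiles.append(wham_solve(kept, cfg))
        dropped_all.append(dropped)
    deltas = []
    for p1, p2 in zip(profiles, profiles[1:]):
        shared = p1.valid & p2.valid
        deltas.append(float(np.max(np.abs(p1.free_energy[shared]
                                          - p2.free_energy[shared]))))
    return profiles, deltas, dropped_all


def bootstrap_pmf(windows: list[UmbrellaWindow], cfg: WhamConfig | None = None,
                  n_boot: int = 50, seed: int = 0) -> np.ndarray:
    """Per-bin SD of the min-anchored PMF over bootstrap resamples.

    Each window's samples are resampled with replacement (window sizes
    preserved), WHAM is re-solved, and the profile re-anchored before the
    SD is taken. Deterministic for a fixed seed.
    """
    if n_boot < 2:
        raise ConfigError("n_boot must be >= 2")
    cfg = cfg or WhamConfig()
    if cfg.bin_edges is None:
        edges = _bin_edges(windows, cfg)
        cfg = WhamConfig(temperature_k=cfg.temperature_k, bin_edges=edges,
                         tolerance_kj=cfg.tolerance_kj,
                         max_iterations=cfg.max_iterations,
                         bias_convention=cfg.bias_convention,
                         output_unit=cfg.output_unit)
    rng = np.random.default_rng(seed)
    gs = []
    for _ in range(n_boot):
        resampled = [
            UmbrellaWindow(w.r_nm, w.k,
                           rng.choice(w.samples, size=w.samples.size,
                                      replace=True),
                           window_id=w.window_id)
            for w in windows]
        gs.append(wham_solve(resampled, cfg).free_energy)
    gs = np.stack(gs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(gs, axis=0)


def extract_binding_energy(pmf: PmfProfile,
                           slope_tol: float = 0.5,
                           min_width_nm: float = 0.4,
                           at_xi_nm: float | None = None
                           ) -> BindingEnergyEstimate:
    """Binding free energy from a PMF.

    Default rule: the bound minimum is the global-minimum bin; the unbound
    plateau is the largest-separation contiguous run of valid bins whose
    local slope |dG/dxi| stays below ``slope_tol`` (output units per nm)
    over at least ``min_width_nm``. Delta G = mean plateau G minus minimum
    G. Passing ``at_xi_nm`` instead reads G at a fixed separation.
    """
    x = pmf.bin_centers_nm[pmf.valid]
    g = pmf.free_energy[pmf.valid]
    if x.size < 5:
        raise ConfigError("PMF needs at least 5 valid bins")
    imin = int(np.argmin(g))
    # local slopes on fine bins are sampling-noise dominated; smooth over a
    # half of the required plateau width before differencing
    from .traj_metrics import MetricSeries, moving_average
    g_s = moving_average(MetricSeries(x, g), min_width_nm / 2.0).values
    if at_xi_nm is not None:
        j = int(np.argmin(np.abs(x - at_xi_nm)))
        return BindingEnergyEstimate(
            delta_g=float(g[j] - g[imin]), unit=pmf.unit,
            minimum_nm=float(x[imin]),
            plateau_interval_nm=(float(x[j]), float(x[j])),
            criterion=f"fixed-xi readout at {at_xi_nm} nm")
    # finite-difference slope over a ~min_width/4 step so sampling noise in
    # individual bins does not masquerade as curvature
    m = max(1, int(np.searchsorted(x, x[0] + min_width_nm / 2.0)))
    m = min(m, x.size - 1)
    slopes = np.abs((g_s[m:] - g_s[:-m]) / (x[m:] - x[:-m]))
    flat = slopes < slope_tol
    # maximal runs of flat intervals; keep the largest-separation run that is
    # wide enough (the far-most bins may be poorly sampled and are not
    # required to belong to it)
    runs, start = [], None
    for i, ok in enumerate(flat):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, flat.size - 1))
    candidates = [(a, b + m) for a, b in runs if x[b + m] - x[a] >= min_width_nm]
    if not candidates:
        raise NoPlateauError(
            "no flat large-separation region of at least "
            f"{min_width_nm} nm; extend the reaction-coordinate coverage")
    lo, hi = max(candidates, key=lambda ab: x[ab[1]])   # plateau bins [lo, hi]
    plateau_g = float(np.mean(g[lo:hi + 1]))
    return BindingEnergyEstimate(
        delta_g=plateau_g - float(g[imin]),
        unit=pmf.unit,
        minimum_nm=float(x[imin]),
        plateau_interval_nm=(float(x[lo]), float(x[hi])),
        criterion=f"plateau mean, slope < {slope_tol} {pmf.unit}/nm over "
                  f">= {min_width_nm} nm")


# ---------------------------------------------------------------------------
# Window manifest I/O
# ---------------------------------------------------------------------------

def read_window_manifest(path, base_dir=None) -> list[UmbrellaWindow]:
    """Load windows from a TSV manifest (window_id, r_nm, k, samples_file);
    each samples file is an XVG-style (time_ps, xi_nm) series."""
    df = pd.read_csv(path, sep="\t")
    required = {"window_id", "r_nm", "k", "samples_file"}
    if not required.issubset(df.columns):
        raise ConfigError(f"manifest must have columns {sorted(required)}")
    base = Path(base_dir) if base_dir else Path(path).parent
    windows = []
    for _, row in df.iterrows():
        t, xi = read_xvg_series(base / row["samples_file"])
        windows.append(UmbrellaWindow(float(row["r_nm"]), float(row["k"]),
                                      xi, t, str(row["window_id"])))
    return windows


def write_window_manifest(windows: list[UmbrellaWindow], out_dir) -> Path:
    """Write windows as manifest + per-window XVG sample files."""
    from .md_io import write_xvg_series
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        wid = w.window_id or f"w{i:03d}"
        fname = f"{wid}.xvg"
        times = (w.times_ps if w.times_ps is not None
                 else np.arange(w.samples.size, dtype=float))
        write_xvg_series(times, w.samples, out / fname,
                         title=f"window {wid} xi samples")
        rows.append({"window_id": wid, "r_nm": w.r_nm, "k": w.k,
                     "samples_file": fname})
    manifest = out / "windows.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
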