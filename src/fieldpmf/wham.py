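"""Weighted-histogram (WHAM) reconstruction of 1-D free-energy profiles.

Harmonically biased umbrella windows along a reaction coordinate are
combined into one unbiased potential of mean force by self-consistent
iteration of the per-window free-energy offsets.  The solve is
deterministic; statistical uncertainty comes from a bootstrap over the
retained samples.  Overlap and first-half/second-half convergence
diagnostics mirror the checks every umbrella-sampling study is expected
to report.

Conventions baked in here (each switchable):

* restraint energy is ``U(x) = k (x - x0)^2`` — the AMBER convention,
  *without* the 1/2 factor — unless ``half_k`` is set;
* the leading ``discard_fraction`` of every window is equilibration and is
  dropped (0.5 by default, i.e. "the last half of each window");
* empty bins are masked, never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import R_KCAL
from .errors import (
    BootstrapFailureError,
    ConvergenceError,
    InsufficientDataError,
    NoBarrierError,
)
from .structures_io import WindowSeries

__all__ = [
    "BiasSpec",
    "UmbrellaWindow",
    "WhamConfig",
    "FreeEnergyProfile",
    "BootstrapResult",
    "OverlapResult",
    "wham_solve",
    "bootstrap_pmf",
    "barrier_from_profile",
    "overlap_diagnostic",
    "convergence_check",
]


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic restraint on the coordinate: center (A), k (kcal/mol/A^2).

    ``half_k=False`` (default) means U = k (x-x0)^2; ``half_k=True`` means
    U = k/2 (x-x0)^2.  The two conventions differ by a factor of two in the
    effective stiffness, so the flag is part of the window definition.
    """

    center: float
    force_constant: float
    half_k: bool = False

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")

    def energy(self, x: np.ndarray) -> np.ndarray:
        k = 0.5 * self.force_constant if self.half_k else self.force_constant
        return k * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass
class UmbrellaWindow:
    """One biased window: restraint spec plus its sampled coordinate series."""

    bias: BiasSpec
    series: WindowSeries

    def __post_init__(self):
        if len(self.series) == 0:
            raise ValueError("window series is empty")


@dataclass
class WhamConfig:
    temperature: float = 343.15      # K
    bin_width: float = 0.02          # A
    tolerance: float = 1e-5          # kcal/mol, max |offset change| per sweep
    max_iterations: int = 1_000_000
    n_bootstrap: int = 100
    discard_fraction: float = 0.5
    seed: int = 0
    damping: float = 1.0             # fixed-point relaxation factor in (0, 1]

    def __post_init__(self):
        if self.temperature <= 0 or self.bin_width <= 0 or self.tolerance <= 0:
            raise ValueError("temperature, bin_width and tolerance must be positive")
        if not 0 <= self.discard_fraction < 1:
            raise ValueError("discard_fraction must be in [0, 1)")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature


@dataclass
class FreeEnergyProfile:
    """Binned PMF (kcal/mol, min-shifted to 0) with bootstrap uncertainties.

    Unoccupied bins carry NaN in ``pmf``/``pmf_std`` and False in
    ``occupied_mask``.
    """

    bin_centers: np.ndarray
    pmf: np.ndarray
    pmf_std: np.ndarray
    window_offsets: np.ndarray
    occupied_mask: np.ndarray

    @property
    def occupied_pmf(self) -> np.ndarray:
        return self.pmf[self.occupied_mask]

    @property
    def occupied_centers(self) -> np.ndarray:
        return self.bin_centers[self.occupied_mask]


@dataclass
class BootstrapResult:
    pmf_std: np.ndarray
    barrier_std: float | None
    n_replicates: int
    n_failed: int


@dataclass
class OverlapResult:
    matrix: np.ndarray
    min_adjacent: float
    order: list[int]   # window indices sorted by bias center


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _retained(w: UmbrellaWindow, discard_fraction: float) -> np.ndarray:
    vals = np.asarray(w.series.values, dtype=float)
    return vals[int(np.floor(discard_fraction * len(vals))):]

def _make_grid(samples: Sequence[np.ndarray], bin_width: float) -> np.ndarray:
    """Uniform bin edges spanning all samples, padded by one bin each side."""
    lo = min(s.min() for s in samples) - bin_width
    hi = max(s.max() for s in samples) + bin_width
    n = max(1, int(np.ceil((hi - lo) / bin_width)))
    return lo + bin_width * np.arange(n + 1)

def _solve(
    samples: Sequence[np.ndarray],
    biases: Sequence[BiasSpec],
    config: WhamConfig,
    edges: np.ndarray,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Self-consistent WHAM on pre-retained samples and a fixed grid.

    Returns (bin_centers, pmf with NaN off-support, occupied mask, offsets).
    """
    rt = config.rt
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    n_per_window = np.array([len(s) for s in samples], dtype=float)
    for s in samples:
        counts += np.histogram(s, bins=edges)[0]
    occupied = counts > 0

    # bias energies at bin centers, in units of RT
    b = np.array([bs.energy(centers) for bs in biases]) / rt      # (W, B)
    log_n = np.where(occupied, np.log(np.maximum(counts, 1)), -np.inf)
    log_nw = np.log(n_per_window)

    f = np.zeros(len(samples)) if f_init is None else np.array(f_init, dtype=float)
    lam = config.damping
    for _ in range(config.max_iterations):
        # log p_j  (unnormalised) on occupied bins
        log_p = log_n - logsumexp(log_nw[:, None] + f[:, None] / rt - b, axis=0)
        log_p -= logsumexp(log_p[occupied])
        f_new = -rt * logsumexp(log_p[None, occupied] - b[:, occupied], axis=1)
        delta = np.max(np.abs(f_new - f))
        f = (1 - lam) * f + lam * f_new
        if delta < config.tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM offsets not converged after {config.max_iterations} iterations "
            f"(residual {delta:.3g} kcal/mol)"
        )

    pmf = np.full(len(centers), np.nan)
    pmf[occupied] = -rt * log_p[occupied]
    pmf[occupied] -= np.nanmin(pmf[occupied])
    return centers, pmf, occupied, f


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    config: WhamConfig,
    edges: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Reconstruct the unbiased PMF from harmonically biased windows.

    Deterministic given inputs; ``pmf_std`` is zero-filled here and
    populated by :func:`bootstrap_pmf`.  Adjacent windows (by bias center)
    with no histogram overlap trigger a warning, not an error — the profile
    is still returned, piecewise.
    """
    if len(windows) < 1:
        raise InsufficientDataError("need at least one window")
    samples = [_retained(w, config.discard_fraction) for w in windows]
    for i, s in enumerate(samples):
        if len(s) == 0:
            raise InsufficientDataError(f"window {i}: no samples retained")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"window {i}: non-finite samples")
    if edges is None:
        edges = _make_grid(samples, config.bin_width)

    if len(windows) > 1:
        ov = overlap_diagnostic(windows, config)
        if ov.min_adjacent == 0.0:
            warnings.warn(
                "adjacent umbrella windows with zero histogram overlap; "
                "the profile is only determined piecewise",
                stacklevel=2,
            )

    biases = [w.bias for w in windows]
    centers, pmf, occupied, f = _solve(samples, biases, config, edges)
    return FreeEnergyProfile(
        bin_centers=centers,
        pmf=pmf,
        pmf_std=np.where(occupied, 0.0, np.nan),
        window_offsets=f,
        occupied_mask=occupied,
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    config: WhamConfig,
    reactant_side: str = "left",
) -> BootstrapResult:
    """Bootstrap uncertainty of the PMF (and of its barrier).

    Each of ``config.n_bootstrap`` replicates resamples the *retained*
    points of every window with replacement (window identities fixed),
    re-solves on the full-data grid, min-shifts, and the per-bin standard
    deviation over replicates is reported.  Seeded and reproducible.
    """
    samples = [_retained(w, config.discard_fraction) for w in windows]
    edges = _make_grid(samples, config.bin_width)
    biases = [w.bias for w in windows]
    centers, pmf_full, occ_full, f_full = _solve(samples, biases, config, edges)

    rng = np.random.default_rng(config.seed)
    boot = np.full((config.n_bootstrap, len(centers)), np.nan)
    barriers = []
    n_failed = 0
    for r in range(config.n_bootstrap):
        resampled = [s[rng.integers(0, len(s), size=len(s))] for s in samples]
        try:
            _, pmf_r, occ_r, _ = _solve(resampled, biases, config, edges, f_init=f_full)
        except ConvergenceError:
            n_failed += 1
            continue
        boot[r] = pmf_r
        try:
            dg, _ = barrier_from_profile(
                FreeEnergyProfile(centers, pmf_r, np.zeros_like(pmf_r), f_full, occ_r),
                reactant_side,
            )
            barriers.append(dg)
        except (NoBarrierError, InsufficientDataError):
            pass

    if n_failed > 0.1 * config.n_bootstrap:
        raise BootstrapFailureError(
            f"{n_failed}/{config.n_bootstrap} bootstrap replicates failed to converge"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        pmf_std = np.nanstd(boot, axis=0, ddof=1)
    pmf_std[~occ_full] = np.nan
    barrier_std = float(np.std(barriers, ddof=1)) if len(barriers) >= 2 else None
    return BootstrapResult(
        pmf_std=pmf_std,
        barrier_std=barrier_std,
        n_replicates=config.n_bootstrap - n_failed,
        n_failed=n_failed,
    )


def barrier_from_profile(
    profile: FreeEnergyProfile,
    reactant_side: str = "left",
) -> tuple[float, float]:
    """Extract (activation free energy, reaction free energy) from a PMF.

    The basins are the global minimum of the occupied profile and the
    local minimum of greatest topographic persistence relative to it (the
    highest separating ridge); the barrier is that ridge measured from the
    reactant-side basin and the reaction free energy is the far basin
    relative to it.  Persistence pairing keeps the extraction insensitive
    to shot-noise dips and spikes in sparsely sampled bins.  Ties break
    toward the reactant side.
    """
    if reactant_side not in ("left", "right"):
        raise ValueError("reactant_side must be 'left' or 'right'")
    y = profile.occupied_pmf
    if len(y) < 3:
        raise InsufficientDataError("profile needs >= 3 occupied bins")
    if reactant_side == "right":
        y = y[::-1]

    pad = np.concatenate([[np.inf], y, [np.inf]])
    minima = np.flatnonzero((y <= pad[:-2]) & (y <= pad[2:]))
    if len(minima) < 2:
        raise NoBarrierError("profile is monotonic: no interior maximum")
    g = int(np.argmin(y))
    best, best_persistence = None, -np.inf
    for m in minima:
        if m == g:
            continue
        lo, hi = (m, g) if m < g else (g, m)
        persistence = float(np.max(y[lo : hi + 1])) - float(y[m])
        if persistence > best_persistence:
            best, best_persistence = int(m), persistence
    i, j = (best, g) if best < g else (g, best)
    t = i + int(np.argmax(y[i : j + 1]))  # first occurrence = reactant side
    top = float(y[t])
    if top <= y[i] or top <= y[j]:
        raise NoBarrierError("no interior maximum between the basin minima")
    # reactant basin is the one nearer the reactant-side end
    return top - float(y[i]), float(y[j]) - float(y[i])


def overlap_diagnostic(
    windows: Sequence[UmbrellaWindow],
    config: WhamConfig,
) -> OverlapResult:
    """Pairwise histogram-overlap matrix and the minimum over adjacent pairs.

    Overlap of two windows is ``sum_bins min(p_i, p_j)`` of their normalised
    histograms on the common grid — 1 for identical sampling, 0 for disjoint
    support.  Zero overlap is a reported outcome, never an error.
    """
    if len(windows) < 2:
        raise InsufficientDataError("need >= 2 windows for overlap")
    samples = [_retained(w, config.discard_fraction) for w in windows]
    edges = _make_grid(samples, config.bin_width)
    p = np.array([np.histogram(s, bins=edges)[0] / len(s) for s in samples])
    n = len(windows)
    mat = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            mat[a, b] = mat[b, a] = np.minimum(p[a], p[b]).sum()
    order = sorted(range(n), key=lambda k: windows[k].bias.center)
    adj = [mat[order[k], order[k + 1]] for k in range(n - 1)]
    return OverlapResult(matrix=mat, min_adjacent=float(min(adj)), order=order)


def convergence_check(
    windows: Sequence[UmbrellaWindow],
    config: WhamConfig,
) -> float:
    """Max |PMF difference| between first-half and second-half solves.

    The retained samples of every window are split into disjoint halves and
    each half is solved on the common grid; both profiles are min-shifted
    and compared on bins occupied in both halves *within the range spanned
    by the bias centers* — outside it only a handful of tail samples land,
    whose histogram shot noise would swamp the drift signal the diagnostic
    is after.  Small values indicate the profile no longer changes with
    additional sampling.
    """
    samples = [_retained(w, config.discard_fraction) for w in windows]
    for i, s in enumerate(samples):
        if len(s) < 4:
            raise InsufficientDataError(
                f"window {i}: {len(s)} retained samples, need >= 4 for half-split"
            )
    edges = _make_grid(samples, config.bin_width)
    biases = [w.bias for w in windows]
    halves = []
    for part in (0, 1):
        sub = [s[: len(s) // 2] if part == 0 else s[len(s) // 2 :] for s in samples]
        _, pmf, occ, _ = _solve(sub, biases, config, edges)
        halves.append((pmf, occ))
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo = min(b.center for b in biases)
    hi = max(b.center for b in biases)
    both = halves[0][1] & halves[1][1]
    if len(biases) > 1:
        both &= (centers >= lo) & (centers <= hi)
    return float(np.max(np.abs(halves[0][0][both] - halves[1][0][both])))
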