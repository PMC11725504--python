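"""Distributional interpolation of gene expression along pseudotime.

Each gene's raw expression-vs-pseudotime scatter is summarized at m equispaced
interpolation points on [0, 1]. At each point t' a Gaussian N(mean, sd) is
estimated by Gaussian-kernel weighting of all cells, with the sd scaled by the
local weighted cell density c_t' so that sparsely populated regions do not
inflate variance. A fixed number of points is then sampled from each Gaussian;
these samples are the data vectors consumed by the MML match cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AlignmentConfig

__all__ = [
    "InterpolatedGene",
    "kernel_weights",
    "interpolate_gene",
    "apply_extreme_case_rules",
]

#: Minimum number of expressing cells for a region/gene to count as expressed.
MIN_EXPRESSING_CELLS = 3

#: Zero-expression runs longer than this fraction of the [0,1] axis trigger
#: the abrupt-zero correction.
ZERO_REGION_MIN_LENGTH = 0.2


@dataclass
class InterpolatedGene:
    """Per-interpolation-point Gaussian summary of one gene's trajectory.

    ``samples`` has shape ``(m, n_samples_per_point)`` and holds draws from
    ``N(means[k], sds[k])`` at each grid point; ``densities`` holds the
    weighted cell density c_t' in (0, 1].
    """

    grid: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    densities: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.grid)
        if not (len(self.means) == len(self.sds) == len(self.densities) == m):
            raise ValueError("grid/means/sds/densities length mismatch")
        if self.samples.shape[0] != m:
            raise ValueError("samples row count must equal grid length")
        if np.any(self.sds < 0):
            raise ValueError("negative interpolated s.d.")

    @property
    def m(self) -> int:
        return len(self.grid)


def kernel_weights(cell_times: np.ndarray, t_prime: float, window_size: float) -> np.ndarray:
    """Gaussian kernel weight of each cell relative to interpolation point t'.

    ``w_i = exp(-(t_i - t')^2 / window_size^2)``; equals 1 exactly when
    ``t_i == t'`` and decays with squared distance on the window scale.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    t = np.asarray(cell_times, dtype=float)
    return np.exp(-((t - t_prime) ** 2) / window_size**2)


def _sample_rng(seed: int, gene_index: int, grid_index: int) -> np.random.Generator:
    # one independent stream per (seed, gene, grid point): per-gene results do
    # not depend on processing order
    return np.random.default_rng(np.random.SeedSequence([seed, gene_index, grid_index]))


def interpolate_gene(
    expr: np.ndarray,
    times: np.ndarray,
    config: AlignmentConfig,
    m: int | None = None,
    gene_index: int = 0,
) -> InterpolatedGene:
    """Interpolate one gene onto m equispaced points of [0, 1].

    The weighted mean at t' is the kernel-weighted average of expression.
    The weighted s.d. takes deviations about the *global* (unweighted) gene
    mean and is scaled by the weighted cell density ``c_t' = sum(w)/n``.
    Samples are drawn from each point's Gaussian with a stream seeded from
    (config.seed, gene_index, grid index).
    """
    expr = np.asarray(expr, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    n = expr.size
    if n != times.size:
        raise ValueError("expression and pseudotime lengths differ")
    if n < 2:
        raise ValueError("need at least two cells to interpolate")
    if m is None:
        if config.n_interp_points is None:
            raise ValueError("number of interpolation points not specified")
        m = config.n_interp_points
    if m < 2:
        raise ValueError("need at least two interpolation points")

    grid = np.linspace(0.0, 1.0, m)
    # W[k, i] = weight of cell i at grid point k
    W = np.exp(-((times[None, :] - grid[:, None]) ** 2) / config.window_size**2)
    wsum = W.sum(axis=1)
    means = (W @ expr) / wsum
    densities = wsum / n
    global_mean = expr.mean()
    dev2 = (global_mean - expr) ** 2
    sds = densities * np.sqrt(n * (W @ dev2) / ((n - 1) * wsum))

    samples = np.empty((m, config.n_samples_per_point))
    for k in range(m):
        rng = _sample_rng(config.seed, gene_index, k)
        samples[k] = rng.normal(means[k], sds[k], size=config.n_samples_per_point)
    return InterpolatedGene(grid=grid, means=means, sds=sds, densities=densities, samples=samples)


def _resample(ig: InterpolatedGene, config: AlignmentConfig, gene_index: int) -> None:
    """Redraw samples after means/sds were corrected (same streams as before)."""
    for k in range(ig.m):
        rng = _sample_rng(config.seed, gene_index, k)
        ig.samples[k] = rng.normal(ig.means[k], ig.sds[k], size=config.n_samples_per_point)


def _zero_region_flags(
    expr: np.ndarray, times: np.ndarray, grid: np.ndarray, window_size: float
) -> np.ndarray:
    """Flag grid points inside long abrupt-zero-expression regions.

    A grid point is locally zero when fewer than MIN_EXPRESSING_CELLS cells
    with pseudotime within +/- window_size of it have expression > 0. Runs of
    adjacent locally-zero points spanning more than ZERO_REGION_MIN_LENGTH of
    the axis are flagged (window stride = grid spacing).
    """
    expressing = expr > 0
    local_zero = np.zeros(len(grid), dtype=bool)
    for k, t in enumerate(grid):
        in_win = np.abs(times - t) <= window_size
        local_zero[k] = int(np.count_nonzero(expressing & in_win)) < MIN_EXPRESSING_CELLS
    flags = np.zeros(len(grid), dtype=bool)
    k = 0
    while k < len(grid):
        if local_zero[k]:
            j = k
            while j + 1 < len(grid) and local_zero[j + 1]:
                j += 1
            if grid[j] - grid[k] > ZERO_REGION_MIN_LENGTH:
                flags[k : j + 1] = True
            k = j + 1
        else:
            k += 1
    return flags


def _low_sigma(sds: np.ndarray, floor: float) -> float:
    """10% of the minimum positive estimated sigma, or the floor if none exist."""
    pos = sds[sds > 0]
    if pos.size == 0:
        return floor
    return max(0.1 * float(pos.min()), 0.0) or floor


def apply_extreme_case_rules(
    ref: InterpolatedGene,
    query: InterpolatedGene,
    ref_expr: np.ndarray,
    ref_times: np.ndarray,
    query_expr: np.ndarray,
    query_times: np.ndarray,
    config: AlignmentConfig,
    gene_index: int = 0,
) -> tuple[InterpolatedGene, InterpolatedGene]:
    """Correct interpolations where the smooth-trajectory assumption breaks.

    Rule 1: within either trajectory, runs of adjacent interpolation points
    with abrupt zero expression (< 3 expressing cells per kernel window)
    spanning more than 0.2 of the pseudotime axis get mean 0 and a common
    very low sigma (10% of that trajectory's minimum estimated sigma).

    Rule 2: a gene with < 3 expressing cells across a whole trajectory has no
    distribution to model; every point of that trajectory gets sigma equal to
    10% of the *other* trajectory's minimum sigma (and vice versa). If both
    sides are degenerate, ``config.sigma_floor`` is used.

    Corrected points have their samples redrawn. Inputs are modified in place
    and returned.
    """
    ref_expr = np.asarray(ref_expr, dtype=float).ravel()
    query_expr = np.asarray(query_expr, dtype=float).ravel()
    ref_changed = query_changed = False

    ref_all_zero = int(np.count_nonzero(ref_expr > 0)) < MIN_EXPRESSING_CELLS
    query_all_zero = int(np.count_nonzero(query_expr > 0)) < MIN_EXPRESSING_CELLS

    if ref_all_zero or query_all_zero:
        ref_low = _low_sigma(ref.sds, config.sigma_floor)
        query_low = _low_sigma(query.sds, config.sigma_floor)
        if ref_all_zero:
            ref.sds[:] = query_low if not query_all_zero else config.sigma_floor
            ref.means[:] = 0.0
            ref_changed = True
        if query_all_zero:
            query.sds[:] = ref_low if not ref_all_zero else config.sigma_floor
            query.means[:] = 0.0
            query_changed = True
    else:
        for ig, expr, times, is_ref in (
            (ref, ref_expr, ref_times, True),
            (query, query_expr, query_times, False),
        ):
            flags = _zero_region_flags(expr, np.asarray(times, float), ig.grid, config.window_size)
            if flags.any():
                low = _low_sigma(ig.sds, config.sigma_floor)
                ig.means[flags] = 0.0
                ig.sds[flags] = low
                if is_ref:
                    ref_changed = True
                else:
                    query_changed = True

    if ref_changed:
        _resample(ref, config, gene_index)
    if query_changed:
        _resample(query, config, gene_index)
    return ref, query
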