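"""Gaussian-process simulation of labeled trajectory pairs.

The simulator is the package's self-contained test bed. It produces
reference/query gene-trajectory pairs with known ground truth:

* matching: both trajectories are noisy draws around one shared mean
  function sampled from a GP with a constant mean and an RBF kernel;
* divergence: two branch functions share the base mean before a change
  point t_CP and deviate independently after it, via a change-point kernel
  whose branch covariance is switched on by a sigmoid at t_CP;
* convergence: a divergence pair with the pseudotime axis reversed;
* unrelated: reference and query drawn around independent GP mean functions
  with well-separated constant levels - no shared process at all.

Each trajectory has 300 cells spread across pseudotime [0, 1]. Expected
match/mismatch length ranges for divergence/convergence follow from where
the change-point kernel's variance first exceeds 0.01.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .data_io import Trajectory

__all__ = [
    "SimulatedPair",
    "BenchmarkReport",
    "simulate_matching_pair",
    "simulate_divergent_pair",
    "simulate_convergent_pair",
    "simulate_unrelated_pair",
    "simulate_battery",
    "invert_pair",
    "perturb_split_real_style",
    "evaluate_battery",
    "PATTERNS",
]

N_CELLS = 300
RBF_LENGTHSCALE = 0.5
#: Output scale of the branch (change-point) kernel.
RBF_OUTPUTSCALE = 1.0
#: Output scale of the GP that draws the shared base mean function; kept
#: below the branch scale so diverging branches can leave the base's value
#: band decisively.
BASE_OUTPUTSCALE = 0.25
SIGMOID_STEEPNESS = 50.0
DIVERGENCE_NOISE_SD = 0.3
BRANCH_COVARIANCE_THRESHOLD = 0.01
#: Clear-divergence filter: branch escape from the base band, in noise-s.d.
#: units (lower bound), and its cap (upper bound, absolute log-expression).
ESCAPE_MIN_NOISE_SD = 2.0
ESCAPE_MAX = 1.5
_JITTER = 1e-8

PATTERNS = (
    "matching",
    "div_early",
    "div_mid",
    "div_late",
    "conv_early",
    "conv_mid",
    "conv_late",
)
_TCP_BY_PATTERN = {"early": 0.25, "mid": 0.5, "late": 0.75}


@dataclass
class SimulatedPair:
    """One labeled reference/query gene-trajectory pair."""

    ref_expr: np.ndarray
    query_expr: np.ndarray
    times: np.ndarray
    label: str
    t_cp: float | None = None
    expected_match_range: tuple[int, int] | None = None
    expected_mismatch_range: tuple[int, int] | None = None
    noise_sd: float | None = None
    branch_ref: np.ndarray | None = None
    branch_query: np.ndarray | None = None


@dataclass
class BenchmarkReport:
    """Per-pattern accuracy of a battery of alignments against templates."""

    accuracy: dict[str, float]
    misclustering_rate: float | None
    per_pair: list[tuple[str, bool, str]]

    @property
    def overall_accuracy(self) -> float:
        n_ok = sum(ok for _, ok, _ in self.per_pair)
        return n_ok / len(self.per_pair)


def _rbf_kernel(t: np.ndarray) -> np.ndarray:
    d2 = (t[:, None] - t[None, :]) ** 2
    return RBF_OUTPUTSCALE * np.exp(-d2 / (2.0 * RBF_LENGTHSCALE**2))


#: Cholesky factors are reused across pairs: the kernels depend only on the
#: (fixed) cell grid and the change point.
_CHOL_CACHE: dict = {}


def _chol(K: np.ndarray, key) -> np.ndarray:
    if key not in _CHOL_CACHE:
        _CHOL_CACHE[key] = np.linalg.cholesky(K + _JITTER * np.eye(len(K)))
    return _CHOL_CACHE[key]


def _sample_gp(mean: np.ndarray, K: np.ndarray, rng: np.random.Generator, key=None) -> np.ndarray:
    if key is None:
        L = np.linalg.cholesky(K + _JITTER * np.eye(len(mean)))
    else:
        L = _chol(K, key)
    return mean + L @ rng.standard_normal(len(mean))


def _times() -> np.ndarray:
    return np.linspace(0.0, 1.0, N_CELLS)


def _sigmoid(t: np.ndarray, t_cp: float, s: float = SIGMOID_STEEPNESS) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-s * (t - t_cp)))


def change_point_kernel(t: np.ndarray, t_cp: float, s: float = SIGMOID_STEEPNESS) -> np.ndarray:
    """Branch covariance: zero before t_CP, RBF after, blended by a sigmoid.

    K_CP(t, t') = sig(t) sig(t') K_RBF(t, t'): the sigmoid weight attaches
    the RBF kernel to the post-change-point side and the zero kernel to the
    pre-change-point side, so branch functions coincide with the base mean
    before t_CP and deviate independently after it.
    """
    sig = _sigmoid(t, t_cp, s)
    return np.outer(sig, sig) * _rbf_kernel(t)


def expected_ranges(t_cp: float, n_points: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Covariance-derived expected match/mismatch length ranges.

    Branching can start slightly before t_CP: the nondivergent segment is
    expected to last at least until the first time i where the change-point
    kernel's variance exceeds 0.01. Match lengths then fall in
    [n_points * i, n_points * t_cp] (integer hull), and mismatch lengths in
    the complementary interval.
    """
    t = np.linspace(0.0, 1.0, 2001)
    var = _sigmoid(t, t_cp) ** 2 * RBF_OUTPUTSCALE
    above = np.flatnonzero(var > BRANCH_COVARIANCE_THRESHOLD)
    i = float(t[above[0]]) if len(above) else 1.0
    lo = int(np.floor(n_points * i))
    hi = int(np.ceil(n_points * t_cp))
    return (lo, hi), (n_points - hi, n_points - lo)


def _base_kernel(t: np.ndarray) -> np.ndarray:
    return BASE_OUTPUTSCALE * _rbf_kernel(t)


def simulate_matching_pair(seed: int, n_points: int = 15) -> SimulatedPair:
    """Two noisy draws around one shared GP mean function.

    The constant mean level c ~ U[0.5, 9.0] and the isotropic noise s.d.
    sigma ~ U[0.05, 1.0], as in a typical log1p expression range.
    """
    rng = np.random.default_rng(seed)
    t = _times()
    c = rng.uniform(0.5, 9.0)
    mu = _sample_gp(np.full(N_CELLS, c), _base_kernel(t), rng, key="base")
    sigma = rng.uniform(0.05, 1.0)
    ref = mu + sigma * rng.standard_normal(N_CELLS)
    query = mu + sigma * rng.standard_normal(N_CELLS)
    return SimulatedPair(
        ref_expr=ref,
        query_expr=query,
        times=t,
        label="matching",
        noise_sd=sigma,
        expected_match_range=(n_points, n_points),
        expected_mismatch_range=(0, 0),
        branch_ref=mu,
        branch_query=mu,
    )


def _divergence_candidates(
    rng: np.random.Generator, t_cp: float, batch: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample a batch of (base mean, branch 1, branch 2) column triples."""
    t = _times()
    Lb = _chol(_base_kernel(t), "base")
    Lcp = _chol(change_point_kernel(t, t_cp), ("cp", t_cp))
    c = rng.uniform(0.5, 9.0, size=batch)
    mu = c[None, :] + Lb @ rng.standard_normal((N_CELLS, batch))
    f1 = mu + Lcp @ rng.standard_normal((N_CELLS, batch))
    f2 = mu + Lcp @ rng.standard_normal((N_CELLS, batch))
    return t, mu, f1, f2


def _clear_divergence(
    t: np.ndarray,
    mu: np.ndarray,
    f1: np.ndarray,
    f2: np.ndarray,
    t_cp: float,
    delta: float = 0.05,
    post_margin: float = 0.1,
) -> bool:
    """Clear-divergence heuristic filter (stable ground truth, no complex patterns).

    Judged on the noiseless base mean and branch functions:

    1. the mean branch gap before the bifurcation (t < t_cp - delta) stays
       below 0.25 noise s.d.;
    2. after the bifurcation (t >= t_cp + post_margin) the branches sit on
       opposite sides of the base function's *entire* value band, each
       escaping it by more than ESCAPE_MIN_NOISE_SD noise s.d. at every
       time point - so neither branch can re-match the shared early
       segment, the other branch, or the base path at any pair of times;
    3. the escape stays below ESCAPE_MAX (moderate divergence): extreme
       excursions inflate the interpolated variance (deviations are taken
       about the global gene mean), which would blur the very boundary the
       pair is supposed to pin down.

    Pairs violating any condition have an ambiguous expected alignment
    (crossing, returning, or runaway branches) and are resampled.
    """
    pre = t < (t_cp - delta)
    post = t >= (t_cp + post_margin)
    if not pre.any() or not post.any():
        return False
    if abs(float(np.mean(f1[pre] - f2[pre]))) >= 0.25 * DIVERGENCE_NOISE_SD:
        return False
    sep = ESCAPE_MIN_NOISE_SD * DIVERGENCE_NOISE_SD
    band_lo, band_hi = float(np.min(mu)), float(np.max(mu))
    for fa, fb in ((f1, f2), (f2, f1)):
        up = fa[post] - band_hi
        down = band_lo - fb[post]
        if (
            np.all(up > sep)
            and np.all(up < ESCAPE_MAX)
            and np.all(down > sep)
            and np.all(down < ESCAPE_MAX)
        ):
            return True
    return False


def simulate_divergent_pair(
    t_cp: float, seed: int, n_points: int = 15, max_attempts: int = 20000
) -> SimulatedPair:
    """A pair sharing its process before t_CP and branching after it.

    Candidates are drawn in batches and resampled until the clear-divergence
    filter accepts one (stable ground truth with no complex patterns);
    isotropic noise is added to the accepted branch pair.
    """
    if not (0.0 < t_cp < 1.0):
        raise ValueError("t_cp must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    accepted = None
    tried = 0
    while accepted is None and tried < max_attempts:
        batch = min(64, max_attempts - tried)
        t, mu, F1, F2 = _divergence_candidates(rng, t_cp, batch)
        tried += batch
        for k in range(batch):
            if _clear_divergence(t, mu[:, k], F1[:, k], F2[:, k], t_cp):
                accepted = (F1[:, k].copy(), F2[:, k].copy())
                break
    if accepted is None:
        raise RuntimeError(
            f"no clear divergence candidate accepted in {max_attempts} attempts"
        )
    f1, f2 = accepted
    ref = f1 + DIVERGENCE_NOISE_SD * rng.standard_normal(N_CELLS)
    query = f2 + DIVERGENCE_NOISE_SD * rng.standard_normal(N_CELLS)
    label = {0.25: "div_early", 0.5: "div_mid", 0.75: "div_late"}.get(t_cp, "div_mid")
    match_rng, mismatch_rng = expected_ranges(t_cp, n_points)
    return SimulatedPair(
        ref_expr=ref,
        query_expr=query,
        times=t,
        label=label,
        t_cp=t_cp,
        expected_match_range=match_rng,
        expected_mismatch_range=mismatch_rng,
        noise_sd=DIVERGENCE_NOISE_SD,
        branch_ref=f1,
        branch_query=f2,
    )


def invert_pair(pair: SimulatedPair) -> SimulatedPair:
    """Reverse the pseudotime axis of a pair (divergence <-> convergence)."""
    flip = {
        "div_early": "conv_late",
        "div_mid": "conv_mid",
        "div_late": "conv_early",
        "conv_late": "div_early",
        "conv_mid": "div_mid",
        "conv_early": "div_late",
    }
    return SimulatedPair(
        ref_expr=pair.ref_expr[::-1].copy(),
        query_expr=pair.query_expr[::-1].copy(),
        times=pair.times.copy(),
        label=flip.get(pair.label, pair.label),
        t_cp=None if pair.t_cp is None else 1.0 - pair.t_cp,
        expected_match_range=pair.expected_match_range,
        expected_mismatch_range=pair.expected_mismatch_range,
        noise_sd=pair.noise_sd,
        branch_ref=None if pair.branch_ref is None else pair.branch_ref[::-1].copy(),
        branch_query=None if pair.branch_query is None else pair.branch_query[::-1].copy(),
    )


def simulate_convergent_pair(t_cp: float, seed: int, n_points: int = 15) -> SimulatedPair:
    """A pair mismatched early and converging at t_CP: an inverted divergence."""
    return invert_pair(simulate_divergent_pair(1.0 - t_cp, seed, n_points=n_points))


def simulate_unrelated_pair(
    seed: int, n_points: int = 15, min_level_gap: float = 3.0
) -> SimulatedPair:
    """Two trajectories with no shared process (negative control).

    Independent GP mean functions with constant levels at least
    ``min_level_gap`` apart guarantee that no region of the two trajectories
    follows a common process.
    """
    rng = np.random.default_rng(seed)
    t = _times()
    while True:
        c_ref, c_query = rng.uniform(0.5, 9.0, size=2)
        if abs(c_ref - c_query) >= min_level_gap:
            break
    mu_ref = _sample_gp(np.full(N_CELLS, c_ref), _base_kernel(t), rng, key="base")
    mu_query = _sample_gp(np.full(N_CELLS, c_query), _base_kernel(t), rng, key="base")
    ref = mu_ref + DIVERGENCE_NOISE_SD * rng.standard_normal(N_CELLS)
    query = mu_query + DIVERGENCE_NOISE_SD * rng.standard_normal(N_CELLS)
    return SimulatedPair(
        ref_expr=ref,
        query_expr=query,
        times=t,
        label="unrelated",
        noise_sd=DIVERGENCE_NOISE_SD,
        expected_match_range=(0, 0),
        expected_mismatch_range=(n_points, n_points),
        branch_ref=mu_ref,
        branch_query=mu_query,
    )


def simulate_battery(
    n_per_pattern: int = 500, seed: int = 0, n_points: int = 15
) -> list[SimulatedPair]:
    """The full 7-pattern battery: matching + 3 divergence + 3 convergence."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(7 * n_per_pattern)]
    pairs: list[SimulatedPair] = []
    k = 0
    for pattern in PATTERNS:
        for _ in range(n_per_pattern):
            s = seeds[k] % (2**31)
            k += 1
            if pattern == "matching":
                pairs.append(simulate_matching_pair(s, n_points))
            elif pattern.startswith("div"):
                t_cp = _TCP_BY_PATTERN[pattern.split("_")[1]]
                pairs.append(simulate_divergent_pair(t_cp, s, n_points))
            else:
                t_cp = _TCP_BY_PATTERN[pattern.split("_")[1]]
                pairs.append(simulate_convergent_pair(t_cp, s, n_points))
    return pairs


def perturb_split_real_style(
    expr: np.ndarray,
    times: np.ndarray,
    n_bins: int = 50,
    mode: str = "delete",
    n_perturbed_bins: int = 0,
    seed: int = 0,
) -> tuple[Trajectory, Trajectory]:
    """Split one trajectory into a reference/query pair with a known mismatch.

    Cells are assigned to ``n_bins`` equal-width pseudotime bins and randomly
    split half/half into reference and query within each bin. ``delete``
    removes query cells from the first ``n_perturbed_bins`` bins (query
    pseudotime is re-min-max-normalized afterwards); ``shift`` adds each
    gene's across-bin s.d. (computed over all query cells) to query
    expression in those bins.
    """
    X = np.atleast_2d(np.asarray(expr, dtype=float))
    if X.shape[0] == 1 and np.asarray(times).size != 1:
        X = X.T
    t = np.asarray(times, dtype=float).ravel()
    n_cells, n_genes = X.shape
    if t.size != n_cells:
        raise ValueError("expression and pseudotime lengths differ")
    if mode not in {"delete", "shift"}:
        raise ValueError("mode must be 'delete' or 'shift'")
    if not (0 <= n_perturbed_bins <= n_bins):
        raise ValueError("n_perturbed_bins out of range")

    rng = np.random.default_rng(seed)
    edges = np.linspace(t.min(), t.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)
    ref_mask = np.zeros(n_cells, dtype=bool)
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        if members.size == 0:
            raise ValueError(f"pseudotime bin {b} is empty")
        picked = rng.permutation(members)[: members.size // 2]
        ref_mask[picked] = True

    genes = [f"gene_{k}" for k in range(n_genes)]
    ref = Trajectory(
        expression=np.clip(X[ref_mask], 0.0, None),
        pseudotime=t[ref_mask],
        gene_names=genes,
        cell_ids=[f"ref_{k}" for k in np.flatnonzero(ref_mask)],
    )
    q_idx = np.flatnonzero(~ref_mask)
    q_expr = X[q_idx].copy()
    q_t = t[q_idx].copy()
    if n_perturbed_bins > 0:
        margin = edges[n_perturbed_bins]
        if mode == "delete":
            keep = q_t > margin
            if keep.sum() < 2:
                raise ValueError("deletion leaves too few query cells")
            q_expr, q_t, q_idx = q_expr[keep], q_t[keep], q_idx[keep]
            q_t = (q_t - q_t.min()) / (q_t.max() - q_t.min())
        else:
            sd = q_expr.std(axis=0, ddof=1)
            early = q_t <= margin
            q_expr[early] = q_expr[early] + sd[None, :]
    query = Trajectory(
        expression=np.clip(q_expr, 0.0, None),
        pseudotime=q_t,
        gene_names=genes,
        cell_ids=[f"query_{k}" for k in q_idx],
    )
    return ref, query


_TEMPLATES = {
    "matching": re.compile(r"^[MVW]+$"),
    "div": re.compile(r"^[MVW]+[ID]+$"),
    "conv": re.compile(r"^[ID]+[MVW]+$"),
    "unrelated": re.compile(r"^[ID]+$"),
}


def _check_pair(string: str, pair: SimulatedPair) -> tuple[bool, str]:
    label = pair.label
    kind = "div" if label.startswith("div") else "conv" if label.startswith("conv") else label
    if not _TEMPLATES[kind].match(string):
        return False, f"string does not fit the {kind} template"
    if kind in {"div", "conv"}:
        lo, hi = pair.expected_mismatch_range
        n_i, n_d = string.count("I"), string.count("D")
        if not (lo <= n_i <= hi):
            return False, f"insertion run {n_i} outside expected [{lo}, {hi}]"
        if not (lo <= n_d <= hi):
            return False, f"deletion run {n_d} outside expected [{lo}, {hi}]"
    return True, ""


def evaluate_battery(
    strings: list[str],
    pairs: list[SimulatedPair],
    cluster_labels: np.ndarray | None = None,
) -> BenchmarkReport:
    """Score alignment strings against their pattern's expected template.

    A pair is correct iff its string matches the pattern template (all
    match-type for matching; a match prefix followed by a mismatch suffix
    with per-trajectory mismatch lengths inside the covariance-derived
    expected range for divergence; mirrored for convergence; mismatch-only
    for the negative control). Optionally also reports the mis-clustering
    rate of provided cluster labels against the ground-truth patterns.
    """
    if len(strings) != len(pairs):
        raise ValueError("one alignment string per simulated pair required")
    per_pair: list[tuple[str, bool, str]] = []
    by_pattern: dict[str, list[bool]] = {}
    for s, pair in zip(strings, pairs):
        ok, reason = _check_pair(s, pair)
        per_pair.append((pair.label, ok, reason))
        by_pattern.setdefault(pair.label, []).append(ok)
    accuracy = {lab: float(np.mean(oks)) for lab, oks in by_pattern.items()}
    mis = None
    if cluster_labels is not None:
        from .analysis import misclustering_rate

        mis = misclustering_rate(cluster_labels, [p.label for p in pairs])
    return BenchmarkReport(accuracy=accuracy, misclustering_rate=mis, per_pair=per_pair)
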