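"""Statistics over sets of gene-level alignments.

Covers the similarity ranking, the cell-level aggregate alignment, string
distances and clustering of alignment patterns, and the empirical-null
significance machinery for MML expression distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from statsmodels.distributions.empirical_distribution import ECDF
from statsmodels.stats.multitest import multipletests

from .alignment import D, I, M, STATES, STEP, V, W, AlignmentResult
from .mml import EncodingParams, GaussianModel, match_cost

__all__ = [
    "alignment_similarity",
    "aggregate_alignment",
    "binary_encode",
    "string_distance_matrix",
    "cluster_alignments",
    "ClusterModel",
    "mml_null_significance",
    "distance_change_test",
]

MATCH_STATES = frozenset("MVW")
#: Fixed preference order used to break modal-state ties.
STATE_PREFERENCE = (M, W, V, D, I)


def alignment_similarity(string: str) -> float:
    """Percentage of match-type characters (M, V, W) in a five-state string."""
    if not string:
        raise ValueError("empty alignment string")
    bad = set(string) - set(STATES)
    if bad:
        raise ValueError(f"invalid alignment characters: {sorted(bad)}")
    return 100.0 * sum(ch in MATCH_STATES for ch in string) / len(string)


def rank_genes_by_similarity(results: dict[str, AlignmentResult]):
    """Genes ordered from temporally most distant to most similar."""
    import pandas as pd

    rows = [
        {
            "gene": g,
            "string": r.string,
            "similarity": r.similarity,
            "match_cost": r.match_cost_total,
            "state_cost": r.state_cost_total,
            "total_cost": r.total_cost,
        }
        for g, r in results.items()
    ]
    return pd.DataFrame(rows).sort_values("similarity").reset_index(drop=True)


def _feasible_states(i: int, j: int) -> tuple[int, ...]:
    if i > 0 and j > 0:
        return STATE_PREFERENCE
    if i == 0 and j > 0:
        return (D,)
    if j == 0 and i > 0:
        return (I,)
    return ()


def aggregate_alignment(results: list[AlignmentResult] | dict[str, AlignmentResult]) -> str:
    """Single cell-level alignment by modal-state traversal of the landscapes.

    Starting from the terminal cell of the optimal-cost landscape, the most
    frequent argmin state across all genes is chosen (ties broken in the
    fixed order M > W > V > D > I), the walk steps according to that state's
    semantics, and the reversed state sequence is returned.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValueError("empty alignment set")
    shape = results[0].matrix_shape
    if any(r.matrix_shape != shape for r in results):
        raise ValueError("alignments span different matrix shapes")
    mQ, mR = shape
    i, j = mQ, mR
    rev: list[int] = []
    while (i, j) != (0, 0):
        feasible = _feasible_states(i, j)
        votes = Counter(
            int(r.state_landscape[i, j]) for r in results if int(r.state_landscape[i, j]) in feasible
        )
        if votes:
            top = max(votes.values())
            x = next(s for s in STATE_PREFERENCE if votes.get(s) == top)
        else:
            x = feasible[0]
        rev.append(x)
        di, dj = STEP[x]
        i, j = i - di, j - dj
    return "".join(STATES[s] for s in reversed(rev))


def binary_encode(string: str, len_R: int, len_Q: int) -> str:
    """Encode a five-state string as a binary string of length |R| + |Q|.

    The alignment path is walked left to right; each reference time point and
    each query time point records 1 if its state is match-type (M, V, W) and
    0 otherwise. The per-point bits are concatenated reference-first.
    """
    r_bits: list[str] = []
    q_bits: list[str] = []
    i = j = 0
    for ch in string:
        bit = "1" if ch in MATCH_STATES else "0"
        if ch == "M":
            i, j = i + 1, j + 1
            r_bits.append(bit)
            q_bits.append(bit)
        elif ch == "W":  # consumes a reference point
            j += 1
            r_bits.append(bit)
        elif ch == "V":  # consumes a query point
            i += 1
            q_bits.append(bit)
        elif ch == "D":
            j += 1
            r_bits.append(bit)
        elif ch == "I":
            i += 1
            q_bits.append(bit)
        else:
            raise ValueError(f"invalid state character {ch!r}")
    if i != len_Q or j != len_R:
        raise ValueError(
            f"string walk ends at (|Q|={i}, |R|={j}), expected ({len_Q}, {len_R})"
        )
    # W marks the shared query point matched, V the shared reference point:
    # every time point gets exactly one bit, so pad counts must already agree
    return "".join(r_bits) + "".join(q_bits)


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def string_distance_matrix(
    strings: list[str],
    metric: str = "levenshtein",
    len_R: int | None = None,
    len_Q: int | None = None,
) -> np.ndarray:
    """Pairwise normalized distances between five-state alignment strings.

    Levenshtein distances are normalized by the longer string in each pair;
    Hamming distances operate on the binary encodings (requiring ``len_R``
    and ``len_Q``) and are normalized by |R| + |Q|. Both live in [0, 1].
    Identical strings are computed once (the matrix of a battery of
    thousands of alignments typically has only ~a hundred unique strings).
    """
    if not strings:
        raise ValueError("empty string set")
    if metric == "levenshtein":
        unique = sorted(set(strings))
        index = {s: k for k, s in enumerate(unique)}
        u = len(unique)
        base = np.zeros((u, u))
        for a in range(u):
            for b in range(a + 1, u):
                d = _levenshtein(unique[a], unique[b]) / max(len(unique[a]), len(unique[b]))
                base[a, b] = base[b, a] = d
        idx = np.array([index[s] for s in strings])
        return base[np.ix_(idx, idx)]
    if metric == "hamming":
        if len_R is None or len_Q is None:
            raise ValueError("hamming distance requires len_R and len_Q")
        bits = np.array(
            [[int(c) for c in binary_encode(s, len_R, len_Q)] for s in strings], dtype=bool
        )
        return cdist(bits, bits, metric="hamming")
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class ClusterModel:
    """Result of hierarchically clustering alignment strings."""

    distance_matrix: np.ndarray
    threshold: float
    labels: np.ndarray
    mean_silhouette: float | None
    cluster_averages: dict[int, str]
    msc_curve: list[tuple[float, int, float | None]] | None = None

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _cut(dist: np.ndarray, threshold: float) -> np.ndarray:
    model = AgglomerativeClustering(
        metric="precomputed",
        linkage="average",
        distance_threshold=threshold,
        n_clusters=None,
    )
    return model.fit_predict(dist)


def _msc(dist: np.ndarray, labels: np.ndarray) -> float | None:
    k = len(np.unique(labels))
    if k < 2 or k >= len(labels):
        return None
    return float(silhouette_score(dist, labels, metric="precomputed"))


def cluster_alignments(
    distance_matrix: np.ndarray,
    threshold: float | str = "auto",
    results: list[AlignmentResult] | None = None,
    msc_step: float = 0.01,
    msc_slack: float = 0.05,
) -> ClusterModel:
    """Agglomerative average-linkage clustering of alignment strings.

    With a numeric ``threshold``, the dendrogram is cut there directly. In
    ``"auto"`` mode, thresholds over [0, 1] at ``msc_step`` are scanned, the
    full MSC-vs-threshold curve is retained for inspection, and the suggested
    cut is the locally optimal MSC with the fewest clusters whose score is
    within ``msc_slack`` of the global optimum. The curve always accompanies
    the suggestion: threshold choice is a resolution tradeoff that warrants a
    human look.

    If per-gene ``results`` are supplied, each cluster also gets its average
    alignment (the aggregate over its members).
    """
    dist = np.asarray(distance_matrix, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    curve = None
    if threshold == "auto":
        curve = []
        for th in np.arange(msc_step, 1.0 + 1e-9, msc_step):
            labels = _cut(dist, float(th))
            curve.append((float(th), len(np.unique(labels)), _msc(dist, labels)))
        scored = [(th, k, s) for th, k, s in curve if s is not None]
        if not scored:
            threshold = 0.0
        else:
            best = max(s for _, _, s in scored)
            eligible = [(th, k, s) for th, k, s in scored if s >= best - msc_slack]
            threshold = min(eligible, key=lambda x: (x[1], -x[2]))[0]
    labels = _cut(dist, float(threshold))
    averages: dict[int, str] = {}
    if results is not None:
        for lab in np.unique(labels):
            members = [results[k] for k in np.flatnonzero(labels == lab)]
            averages[int(lab)] = aggregate_alignment(members)
    return ClusterModel(
        distance_matrix=dist,
        threshold=float(threshold),
        labels=labels,
        mean_silhouette=_msc(dist, labels),
        cluster_averages=averages,
        msc_curve=curve,
    )


def misclustering_rate(labels: np.ndarray, truth: list) -> float:
    """Percentage of members disagreeing with their cluster's majority label."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    outliers = 0
    for lab in np.unique(labels):
        members = truth[labels == lab]
        majority = Counter(members.tolist()).most_common(1)[0][1]
        outliers += len(members) - majority
    return 100.0 * outliers / len(labels)


def _group_distance(
    a: np.ndarray, b: np.ndarray, params: EncodingParams, sigma_floor: float
) -> float:
    """MML distance between two cell sets of one gene's expression."""
    mu_a, sd_a = float(np.mean(a)), float(np.std(a, ddof=1))
    mu_b, sd_b = float(np.mean(b)), float(np.std(b, ddof=1))
    model_a = GaussianModel(mu_a, max(sd_a, sigma_floor))
    model_b = GaussianModel(mu_b, max(sd_b, sigma_floor))
    return match_cost(a, model_a, b, model_b, params)


def mml_null_significance(
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_names: list[str] | None = None,
    n_iter: int = 50,
    subset_size: int = 50,
    seed: int = 0,
    params: EncodingParams = EncodingParams(),
    sigma_floor: float = 0.001,
):
    """Empirical-null significance of per-gene MML expression distances.

    A null distribution of distances is built from random within-group subset
    pairs: for every gene and every iteration, two disjoint ``subset_size``
    cell subsets are drawn (without replacement) from the same group and
    their MML distance recorded; both groups contribute. The observed
    statistic per gene is the distance between a random subset of group A
    and a random subset of group B (same subset size, so observed and null
    draws are exchangeable under the null). Right-tail p-values under the
    pooled empirical CDF are Benjamini-Hochberg adjusted across genes.

    ``group_a``/``group_b`` are cells x genes arrays over the same genes.
    Returns a DataFrame with distance, p and adjusted p per gene.
    """
    import pandas as pd

    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the same genes")
    n_genes = A.shape[1]
    if gene_names is None:
        gene_names = [f"gene_{k}" for k in range(n_genes)]
    for grp, name in ((A, "A"), (B, "B")):
        if grp.shape[0] < 2 * subset_size:
            raise ValueError(
                f"group {name} has {grp.shape[0]} cells; needs >= {2 * subset_size} "
                "for disjoint subset pairs"
            )
    rng = np.random.default_rng(seed)
    null: list[float] = []
    for grp in (A, B):
        n_cells = grp.shape[0]
        for g in range(n_genes):
            for _ in range(n_iter):
                pick = rng.choice(n_cells, size=2 * subset_size, replace=False)
                null.append(
                    _group_distance(
                        grp[pick[:subset_size], g], grp[pick[subset_size:], g], params, sigma_floor
                    )
                )
    ecdf = ECDF(np.asarray(null))

    observed = np.empty(n_genes)
    for g in range(n_genes):
        sub_a = rng.choice(A.shape[0], size=subset_size, replace=False)
        sub_b = rng.choice(B.shape[0], size=subset_size, replace=False)
        observed[g] = _group_distance(A[sub_a, g], B[sub_b, g], params, sigma_floor)
    # right-tail p with an add-one guard so p is never exactly zero
    n_null = len(null)
    p = (n_null * (1.0 - ecdf(observed)) + 1.0) / (n_null + 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": gene_names, "distance": observed, "p": p, "p_adj": adj}
    )


def distance_change_test(distances_1: np.ndarray, distances_2: np.ndarray):
    """Rank-sum (Mann-Whitney U) test between two distance samples.

    Thin utility for asking whether gene expression distances to a common
    reference changed between two conditions.
    """
    return mannwhitneyu(distances_1, distances_2, alternative="two-sided")
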