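"""Five-state dynamic-programming alignment of two interpolated trajectories.

The aligner extends the classic three-state (match/insert/delete) affine-gap
machine of biological sequence alignment with the two DTW warp states:

* ``M`` one-to-one match (consumes one reference and one query point),
* ``W`` many-to-one warp (consumes a reference point; pays the match cost),
* ``V`` one-to-many warp (consumes a query point; pays the match cost),
* ``D`` deletion (reference point with no counterpart),
* ``I`` insertion (query point with no counterpart).

State-assignment costs are Shannon information of the transitions of a
five-state machine; match costs are the MML compression statistic Delta.
The optimal alignment minimizes total match cost + total state cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AlignmentConfig
from .interpolation import InterpolatedGene
from .mml import EncodingParams, match_cost_matrix

__all__ = [
    "STATES",
    "StateMachine",
    "AlignmentResult",
    "build_state_machine",
    "align_gene",
    "align_cost_matrix",
    "brute_force_align",
]

STATES = ("M", "W", "V", "D", "I")
M, W, V, D, I = range(5)
_START = -1

#: Mirror image of each state under swapping the roles of reference and query.
SWAP = {M: M, W: V, V: W, D: I, I: D}

#: Step taken backwards through the DP grid by each state: (di, dj).
STEP = {M: (1, 1), W: (0, 1), V: (1, 0), D: (0, 1), I: (1, 0)}

#: Predecessor states allowed by each recurrence (I->W and D->V prohibited).
PREDECESSORS = {
    M: (M, W, V, D, I),
    W: (M, W, V, D),
    V: (M, W, V, I),
    D: (M, W, V, D, I),
    I: (M, W, V, D, I),
}

INF = np.inf


@dataclass(frozen=True)
class StateMachine:
    """The five-state transition machine and its information costs.

    ``probs[y][x]`` is Pr(x | y) for the 23 allowed transitions;
    ``costs[y, x] = -ln Pr(x | y)`` (infinite for prohibited transitions).
    ``initial_costs[x]`` is the cost of the very first alignment state.
    """

    free_params: tuple[float, float, float]
    probs: dict = field(repr=False, default_factory=dict)
    costs: np.ndarray = field(repr=False, default=None)
    initial_costs: np.ndarray = field(repr=False, default=None)

    @property
    def n_transitions(self) -> int:
        return sum(len(row) for row in self.probs.values())


def build_state_machine(
    p_mm: float = 0.99,
    p_ii: float = 0.1,
    p_mi: float = 0.7,
    initial_probs: tuple[float, float, float] = (0.99, 5e-5, 5e-5),
    uniform_initial: bool = False,
) -> StateMachine:
    """Derive all 23 transition probabilities from the three free parameters.

    Constraints: costs are invariant under the reference/query swap (I<->D,
    W<->V); I->W and D->V are prohibited (they would imply a single M); each
    state's outgoing probabilities sum to 1. The remaining freedom is closed
    by equality classes: from M, the four non-match transitions share
    ``(1 - p_mm)/4``; from I (resp. D), the two remaining targets share the
    leftover mass equally; warp states behave gap-like, keeping ``p_ii`` for
    self-transitions and ``p_mi`` back to M, with the leftover spread equally
    over their three remaining targets.
    """
    for name, p in (("Pr(M|M)", p_mm), ("Pr(I|I)", p_ii), ("Pr(M|I)", p_mi)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} = {p} outside (0, 1)")
    rest_m = (1.0 - p_mm) / 4.0
    rest_gap = 1.0 - p_ii - p_mi
    if rest_gap <= 0:
        raise ValueError(
            f"infeasible triple: Pr(I|I) + Pr(M|I) = {p_ii + p_mi} leaves no "
            "probability mass for the remaining transitions"
        )
    probs: dict[int, dict[int, float]] = {
        M: {M: p_mm, W: rest_m, V: rest_m, D: rest_m, I: rest_m},
        W: {M: p_mi, W: p_ii, V: rest_gap / 3, D: rest_gap / 3, I: rest_gap / 3},
        V: {M: p_mi, V: p_ii, W: rest_gap / 3, D: rest_gap / 3, I: rest_gap / 3},
        D: {M: p_mi, D: p_ii, W: rest_gap / 2, I: rest_gap / 2},
        I: {M: p_mi, I: p_ii, V: rest_gap / 2, D: rest_gap / 2},
    }
    costs = np.full((5, 5), INF)
    for y, row in probs.items():
        for x, p in row.items():
            costs[y, x] = -np.log(p)

    initial_costs = np.full(5, INF)
    if uniform_initial:
        initial_costs[[M, I, D]] = np.log(3.0)
    else:
        pm, pi, pd = initial_probs
        initial_costs[M] = -np.log(pm)
        initial_costs[I] = -np.log(pi)
        initial_costs[D] = -np.log(pd)
    return StateMachine(
        free_params=(p_mm, p_ii, p_mi),
        probs=probs,
        costs=costs,
        initial_costs=initial_costs,
    )


@dataclass
class AlignmentResult:
    """Optimal five-state alignment of one gene.

    ``string`` reads left to right along the alignment; ``path`` lists
    ``(i, j, state)`` with i/j the (1-based) query/reference time points
    consumed so far. ``landscape`` is the optimal-cost matrix
    ``L(i,j) = min_x Hist_x(i,j)`` and ``state_landscape`` its argmin state
    (used for aggregate alignments). ``similarity`` is the percentage of
    match-type characters (M, V, W).
    """

    string: str
    path: list[tuple[int, int, int]]
    match_cost_total: float
    state_cost_total: float
    landscape: np.ndarray
    state_landscape: np.ndarray
    matrix_shape: tuple[int, int]

    @property
    def total_cost(self) -> float:
        return self.match_cost_total + self.state_cost_total

    @property
    def similarity(self) -> float:
        from .analysis import alignment_similarity

        return alignment_similarity(self.string)


def align_cost_matrix(cost: np.ndarray, machine: StateMachine) -> AlignmentResult:
    """Run the five-state DP over a precomputed match-cost matrix.

    ``cost[i-1, j-1]`` is the match cost of query point i and reference
    point j (1-based). Ties in every min are broken in the fixed state
    preference order M > W > V > D > I for reproducibility.
    """
    cost = np.asarray(cost, dtype=float)
    mQ, mR = cost.shape
    H = np.full((5, mQ + 1, mR + 1), INF)
    choice = np.full((5, mQ + 1, mR + 1), _START, dtype=np.int8)
    tc = machine.costs

    # gap borders: runs of I down column 0 and D along row 0, opened at the
    # initial-state cost
    for i in range(1, mQ + 1):
        H[I, i, 0] = machine.initial_costs[I] + (i - 1) * tc[I, I]
        choice[I, i, 0] = _START if i == 1 else I
    for j in range(1, mR + 1):
        H[D, 0, j] = machine.initial_costs[D] + (j - 1) * tc[D, D]
        choice[D, 0, j] = _START if j == 1 else D

    for i in range(1, mQ + 1):
        for j in range(1, mR + 1):
            c = cost[i - 1, j - 1]
            # M from the diagonal; the very first pair has no predecessor
            if i == 1 and j == 1:
                H[M, 1, 1] = c + machine.initial_costs[M]
                choice[M, 1, 1] = _START
            else:
                best, arg = INF, _START
                for y in PREDECESSORS[M]:
                    v = H[y, i - 1, j - 1] + tc[y, M]
                    if v < best:
                        best, arg = v, y
                H[M, i, j] = c + best
                choice[M, i, j] = arg
            # W advances the reference only, but pays the match cost
            best, arg = INF, _START
            for y in PREDECESSORS[W]:
                v = H[y, i, j - 1] + tc[y, W]
                if v < best:
                    best, arg = v, y
            H[W, i, j] = c + best
            choice[W, i, j] = arg
            # V advances the query only, but pays the match cost
            best, arg = INF, _START
            for y in PREDECESSORS[V]:
                v = H[y, i - 1, j] + tc[y, V]
                if v < best:
                    best, arg = v, y
            H[V, i, j] = c + best
            choice[V, i, j] = arg
            # D and I are pure gaps: no match cost
            best, arg = INF, _START
            for y in PREDECESSORS[D]:
                v = H[y, i, j - 1] + tc[y, D]
                if v < best:
                    best, arg = v, y
            H[D, i, j] = best
            choice[D, i, j] = arg
            best, arg = INF, _START
            for y in PREDECESSORS[I]:
                v = H[y, i - 1, j] + tc[y, I]
                if v < best:
                    best, arg = v, y
            H[I, i, j] = best
            choice[I, i, j] = arg

    landscape = H.min(axis=0)
    state_landscape = H.argmin(axis=0).astype(np.int8)

    # backtrack from the best terminal state
    x = int(np.argmin(H[:, mQ, mR]))
    i, j = mQ, mR
    rev_states: list[int] = []
    rev_path: list[tuple[int, int, int]] = []
    match_total = 0.0
    while True:
        rev_states.append(x)
        rev_path.append((i, j, x))
        if x in (M, W, V):
            match_total += cost[i - 1, j - 1]
        y = int(choice[x, i, j])
        di, dj = STEP[x]
        i, j = i - di, j - dj
        if y == _START:
            break
        x = y
    assert (i, j) == (0, 0), "backtracking did not reach the origin"

    string = "".join(STATES[s] for s in reversed(rev_states))
    path = list(reversed(rev_path))
    total = float(H[:, mQ, mR].min())
    return AlignmentResult(
        string=string,
        path=path,
        match_cost_total=match_total,
        state_cost_total=total - match_total,
        landscape=landscape,
        state_landscape=state_landscape,
        matrix_shape=(mQ, mR),
    )


def gene_cost_matrix(
    ref: InterpolatedGene, query: InterpolatedGene, params: EncodingParams, sigma_floor: float = 0.001
) -> np.ndarray:
    """MML match-cost matrix between two interpolated genes (query rows)."""
    sr = np.maximum(ref.sds, sigma_floor)
    sq = np.maximum(query.sds, sigma_floor)
    return match_cost_matrix(
        ref.samples, sr, ref.means, query.samples, sq, query.means, params=params
    )


def align_gene(
    ref: InterpolatedGene,
    query: InterpolatedGene,
    machine: StateMachine | None = None,
    params: EncodingParams = EncodingParams(),
    config: AlignmentConfig | None = None,
) -> AlignmentResult:
    """Align one gene's reference and query interpolated trajectories."""
    if ref.m < 2 or query.m < 2:
        raise ValueError("need at least two interpolation points per trajectory")
    if machine is None:
        cfg = config or AlignmentConfig()
        machine = build_state_machine(
            *cfg.state_probs, initial_probs=cfg.initial_probs, uniform_initial=cfg.uniform_initial
        )
    floor = config.sigma_floor if config is not None else 0.001
    cost = gene_cost_matrix(ref, query, params, sigma_floor=floor)
    return align_cost_matrix(cost, machine)


def score_alignment_string(cost: np.ndarray, machine: StateMachine, string: str) -> float:
    """Total cost (match + state) of a given five-state string on a problem.

    Walks the string over the cost matrix exactly as the DP recurrences
    charge it; useful as an independent check that a string is (co-)optimal.
    Raises if the walk is invalid or a prohibited transition appears.
    """
    cost = np.asarray(cost, dtype=float)
    mQ, mR = cost.shape
    i = j = 0
    last = _START
    total = 0.0
    for ch in string:
        x = STATES.index(ch)
        if last == _START:
            trans = machine.initial_costs[x]
        else:
            if last not in PREDECESSORS[x]:
                raise ValueError(f"prohibited transition {STATES[last]}->{ch}")
            trans = machine.costs[last, x]
        if x == M:
            i, j = i + 1, j + 1
            total += cost[i - 1, j - 1]
        elif x == W:
            if i < 1:
                raise ValueError("W warp before any query point is consumed")
            j += 1
            total += cost[i - 1, j - 1]
        elif x == V:
            if j < 1:
                raise ValueError("V warp before any reference point is consumed")
            i += 1
            total += cost[i - 1, j - 1]
        elif x == D:
            j += 1
        else:
            i += 1
        if i > mQ or j > mR:
            raise ValueError("string walks off the cost matrix")
        total += trans
        last = x
    if (i, j) != (mQ, mR):
        raise ValueError(f"walk ends at ({i}, {j}), expected ({mQ}, {mR})")
    return float(total)


def brute_force_align(
    cost: np.ndarray, machine: StateMachine, max_len: int = 5
) -> tuple[float, str]:
    """Exhaustive test oracle: enumerate every legal five-state path.

    Returns the global minimum of total match cost + state cost and one
    minimizing string. Only feasible for tiny problems (lengths <= max_len).
    """
    cost = np.asarray(cost, dtype=float)
    mQ, mR = cost.shape
    if mQ > max_len or mR > max_len:
        raise ValueError("problem too large for exhaustive enumeration")
    tc = machine.costs
    best = [INF, ""]

    def recurse(i: int, j: int, last: int, acc: float, states: list[int]) -> None:
        if i == mQ and j == mR and states:
            if acc < best[0]:
                best[0] = acc
                best[1] = "".join(STATES[s] for s in states)
            return
        for x in (M, W, V, D, I):
            if last == _START:
                trans = machine.initial_costs[x]
                if not np.isfinite(trans):
                    continue
            else:
                if last not in PREDECESSORS[x]:
                    continue
                trans = tc[last, x]
            if x == M:
                if i >= mQ or j >= mR:
                    continue
                step_cost = cost[i, j] + trans
                ni, nj = i + 1, j + 1
            elif x == W:
                if j >= mR or i < 1:
                    continue
                step_cost = cost[i - 1, j] + trans
                ni, nj = i, j + 1
            elif x == V:
                if i >= mQ or j < 1:
                    continue
                step_cost = cost[i, j - 1] + trans
                ni, nj = i + 1, j
            elif x == D:
                if j >= mR:
                    continue
                step_cost = trans
                ni, nj = i, j + 1
            else:  # I
                if i >= mQ:
                    continue
                step_cost = trans
                ni, nj = i + 1, j
            states.append(x)
            recurse(ni, nj, x, acc + step_cost, states)
            states.pop()

    recurse(0, 0, _START, 0.0, [])
    return float(best[0]), best[1]
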