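"""High-level entry points tying interpolation, scoring and the DP together."""

from __future__ import annotations

import logging

import numpy as np

from .alignment import AlignmentResult, align_gene, build_state_machine
from .data_io import AlignmentConfig, Trajectory, choose_num_interp_points, shared_genes
from .interpolation import apply_extreme_case_rules, interpolate_gene
from .mml import EncodingParams
from .simulation import SimulatedPair

logger = logging.getLogger(__name__)

__all__ = ["align_trajectories", "align_arrays", "align_pair"]


def align_arrays(
    ref_expr: np.ndarray,
    ref_times: np.ndarray,
    query_expr: np.ndarray,
    query_times: np.ndarray,
    config: AlignmentConfig,
    m: int,
    params: EncodingParams = EncodingParams(),
    gene_index: int = 0,
) -> AlignmentResult:
    """Interpolate one gene's two expression series and align them."""
    ref_ig = interpolate_gene(ref_expr, ref_times, config, m=m, gene_index=gene_index)
    query_ig = interpolate_gene(query_expr, query_times, config, m=m, gene_index=gene_index)
    apply_extreme_case_rules(
        ref_ig, query_ig, ref_expr, ref_times, query_expr, query_times, config, gene_index
    )
    machine = build_state_machine(
        *config.state_probs,
        initial_probs=config.initial_probs,
        uniform_initial=config.uniform_initial,
    )
    return align_gene(ref_ig, query_ig, machine, params, config)


def align_pair(
    pair: SimulatedPair,
    config: AlignmentConfig | None = None,
    m: int = 15,
    params: EncodingParams = EncodingParams(),
) -> AlignmentResult:
    """Align a simulated reference/query pair at m interpolation points."""
    config = config or AlignmentConfig()
    return align_arrays(
        pair.ref_expr, pair.times, pair.query_expr, pair.times, config, m, params
    )


def align_trajectories(
    ref: Trajectory,
    query: Trajectory,
    genes: list[str] | None = None,
    config: AlignmentConfig | None = None,
    params: EncodingParams = EncodingParams(),
) -> dict[str, AlignmentResult]:
    """Gene-level alignment of two trajectories over a gene list.

    Pseudotime is min-max normalized, the interpolation resolution is taken
    from the config or chosen heuristically (min over the two trajectories),
    and each shared gene is interpolated and aligned independently.
    """
    config = config or AlignmentConfig()
    ref = ref.with_normalized_time()
    query = query.with_normalized_time()
    common = shared_genes(ref, query)
    if genes is not None:
        missing = [g for g in genes if g not in common]
        if missing:
            logger.warning("requested genes not shared by both trajectories: %s", missing[:10])
        common = [g for g in genes if g in common]
    if not common:
        raise ValueError("no shared genes to align")
    m = choose_num_interp_points(ref.pseudotime, query.pseudotime, config.n_interp_points)
    results: dict[str, AlignmentResult] = {}
    for k, gene in enumerate(common):
        results[gene] = align_arrays(
            ref.gene(gene),
            ref.pseudotime,
            query.gene(gene),
            query.pseudotime,
            config,
            m,
            params,
            gene_index=k,
        )
        logger.info("aligned %s (%d/%d): %s", gene, k + 1, len(common), results[gene].string)
    return results
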