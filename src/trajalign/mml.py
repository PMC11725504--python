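"""Minimum-message-length match cost between two Gaussian expression models.

The match cost between a reference time point and a query time point is a
compression statistic Delta comparing two hypotheses for their pooled sampled
expression data:

* match (A): one shared Gaussian explains all the data; its encoding length
  is averaged over stating the reference's or the query's model, which makes
  the statistic symmetric;
* mismatch (Phi): each side's data is explained by its own Gaussian, paying
  for two model statements.

Encoding lengths use the Wallace-Freeman two-part message approximation for a
Gaussian with uniform priors on mu and log(sigma), measured in nits and
normalized per datum. Delta > 0 means the mismatch hypothesis compresses
better (the distributions diverge); Delta < 0 favours the match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncodingParams",
    "GaussianModel",
    "encoding_length",
    "match_cost",
    "match_cost_matrix",
]

#: Conway-Sloane optimal quantizing lattice constant for d = 2.
KAPPA_2 = 5.0 / (36.0 * np.sqrt(3.0))


@dataclass(frozen=True)
class EncodingParams:
    """Constants of the Wallace-Freeman Gaussian encoding.

    ``R_mu`` and ``R_sigma`` are the lengths of the uniform prior ranges over
    mu and log(sigma), chosen as reasonable for log1p-normalized expression.
    ``epsilon`` is the measurement precision of a datum.
    """

    R_mu: float = 15.0
    R_sigma: float = 3.0
    epsilon: float = 0.001
    d: int = 2
    kappa_d: float = KAPPA_2

    def __post_init__(self) -> None:
        if min(self.R_mu, self.R_sigma, self.epsilon) <= 0:
            raise ValueError("R_mu, R_sigma and epsilon must be positive")


@dataclass(frozen=True)
class GaussianModel:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def fisher_determinant(n_data: int, sigma: float) -> float:
    """det of the expected Fisher information of (mu, sigma): 2 X^2 / sigma^4."""
    return 2.0 * n_data**2 / sigma**4


def negative_log_likelihood(
    sigma: float, n_data: int, sse: float, epsilon: float
) -> float:
    """Gaussian negative log likelihood plus the datum-precision term.

    ``sse`` is the sum of squared deviations of the data about the model mean.
    """
    return (
        n_data * np.log(sigma)
        + 0.5 * n_data * np.log(2.0 * np.pi)
        + sse / (2.0 * sigma**2)
        - n_data * np.log(epsilon)
    )


def encoding_length(
    data: np.ndarray, model: GaussianModel, params: EncodingParams = EncodingParams()
) -> float:
    """Two-part Wallace-Freeman encoding length I(theta, D) in nits.

    I = (d/2) log kappa_d - log h(theta) + (1/2) log det Fisher + L(theta) + d/2
    with -log h(theta) = log sigma + log(R_mu R_sigma).
    """
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty data vector")
    X = x.size
    sse = float(np.sum((x - model.mu) ** 2))
    return (
        0.5 * params.d * np.log(params.kappa_d)
        + np.log(model.sigma)
        + np.log(params.R_mu * params.R_sigma)
        + 0.5 * np.log(fisher_determinant(X, model.sigma))
        + negative_log_likelihood(model.sigma, X, sse, params.epsilon)
        + 0.5 * params.d
    )


def match_cost(
    ref_data: np.ndarray,
    ref_model: GaussianModel,
    query_data: np.ndarray,
    query_model: GaussianModel,
    params: EncodingParams = EncodingParams(),
) -> float:
    """Compression statistic Delta (nits per datum) between two time points.

    Symmetric under swapping reference and query by construction.
    """
    ref_data = np.asarray(ref_data, dtype=float).ravel()
    query_data = np.asarray(query_data, dtype=float).ravel()
    pooled = np.concatenate([ref_data, query_data])
    n_total = pooled.size

    i_phi = encoding_length(ref_data, ref_model, params) + encoding_length(
        query_data, query_model, params
    )
    i_a = 0.5 * (
        encoding_length(pooled, ref_model, params)
        + encoding_length(pooled, query_model, params)
    )
    return (i_a - i_phi) / n_total


def _model_statement_cost(sigmas: np.ndarray, n_data: int, params: EncodingParams) -> np.ndarray:
    """Data-independent part of the encoding: prior + Fisher + lattice terms."""
    return (
        0.5 * params.d * np.log(params.kappa_d)
        + np.log(sigmas)
        + np.log(params.R_mu * params.R_sigma)
        + 0.5 * np.log(2.0 * n_data**2 / sigmas**4)
        + 0.5 * params.d
    )


def match_cost_matrix(
    ref_samples: np.ndarray,
    ref_sigmas: np.ndarray,
    ref_mus: np.ndarray,
    query_samples: np.ndarray,
    query_sigmas: np.ndarray,
    query_mus: np.ndarray,
    params: EncodingParams = EncodingParams(),
) -> np.ndarray:
    """Delta for every (query point i, reference point j) pair, vectorized.

    ``ref_samples``/``query_samples`` are ``(m, n_samples)`` arrays of the
    interpolated data; the sigma and mu vectors give each point's Gaussian
    model. Returns a ``(m_query, m_ref)`` matrix identical, cell for cell,
    to calling :func:`match_cost` on each pair.
    """
    ref_samples = np.asarray(ref_samples, dtype=float)
    query_samples = np.asarray(query_samples, dtype=float)
    sr = np.asarray(ref_sigmas, dtype=float)
    sq = np.asarray(query_sigmas, dtype=float)
    mur = np.asarray(ref_mus, dtype=float)
    muq = np.asarray(query_mus, dtype=float)

    nR = ref_samples.shape[1]
    nQ = query_samples.shape[1]
    n_total = nR + nQ

    # per-point sufficient statistics
    s1_r = ref_samples.sum(axis=1)
    s2_r = (ref_samples**2).sum(axis=1)
    s1_q = query_samples.sum(axis=1)
    s2_q = (query_samples**2).sum(axis=1)

    def sse(s2: np.ndarray, s1: np.ndarray, n: int, mu: np.ndarray) -> np.ndarray:
        return s2 - 2.0 * mu * s1 + n * mu**2

    sse_r_own = sse(s2_r, s1_r, nR, mur)  # (mR,)
    sse_q_own = sse(s2_q, s1_q, nQ, muq)  # (mQ,)

    eps = params.epsilon
    # mismatch hypothesis: own data under own model, full two-part lengths
    i_phi = (
        _model_statement_cost(sr, nR, params)
        + negative_log_likelihood_vec(sr, nR, sse_r_own, eps)
    )[None, :] + (
        _model_statement_cost(sq, nQ, params)
        + negative_log_likelihood_vec(sq, nQ, sse_q_own, eps)
    )[:, None]

    # match hypothesis: pooled data under the ref model and under the query
    # model, averaged
    sse_pooled_ref = sse_r_own[None, :] + (
        s2_q[:, None] - 2.0 * mur[None, :] * s1_q[:, None] + nQ * mur[None, :] ** 2
    )
    sse_pooled_query = sse_q_own[:, None] + (
        s2_r[None, :] - 2.0 * muq[:, None] * s1_r[None, :] + nR * muq[:, None] ** 2
    )
    i_a_ref = _model_statement_cost(sr, n_total, params)[None, :] + negative_log_likelihood_vec(
        sr[None, :], n_total, sse_pooled_ref, eps
    )
    i_a_query = _model_statement_cost(sq, n_total, params)[:, None] + negative_log_likelihood_vec(
        sq[:, None], n_total, sse_pooled_query, eps
    )
    i_a = 0.5 * (i_a_ref + i_a_query)
    return (i_a - i_phi) / n_total


def negative_log_likelihood_vec(
    sigma: np.ndarray, n_data: int, sse: np.ndarray, epsilon: float
) -> np.ndarray:
    """Broadcasting form of :func:`negative_log_likelihood`."""
    return (
        n_data * np.log(sigma)
        + 0.5 * n_data * np.log(2.0 * np.pi)
        + sse / (2.0 * sigma**2)
        - n_data * np.log(epsilon)
    )
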