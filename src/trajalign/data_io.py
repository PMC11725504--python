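"""Loading and validation of expression trajectories.

A trajectory is a cells x genes matrix of log1p-normalized expression plus a
per-cell pseudotime. Pseudotime is min-max normalized to [0, 1] before
alignment so that the interpolation grid and the kernel window are comparable
across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "AlignmentConfig",
    "load_trajectory",
    "normalize_pseudotime",
    "choose_num_interp_points",
]


@dataclass
class Trajectory:
    """A cells x genes expression matrix with per-cell pseudotime.

    Parameters
    ----------
    expression
        Dense array of shape ``(n_cells, n_genes)`` of log1p-normalized,
        non-negative expression values.
    pseudotime
        One value per cell. Use :func:`normalize_pseudotime` (or
        ``normalize=True`` here) to map it onto [0, 1].
    gene_names, cell_ids
        Unique identifiers for columns and rows respectively.
    """

    expression: np.ndarray
    pseudotime: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float).ravel()
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.expression.shape
        if len(self.pseudotime) != n_cells:
            raise ValueError(
                f"pseudotime length {len(self.pseudotime)} does not match "
                f"cell count {n_cells}"
            )
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene_names are not unique")
        bad = ~np.isfinite(self.pseudotime)
        if bad.any():
            cell = self.cell_ids[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"non-finite pseudotime for cell {cell!r}")
        if np.any(self.expression < 0):
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def gene(self, name: str) -> np.ndarray:
        """Expression vector of a single gene across cells."""
        try:
            j = self.gene_names.index(name)
        except ValueError:
            raise KeyError(f"gene {name!r} not in trajectory") from None
        return self.expression[:, j]

    def with_normalized_time(self) -> "Trajectory":
        """Return a copy whose pseudotime is min-max normalized to [0, 1]."""
        return Trajectory(
            expression=self.expression,
            pseudotime=normalize_pseudotime(self.pseudotime),
            gene_names=list(self.gene_names),
            cell_ids=list(self.cell_ids),
        )


@dataclass
class AlignmentConfig:
    """Tunable parameters of the interpolation + alignment pipeline.

    ``state_probs`` are the three free transition probabilities
    (Pr(M|M), Pr(I|I), Pr(M|I)) of the five-state machine; ``initial_probs``
    are (Pr(M), Pr(I), Pr(D)) used for the very first alignment step.
    ``window_size`` is the Gaussian kernel bandwidth on the normalized
    pseudotime axis.
    """

    n_interp_points: int | None = None
    window_size: float = 0.1
    state_probs: tuple[float, float, float] = (0.99, 0.1, 0.7)
    initial_probs: tuple[float, float, float] = (0.99, 5e-5, 5e-5)
    uniform_initial: bool = False
    n_samples_per_point: int = 50
    seed: int = 0
    sigma_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for p in (*self.state_probs, *self.initial_probs):
            if not (0.0 < p < 1.0):
                raise ValueError(f"probability {p} outside (0, 1)")
        if self.n_interp_points is not None and self.n_interp_points < 2:
            raise ValueError("need at least two interpolation points")
        if self.n_samples_per_point < 2:
            raise ValueError("need at least two samples per interpolation point")


def normalize_pseudotime(times: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max normalize a pseudotime vector onto [0, 1].

    Raises ``ValueError`` on a constant vector (zero range), where the map
    is undefined.
    """
    t = np.asarray(times, dtype=float).ravel()
    if t.size < 2:
        raise ValueError("need at least two pseudotime values")
    lo, hi = float(np.min(t)), float(np.max(t))
    if hi == lo:
        raise ValueError("pseudotime vector is constant; cannot normalize")
    return (t - lo) / (hi - lo)


def _fd_bin_count(times: np.ndarray, lo: int = 5, hi: int = 50) -> int:
    """Freedman-Diaconis bin count of a pseudotime distribution, clamped.

    Transparent stand-in for an optimal-binning procedure: the alignment
    resolution, not the binner, is what matters, and an explicit user choice
    always overrides this heuristic.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two cells to choose a bin count")
    q75, q25 = np.percentile(t, [75, 25])
    iqr = q75 - q25
    span = float(np.max(t) - np.min(t))
    if iqr <= 0 or span <= 0:
        return lo
    width = 2.0 * iqr / np.cbrt(t.size)
    m = int(np.ceil(span / width))
    return int(np.clip(m, lo, hi))


def choose_num_interp_points(
    times_ref: np.ndarray,
    times_query: np.ndarray,
    user_m: int | None = None,
) -> int:
    """Pick the number of equispaced interpolation points m.

    Each trajectory suggests a bin count from its pseudotime distribution;
    the smaller of the two is used so both trajectories are interpolated at
    a resolution supported by both. An explicit ``user_m`` wins outright.
    """
    if user_m is not None:
        if user_m < 2:
            raise ValueError("m must be at least 2")
        return int(user_m)
    return min(_fd_bin_count(times_ref), _fd_bin_count(times_query))


def _read_csv_trajectory(path: Path, pseudotime_key: str) -> Trajectory:
    df = pd.read_csv(path, index_col=0)
    if pseudotime_key not in df.columns:
        raise KeyError(f"pseudotime column {pseudotime_key!r} not found in {path}")
    times = df[pseudotime_key].to_numpy(dtype=float)
    expr = df.drop(columns=[pseudotime_key])
    return Trajectory(
        expression=expr.to_numpy(dtype=float),
        pseudotime=times,
        gene_names=list(expr.columns),
        cell_ids=[str(i) for i in df.index],
    )


def _read_h5ad_trajectory(path: Path, pseudotime_key: str) -> Trajectory:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if pseudotime_key not in adata.obs.columns:
        raise KeyError(f"pseudotime key {pseudotime_key!r} not in .obs")
    X = adata.X
    if not isinstance(X, np.ndarray):
        X = X.toarray()
    return Trajectory(
        expression=np.asarray(X, dtype=float),
        pseudotime=adata.obs[pseudotime_key].to_numpy(dtype=float),
        gene_names=list(adata.var_names),
        cell_ids=list(adata.obs_names),
    )


def _read_mtx_trajectory(path: Path, pseudotime_key: str) -> Trajectory:
    """Read a MatrixMarket triplet directory.

    Expects ``matrix.mtx`` (cells x genes), ``genes.tsv`` (or
    ``features.tsv``), ``barcodes.tsv``, and a two-column
    ``pseudotime.tsv`` (cell id, value); ``pseudotime_key`` is ignored for
    this layout beyond documentation.
    """
    from scipy.io import mmread

    mat = mmread(path / "matrix.mtx")
    expr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    genes_file = path / "genes.tsv"
    if not genes_file.exists():
        genes_file = path / "features.tsv"
    genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    pt = pd.read_csv(path / "pseudotime.tsv", sep="\t", header=None, index_col=0)
    pt.index = pt.index.astype(str)
    missing = [c for c in cells if c not in pt.index]
    if missing:
        raise KeyError(f"pseudotime missing for cell {missing[0]!r}")
    times = pt.loc[cells, 1].to_numpy(dtype=float)
    return Trajectory(expression=expr, pseudotime=times, gene_names=genes, cell_ids=cells)


def load_trajectory(matrix_source: str | Path, pseudotime_key: str = "pseudotime") -> Trajectory:
    """Load a validated :class:`Trajectory` from ``.h5ad``, CSV, or an MTX triplet.

    CSV layout: one row per cell (index = cell id), one column per gene plus a
    pseudotime column named ``pseudotime_key``. MTX layout: a directory with
    ``matrix.mtx`` + ``genes.tsv``/``features.tsv`` + ``barcodes.tsv`` +
    ``pseudotime.tsv``.
    """
    path = Path(matrix_source)
    if path.is_dir():
        return _read_mtx_trajectory(path, pseudotime_key)
    if path.suffix == ".h5ad":
        return _read_h5ad_trajectory(path, pseudotime_key)
    if path.suffix in {".csv", ".txt", ".tsv"}:
        return _read_csv_trajectory(path, pseudotime_key)
    raise ValueError(f"unsupported trajectory source: {path}")


def shared_genes(ref: Trajectory, query: Trajectory) -> list[str]:
    """Genes present in both trajectories; one-sided genes are dropped with a warning."""
    common = [g for g in ref.gene_names if g in set(query.gene_names)]
    dropped = (set(ref.gene_names) | set(query.gene_names)) - set(common)
    if dropped:
        logger.warning(
            "dropping %d genes present in only one trajectory: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    return common
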