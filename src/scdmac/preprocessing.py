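"""Count-matrix preprocessing: library-size normalization, log transform,
highly-variable-gene selection, cosine KNN graph, and training-time
augmentations.

The denoising stage consumes raw counts together with the size factors
computed here; the log1p transform is applied only to the denoised matrix
that feeds masked representation learning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import cosine_distances

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw non-negative counts, cells × genes, with identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (cells × genes)")
        if np.any(self.values < 0):
            raise ValueError("count matrix has negative entries")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != g:
            raise ValueError("identifiers must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, idx], self.cell_ids,
                           [self.gene_ids[i] for i in idx])


@dataclass
class NormalizedMatrix:
    """Per-cell depth-normalized expression; every kept row sums to `scale`.

    `size_factors` are library size over median library size, the per-cell
    scalars that later scale the mean head of the count model.
    """

    values: np.ndarray
    scale: float
    size_factors: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    kept_cells: np.ndarray  # indices into the original matrix


@dataclass
class KNNGraph:
    k: int
    neighbor_indices: np.ndarray  # (n_cells, k), no self-neighbors
    metric: str = "cosine"


@dataclass
class AugmentationConfig:
    """Training-time view augmentations: per-cell gene masking, additive
    Gaussian noise, and expression swaps with a random KNN neighbor."""

    mask_fraction: float = 0.10
    noise_variance: float = 0.6
    swap_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mask_fraction", "swap_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_library_size(X: CountMatrix, s0: float = 1e4) -> NormalizedMatrix:
    """Rescale each cell so its total expression equals `s0`.

    All-zero cells have no defined scale; they are dropped with a warning.
    Size factors are library size divided by the median library size over the
    kept cells.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    lib = X.values.sum(axis=1)
    keep = lib > 0
    if not np.all(keep):
        dropped = [X.cell_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d all-zero cell(s): %s", len(dropped), dropped)
    lib = lib[keep]
    vals = X.values[keep] * (s0 / lib)[:, None]
    size_factors = lib / np.median(lib)
    return NormalizedMatrix(
        values=vals, scale=float(s0), size_factors=size_factors,
        cell_ids=[X.cell_ids[i] for i in np.flatnonzero(keep)],
        gene_ids=list(X.gene_ids), kept_cells=np.flatnonzero(keep))


def log1p_transform(values: np.ndarray | NormalizedMatrix) -> np.ndarray:
    """Elementwise ln(x + 1); input must be non-negative."""
    arr = values.values if isinstance(values, NormalizedMatrix) else np.asarray(values)
    if np.any(arr < 0):
        raise ValueError("log1p requires non-negative input")
    return np.log1p(arr)


def select_hvg(X: CountMatrix, n_top: int = 2000) -> np.ndarray:
    """Indices of the `n_top` highly variable genes, in original gene order.

    Ranking is Seurat-flavored normalized dispersion (dispersion z-scored
    within mean bins) computed on the log1p depth-normalized matrix, as
    implemented by scanpy. If `n_top >= n_genes` all genes are kept.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    n_genes = X.n_genes
    if n_top >= n_genes:
        return np.arange(n_genes)
    import anndata as ad
    import scanpy as sc

    norm = normalize_library_size(X)
    adata = ad.AnnData(np.log1p(norm.values))
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    idx = np.flatnonzero(adata.var["highly_variable"].to_numpy())
    if idx.size > n_top:  # ties at the cutoff: keep lowest indices
        idx = idx[:n_top]
    elif idx.size < n_top:  # fill from best-ranked leftovers
        rank = adata.var["dispersions_norm"].to_numpy()
        rest = np.setdiff1d(np.argsort(-rank, kind="stable"), idx,
                            assume_unique=False)
        idx = np.sort(np.concatenate([idx, rest[: n_top - idx.size]]))
    return idx


def build_knn_graph(X: np.ndarray, k: int = 15) -> KNNGraph:
    """K nearest neighbors per cell under cosine distance.

    Ties are broken toward the lower cell index; a cell is never its own
    neighbor. Zero-norm rows are rejected (cosine distance undefined).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError("need 0 < k < n_cells")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm rows have undefined cosine distance; "
                         "remove empty cells upstream")
    D = cosine_distances(X)
    np.fill_diagonal(D, np.inf)
    # stable argsort on distance ⇒ ties resolved by lower index
    order = np.argsort(D, axis=1, kind="stable")
    return KNNGraph(k=k, neighbor_indices=order[:, :k])


def augment(X: np.ndarray, graph: KNNGraph, cfg: AugmentationConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Return an augmented copy of `X`: random gene masking, Gaussian noise,
    and per-cell expression swaps with one random KNN neighbor.

    The three perturbations are applied in that order; `X` is not modified.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = np.array(X, dtype=float, copy=True)
    n, g = out.shape
    n_mask = int(round(cfg.mask_fraction * g))
    for i in range(n):
        if n_mask:
            out[i, rng.choice(g, size=n_mask, replace=False)] = 0.0
    if cfg.noise_variance > 0:
        out += rng.normal(0.0, np.sqrt(cfg.noise_variance), size=out.shape)
    n_swap = int(round(cfg.swap_ratio * g))
    if n_swap:
        if graph.neighbor_indices.shape[0] != n:
            raise ValueError("KNN graph was built on a different cell set")
        for i in range(n):
            j = graph.neighbor_indices[i, rng.integers(graph.k)]
            cols = rng.choice(g, size=n_swap, replace=False)
            out[i, cols], out[j, cols] = out[j, cols].copy(), out[i, cols].copy()
    return out
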