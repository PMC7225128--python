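"""Quality control, normalization, PCA embedding and variance decomposition.

QC mirrors standard droplet single-cell practice: cells with a high
mitochondrial read fraction (suspected dead, > 10%) or an outlying
number of detected genes (suspected doublets, > 5000) are removed, and
a small blocklist of rRNA-contaminated transcripts is dropped before
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EmbeddingState, LayeredCountMatrix

DEFAULT_BLOCKLIST = ("Gm42418", "AY036118")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    removed_mito: int
    removed_genes_max: int
    n_genes_in: int
    n_genes_out: int
    blocklisted: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(
    m: LayeredCountMatrix,
    mito_max: float = 0.10,
    genes_max: int = 5000,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
) -> tuple[LayeredCountMatrix, QCReport]:
    """Remove suspect cells and blocklisted genes.

    Cells are removed when mito_fraction is strictly greater than
    ``mito_max`` or genes_detected strictly greater than ``genes_max``;
    blocklisted gene rows are dropped from both layers.
    """
    m = m.with_qc_columns()
    meta = m.cell_metadata
    bad_mito = meta["mito_fraction"].to_numpy() > mito_max
    bad_genes = meta["genes_detected"].to_numpy() > genes_max
    keep_cells = ~(bad_mito | bad_genes)
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filters")

    keep_genes = np.array([g not in blocklist for g in m.gene_ids], dtype=bool)
    filtered = LayeredCountMatrix(
        m.spliced[np.ix_(keep_genes, keep_cells)],
        m.unspliced[np.ix_(keep_genes, keep_cells)],
        [g for g, k in zip(m.gene_ids, keep_genes) if k],
        meta.loc[keep_cells].reset_index(drop=True),
    )
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_out=filtered.n_cells,
        removed_mito=int(bad_mito.sum()),
        removed_genes_max=int(bad_genes.sum()),
        n_genes_in=m.n_genes,
        n_genes_out=filtered.n_genes,
        blocklisted=[g for g, k in zip(m.gene_ids, keep_genes) if not k],
    )
    return filtered, report


def normalize_log(
    counts: np.ndarray, scale_total: float = 10000.0
) -> np.ndarray:
    """Depth-normalize each cell (column) to ``scale_total`` counts and
    apply log1p. Genes x cells in, genes x cells out."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(counts / safe * scale_total)


def select_hvg(lognorm: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the top ``n_hvg`` genes by variance-to-mean dispersion
    of the log-normalized values; ties broken by gene order."""
    mean = lognorm.mean(axis=1)
    var = lognorm.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-dispersion, kind="stable")
    return np.sort(order[:n_hvg])


def preprocess_embed(
    m: LayeredCountMatrix,
    scale_total: float = 10000.0,
    n_hvg: int = 2000,
    d: int = 2,
) -> EmbeddingState:
    """Log-normalize, select highly variable genes, and embed by PCA.

    PCA is computed by SVD on the centered HVG matrix with a fixed sign
    convention (the largest-magnitude loading of each component is made
    positive), so the embedding is deterministic given the input.
    """
    lognorm = normalize_log(m.spliced, scale_total)
    n_hvg = min(n_hvg, m.n_genes)
    hvg_idx = select_hvg(lognorm, n_hvg)
    X = lognorm[hvg_idx].T  # cells x hvg genes
    if d > min(X.shape):
        raise ValueError(
            f"d={d} exceeds the available rank min{X.shape} of the HVG matrix"
        )
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:d].T  # genes x d
    # sign convention: largest-|loading| entry of each component positive
    for j in range(d):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    coords = Xc @ loadings
    n = X.shape[0]
    explained = (S[:d] ** 2) / max(n - 1, 1)
    return EmbeddingState(
        coordinates=coords,
        loadings=loadings,
        gene_means=means,
        gene_ids=[m.gene_ids[i] for i in hvg_idx],
        explained_variance=explained,
    )


def variance_explained(
    expr: np.ndarray, factors: pd.DataFrame
) -> pd.Series:
    """Fraction of expression variance attributable to each factor.

    Per gene, a linear model is fitted on the categorical factors using
    sequential (type-I) sums of squares in the column order given by the
    caller; each factor's SS fraction of the total is averaged over
    genes. Fractions per gene sum to <= 1, the residual making up the
    remainder. Aliased factors (no added rank) get NaN with a warning.

    Parameters
    ----------
    expr : genes x cells normalized expression
    factors : per-cell categorical table, >= 2 levels per factor
    """
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    n_cells = expr.shape[1]
    if len(factors) != n_cells:
        raise ValueError("factor table length does not match cell count")
    for col in factors.columns:
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")

    Y = expr.T - expr.mean(axis=1)  # cells x genes, centered
    ss_total = (Y**2).sum(axis=0)
    nonconstant = ss_total > 0
    design_blocks = [np.ones((n_cells, 1))]
    fractions: dict[str, float] = {}
    prev_rank = 1
    prev_fit = np.zeros_like(Y)
    for col in factors.columns:
        dummies = pd.get_dummies(factors[col], drop_first=True).to_numpy(float)
        design_blocks.append(dummies)
        X = np.hstack(design_blocks)
        Q, R = np.linalg.qr(X)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(X.shape)))
        if rank <= prev_rank:
            warnings.warn(
                f"factor {col!r} is aliased with preceding factors; reporting NaN"
            )
            fractions[col] = float("nan")
            continue
        fit = Q @ (Q.T @ Y)
        ss_factor = ((fit - prev_fit) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(nonconstant, ss_factor / np.where(nonconstant, ss_total, 1.0), 0.0)
        fractions[col] = float(frac[nonconstant].mean()) if nonconstant.any() else 0.0
        prev_fit = fit
        prev_rank = rank
    return pd.Series(fractions, name="variance_fraction")
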