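"""Core data containers shared across the pipeline.

The transcriptome substrate is a genes x cells pair of spliced/unspliced
UMI count layers with per-cell categorical metadata; the behavioral
substrate is a set of fixed-interval 2-D position tracks. Both are plain
dataclasses with I/O helpers (MTX + TSV, AnnData/h5ad, CSV) so that every
downstream stage can be tested on small in-memory objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class LayeredCountMatrix:
    """Genes x cells spliced and unspliced UMI counts plus cell metadata.

    Parameters
    ----------
    spliced, unspliced
        Nonnegative integer matrices of identical shape (genes x cells).
    gene_ids
        Unique gene identifiers, one per row.
    cell_metadata
        Per-cell table indexed like the columns; categorical columns
        (``age``, ``lrc``, ``timepoint``) plus optional QC columns
        (``total_umis``, ``genes_detected``, ``mito_fraction``).
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    gene_ids: list[str]
    cell_metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.spliced = np.asarray(self.spliced)
        self.unspliced = np.asarray(self.unspliced)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError(
                f"layer shapes differ: spliced {self.spliced.shape} vs "
                f"unspliced {self.unspliced.shape}"
            )
        if len(self.gene_ids) != self.spliced.shape[0]:
            raise ValueError("gene_ids length does not match layer rows")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(self.cell_metadata) != self.spliced.shape[1]:
            raise ValueError("cell_metadata length does not match layer columns")
        if (self.spliced < 0).any() or (self.unspliced < 0).any():
            raise ValueError("count layers must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[1]

    def with_qc_columns(self) -> "LayeredCountMatrix":
        """Return a copy whose metadata carries total_umis, genes_detected
        and mito_fraction (computed from ``mt-``-prefixed genes when the
        column is absent)."""
        meta = self.cell_metadata.copy()
        total = self.spliced.sum(axis=0) + self.unspliced.sum(axis=0)
        if "total_umis" not in meta:
            meta["total_umis"] = total
        if "genes_detected" not in meta:
            meta["genes_detected"] = (self.spliced > 0).sum(axis=0)
        if "mito_fraction" not in meta:
            mito = np.array(
                [g.lower().startswith("mt-") for g in self.gene_ids], dtype=bool
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(
                    total > 0, self.spliced[mito].sum(axis=0) / np.maximum(total, 1), 0.0
                )
            meta["mito_fraction"] = frac
        return LayeredCountMatrix(self.spliced, self.unspliced, list(self.gene_ids), meta)

    # ---- I/O -------------------------------------------------------------

    def to_mtx_dir(self, path: str | Path) -> None:
        """Write one MTX file per layer plus gene and cell metadata TSVs."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "spliced.mtx", sparse.csr_matrix(self.spliced))
        spio.mmwrite(path / "unspliced.mtx", sparse.csr_matrix(self.unspliced))
        pd.Series(self.gene_ids, name="gene_id").to_csv(
            path / "genes.tsv", sep="\t", index=False
        )
        self.cell_metadata.to_csv(path / "cells.tsv", sep="\t", index=False)

    @classmethod
    def from_mtx_dir(cls, path: str | Path) -> "LayeredCountMatrix":
        path = Path(path)
        spliced = np.asarray(spio.mmread(path / "spliced.mtx").todense())
        unspliced = np.asarray(spio.mmread(path / "unspliced.mtx").todense())
        genes = pd.read_csv(path / "genes.tsv", sep="\t")["gene_id"].tolist()
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        return cls(spliced.astype(int), unspliced.astype(int), genes, cells)

    def to_anndata(self):
        """Cells x genes AnnData with layers ``spliced``/``unspliced``."""
        import anndata as ad

        adata = ad.AnnData(
            X=sparse.csr_matrix(self.spliced.T),
            obs=self.cell_metadata.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.layers["spliced"] = sparse.csr_matrix(self.spliced.T)
        adata.layers["unspliced"] = sparse.csr_matrix(self.unspliced.T)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "LayeredCountMatrix":
        def dense(layer):
            return np.asarray(
                layer.todense() if sparse.issparse(layer) else layer
            ).T.astype(int)

        return cls(
            dense(adata.layers["spliced"]),
            dense(adata.layers["unspliced"]),
            adata.var_names.tolist(),
            adata.obs.reset_index(drop=True),
        )


@dataclass
class TrackSet:
    """Per-cell 2-D position time series sampled at a fixed frame interval.

    ``positions`` has shape (n_cells, n_frames, 2) in micrometres;
    ``frame_interval`` is in minutes; ``window`` is the analyzed span in
    hours (default 10-35 h). ``cell_metadata`` may carry group labels.
    """

    positions: np.ndarray
    frame_interval: float
    window: tuple[float, float] = (10.0, 35.0)
    cell_ids: Optional[list[str]] = None
    cell_metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_cells, n_frames, 2)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.cell_ids is None:
            self.cell_ids = [f"cell_{i}" for i in range(self.positions.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def window_slice(self, window: Optional[tuple[float, float]] = None) -> np.ndarray:
        """Positions restricted to frames inside the analysis window."""
        lo, hi = window if window is not None else self.window
        t_hours = np.arange(self.n_frames) * self.frame_interval / 60.0
        mask = (t_hours >= lo) & (t_hours <= hi)
        if mask.sum() < 3:
            raise ValueError("analysis window covers fewer than 3 frames")
        return self.positions[:, mask, :]

    def to_csv(self, path: str | Path) -> None:
        n_cells, n_frames, _ = self.positions.shape
        frames = np.tile(np.arange(n_frames), n_cells)
        ids = np.repeat(self.cell_ids, n_frames)
        flat = self.positions.reshape(-1, 2)
        pd.DataFrame(
            {"cell_id": ids, "frame": frames, "x_um": flat[:, 0], "y_um": flat[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, frame_interval: float = 6.5, **kwargs
    ) -> "TrackSet":
        df = pd.read_csv(path)
        pivots = df.sort_values(["cell_id", "frame"])
        ids = pivots["cell_id"].unique().tolist()
        n_frames = pivots.groupby("cell_id")["frame"].size()
        if n_frames.nunique() != 1:
            raise ValueError("all tracks must share the same frame count")
        nf = int(n_frames.iloc[0])
        pos = pivots[["x_um", "y_um"]].to_numpy().reshape(len(ids), nf, 2)
        return cls(pos, frame_interval, cell_ids=[str(i) for i in ids], **kwargs)


@dataclass
class EmbeddingState:
    """A PCA state space for cells, optionally annotated with pseudotime.

    ``coordinates`` is cells x d (scores); ``loadings`` genes x d with
    orthonormal columns; ``gene_means`` the centering vector so that
    ``project(x) = (x - gene_means) @ loadings``.
    """

    coordinates: np.ndarray
    loadings: np.ndarray
    gene_means: np.ndarray
    gene_ids: list[str]
    pseudotime: Optional[np.ndarray] = None
    explained_variance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.gene_means = np.asarray(self.gene_means, dtype=float)
        d = self.coordinates.shape[1]
        if self.loadings.shape[1] != d:
            raise ValueError("loadings and coordinates disagree on dimension d")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(d), atol=1e-6):
            raise ValueError("loadings columns are not orthonormal (tol 1e-6)")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if np.nanmin(self.pseudotime) < 0:
                raise ValueError("pseudotime must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def project(self, expr: np.ndarray) -> np.ndarray:
        """Map cells x genes expression into the embedding."""
        expr = np.atleast_2d(np.asarray(expr, dtype=float))
        return (expr - self.gene_means) @ self.loadings

    def to_tsv(self, path: str | Path, cell_ids: Optional[list[str]] = None) -> None:
        cols = {f"PC{i + 1}": self.coordinates[:, i] for i in range(self.d)}
        df = pd.DataFrame(cols)
        df.insert(
            0,
            "cell_id",
            cell_ids if cell_ids is not None else np.arange(self.n_cells),
        )
        if self.pseudotime is not None:
            df["pseudotime"] = self.pseudotime
        df.to_csv(path, sep="\t", index=False)


@dataclass
class VelocityField:
    """Per-gene degradation ratios and per-cell velocity vectors.

    ``velocity_gene`` is cells x genes (v = u - gamma_hat * s on the
    normalized layers); ``velocity_embed`` is cells x d in an
    EmbeddingState coordinate system; ``delta_t`` the dimensionless
    extrapolation step.
    """

    gamma_hat: np.ndarray
    velocity_gene: np.ndarray
    gene_ids: list[str]
    delta_t: float = 1.0
    velocity_embed: Optional[np.ndarray] = None
    future_spliced: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        if (self.gamma_hat < 0).any():
            raise ValueError("gamma_hat must be nonnegative")


@dataclass
class PhaseSimResult:
    """Trajectories of phase points advected through a velocity field."""

    trajectories: np.ndarray  # n_points x (n_steps + 1) x d
    terminal_positions: np.ndarray  # n_points x d
    density_grid: np.ndarray  # grid x grid visit counts
    density_edges: tuple[np.ndarray, np.ndarray]
    inferred_pseudotime: Optional[np.ndarray] = None  # n_points x (n_steps + 1)
    config: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.trajectories.shape[0]

    @property
    def n_steps(self) -> int:
        return self.trajectories.shape[1] - 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            trajectories=self.trajectories,
            terminal_positions=self.terminal_positions,
            density_grid=self.density_grid,
            density_x=self.density_edges[0],
            density_y=self.density_edges[1],
            **(
                {"inferred_pseudotime": self.inferred_pseudotime}
                if self.inferred_pseudotime is not None
                else {}
            ),
        )
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(self.config, fh, indent=2)
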