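"""Breadth of promiscuous gene expression by single-cell resampling.

Cells are first depth-matched by downsampling each library to a fixed number
of transcriptomic fragments.  Increasing numbers of cells are then resampled
(without replacement, many replicates) and the mean number of detectable
genes per gene category is recorded; groups are compared at a fixed cell
number with rank-sum tests under Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.io import mmread, mmwrite

from .errors import ConfigurationError, InputError

GENE_CATEGORIES = ("aire_dependent", "aire_enhanced", "aire_independent_tra", "other")


@dataclass
class CellCountMatrix:
    """Sparse cells × genes counts with per-cell and per-gene annotations."""

    counts: sparse.csr_matrix
    cell_meta: pd.DataFrame  # index: cell id; columns: population [, aire_count]
    gene_meta: pd.DataFrame  # index: gene id; column: category

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise InputError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.cell_meta)} cells × {len(self.gene_meta)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InputError("counts must be non-negative")
        bad = set(self.gene_meta["category"]) - set(GENE_CATEGORIES)
        if bad:
            raise InputError(f"unknown gene categories: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, index: np.ndarray) -> "CellCountMatrix":
        return CellCountMatrix(
            counts=self.counts[index],
            cell_meta=self.cell_meta.iloc[index],
            gene_meta=self.gene_meta,
        )

    @classmethod
    def from_files(
        cls, mtx: str | Path, genes_tsv: str | Path, cells_tsv: str | Path
    ) -> "CellCountMatrix":
        """Load MatrixMarket counts (cells × genes) plus TSV annotations."""
        counts = sparse.csr_matrix(mmread(str(mtx)))
        genes = pd.read_csv(genes_tsv, sep="\t", index_col=0)
        cells = pd.read_csv(cells_tsv, sep="\t", index_col=0)
        return cls(counts=counts, cell_meta=cells, gene_meta=genes)

    def to_files(self, mtx: str | Path, genes_tsv: str | Path, cells_tsv: str | Path) -> None:
        mmwrite(str(mtx), sparse.coo_matrix(self.counts))
        self.gene_meta.to_csv(genes_tsv, sep="\t")
        self.cell_meta.to_csv(cells_tsv, sep="\t")


def downsample_fragments(
    cell_counts: np.ndarray,
    target: int = 200_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Downsample one cell's gene counts to ``target`` total fragments.

    Fragments are drawn without replacement (multivariate hypergeometric).
    A cell at or below the target is returned unchanged.
    """
    if target < 1:
        raise InputError(f"target must be >= 1, got {target}")
    counts = np.asarray(cell_counts, dtype=np.int64)
    if counts.ndim != 1:
        raise InputError("cell_counts must be a 1-D vector")
    if counts.min(initial=0) < 0:
        raise InputError("counts must be non-negative")
    total = int(counts.sum())
    if total <= target:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, target)


def downsample_matrix(
    matrix: CellCountMatrix,
    target: int = 200_000,
    seed: int | None = None,
    drop_under_depth: bool = True,
) -> tuple[CellCountMatrix, np.ndarray]:
    """Depth-match every cell to ``target`` fragments.

    Returns the downsampled matrix and the boolean under-depth flags of the
    *original* cells.  Under-depth cells are dropped by default (mixing
    depths biases detection); set ``drop_under_depth=False`` to keep them
    unscaled.
    """
    rng = np.random.default_rng(seed)
    dense_rows = []
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    under = totals < target
    for i in range(matrix.n_cells):
        row = np.asarray(matrix.counts[i].todense()).ravel()
        dense_rows.append(downsample_fragments(row, target, rng))
    counts = sparse.csr_matrix(np.vstack(dense_rows))
    out = CellCountMatrix(counts=counts, cell_meta=matrix.cell_meta.copy(), gene_meta=matrix.gene_meta)
    if drop_under_depth and under.any():
        out = out.subset_cells(np.flatnonzero(~under))
    return out, under


def select_aire_cells(
    matrix: CellCountMatrix,
    aire_gene: str = "Aire",
    threshold: int = 1,
) -> np.ndarray:
    """Indices of cells expressing the Aire gene at >= ``threshold`` counts.

    Uses the per-cell ``aire_count`` annotation when present, otherwise the
    counts of ``aire_gene`` itself.
    """
    if "aire_count" in matrix.cell_meta.columns:
        aire = matrix.cell_meta["aire_count"].to_numpy()
    else:
        if aire_gene not in matrix.gene_meta.index:
            raise ConfigurationError(
                f"gene {aire_gene!r} absent and no aire_count annotation present"
            )
        col = matrix.gene_meta.index.get_loc(aire_gene)
        aire = np.asarray(matrix.counts[:, col].todense()).ravel()
    idx = np.flatnonzero(aire >= threshold)
    if idx.size == 0:
        warnings.warn("no Aire-expressing cells found", stacklevel=2)
    return idx


@dataclass(frozen=True)
class BreadthCurve:
    """Mean detectable genes per category over resampled cell numbers."""

    categories: tuple[str, ...]
    n_grid: tuple[int, ...]
    mean: np.ndarray  # categories × n_grid
    sd: np.ndarray
    replicates: Mapping[tuple[str, int], np.ndarray]  # (category, n) -> n_rep values
    n_rep: int
    seed: int | None
    target_fragments: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cat in enumerate(self.categories):
            for j, n in enumerate(self.n_grid):
                rows.append(
                    {"category": cat, "n_cells": n, "mean": self.mean[i, j], "sd": self.sd[i, j]}
                )
        return pd.DataFrame(rows)


def detectable_gene_curve(
    matrix: CellCountMatrix,
    n_grid: Sequence[int],
    n_rep: int = 100,
    seed: int | None = None,
    detect_threshold: int = 1,
) -> BreadthCurve:
    """Resample ``n`` cells without replacement ``n_rep`` times per grid point.

    A gene is detectable in a draw iff its summed count over the drawn cells
    reaches ``detect_threshold``.  One child RNG per (n, replicate) keeps the
    draws independent and the whole curve deterministic given ``seed``.
    """
    n_grid = [int(n) for n in n_grid]
    if max(n_grid) > matrix.n_cells:
        raise InputError(
            f"n_grid maximum {max(n_grid)} exceeds available cells {matrix.n_cells}"
        )
    if min(n_grid) < 1:
        raise InputError("n_grid entries must be >= 1")
    cats = tuple(c for c in GENE_CATEGORIES if (matrix.gene_meta["category"] == c).any())
    cat_masks = {c: (matrix.gene_meta["category"] == c).to_numpy() for c in cats}
    csr = matrix.counts
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(n_grid) * n_rep)

    mean = np.empty((len(cats), len(n_grid)))
    sd = np.empty_like(mean)
    replicates: dict[tuple[str, int], np.ndarray] = {}
    per_rep = {c: np.empty(n_rep) for c in cats}
    for j, n in enumerate(n_grid):
        for r in range(n_rep):
            rng = np.random.default_rng(children[j * n_rep + r])
            cells = rng.choice(matrix.n_cells, size=n, replace=False)
            summed = np.asarray(csr[cells].sum(axis=0)).ravel()
            detected = summed >= detect_threshold
            for c in cats:
                per_rep[c][r] = int(np.count_nonzero(detected & cat_masks[c]))
        for i, c in enumerate(cats):
            vals = per_rep[c].copy()
            replicates[(c, n)] = vals
            mean[i, j] = vals.mean()
            sd[i, j] = vals.std(ddof=1) if n_rep > 1 else 0.0
    return BreadthCurve(
        categories=cats,
        n_grid=tuple(n_grid),
        mean=mean,
        sd=sd,
        replicates=replicates,
        n_rep=n_rep,
        seed=seed,
    )


def expected_detectable(matrix: CellCountMatrix, n: int, detect_threshold: int = 1) -> dict[str, float]:
    """Closed-form expectation Σ_g [1 − C(N−k_g, n)/C(N, n)] per category,
    with k_g = number of cells in which gene g reaches the detect threshold."""
    N = matrix.n_cells
    if n > N:
        raise InputError("n exceeds available cells")
    binary = (matrix.counts >= detect_threshold).astype(np.int64)
    k = np.asarray(binary.sum(axis=0)).ravel()
    # P(gene undetected in n draws without replacement) = C(N-k, n)/C(N, n)
    from scipy.special import gammaln

    def log_choose(a, b):
        out = np.full(np.shape(a), -np.inf, dtype=float)
        a = np.asarray(a, dtype=float)
        ok = a >= b
        out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1.0) - gammaln(a[ok] - b + 1)
        return out

    p_miss = np.exp(log_choose(N - k, n) - log_choose(np.array([float(N)]), n)[0])
    p_detect = 1.0 - p_miss
    out = {}
    for c in GENE_CATEGORIES:
        mask = (matrix.gene_meta["category"] == c).to_numpy()
        if mask.any():
            out[c] = float(p_detect[mask].sum())
    return out


@dataclass(frozen=True)
class BreadthComparison:
    category: str
    fold_change: float  # mean(A)/mean(B)
    statistic: float
    p_value: float
    p_bh: float


def compare_breadth(
    group_a: BreadthCurve,
    group_b: BreadthCurve,
    n_cells: int = 130,
) -> list[BreadthComparison]:
    """Per-category two-sided Wilcoxon rank-sum on replicate detectable-gene
    counts at ``n_cells``, Benjamini-Hochberg corrected across categories."""
    cats = [c for c in group_a.categories if c in group_b.categories]
    raw = []
    for c in cats:
        key = (c, n_cells)
        if key not in group_a.replicates or key not in group_b.replicates:
            raise InputError(f"n_cells={n_cells} missing from the grid for category {c!r}")
        a = group_a.replicates[key]
        b = group_b.replicates[key]
        if np.array_equal(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ranksums(a, b)
        raw.append((c, float(stat), float(p), float(a.mean()), float(b.mean())))
    p_bh = stats.false_discovery_control([r[2] for r in raw], method="bh")
    return [
        BreadthComparison(
            category=c,
            fold_change=ma / mb if mb != 0 else float("inf"),
            statistic=stat,
            p_value=p,
            p_bh=float(q),
        )
        for (c, stat, p, ma, mb), q in zip(raw, p_bh)
    ]
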