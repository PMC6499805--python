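"""SVD eigengene / eigenarray analysis of the significant-gene matrix.

The expression matrix restricted to the significantly changing genes is
decomposed as X = U S V^T: columns of U are "eigenarrays" (a basis over
genes), rows of V^T are "eigengenes" (a basis over samples), and each
squared singular value's share of the total is that dimension's
"eigenexpression" fraction — the variance captured by SVD1, SVD2, ...
Individual genes and per-sample sums of the significant genes are
mapped into the plane of two chosen dimensions and reported in polar
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountMatrix, GeneSet
from .diffexpr import cpm

__all__ = [
    "ExpressionMatrix",
    "EigenDecomposition",
    "transform_expression",
    "eigen_decompose",
    "eigenspace_coordinates",
]


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression shape does not match id lists")


@dataclass
class EigenDecomposition:
    """X = eigenarrays @ diag(singular_values) @ eigengenes.

    eigenarrays: (genes x r) left basis; eigengenes: (r x samples) right
    basis; fractions: squared singular value shares, non-increasing.
    Sign convention: the first nonzero loading of each eigenarray is
    positive, so outputs are backend-independent.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    eigenarrays: np.ndarray
    eigengenes: np.ndarray
    singular_values: np.ndarray

    @property
    def fractions(self) -> np.ndarray:
        s2 = self.singular_values**2
        total = s2.sum()
        return s2 / total if total > 0 else s2

    def gene_projections(self) -> np.ndarray:
        """Rows of X expressed in eigengene coordinates: U @ S."""
        return self.eigenarrays * self.singular_values

    def sample_projections(self) -> np.ndarray:
        """Columns of X expressed in eigenarray coordinates: (S @ Vt)^T."""
        return (self.singular_values[:, None] * self.eigengenes).T


def transform_expression(cm: CountMatrix, method: str = "log2cpm") -> ExpressionMatrix:
    """Counts -> expression values.

    "log2cpm" (default): log2(CPM + 1).  "raw": counts as floats.
    "log2cpm_centered": log2(CPM + 1) with each gene row centered.
    """
    if method == "raw":
        vals = cm.counts.astype(float)
    elif method in ("log2cpm", "log2cpm_centered"):
        vals = np.log2(cpm(cm.counts) + 1.0)
        if method == "log2cpm_centered":
            vals = vals - vals.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), vals, method)


def eigen_decompose(
    expr: ExpressionMatrix, gene_subset: GeneSet | None = None
) -> EigenDecomposition:
    """SVD of the expression matrix restricted to ``gene_subset`` rows."""
    if gene_subset is not None:
        keep = [i for i, g in enumerate(expr.gene_ids) if g in gene_subset]
        if not keep:
            raise ValueError("gene_subset does not intersect the expression rows")
        gene_ids = [expr.gene_ids[i] for i in keep]
        x = expr.values[keep, :]
    else:
        gene_ids, x = list(expr.gene_ids), expr.values
    if len(gene_ids) < 2 or len(expr.sample_ids) < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs: first nonzero loading of each eigenarray positive
    for k in range(u.shape[1]):
        col = u[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            u[:, k] = -col
            vt[k, :] = -vt[k, :]
    return EigenDecomposition(gene_ids, list(expr.sample_ids), u, vt, s)


def _to_polar(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.hypot(xy[:, 0], xy[:, 1])
    theta = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
    theta[r == 0] = 0.0  # angle of the origin defined as 0 by convention
    return r, theta


def eigenspace_coordinates(
    dec: EigenDecomposition,
    entity: str = "genes",
    dims: tuple[int, int] = (1, 2),
    group_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Polar coordinates of genes, samples, or per-group sample sums.

    ``dims`` are 1-based dimension indices (SVD1 = 1).  For
    entity="group_sums" the coordinate of a group is the vector sum of
    its member samples' projections; a group mapping is required.
    Returns a table (entity, x, y, r, theta_deg) with theta measured
    counter-clockwise from the +axis of the first requested dimension.
    """
    j, k = dims
    rank = len(dec.singular_values)
    if not (1 <= j <= rank and 1 <= k <= rank):
        raise ValueError(f"dims {dims} out of range for rank {rank}")
    jj, kk = j - 1, k - 1

    if entity == "genes":
        proj = dec.gene_projections()[:, [jj, kk]]
        names = dec.gene_ids
    elif entity == "samples":
        proj = dec.sample_projections()[:, [jj, kk]]
        names = dec.sample_ids
    elif entity == "group_sums":
        if group_of is None:
            raise ValueError("group_sums requires a group mapping")
        sp = dec.sample_projections()[:, [jj, kk]]
        names = list(dict.fromkeys(group_of[s] for s in dec.sample_ids))
        proj = np.vstack(
            [
                sp[[i for i, s in enumerate(dec.sample_ids) if group_of[s] == g]].sum(
                    axis=0
                )
                for g in names
            ]
        )
    else:
        raise ValueError(f"unknown entity {entity!r}")

    r, theta = _to_polar(proj)
    return pd.DataFrame(
        {"entity": names, "x": proj[:, 0], "y": proj[:, 1], "r": r, "theta_deg": theta}
    )
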