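"""Reference preparation: from a pseudotime-annotated single-cell reference to the
fixed/random design objects consumed by the mixed-model core.

The deconvolution target ("focal") cell type carries a one-dimensional trajectory
coordinate (pseudotime).  Its cells are ranked along that coordinate and subdivided
into ``m`` consecutive states; each state's mean signature-gene profile becomes one
fixed-effect column, the individual focal cells become random-effect columns, and the
other cell types enter as per-type mean covariates.  Pairwise trajectory distances
define a Gaussian weight graph ``w_ij = exp(-d_ij^2)`` from which the conditional
autoregressive random-effect covariance is built downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "ReferenceSet",
    "StateDesign",
    "TrajectoryWeights",
    "filter_genes",
    "select_signature_genes",
    "build_states",
    "build_trajectory_weights",
    "cp10k",
]


@dataclass
class ReferenceSet:
    """Single-cell reference: genes x cells expression with labels and pseudotime.

    ``pseudotime`` must be finite for every cell of ``focal_type``; it may be NaN
    elsewhere.  Expression is non-negative (counts or library-size-normalized values).
    """

    expr: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray
    pseudotime: np.ndarray
    focal_type: str

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        self.cell_type = np.asarray(self.cell_type)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        n_genes, n_cells = self.expr.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match expression rows")
        if not (len(self.cell_ids) == len(self.cell_type) == len(self.pseudotime) == n_cells):
            raise ValueError("cell annotation lengths do not match expression columns")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if np.any(self.expr < 0):
            raise ValueError("expression matrix has negative entries")
        focal = self.focal_mask
        if not focal.any():
            raise ValueError(f"no cells of focal type {self.focal_type!r} in reference")
        if not np.all(np.isfinite(self.pseudotime[focal])):
            raise ValueError("pseudotime must be finite for every focal-type cell")

    @property
    def focal_mask(self) -> np.ndarray:
        return self.cell_type == self.focal_type

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    def focal_order(self) -> np.ndarray:
        """Column indices of focal cells sorted by (pseudotime, cell_id).

        The cell-id tiebreak makes every downstream design matrix invariant to the
        storage order of cells.
        """
        idx = np.flatnonzero(self.focal_mask)
        key = np.lexsort((self.cell_ids[idx].astype(str), self.pseudotime[idx]))
        return idx[key]


@dataclass
class StateDesign:
    """Fixed/random design built from a reference: one column of ``X`` per focal
    state (per-state mean), ``C`` the per-other-type mean covariates, ``Z`` the
    individual focal cells, all restricted to the signature genes."""

    m_states: int
    state_members: list[np.ndarray]
    state_pseudotime: np.ndarray
    X: np.ndarray
    C: np.ndarray
    Z: np.ndarray
    signature_genes: np.ndarray
    cell_pseudotime: np.ndarray
    cell_ids: np.ndarray
    other_types: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]

    @property
    def k_cells(self) -> int:
        return self.Z.shape[1]


@dataclass
class TrajectoryWeights:
    """Gaussian trajectory-distance weight graph: ``W`` symmetric, zero diagonal,
    ``d`` the row sums (diagonal of ``D``)."""

    W: np.ndarray
    dist: np.ndarray
    d: np.ndarray

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.d)

    def precision(self, theta: float) -> np.ndarray:
        """CAR precision matrix ``(D - theta W) / lambda^2`` without the scale.

        Strictly diagonally dominant, hence positive definite, for theta in [0, 1).
        """
        if not 0.0 <= theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {theta}")
        return np.diag(self.d) - theta * self.W


def cp10k(matrix: np.ndarray) -> np.ndarray:
    """Library-size normalize columns to counts-per-10,000 (no log)."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("cannot library-size normalize: a column sums to zero")
    return matrix * (1e4 / sums)


def filter_genes(ref: ReferenceSet, min_frac: float = 0.10) -> ReferenceSet:
    """Drop genes expressed (>0) in fewer than ``min_frac`` of focal-type cells.

    A gene expressed in exactly ``min_frac`` of cells is retained.  Idempotent.
    """
    if not 0.0 <= min_frac < 1.0:
        raise ValueError(f"min_frac must be in [0, 1), got {min_frac}")
    focal = ref.focal_mask
    frac = (ref.expr[:, focal] > 0).mean(axis=1)
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("gene filter removed every gene; reference is empty")
    return ReferenceSet(
        expr=ref.expr[keep],
        gene_ids=ref.gene_ids[keep],
        cell_ids=ref.cell_ids,
        cell_type=ref.cell_type,
        pseudotime=ref.pseudotime,
        focal_type=ref.focal_type,
    )


def _spline_basis(t: np.ndarray, n_internal_knots: int = 4) -> np.ndarray:
    """Clamped cubic B-spline basis on trajectory coordinates in [0, 1]."""
    internal = np.unique(np.quantile(t, np.linspace(0, 1, n_internal_knots + 2)[1:-1]))
    knots = np.concatenate(([0.0] * 4, internal, [1.0] * 4))
    x = np.clip(t, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(x, knots, 3).toarray()


def select_signature_genes(
    ref: ReferenceSet,
    n_genes: int = 500,
    n_segments: int = 10,
) -> np.ndarray:
    """Select genes whose focal-type expression tracks the trajectory.

    Each gene is scored by the F statistic of a cubic-spline regression of its
    focal-cell expression on pseudotime (against an intercept-only model).  To spread
    information along the trajectory, up to ``n_genes / n_segments`` genes with a
    significant association (F-test p < 0.01) whose fitted-profile peak falls in
    each of ``n_segments`` equal trajectory segments are taken first — the
    significance gate keeps segments without genuine trajectory genes from forcing
    noise picks — and the shortfall is filled from the global F ranking.  Constant
    genes (zero trajectory association) are never selected.  Deterministic and
    invariant to cell storage order.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if n_genes > ref.n_genes:
        raise ValueError(
            f"requested {n_genes} signature genes but only {ref.n_genes} available"
        )
    order = ref.focal_order()
    t = ref.pseudotime[order]
    span = t.max() - t.min()
    tr = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    basis = _spline_basis(tr)
    nc = len(tr)
    # orthonormal column space of the basis (rank-safe via SVD)
    u, sv, _ = np.linalg.svd(basis, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    q = u[:, :rank]
    if nc <= rank:
        raise ValueError("too few focal cells for the spline association test")

    y = ref.expr[:, order].T  # cells x genes
    coef = q.T @ y
    rss1 = np.maximum(np.einsum("ij,ij->j", y, y) - np.einsum("ij,ij->j", coef, coef), 0.0)
    centered = y - y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    df_model = rank - 1
    df_resid = nc - rank
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / df_model) / (rss1 / df_resid)
    f_stat = np.where(rss0 <= 1e-12 * nc, 0.0, f_stat)
    f_stat = np.where(np.isnan(f_stat), np.inf, f_stat)  # perfect fit, rss1 == 0

    fitted = q @ coef
    peak_t = tr[np.argmax(fitted, axis=0)]
    segment = np.clip((peak_t * n_segments).astype(int), 0, n_segments - 1)

    candidates = np.flatnonzero(f_stat > 0)
    if len(candidates) < n_genes:
        raise ValueError(
            f"only {len(candidates)} trajectory-associated genes available, "
            f"need {n_genes}"
        )
    # deterministic ordering: descending F, gene id as tiebreak
    gene_key = ref.gene_ids.astype(str)
    order_key = np.lexsort((gene_key[candidates], -f_stat[candidates]))
    ranked = candidates[order_key]

    from scipy.stats import f as f_dist

    with np.errstate(invalid="ignore"):
        significant = f_dist.sf(f_stat, df_model, df_resid) < 0.01
    significant |= np.isinf(f_stat)

    per_segment = n_genes // n_segments
    chosen: list[int] = []
    chosen_mask = np.zeros(ref.n_genes, dtype=bool)
    if per_segment > 0:
        for seg in range(n_segments):
            in_seg = ranked[(segment[ranked] == seg) & significant[ranked]][:per_segment]
            chosen.extend(in_seg.tolist())
            chosen_mask[in_seg] = True
    for g in ranked:
        if len(chosen) >= n_genes:
            break
        if not chosen_mask[g]:
            chosen.append(g)
            chosen_mask[g] = True
    chosen_arr = np.array(chosen[:n_genes])
    final_key = np.lexsort((gene_key[chosen_arr], -f_stat[chosen_arr]))
    return ref.gene_ids[chosen_arr[final_key]]


def build_states(
    ref: ReferenceSet,
    m_states: int,
    signature_genes: np.ndarray,
) -> StateDesign:
    """Bin focal cells into ``m_states`` contiguous equal-count states and assemble
    the fixed/random designs restricted to the signature genes.

    States are equal-count bins of the pseudotime ranking (robust to non-uniform
    pseudotime density); the representative state coordinate is the member median.
    """
    if m_states < 2:
        raise ValueError(f"m_states must be >= 2, got {m_states}")
    signature_genes = np.asarray(signature_genes)
    gene_row = {g: i for i, g in enumerate(ref.gene_ids)}
    missing = [g for g in signature_genes if g not in gene_row]
    if missing:
        raise ValueError(f"signature genes absent from reference: {missing[:5]}")
    rows = np.array([gene_row[g] for g in signature_genes])

    order = ref.focal_order()
    k = len(order)
    if m_states > k:
        raise ValueError(f"m_states={m_states} exceeds {k} focal cells")
    Z = ref.expr[np.ix_(rows, order)]
    t = ref.pseudotime[order]

    members = np.array_split(np.arange(k), m_states)
    X = np.column_stack([Z[:, mem].mean(axis=1) for mem in members])
    state_pt = np.array([np.median(t[mem]) for mem in members])

    other_types = sorted(set(ref.cell_type.astype(str)) - {str(ref.focal_type)})
    if other_types:
        C = np.column_stack(
            [
                ref.expr[np.ix_(rows, np.flatnonzero(ref.cell_type.astype(str) == ct))].mean(axis=1)
                for ct in other_types
            ]
        )
    else:
        C = np.empty((len(rows), 0))

    return StateDesign(
        m_states=m_states,
        state_members=[np.asarray(m) for m in members],
        state_pseudotime=state_pt,
        X=X,
        C=C,
        Z=Z,
        signature_genes=signature_genes,
        cell_pseudotime=t,
        cell_ids=ref.cell_ids[order],
        other_types=other_types,
    )


def build_trajectory_weights(
    pseudotime: np.ndarray,
    bandwidth: float | None = None,
) -> TrajectoryWeights:
    """Gaussian trajectory-distance weights ``w_ij = exp(-d_ij^2)``.

    Coordinates are min-max rescaled to [0, 1] first; exp(-d^2) is scale-sensitive,
    so distances are then multiplied by ``bandwidth``.  With ``bandwidth=None`` the
    scale is set to sqrt(ln 2) / median(|dt|), which puts the median off-diagonal
    weight at exactly 0.5.
    """
    t = np.asarray(pseudotime, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least 2 trajectory coordinates")
    span = t.max() - t.min()
    if span == 0:
        warnings.warn(
            "all trajectory coordinates identical; weights are all-ones off-diagonal",
            stacklevel=2,
        )
        tr = np.zeros_like(t)
    else:
        tr = (t - t.min()) / span
    dt = np.abs(tr[:, None] - tr[None, :])
    if bandwidth is None:
        off = dt[np.triu_indices(len(t), k=1)]
        med = np.median(off)
        bandwidth = np.sqrt(np.log(2.0)) / med if med > 0 else 1.0
    dist = dt * float(bandwidth)
    W = np.exp(-(dist**2))
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    return TrajectoryWeights(W=W, dist=dist, d=d)
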