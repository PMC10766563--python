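"""End-to-end deconvolution pipeline: gene matching, normalization, reference
preparation, per-sample REML + GLS, smoothing and rescaling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .lmm import (
    NullModelWorkspace,
    VarianceComponents,
    estimate_state_abundances,
    normalize_abundances,
    smooth_abundances,
    test_random_effect,
)
from .reference import (
    ReferenceSet,
    StateDesign,
    TrajectoryWeights,
    build_states,
    build_trajectory_weights,
    cp10k,
    filter_genes,
    select_signature_genes,
)

log = logging.getLogger(__name__)

__all__ = ["DeconvolutionResult", "PipelineContext", "prepare_pipeline", "deconvolve", "quartile_abundance"]

MIN_SHARED_GENES = 50


@dataclass
class DeconvolutionResult:
    """States x samples abundance tables (the tool's main product) plus per-sample
    variance components and random-effect test p-values."""

    raw: pd.DataFrame
    se: pd.DataFrame
    smoothed: pd.DataFrame
    normalized: pd.DataFrame
    state_pseudotime: np.ndarray
    gamma_hat: pd.DataFrame
    variance_components: dict[str, VarianceComponents] = field(default_factory=dict)
    random_effect_p: pd.Series | None = None


@dataclass
class PipelineContext:
    """Prepared design shared across samples (and across gene-shuffling
    permutations in the group test)."""

    design: StateDesign
    weights: TrajectoryWeights
    workspace: NullModelWorkspace
    Y: np.ndarray  # signature genes x samples, normalized bulk
    samples: list[str]
    config: RunConfig


def _match_genes(ref: ReferenceSet, bulk: pd.DataFrame) -> tuple[ReferenceSet, pd.DataFrame]:
    if bulk.index.duplicated().any():
        raise ValueError("bulk expression has duplicated gene ids")
    shared = [g for g in ref.gene_ids if g in set(bulk.index)]
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between reference and bulk "
            f"(need >= {MIN_SHARED_GENES})"
        )
    keep = np.isin(ref.gene_ids, shared)
    ref2 = ReferenceSet(
        expr=ref.expr[keep],
        gene_ids=ref.gene_ids[keep],
        cell_ids=ref.cell_ids,
        cell_type=ref.cell_type,
        pseudotime=ref.pseudotime,
        focal_type=ref.focal_type,
    )
    return ref2, bulk.loc[ref2.gene_ids]


def prepare_pipeline(
    ref: ReferenceSet,
    bulk: pd.DataFrame,
    config: RunConfig | None = None,
) -> PipelineContext:
    """Normalize, filter, select signature genes and build the shared design.

    Both reference and bulk are library-size normalized to counts-per-10^4 so the
    fixed/random designs and the bulk response are commensurate.
    """
    config = config or RunConfig()
    ref, bulk = _match_genes(ref, bulk)
    ref = ReferenceSet(
        expr=cp10k(ref.expr),
        gene_ids=ref.gene_ids,
        cell_ids=ref.cell_ids,
        cell_type=ref.cell_type,
        pseudotime=ref.pseudotime,
        focal_type=ref.focal_type,
    )
    bulk_norm = pd.DataFrame(
        cp10k(bulk.to_numpy(float)), index=bulk.index, columns=bulk.columns
    )
    ref = filter_genes(ref, config.min_gene_fraction)
    signature = select_signature_genes(ref, config.n_signature_genes)
    design = build_states(ref, config.m_states, signature)
    Y = bulk_norm.loc[design.signature_genes].to_numpy(float)
    if config.gene_scaling == "mean":
        # per-gene GLS weighting: dividing a gene's row of y, X, C and Z by the
        # same factor leaves every abundance coefficient unchanged while making
        # the residual variance comparable across genes (measurement noise in
        # bulk RNA-seq scales with expression level)
        scale = design.Z.mean(axis=1)
        design.X = design.X / scale[:, None]
        design.Z = design.Z / scale[:, None]
        if design.C.size:
            design.C = design.C / scale[:, None]
        Y = Y / scale[:, None]
    weights = build_trajectory_weights(design.cell_pseudotime, bandwidth=config.bandwidth)
    workspace = NullModelWorkspace(design, weights, theta_grid=config.theta_grid())
    log.info(
        "pipeline prepared: %d signature genes, %d states, %d random-effect cells, %d samples",
        design.n_genes, design.m_states, design.k_cells, Y.shape[1],
    )
    return PipelineContext(
        design=design,
        weights=weights,
        workspace=workspace,
        Y=Y,
        samples=list(bulk.columns),
        config=config,
    )


def deconvolve_from_context(ctx: PipelineContext, Y: np.ndarray | None = None) -> DeconvolutionResult:
    """Run REML + GLS + smoothing + rescaling for every sample column of Y."""
    cfg = ctx.config
    design = ctx.design
    Y = ctx.Y if Y is None else Y
    m = design.m_states
    raw = np.empty((m, Y.shape[1]))
    se = np.empty_like(raw)
    smoothed = np.empty_like(raw)
    normalized = np.full_like(raw, np.nan)
    gammas = np.empty((design.C.shape[1], Y.shape[1]))
    vcs: dict[str, VarianceComponents] = {}
    pvals = []
    knn_q = cfg.knn_q if cfg.knn_q > 0 else None
    for j, sample in enumerate(ctx.samples):
        y = Y[:, j]
        vc = ctx.workspace.fit(y)
        r, s, g = estimate_state_abundances(y, design, vc, workspace=ctx.workspace)
        raw[:, j] = r
        se[:, j] = s
        gammas[:, j] = g
        smoothed[:, j] = smooth_abundances(
            r, design.state_pseudotime, method=cfg.smoothing_method,
            span=cfg.smoothing_span, q=knn_q,
        )
        if cfg.normalize:
            normalized[:, j] = normalize_abundances(smoothed[:, j])
        vcs[sample] = vc
        pvals.append(test_random_effect(vc))
    idx = pd.RangeIndex(m, name="state")
    return DeconvolutionResult(
        raw=pd.DataFrame(raw, index=idx, columns=ctx.samples),
        se=pd.DataFrame(se, index=idx, columns=ctx.samples),
        smoothed=pd.DataFrame(smoothed, index=idx, columns=ctx.samples),
        normalized=pd.DataFrame(normalized, index=idx, columns=ctx.samples),
        state_pseudotime=design.state_pseudotime,
        gamma_hat=pd.DataFrame(gammas, index=design.other_types, columns=ctx.samples),
        variance_components=vcs,
        random_effect_p=pd.Series(pvals, index=ctx.samples, name="random_effect_p"),
    )


def deconvolve(
    ref: ReferenceSet,
    bulk: pd.DataFrame,
    config: RunConfig | None = None,
) -> DeconvolutionResult:
    """Estimate cell-state abundances along the focal trajectory for every bulk
    sample (genes x samples DataFrame)."""
    ctx = prepare_pipeline(ref, bulk, config)
    return deconvolve_from_context(ctx)


def quartile_abundance(result: DeconvolutionResult) -> pd.DataFrame:
    """Per-sample summed normalized abundance over each trajectory quartile
    (Q1..Q4 of the state coordinate range), the per-sample covariate used in
    cell-state-dependent eQTL mapping."""
    t = np.asarray(result.state_pseudotime, dtype=float)
    span = t.max() - t.min()
    tr = (t - t.min()) / span if span > 0 else np.zeros_like(t)
    q = np.clip((tr * 4).astype(int), 0, 3)
    rows = {}
    for qi in range(4):
        rows[f"Q{qi + 1}"] = result.normalized.iloc[q == qi].sum(axis=0)
    return pd.DataFrame(rows)
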