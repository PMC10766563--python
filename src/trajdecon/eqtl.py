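"""Cell-state-dependent eQTL mapping and matched-control fold enrichment.

A variant is a cell-state-dependent eQTL (csd-eQTL) for a gene when its effect on
bulk expression depends on the abundance of cells in a stretch of the trajectory
(here: one of the four trajectory quartiles).  Per (gene, variant, quartile) the
interaction model

    y_i = x_i * alpha + s_i * beta + x_i * s_i * gamma + sum_j c_ij * delta_j + e_i

is fit by OLS, with y the rank-based inverse-normal-transformed expression, x the
0/1/2 minor-allele dosage, s the transformed quartile abundance and c covariates
(supplied factors plus top expression PCs as hidden-factor surrogates).  The
two-sided t test on gamma gives the interaction p-value; per-gene multiple testing
uses a Bonferroni correction on the tested-variant count followed by
Benjamini-Hochberg FDR across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm, rankdata
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "inverse_normal_transform",
    "map_csd_eqtl",
    "multiple_testing",
    "fold_enrichment",
    "csd_egenes",
]


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transformation with the Blom offset:
    v_i -> Phi^-1((rank_i - 3/8) / (n + 1/4)), average ranks for ties."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a vector of at least 2 values")
    if np.all(v == v[0]):
        raise ValueError("all values identical; ranks are undefined")
    ranks = rankdata(v, method="average")
    return norm.ppf((ranks - 0.375) / (len(v) + 0.25))


def _expression_pcs(expr_int: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top sample-score PCs of the (samples x genes) transformed expression."""
    if n_pcs == 0:
        return np.empty((expr_int.shape[0], 0))
    centered = expr_int - expr_int.mean(axis=0)
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    n_pcs = min(n_pcs, len(sv))
    return u[:, :n_pcs] * sv[:n_pcs]


def map_csd_eqtl(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    state_abundance: pd.DataFrame,
    gene_tss: pd.DataFrame,
    variant_pos: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    cis_window: int = 1_000_000,
    n_expression_pcs: int = 15,
) -> pd.DataFrame:
    """Map csd-eQTLs: one OLS interaction fit per (gene, cis variant, quartile).

    expression: genes x samples; genotypes: variants x samples 0/1/2 dosages;
    state_abundance: samples x quartile columns; gene_tss: index gene_id with
    columns (chrom, tss); variant_pos: index variant_id with columns (chrom, pos).
    The cis window is the closed interval [tss - cis_window, tss + cis_window];
    MAF is computed from the analyzed samples and variants below ``maf_min`` or
    monomorphic are skipped (counts logged).  Returns one record per test with the
    gene-level Bonferroni-adjusted p and BH FDR merged in.
    """
    samples = [s for s in expression.columns if s in set(genotypes.columns)]
    samples = [s for s in samples if s in set(state_abundance.index)]
    if covariates is not None:
        samples = [s for s in samples if s in set(covariates.index)]
    n = len(samples)
    if n < 10:
        raise ValueError(f"only {n} samples shared across inputs")
    expr = expression[samples]
    geno = genotypes[samples].to_numpy(float)
    abun = state_abundance.loc[samples]

    for col in abun.columns:
        if abun[col].nunique() <= 1:
            raise ValueError(
                f"state abundance {col!r} is constant across samples; the "
                "genotype-by-state interaction is unidentifiable"
            )

    expr_int = np.vstack([inverse_normal_transform(expr.loc[g].to_numpy()) for g in expr.index])
    abun_int = {c: inverse_normal_transform(abun[c].to_numpy()) for c in abun.columns}

    # covariates: intercept + supplied factors + expression PCs
    cov_blocks = [np.ones((n, 1))]
    if covariates is not None:
        cov_blocks.append(covariates.loc[samples].to_numpy(float))
    cov_blocks.append(_expression_pcs(expr_int.T, n_expression_pcs))
    Cov = np.hstack(cov_blocks)
    if np.linalg.matrix_rank(Cov) < Cov.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    # variant filters: polymorphic, MAF >= threshold in the analyzed samples
    freq = geno.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    mono = np.array([len(np.unique(row)) < 2 for row in geno])
    keep = (~mono) & (maf >= maf_min)
    n_mono, n_rare = int(mono.sum()), int(((~mono) & (maf < maf_min)).sum())
    if n_mono or n_rare:
        log.info("skipped %d monomorphic and %d low-MAF variants", n_mono, n_rare)
    variant_ids = genotypes.index.to_numpy()

    vpos = variant_pos.loc[[v for v in variant_ids if v in variant_pos.index]]
    records = []
    gene_rows = {g: i for i, g in enumerate(expr.index)}
    var_rows = {v: i for i, v in enumerate(variant_ids)}
    for gene in expr.index:
        if gene not in gene_tss.index:
            continue
        chrom, tss = gene_tss.loc[gene, "chrom"], int(gene_tss.loc[gene, "tss"])
        in_cis = vpos[
            (vpos["chrom"] == chrom)
            & (vpos["pos"] >= tss - cis_window)
            & (vpos["pos"] <= tss + cis_window)
        ]
        y = expr_int[gene_rows[gene]]
        for vid, row in in_cis.iterrows():
            vi = var_rows[vid]
            if not keep[vi]:
                continue
            x = geno[vi]
            for qcol in abun.columns:
                s = abun_int[qcol]
                A = np.hstack([x[:, None], s[:, None], (x * s)[:, None], Cov])
                coef, se, pval, ok = _ols_t(A, y, test_col=2)
                if not ok:
                    continue
                records.append(
                    {
                        "gene_id": gene,
                        "variant_id": vid,
                        "position": int(row["pos"]),
                        "quartile": qcol,
                        "alpha": coef[0],
                        "beta": coef[1],
                        "gamma": coef[2],
                        "se_gamma": se,
                        "p_interaction": pval,
                    }
                )
    result = pd.DataFrame(records)
    if result.empty:
        return result
    # per-gene adjustment on the number of tested variants, then BH across genes
    n_variants = result.groupby("gene_id")["variant_id"].nunique()
    p_lists = {g: grp["p_interaction"].to_numpy() for g, grp in result.groupby("gene_id")}
    adjusted = multiple_testing(p_lists, m_eff={g: int(n_variants[g]) for g in p_lists})
    result = result.merge(adjusted, on="gene_id", how="left")
    return result


def _ols_t(A: np.ndarray, y: np.ndarray, test_col: int) -> tuple[np.ndarray, float, float, bool]:
    """OLS fit returning (coefficients, se of tested column, two-sided p, ok)."""
    n, p = A.shape
    G = A.T @ A
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return np.empty(0), np.nan, np.nan, False
    coef = Ginv @ (A.T @ y)
    resid = y - A @ coef
    dof = n - p
    if dof <= 0:
        return coef, np.nan, np.nan, False
    sigma2 = float(resid @ resid) / dof
    var_c = sigma2 * Ginv[test_col, test_col]
    if var_c <= 0 or not np.isfinite(var_c):
        return coef, np.nan, np.nan, False
    se = float(np.sqrt(var_c))
    tval = coef[test_col] / se
    pval = float(2.0 * t_dist.sf(abs(tval), dof))
    return coef, se, pval, True


def multiple_testing(
    p_per_gene: dict[str, np.ndarray],
    m_eff: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Gene-level multiple-testing correction.

    Per gene: adjusted p = min(1, min p * M_eff) with M_eff the tested-variant
    count (a conservative, dependency-free stand-in for an effective-test
    estimator); then Benjamini-Hochberg FDR across genes on the adjusted values.
    """
    if not p_per_gene:
        raise ValueError("empty p-value input")
    genes = sorted(p_per_gene)
    adj = []
    for g in genes:
        ps = np.asarray(p_per_gene[g], dtype=float)
        if len(ps) == 0:
            raise ValueError(f"gene {g} has no tested variants")
        m = m_eff[g] if m_eff is not None else len(ps)
        adj.append(min(1.0, float(np.nanmin(ps)) * m))
    fdr = false_discovery_control(np.array(adj), method="bh")
    return pd.DataFrame({"gene_id": genes, "p_gene_adjusted": adj, "fdr": fdr})


def csd_egenes(records: pd.DataFrame, fdr_threshold: float = 0.05) -> list[str]:
    """Genes with at least one state-dependent eQTL at the given FDR."""
    if records.empty:
        return []
    hits = records.loc[records["fdr"] < fdr_threshold, "gene_id"].unique()
    return sorted(hits)


@dataclass
class EnrichmentResult:
    """Fold enrichment of a query score set over count- and MAF-matched control
    draws, with its delta-method sampling variance."""

    fold: float
    variance: float
    ci95: tuple[float, float]
    n_control_sets: int
    matched_on: dict


def fold_enrichment(
    query_scores: np.ndarray,
    pool_scores: np.ndarray,
    pool_maf: np.ndarray,
    query_maf: np.ndarray,
    n_sets: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> EnrichmentResult:
    """Fold enrichment x / y-bar of the mean query score over matched controls.

    Each of ``n_sets`` control sets is drawn from the pool without replacement,
    matching the query's size and MAF-bin distribution (equal-width bins over
    ``maf_range``).  With x the mean query score, y_i the control-set means, y-bar
    their average and var-hat(y) their variance, the delta-method sampling variance
    is  var(x/y-bar) ~= (x/y-bar)^2 [var-hat(y)/x^2 + var-hat(y)/(m y-bar^2)]
    under cov(x, y-bar) ~= 0 and var(x) ~= var-hat(y).
    """
    q = np.asarray(query_scores, dtype=float)
    pool = np.asarray(pool_scores, dtype=float)
    qm = np.asarray(query_maf, dtype=float)
    pm = np.asarray(pool_maf, dtype=float)
    if len(q) != len(qm) or len(pool) != len(pm):
        raise ValueError("scores and MAF vectors must align")
    if n_sets < 2:
        raise ValueError("need at least 2 control sets")
    edges = np.linspace(maf_range[0], maf_range[1], n_bins + 1)
    qbin = np.clip(np.digitize(qm, edges) - 1, 0, n_bins - 1)
    pbin = np.clip(np.digitize(pm, edges) - 1, 0, n_bins - 1)
    need = np.bincount(qbin, minlength=n_bins)
    pool_by_bin = [np.flatnonzero(pbin == b) for b in range(n_bins)]
    short = [b for b in range(n_bins) if need[b] > len(pool_by_bin[b])]
    if short:
        detail = ", ".join(
            f"bin [{edges[b]:.3f}, {edges[b + 1]:.3f}): need {need[b]}, have {len(pool_by_bin[b])}"
            for b in short
        )
        raise ValueError(f"MAF matching infeasible: {detail}")

    rng = np.random.default_rng(seed)
    set_means = np.empty(n_sets)
    for i in range(n_sets):
        picks = [
            rng.choice(pool_by_bin[b], size=need[b], replace=False)
            for b in range(n_bins)
            if need[b] > 0
        ]
        set_means[i] = pool[np.concatenate(picks)].mean()
    x = q.mean()
    ybar = set_means.mean()
    var_y = set_means.var(ddof=1)
    fold = x / ybar
    variance = fold**2 * (var_y / x**2 + var_y / (n_sets * ybar**2))
    half = 1.96 * np.sqrt(variance)
    return EnrichmentResult(
        fold=float(fold),
        variance=float(variance),
        ci95=(float(fold - half), float(fold + half)),
        n_control_sets=n_sets,
        matched_on={"count": int(len(q)), "maf_bins": n_bins, "maf_range": maf_range},
    )
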