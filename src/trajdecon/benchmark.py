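"""Self-contained benchmark routines on synthetic data.

Each function generates its own fixtures from a seed, runs the relevant part of
the package and returns summary statistics.  They exist so that the test suite
and reproduction scripts measure exactly the same quantities under exactly the
same study conditions.

Study conditions (chosen once, see docs/methods.md): references of 800 genes x
2400 cells (3 types, 300 planted trajectory genes, latent-factor heterogeneity
0.35); split-half source/reference protocol; bulk mixtures with multiplicative
log-normal noise sd 0.2 and 30% other-type content; deconvolution at m = 50
states with 500 signature genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .ablations import fixed_bin_estimate, random_bin_estimate
from .config import RunConfig
from .eqtl import csd_egenes, fold_enrichment, map_csd_eqtl
from .grouptest import manova_pro, permutation_group_test
from .lmm import (
    NullModelWorkspace,
    estimate_state_abundances,
    normalize_abundances,
    smooth_abundances,
)
from .pipeline import deconvolve_from_context, prepare_pipeline
from .reference import StateDesign, build_trajectory_weights
from .simulate import (
    SHAPES,
    ShapeSpec,
    evaluate_accuracy,
    generate_csd_eqtl_data,
    generate_synthetic_reference,
    split_reference,
    synthesize_bulk,
)

__all__ = [
    "deconvolution_benchmark",
    "reml_recovery_benchmark",
    "manova_type1_benchmark",
    "permutation_calibration_benchmark",
    "eqtl_benchmark",
    "enrichment_benchmark",
]


def _sub_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


def deconvolution_benchmark(
    seed: int = 0,
    n_refs: int = 3,
    samples_per_shape: int = 3,
    noise_sd: float = 0.2,
    m_states: int = 50,
) -> dict:
    """End-to-end recovery of the four abundance shapes, with the fixed-bin and
    random-bin ablations measured on the same fixtures.

    Returns per-shape and overall mean CCC for the full model and the two
    ablations, averaged over ``n_refs`` independent synthetic references.
    """
    cfg = RunConfig(m_states=m_states, n_signature_genes=500, smoothing_method="knn")
    per_shape: dict[str, list[float]] = {s: [] for s in SHAPES}
    ccc_full: list[float] = []
    ccc_fixed: list[float] = []
    ccc_random: list[float] = []
    for r in range(n_refs):
        ref, _ = generate_synthetic_reference(
            800, 2400, 3, 300, seed=_sub_seed(seed, r), factor_sd=0.35
        )
        src, ref_dec = split_reference(ref, _sub_seed(seed, 100 + r))
        pbs = []
        for shape in SHAPES:
            spec = ShapeSpec(shape, L=m_states)
            for s in range(samples_per_shape):
                pbs.append(
                    (
                        shape,
                        synthesize_bulk(
                            src, spec, noise_sd=noise_sd,
                            seed=_sub_seed(seed, 1000 + 17 * r + s), other_frac=0.3,
                        ),
                    )
                )
        bulk = pd.DataFrame(
            {f"s{i}": pb.y for i, (_, pb) in enumerate(pbs)}, index=ref.gene_ids
        )
        ctx = prepare_pipeline(ref_dec, bulk, cfg)
        res = deconvolve_from_context(ctx)
        for j, (shape, pb) in enumerate(pbs):
            ccc = evaluate_accuracy(res.normalized[f"s{j}"].to_numpy(), pb.truth)["ccc"]
            per_shape[shape].append(ccc)
            ccc_full.append(ccc)
            for est_fn, acc in (
                (fixed_bin_estimate, ccc_fixed),
                (random_bin_estimate, ccc_random),
            ):
                raw = est_fn(ctx.Y[:, j], ctx.design)
                sm = smooth_abundances(
                    raw, ctx.design.state_pseudotime, method="knn"
                )
                acc.append(
                    evaluate_accuracy(normalize_abundances(sm), pb.truth)["ccc"]
                )
    out = {f"ccc_{s}": float(np.mean(v)) for s, v in per_shape.items()}
    out["ccc_mean"] = float(np.mean([np.mean(v) for v in per_shape.values()]))
    out["ccc_fixed_bin"] = float(np.mean(ccc_fixed))
    out["ccc_random_bin"] = float(np.mean(ccc_random))
    out["n_samples"] = len(ccc_full)
    return out


def reml_recovery_benchmark(
    seed: int = 0,
    n_reps: int = 50,
    n_genes: int = 500,
    k_cells: int = 100,
    theta: float = 0.5,
    lambda2: float = 2.0,
    sigma_e2: float = 1.0,
) -> dict:
    """Mean REML estimates over replicates simulated exactly from the model
    y = C gamma + Z alpha + e with alpha ~ N(0, (D - theta W)^-1 lambda^2).

    The fixture is the identifiable regime for the dependence parameter: equally
    spaced trajectory coordinates with a decaying-chain weight graph (immediate
    neighbors ~0.5, next neighbors ~0.2) and a standardized Gaussian design.
    With near-uniform weights the restricted likelihood is almost flat in theta
    (theta and lambda^2 trade off) and no estimator can recover it.
    """
    rng = np.random.default_rng(_sub_seed(seed, 7))
    Z = rng.normal(0.0, 1.0, (n_genes, k_cells))
    C = np.abs(rng.normal(1.0, 0.5, (n_genes, 2)))
    pt = np.linspace(0.0, 1.0, k_cells)
    weights = build_trajectory_weights(pt, bandwidth=80.0)
    design = StateDesign(
        m_states=2,
        state_members=[np.arange(k_cells // 2), np.arange(k_cells // 2, k_cells)],
        state_pseudotime=np.array([0.25, 0.75]),
        X=Z[:, :2],
        C=C,
        Z=Z,
        signature_genes=np.array([f"g{i}" for i in range(n_genes)]),
        cell_pseudotime=pt,
        cell_ids=np.array([f"c{i}" for i in range(k_cells)]),
    )
    workspace = NullModelWorkspace(design, weights)
    L = np.linalg.cholesky(np.linalg.inv(weights.precision(theta)))
    ests = []
    for _ in range(n_reps):
        alpha = np.sqrt(lambda2) * (L @ rng.standard_normal(k_cells))
        gamma = rng.normal(0, 1, 2)
        y = C @ gamma + Z @ alpha + rng.normal(0, np.sqrt(sigma_e2), n_genes)
        vc = workspace.fit(y)
        ests.append([vc.theta, vc.lambda2, vc.sigma_e2])
    mean = np.asarray(ests).mean(axis=0)
    truth = np.array([theta, lambda2, sigma_e2])
    bias = (mean - truth) / truth
    return {
        "theta_mean": float(mean[0]),
        "lambda2_mean": float(mean[1]),
        "sigma_e2_mean": float(mean[2]),
        "theta_rel_bias": float(bias[0]),
        "lambda2_rel_bias": float(bias[1]),
        "sigma_e2_rel_bias": float(bias[2]),
        "n_reps": n_reps,
    }


def manova_type1_benchmark(seed: int = 0, n_reps: int = 2000) -> dict:
    """Parametric Pillai-trace test on independent Gaussian coefficient vectors:
    empirical type-I error at nominal 0.05."""
    rng = np.random.default_rng(_sub_seed(seed, 55))
    groups = np.array(["a"] * 20 + ["b"] * 20)
    rejections = 0
    for _ in range(n_reps):
        B = rng.normal(0, 1, (40, 3))
        if manova_pro(B, groups).p_parametric < 0.05:
            rejections += 1
    return {"type1_rate": rejections / n_reps, "n_reps": n_reps}


def permutation_calibration_benchmark(
    seed: int = 0,
    n_datasets: int = 10,
    redraws_per_dataset: int = 20,
    n_perm: int = 100,
) -> dict:
    """Empirical p-values of the gene-shuffling group test under the null.

    Each dataset is an independent synthetic cohort with no group effect; for
    each, the deconvolution and its permutation F distribution are computed once
    and the test is repeated under independent random group labelings (labels
    are independent of the data under the null, so conditional p-values are iid
    across redraws).  Reduced problem size: 200 genes, 240 cells, 8 states,
    60 signature genes, a coarse theta grid and 12 bulk samples per cohort.
    """
    labels = np.array(["a"] * 6 + ["b"] * 6)
    cfg = RunConfig(m_states=8, n_signature_genes=60, theta_step=0.25, theta_max=0.8)
    pvals = []
    for d in range(n_datasets):
        ref, _ = generate_synthetic_reference(200, 240, 2, 80, seed=_sub_seed(seed, 300 + d))
        src, ref_dec = split_reference(ref, _sub_seed(seed, 400 + d))
        spec = ShapeSpec("unimodal", L=10)
        pbs = [
            synthesize_bulk(src, spec, noise_sd=0.2, seed=_sub_seed(seed, 500 + 31 * d + i),
                            other_frac=0.3)
            for i in range(12)
        ]
        bulk = pd.DataFrame({f"s{i}": pb.y for i, pb in enumerate(pbs)}, index=ref.gene_ids)
        ctx = prepare_pipeline(ref_dec, bulk, cfg)
        res = permutation_group_test(
            bulk, ref_dec, labels, n_perm=n_perm, seed=_sub_seed(seed, 600 + d),
            config=cfg, ctx=ctx, keep_profiles=True,
        )
        pvals.append(res.p_empirical)
        rng = np.random.default_rng(_sub_seed(seed, 700 + d))
        for _ in range(redraws_per_dataset - 1):
            labs = rng.permutation(labels)
            f_obs = manova_pro(res.profiles_observed, labs).F
            f_perm = np.array([manova_pro(bp, labs).F for bp in res.profiles_permuted])
            pvals.append((1 + np.sum(f_perm >= f_obs)) / (1 + len(f_perm)))
    pvals = np.asarray(pvals)
    ks = kstest(pvals, "uniform")
    return {
        "ks_pvalue": float(ks.pvalue),
        "rejection_rate_005": float(np.mean(pvals < 0.05)),
        "n_tests": len(pvals),
    }


def eqtl_benchmark(seed: int = 0) -> dict:
    """Interaction-test type-I error under gamma = 0 (1000 gene-variant pairs at
    n = 500) and detection power at planted standardized gamma = 0.5, MAF 0.3,
    after per-gene Bonferroni and across-gene BH FDR at 0.05."""
    null = generate_csd_eqtl_data(
        n_samples=500, n_genes=50, n_variants_per_gene=5, gamma=0.0,
        seed=_sub_seed(seed, 21),
    )
    rec = map_csd_eqtl(
        null["expression"], null["genotypes"], null["abundance"],
        null["gene_tss"], null["variant_pos"], n_expression_pcs=5,
    )
    type1 = float(np.mean(rec["p_interaction"] < 0.05))
    n_null = len(rec)

    hits, total = 0, 0
    for r in range(3):
        data = generate_csd_eqtl_data(
            n_samples=500, n_genes=20, n_variants_per_gene=5,
            gamma=0.5, n_causal_genes=10, maf=0.3, seed=_sub_seed(seed, 33 + r),
        )
        rec = map_csd_eqtl(
            data["expression"], data["genotypes"], data["abundance"],
            data["gene_tss"], data["variant_pos"], n_expression_pcs=5,
        )
        egenes = set(csd_egenes(rec, 0.05))
        for gene, _ in data["planted"]:
            total += 1
            hits += gene in egenes
    return {
        "type1_rate": type1,
        "n_null_tests": n_null,
        "power": hits / total,
        "n_planted": total,
    }


def enrichment_benchmark(seed: int = 0, n_redraws: int = 500) -> dict:
    """Null behavior of the matched-control fold enrichment: fold for a query
    drawn from the pool itself, CI coverage of 1 over seeded repetitions, and
    the delta-method variance against the empirical variance of the fold across
    re-drawn query sets."""
    rng = np.random.default_rng(_sub_seed(seed, 77))
    pool = rng.chisquare(2, 5000)
    maf = rng.uniform(0.05, 0.5, 5000)

    covered = 0
    n_cov = 20
    folds_cov = []
    for r in range(n_cov):
        q = rng.choice(5000, 200, replace=False)
        res = fold_enrichment(pool[q], pool, maf, maf[q], n_sets=200,
                              seed=_sub_seed(seed, 80 + r))
        covered += res.ci95[0] <= 1.0 <= res.ci95[1]
        folds_cov.append(res.fold)

    folds = []
    for r in range(n_redraws):
        q = rng.choice(5000, 200, replace=False)
        res = fold_enrichment(pool[q], pool, maf, maf[q], n_sets=200,
                              seed=_sub_seed(seed, 1000 + r))
        folds.append(res.fold)
    empirical_var = float(np.var(folds, ddof=1))
    # delta variance from one representative draw
    q = rng.choice(5000, 200, replace=False)
    res = fold_enrichment(pool[q], pool, maf, maf[q], n_sets=200,
                          seed=_sub_seed(seed, 99))
    return {
        "null_fold_mean": float(np.mean(folds)),
        "ci_coverage_of_one": covered / n_cov,
        "delta_variance": float(res.variance),
        "empirical_variance": empirical_var,
        "variance_ratio": float(res.variance / empirical_var),
        "n_redraws": n_redraws,
    }
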