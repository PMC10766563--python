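"""Synthetic data: trajectory-structured single-cell references, pseudo-bulk
mixtures under four pre-designed cell-state abundance shapes, and accuracy metrics.

Pseudo-bulk samples are mixtures of single-cell profiles: cells are grouped into L
states along the trajectory, each state l receives an abundance a_l = f(t_l) from a
shape function of the state coordinate, round(n * a_l) cells are drawn with
replacement from state l, and the bulk profile is the mean over the drawn cells with
multiplicative log-normal noise mimicking platform/batch differences between
single-cell and bulk measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceSet

__all__ = [
    "ShapeSpec",
    "PseudoBulk",
    "SHAPES",
    "shape_abundance",
    "synthesize_bulk",
    "generate_synthetic_reference",
    "split_reference",
    "evaluate_accuracy",
    "mixture_size",
]

SHAPES = ("increasing", "decreasing", "unimodal", "bimodal")


@dataclass
class ShapeSpec:
    """A pre-designed cell-state abundance distribution along the trajectory.

    shape: increasing t^k / decreasing (1-t)^k / unimodal [-(t-0.5)^2 + max]^k /
    bimodal sin(3*pi*t) - min(sin(3*pi*t)).  curvature k > 0 sharpens the profile
    (the bimodal shape takes no exponent); the default k = 2 gives pronounced,
    clearly nonlinear abundance distributions.  L is the number of states.
    """

    shape: str
    curvature: float = 2.0
    L: int = 50

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.curvature <= 0:
            raise ValueError("curvature must be positive")
        if self.L < 2:
            raise ValueError("need at least 2 states")


@dataclass
class PseudoBulk:
    """One synthetic bulk sample with its ground truth."""

    y: np.ndarray
    truth: np.ndarray
    n_cells_sampled: int
    seed: int
    drawn_cells: list[np.ndarray] = field(default_factory=list)


def shape_abundance(
    spec: ShapeSpec, t: np.ndarray | None = None, normalize: bool = True
) -> np.ndarray:
    """Evaluate the shape function on the state coordinates and normalize to one.

    ``t`` defaults to state-bin midpoints (l + 0.5)/L on [0, 1]; pass the median
    trajectory ranks of real states to match a particular binning.  The unimodal
    max and bimodal min are taken over the supplied grid, so both shapes are
    non-negative by construction.  ``normalize=False`` returns the raw shape
    values.
    """
    if t is None:
        t = (np.arange(spec.L) + 0.5) / spec.L
    t = np.asarray(t, dtype=float)
    k = spec.curvature
    if spec.shape == "increasing":
        a = t**k
    elif spec.shape == "decreasing":
        a = (1.0 - t) ** k
    elif spec.shape == "unimodal":
        q = (t - 0.5) ** 2
        a = (-q + q.max()) ** k
    else:  # bimodal
        s = np.sin(3.0 * np.pi * t)
        a = s - s.min()
    if not normalize:
        return a
    total = a.sum()
    if total <= 0:
        raise ValueError("shape function vanished on the supplied grid")
    return a / total


def mixture_size(truth: np.ndarray) -> int:
    """Smallest n with n * a_l >= 1 for every non-zero a_l (so every non-empty
    state contributes at least one cell)."""
    nz = truth[truth > 0]
    if len(nz) == 0:
        raise ValueError("all state abundances are zero")
    return int(np.ceil(1.0 / nz.min() - 1e-9))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def synthesize_bulk(
    source_sc: ReferenceSet,
    spec: ShapeSpec,
    noise_sd: float = 0.2,
    seed: int = 0,
    other_frac: float = 0.0,
    zero_floor: float = 1e-4,
    truth_override: np.ndarray | None = None,
    n_scale: int = 1,
) -> PseudoBulk:
    """Mix single-cell profiles from ``source_sc`` into one pseudo-bulk sample.

    Focal cells are ranked by pseudotime into L equal-count states; the state
    coordinate t_l is the median trajectory rank rescaled to [0, 1].  round(n*a_l)
    cells are drawn with replacement per state (half-up rounding), the bulk profile
    is the mean over drawn cells, and exp(N(0, noise_sd^2)) noise multiplies each
    gene.  ``other_frac`` optionally mixes in that fraction of cells drawn uniformly
    from the non-focal types (the truth refers to the focal trajectory only).

    Shape values below ``zero_floor`` are treated as empty states before the
    mixture size n = min{n a_l >= 1 | a_l != 0} is computed: the continuous shape
    functions touch zero without reaching it exactly, and a state that cannot
    contribute a whole cell at any practical mixture size would otherwise drive n
    to astronomical values.

    ``truth_override`` replaces the shape-derived abundances with an arbitrary
    distribution over the L states (it is renormalized); ``n_scale`` multiplies
    the mixture size for convergence studies.
    """
    if not 0.0 <= other_frac < 1.0:
        raise ValueError("other_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = source_sc.focal_order()
    k = len(order)
    if spec.L > k:
        raise ValueError(f"L={spec.L} states but only {k} focal cells")
    states = np.array_split(np.arange(k), spec.L)
    ranks = np.arange(k, dtype=float) / max(k - 1, 1)
    t = np.array([np.median(ranks[s]) for s in states])
    if truth_override is not None:
        truth = np.asarray(truth_override, dtype=float)
        if len(truth) != spec.L or np.any(truth < 0) or truth.sum() <= 0:
            raise ValueError("truth_override must be a non-negative length-L vector")
    else:
        truth = shape_abundance(spec, t)
    truth = np.where(truth < zero_floor, 0.0, truth)
    truth = truth / truth.sum()

    n = mixture_size(truth) * int(n_scale)
    counts = _round_half_up(n * truth)
    drawn: list[np.ndarray] = []
    for l, cnt in enumerate(counts):
        if cnt == 0:
            drawn.append(np.empty(0, dtype=int))
            continue
        if len(states[l]) == 0:
            raise ValueError(f"state {l} must contribute {cnt} cells but is empty")
        drawn.append(rng.choice(order[states[l]], size=cnt, replace=True))
    all_focal = np.concatenate([d for d in drawn if len(d)])

    total = source_sc.expr[:, all_focal].sum(axis=1)
    n_drawn = len(all_focal)
    if other_frac > 0:
        others = np.flatnonzero(~source_sc.focal_mask)
        if len(others) == 0:
            raise ValueError("other_frac > 0 but reference has no non-focal cells")
        n_other = int(round(n_drawn * other_frac / (1.0 - other_frac)))
        if n_other > 0:
            pick = rng.choice(others, size=n_other, replace=True)
            total = total + source_sc.expr[:, pick].sum(axis=1)
            n_drawn += n_other
    y = total / n_drawn
    if noise_sd > 0:
        y = y * np.exp(rng.normal(0.0, noise_sd, size=len(y)))
    return PseudoBulk(y=y, truth=truth, n_cells_sampled=n, seed=seed, drawn_cells=drawn)


def generate_synthetic_reference(
    n_genes: int,
    n_cells: int,
    n_types: int = 3,
    n_signature: int = 100,
    seed: int = 0,
    focal_frac: float = 0.5,
    nb_size: float = 2.0,
    n_factors: int = 2,
    factor_sd: float = 0.35,
) -> tuple[ReferenceSet, np.ndarray]:
    """Seed-deterministic synthetic reference with a planted trajectory.

    Focal cells receive latent pseudotime ~ U(0, 1).  The first block of
    ``n_signature`` genes gets smooth focal mean-curves over pseudotime (a mixture
    of monotone logistic and Gaussian-peak profiles); the remaining genes are flat
    in the focal type.  Each non-focal type perturbs every gene's mean by an
    independent log-normal factor, giving it a distinct profile.  On top of the
    trajectory, every focal cell carries ``n_factors`` latent factor scores with
    log-normal gene loadings of scale ``factor_sd`` — the correlated
    cell-to-cell heterogeneity (cell cycle, stress, microenvironment) that real
    single-cell data shows beyond pseudotime, and the reason individual cells
    rather than bin means are worth modeling.  Counts are negative-binomial with
    dispersion ``nb_size`` (moderate UMI-like overdispersion).  Returns
    (reference, planted signature gene ids).
    """
    if n_signature > n_genes:
        raise ValueError("n_signature cannot exceed n_genes")
    if n_types < 1 or n_cells < n_types:
        raise ValueError("impossible dimensions")
    rng = np.random.default_rng(seed)

    n_focal = max(int(round(n_cells * focal_frac)), 1) if n_types > 1 else n_cells
    n_rest = n_cells - n_focal
    type_names = ["focal"] + [f"type{j}" for j in range(1, n_types)]
    cell_type = np.array(
        ["focal"] * n_focal
        + [type_names[1 + (i % (n_types - 1))] for i in range(n_rest)]
    )
    pseudotime = np.full(n_cells, np.nan)
    pseudotime[:n_focal] = rng.uniform(0.0, 1.0, size=n_focal)

    base = rng.lognormal(mean=0.7, sigma=0.8, size=n_genes)
    t = pseudotime[:n_focal]
    mean_focal = np.tile(base[:, None], (1, n_focal))
    for g in range(n_signature):
        kind = rng.integers(0, 3)
        if kind == 0:  # increasing logistic
            c, a = rng.uniform(0.2, 0.8), rng.uniform(6.0, 12.0)
            prof = 1.0 / (1.0 + np.exp(-a * (t - c)))
        elif kind == 1:  # decreasing logistic
            c, a = rng.uniform(0.2, 0.8), rng.uniform(6.0, 12.0)
            prof = 1.0 / (1.0 + np.exp(a * (t - c)))
        else:  # Gaussian peak
            c, w = rng.uniform(0.1, 0.9), rng.uniform(0.08, 0.25)
            prof = np.exp(-((t - c) ** 2) / (2.0 * w**2))
        amp = rng.uniform(2.0, 5.0)
        mean_focal[g] = base[g] * (0.25 + amp * prof)

    if n_factors > 0 and factor_sd > 0:
        loadings = rng.normal(0.0, factor_sd, size=(n_genes, n_factors))
        scores = rng.normal(0.0, 1.0, size=(n_factors, n_focal))
        lf = loadings @ scores
        mean_focal = mean_focal * np.exp(lf - lf.var(axis=1, keepdims=True) / 2.0)

    expr = np.empty((n_genes, n_cells))
    p_focal = nb_size / (nb_size + mean_focal)
    expr[:, :n_focal] = rng.negative_binomial(nb_size, p_focal)
    for j, name in enumerate(type_names[1:], start=1):
        cols = np.flatnonzero(cell_type == name)
        if len(cols) == 0:
            continue
        factor = rng.lognormal(mean=0.0, sigma=0.7, size=n_genes)
        mu = np.tile((base * factor)[:, None], (1, len(cols)))
        expr[:, cols] = rng.negative_binomial(nb_size, nb_size / (nb_size + mu))

    gene_ids = np.array([f"gene{g:05d}" for g in range(n_genes)])
    cell_ids = np.array([f"cell{c:05d}" for c in range(n_cells)])
    ref = ReferenceSet(
        expr=expr,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=cell_type,
        pseudotime=pseudotime,
        focal_type="focal",
    )
    return ref, gene_ids[:n_signature]


def split_reference(
    ref: ReferenceSet, seed: int = 0
) -> tuple[ReferenceSet, ReferenceSet]:
    """Randomly split cells into two halves: one as pseudo-bulk simulation source,
    the other as the deconvolution reference, so the evaluated estimates never see
    the cells that built the bulk mixtures."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ref.n_cells)
    half = ref.n_cells // 2

    def _sub(cols: np.ndarray) -> ReferenceSet:
        cols = np.sort(cols)
        return ReferenceSet(
            expr=ref.expr[:, cols],
            gene_ids=ref.gene_ids,
            cell_ids=ref.cell_ids[cols],
            cell_type=ref.cell_type[cols],
            pseudotime=ref.pseudotime[cols],
            focal_type=ref.focal_type,
        )

    return _sub(perm[:half]), _sub(perm[half:])


def generate_csd_eqtl_data(
    n_samples: int = 500,
    n_genes: int = 20,
    n_variants_per_gene: int = 5,
    gamma: float = 0.0,
    n_causal_genes: int = 0,
    maf: float | None = None,
    seed: int = 0,
):
    """Synthetic cohort for state-dependent eQTL mapping.

    Per-sample quartile abundances are correlated fractions (log-normal,
    normalized across the four quartiles).  Dosages are Binomial(2, MAF) with
    MAF ~ U(0.1, 0.5) unless fixed.  Expression has additive genotype and
    abundance effects everywhere; the first ``n_causal_genes`` genes additionally
    carry a genotype-by-Q1-abundance interaction of standardized size ``gamma``
    on their first variant.  Genes are spaced 3 Mb apart on one chromosome so
    cis windows do not overlap.  Returns a dict of the mapping inputs plus the
    planted (gene, variant) pairs.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    samples = [f"sample{i:04d}" for i in range(n_samples)]
    genes = [f"gene{g:03d}" for g in range(n_genes)]

    raw = rng.lognormal(0.0, 0.6, size=(n_samples, 4))
    abun = raw / raw.sum(axis=1, keepdims=True)
    abundance = pd.DataFrame(abun, index=samples, columns=["Q1", "Q2", "Q3", "Q4"])
    s_std = (abun[:, 0] - abun[:, 0].mean()) / abun[:, 0].std()

    variant_rows, geno_rows, var_ids = [], [], []
    expr_rows = []
    planted = []
    for g, gene in enumerate(genes):
        tss = 2_000_000 + g * 3_000_000
        y = rng.normal(0.0, 1.0, n_samples)
        for v in range(n_variants_per_gene):
            f = maf if maf is not None else rng.uniform(0.1, 0.5)
            x = rng.binomial(2, f, n_samples).astype(float)
            vid = f"var{g:03d}_{v}"
            var_ids.append(vid)
            geno_rows.append(x)
            variant_rows.append(
                {"variant_id": vid, "chrom": "1", "pos": tss + (v - 2) * 200_000}
            )
            xs = x.std()
            x_std = (x - x.mean()) / xs if xs > 0 else x * 0.0
            y = y + 0.2 * x_std
            if v == 0:
                y = y + 0.3 * s_std
                if g < n_causal_genes and gamma != 0.0:
                    inter = x_std * s_std
                    istd = inter.std()
                    if istd > 0:
                        y = y + gamma * inter / istd
                    planted.append((gene, vid))
        expr_rows.append(y)

    return {
        "expression": pd.DataFrame(np.array(expr_rows), index=genes, columns=samples),
        "genotypes": pd.DataFrame(np.array(geno_rows), index=var_ids, columns=samples),
        "abundance": abundance,
        "gene_tss": pd.DataFrame(
            {"chrom": "1", "tss": [2_000_000 + g * 3_000_000 for g in range(n_genes)]},
            index=pd.Index(genes, name="gene_id"),
        ),
        "variant_pos": pd.DataFrame(variant_rows).set_index("variant_id"),
        "planted": planted,
    }


def evaluate_accuracy(estimate: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Concordance correlation coefficient, Pearson's R and RMSD.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2) with population
    (ddof=0) moments; it penalizes both decorrelation and location/scale shift.
    CCC and R are NaN when both inputs have zero variance.
    """
    x = np.asarray(estimate, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("estimate and truth must be equal-length vectors (n >= 2)")
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        return {"ccc": np.nan, "r": np.nan, "rmsd": rmsd}
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    ccc = 2.0 * cov / (vx + vy + (x.mean() - y.mean()) ** 2)
    r = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else np.nan
    return {"ccc": float(ccc), "r": float(r), "rmsd": rmsd}
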