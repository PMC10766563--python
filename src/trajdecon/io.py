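"""Readers and writers for the tool's plain-text interchange formats.

All tables are tab-separated UTF-8 with a header row (MTX triplet components and
their id files follow the sparse-matrix convention instead).  Floats are written
with a fixed format so reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .config import RunConfig
from .pipeline import DeconvolutionResult
from .reference import ReferenceSet

__all__ = [
    "read_reference",
    "read_bulk",
    "read_groups",
    "read_dosages",
    "read_vcf_dosages",
    "read_variant_table",
    "read_gene_table",
    "write_abundance_bundle",
    "write_fixture_bundle",
]

FLOAT_FMT = "%.10g"
METADATA_COLUMNS = ("cell_id", "cell_type", "pseudotime")


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(path)
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"cell metadata is missing required column {col!r}")
    return meta


def read_reference(
    expr_path: str | Path,
    metadata_path: str | Path,
    focal_type: str,
) -> ReferenceSet:
    """Load a reference from a dense TSV (genes x cells, first column gene id) or
    an MTX triplet directory (matrix.mtx + features.tsv + barcodes.tsv), together
    with a cell metadata TSV (cell_id, cell_type, pseudotime)."""
    expr_path = Path(expr_path)
    if expr_path.is_dir():
        mat = spio.mmread(expr_path / "matrix.mtx")
        expr = np.asarray(mat.todense(), dtype=float) if sparse.issparse(mat) else np.asarray(mat, float)
        gene_ids = np.loadtxt(expr_path / "features.tsv", dtype=str, ndmin=1)
        if gene_ids.ndim > 1:
            gene_ids = gene_ids[:, 0]
        cell_ids = np.loadtxt(expr_path / "barcodes.tsv", dtype=str, ndmin=1)
    else:
        table = _read_tsv(expr_path, index_col=0)
        expr = table.to_numpy(float)
        gene_ids = table.index.to_numpy(str)
        cell_ids = table.columns.to_numpy(str)
    meta = read_cell_metadata(metadata_path).set_index("cell_id")
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cells missing from metadata (e.g. {missing[:3]})")
    meta = meta.loc[cell_ids]
    return ReferenceSet(
        expr=expr,
        gene_ids=gene_ids,
        cell_ids=np.asarray(cell_ids),
        cell_type=meta["cell_type"].to_numpy(str),
        pseudotime=meta["pseudotime"].to_numpy(float),
        focal_type=focal_type,
    )


def read_bulk(path: str | Path) -> pd.DataFrame:
    bulk = _read_tsv(path, index_col=0)
    if bulk.index.duplicated().any():
        raise ValueError("bulk expression has duplicated gene ids")
    return bulk


def read_groups(path: str | Path) -> pd.Series:
    table = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in table.columns:
            raise ValueError(f"group table is missing required column {col!r}")
    return table.set_index("sample_id")["group"]


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Variant x sample 0/1/2 dosage TSV (first column variant id)."""
    return _read_tsv(path, index_col=0)


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Minor-allele dosages from an (uncompressed or gzipped) VCF: DS when
    present, otherwise the GT alternate-allele count."""
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0 HOM_REF,1 HET,2 UNKNOWN,3 HOM_ALT
            ds = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        ids.append(vid)
        rows.append(ds)
    return pd.DataFrame(np.array(rows), index=ids, columns=samples)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    for col in ("variant_id", "chrom", "pos"):
        if col not in table.columns:
            raise ValueError(f"variant table is missing required column {col!r}")
    return table.set_index("variant_id")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    for col in ("gene_id", "chrom", "tss"):
        if col not in table.columns:
            raise ValueError(f"gene table is missing required column {col!r}")
    return table.set_index("gene_id")


def _write_states_table(df: pd.DataFrame, state_pt: np.ndarray, path: Path) -> None:
    out = df.copy()
    out.insert(0, "state_pseudotime", state_pt)
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_abundance_bundle(
    result: DeconvolutionResult,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Write raw/smoothed/normalized abundance TSVs plus a run log recording the
    parameters and per-sample variance-component estimates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_states_table(result.raw, result.state_pseudotime, out / "abundance_raw.tsv")
    _write_states_table(result.se, result.state_pseudotime, out / "abundance_se.tsv")
    _write_states_table(result.smoothed, result.state_pseudotime, out / "abundance_smoothed.tsv")
    _write_states_table(result.normalized, result.state_pseudotime, out / "abundance_normalized.tsv")
    if len(result.gamma_hat):
        result.gamma_hat.to_csv(out / "covariate_effects.tsv", sep="\t", float_format=FLOAT_FMT)

    from . import __version__

    lines = [f"trajdecon version {__version__}", ""]
    if config is not None:
        lines.append("[config]")
        from dataclasses import fields

        for f in fields(config):
            lines.append(f"{f.name} = {getattr(config, f.name)}")
        lines.append("")
    lines.append("[per-sample variance components]")
    lines.append("sample\ttheta\tlambda2\tsigma_e2\tloglik_reml\trandom_effect_p")
    for sample, vc in result.variance_components.items():
        p = result.random_effect_p[sample] if result.random_effect_p is not None else np.nan
        lines.append(
            f"{sample}\t{vc.theta:.6g}\t{vc.lambda2:.6g}\t{vc.sigma_e2:.6g}"
            f"\t{vc.loglik_reml:.6f}\t{p:.6g}"
        )
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def write_fixture_bundle(
    ref: ReferenceSet,
    bulk: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Write a complete synthetic fixture: reference MTX triplet + metadata TSV,
    bulk TSV, ground-truth TSV and the generating config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.csr_matrix(ref.expr))
    np.savetxt(out / "features.tsv", ref.gene_ids, fmt="%s")
    np.savetxt(out / "barcodes.tsv", ref.cell_ids, fmt="%s")
    meta = pd.DataFrame(
        {
            "cell_id": ref.cell_ids,
            "cell_type": ref.cell_type,
            "pseudotime": ref.pseudotime,
        }
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    bulk.to_csv(out / "bulk.tsv", sep="\t", float_format=FLOAT_FMT)
    truth.to_csv(out / "truth.tsv", sep="\t", float_format=FLOAT_FMT)
    if config is not None:
        config.to_file(out / "config.txt")
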