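"""Shared fixtures: small synthetic references and prepared pipeline designs.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from trajdecon import (
    ReferenceSet,
    build_states,
    build_trajectory_weights,
    cp10k,
    filter_genes,
    generate_synthetic_reference,
)
from trajdecon.lmm import NullModelWorkspace


@pytest.fixture(scope="session")
def small_reference() -> ReferenceSet:
    ref, _ = generate_synthetic_reference(
        n_genes=300, n_cells=240, n_types=3, n_signature=100, seed=11
    )
    return ref


@pytest.fixture(scope="session")
def tiny_design():
    """50-gene / ~30-cell prepared design with gene-scaled rows, as the GLS and
    REML exact-math checks use."""
    ref, _ = generate_synthetic_reference(
        n_genes=60, n_cells=30, n_types=2, n_signature=30, seed=5, focal_frac=0.95
    )
    refn = filter_genes(
        ReferenceSet(
            cp10k(ref.expr), ref.gene_ids, ref.cell_ids, ref.cell_type,
            ref.pseudotime, ref.focal_type,
        ),
        0.1,
    )
    sig = refn.gene_ids[:50]
    design = build_states(refn, 5, sig)
    scale = design.Z.mean(axis=1)
    design.X = design.X / scale[:, None]
    design.Z = design.Z / scale[:, None]
    if design.C.size:
        design.C = design.C / scale[:, None]
    weights = build_trajectory_weights(design.cell_pseudotime)
    workspace = NullModelWorkspace(design, weights)
    return design, weights, workspace


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
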