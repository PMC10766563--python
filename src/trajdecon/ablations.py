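"""Ablated estimators used to quantify what fitting individual cells buys.

Both keep the per-state GLS estimation identical to the full model and only
change what stands behind the covariance: ``fixed_bin_estimate`` drops the random
term entirely and fits all bins jointly as fixed effects by OLS;
``random_bin_estimate`` replaces the individual-cell CAR random effects with iid
random effects of the m bin-mean profiles.  Neither models within-state
heterogeneity, which is exactly what the cell-level random term captures.
"""

from __future__ import annotations

import numpy as np

from .lmm import NullModelWorkspace, estimate_state_abundances
from .reference import StateDesign, TrajectoryWeights

__all__ = ["fixed_bin_estimate", "random_bin_estimate"]


def fixed_bin_estimate(y: np.ndarray, design: StateDesign) -> np.ndarray:
    """Joint OLS of y on all state-mean profiles plus the other-type covariates;
    returns the m per-state coefficients."""
    A = np.column_stack([design.X, design.C])
    coef, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
    return coef[: design.m_states]


def _bin_design(design: StateDesign) -> tuple[StateDesign, TrajectoryWeights]:
    m = design.m_states
    bin_design = StateDesign(
        m_states=m,
        state_members=[np.array([i]) for i in range(m)],
        state_pseudotime=design.state_pseudotime,
        X=design.X,
        C=design.C,
        Z=design.X,  # bins, not cells, stand behind the random term
        signature_genes=design.signature_genes,
        cell_pseudotime=design.state_pseudotime,
        cell_ids=np.array([f"bin{i}" for i in range(m)]),
        other_types=design.other_types,
    )
    # iid bins: unit precision, no trajectory coupling
    weights = TrajectoryWeights(
        W=np.zeros((m, m)), dist=np.zeros((m, m)), d=np.ones(m)
    )
    return bin_design, weights


def random_bin_estimate(y: np.ndarray, design: StateDesign) -> np.ndarray:
    """Same pipeline as the full model but with iid bin-mean random effects:
    null REML of y ~ N(C gamma, lambda^2 X X' + I sigma_e^2), then the per-state
    GLS with the focal bin moved from the random term to the fixed profile."""
    bin_design, weights = _bin_design(design)
    ws = NullModelWorkspace(bin_design, weights, theta_grid=np.array([0.0]))
    vc = ws.fit(np.asarray(y, float))
    raw, _, _ = estimate_state_abundances(y, bin_design, vc, workspace=ws)
    return raw
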