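"""Reference preparation: state binning, gene filtering, signature selection and
the trajectory weight graph."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajdecon import (
    ReferenceSet,
    build_states,
    build_trajectory_weights,
    cp10k,
    filter_genes,
    generate_synthetic_reference,
    select_signature_genes,
)


def _toy_reference(n_genes=20, seed=0):
    """3 cell types, focal 'epi' with known pseudotime."""
    rng = np.random.default_rng(seed)
    types = np.array(["epi"] * 10 + ["fib"] * 5 + ["imm"] * 5)
    pt = np.full(20, np.nan)
    pt[:10] = np.linspace(0, 1, 10)
    expr = rng.uniform(0.1, 5.0, size=(n_genes, 20))
    return ReferenceSet(
        expr=expr,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)]),
        cell_ids=np.array([f"c{i:02d}" for i in range(20)]),
        cell_type=types,
        pseudotime=pt,
        focal_type="epi",
    )


class TestBuildStates:
    def test_one_cell_per_state_makes_X_equal_Z(self):
        ref = _toy_reference()
        design = build_states(ref, 10, ref.gene_ids[:8])
        np.testing.assert_allclose(design.X, design.Z)

    def test_equal_count_binning_ordered_by_pseudotime(self):
        ref = _toy_reference()
        design = build_states(ref, 5, ref.gene_ids)
        assert [len(m) for m in design.state_members] == [2] * 5
        assert np.all(np.diff(design.cell_pseudotime) >= 0)
        assert np.all(np.diff(design.state_pseudotime) > 0)

    def test_covariate_columns_are_per_type_means(self):
        ref = _toy_reference()
        design = build_states(ref, 5, ref.gene_ids)
        assert design.other_types == ["fib", "imm"]
        np.testing.assert_allclose(design.C[:, 0], ref.expr[:, 10:15].mean(axis=1))
        np.testing.assert_allclose(design.C[:, 1], ref.expr[:, 15:20].mean(axis=1))

    def test_X_columns_are_member_means_to_machine_precision(self):
        ref = _toy_reference()
        design = build_states(ref, 4, ref.gene_ids)
        for i, members in enumerate(design.state_members):
            np.testing.assert_allclose(
                design.X[:, i], design.Z[:, members].mean(axis=1), rtol=0, atol=1e-14
            )

    @pytest.mark.parametrize("m", [0, 1])
    def test_too_few_states_rejected(self, m):
        ref = _toy_reference()
        with pytest.raises(ValueError):
            build_states(ref, m, ref.gene_ids)

    def test_more_states_than_cells_rejected(self):
        ref = _toy_reference()
        with pytest.raises(ValueError):
            build_states(ref, 11, ref.gene_ids)

    def test_missing_signature_gene_rejected(self):
        ref = _toy_reference()
        with pytest.raises(ValueError, match="absent"):
            build_states(ref, 5, np.array(["nope"]))


class TestFilterGenes:
    def test_fraction_boundary_is_inclusive(self):
        # 100 focal cells: expressed in 9 -> removed at 0.10, in 10 -> kept
        expr = np.zeros((2, 100))
        expr[0, :9] = 1.0
        expr[1, :10] = 1.0
        ref = ReferenceSet(
            expr=expr,
            gene_ids=np.array(["a", "b"]),
            cell_ids=np.array([f"c{i}" for i in range(100)]),
            cell_type=np.array(["t"] * 100),
            pseudotime=np.linspace(0, 1, 100),
            focal_type="t",
        )
        out = filter_genes(ref, 0.10)
        assert list(out.gene_ids) == ["b"]

    def test_never_expressed_removed_always_expressed_kept(self, small_reference):
        ref = small_reference
        out = filter_genes(ref, 0.5)
        focal = out.expr[:, out.focal_mask]
        assert np.all((focal > 0).mean(axis=1) >= 0.5)

    def test_idempotent(self, small_reference):
        once = filter_genes(small_reference, 0.10)
        twice = filter_genes(once, 0.10)
        assert list(once.gene_ids) == list(twice.gene_ids)

    def test_all_removed_is_explicit_error(self):
        expr = np.zeros((2, 10))
        ref = ReferenceSet(
            expr=expr,
            gene_ids=np.array(["a", "b"]),
            cell_ids=np.array([f"c{i}" for i in range(10)]),
            cell_type=np.array(["t"] * 10),
            pseudotime=np.linspace(0, 1, 10),
            focal_type="t",
        )
        with pytest.raises(ValueError, match="empty"):
            filter_genes(ref, 0.10)

    def test_invalid_fraction_rejected(self, small_reference):
        with pytest.raises(ValueError):
            filter_genes(small_reference, 1.0)


class TestTrajectoryWeights:
    def test_zero_distance_gives_unit_weight(self):
        w = build_trajectory_weights(np.array([0.3, 0.3]), bandwidth=1.0)
        assert w.W[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(w.D), [1.0, 1.0])

    def test_far_cells_effectively_independent(self):
        w = build_trajectory_weights(np.array([0.0, 1.0]), bandwidth=10.0)
        assert w.W[0, 1] == pytest.approx(np.exp(-100.0))

    def test_three_point_grid_matches_direct_evaluation(self):
        w = build_trajectory_weights(np.array([0.0, 0.5, 1.0]), bandwidth=1.0)
        assert w.W[0, 1] == pytest.approx(np.exp(-0.25))
        assert w.W[0, 2] == pytest.approx(np.exp(-1.0))
        assert w.d[0] == pytest.approx(np.exp(-0.25) + np.exp(-1.0))

    def test_symmetric_zero_diagonal(self, rng):
        w = build_trajectory_weights(rng.uniform(0, 1, 15))
        np.testing.assert_allclose(w.W, w.W.T)
        np.testing.assert_allclose(np.diag(w.W), 0.0)
        assert np.all(w.d > 0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pt = rng.uniform(0, 1, 8)
        perm = rng.permutation(8)
        w = build_trajectory_weights(pt, bandwidth=2.0)
        wp = build_trajectory_weights(pt[perm], bandwidth=2.0)
        np.testing.assert_allclose(wp.W, w.W[np.ix_(perm, perm)], atol=1e-12)

    def test_identical_coordinates_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            w = build_trajectory_weights(np.array([0.5, 0.5, 0.5]))
        off = w.W[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_auto_bandwidth_targets_median_weight_half(self, rng):
        w = build_trajectory_weights(rng.uniform(0, 1, 40))
        med = np.median(w.W[np.triu_indices(40, k=1)])
        assert med == pytest.approx(0.5, abs=1e-6)

    def test_precision_positive_definite_on_theta_domain(self, rng):
        w = build_trajectory_weights(rng.uniform(0, 1, 12))
        for theta in (0.0, 0.5, 0.99):
            eig = np.linalg.eigvalsh(w.precision(theta))
            assert eig.min() > 0
        with pytest.raises(ValueError):
            w.precision(1.0)


class TestSignatureSelection:
    def test_constant_gene_never_selected(self):
        ref = _toy_reference(n_genes=10)
        ref.expr[3, :] = 2.0  # flat everywhere
        selected = select_signature_genes(ref, 5)
        assert "g3" not in selected

    def test_noiseless_monotone_gene_outranks_noise(self, rng):
        ref = _toy_reference(n_genes=30, seed=4)
        order = ref.focal_order()
        ref.expr[0, order] = np.linspace(0.5, 4.0, len(order))  # perfect trend
        selected = select_signature_genes(ref, 5)
        assert "g0" in selected

    def test_planted_signal_recall(self):
        ref, planted = generate_synthetic_reference(500, 400, 2, 50, seed=21)
        ref = filter_genes(ref, 0.10)
        selected = set(select_signature_genes(ref, 50))
        recall = len(selected & set(planted)) / len(planted)
        assert recall >= 0.9

    def test_invariant_to_cell_order(self, small_reference):
        ref = small_reference
        rng = np.random.default_rng(3)
        perm = rng.permutation(ref.n_cells)
        shuffled = ReferenceSet(
            expr=ref.expr[:, perm],
            gene_ids=ref.gene_ids,
            cell_ids=ref.cell_ids[perm],
            cell_type=ref.cell_type[perm],
            pseudotime=ref.pseudotime[perm],
            focal_type=ref.focal_type,
        )
        a = select_signature_genes(filter_genes(ref, 0.1), 40)
        b = select_signature_genes(filter_genes(shuffled, 0.1), 40)
        assert list(a) == list(b)

    def test_requesting_too_many_genes_rejected(self, small_reference):
        with pytest.raises(ValueError):
            select_signature_genes(small_reference, small_reference.n_genes + 1)


def test_cp10k_columns_sum_to_ten_thousand(rng):
    m = rng.uniform(0, 5, size=(30, 8))
    out = cp10k(m)
    np.testing.assert_allclose(out.sum(axis=0), 1e4)
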