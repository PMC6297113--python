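"""Generator correctness: the planted model, overlap, permutation, determinism."""

import numpy as np
import pytest

import mfbiclust as mb
from conftest import brute_force_model


class TestConstantColumnModel:
    def test_noiseless_matches_brute_force_evaluator(self):
        params = mb.SimParams(
            m=30, n=40, k=4, beta_values=(1.0, 2.5, 4.0), noise_sd=0.0,
            overlap_fraction=0.3, seed=7,
        )
        ds = mb.generate_constant_column(params)
        np.testing.assert_allclose(ds.matrix.values, brute_force_model(ds))

    def test_single_bicluster_noiseless_is_exact(self):
        params = mb.SimParams(m=6, n=6, k=1, beta_values=(2.0,), noise_sd=0.0, seed=0)
        ds = mb.generate_constant_column(params)
        b = ds.truth[0]
        mask = np.zeros((6, 6), dtype=bool)
        mask[np.ix_(sorted(b.rows), sorted(b.cols))] = True
        assert np.all(ds.matrix.values[mask] == 2.0)
        assert np.all(ds.matrix.values[~mask] == 0.0)

    def test_overlap_cells_sum_both_effects(self):
        params = mb.SimParams(
            m=12, n=12, k=2, beta_values=(1.0, 3.0), noise_sd=0.0,
            overlap_fraction=0.5, seed=3,
        )
        ds = mb.generate_constant_column(params)
        b0, b1 = ds.truth[0], ds.truth[1]
        shared_rows = b0.rows & b1.rows
        shared_cols = b0.cols & b1.cols
        assert shared_rows and shared_cols
        for i in shared_rows:
            for j in shared_cols:
                assert ds.matrix.values[i, j] == pytest.approx(
                    ds.betas[0][j] + ds.betas[1][j]
                )

    def test_mu_and_noise_moments(self):
        params = mb.SimParams(
            m=80, n=120, k=3, mu=2.0, noise_sd=0.1, seed=11
        )
        ds = mb.generate_constant_column(params)
        resid = ds.matrix.values - brute_force_model(ds)
        member = np.zeros((80, 120), dtype=bool)
        for b in ds.truth:
            member[np.ix_(sorted(b.rows), sorted(b.cols))] = True
        assert ds.matrix.values[~member].mean() == pytest.approx(2.0, abs=0.02)
        assert resid.std() == pytest.approx(0.1, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 0, "n": 5, "k": 1},
            {"m": 5, "n": 5, "k": 6},
            {"m": 5, "n": 5, "k": 2, "noise_sd": -1.0},
            {"m": 5, "n": 5, "k": 2, "overlap_fraction": 1.0},
            {"m": 5, "n": 5, "k": 2, "beta_values": (0.0,)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mb.SimParams(**kwargs)


class TestPaperDataset1:
    def test_shape_truth_and_overlap_structure(self):
        ds = mb.generate_benchmark_dataset1(seed=4)
        assert ds.matrix.shape == (50, 250)
        assert ds.truth.k == 3
        b0, b1, b2 = ds.truth
        assert b0.rows & b1.rows and b0.cols & b1.cols
        assert not (b2.rows & b0.rows) and not (b2.rows & b1.rows)
        assert not (b2.cols & b0.cols) and not (b2.cols & b1.cols)
        assert ds.matrix.values.min() >= 0.0

    def test_same_seed_bit_identical(self):
        a = mb.generate_benchmark_dataset1(seed=9)
        b = mb.generate_benchmark_dataset1(seed=9)
        assert np.array_equal(a.matrix.values, b.matrix.values)
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_noiseless_unpermutes_to_contiguous_blocks(self):
        ds = mb.generate_benchmark_dataset1(seed=2, noise_sd=0.0)
        restored = mb.unpermute_dataset(ds)
        for b in restored.truth:
            rows, cols = sorted(b.rows), sorted(b.cols)
            assert rows == list(range(rows[0], rows[-1] + 1))
            assert cols == list(range(cols[0], cols[-1] + 1))
        # each bicluster's columns are constant over its member rows
        for b, beta in zip(restored.truth, restored.betas):
            sub = restored.matrix.values[np.ix_(sorted(b.rows), sorted(b.cols))]
            expected = np.array([beta[j] for j in sorted(b.cols)])
            overlap_rows = [
                r for other in restored.truth if other is not b for r in b.rows & other.rows
            ]
            pure = [r for r in sorted(b.rows) if r not in overlap_rows]
            idx = [sorted(b.rows).index(r) for r in pure]
            np.testing.assert_allclose(sub[idx], np.tile(expected, (len(idx), 1)))


class TestGeneExpressionStyle:
    def test_noiseless_block_bookkeeping(self):
        ds = mb.generate_gene_expression_style(3, seed=1, noise_sd=0.0)
        assert ds.matrix.shape == (500, 200)
        assert (ds.matrix.values != 0).sum() == 3 * 50 * 50
        for b in ds.truth:
            assert b.shape == (50, 50)

    def test_column_budget_boundary(self):
        ds = mb.generate_gene_expression_style(4, seed=0, noise_sd=0.0)
        assert ds.truth.k == 4
        with pytest.raises(ValueError):
            mb.generate_gene_expression_style(5, seed=0)

    def test_noisy_truth_matches_noiseless_signal(self):
        noisy = mb.generate_gene_expression_style(3, seed=8, noise_sd=0.25)
        clean = mb.generate_gene_expression_style(3, seed=8, noise_sd=0.0)
        # the planted support is identical; thresholding the clean signal at
        # half the smallest block value recovers the truth exactly
        cut = min(min(b.values()) for b in clean.betas) / 2
        support = clean.matrix.values > cut
        for b in noisy.truth:
            expected = np.zeros_like(support)
            expected[np.ix_(sorted(b.rows), sorted(b.cols))] = True
            assert np.array_equal(support & expected, expected)


class TestPermutation:
    def test_value_multiset_invariant(self):
        ds = mb.generate_block_example(noise_sd=0.2, seed=5)
        perm = mb.permute_dataset(ds, seed=77)
        assert np.allclose(
            np.sort(ds.matrix.values.ravel()), np.sort(perm.matrix.values.ravel())
        )

    def test_permute_then_unpermute_restores_everything(self):
        ds = mb.generate_block_example(noise_sd=0.1, seed=6)
        restored = mb.unpermute_dataset(mb.permute_dataset(ds, seed=13))
        np.testing.assert_array_equal(restored.matrix.values, ds.matrix.values)
        assert restored.truth.to_dict() == ds.truth.to_dict()
        assert restored.matrix.row_labels == ds.matrix.row_labels

    def test_truth_remap_tracks_cell_values(self):
        ds = mb.generate_block_example(noise_sd=0.0, seed=6)
        perm = mb.permute_dataset(ds, seed=21)
        for b_old, b_new in zip(ds.truth, perm.truth):
            old = ds.matrix.values[np.ix_(sorted(b_old.rows), sorted(b_old.cols))]
            new = perm.matrix.values[np.ix_(sorted(b_new.rows), sorted(b_new.cols))]
            assert np.allclose(np.sort(old.ravel()), np.sort(new.ravel()))


def test_save_dataset_roundtrip(tmp_path):
    ds = mb.generate_block_example(noise_sd=0.1, seed=2)
    paths = mb.save_dataset(ds, tmp_path / "demo")
    loaded = mb.read_matrix(paths["matrix"])
    np.testing.assert_allclose(loaded.values, ds.matrix.values)
    assert loaded.row_labels == ds.matrix.row_labels
    truth = mb.BiclusterSet.load(paths["truth"])
    assert truth.to_dict() == ds.truth.to_dict()
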