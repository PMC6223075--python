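"""Missingness filtering, kNN imputation, batch correction, protein rollup,
QC metrics and PCA."""

import numpy as np
import pandas as pd
import pytest

from plexcal import (
    correct_batch,
    filter_missingness,
    groups_from_design,
    impute_knn,
    pca,
    qc_metrics,
    rollup_peptide_to_protein,
)


def _groups(samples, group, batch="b1", channel=None):
    return pd.DataFrame(
        {
            "group": group,
            "batch": batch,
            "channel": channel if channel is not None else samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )


@pytest.fixture
def two_group_matrix():
    """12 samples, two groups of 6."""
    samples = [f"s{i}" for i in range(12)]
    groups = _groups(samples, ["A"] * 6 + ["B"] * 6)
    rng = np.random.default_rng(0)
    matrix = pd.DataFrame(
        rng.normal(size=(8, 12)), index=[f"f{i}" for i in range(8)], columns=samples
    )
    return matrix, groups


class TestMissingnessFilter:
    def test_boundary_two_of_six_kept(self, two_group_matrix):
        """2/6 missing (33%) in every group is at most 35%: kept."""
        matrix, groups = two_group_matrix
        matrix.iloc[0, [0, 1, 6, 7]] = np.nan
        kept, log = filter_missingness(matrix, groups)
        assert "f0" in kept.index and log.empty

    def test_boundary_three_of_six_removed(self, two_group_matrix):
        """3/6 missing (50%) in one group exceeds 35%: removed."""
        matrix, groups = two_group_matrix
        matrix.iloc[0, [0, 1, 2]] = np.nan
        kept, log = filter_missingness(matrix, groups)
        assert "f0" not in kept.index
        assert log.iloc[0]["feature"] == "f0"
        assert log.iloc[0]["offending_group"] == "A"
        assert log.iloc[0]["missing_fraction"] == pytest.approx(0.5)

    def test_complete_matrix_unchanged(self, two_group_matrix):
        matrix, groups = two_group_matrix
        kept, log = filter_missingness(matrix, groups)
        pd.testing.assert_frame_equal(kept, matrix)
        assert log.empty

    def test_gate_is_per_group(self, two_group_matrix):
        """35% overall missingness spread evenly does not trigger the
        per-group rule, but the same count concentrated in one group does."""
        matrix, groups = two_group_matrix
        matrix.iloc[1, [0, 6]] = np.nan  # 1/6 per group
        kept, _ = filter_missingness(matrix, groups)
        assert "f1" in kept.index

    def test_unassigned_sample_errors(self, two_group_matrix):
        matrix, groups = two_group_matrix
        with pytest.raises(ValueError):
            filter_missingness(matrix, groups.iloc[:-1])


class TestKnnImputation:
    def test_hand_computed_toy_block(self):
        """f2 and f3 are f1's nearest neighbours (distance 0 on the shared
        columns); the imputed cell is mean(2, 4) = 3."""
        samples = ["s1", "s2", "s3"]
        groups = _groups(samples, ["G"] * 3)
        matrix = pd.DataFrame(
            [[1.0, 1.0, np.nan], [1.0, 1.0, 2.0], [1.0, 1.0, 4.0], [9.0, 9.0, 9.0]],
            index=["f1", "f2", "f3", "f4"],
            columns=samples,
        )
        out = impute_knn(matrix, groups, k=2)
        assert out.loc["f1", "s3"] == pytest.approx(3.0)
        # observed cells untouched
        assert (out.drop(index="f1") == matrix.drop(index="f1")).all().all()

    def test_exact_duplicate_recovered(self):
        """A zero-distance duplicate dominates: the masked cell is recovered
        exactly (k=1)."""
        samples = ["s1", "s2", "s3", "s4"]
        groups = _groups(samples, ["G"] * 4)
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 4))
        matrix = pd.DataFrame(
            np.vstack([base, base[2]]),
            index=[f"f{i}" for i in range(5)] + ["dup"],
            columns=samples,
        )
        truth = matrix.loc["dup", "s2"]
        matrix.loc["dup", "s2"] = np.nan
        out = impute_knn(matrix, groups, k=1)
        assert out.loc["dup", "s2"] == pytest.approx(truth)

    def test_complete_matrix_unchanged(self, two_group_matrix):
        matrix, groups = two_group_matrix
        pd.testing.assert_frame_equal(impute_knn(matrix, groups), matrix)

    def test_imputation_is_within_group(self):
        """Neighbours from the other experimental group cannot donate; with
        no eligible within-group neighbour the feature's within-group
        observed mean is used."""
        samples = ["a1", "a2", "b1", "b2"]
        groups = _groups(samples, ["A", "A", "B", "B"])
        matrix = pd.DataFrame(
            [[1.0, np.nan, 5.0, 5.0],
             [np.nan, 2.0, 5.0, 5.0]],
            index=["f1", "f2"],
            columns=samples,
        )
        out = impute_knn(matrix, groups, k=2)
        # f1 at a2: candidate f2 shares no observed column in group A ->
        # fallback to f1's within-group observed mean, not group B's 5.0
        assert out.loc["f1", "a2"] == pytest.approx(1.0)
        assert out.loc["f2", "a1"] == pytest.approx(2.0)

    def test_filter_impute_filter_fixed_point(self, small_experiment):
        from plexcal import quantify_plexes

        matrix, _ = quantify_plexes(
            small_experiment.psm_tables, small_experiment.design
        )
        groups = groups_from_design(small_experiment.design)
        filtered, _ = filter_missingness(matrix, groups)
        imputed = impute_knn(filtered, groups)
        assert not imputed.isna().any().any()
        refiltered, log = filter_missingness(imputed, groups)
        assert log.empty
        pd.testing.assert_frame_equal(refiltered, imputed)

    def test_matches_sklearn_on_unambiguous_block(self):
        """Cross-check against sklearn's KNNImputer on a block where
        neighbour ranking is unambiguous (distinct distances, all donors
        observed at the missing column)."""
        from sklearn.impute import KNNImputer

        samples = [f"s{i}" for i in range(5)]
        groups = _groups(samples, ["G"] * 5)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 5))
        X[3, 2] = np.nan
        matrix = pd.DataFrame(X, index=[f"f{i}" for i in range(10)], columns=samples)
        ours = impute_knn(matrix, groups, k=2)
        # sklearn imputes rows from rows: features are rows here already
        skl = KNNImputer(n_neighbors=2).fit_transform(X)
        assert ours.loc["f3", "s2"] == pytest.approx(skl[3, 2])


class TestBatchCorrection:
    def _balanced(self, noisy: bool = False):
        """Two batches, two groups, fully crossed and balanced. The base
        matrix carries feature means and a group effect only, so its
        least-squares fit puts nothing on the batch/channel columns."""
        samples = [f"s{i}" for i in range(8)]
        groups = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B"] * 2,
                "batch": ["b1"] * 4 + ["b2"] * 4,
                "channel": ["c1", "c2", "c3", "c4"] * 2,
            },
            index=pd.Index(samples, name="sample_id"),
        )
        rng = np.random.default_rng(2)
        mu = rng.normal(size=(20, 1))
        delta = rng.normal(size=(20, 1))
        is_b = (groups["group"] == "B").to_numpy(float)
        base = pd.DataFrame(
            mu + delta * is_b, index=[f"f{i}" for i in range(20)], columns=samples
        )
        if noisy:
            base += rng.normal(0, 0.3, size=base.shape)
        return base, groups

    @pytest.mark.parametrize("offset", [1.0, -2.0, 2.0])
    def test_pure_offset_removed_exactly(self, offset):
        """Per-batch offsets up to +/-2 log2 units vanish on a balanced
        design, restoring the pre-offset matrix to 1e-9."""
        base, groups = self._balanced()
        shifted = base.copy()
        shifted.loc[:, groups.index[groups["batch"] == "b2"]] += offset
        corrected = correct_batch(shifted, groups)
        np.testing.assert_allclose(corrected.to_numpy(), base.to_numpy(), atol=1e-9)

    def test_offset_removal_invariance_with_noise(self):
        """With residual noise present the correction is the same linear map,
        so corrected(base + offset) equals corrected(base) exactly."""
        base, groups = self._balanced(noisy=True)
        shifted = base.copy()
        shifted.loc[:, groups.index[groups["batch"] == "b2"]] += 1.7
        np.testing.assert_allclose(
            correct_batch(shifted, groups).to_numpy(),
            correct_batch(base, groups).to_numpy(),
            atol=1e-9,
        )

    def test_group_effect_preserved_on_balanced_design(self):
        base, groups = self._balanced(noisy=True)
        shifted = base.copy()
        bcols = groups.index[groups["group"] == "B"]
        acols = groups.index[groups["group"] == "A"]
        shifted.loc[:, bcols] += 1.5
        shifted.loc[:, groups.index[groups["batch"] == "b2"]] += 0.8
        corrected = correct_batch(shifted, groups)
        corrected_base = correct_batch(base, groups)
        diff = corrected[bcols].mean(axis=1) - corrected[acols].mean(axis=1)
        base_diff = corrected_base[bcols].mean(axis=1) - corrected_base[acols].mean(axis=1)
        np.testing.assert_allclose(diff, base_diff + 1.5, atol=1e-9)

    def test_single_batch_single_channel_unchanged(self):
        samples = ["s0", "s1", "s2", "s3"]
        groups = _groups(samples, ["A", "A", "B", "B"], batch="b1", channel=["c"] * 4)
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(5, 4)), columns=samples)
        pd.testing.assert_frame_equal(correct_batch(m, groups), m)

    def test_incomplete_matrix_rejected(self):
        base, groups = self._balanced()
        base.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            correct_batch(base, groups)


class TestProteinRollup:
    def _matrix(self, values, genes, phospho=None, unique=None):
        n = len(values)
        matrix = pd.DataFrame(
            {"s1": values}, index=pd.Index([f"p{i}" for i in range(n)], name="peptide_sequence")
        )
        anno = pd.DataFrame(
            {
                "gene": genes,
                "is_phospho": phospho if phospho is not None else [False] * n,
                "is_unique_gene_match": unique if unique is not None else [True] * n,
            },
            index=matrix.index,
        )
        return matrix, anno

    def test_trimmed_mean_hand_example(self):
        """(1,2,3,4,10) at trim 0.2: one value cut per tail, mean(2,3,4)=3."""
        matrix, anno = self._matrix([1.0, 2.0, 3.0, 4.0, 10.0], ["G"] * 5)
        out = rollup_peptide_to_protein(matrix, anno, trim=0.2)
        assert out.loc["G", "s1"] == pytest.approx(3.0)

    def test_small_n_is_plain_mean(self):
        matrix, anno = self._matrix([1.0, 2.0, 3.0, 10.0], ["G"] * 4)
        out = rollup_peptide_to_protein(matrix, anno, trim=0.2)
        assert out.loc["G", "s1"] == pytest.approx(4.0)  # floor(0.2*4)=0 trimmed

    def test_phospho_and_shared_peptides_excluded(self):
        matrix, anno = self._matrix(
            [1.0, 2.0, 100.0, 200.0],
            ["G", "G", "G", "G"],
            phospho=[False, False, True, False],
            unique=[True, True, True, False],
        )
        out = rollup_peptide_to_protein(matrix, anno, trim=0.2)
        assert out.loc["G", "s1"] == pytest.approx(1.5)

    def test_gene_with_only_phospho_peptides_omitted(self):
        matrix, anno = self._matrix([1.0, 2.0], ["G", "H"], phospho=[True, False])
        out = rollup_peptide_to_protein(matrix, anno, trim=0.2)
        assert "G" not in out.index and "H" in out.index

    def test_single_eligible_peptide_reproduces_row(self):
        matrix, anno = self._matrix([0.42, 1.0], ["G", "H"])
        out = rollup_peptide_to_protein(matrix, anno, trim=0.2)
        assert out.loc["G", "s1"] == pytest.approx(0.42)


class TestQc:
    def test_identical_samples_unflagged(self):
        m = pd.DataFrame(np.tile(np.arange(10.0), (4, 1)).T, columns=list("abcd"))
        rep = qc_metrics(m)
        assert rep.outliers == []

    def test_iqr_linear_interpolation_convention(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0],
                          "c": [1.0, 2.0, 3.0, 4.0]})
        rep = qc_metrics(m)
        assert rep.table.loc["a", "iqr"] == pytest.approx(1.5)

    def test_shifted_sample_flagged(self, rng):
        # 24 samples: a single extreme sample can exceed the 3-SD rule
        # (the max attainable z for one outlier is (n-1)/sqrt(n))
        vals = rng.normal(0, 0.1, size=(50, 24))
        m = pd.DataFrame(vals, columns=[f"s{i}" for i in range(24)])
        m["s23"] += 10.0  # shift far beyond 3 SD of the sample medians
        rep = qc_metrics(m)
        assert rep.table.loc["s23", "median_outlier"]
        assert rep.outliers == ["s23"]

    def test_fewer_than_three_samples_has_no_flags(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [100.0, 200.0]})
        rep = qc_metrics(m)
        assert rep.outliers == []


class TestPca:
    def test_variance_fractions_valid(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 10)))
        res = pca(m)
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_rank_one_data(self, rng):
        latent = rng.normal(size=10)
        loadings = rng.normal(size=15)
        m = pd.DataFrame(np.outer(loadings, latent))
        res = pca(m)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_two_orthogonal_effects_split_four_to_one(self, rng):
        """Two orthogonal latent axes with variance ratio 4:1 give
        variance-explained fractions near 0.8/0.2."""
        n, p = 200, 40
        z1 = rng.normal(0, 2.0, n)
        z2 = rng.normal(0, 1.0, n)
        w1 = rng.normal(size=p)
        w1 /= np.linalg.norm(w1)
        w2 = rng.normal(size=p)
        w2 -= w2 @ w1 * w1
        w2 /= np.linalg.norm(w2)
        X = np.outer(z1, w1) + np.outer(z2, w2)
        res = pca(pd.DataFrame(X.T))
        assert res.variance_explained[0] == pytest.approx(0.8, abs=0.05)
        assert res.variance_explained[1] == pytest.approx(0.2, abs=0.05)

    def test_sign_convention(self, rng):
        m = pd.DataFrame(rng.normal(size=(12, 8)))
        res = pca(m)
        for c in res.loadings.columns:
            col = res.loadings[c]
            assert col.iloc[int(np.argmax(col.abs()))] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame({"a": [1.0, 2.0]}))
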