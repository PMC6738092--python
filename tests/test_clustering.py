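"""Hierarchical subtype clustering: standardisation, cuts, labelling, dendrograms."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from lvisig import ClusteringParams, GeneSignature, assign_subtypes
from lvisig.clustering import (cluster_samples, label_subtypes, linkage_to_newick,
                               restrict_to_signature, signature_scores,
                               standardize_rows)
from lvisig.errors import CoverageError, DomainError

from conftest import make_matrix


def two_blob_matrix(n_genes=20, n_per=15, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    left = rng.normal(0, 1, size=(n_genes, n_per))
    right = rng.normal(0, 1, size=(n_genes, n_per)) + sep
    values = np.hstack([left, right])
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"L{i}" for i in range(n_per)] + [f"R{i}" for i in range(n_per)]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestStandardize:
    def test_unit_row_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = standardize_rows(df)
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_constant_row_dropped(self, caplog):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["c", "v"],
                          columns=list("abc"))
        with caplog.at_level("WARNING", logger="lvisig.clustering"):
            z = standardize_rows(df)
        assert list(z.index) == ["v"]

    def test_idempotent_to_tolerance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(5, 8)))
        once = standardize_rows(df)
        twice = standardize_rows(once)
        assert np.allclose(once, twice, atol=1e-12)


class TestClusterSamples:
    def test_separable_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        df = two_blob_matrix()
        asg = cluster_samples(df, ClusteringParams(distance="euclidean"))
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, asg.labels.to_numpy()) == 1.0

    def test_partition_invariant_to_sample_order(self):
        df = two_blob_matrix(seed=2)
        perm = np.random.default_rng(0).permutation(df.shape[1])
        asg1 = cluster_samples(df)
        asg2 = cluster_samples(df.iloc[:, perm])
        part1 = {frozenset(asg1.labels[asg1.labels == c].index) for c in (1, 2)}
        part2 = {frozenset(asg2.labels[asg2.labels == c].index) for c in (1, 2)}
        assert part1 == part2

    def test_dendrogram_shape_and_monotone_heights(self):
        df = two_blob_matrix(n_per=10, seed=3)
        asg = cluster_samples(df)
        assert asg.sample_linkage.shape == (df.shape[1] - 1, 4)
        heights = asg.sample_linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()  # average linkage is monotone

    def test_cut_at_two_removes_last_merge(self):
        df = two_blob_matrix(n_per=8, seed=4)
        asg = cluster_samples(df)
        by_cut = fcluster(asg.sample_linkage, t=2, criterion="maxclust")
        # the two subtrees joined by the final merge are exactly the two clusters
        assert len(set(by_cut)) == 2
        assert set(asg.labels) == {1, 2}

    def test_too_few_samples_rejected(self):
        df = two_blob_matrix(n_per=1)
        with pytest.raises(DomainError):
            cluster_samples(df.iloc[:, :1])


class TestLabelRule:
    def make_assignment(self, labels):
        s = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])
        from lvisig.clustering import SubtypeAssignment
        return SubtypeAssignment(labels=s, scores=pd.Series(np.nan, index=s.index),
                                 sample_linkage=np.zeros((len(labels) - 1, 4)))

    def test_higher_score_cluster_becomes_subtype_two(self):
        asg = self.make_assignment([1, 1, 2, 2])
        scores = pd.Series([-0.5, -0.5, 0.7, 0.7], index=asg.labels.index)
        out = label_subtypes(asg, scores)
        assert list(out.labels) == [1, 1, 2, 2]
        out2 = label_subtypes(asg, -scores)   # swap: cluster 1 now scores higher
        assert list(out2.labels) == [2, 2, 1, 1]

    def test_tie_labels_smaller_cluster_adverse(self):
        asg = self.make_assignment([1, 1, 1, 2])
        scores = pd.Series([0.0, 0.0, 0.0, 0.0], index=asg.labels.index)
        out = label_subtypes(asg, scores)
        assert list(out.labels) == [1, 1, 1, 2]  # the singleton is subtype 2


class TestSignatureRestriction:
    def test_coverage_below_half_raises(self):
        m = make_matrix(np.ones((2, 3)), ["g1", "g2"], ["a", "b", "c"])
        sig = GeneSignature(up=["g1", "x1", "x2"], down=["x3", "x4"])
        with pytest.raises(CoverageError):
            restrict_to_signature(m, sig)

    def test_partial_coverage_keeps_present_genes(self):
        m = make_matrix(np.ones((3, 3)), ["g1", "g2", "g3"], ["a", "b", "c"])
        sig = GeneSignature(up=["g1", "g2"], down=["g3", "x1"])
        sub = restrict_to_signature(m, sig)
        assert list(sub.index) == ["g1", "g2", "g3"]


class TestEndToEndSubtyping:
    def test_validation_cohort_recovers_latent_subtype(self, small_study):
        from sklearn.metrics import adjusted_rand_score

        study = small_study
        sig = GeneSignature(up=study.up_genes, down=study.down_genes)
        v = study["validation"]
        asg = assign_subtypes(v.expression, sig)
        ari = adjusted_rand_score(v.truth.subtype.to_numpy(), asg.labels.to_numpy())
        assert ari >= 0.8
        # the adverse label coincides with the latent high-hazard subtype
        agree = (asg.labels == v.truth.subtype).mean()
        assert agree >= 0.9

    def test_lvi_more_prevalent_in_subtype_two(self, small_study):
        study = small_study
        sig = GeneSignature(up=study.up_genes, down=study.down_genes)
        v = study["validation"]
        asg = assign_subtypes(v.expression, sig)
        lvi = v.clinical.data["lvi_status"] == "positive"
        prev2 = lvi[asg.labels == 2].mean()
        prev1 = lvi[asg.labels == 1].mean()
        assert prev2 > prev1

    def test_scores_separate_subtypes(self, small_study):
        study = small_study
        sig = GeneSignature(up=study.up_genes, down=study.down_genes)
        v = study["validation"]
        values = restrict_to_signature(v.expression, sig)
        scores = signature_scores(standardize_rows(values), sig)
        truth = v.truth.subtype
        assert scores[truth == 2].mean() > scores[truth == 1].mean()


class TestNewick:
    def test_roundtrip_leaf_names_and_terminator(self):
        df = two_blob_matrix(n_genes=5, n_per=3, seed=5)
        asg = cluster_samples(df, cluster_genes=False)
        text = linkage_to_newick(asg.sample_linkage, list(df.columns))
        assert text.endswith(";")
        assert text.count(",") == df.shape[1] - 1
        for leaf in df.columns:
            assert leaf in text
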