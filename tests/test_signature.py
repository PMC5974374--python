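import numpy as np
import pandas as pd
import pytest

from e2fsig import (
    GeneSet,
    SignatureDefinition,
    bundled_signature,
    classify,
    cluster_samples,
    normalize_sum100,
    ratio_median,
    supervised_cluster,
)
from e2fsig.exceptions import ClassificationError, GMTFormatError, ParameterError
from e2fsig.io import ExpressionMatrix
from e2fsig.signature import LABEL_HIGH, LABEL_LOW, LABEL_TIE

from conftest import random_matrix

TCGA_MISSING = ["LOC100505633", "DLEU7-AS1", "RHBDL2"]


class TestSignatureDefinition:
    def test_bundled_is_11_up_13_down(self):
        sig = bundled_signature()
        assert len(sig.up_genes) == 11
        assert len(sig.down_genes) == 13
        assert len(sig) == 24
        assert "BIRC5" in sig.up_genes and "AURKA" in sig.up_genes
        assert "TXNIP" in sig.down_genes
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_gmt_round_trip(self, tmp_path):
        sig = bundled_signature()
        sig.to_gmt(tmp_path / "s.gmt")
        back = SignatureDefinition.from_gmt(tmp_path / "s.gmt")
        assert back.up_genes == sig.up_genes
        assert back.down_genes == sig.down_genes

    def test_overlap_rejected(self):
        with pytest.raises(GMTFormatError, match="overlap"):
            SignatureDefinition("x", ("a", "b"), ("b", "c"))

    def test_empty_side_rejected(self):
        with pytest.raises(GMTFormatError):
            SignatureDefinition("x", (), ("a",))


class TestNormalizeSum100:
    def test_forced_arithmetic(self):
        df = pd.DataFrame([[1.0, 1.0, 2.0]], index=["g"], columns=list("abc"))
        norm, excluded = normalize_sum100(ExpressionMatrix(df))
        np.testing.assert_allclose(norm.loc["g"], [25, 25, 50])
        assert excluded == []

    def test_row_already_100_unchanged(self):
        df = pd.DataFrame([[20.0, 30.0, 50.0]], index=["g"], columns=list("abc"))
        norm, _ = normalize_sum100(ExpressionMatrix(df))
        np.testing.assert_allclose(norm.loc["g"], [20, 30, 50])

    def test_rows_sum_to_100(self, rng):
        m = random_matrix(rng, 15, 7)
        norm, _ = normalize_sum100(m)
        np.testing.assert_allclose(norm.sum(axis=1), 100.0, rtol=1e-9)

    def test_per_gene_scaling_cancels(self, rng):
        m = random_matrix(rng, 10, 5)
        scaled = m.values.copy()
        scaled.loc["G3"] *= 17.5
        n1, _ = normalize_sum100(m)
        n2, _ = normalize_sum100(ExpressionMatrix(scaled))
        pd.testing.assert_frame_equal(n1, n2)

    def test_log2_input_hard_error(self, rng):
        m = random_matrix(rng, 5, 3, scale="log2")
        with pytest.raises(ParameterError, match="linear"):
            normalize_sum100(m)


class TestRatioMedian:
    def test_two_by_two_toy(self):
        # normalized up=(40,60), down=(20,80): ratios {2.0,0.5,3.0,0.75}
        norm = pd.DataFrame({"s": [40.0, 60.0, 20.0, 80.0]}, index=["u1", "u2", "d1", "d2"])
        sig = SignatureDefinition("toy", ("u1", "u2"), ("d1", "d2"))
        med, n_used, n_drop = ratio_median(norm, sig, "s")
        assert med == pytest.approx(1.375)
        assert (n_used, n_drop) == (4, 0)

    def test_full_signature_gives_143_ratios(self, averaged_matrix):
        sig = bundled_signature()
        genes = list(sig.up_genes) + list(sig.down_genes)
        norm, _ = normalize_sum100(averaged_matrix, genes=genes)
        _, n_used, _ = ratio_median(norm, sig, averaged_matrix.sample_ids[0])
        assert n_used == 11 * 13 == 143

    def test_identical_samples_all_ratios_one(self):
        # every gene constant across samples → normalized values equal → ratio 1
        df = pd.DataFrame(
            np.outer([3.0, 7.0, 2.0, 9.0], np.ones(4)),
            index=["u1", "u2", "d1", "d2"],
            columns=list("wxyz"),
        )
        sig = SignatureDefinition("toy", ("u1", "u2"), ("d1", "d2"))
        norm, _ = normalize_sum100(ExpressionMatrix(df))
        for s in "wxyz":
            med, _, _ = ratio_median(norm, sig, s)
            assert med == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        # independent oracle: enumerate every up/down pair explicitly
        for trial in range(30):
            n_up, n_down = rng.integers(1, 6), rng.integers(1, 6)
            up = [f"u{i}" for i in range(n_up)]
            down = [f"d{i}" for i in range(n_down)]
            m = random_matrix(rng, n_up + n_down, 4)
            m.values.index = up + down
            sig = SignatureDefinition("t", tuple(up), tuple(down))
            norm, _ = normalize_sum100(m)
            s = m.sample_ids[rng.integers(0, 4)]
            expected = float(
                np.median([norm.loc[u, s] / norm.loc[d, s] for u in up for d in down])
            )
            med, n_used, _ = ratio_median(norm, sig, s)
            assert med == pytest.approx(expected, rel=1e-12)
            assert n_used == n_up * n_down


class TestClassify:
    def test_recovers_latent_labels(self, default_cohort, averaged_matrix):
        res = classify(averaged_matrix, reference_labels=default_cohort.truth.sample_labels)
        pred = res.scores["label"]
        ref = default_cohort.truth.sample_labels.reindex(pred.index)
        assert (pred == ref).mean() >= 0.9
        assert res.n_missing == 0
        assert (res.scores["n_ratios"] == 143).all()

    def test_missing_marker_mechanism(self, averaged_matrix):
        # platform lacking exactly the 3 TCGA-missing markers
        reduced = ExpressionMatrix(
            averaged_matrix.values.drop(index=TCGA_MISSING), scale="linear"
        )
        res = classify(reduced)
        assert sorted(res.missing_down) == sorted(TCGA_MISSING)
        assert res.missing_up == []
        assert res.n_missing == 3
        assert (res.scores["n_ratios"] == 11 * 10).all()

    def test_confusion_counts_false_positives(self, default_cohort, averaged_matrix):
        truth = default_cohort.truth.sample_labels.copy()
        # flip two truly-low samples to "high" reference → 2 false negatives;
        # flipping reference lows that are predicted high creates false positives
        lows = truth.index[truth == LABEL_LOW][:3]
        flipped = truth.copy()
        flipped[lows] = LABEL_HIGH
        res = classify(averaged_matrix, reference_labels=flipped)
        # classifier still calls those samples low → false negatives = 3
        assert res.false_negatives == 3
        assert res.false_positives == 0
        assert res.confusion.values.sum() == 55

    def test_tie_is_indeterminate(self):
        # up and down rows identical → every ratio 1 → median exactly 1
        df = pd.DataFrame(
            [[5.0, 10.0], [5.0, 10.0]], index=["u", "d"], columns=["s1", "s2"]
        )
        sig = SignatureDefinition("t", ("u",), ("d",))
        res = classify(ExpressionMatrix(df), sig)
        assert (res.scores["label"] == LABEL_TIE).all()

    def test_all_up_missing_is_error(self, rng):
        m = random_matrix(rng, 4, 3)  # genes G0..G3
        sig = SignatureDefinition("t", ("absent1", "absent2"), ("G0",))
        with pytest.raises(ClassificationError, match="missing"):
            classify(m, sig)

    def test_sample_permutation_equivariance(self, rng):
        m = random_matrix(rng, 8, 6)
        sig = SignatureDefinition("t", ("G0", "G1", "G2"), ("G3", "G4"))
        res = classify(m, sig)
        permuted = ExpressionMatrix(m.values.iloc[:, ::-1], "linear")
        res_p = classify(permuted, sig)
        pd.testing.assert_frame_equal(
            res.scores.sort_index(), res_p.scores.sort_index()
        )

    def test_cohort_dependence_documented(self, rng):
        # adding a sample changes the row sums, hence other samples' scores
        m = random_matrix(rng, 6, 4)
        sig = SignatureDefinition("t", ("G0", "G1"), ("G2", "G3"))
        base = classify(m, sig).scores["median_ratio"]
        extra = m.values.copy()
        extra["new"] = m.values.mean(axis=1) * rng.uniform(0.2, 5.0, size=6)
        grown = classify(ExpressionMatrix(extra), sig).scores["median_ratio"]
        shared = base.index
        assert not np.allclose(base[shared], grown[shared])


class TestScaleInvariance:
    def test_single_gene_rescaling_preserves_scores(self, rng):
        sig = SignatureDefinition("t", ("G0", "G1", "G2"), ("G3", "G4", "G5"))
        for trial in range(20):
            m = random_matrix(rng, 6, 5)
            base = classify(m, sig).scores
            scaled = m.values.copy()
            gene = f"G{rng.integers(0, 6)}"
            scaled.loc[gene] *= float(rng.uniform(0.01, 100))
            after = classify(ExpressionMatrix(scaled), sig).scores
            np.testing.assert_allclose(
                base["median_ratio"], after["median_ratio"], rtol=1e-9
            )
            assert (base["label"] == after["label"]).all()


class TestSupervisedCluster:
    def test_matches_latent_subgroups(self, default_cohort, averaged_matrix):
        report = supervised_cluster(
            averaged_matrix.to_log2(), default_cohort.gene_set, k=2
        )
        truth = default_cohort.truth.sample_labels.reindex(report.labels.index)
        assert (report.labels == truth).mean() >= 0.9

    def test_high_cluster_has_higher_gene_set_expression(self, default_cohort, averaged_matrix):
        work = averaged_matrix.to_log2()
        report = supervised_cluster(work, default_cohort.gene_set, k=2)
        sub = work.subset_genes(default_cohort.gene_set.members)
        means = sub.values.mean(axis=0)
        hi = report.labels.index[report.labels == LABEL_HIGH]
        lo = report.labels.index[report.labels == LABEL_LOW]
        assert means[hi].mean() > means[lo].mean()

    def test_disjoint_gene_set_rejected(self, rng):
        m = random_matrix(rng, 6, 5)
        gs = GeneSet("other", "d", ["x1", "x2", "x3"])
        with pytest.raises(ParameterError, match="fewer than 2"):
            supervised_cluster(m, gs)

    def test_equals_clustering_pre_subset_matrix(self, default_cohort, averaged_matrix):
        work = averaged_matrix.to_log2()
        gs = default_cohort.gene_set
        with np.errstate(all="ignore"):
            report = supervised_cluster(work, gs, k=2)
        direct = cluster_samples(work.subset_genes(gs.members), k=2)
        pd.testing.assert_series_equal(report.assignment, direct.assignment)

    def test_absent_members_warn(self, default_cohort, averaged_matrix):
        gs = GeneSet("aug", "d", default_cohort.gene_set.members + ["NOT_A_GENE"])
        with pytest.warns(UserWarning, match="absent"):
            supervised_cluster(averaged_matrix.to_log2(), gs, k=2)
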