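import numpy as np
import pandas as pd
import pytest

from ogmap.counting import SampleCounts
from ogmap.integration import (
    concordance_cluster,
    der_deg_correlation,
    filter_present,
    promoter_signal,
    zscore_rows,
)

GENOTYPES = ["WT", "MUTYH", "OGG1", "DKO"]


def make_samples(counts_by_sample, assay, idx):
    out = []
    for sid, (genotype, clone, bio, vec) in counts_by_sample.items():
        out.append(SampleCounts(sid, genotype, clone, bio, assay, np.asarray(vec), idx))
    return out


class TestPromoterSignal:
    def test_identical_samples_collapse_is_identity(self):
        idx = pd.Index(["g1", "g2"], name="gene")
        ogs = make_samples(
            {
                "A_c1_r1_OG": ("WT", 1, 1, [10, 6]),
                "A_c2_r1_OG": ("WT", 2, 1, [10, 6]),
            },
            "OG",
            idx,
        )
        inputs = make_samples(
            {
                "A_c1_r1_in": ("WT", 1, 1, [4, 2]),
                "A_c2_r1_in": ("WT", 2, 1, [4, 2]),
            },
            "input",
            idx,
        )
        ses = {"WT_c1_r1": 1.0, "WT_c2_r1": 1.0}
        lib = {s.sample_id: 1.0 for s in ogs}
        out = promoter_signal(ogs, inputs, ses, lib, ["WT"])
        np.testing.assert_allclose(out["WT"].to_numpy(), [6.0, 4.0])

    def test_og_equal_scaled_input_gives_zero_matrix(self):
        idx = pd.Index(["g1"], name="gene")
        ogs = make_samples({"A_c1_r1_OG": ("WT", 1, 1, [8])}, "OG", idx)
        inputs = make_samples({"A_c1_r1_in": ("WT", 1, 1, [4])}, "input", idx)
        out = promoter_signal(ogs, inputs, {"WT_c1_r1": 2.0}, {"A_c1_r1_OG": 1.0}, ["WT"])
        assert out["WT"].iloc[0] == 0.0

    def test_hand_computed_example(self):
        # two genotypes x two samples, worked by hand:
        # damage = max(og - ses*input, 0) / lib, then genotype mean
        idx = pd.Index(["g1", "g2", "g3"], name="gene")
        ogs = make_samples(
            {
                "WT_c1_r1_OG": ("WT", 1, 1, [10, 0, 6]),
                "WT_c2_r1_OG": ("WT", 2, 1, [20, 2, 6]),
                "KO_c1_r1_OG": ("KO", 1, 1, [30, 9, 0]),
                "KO_c2_r1_OG": ("KO", 2, 1, [10, 9, 0]),
            },
            "OG",
            idx,
        )
        inputs = make_samples(
            {
                "WT_c1_r1_in": ("WT", 1, 1, [4, 4, 4]),
                "WT_c2_r1_in": ("WT", 2, 1, [8, 4, 8]),
                "KO_c1_r1_in": ("KO", 1, 1, [10, 2, 2]),
                "KO_c2_r1_in": ("KO", 2, 1, [2, 2, 2]),
            },
            "input",
            idx,
        )
        ses = {"WT_c1_r1": 0.5, "WT_c2_r1": 1.0, "KO_c1_r1": 2.0, "KO_c2_r1": 1.0}
        lib = {"WT_c1_r1_OG": 1.0, "WT_c2_r1_OG": 2.0, "KO_c1_r1_OG": 0.5, "KO_c2_r1_OG": 1.0}
        out = promoter_signal(ogs, inputs, ses, lib, ["WT", "KO"])
        # WT: c1 -> ([8,0,4])/1 ; c2 -> ([12,0,0])/2 -> mean ([8,0,4]+[6,0,0])/2
        np.testing.assert_allclose(out["WT"].to_numpy(), [7.0, 0.0, 2.0])
        # KO: c1 -> ([10,5,0])/0.5=[20,10,0]; c2 -> [8,7,0] -> mean [14, 8.5, 0]
        np.testing.assert_allclose(out["KO"].to_numpy(), [14.0, 8.5, 0.0])

    def test_unpaired_og_sample_raises(self):
        idx = pd.Index(["g1"], name="gene")
        ogs = make_samples({"A_c1_r1_OG": ("WT", 1, 1, [8])}, "OG", idx)
        with pytest.raises(KeyError, match="A_c1_r1_OG"):
            promoter_signal(ogs, [], {}, {}, ["WT"])


class TestFilterPresent:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=GENOTYPES, index=[f"g{i}" for i in range(len(rows))]
        )

    def test_and_rule_across_assays(self):
        og = self.frame([[1, 1, 1, 1]])
        rna = self.frame([[1, 1, 0, 0]])
        assert len(filter_present(og, rna)) == 0

    def test_boundary_three_of_four_kept(self):
        og = self.frame([[1, 1, 1, 0]])
        rna = self.frame([[0, 2, 2, 2]])
        assert list(filter_present(og, rna)) == ["g0"]

    def test_monotone_in_signal(self, rng):
        og = self.frame(rng.poisson(1.0, size=(100, 4)))
        rna = self.frame(rng.poisson(1.0, size=(100, 4)))
        kept = set(filter_present(og, rna))
        kept_more = set(filter_present(og + 1, rna + 1))
        assert kept <= kept_more


class TestZscore:
    def test_rows_mean_zero_sd_one(self, rng):
        m = pd.DataFrame(rng.random((50, 4)) * 100, columns=GENOTYPES)
        z = zscore_rows(m)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_constant_rows_dropped(self):
        m = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], columns=GENOTYPES)
        z = zscore_rows(m)
        assert len(z) == 1


class TestConcordanceCluster:
    def embed(self, og_rows, rna_rows, n_background=0, rng=None):
        idx = [f"g{i}" for i in range(len(og_rows) + n_background)]
        og = list(og_rows)
        rna = list(rna_rows)
        if n_background:
            og += list(rng.random((n_background, 4)) * 10 + 1)
            rna += list(rng.random((n_background, 4)) * 10 + 1)
        return (
            pd.DataFrame(og, columns=GENOTYPES, index=idx),
            pd.DataFrame(rna, columns=GENOTYPES, index=idx),
        )

    def test_sign_rule_positive(self, rng):
        og, rna = self.embed([[5, 6, 1, 2]], [[50, 60, 10, 20]], 20, rng)
        out = concordance_cluster(og, rna, require_cluster_support=False)
        assert out.loc["g0", "sign_class"] == "positive"
        assert out.loc["g0", "classification"] == "positive"

    def test_sign_rule_negative(self, rng):
        og, rna = self.embed([[5, 6, 1, 2]], [[10, 20, 50, 60]], 20, rng)
        out = concordance_cluster(og, rna, require_cluster_support=False)
        assert out.loc["g0", "sign_class"] == "negative"

    def test_mixed_signs_unclassified(self, rng):
        og, rna = self.embed([[5, 6, 1, 2]], [[50, 10, 60, 20]], 20, rng)
        out = concordance_cluster(og, rna, require_cluster_support=False)
        assert out.loc["g0", "sign_class"] == "unclassified"

    def test_invariant_under_positive_rescaling(self, rng):
        og = pd.DataFrame(rng.random((60, 4)) * 20 + 1, columns=GENOTYPES)
        rna = pd.DataFrame(rng.random((60, 4)) * 200 + 1, columns=GENOTYPES)
        og.index = rna.index = [f"g{i}" for i in range(60)]
        base = concordance_cluster(og, rna)
        scaled = concordance_cluster(og * 3.7, rna * 0.002)
        assert (base["sign_class"] == scaled["sign_class"]).all()
        assert (base["classification"] == scaled["classification"]).all()

    def test_classification_robust_to_k(self, rng):
        og = pd.DataFrame(rng.random((80, 4)) * 20 + 1, columns=GENOTYPES)
        rna = pd.DataFrame(rng.random((80, 4)) * 20 + 1, columns=GENOTYPES)
        og.index = rna.index = [f"g{i}" for i in range(80)]
        a = concordance_cluster(og, rna, k=4)
        b = concordance_cluster(og, rna, k=16)
        assert (a["classification"] == b["classification"]).all()

    def test_null_positive_negative_balance(self, rng):
        """With no planted coupling the sign rule is symmetric."""
        og = pd.DataFrame(rng.random((3000, 4)), columns=GENOTYPES)
        rna = pd.DataFrame(rng.random((3000, 4)), columns=GENOTYPES)
        og.index = rna.index = [f"g{i}" for i in range(3000)]
        out = concordance_cluster(og, rna, require_cluster_support=False)
        n_pos = (out["sign_class"] == "positive").sum()
        n_neg = (out["sign_class"] == "negative").sum()
        assert abs(n_pos - n_neg) < 4 * np.sqrt(n_pos + n_neg)


class TestDerDegCorrelation:
    def test_identical_fold_changes(self):
        ders = pd.DataFrame(
            {"gene": ["a", "b", "c", "d"], "log2FC": [1.0, -0.5, 2.0, 0.3],
             "feature_class": ["cpg_island"] * 4}
        )
        degs = pd.DataFrame(
            {"log2FC": [1.0, -0.5, 2.0, 0.3], "is_deg": [True, False, True, False]},
            index=["a", "b", "c", "d"],
        )
        out = der_deg_correlation(ders, degs)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["overlap_by_class"]["cpg_island"] == pytest.approx(0.5)

    def test_anticorrelated_fold_changes(self):
        ders = pd.DataFrame({"gene": list("abcd"), "log2FC": [1.0, -0.5, 2.0, 0.3]})
        degs = pd.DataFrame({"log2FC": [-1.0, 0.5, -2.0, -0.3]}, index=list("abcd"))
        out = der_deg_correlation(ders, degs)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_too_few_genes_warns_and_skips(self):
        ders = pd.DataFrame({"gene": ["a"], "log2FC": [1.0]})
        degs = pd.DataFrame({"log2FC": [1.0]}, index=["a"])
        with pytest.warns(UserWarning, match="skipped"):
            assert der_deg_correlation(ders, degs) is None

    def test_independent_planting_overlap_matches_product(self, rng):
        """DER genes and DEG flags drawn independently overlap at about the
        product of their marginal rates."""
        genes = [f"g{i}" for i in range(2000)]
        der_genes = rng.choice(genes, size=400, replace=False)
        ders = pd.DataFrame(
            {"gene": der_genes, "log2FC": rng.normal(0, 1, 400),
             "feature_class": ["exon"] * 400}
        )
        degs = pd.DataFrame(
            {"log2FC": rng.normal(0, 1, 2000), "is_deg": rng.random(2000) < 0.1},
            index=genes,
        )
        out = der_deg_correlation(ders, degs)
        assert out["overlap_by_class"]["exon"] == pytest.approx(0.1, abs=0.04)
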