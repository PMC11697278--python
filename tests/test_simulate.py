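import filecmp

import numpy as np
import pandas as pd
import pytest

from ogmap.counting import counts_matrix
from ogmap.g4 import scan_g4
from ogmap.intervals import make_bins
from ogmap.simulate import (
    GroundTruth,
    SimConfig,
    plant_enriched_bins,
    simulate_bundle,
    simulate_genome,
    simulate_og_counts,
    simulate_promoter_study,
    simulate_rna_counts,
)


def tiny_cfg(**kw):
    base = dict(seed=11, n_chroms=1, chrom_length=60_000, n_genes=10,
                n_pos_corr_genes=2, n_neg_corr_genes=2, deg_genes_per_genotype=2)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="frac_enriched_bins"):
            tiny_cfg(frac_enriched_bins=1.5).validate()

    def test_fold_must_exceed_one(self):
        with pytest.raises(ValueError, match="der_fold"):
            tiny_cfg(der_fold=0.9).validate()

    def test_correlated_sets_cannot_exceed_genes(self):
        with pytest.raises(ValueError, match="exceed"):
            tiny_cfg(n_pos_corr_genes=8, n_neg_corr_genes=8).validate()

    def test_too_small_chromosome_for_genes(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(tiny_cfg(chrom_length=20_000, n_genes=10))


class TestSimulateGenome:
    def test_deterministic_fasta(self, tmp_path):
        for sub in ("a", "b"):
            simulate_bundle(tiny_cfg(), tmp_path / sub)
        assert filecmp.cmp(tmp_path / "a" / "genome.fa", tmp_path / "b" / "genome.fa", shallow=False)

    def test_zero_g4_density_means_no_motifs_at_all(self):
        genome = simulate_genome(tiny_cfg(g4_density=0.0))
        assert all(len(v) == 0 for v in genome.truth.g4_spans.values())
        for seq in genome.sequences.values():
            assert scan_g4(seq) == []

    def test_exons_and_introns_tile_gene_bodies(self):
        genome = simulate_genome(tiny_cfg(n_chroms=2, chrom_length=100_000, n_genes=20))
        exons = genome.features.classes["exon"]
        introns = genome.features.classes["intron"]
        for _, g in genome.genes.iterrows():
            segs = pd.concat(
                [
                    exons[exons["name"] == g["name"]],
                    introns[introns["name"] == g["name"]],
                ]
            ).sort_values("start")
            assert segs["start"].iloc[0] == g["start"]
            assert segs["end"].iloc[-1] == g["end"]
            assert (segs["end"].to_numpy()[:-1] == segs["start"].to_numpy()[1:]).all()

    def test_planted_g4_sequences_scan_positive(self):
        genome = simulate_genome(tiny_cfg(g4_density=2.0))
        for chrom, spans in genome.truth.g4_spans.items():
            seq = genome.sequences[chrom]
            for s, e, strand in spans:
                got = scan_g4(seq[s:e], both_strands=False)
                assert len(got) == 1
                # greedy shortest matching may leave the surplus of a
                # trailing 4-G run unconsumed
                assert got[0][0] == 0 and got[0][1] >= (e - s) - 1

    def test_intergenic_is_gene_complement(self):
        genome = simulate_genome(tiny_cfg())
        inter = genome.features.classes["intergenic"]
        genes = genome.genes
        total = sum(genome.chrom_sizes.values())
        assert (
            int((inter["end"] - inter["start"]).sum())
            + int((genes["end"] - genes["start"]).sum())
            == total
        )


class TestSimulateCounts:
    def bins_and_truth(self, cfg):
        genome = simulate_genome(cfg)
        bins = make_bins(genome.chrom_sizes, cfg.bin_size)
        return genome, bins, genome.truth

    def test_deterministic_counts(self):
        cfg = tiny_cfg()
        _, bins, truth = self.bins_and_truth(cfg)
        m1 = counts_matrix(simulate_og_counts(cfg, bins, GroundTruth(), stream="t"))
        m2 = counts_matrix(simulate_og_counts(cfg, bins, GroundTruth(), stream="t"))
        pd.testing.assert_frame_equal(m1, m2)

    def test_null_model_means_match_up_to_factors(self):
        """Without planted enrichment, OG means equal input means times the
        pair's SES factor (library factor shared)."""
        cfg = SimConfig(seed=3, n_chroms=1, chrom_length=2_000_000, n_genes=4,
                        background_mean=30.0, dispersion=0.05,
                        n_pos_corr_genes=0, n_neg_corr_genes=0)
        bins = make_bins({"chr1": cfg.chrom_length}, 1000)
        truth = GroundTruth()
        samples = simulate_og_counts(cfg, bins, truth, stream="null")
        ogs = {s.pair_id: s for s in samples if s.assay == "OG"}
        for inp in (s for s in samples if s.assay == "input"):
            og = ogs[inp.pair_id]
            ratio = og.counts.mean() / inp.counts.mean()
            assert ratio == pytest.approx(truth.true_ses_factor[inp.pair_id], rel=0.02)

    def test_planted_fold_recovered_in_expectation(self):
        """Monte-Carlo mean of OG/(ses-scaled input) over many bins ~ the
        planted enrichment fold."""
        cfg = SimConfig(seed=5, n_chroms=1, chrom_length=1_000_000, n_genes=4,
                        background_mean=50.0, dispersion=0.05, enrichment_fold=8.0,
                        frac_enriched_bins=0.5, n_pos_corr_genes=0, n_neg_corr_genes=0)
        bins = make_bins({"chr1": cfg.chrom_length}, 1000)
        truth = GroundTruth()
        enriched = plant_enriched_bins(cfg, bins, truth, gc_bias=False)
        samples = simulate_og_counts(cfg, bins, truth, stream="mc",
                                     enriched_ids=enriched)
        og = next(s for s in samples if s.assay == "OG")
        inp = next(s for s in samples if s.assay == "input" and s.pair_id == og.pair_id)
        ses = truth.true_ses_factor[og.pair_id]
        mask = bins.index.isin(enriched[og.genotype])
        fold = og.counts[mask].mean() / (inp.counts[mask].mean() * ses)
        assert fold == pytest.approx(8.0, rel=0.05)

    def test_nb_moment_identity(self):
        cfg = SimConfig(seed=9, n_chroms=1, chrom_length=20_000_000, n_genes=4,
                        background_mean=10.0, dispersion=0.1,
                        library_factor_range=(1.0, 1.0), n_pos_corr_genes=0,
                        n_neg_corr_genes=0)
        bins = make_bins({"chr1": cfg.chrom_length}, 1000)
        samples = simulate_og_counts(cfg, bins, GroundTruth(), stream="mom")
        inp = next(s for s in samples if s.assay == "input")
        mu = inp.counts.mean()
        var = inp.counts.var(ddof=1)
        assert var == pytest.approx(mu + cfg.dispersion * mu**2, rel=0.1)

    def test_ground_truth_ids_resolve(self, small_cfg, bundle_dir):
        import json

        truth = json.load(open(bundle_dir / "truth.json"))
        bins = pd.read_csv(bundle_dir / "counts" / "og_bins.tsv", sep="\t", index_col=0)
        for ids in truth["enriched_bin_ids"].values():
            assert set(ids) <= set(bins.index)
        rna = pd.read_csv(bundle_dir / "counts" / "rna.tsv", sep="\t", index_col=0)
        for sign, ids in truth["correlated_gene_ids"].items():
            assert set(ids) <= set(rna.index)
        assert not (
            set(truth["correlated_gene_ids"]["positive"])
            & set(truth["correlated_gene_ids"]["negative"])
        )


class TestSimulateRna:
    def test_no_coupling_means_independence(self):
        cfg = SimConfig(seed=13, n_genes=5000, n_pos_corr_genes=0, n_neg_corr_genes=0,
                        deg_genes_per_genotype=0)
        og, rna_geno, rna, truth = simulate_promoter_study(cfg)
        # correlation between per-gene OG and RNA deviations across the
        # gene axis is ~0 when nothing is planted
        r = np.corrcoef(og["DKO"] - og.mean(axis=1), rna_geno["DKO"] - rna_geno.mean(axis=1))[0, 1]
        assert abs(r) < 0.05

    def test_planted_positive_gene_correlates(self):
        cfg = SimConfig(seed=17, n_genes=500, n_pos_corr_genes=30, n_neg_corr_genes=30)
        og, rna_geno, rna, truth = simulate_promoter_study(cfg)
        rs = []
        for g in truth.correlated_gene_ids["positive"]:
            x, y = og.loc[g].to_numpy(), rna_geno.loc[g].to_numpy()
            rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) > 0.5

    def test_deterministic_matrix(self):
        cfg = tiny_cfg()
        out1 = simulate_promoter_study(cfg)[2]
        out2 = simulate_promoter_study(cfg)[2]
        pd.testing.assert_frame_equal(out1, out2)

    def test_oversized_correlated_sets_rejected(self):
        cfg = tiny_cfg()
        truth = GroundTruth()
        truth.correlated_gene_ids["positive"] = set("abcdefgh")
        sig = pd.DataFrame(np.ones((4, 4)), index=list("wxyz"), columns=list(cfg.genotypes))
        cfg.n_pos_corr_genes = 8
        with pytest.raises(ValueError, match="exceed"):
            simulate_rna_counts(cfg, truth, sig)
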