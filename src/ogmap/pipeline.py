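"""End-to-end pipeline: one configuration file drives all stages in
dependency order (bins -> SES -> enriched-bin calling -> annotation and
observed/expected -> differential enrichment per feature class and G4
windows -> RNA differential expression -> promoter OG/RNA integration).

Outputs are plain text (BED/TSV/JSON) plus a parameter manifest; a rerun
with the same inputs and seed reproduces every output byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .counting import SampleCounts, samples_from_matrix
from .differential import call_ders, der_summary, filter_low_reads, nb_test
from .enrichment import call_enriched_bins
from .g4 import eb_g4_overlap, g4_window_set
from .integration import (
    concordance_cluster,
    der_deg_correlation,
    filter_present,
    promoter_signal,
)
from .intervals import FeatureSet, annotate, make_bins, observed_expected, region_id
from .rna import deg_overlap, rna_de
from .ses import library_factors, ses_fit

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "bin_size": 1000,
    "percentile": 95.0,
    "min_bio_reps": 2,
    "pseudocount": 0.5,
    "min_total": 10,
    "der_p_max": 0.01,
    "der_min_abs_lfc": 0.5,
    "deg_p_max": 0.05,
    "deg_min_abs_lfc": 1.0,
    "promoter_flank": 1000,
    "g4_window": 100,
    "k_clusters": 8,
    "seed": 0,
}

FEATURE_CLASSES = ("cpg_island", "upstream", "exon", "intron", "downstream")


@dataclass
class PipelineConfig:
    """Validated paths + parameters for one pipeline run."""

    bundle_dir: Path
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bundle = Path(raw.get("bundle_dir", Path(path).parent))
        params = {**DEFAULT_PARAMS, **raw.get("params", {})}
        return cls(bundle_dir=bundle, params=params)

    def __post_init__(self):
        self.bundle_dir = Path(self.bundle_dir)
        self.params = {**DEFAULT_PARAMS, **self.params}

    def validate(self) -> None:
        required = [
            "genome.fa",
            "chrom.sizes",
            "samples_og.tsv",
            "counts/og_bins.tsv",
            "counts/rna.tsv",
            "samples_rna.tsv",
        ]
        missing = [p for p in required if not (self.bundle_dir / p).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")
        sheet = pd.read_csv(self.bundle_dir / "samples_og.tsv", sep="\t")
        genotypes = sorted(sheet["genotype"].unique())
        for g in genotypes:
            sub = sheet[sheet["genotype"] == g]
            cells = {(r.clone, r.bio_rep, r.assay) for r in sub.itertuples()}
            clones = sorted({c for c, _, _ in cells})
            bios = sorted({b for _, b, _ in cells})
            for c in clones:
                for b in bios:
                    for assay in ("OG", "input"):
                        if (c, b, assay) not in cells:
                            raise ValueError(
                                f"sample sheet missing cell (genotype={g}, clone={c}, "
                                f"bio_rep={b}, assay={assay})"
                            )


def _load_feature_set(bundle: Path) -> FeatureSet:
    classes = {}
    fdir = bundle / "features"
    for bed in sorted(fdir.glob("*.bed")):
        name = bed.stem
        if name == "blacklist":
            continue
        cols = (
            ["chrom", "start", "end", "name", "score", "strand"]
            if name in ("gene", "exon", "intron", "utr5", "utr3", "upstream")
            else None
        )
        try:
            classes[name] = io.read_bed(bed, names=cols)
        except pd.errors.EmptyDataError:
            continue
    genes = classes.get("gene")
    blacklist_path = fdir / "blacklist.bed"
    blacklist = None
    if blacklist_path.exists():
        try:
            blacklist = io.read_bed(blacklist_path)
        except pd.errors.EmptyDataError:
            blacklist = None
    return FeatureSet(classes=classes, genes=genes, blacklist=blacklist)


def _og_input_pairs(samples: list[SampleCounts]):
    ogs = {s.pair_id: s for s in samples if s.assay == "OG"}
    inputs = {s.pair_id: s for s in samples if s.assay == "input"}
    missing = set(ogs) ^ set(inputs)
    if missing:
        raise ValueError(f"unpaired OG/input samples: {sorted(missing)}")
    return [(ogs[k], inputs[k]) for k in sorted(ogs)]


def _damage_matrix(samples, ses_factors) -> pd.DataFrame:
    """Per-sample floored damage signal (OG - SES-scaled input)."""
    cols = {}
    for og, inp in _og_input_pairs(samples):
        scaled = inp.counts * ses_factors[og.pair_id]
        cols[og.sample_id] = np.maximum(og.counts - scaled, 0).round().astype(np.int64)
    return pd.DataFrame(cols, index=samples[0].region_index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns a dict of the main result tables."""
    config.validate()
    p = config.params
    bundle = config.bundle_dir
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    genome = io.read_fasta(bundle / "genome.fa")
    chrom_sizes = io.read_chrom_sizes(bundle / "chrom.sizes")
    features = _load_feature_set(bundle)
    og_sheet = pd.read_csv(bundle / "samples_og.tsv", sep="\t")
    genotypes = list(dict.fromkeys(og_sheet["genotype"]))
    wt = genotypes[0]
    contrasts = [(g, wt) for g in genotypes if g != wt]

    # --- bins + bin counts -------------------------------------------------
    bin_matrix = io.read_matrix(bundle / "counts" / "og_bins.tsv")
    blacklist = features.blacklist
    bins = make_bins(chrom_sizes, p["bin_size"], blacklist)
    bins = bins.loc[bins.index.intersection(bin_matrix.index)]
    bin_matrix = bin_matrix.loc[bins.index]
    samples = samples_from_matrix(bin_matrix, og_sheet)

    # --- SES per pair + inter-genotype library factors ---------------------
    ses_factors = {}
    for og, inp in _og_input_pairs(samples):
        ses_factors[og.pair_id] = ses_fit(og.counts, inp.counts).input_scale_factor
    io.write_json(ses_factors, outdir / "ses_factors.json")
    og_lib = library_factors({s.sample_id: s.library_size for s in samples if s.assay == "OG"})
    io.write_json(og_lib, outdir / "library_factors.json")
    results["ses_factors"] = ses_factors
    results["library_factors"] = og_lib

    # --- OG-enriched bins per genotype -------------------------------------
    eb_regions = {}
    for g in genotypes:
        og_g = [s for s in samples if s.genotype == g and s.assay == "OG"]
        in_g = [s for s in samples if s.genotype == g and s.assay == "input"]
        regions, consensus, _ = call_enriched_bins(
            og_g, in_g, bins,
            percentile=p["percentile"],
            pseudocount=p["pseudocount"],
            min_bio=p["min_bio_reps"],
        )
        regions["genotype"] = g
        eb_regions[g] = regions
        bed = regions.reset_index()[["chrom", "start", "end", "region", "mean_log2_ratio"]]
        bed.columns = ["chrom", "start", "end", "name", "score"]
        io.write_bed(bed, outdir / f"og_ebs_{g}.bed")
    results["enriched_regions"] = eb_regions

    # --- annotation + observed/expected ------------------------------------
    genome_size = sum(chrom_sizes.values())
    obs_exp = {}
    for g, regions in eb_regions.items():
        if len(regions) == 0:
            continue
        ann = annotate(regions, features)
        regions["feature_class"] = ann["feature_class"].to_numpy()
        regions["nearest_gene"] = ann["nearest_gene"].to_numpy()
        from .intervals import gc_content

        regions["gc"] = gc_content(regions, genome)
        obs_exp[g] = observed_expected(ann, features, genome_size).to_dict()
        regions.to_csv(outdir / f"og_ebs_{g}.tsv", sep="\t")
    io.write_json(obs_exp, outdir / "observed_expected.json")
    results["observed_expected"] = obs_exp

    # --- G4 windows + EB overlap -------------------------------------------
    g4 = g4_window_set(genome, chrom_sizes, window=p["g4_window"])
    retained = g4[g4["has_motif"]]
    io.write_bed(retained, outdir / "g4_windows.bed")
    g4_frac = {
        g: eb_g4_overlap(regions, retained) for g, regions in eb_regions.items() if len(regions)
    }
    io.write_json(g4_frac, outdir / "eb_g4_overlap.json")
    results["eb_g4_overlap"] = g4_frac

    # --- differential enrichment per feature class and G4 windows ----------
    der_tables = []
    region_sets = {cls: f"og_{cls}.tsv" for cls in FEATURE_CLASSES}
    region_sets["g4"] = "og_g4.tsv"
    for cls, fname in region_sets.items():
        path = bundle / "counts" / fname
        if not path.exists():
            continue
        matrix = io.read_matrix(path)
        gene_col = None
        region_bed = bundle / "regions" / f"{cls}.bed"
        if region_bed.exists():
            try:
                rb = io.read_bed(region_bed, names=["chrom", "start", "end", "gene"])
                if rb.shape[1] >= 4:
                    gene_col = pd.Series(rb["gene"].to_numpy(), index=matrix.index[: len(rb)])
            except (pd.errors.EmptyDataError, KeyError):
                gene_col = None
        reg_samples = samples_from_matrix(matrix, og_sheet)
        damage = _damage_matrix(reg_samples, ses_factors)
        damage = filter_low_reads(damage, p["min_total"])
        for ko, ref in contrasts:
            a_cols = [s.sample_id for s in reg_samples if s.assay == "OG" and s.genotype == ko]
            b_cols = [s.sample_id for s in reg_samples if s.assay == "OG" and s.genotype == ref]
            fa = np.array([og_lib[c] for c in a_cols])
            fb = np.array([og_lib[c] for c in b_cols])
            res = nb_test(damage[a_cols], damage[b_cols], fa, fb)
            res = call_ders(res, p["der_p_max"], p["der_min_abs_lfc"])
            res["feature_class"] = cls
            res["contrast"] = f"{ko}_vs_{ref}"
            if gene_col is not None:
                res["gene"] = gene_col.reindex(res.index)
            der_tables.append(res)
    ders = pd.concat(der_tables) if der_tables else pd.DataFrame()
    if len(ders):
        ders.to_csv(outdir / "og_ders.tsv", sep="\t")
        summary = der_summary(ders.assign(cls_contrast=ders["feature_class"] + "|" + ders["contrast"]), by="cls_contrast")
        summary.to_csv(outdir / "og_der_summary.tsv", sep="\t", index=False)
        results["der_summary"] = summary
    results["ders"] = ders

    # --- RNA differential expression ---------------------------------------
    rna = io.read_matrix(bundle / "counts" / "rna.tsv")
    rna_sheet = pd.read_csv(bundle / "samples_rna.tsv", sep="\t")
    groups = dict(zip(rna_sheet["sample_id"], rna_sheet["genotype"]))
    deg_tables = {}
    for ko, ref in contrasts:
        res = rna_de(rna, groups, (ko, ref), p["deg_p_max"], p["deg_min_abs_lfc"])
        res.to_csv(outdir / f"degs_{ko}_vs_{ref}.tsv", sep="\t")
        deg_tables[ko] = res
    results["degs"] = deg_tables
    if len(deg_tables) >= 2:
        sets = {g: set(t.index[t["is_deg"]]) for g, t in deg_tables.items()}
        ov = deg_overlap(sets)
        io.write_json(
            {
                "sizes": ov["sizes"],
                "all_intersection": sorted(ov["all_intersection"]),
                "shared_fraction": ov["shared_fraction"],
            },
            outdir / "deg_overlap.json",
        )
        results["deg_overlap"] = ov

    # --- promoter OG / RNA concordance -------------------------------------
    prom_path = bundle / "counts" / "og_promoters.tsv"
    if prom_path.exists():
        prom_matrix = io.read_matrix(prom_path)
        prom_samples = samples_from_matrix(prom_matrix, og_sheet)
        ogs = [s for s in prom_samples if s.assay == "OG"]
        inputs = [s for s in prom_samples if s.assay == "input"]
        og_prom = promoter_signal(ogs, inputs, ses_factors, og_lib, genotypes)
        rna_geno = pd.DataFrame(
            {g: rna[[s for s, gg in groups.items() if gg == g]].mean(axis=1) for g in genotypes}
        )
        keep = filter_present(og_prom, rna_geno)
        conc = concordance_cluster(og_prom.loc[keep], rna_geno.loc[keep], k=p["k_clusters"])
        conc.to_csv(outdir / "concordance.tsv", sep="\t")
        results["concordance"] = conc

        if len(ders) and "gene" in ders.columns and deg_tables:
            ko = contrasts[0][0]
            sub = ders[(ders["contrast"] == f"{ko}_vs_{wt}") & ders["passes"]]
            corr = der_deg_correlation(sub.dropna(subset=["gene"]), deg_tables[ko])
            if corr is not None:
                corr["pairs"].to_csv(outdir / "der_deg_pairs.tsv", sep="\t", index=False)
                io.write_json(
                    {"pearson_r": corr["pearson_r"], "overlap_by_class": corr["overlap_by_class"]},
                    outdir / "der_deg_correlation.json",
                )
                results["der_deg_correlation"] = corr

    manifest = {"params": p, "stages": [
        "bins", "ses", "call-ebs", "annotate", "g4", "der", "rna-de", "integrate",
    ]}
    io.write_json(manifest, outdir / "manifest.json")
    return results
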