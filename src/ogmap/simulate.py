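"""Synthetic OG-seq / RNA-seq study generator with known ground truth.

Emulates the study design the pipeline targets: four genotypes (wild
type, MUTYH-/-, OGG1-/-, and the double knockout) with two knockout
clones (technical replicates) across three independent experiments
(biological replicates), pulldown and input libraries with negative-
binomial background counts, planted enriched bins, planted genotype-
specific differential regions, planted canonical G4 motifs, and RNA
counts coupled to promoter damage for designated genes.

Every emitted file draws from its own RNG stream (seeded from the global
seed plus a stable hash of the stream name), so adding samples never
perturbs existing ones and a fixed seed reproduces outputs byte for byte.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .counting import SampleCounts
from .g4 import g4_window_set, scan_g4
from .intervals import (
    FeatureSet,
    complement_intervals,
    derive_promoters,
    gc_content,
    intervals_frame,
    make_bins,
)

GENOTYPES = ("WT", "MUTYH", "OGG1", "DKO")


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Count model: counts ~ NB with variance mu + dispersion * mu^2.
    Enrichment and differential folds act multiplicatively on the mean.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    bin_size: int = 1000
    n_genes: int = 60
    genotypes: tuple = GENOTYPES
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    background_mean: float = 10.0
    dispersion: float = 0.1
    frac_enriched_bins: float = 0.01
    enrichment_fold: float = 8.0
    frac_der_regions: float = 0.05
    der_fold: float = 2.0
    #: baseline pulldown enrichment over feature regions; keeps the floored
    #: input subtraction away from zero so damage loss remains observable
    regional_enrichment: float = 4.0
    #: CV of an optional global (sequence-driven) per-region rate effect
    #: shared by every library; 0 keeps the marginal count law exactly NB
    bin_effect_cv: float = 0.0
    library_factor_range: tuple = (0.7, 1.3)
    library_factors: dict | None = None
    ses_factor_range: tuple = (0.6, 1.4)
    n_pos_corr_genes: int = 10
    n_neg_corr_genes: int = 10
    #: promoter-damage multiplier per genotype for correlated genes. OGG1 is
    #: the glycosylase that excises OG itself (MUTYH removes the adenine
    #: misinserted opposite it), so promoter damage is low while OGG1 is
    #: present (WT, MUTYH-/-) and high once it is lost (OGG1-/-, DKO).
    promoter_pattern: tuple = (1.0, 1.1, 3.5, 3.8)
    #: linear OG->RNA coupling slope on the promoter-damage z-score; linear
    #: (not exponential) so the expected expression deviation from the row
    #: mean carries the same sign as the damage z-score in every genotype
    og_rna_beta: float = 0.6
    deg_genes_per_genotype: int = 5
    deg_fold: float = 4.0
    n_rna_reps: int = 2
    rna_mean: float = 100.0
    rna_lognormal_sigma: float = 0.5
    rna_dispersion: float = 0.05
    g4_density: float = 1.0  # planted motifs per 10 kb
    cpg_island_frac: float = 0.05
    gc_background: float = 0.41
    gc_island: float = 0.65
    blacklist_frac: float = 0.005

    def validate(self) -> None:
        for name in ("frac_enriched_bins", "frac_der_regions", "cpg_island_frac", "blacklist_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("enrichment_fold", "der_fold", "deg_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if self.bin_size <= 0 or self.chrom_length <= 0:
            raise ValueError("bin_size and chrom_length must be positive")
        if self.n_pos_corr_genes + self.n_neg_corr_genes > self.n_genes:
            raise ValueError("correlated gene sets exceed n_genes")
        if len(self.promoter_pattern) != len(self.genotypes):
            raise ValueError("promoter_pattern must give one multiplier per genotype")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study; all ids resolve to emitted
    intervals or genes."""

    enriched_bin_ids: dict = field(default_factory=dict)  # genotype -> set
    der_region_ids: dict = field(default_factory=dict)  # (genotype, class, direction) -> set
    correlated_gene_ids: dict = field(default_factory=lambda: {"positive": set(), "negative": set()})
    deg_gene_ids: dict = field(default_factory=dict)  # genotype -> set
    true_ses_factor: dict = field(default_factory=dict)  # pair_id -> float
    true_library_factor: dict = field(default_factory=dict)  # sample_id -> float
    g4_spans: dict = field(default_factory=dict)  # chrom -> [(start, end, strand)]

    def to_json(self) -> dict:
        return {
            "enriched_bin_ids": {k: sorted(v) for k, v in self.enriched_bin_ids.items()},
            "der_region_ids": {
                f"{g}|{c}|{d}": sorted(v) for (g, c, d), v in self.der_region_ids.items()
            },
            "correlated_gene_ids": {k: sorted(v) for k, v in self.correlated_gene_ids.items()},
            "deg_gene_ids": {k: sorted(v) for k, v in self.deg_gene_ids.items()},
            "true_ses_factor": self.true_ses_factor,
            "true_library_factor": self.true_library_factor,
            "g4_spans": {k: [list(s) for s in v] for k, v in self.g4_spans.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        gt = cls()
        gt.enriched_bin_ids = {k: set(v) for k, v in obj["enriched_bin_ids"].items()}
        for key, v in obj["der_region_ids"].items():
            g, c, d = key.split("|")
            gt.der_region_ids[(g, c, d)] = set(v)
        gt.correlated_gene_ids = {k: set(v) for k, v in obj["correlated_gene_ids"].items()}
        gt.deg_gene_ids = {k: set(v) for k, v in obj["deg_gene_ids"].items()}
        gt.true_ses_factor = obj["true_ses_factor"]
        gt.true_library_factor = obj["true_library_factor"]
        gt.g4_spans = {k: [tuple(s) for s in v] for k, v in obj["g4_spans"].items()}
        return gt


@dataclass
class SimGenome:
    sequences: dict
    chrom_sizes: dict
    features: FeatureSet
    genes: pd.DataFrame
    truth: GroundTruth


_BASES = np.array(list("ACGT"))


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _g4_motif(rng) -> str:
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 8))
            # loops avoid G so a planted instance has an unambiguous span
            parts.append("".join(rng.choice(np.array(list("ACT")), size=loop_len)))
    return "".join(parts)


def _spans_overlap(s, e, spans) -> bool:
    return any(s < e2 and e > s2 for s2, e2, *_ in spans)


def _scrub_chance_motifs(seq: np.ndarray, planted: list, rng) -> None:
    """Disrupt canonical G4 matches that were not planted (in place).

    A G (plus strand) or C (minus strand) inside the stray span but
    outside every planted span is flipped to T/A; iterated until the only
    remaining matches overlap planted spans.
    """
    for _ in range(60):
        stray = [
            (s, e, st)
            for s, e, st in scan_g4("".join(seq))
            if not _spans_overlap(s, e, planted)
        ]
        if not stray:
            return
        for s, e, strand in stray:
            target = "G" if strand == "+" else "C"
            repl = "T" if strand == "+" else "A"
            for i in range(s, e):
                if seq[i] == target and not _spans_overlap(i, i + 1, planted):
                    seq[i] = repl
                    break
    raise RuntimeError("could not scrub chance G4 motifs")


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Generate chromosome sequences, features and planted G4 motifs.

    Each chromosome gets GC-elevated CpG islands, strand-assigned genes
    whose exons and introns tile the gene body exactly, a blacklist
    track, planted canonical G4 motifs at recorded positions (aligned to
    100 bp windows), and no other canonical G4 match anywhere.
    """
    cfg.validate()
    L = cfg.chrom_length
    genes_per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    genes_per_chrom[0] += cfg.n_genes % cfg.n_chroms

    truth = GroundTruth()
    sequences = {}
    chrom_sizes = {}
    gene_rows, exon_rows, intron_rows, utr5_rows, utr3_rows = [], [], [], [], []
    cpg_rows, black_rows = [], []

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        rng = _rng(cfg.seed, f"genome:{chrom}")
        seq = _random_sequence(rng, L, cfg.gc_background)

        # CpG islands: GC-rich patches, non-overlapping
        n_islands = int(cfg.cpg_island_frac * L / 1000)
        islands = []
        attempts = 0
        while len(islands) < n_islands and attempts < 50 * max(n_islands, 1):
            attempts += 1
            length = int(rng.integers(600, 1500))
            s = int(rng.integers(0, max(L - length, 1)))
            if not _spans_overlap(s, s + length, islands):
                islands.append((s, s + length))
        for s, e in sorted(islands):
            seq[s:e] = _random_sequence(rng, e - s, cfg.gc_island)
            cpg_rows.append((chrom, s, e))

        # genes in fixed slots, exon/intron alternation tiling the body
        n_g = genes_per_chrom[ci]
        if n_g:
            slot = L // n_g
            if slot < 4400:
                raise ValueError(
                    f"chrom_length {L} too small to place {n_g} genes on {chrom}"
                )
            for gi in range(n_g):
                name = f"gene_{chrom}_{gi:04d}"
                slot_start = gi * slot
                max_len = min(slot - 2400, 8000)
                glen = int(rng.integers(2000, max_len + 1))
                gs = slot_start + 1200
                ge = gs + glen
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((chrom, gs, ge, name, 0, strand))
                n_ex = int(rng.integers(2, 6))
                n_cuts = 2 * n_ex - 2
                cuts = np.sort(rng.choice(np.arange(1, glen), size=n_cuts, replace=False))
                bounds = np.concatenate([[0], cuts, [glen]])
                segs = [(gs + bounds[i], gs + bounds[i + 1]) for i in range(len(bounds) - 1)]
                for si, (ss, se) in enumerate(segs):
                    (exon_rows if si % 2 == 0 else intron_rows).append(
                        (chrom, ss, se, name, 0, strand)
                    )
                first, last = segs[0], segs[-1]
                if strand == "-":
                    first, last = last, first
                utr5_rows.append((chrom, first[0], first[1], name, 0, strand))
                utr3_rows.append((chrom, last[0], last[1], name, 0, strand))

        # blacklist
        n_black = int(cfg.blacklist_frac * L / 1000)
        for s in sorted(rng.integers(0, L - 1000, size=n_black).tolist()):
            black_rows.append((chrom, int(s), int(s) + 1000))

        # planted G4 motifs, each inside a single 100 bp window
        n_g4 = int(round(cfg.g4_density * L / 10_000))
        planted = []
        attempts = 0
        while len(planted) < n_g4 and attempts < 200 * max(n_g4, 1):
            attempts += 1
            motif = _g4_motif(rng)
            win = int(rng.integers(0, L // 100))
            offset = int(rng.integers(0, 100 - len(motif)))
            s = win * 100 + offset
            if _spans_overlap(s - 25, s + len(motif) + 25, planted):
                continue
            planted.append((s, s + len(motif), "+"))
            seq[s : s + len(motif)] = np.array(list(motif))
        _scrub_chance_motifs(seq, planted, rng)
        truth.g4_spans[chrom] = sorted(planted)

        sequences[chrom] = "".join(seq)
        chrom_sizes[chrom] = L

    genes = intervals_frame(gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    cpg = intervals_frame(cpg_rows)
    blacklist = intervals_frame(black_rows)
    classes = {
        "upstream": derive_promoters(genes, 1000, chrom_sizes).reset_index(drop=True),
        "cpg_island": cpg,
        "exon": intervals_frame(exon_rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        "intron": intervals_frame(intron_rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        "utr5": intervals_frame(utr5_rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        "utr3": intervals_frame(utr3_rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
        "downstream": _downstream(genes, 1000, chrom_sizes),
        "intergenic": complement_intervals(genes, chrom_sizes),
        "gene": genes,
    }
    features = FeatureSet(classes=classes, genes=genes, blacklist=blacklist)
    return SimGenome(sequences, chrom_sizes, features, genes, truth)


def _downstream(genes: pd.DataFrame, flank: int, chrom_sizes: dict) -> pd.DataFrame:
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["end"], genes["start"] - flank)
    end = np.where(plus, genes["end"] + flank, genes["start"])
    start = np.maximum(start, 0)
    limits = genes["chrom"].map(chrom_sizes).to_numpy()
    end = np.minimum(end, limits)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start.astype(np.int64),
            "end": np.maximum(end, start).astype(np.int64),
            "name": genes["name"].to_numpy(),
        }
    )


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def sample_layout(cfg: SimConfig):
    """(genotype, clone, bio_rep) triples of the OG-seq design."""
    return [
        (g, c, b)
        for g in cfg.genotypes
        for c in range(1, cfg.n_tech_reps + 1)
        for b in range(1, cfg.n_bio_reps + 1)
    ]


def _library_factor(cfg: SimConfig, sample_id: str) -> float:
    if cfg.library_factors and sample_id in cfg.library_factors:
        return float(cfg.library_factors[sample_id])
    lo, hi = cfg.library_factor_range
    return float(_rng(cfg.seed, f"libfactor:{sample_id}").uniform(lo, hi))


def _ses_factor(cfg: SimConfig, pair_id: str) -> float:
    lo, hi = cfg.ses_factor_range
    return float(_rng(cfg.seed, f"sesfactor:{pair_id}").uniform(lo, hi))


def simulate_og_counts(
    cfg: SimConfig,
    regions: pd.DataFrame,
    truth: GroundTruth,
    stream: str = "bins",
    enriched_ids: dict | None = None,
    der_ids: dict | None = None,
    regional_enrichment: float = 1.0,
    per_gene_multipliers: pd.DataFrame | None = None,
) -> list[SampleCounts]:
    """NB-distributed OG pulldown and input counts over a region set.

    Input means are background_mean scaled by region length and the
    sample's library factor; OG means additionally carry the pair's true
    SES factor, the baseline ``regional_enrichment``, the enrichment fold
    at planted enriched bins (``enriched_ids``: genotype -> region id
    set), the differential fold at planted regions (``der_ids``:
    (genotype, direction) -> set, direction gain multiplies and loss
    divides), and optional per-gene genotype multipliers (regions indexed
    by gene).

    Counts are Gamma-Poisson: each pulldown/input pair shares a per-region
    Gamma(1/dispersion) rate effect (the input is the same DNA prep, and
    background pulldown tracks abundance), so marginal counts are
    NB(mu, dispersion) while the biological bin effect cancels inside a
    pair — the structure SES normalization relies on. The effect is drawn
    independently across pairs, where it acts as replicate variability for
    the differential tests. An optional global bin effect
    (``bin_effect_cv``) shared by all libraries models sequence-driven
    coverage bias on top.
    """
    cfg.validate()
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    base = cfg.background_mean * lengths / cfg.bin_size
    index = regions.index
    if cfg.bin_effect_cv > 0:
        sigma = np.sqrt(np.log(1 + cfg.bin_effect_cv**2))
        rng_bin = _rng(cfg.seed, f"{stream}:bin_effects")
        base = base * rng_bin.lognormal(-(sigma**2) / 2, sigma, len(regions))
    samples = []
    for g, c, b in sample_layout(cfg):
        pair = f"{g}_c{c}_r{b}"
        og_id, in_id = f"{pair}_OG", f"{pair}_input"
        lf_in = _library_factor(cfg, in_id)  # one library -> one factor, all region sets
        ses = _ses_factor(cfg, pair)
        truth.true_ses_factor.setdefault(pair, ses)
        truth.true_library_factor.setdefault(in_id, lf_in)
        truth.true_library_factor.setdefault(og_id, lf_in * ses)

        mult = np.full(len(regions), regional_enrichment, dtype=float)
        if enriched_ids and g in enriched_ids:
            mult[index.isin(enriched_ids[g])] *= cfg.enrichment_fold
        if der_ids:
            gain = der_ids.get((g, "gain"))
            loss = der_ids.get((g, "loss"))
            if gain:
                mult[index.isin(gain)] *= cfg.der_fold
            if loss:
                mult[index.isin(loss)] /= cfg.der_fold
        if per_gene_multipliers is not None:
            mult = mult * per_gene_multipliers[g].reindex(index).fillna(1.0).to_numpy()

        rng_in = _rng(cfg.seed, f"{stream}:{in_id}")
        rng_og = _rng(cfg.seed, f"{stream}:{og_id}")
        if cfg.dispersion > 0:
            # pair-shared biological rate effect; marginal law stays NB
            rng_pair = _rng(cfg.seed, f"{stream}:bioeffect:{pair}")
            lam = rng_pair.gamma(1 / cfg.dispersion, cfg.dispersion, len(regions))
        else:
            lam = 1.0
        inp = rng_in.poisson(base * lf_in * lam)
        og = rng_og.poisson(base * lf_in * ses * mult * lam)
        samples.append(SampleCounts(in_id, g, c, b, "input", inp, index))
        samples.append(SampleCounts(og_id, g, c, b, "OG", og, index))
    return samples


def plant_enriched_bins(
    cfg: SimConfig, bins: pd.DataFrame, truth: GroundTruth, gc_bias: bool = True
) -> dict:
    """Choose planted enriched bins per genotype (preferring GC-rich bins
    when a gc column is available)."""
    n = int(round(cfg.frac_enriched_bins * len(bins)))
    rng = _rng(cfg.seed, "enriched_bins")
    if gc_bias and "gc" in bins.columns and bins["gc"].notna().all():
        order = bins["gc"].to_numpy().argsort()[::-1]
        pool = bins.index[order[: max(n * 3, n)]]
    else:
        pool = bins.index
    for g in cfg.genotypes:
        chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        truth.enriched_bin_ids[g] = set(pool[np.sort(chosen)])
    return truth.enriched_bin_ids


def plant_der_regions(
    cfg: SimConfig, regions: pd.DataFrame, truth: GroundTruth, feature_class: str
) -> dict:
    """Plant genotype-specific differential regions (half gain, half loss)
    in each non-WT genotype; returns (genotype, direction) -> id set."""
    rng = _rng(cfg.seed, f"der:{feature_class}")
    n = int(round(cfg.frac_der_regions * len(regions)))
    out = {}
    for g in cfg.genotypes:
        if g == "WT":
            continue
        chosen = rng.choice(len(regions), size=min(n, len(regions)), replace=False)
        ids = regions.index[np.sort(chosen)]
        half = len(ids) // 2
        out[(g, "gain")] = set(ids[:half])
        out[(g, "loss")] = set(ids[half:])
        truth.der_region_ids[(g, feature_class, "gain")] = out[(g, "gain")]
        truth.der_region_ids[(g, feature_class, "loss")] = out[(g, "loss")]
    return out


def choose_correlated_genes(cfg: SimConfig, gene_names, truth: GroundTruth):
    """Disjoint positive/negative promoter-concordance gene sets."""
    rng = _rng(cfg.seed, "correlated_genes")
    total = cfg.n_pos_corr_genes + cfg.n_neg_corr_genes
    if total > len(gene_names):
        raise ValueError("correlated gene sets exceed available genes")
    chosen = rng.choice(len(gene_names), size=total, replace=False)
    names = pd.Index(gene_names)[chosen]
    truth.correlated_gene_ids["positive"] = set(names[: cfg.n_pos_corr_genes])
    truth.correlated_gene_ids["negative"] = set(names[cfg.n_pos_corr_genes :])
    return truth.correlated_gene_ids


def promoter_multipliers(cfg: SimConfig, gene_names, truth: GroundTruth) -> pd.DataFrame:
    """Per-gene genotype multipliers for promoter OG means: correlated
    genes follow the shared promoter damage pattern, others are flat."""
    M = pd.DataFrame(1.0, index=pd.Index(gene_names), columns=list(cfg.genotypes))
    corr = truth.correlated_gene_ids["positive"] | truth.correlated_gene_ids["negative"]
    for g, m in zip(cfg.genotypes, cfg.promoter_pattern):
        M.loc[M.index.isin(corr), g] = m
    return M


def true_promoter_signal(
    cfg: SimConfig, samples: list[SampleCounts], truth: GroundTruth
) -> pd.DataFrame:
    """Per-gene per-genotype promoter damage from the simulated counts,
    using the generator's true SES and library factors (input-subtracted,
    floored, averaged within genotype)."""
    ogs = [s for s in samples if s.assay == "OG"]
    inputs = {s.pair_id: s for s in samples if s.assay == "input"}
    per_geno: dict = {g: [] for g in cfg.genotypes}
    for og in ogs:
        inp = inputs[og.pair_id]
        scaled = inp.counts * truth.true_ses_factor[og.pair_id]
        damage = np.maximum(og.counts - scaled, 0) / truth.true_library_factor[og.sample_id]
        per_geno[og.genotype].append(damage)
    return pd.DataFrame(
        {g: np.mean(v, axis=0) for g, v in per_geno.items()}, index=ogs[0].region_index
    )


def simulate_rna_counts(
    cfg: SimConfig,
    truth: GroundTruth,
    og_promoter_signal: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RNA count matrix coupled to promoter damage for correlated genes.

    Baseline per-gene means are log-normal. For positively correlated
    genes the genotype mean is scaled by 1 + beta * z where z is that
    genotype's promoter damage z-score (1 - beta * z for the negative
    set, both floored at 0.05) — a monotone coupling whose expected
    deviation from the gene's mean keeps the sign of z. Designated DEG
    genes get the DEG fold in their genotype. Returns (counts genes x
    samples, sample sheet).
    """
    cfg.validate()
    genes = og_promoter_signal.index
    if cfg.n_pos_corr_genes + cfg.n_neg_corr_genes > len(genes):
        raise ValueError("correlated gene sets exceed n_genes")
    rng_base = _rng(cfg.seed, "rna_baseline")
    baseline = rng_base.lognormal(np.log(cfg.rna_mean), cfg.rna_lognormal_sigma, size=len(genes))

    vals = og_promoter_signal.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sd > 0, (vals - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z, index=genes, columns=og_promoter_signal.columns)

    M = pd.DataFrame(1.0, index=genes, columns=list(cfg.genotypes))
    pos = genes.isin(truth.correlated_gene_ids["positive"])
    neg = genes.isin(truth.correlated_gene_ids["negative"])
    for g in cfg.genotypes:
        M.loc[pos, g] = np.clip(1 + cfg.og_rna_beta * zdf.loc[pos, g], 0.05, None)
        M.loc[neg, g] = np.clip(1 - cfg.og_rna_beta * zdf.loc[neg, g], 0.05, None)

    # planted DEGs, disjoint from the correlated sets
    rng_deg = _rng(cfg.seed, "deg_genes")
    free = genes[~(pos | neg)]
    for g in cfg.genotypes:
        if g == "WT":
            continue
        k = min(cfg.deg_genes_per_genotype, len(free))
        chosen = free[np.sort(rng_deg.choice(len(free), size=k, replace=False))]
        truth.deg_gene_ids[g] = set(chosen)
        half = k // 2
        M.loc[chosen[:half], g] *= cfg.deg_fold
        M.loc[chosen[half:], g] /= cfg.deg_fold

    cols, sheet = {}, []
    for g in cfg.genotypes:
        for r in range(1, cfg.n_rna_reps + 1):
            sid = f"{g}_rna{r}"
            lf = _library_factor(cfg, f"rna:{sid}")
            truth.true_library_factor.setdefault(sid, lf)
            rng = _rng(cfg.seed, f"rna:{sid}")
            mu = baseline * M[g].to_numpy() * lf
            cols[sid] = _nb_draw(rng, mu, cfg.rna_dispersion)
            sheet.append({"sample_id": sid, "genotype": g, "clone": r, "bio_rep": 1, "assay": "RNA"})
    counts = pd.DataFrame(cols, index=genes)
    counts.index.name = "gene"
    return counts, pd.DataFrame(sheet)


def simulate_promoter_study(cfg: SimConfig):
    """Promoter-level concordance study without a sequence genome.

    Generates promoter OG/input counts with the concordance coupling,
    collapses the damage signal per genotype using the generator's true
    normalization factors, and draws RNA counts from it. Returns
    (og_matrix, rna_genotype_matrix, rna_counts, truth), the first two
    being gene x genotype tables ready for concordance clustering.
    """
    cfg.validate()
    genes = pd.Index([f"gene_{i:05d}" for i in range(cfg.n_genes)], name="gene")
    promoters = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(cfg.n_genes, dtype=np.int64) * 2 * cfg.bin_size,
            "end": np.arange(cfg.n_genes, dtype=np.int64) * 2 * cfg.bin_size + cfg.bin_size,
        },
        index=genes,
    )
    truth = GroundTruth()
    choose_correlated_genes(cfg, genes, truth)
    mult = promoter_multipliers(cfg, genes, truth)
    samples = simulate_og_counts(
        cfg,
        promoters,
        truth,
        stream="promoters",
        regional_enrichment=cfg.regional_enrichment,
        per_gene_multipliers=mult,
    )
    og_matrix = true_promoter_signal(cfg, samples, truth)
    rna, sheet = simulate_rna_counts(cfg, truth, og_matrix)
    geno = dict(zip(sheet["sample_id"], sheet["genotype"]))
    rna_geno = pd.DataFrame(
        {g: rna[[s for s, gg in geno.items() if gg == g]].mean(axis=1) for g in cfg.genotypes}
    )
    return og_matrix, rna_geno, rna, truth


DER_FEATURE_CLASSES = ("cpg_island", "upstream", "exon", "intron", "downstream")


def simulate_bundle(cfg: SimConfig, outdir) -> dict:
    """Full synthetic study written to ``outdir``; returns emitted paths.

    Layout: genome.fa, chrom.sizes, features/<class>.bed, regions/<set>.bed,
    counts/og_bins.tsv, counts/og_<class>.tsv, counts/og_g4.tsv,
    counts/og_promoters.tsv, counts/rna.tsv, samples_og.tsv,
    samples_rna.tsv, truth.json, sim_config.json.
    """
    cfg.validate()
    outdir = Path(outdir)
    (outdir / "features").mkdir(parents=True, exist_ok=True)
    (outdir / "regions").mkdir(exist_ok=True)
    (outdir / "counts").mkdir(exist_ok=True)

    genome = simulate_genome(cfg)
    truth = genome.truth
    io.write_fasta(genome.sequences, outdir / "genome.fa")
    io.write_chrom_sizes(genome.chrom_sizes, outdir / "chrom.sizes")
    for cls, df in genome.features.classes.items():
        io.write_bed(df, outdir / "features" / f"{cls}.bed")
    io.write_bed(genome.features.blacklist, outdir / "features" / "blacklist.bed")

    bins = make_bins(genome.chrom_sizes, cfg.bin_size, genome.features.blacklist)
    bins["gc"] = gc_content(bins, genome.sequences)
    plant_enriched_bins(cfg, bins, truth)
    og_bin_samples = simulate_og_counts(
        cfg, bins, truth, stream="bins", enriched_ids=truth.enriched_bin_ids
    )
    _write_counts(og_bin_samples, outdir / "counts" / "og_bins.tsv")
    io.write_bed(bins, outdir / "regions" / "bins.bed")

    sheet = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "genotype": s.genotype,
                "clone": s.clone,
                "bio_rep": s.bio_rep,
                "assay": s.assay,
            }
            for s in og_bin_samples
        ]
    )
    sheet.to_csv(outdir / "samples_og.tsv", sep="\t", index=False)

    # feature-class region sets with planted DERs
    for cls in DER_FEATURE_CLASSES:
        df = genome.features.classes[cls]
        cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
        regions = df[cols].copy()
        regions = regions[regions["end"] > regions["start"]].reset_index(drop=True)
        if "name" in regions.columns:
            regions = regions.rename(columns={"name": "gene"})
        regions.index = pd.Index(
            [f"{cls}:{c}:{s}-{e}" for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])],
            name="region",
        )
        der = plant_der_regions(cfg, regions, truth, cls)
        samples = simulate_og_counts(
            cfg,
            regions,
            truth,
            stream=f"regions:{cls}",
            der_ids=der,
            regional_enrichment=cfg.regional_enrichment,
        )
        _write_counts(samples, outdir / "counts" / f"og_{cls}.tsv")
        io.write_bed(regions, outdir / "regions" / f"{cls}.bed")

    # G4 windows (retained = containing a canonical motif)
    g4 = g4_window_set(genome.sequences, genome.chrom_sizes, window=100)
    retained = g4[g4["has_motif"]]
    if len(retained):
        der = plant_der_regions(cfg, retained, truth, "g4")
        samples = simulate_og_counts(
            cfg,
            retained,
            truth,
            stream="regions:g4",
            der_ids=der,
            regional_enrichment=cfg.regional_enrichment,
        )
        _write_counts(samples, outdir / "counts" / "og_g4.tsv")
    io.write_bed(retained, outdir / "regions" / "g4_windows.bed")

    # promoters with concordance-coupled damage, then RNA
    promoters = derive_promoters(genome.genes, 1000, genome.chrom_sizes)
    promoters = promoters[promoters["end"] > promoters["start"]]
    choose_correlated_genes(cfg, promoters.index, truth)
    mult = promoter_multipliers(cfg, promoters.index, truth)
    prom_samples = simulate_og_counts(
        cfg,
        promoters,
        truth,
        stream="promoters",
        regional_enrichment=cfg.regional_enrichment,
        per_gene_multipliers=mult,
    )
    _write_counts(prom_samples, outdir / "counts" / "og_promoters.tsv")
    io.write_bed(promoters, outdir / "regions" / "promoters.bed")

    signal = true_promoter_signal(cfg, prom_samples, truth)
    rna, rna_sheet = simulate_rna_counts(cfg, truth, signal)
    io.write_matrix(rna, outdir / "counts" / "rna.tsv")
    rna_sheet.to_csv(outdir / "samples_rna.tsv", sep="\t", index=False)

    io.write_json(truth.to_json(), outdir / "truth.json")
    io.write_json(asdict(cfg), outdir / "sim_config.json")
    return {"outdir": outdir, "truth": truth, "config": cfg}


def _write_counts(samples: list[SampleCounts], path) -> None:
    from .counting import counts_matrix

    m = counts_matrix(samples)
    m.index.name = "region"
    io.write_matrix(m, path)
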