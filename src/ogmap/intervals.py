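"""Genome interval arithmetic: fixed-width binning, promoter derivation,
GC content, feature annotation, and observed/expected feature enrichment.

All coordinates are 0-based half-open (BED convention). Interval sets are
held as pandas DataFrames with at least ``chrom``, ``start``, ``end``
columns; genes additionally carry ``name`` and ``strand``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default chromosome universe: human standard chromosomes 1-22 and X.
STANDARD_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

#: Priority order used to break exact overlap ties in :func:`annotate`.
#: Larger overlap always wins first; this order only decides equal overlaps.
CLASS_PRIORITY = (
    "upstream",
    "utr5",
    "exon",
    "utr3",
    "intron",
    "downstream",
    "intergenic",
)


def region_id(chrom: str, start: int, end: int) -> str:
    """Canonical string id for an interval, ``chrom:start-end``."""
    return f"{chrom}:{start}-{end}"


def intervals_frame(records, columns=("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=list(columns))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass
class FeatureSet:
    """Per-class genomic feature intervals.

    ``classes`` maps a feature-class name (``upstream``, ``cpg_island``,
    ``exon``, ``intron``, ``downstream``, ``intergenic``, ``utr5``,
    ``utr3``) to an interval DataFrame. ``genes`` carries strand and is
    the source of TSS positions; ``blacklist`` is kept separately.
    """

    classes: dict = field(default_factory=dict)
    genes: pd.DataFrame | None = None
    blacklist: pd.DataFrame | None = None

    def __post_init__(self):
        if self.genes is not None and "strand" in self.genes.columns:
            bad = self.genes[~self.genes["strand"].isin(["+", "-"])]
            if len(bad):
                raise ValueError(
                    f"genes without strand: {', '.join(map(str, bad['name']))}"
                )

    @property
    def tss(self) -> pd.DataFrame:
        """Per-gene transcription start site (strand-aware)."""
        g = self.genes
        pos = np.where(g["strand"] == "+", g["start"], g["end"])
        return pd.DataFrame({"chrom": g["chrom"], "tss": pos, "name": g["name"]})

    def footprint(self, class_name: str) -> int:
        """Total bp covered by a feature class (overlaps merged)."""
        df = self.classes[class_name]
        total = 0
        for _, sub in df.groupby("chrom", sort=False):
            total += merged_length(sub["start"].to_numpy(), sub["end"].to_numpy())
        return total


def merged_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Length of the union of intervals on one chromosome."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    total, cur_s, cur_e = 0, s[0], e[0]
    for i in range(1, len(s)):
        if s[i] > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s[i], e[i]
        else:
            cur_e = max(cur_e, e[i])
    return int(total + (cur_e - cur_s))


def make_bins(
    chrom_sizes: dict,
    bin_size: int = 1000,
    blacklist: pd.DataFrame | None = None,
    chroms=None,
) -> pd.DataFrame:
    """Tile chromosomes with non-overlapping fixed-width bins.

    Incomplete terminal bins (shorter than ``bin_size``) are dropped, and
    any bin overlapping a blacklist interval by >= 1 bp is removed.
    Returns a DataFrame with ``chrom``, ``start``, ``end`` and a
    ``bin_id`` index.

    Parameters
    ----------
    chrom_sizes : dict
        chromosome -> length (bp).
    bin_size : int
        bin width in bp (default 1000).
    blacklist : DataFrame, optional
        intervals to exclude; unknown chromosomes are ignored with a warning.
    chroms : sequence, optional
        restrict to this chromosome universe (order preserved); by default
        all chromosomes in ``chrom_sizes`` are used.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    use = list(chroms) if chroms is not None else list(chrom_sizes)
    frames = []
    for chrom in use:
        if chrom not in chrom_sizes:
            continue
        n = chrom_sizes[chrom] // bin_size
        starts = np.arange(n, dtype=np.int64) * bin_size
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size})
        )
    bins = pd.concat(frames, ignore_index=True) if frames else intervals_frame([])
    if blacklist is not None and len(blacklist):
        unknown = set(blacklist["chrom"]) - set(use)
        if unknown:
            warnings.warn(
                f"blacklist intervals on unknown chromosomes ignored: {sorted(unknown)}"
            )
        keep = np.ones(len(bins), dtype=bool)
        for chrom, sub in blacklist.groupby("chrom", sort=False):
            if chrom not in use:
                continue
            mask = bins["chrom"].to_numpy() == chrom
            bs = bins.loc[mask, "start"].to_numpy()
            be = bins.loc[mask, "end"].to_numpy()
            hit = np.zeros(mask.sum(), dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                hit |= (bs < e) & (be > s)
            keep[np.flatnonzero(mask)[hit]] = False
        bins = bins[keep].reset_index(drop=True)
    bins.index = pd.Index(
        [region_id(c, s, e) for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])],
        name="bin_id",
    )
    return bins


def derive_promoters(
    genes: pd.DataFrame, flank: int = 1000, chrom_sizes: dict | None = None
) -> pd.DataFrame:
    """Strand-aware promoters: the ``flank`` bp immediately upstream of each TSS.

    A + strand gene [s, e) yields [s - flank, s); a - strand gene yields
    [e, e + flank). Promoters are clamped at chromosome bounds and never
    extend below 0; genes whose promoter is fully truncated (zero length)
    are still emitted with start == end so callers can filter them.
    """
    if "strand" not in genes.columns or genes["strand"].isna().any():
        raise ValueError("every gene needs a strand")
    bad = genes[~genes["strand"].isin(["+", "-"])]
    if len(bad):
        names = ", ".join(map(str, bad.get("name", bad.index)))
        raise ValueError(f"gene(s) without valid strand: {names}")
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["start"] - flank, genes["end"])
    end = np.where(plus, genes["start"], genes["end"] + flank)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = genes["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    end = np.maximum(end, start)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "name": genes["name"].to_numpy(),
            "strand": genes["strand"].to_numpy(),
        }
    )
    out.index = pd.Index(out["name"], name="gene")
    return out


def gc_content(intervals: pd.DataFrame, genome) -> np.ndarray:
    """GC fraction per interval: (G+C) / (A+C+G+T), both cases counted.

    Ambiguous bases (N etc.) are excluded from the denominator; an interval
    with no unambiguous bases gets NaN. ``genome`` is a mapping from
    chromosome name to sequence (plain strings or a pyfaidx.Fasta).
    """
    out = np.empty(len(intervals), dtype=float)
    for i, (chrom, s, e) in enumerate(
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        seq = str(genome[chrom][s:e]).upper()
        if e > s and len(seq) < e - s:
            raise ValueError(f"interval {region_id(chrom, s, e)} beyond sequence end")
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        out[i] = gc / (gc + at) if gc + at else np.nan
    return out


def _overlap_bp(starts, ends, s, e):
    """Vectorized overlap in bp of intervals with [s, e)."""
    return np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)


def annotate(regions: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    """Assign each region a primary feature class and its nearest gene.

    The primary class is the one with maximal bp overlap; exact overlap
    ties are broken by :data:`CLASS_PRIORITY`. Regions overlapping nothing
    are ``intergenic``. CpG-island overlap is reported as a separate
    boolean overlay, not a primary class. The nearest gene minimizes
    |TSS - region center|; ``distance_to_tss`` is signed (region center
    minus TSS, flipped for - strand genes so negative means upstream).
    """
    if not features.classes:
        raise ValueError("empty FeatureSet")
    primary = [c for c in CLASS_PRIORITY if c in features.classes]
    rank = {c: i for i, c in enumerate(primary)}
    by_chrom = {
        c: {k: v for k, v in features.classes[c].groupby("chrom", sort=False)}
        for c in primary
    }
    cpg = None
    if "cpg_island" in features.classes:
        cpg = {k: v for k, v in features.classes["cpg_island"].groupby("chrom", sort=False)}
    tss = features.tss if features.genes is not None else None
    tss_by_chrom = (
        {k: v for k, v in tss.groupby("chrom", sort=False)} if tss is not None else {}
    )
    gene_strand = (
        dict(zip(features.genes["name"], features.genes["strand"]))
        if features.genes is not None
        else {}
    )

    rows = []
    for rid, chrom, s, e in zip(
        regions.index, regions["chrom"], regions["start"], regions["end"]
    ):
        best_class, best_ov, best_rank = "intergenic", 0, rank.get("intergenic", 99)
        for cls in primary:
            sub = by_chrom[cls].get(chrom)
            if sub is None:
                continue
            ov = _overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(), s, e)
            total = int(ov.max()) if len(ov) else 0
            if total > best_ov or (total == best_ov and total > 0 and rank[cls] < best_rank):
                best_class, best_ov, best_rank = cls, total, rank[cls]
        has_cpg = False
        if cpg is not None:
            sub = cpg.get(chrom)
            if sub is not None:
                has_cpg = bool(
                    (_overlap_bp(sub["start"].to_numpy(), sub["end"].to_numpy(), s, e) > 0).any()
                )
        nearest, dist = None, np.nan
        sub = tss_by_chrom.get(chrom)
        if sub is not None and len(sub):
            center = (s + e) / 2
            d = center - sub["tss"].to_numpy()
            i = int(np.argmin(np.abs(d)))
            nearest = sub["name"].iloc[i]
            dist = float(d[i])
            if gene_strand.get(nearest) == "-":
                dist = -dist
        rows.append((rid, best_class, has_cpg, nearest, dist))
    return pd.DataFrame(
        rows,
        columns=["region", "feature_class", "cpg_island", "nearest_gene", "distance_to_tss"],
    ).set_index("region")


def observed_expected(
    annotations: pd.DataFrame, features: FeatureSet, genome_size: int
) -> pd.Series:
    """log2(observed / expected) fraction of regions per primary feature class.

    Expected fraction = merged class footprint / genome size; observed =
    fraction of regions whose primary class is that class. Classes with
    zero observed regions return -inf.
    """
    if len(annotations) == 0:
        raise ValueError("need at least one annotated region")
    classes = [c for c in CLASS_PRIORITY if c in features.classes]
    obs = annotations["feature_class"].value_counts(normalize=True)
    out = {}
    for cls in classes:
        fp = features.footprint(cls)
        o = obs.get(cls, 0.0)
        if fp == 0:
            if o > 0:
                raise ValueError(f"class {cls} has zero footprint but observed regions")
            continue
        exp = fp / genome_size
        out[cls] = np.log2(o / exp) if o > 0 else -np.inf
    return pd.Series(out, name="log2_obs_exp")


def complement_intervals(intervals: pd.DataFrame, chrom_sizes: dict) -> pd.DataFrame:
    """Genomic complement of an interval set (used for intergenic regions)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = intervals[intervals["chrom"] == chrom].sort_values("start")
        pos = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > pos:
                rows.append((chrom, pos, min(s, size)))
            pos = max(pos, e)
        if pos < size:
            rows.append((chrom, pos, size))
    return intervals_frame(rows)
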