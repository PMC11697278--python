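"""OG-enriched bin (OG-EB) calling.

Per technical replicate, bins are scored by the log2 ratio of OG to
SES-scaled input and thresholded at a percentile of that ratio. Bins are
kept only when present in both technical replicates of at least two of
three biological replicates, and surviving bookended (zero-gap adjacent)
bins are merged into enriched regions.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def log2_ratio(
    og: np.ndarray, scaled_input: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """log2((og + pc) / (scaled_input + pc)).

    With pc = 0 a bin where both signals are zero returns 0 (degenerate
    bin, treated as no enrichment).
    """
    og = np.asarray(og, dtype=float)
    inp = np.asarray(scaled_input, dtype=float)
    if (og < 0).any() or (inp < 0).any():
        raise ValueError("negative counts")
    num = og + pseudocount
    den = inp + pseudocount
    out = np.zeros_like(num)
    ok = (num > 0) & (den > 0)
    out[ok] = np.log2(num[ok] / den[ok])
    out[(num > 0) & (den == 0)] = np.inf
    out[(num == 0) & (den > 0)] = -np.inf
    return out


def threshold_bins(ratios: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Boolean mask of bins at or above the given ratio percentile.

    The percentile uses linear interpolation between order statistics.
    If all ratios are equal the threshold equals that common value and
    every bin is selected (with a warning).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < 20:
        raise ValueError("need at least 20 bins to threshold")
    if np.all(ratios == ratios[0]):
        warnings.warn("all ratios equal: every bin meets the threshold")
        return np.ones(len(ratios), dtype=bool)
    thr = np.percentile(ratios, percentile)
    return ratios >= thr


def replicate_consensus(
    support: dict,
    n_tech: int = 2,
    min_bio: int = 2,
) -> set:
    """Replicate-consensus bin set.

    ``support`` maps (bio_rep, tech_rep) -> set of bin ids passing the
    threshold in that technical replicate. A bin is retained iff it is
    present in *all* technical replicates of a biological replicate, in at
    least ``min_bio`` biological replicates.
    """
    bio_reps = sorted({b for b, _ in support})
    for b in bio_reps:
        techs = sorted(t for bb, t in support if bb == b)
        if len(techs) != n_tech:
            raise KeyError(
                f"biological replicate {b} has technical replicates {techs}, expected {n_tech}"
            )
    kept: dict = {}
    for b in bio_reps:
        sets = [support[(b, t)] for bb, t in support if bb == b]
        both = set.intersection(*sets) if sets else set()
        for bin_id in both:
            kept[bin_id] = kept.get(bin_id, 0) + 1
    return {bin_id for bin_id, n in kept.items() if n >= min_bio}


def merge_bookended(
    bin_ids: set,
    bins: pd.DataFrame,
    ratios: np.ndarray | None = None,
) -> pd.DataFrame:
    """Merge maximal runs of bookended (zero-gap adjacent) bins.

    Parameters
    ----------
    bin_ids : set
        consensus bin ids (index values of ``bins``).
    bins : DataFrame
        the full bin table (chrom/start/end, bin_id index).
    ratios : ndarray, optional
        per-bin scores aligned to ``bins`` (e.g. the mean log2 OG/input
        ratio across replicates); region scores are the mean over
        constituent bins.

    Returns
    -------
    DataFrame with chrom, start, end, n_bins, mean_log2_ratio.
    """
    sel = bins.loc[bins.index.isin(bin_ids)].sort_values(["chrom", "start"])
    score = None
    if ratios is not None:
        score = pd.Series(np.asarray(ratios, dtype=float), index=bins.index)
    rows = []
    cur = None  # [chrom, start, end, n, score_sum]
    for bin_id, r in sel.iterrows():
        s = float(score.loc[bin_id]) if score is not None else np.nan
        if cur is not None and r["chrom"] == cur[0] and r["start"] == cur[2]:
            cur[2] = r["end"]
            cur[3] += 1
            cur[4] += s
        else:
            if cur is not None:
                rows.append(cur)
            cur = [r["chrom"], r["start"], r["end"], 1, s]
    if cur is not None:
        rows.append(cur)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "score_sum"])
    out["mean_log2_ratio"] = out["score_sum"] / out["n_bins"]
    out = out.drop(columns="score_sum")
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out.index = pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])],
        name="region",
    )
    return out


def call_enriched_bins(
    og_samples: list,
    input_samples: list,
    bins: pd.DataFrame,
    percentile: float = 95.0,
    pseudocount: float = 0.5,
    min_bio: int = 2,
):
    """Full OG-EB calling for one genotype.

    ``og_samples`` and ``input_samples`` are SampleCounts lists for a
    single genotype, matched by (clone, bio_rep). Each pair is SES-fitted
    and thresholded individually; consensus and bookended merging follow.

    Returns (regions DataFrame, consensus bin id set, mean ratio vector).
    """
    from .ses import ses_fit

    inputs = {(s.clone, s.bio_rep): s for s in input_samples}
    support = {}
    ratio_sum = np.zeros(len(bins))
    n_pairs = 0
    for og in og_samples:
        key = (og.clone, og.bio_rep)
        if key not in inputs:
            raise KeyError(f"no input sample for {og.sample_id} (clone={key[0]}, bio_rep={key[1]})")
        inp = inputs[key]
        fit = ses_fit(og.counts, inp.counts)
        ratios = log2_ratio(og.counts, fit.scale_input(inp.counts), pseudocount)
        mask = threshold_bins(ratios, percentile)
        support[(og.bio_rep, og.clone)] = set(bins.index[mask])
        ratio_sum += ratios
        n_pairs += 1
    n_tech = len({c for _, c in support})
    consensus = replicate_consensus(support, n_tech=n_tech, min_bio=min_bio)
    mean_ratio = ratio_sum / max(n_pairs, 1)
    regions = merge_bookended(consensus, bins, mean_ratio)
    return regions, consensus, mean_ratio
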