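"""Read-interval counting over bins and arbitrary region sets.

Counting follows bedtools-multicov semantics: a read increments every
region it overlaps by at least 1 bp. Reads are plain intervals (BED); an
optional ``duplicate`` column marks PCR duplicates, excluded by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class SampleCounts:
    """Counts for one sequencing library over a named region set."""

    sample_id: str
    genotype: str
    clone: int
    bio_rep: int
    assay: str  # "OG" or "input"
    counts: np.ndarray
    region_index: pd.Index

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.counts) != len(self.region_index):
            raise ValueError("counts length != region count")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())

    @property
    def pair_id(self) -> str:
        return f"{self.genotype}_c{self.clone}_r{self.bio_rep}"


def _regions_sorted_nonoverlapping(starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) < 2:
        return True
    return bool(np.all(np.diff(starts) >= 0) and np.all(ends[:-1] <= starts[1:]))


def count_reads(
    reads: pd.DataFrame,
    regions: pd.DataFrame,
    exclude_duplicates: bool = True,
) -> np.ndarray:
    """Count reads over regions with >= 1 bp-overlap (multicov) semantics.

    Parameters
    ----------
    reads : DataFrame
        columns ``chrom``, ``start``, ``end`` and optionally ``duplicate``.
    regions : DataFrame
        target intervals; may overlap each other (feature sets) or not
        (bins). Within a chromosome, sorted non-overlapping regions take a
        fast vectorized path; otherwise an interval tree is used.
    exclude_duplicates : bool
        drop reads flagged as duplicates before counting (default True).

    Returns
    -------
    ndarray of int64 aligned to ``regions`` rows. Reads on chromosomes not
    present in ``regions`` are skipped and logged.
    """
    if exclude_duplicates and "duplicate" in reads.columns:
        reads = reads[~reads["duplicate"].astype(bool)]
    counts = np.zeros(len(regions), dtype=np.int64)
    region_chroms = set(regions["chrom"])
    skipped = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in region_chroms:
            skipped += len(sub)
            continue
        mask = (regions["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        rs = regions["start"].to_numpy()[idx]
        re_ = regions["end"].to_numpy()[idx]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        if _regions_sorted_nonoverlapping(rs, re_):
            # region i overlaps read iff start_i < read_end and end_i > read_start
            lo = np.searchsorted(re_, qs, side="right")
            hi = np.searchsorted(rs, qe, side="left")
            valid = hi > lo
            diff = np.zeros(len(idx) + 1, dtype=np.int64)
            np.add.at(diff, lo[valid], 1)
            np.add.at(diff, hi[valid], -1)
            counts[idx] += np.cumsum(diff[:-1])
        else:
            tree = IntervalTree()
            for j, (s, e) in enumerate(zip(rs, re_)):
                if e > s:
                    tree.addi(s, e, j)
            local = np.zeros(len(idx), dtype=np.int64)
            for s, e in zip(qs, qe):
                for iv in tree.overlap(s, e):
                    local[iv.data] += 1
            counts[idx] += local
    if skipped:
        log.warning("%d reads on chromosomes absent from the region set were skipped", skipped)
    return counts


def counts_matrix(samples: list[SampleCounts]) -> pd.DataFrame:
    """Region x sample count matrix from a list of SampleCounts."""
    if not samples:
        raise ValueError("no samples")
    index = samples[0].region_index
    for s in samples:
        if not s.region_index.equals(index):
            raise ValueError(f"sample {s.sample_id} on a different region set")
    return pd.DataFrame(
        {s.sample_id: s.counts for s in samples}, index=index
    )


def samples_from_matrix(matrix: pd.DataFrame, sheet: pd.DataFrame) -> list[SampleCounts]:
    """Build SampleCounts from a count matrix and a sample sheet.

    The sheet needs columns ``sample_id``, ``genotype``, ``clone``,
    ``bio_rep``, ``assay``; every sheet sample must be a matrix column.
    """
    out = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        if sid not in matrix.columns:
            raise KeyError(f"sample {sid} missing from count matrix")
        out.append(
            SampleCounts(
                sample_id=sid,
                genotype=row["genotype"],
                clone=int(row["clone"]),
                bio_rep=int(row["bio_rep"]),
                assay=row["assay"],
                counts=matrix[sid].to_numpy(),
                region_index=matrix.index,
            )
        )
    return out
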