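"""Differential gene expression on RNA count matrices.

Uses the same conditional NB exact test as the damage-region analysis,
with total-count library factors, and flags differentially expressed
genes at |log2FC| > 1 and p <= 0.05.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import nb_test
from .ses import library_factors

log = logging.getLogger(__name__)

DEG_P_MAX = 0.05
DEG_MIN_ABS_LFC = 1.0


def rna_de(
    counts: pd.DataFrame,
    groups: dict,
    contrast: tuple[str, str],
    p_max: float = DEG_P_MAX,
    min_abs_lfc: float = DEG_MIN_ABS_LFC,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group differential expression, group A vs group B.

    Parameters
    ----------
    counts : DataFrame
        genes x samples raw counts.
    groups : dict
        sample id -> group label (e.g. genotype).
    contrast : (str, str)
        (A, B) group labels; log2FC is A over B (typically KO vs WT).
    p_max, min_abs_lfc : float
        DEG gate: p <= p_max and |log2FC| strictly > min_abs_lfc.

    Library factors are computed from the total counts of the samples in
    the contrast. All-zero gene rows are excluded and logged.
    """
    a_label, b_label = contrast
    a_cols = [s for s, g in groups.items() if g == a_label and s in counts.columns]
    b_cols = [s for s, g in groups.items() if g == b_label and s in counts.columns]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least two replicates per group")
    sub = counts[a_cols + b_cols]
    nonzero = sub.sum(axis=1) > 0
    if (~nonzero).any():
        log.info("excluding %d all-zero genes", int((~nonzero).sum()))
    sub = sub.loc[nonzero]
    factors = library_factors({c: sub[c].sum() for c in sub.columns})
    fa = np.array([factors[c] for c in a_cols])
    fb = np.array([factors[c] for c in b_cols])
    res = nb_test(sub[a_cols], sub[b_cols], fa, fb, dispersion=dispersion)
    res["is_deg"] = (res["p_value"] <= p_max) & (res["log2FC"].abs() > min_abs_lfc)
    res["contrast"] = f"{a_label}_vs_{b_label}"
    return res


def deg_overlap(deg_sets: dict) -> dict:
    """Intersection/union structure of per-genotype DEG sets.

    Returns pairwise intersections, the intersection and union over all
    sets, and per-genotype shared fractions (fraction of a genotype's
    DEGs found in at least one other genotype).
    """
    names = list(deg_sets)
    if len(names) < 2:
        raise ValueError("need at least two DEG sets")
    out = {
        "sizes": {n: len(deg_sets[n]) for n in names},
        "pairwise": {},
        "all_intersection": set.intersection(*map(set, deg_sets.values())),
        "union": set.union(*map(set, deg_sets.values())),
        "shared_fraction": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out["pairwise"][(a, b)] = set(deg_sets[a]) & set(deg_sets[b])
        others = set().union(*(deg_sets[o] for o in names if o != a))
        n = len(deg_sets[a])
        out["shared_fraction"][a] = len(set(deg_sets[a]) & others) / n if n else np.nan
    return out
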