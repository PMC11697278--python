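"""Promoter-level integration of OG damage and gene expression.

Promoter OG signal (input-subtracted, library-normalized, averaged per
genotype) is matched to RNA counts per gene, both are z-scored by row
within their assay, and genes are classified as consistently positive or
negative in OG-expression concordance across genotypes. Hierarchical
clustering (Euclidean, average linkage) groups genes; a gene's sign-rule
class is only reported when its cluster reaches a consensus, which keeps
the chance sign-pattern coincidences of null genes unclassified.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .ses import subtract_input

log = logging.getLogger(__name__)


def promoter_signal(
    og_samples: list,
    input_samples: list,
    ses_factors: dict,
    lib_factors: dict,
    genotypes: list[str],
) -> pd.DataFrame:
    """Per-gene, per-genotype promoter damage signal.

    For each OG/input pair the SES-scaled input is subtracted from the OG
    counts (floored at 0), the result is divided by the OG sample's
    library factor, and samples of a genotype are averaged ("collapsed to
    meta-features by mean").

    Parameters
    ----------
    og_samples, input_samples : list of SampleCounts
        counted over promoters (index = gene ids), matched by pair_id.
    ses_factors : dict
        pair_id -> input scale factor from the bin-level SES fit.
    lib_factors : dict
        sample_id -> library factor.
    genotypes : list
        column order of the output matrix.
    """
    inputs = {s.pair_id: s for s in input_samples}
    index = og_samples[0].region_index
    zero_len = [g for g in index if isinstance(g, str) and g.endswith(":empty")]
    per_geno: dict = {g: [] for g in genotypes}
    for og in og_samples:
        if og.pair_id not in inputs:
            raise KeyError(f"no input sample paired with {og.sample_id}")
        inp = inputs[og.pair_id]
        scaled = inp.counts * ses_factors[og.pair_id]
        damage = subtract_input(og.counts, scaled) / lib_factors[og.sample_id]
        per_geno[og.genotype].append(damage)
    cols = {}
    for g in genotypes:
        if not per_geno[g]:
            raise ValueError(f"no OG samples for genotype {g}")
        cols[g] = np.mean(per_geno[g], axis=0)
    out = pd.DataFrame(cols, index=index)
    if zero_len:
        log.info("excluding %d genes with truncated (empty) promoters", len(zero_len))
        out = out.drop(index=zero_len)
    return out


def filter_present(
    og_matrix: pd.DataFrame, rna_matrix: pd.DataFrame, min_genotypes: int = 3
) -> pd.Index:
    """Genes with nonzero signal in >= min_genotypes genotypes in BOTH assays.

    Matrices are gene x genotype (already averaged over replicates).
    """
    common = og_matrix.index.intersection(rna_matrix.index)
    og_ok = (og_matrix.loc[common] > 0).sum(axis=1) >= min_genotypes
    rna_ok = (rna_matrix.loc[common] > 0).sum(axis=1) >= min_genotypes
    return common[og_ok & rna_ok]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores with sample sd (ddof=1); constant rows are dropped."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    if (~ok).any():
        log.info("excluding %d constant rows from z-scoring", int((~ok).sum()))
    z = (values[ok] - mean[ok]) / sd[ok]
    return pd.DataFrame(z, index=matrix.index[ok], columns=matrix.columns)


def _sign_class(og_z: np.ndarray, rna_z: np.ndarray, zero_tol: float = 0.2) -> str:
    """Per-gene sign-concordance class over genotypes.

    A genotype constrains the class only when both z-scores are clearly
    away from zero (|z| > zero_tol; with continuous data an exact zero is
    measure-null, so "no signal" is read as a small-magnitude band).
    Genes with fewer than (n_genotypes - 1) constrained genotypes are
    unclassified.
    """
    constrained = (np.abs(og_z) > zero_tol) & (np.abs(rna_z) > zero_tol)
    if constrained.sum() < len(og_z) - 1:
        return "unclassified"
    same = np.sign(og_z[constrained]) == np.sign(rna_z[constrained])
    if same.all():
        return "positive"
    if (~same).all():
        return "negative"
    return "unclassified"


def _dense_cores(
    Z, X: np.ndarray, raw: np.ndarray,
    min_size: int, min_classified_frac: float, consensus: float, min_enrichment: float,
) -> list:
    """Maximal dendrogram nodes that are sign-consistent *and* denser than
    the gene background.

    Walking the tree top-down, a node is selected when (a) it has at least
    ``min_size`` members, (b) at least ``min_classified_frac`` of them
    carry a sign-rule class, (c) at least ``consensus`` of the classified
    members share one class, and (d) the node holds ``min_enrichment``
    times more genes than an average ball of its own rms radius placed at
    a random gene (local density enrichment — chance sign-consistent
    clumps are locally uniform, reliably coupled gene groups are not).
    Selection stops descending below a selected node. Returns
    (class, centroid) pairs; the centroid averages the class-matching
    members only.
    """
    n = len(X)
    step = max(1, n // 400)
    probes = np.arange(0, n, step)  # deterministic probe subsample
    D = np.sqrt(((X[probes][:, None, :] - X[None, :, :]) ** 2).sum(-1))

    def background(radius: float) -> float:
        return max(float((D <= radius).sum(1).mean()), 1.0)

    cores: list = []

    def walk(node):
        leaves = np.array(node.pre_order(lambda x: x.id))
        sub = raw[leaves]
        n_pos = int((sub == "positive").sum())
        n_neg = int((sub == "negative").sum())
        tot = n_pos + n_neg
        cls = None
        if len(leaves) >= min_size and tot > 0 and tot / len(leaves) >= min_classified_frac:
            if n_pos / tot >= consensus:
                cls = "positive"
            elif n_neg / tot >= consensus:
                cls = "negative"
        if cls is not None:
            members = leaves[raw[leaves] == cls]
            centroid = X[members].mean(axis=0)
            rms = float(np.sqrt(((X[leaves] - centroid) ** 2).sum(1).mean()))
            if len(leaves) / background(rms) >= min_enrichment:
                cores.append((cls, centroid))
                return
        if not node.is_leaf():
            walk(node.left)
            walk(node.right)

    walk(to_tree(Z))
    return cores


def concordance_cluster(
    og_matrix: pd.DataFrame,
    rna_matrix: pd.DataFrame,
    k: int = 8,
    zero_tol: float = 0.2,
    cluster_consensus: float = 0.8,
    min_cluster_size: int = 40,
    min_classified_frac: float = 0.5,
    min_enrichment: float = 5.0,
    assign_radius: float = 1.3,
    require_cluster_support: bool = True,
) -> pd.DataFrame:
    """Classify genes by OG-expression concordance across genotypes.

    Both matrices (gene x genotype, filtered with :func:`filter_present`)
    are z-scored by row; each gene is embedded as the concatenation of its
    OG and RNA z-score rows and clustered hierarchically (Euclidean
    distance, average linkage). A gene's raw class follows the sign rule:
    positive when OG and RNA z-scores agree in sign in every constrained
    genotype, negative when they are opposite in every one (see
    :func:`_sign_class`).

    With 4 genotypes the sign rule alone passes ~1 in 7 unrelated genes
    by chance, so when ``require_cluster_support`` is set the final
    classification is restricted to reliably co-varying groups: dendrogram
    nodes that are sign-consistent and locally denser than background
    (:func:`_dense_cores`), plus raw-classified genes within
    ``assign_radius`` of a detected core centroid. Without cluster
    support the raw sign rule is reported as the classification.

    ``cluster`` is the flat ``k``-cluster cut of the same tree, kept for
    heatmap-style reporting; classification does not depend on ``k``.

    Returns a DataFrame with og_z_* and rna_z_* columns, ``cluster``,
    ``sign_class`` and ``classification``.
    """
    genes = og_matrix.index.intersection(rna_matrix.index)
    og_z = zscore_rows(og_matrix.loc[genes])
    rna_z = zscore_rows(rna_matrix.loc[genes])
    genes = og_z.index.intersection(rna_z.index)
    og_z, rna_z = og_z.loc[genes], rna_z.loc[genes]
    X = np.hstack([og_z.to_numpy(), rna_z.to_numpy()])
    if len(genes) < 2:
        raise ValueError("need at least two genes to cluster")
    Z = linkage(X, method="average", metric="euclidean")
    clusters = fcluster(Z, t=min(k, len(genes)), criterion="maxclust")

    sign_class = np.array(
        [
            _sign_class(og_z.iloc[i].to_numpy(), rna_z.iloc[i].to_numpy(), zero_tol)
            for i in range(len(genes))
        ]
    )
    if require_cluster_support:
        classification = np.full(len(genes), "unclassified", dtype=object)
        cores = _dense_cores(
            Z, X, sign_class,
            min_cluster_size, min_classified_frac, cluster_consensus, min_enrichment,
        )
        for cls, centroid in cores:
            dist = np.sqrt(((X - centroid) ** 2).sum(1))
            classification[(sign_class == cls) & (dist <= assign_radius)] = cls
    else:
        classification = sign_class.copy()

    out = pd.DataFrame(index=genes)
    for j, g in enumerate(og_z.columns):
        out[f"og_z_{g}"] = og_z.iloc[:, j]
    for j, g in enumerate(rna_z.columns):
        out[f"rna_z_{g}"] = rna_z.iloc[:, j]
    out["cluster"] = clusters
    out["sign_class"] = sign_class
    out["classification"] = classification
    return out


def der_deg_correlation(
    ders: pd.DataFrame,
    degs: pd.DataFrame,
    min_genes: int = 3,
) -> dict | None:
    """Correlate damage and expression fold changes over shared genes.

    ``ders`` needs columns ``gene``, ``log2FC`` and optionally
    ``feature_class``; ``degs`` is indexed by gene with a ``log2FC``
    column (both from the same KO-vs-WT contrast). Returns the paired
    fold-change table, the Pearson correlation, an average-linkage
    clustering of the paired vectors under the 1 - r distance, and
    per-feature-class overlap fractions (fraction of a class's DER genes
    that are DE-tested DEGs).
    """
    d = ders.dropna(subset=["gene"]).copy()
    d = d[np.isfinite(d["log2FC"])]
    d = d.groupby(["gene"] + (["feature_class"] if "feature_class" in d else []), as_index=False)[
        "log2FC"
    ].mean()
    merged = d.merge(
        degs[["log2FC"]].rename(columns={"log2FC": "rna_log2FC"}),
        left_on="gene",
        right_index=True,
        how="inner",
    ).rename(columns={"log2FC": "og_log2FC"})
    merged = merged[np.isfinite(merged["rna_log2FC"])]
    if len(merged) < min_genes:
        warnings.warn(f"only {len(merged)} overlapping genes: correlation skipped")
        return None
    r = float(np.corrcoef(merged["og_log2FC"], merged["rna_log2FC"])[0, 1])
    X = merged[["og_log2FC", "rna_log2FC"]].to_numpy()
    with np.errstate(invalid="ignore"):
        dist = pdist(X, metric="correlation") if X.shape[0] > 2 and X.shape[1] > 1 else None
    Z = linkage(dist, method="average") if dist is not None and np.isfinite(dist).all() else None
    overlaps = {}
    if "feature_class" in merged:
        deg_genes = set(degs.index[degs.get("is_deg", pd.Series(False, index=degs.index))])
        for cls, sub in d.groupby("feature_class"):
            genes = set(sub["gene"])
            overlaps[cls] = len(genes & deg_genes) / len(genes) if genes else np.nan
    return {"pairs": merged, "pearson_r": r, "linkage": Z, "overlap_by_class": overlaps}
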