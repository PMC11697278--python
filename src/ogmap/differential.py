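"""Two-group differential testing of region counts (OG-DERs, DEGs).

The test is a conditional negative-binomial exact test: group sums are
modelled as NB with a common dispersion estimated by method of moments
across regions, and the p-value sums the conditional probabilities of all
group-A sums at least as unlikely as the observed one given the total.
In the zero-dispersion limit this is exactly the conditional Poisson
(binomial) test. Fold changes come from normalization-factor-adjusted
group means with a pseudocount.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

#: relative slack when collecting outcomes no more likely than the observed
#: one (two-sided "minimum likelihood" rule, as in scipy's binomtest).
_REL_TOL = 1 + 1e-7


def filter_low_reads(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep regions whose total count across all samples is >= min_total."""
    return counts.loc[counts.sum(axis=1) >= min_total]


def estimate_dispersion(
    counts_a: np.ndarray, counts_b: np.ndarray,
    factors_a: np.ndarray, factors_b: np.ndarray,
) -> float:
    """Common NB dispersion by pooled method of moments.

    On factor-adjusted counts y/f, the within-group moment identity
    Var = mu + phi * mu^2 is solved in aggregate:
    phi = sum_g (n_g - 1)(v_g - m_g) / sum_g (n_g - 1) m_g^2, summed over
    regions and groups, clipped at 0.
    """
    num = 0.0
    den = 0.0
    for counts, factors in ((counts_a, factors_a), (counts_b, factors_b)):
        y = np.asarray(counts, dtype=float) / np.asarray(factors, dtype=float)
        n = y.shape[1]
        if n < 2:
            continue
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        num += ((n - 1) * (v - m)).sum()
        den += ((n - 1) * m**2).sum()
    if den <= 0:
        return 0.0
    return float(max(num / den, 0.0))


def _group_logpmf(x: np.ndarray, mean: float, n_samples: int, dispersion: float):
    """log pmf of a group sum: NB(total mean, dispersion/n) or Poisson."""
    if mean <= 0:
        out = np.full(len(x), -np.inf)
        out[x == 0] = 0.0
        return out
    if dispersion < 1e-10:
        return stats.poisson.logpmf(x, mean)
    size = n_samples / dispersion  # sum of n iid NB(mu, phi) is NB(n*mu, phi/n)
    p = size / (size + mean)
    return stats.nbinom.logpmf(x, size, p)


def nb_exact_test_single(
    a: np.ndarray, b: np.ndarray,
    factors_a: np.ndarray, factors_b: np.ndarray,
    dispersion: float,
    pseudocount: float = 0.5,
    max_total: int = 500_000,
) -> tuple[float, float]:
    """(log2FC, p) for one region.

    log2FC compares factor-adjusted group means (A over B) with the
    pseudocount; a group whose raw sum is zero yields a +/-inf sentinel.
    The p-value conditions on the total of the two group sums.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fa = np.asarray(factors_a, dtype=float)
    fb = np.asarray(factors_b, dtype=float)
    sa, sb = int(round(a.sum())), int(round(b.sum()))
    mean_a = (a / fa).mean()
    mean_b = (b / fb).mean()
    if sa == 0:
        lfc = -np.inf if sb > 0 else 0.0
    elif sb == 0:
        lfc = np.inf
    else:
        lfc = float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))

    s = sa + sb
    if s == 0:
        return lfc, 1.0
    fa_tot, fb_tot = fa.sum(), fb.sum()
    mu = s / (fa_tot + fb_tot)  # per-unit-factor mean under the null
    if s > max_total:
        # normal approximation to the conditional distribution for very
        # deep regions; two-sided via the z statistic
        va = mu * fa_tot * (1 + dispersion * mu * fa_tot / len(a))
        vb = mu * fb_tot * (1 + dispersion * mu * fb_tot / len(b))
        z = (sa - mu * fa_tot) / np.sqrt(va * vb / (va + vb) + 1e-300)
        return lfc, float(2 * stats.norm.sf(abs(z)))
    x = np.arange(s + 1)
    la = _group_logpmf(x, mu * fa_tot, len(a), dispersion)
    lb = _group_logpmf(x[::-1], mu * fb_tot, len(b), dispersion)
    joint = la + lb
    norm = logsumexp(joint)
    obs = joint[sa]
    keep = joint <= obs + np.log(_REL_TOL)
    p = float(np.exp(logsumexp(joint[keep]) - norm))
    return lfc, min(p, 1.0)


def nb_test(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    factors_a: np.ndarray,
    factors_b: np.ndarray,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Region-wise NB exact test of group A vs group B.

    Rows of ``counts_a``/``counts_b`` are regions, columns samples.
    ``dispersion`` defaults to the pooled method-of-moments estimate over
    all regions. Returns a DataFrame with ``log2FC`` and ``p_value``.
    """
    index = counts_a.index if isinstance(counts_a, pd.DataFrame) else None
    A = np.asarray(counts_a, dtype=float)
    B = np.asarray(counts_b, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
        B = B[None, :]
    if A.shape[0] != B.shape[0]:
        raise ValueError("groups must cover the same regions")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("need at least two samples per group")
    fa = np.asarray(factors_a, dtype=float)
    fb = np.asarray(factors_b, dtype=float)
    if dispersion is None:
        dispersion = estimate_dispersion(A, B, fa, fb)
    out = np.empty((A.shape[0], 2))
    for i in range(A.shape[0]):
        out[i] = nb_exact_test_single(A[i], B[i], fa, fb, dispersion, pseudocount)
    res = pd.DataFrame(out, columns=["log2FC", "p_value"], index=index)
    res.attrs["dispersion"] = dispersion
    return res


def call_ders(
    results: pd.DataFrame,
    p_max: float = 0.01,
    min_abs_lfc: float = 0.5,
) -> pd.DataFrame:
    """Flag differentially enriched regions and add direction + FDR.

    A region passes at p <= p_max (inclusive) and |log2FC| strictly
    greater than ``min_abs_lfc``. ``direction`` is gain for positive and
    loss for negative fold changes. A Benjamini-Hochberg FDR column is
    emitted for transparency but does not gate the call.
    """
    out = results.copy()
    lfc = out["log2FC"].to_numpy()
    p = out["p_value"].to_numpy()
    out["passes"] = (p <= p_max) & (np.abs(lfc) > min_abs_lfc)
    out["direction"] = np.where(lfc > 0, "gain", "loss")
    m = len(p)
    if m:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr = np.empty(m)
        fdr[order] = np.minimum(fdr_sorted, 1.0)
        out["fdr"] = fdr
    return out


def der_summary(ders: pd.DataFrame, by: str = "feature_class") -> pd.DataFrame:
    """Percent of regions affected per feature class with gain/loss split."""
    rows = []
    for cls, sub in ders.groupby(by, sort=False):
        n = len(sub)
        hit = sub[sub["passes"]]
        rows.append(
            {
                by: cls,
                "n_regions": n,
                "n_der": len(hit),
                "pct_affected": 100.0 * len(hit) / n if n else np.nan,
                "n_gain": int((hit["direction"] == "gain").sum()),
                "n_loss": int((hit["direction"] == "loss").sum()),
            }
        )
    return pd.DataFrame(rows)
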