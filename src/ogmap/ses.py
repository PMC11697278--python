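"""Signal extraction scaling (SES) normalization of pulldown vs input.

SES separates binned counts into background (shared between pulldown and
input) and signal (pulldown-specific) by ranking bins by pulldown
intensity and finding the split that maximizes the gap between the
cumulative input fraction and the cumulative pulldown fraction. The input
library is then rescaled using background bins only, so that genuine
enrichment does not deflate the normalization factor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SESResult:
    """Outcome of an SES fit for one pulldown/input pair.

    Attributes
    ----------
    order : ndarray
        permutation sorting bins ascending by pulldown count (ties broken
        by input count, then original position).
    split_index : int
        k* in 1..n — the number of lowest-ranked bins treated as background.
    input_scale_factor : float
        multiplier applied to input counts (background pulldown mass over
        background input mass).
    background_mask : ndarray of bool
        True for bins (in original order) in the background set.
    """

    order: np.ndarray
    split_index: int
    input_scale_factor: float
    background_mask: np.ndarray

    def scale_input(self, input_counts: np.ndarray) -> np.ndarray:
        return np.asarray(input_counts, dtype=float) * self.input_scale_factor


def ses_fit(og: np.ndarray, input_: np.ndarray) -> SESResult:
    """Fit the SES background split and input scale factor.

    Bins are sorted ascending by OG count; with p_k the cumulative input
    fraction and q_k the cumulative OG fraction over the first k sorted
    bins, the background is the first k* bins where k* is the smallest
    argmax of (p_k - q_k). The factor is the OG/input mass ratio over the
    background. Degenerate inputs (all OG counts equal, or p - q never
    positive) fall back to the global ratio with a warning.
    """
    og = np.asarray(og, dtype=float)
    inp = np.asarray(input_, dtype=float)
    if og.shape != inp.shape:
        raise ValueError("OG and input vectors must be the same length")
    n = len(og)
    if n == 0:
        raise ValueError("empty count vectors")
    tot_og, tot_in = og.sum(), inp.sum()
    if tot_og <= 0 or tot_in <= 0:
        raise ValueError("both libraries need positive total counts")

    order = np.lexsort((np.arange(n), inp, og))
    if np.all(og == og[0]):
        warnings.warn("all OG counts equal: no separable signal, using global ratio")
        mask = np.ones(n, dtype=bool)
        return SESResult(order, n, tot_og / tot_in, mask)

    q = np.cumsum(og[order]) / tot_og
    p = np.cumsum(inp[order]) / tot_in
    diff = p - q
    k_star = int(np.argmax(diff)) + 1  # smallest argmax (argmax returns first)
    if diff[k_star - 1] <= 0:
        warnings.warn("cumulative input never exceeds OG: using global ratio")
        mask = np.ones(n, dtype=bool)
        return SESResult(order, n, tot_og / tot_in, mask)

    bg = order[:k_star]
    bg_in = inp[bg].sum()
    factor = og[bg].sum() / bg_in if bg_in > 0 else tot_og / tot_in
    mask = np.zeros(n, dtype=bool)
    mask[bg] = True
    return SESResult(order, k_star, float(factor), mask)


def library_factors(library_sizes: dict) -> dict:
    """Per-sample library factors: size_i / mean(all sizes).

    These are the fixed normalization factors used by the differential
    tests; their arithmetic mean is exactly 1.
    """
    if len(library_sizes) < 2:
        raise ValueError("need at least two samples")
    sizes = np.array(list(library_sizes.values()), dtype=float)
    if (sizes <= 0).any():
        zero = [k for k, v in library_sizes.items() if v <= 0]
        raise ValueError(f"zero library size for sample(s): {zero}")
    mean = sizes.mean()
    return {k: float(v / mean) for k, v in library_sizes.items()}


def subtract_input(og: np.ndarray, scaled_input: np.ndarray) -> np.ndarray:
    """Floored subtraction: max(og - scaled_input, 0) element-wise."""
    og = np.asarray(og, dtype=float)
    scaled = np.asarray(scaled_input, dtype=float)
    if og.shape != scaled.shape:
        raise ValueError("vectors must align")
    return np.maximum(og - scaled, 0.0)
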