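"""Supervised entropy-based discretization with the MDL stopping criterion.

Recursive binary splitting of a continuous attribute: at each step the cut
point minimizing the class-entropy of the induced partition is chosen among
boundary points (midpoints between adjacent sorted values whose class
composition differs), and accepted only if the information gain exceeds the
minimum-description-length cost of encoding the split.  Attributes for
which no split is accepted end up with a single bin, i.e. carry no usable
class information for the correlation measures built on top.
"""

from __future__ import annotations

import numpy as np


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def _best_cut(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Best boundary cut of a sorted block, or None.

    Returns (cut_value, gain, stats needed by the MDL test).
    """
    n = len(x)
    counts_total = _class_counts(y, n_classes)
    ent_total = _entropy(counts_total)
    # prefix class counts
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    prefix = np.cumsum(onehot, axis=0)
    # candidate positions: value changes AND (class mixture changes across the gap)
    diff_val = x[1:] != x[:-1]
    idx = np.nonzero(diff_val)[0]  # cut between position i and i+1
    if len(idx) == 0:
        return None
    best = None
    for i in idx:
        left = prefix[i]
        right = counts_total - left
        ent = (left.sum() * _entropy(left) + right.sum() * _entropy(right)) / n
        if best is None or ent < best[1] - 1e-15:
            best = (i, ent, left, right)
    i, ent, left, right = best
    gain = ent_total - ent
    k = int((counts_total > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = np.log2(3.0 ** k - 2.0) - (k * ent_total
                                       - k1 * _entropy(left) - k2 * _entropy(right))
    threshold = (np.log2(n - 1) + delta) / n
    if gain <= threshold:
        return None
    cut = (x[i] + x[i + 1]) / 2.0
    return cut, i


def mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """All accepted cut points for one attribute (ascending).

    ``labels`` must be integer class codes; rows with non-finite values are
    the caller's responsibility to exclude.
    """
    order = np.argsort(values, kind="mergesort")
    x = np.asarray(values, float)[order]
    y = np.asarray(labels)[order]
    n_classes = int(y.max()) + 1 if len(y) else 0
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        res = _best_cut(x[lo:hi], y[lo:hi], n_classes)
        if res is None:
            return
        cut, i = res
        cuts.append(cut)
        recurse(lo, lo + i + 1)
        recurse(lo + i + 1, hi)

    if len(x):
        recurse(0, len(x))
    return sorted(cuts)


def apply_cut_points(values: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Bin indices (0..len(cuts)); NaN maps to -1."""
    out = np.searchsorted(np.asarray(cuts, float), values, side="right").astype(int)
    out[~np.isfinite(values)] = -1
    return out
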