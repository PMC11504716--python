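"""Correlation-based feature subset selection (CFS) and attribute importance.

CFS scores a subset S of k attributes by the merit

    merit(S) = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff))

where r_cf is the attribute-class correlation and r_ff the attribute-
attribute correlation, both measured as symmetrical uncertainty

    SU(X, Y) = 2 * I(X; Y) / (H(X) + H(Y))            in [0, 1]

over MDL-discretized attributes; mean(r_ff) runs over the unordered pairs
within S.  High merit means individually predictive, mutually
non-redundant attributes.

The best subset is searched with a forward best-first search: start from
the empty set, expand states by single-attribute additions, keep all open
states in a priority queue, and stop after a fixed number of consecutive
expansions that fail to improve the best merit found (the backtracking
"stale" limit, default 5).  Ties are broken toward the lower attribute
registry index, making the search deterministic.

:func:`repeated_selection` applies the search to the training side of each
partition of a repeated stratified k-fold plan (default 10 x 5 = 50 runs)
and reports each attribute's selection frequency in [0, 1] — the attribute
importance (AI) — plus nested subsets at configurable AI thresholds.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .discretize import apply_cut_points, mdl_cut_points

DEFAULT_THRESHOLDS = (">0", ">=0.1", ">=0.3", ">=0.4", ">=0.6", ">=0.9", "=1")


@dataclass
class CfsModel:
    """Precomputed correlations for CFS merit evaluation."""

    attributes: list[str]
    feature_class: np.ndarray        # r_cf per attribute, in [0, 1]
    feature_feature: np.ndarray      # symmetric r_ff matrix, zero diagonal
    cut_points: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.attributes)
        assert self.feature_class.shape == (k,)
        assert self.feature_feature.shape == (k, k)


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU between two integer-coded variables; pairs with a -1 code are skipped."""
    keep = (x >= 0) & (y >= 0)
    x, y = x[keep], y[keep]
    if len(x) == 0:
        return 0.0
    joint = pd.crosstab(x, y).to_numpy().astype(float)
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    pj = joint[joint > 0] / n
    hxy = float(-(pj * np.log2(pj)).sum())
    denom = hx + hy
    if denom <= 0.0:
        return 0.0
    return max(0.0, 2.0 * (hx + hy - hxy) / denom)


def build_cfs_model(frame: pd.DataFrame, labels: pd.Series | np.ndarray) -> CfsModel:
    """Discretize attributes (MDL) and compute the SU correlation structure.

    Missing cells are excluded pairwise.  Attributes the discretizer leaves
    with a single bin get r_cf = 0 (warned): they carry no class information
    at the resolution the MDL criterion accepts.
    """
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to build a CFS model")
    y = np.searchsorted(classes, y_raw)
    attrs = list(frame.columns)
    coded = np.empty((len(frame), len(attrs)), dtype=int)
    cut_points: dict[str, list[float]] = {}
    for j, a in enumerate(attrs):
        col = frame[a].to_numpy(dtype=float)
        ok = np.isfinite(col)
        cuts = mdl_cut_points(col[ok], y[ok]) if ok.any() else []
        cut_points[a] = cuts
        if not cuts:
            warnings.warn(f"attribute {a!r}: no MDL split accepted; r_cf = 0",
                          stacklevel=2)
        coded[:, j] = apply_cut_points(col, cuts)
    k = len(attrs)
    r_cf = np.array([symmetrical_uncertainty(coded[:, j], y) for j in range(k)])
    r_ff = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r_ff[i, j] = r_ff[j, i] = symmetrical_uncertainty(coded[:, i], coded[:, j])
    return CfsModel(attrs, r_cf, r_ff, cut_points)


def cfs_merit(subset, model: CfsModel) -> float:
    """Merit of a subset given by attribute indices or names."""
    idx = np.asarray([model.attributes.index(a) if isinstance(a, str) else int(a)
                      for a in subset], dtype=int)
    k = len(idx)
    if k == 0:
        raise ValueError("merit of an empty subset is undefined")
    rcf = float(model.feature_class[idx].mean())
    if k == 1:
        return rcf
    sub = model.feature_feature[np.ix_(idx, idx)]
    rff = float(sub[np.triu_indices(k, 1)].mean())
    return k * rcf / float(np.sqrt(k + k * (k - 1) * rff))


def best_first_search(
    model: CfsModel, stale_limit: int = 5
) -> tuple[tuple[int, ...], float]:
    """Forward best-first search for the highest-merit subset.

    Returns (attribute indices in registry order, merit).  Expansion order
    and the priority queue are tie-broken by insertion order, which itself
    follows registry order, so the result is deterministic.
    """
    n = len(model.attributes)
    if n == 0:
        raise ValueError("model has no attributes")
    counter = 0
    start: tuple[int, ...] = ()
    open_heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, counter, start)]
    visited: set[tuple[int, ...]] = {start}
    best_subset: tuple[int, ...] = start
    best_merit = -np.inf
    stale = 0
    while open_heap and stale < stale_limit:
        neg_merit, _, subset = heapq.heappop(open_heap)
        improved = False
        for j in range(n):
            if j in subset:
                continue
            child = tuple(sorted(subset + (j,)))
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(child, model)
            counter += 1
            heapq.heappush(open_heap, (-merit, counter, child))
            if merit > best_merit + 1e-10:
                best_merit, best_subset = merit, child
                improved = True
        if improved:
            stale = 0
        else:
            stale += 1
    if not best_subset and n:
        # degenerate: all merits non-positive; fall back to best singleton
        best_subset = (int(np.argmax(model.feature_class)),)
        best_merit = cfs_merit(best_subset, model)
    return best_subset, best_merit


@dataclass
class AttributeImportance:
    """Per-attribute selection frequency over the repeated selection runs."""

    frequencies: pd.Series          # attribute -> selections / total_runs
    total_runs: int
    subsets: dict[str, list[str]]   # threshold label -> attribute list

    def counts(self) -> pd.Series:
        return (self.frequencies * self.total_runs).round().astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies, "count": self.counts()})


def threshold_mask(freq: pd.Series, label: str) -> pd.Series:
    if label.startswith(">="):
        return freq >= float(label[2:]) - 1e-12
    if label.startswith(">"):
        return freq > float(label[1:]) + 1e-12 if float(label[1:]) else freq > 0
    if label.startswith("="):
        return (freq - float(label[1:])).abs() <= 1e-12
    raise ValueError(f"unrecognized threshold label {label!r}")


def repeated_selection(
    frame: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    thresholds: tuple[str, ...] = DEFAULT_THRESHOLDS,
    stale_limit: int = 5,
) -> AttributeImportance:
    """CFS + best-first over every training partition; frequency per attribute.

    Each of ``repeats`` stratified ``folds``-fold splits contributes
    ``folds`` training partitions (each holding (folds-1)/folds of the
    examples); selection counts are divided by the ``repeats * folds`` runs.
    Randomness enters only through the fold assignment.
    """
    y = np.asarray(labels)
    counts = pd.Series(0, index=frame.columns, dtype=int)
    total = 0
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for train_idx, _test_idx in splitter.split(frame, y):
            with warnings.catch_warnings():
                # uninformative attributes are expected across many runs
                warnings.filterwarnings("ignore", message=".*no MDL split accepted.*")
                model = build_cfs_model(frame.iloc[train_idx], y[train_idx])
            subset, _ = best_first_search(model, stale_limit=stale_limit)
            for j in subset:
                counts[model.attributes[j]] += 1
            total += 1
    freq = counts / total
    subsets = {label: list(freq.index[threshold_mask(freq, label)]) for label in thresholds}
    return AttributeImportance(freq, total, subsets)
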