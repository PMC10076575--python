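"""Correlation-based feature-subset selection (CFS) with best-first search.

The merit of a feature subset S with |S| = k is

    merit(S) = k * r_cf / sqrt(k + k*(k-1) * r_ff)

where ``r_cf`` is the mean absolute feature-class correlation over S and
``r_ff`` the mean absolute pairwise feature-feature correlation.  A good
subset is strongly correlated with the class while its members are
mutually uncorrelated.  Correlations are absolute Pearson coefficients;
against the binary class this is the point-biserial correlation.
Constant features have all their correlations defined as 0.

The search is forward best-first: starting from the empty set, states
(subsets) are kept in a priority queue ordered by merit; the best open
state is expanded by adding each unused feature; the search stops after a
configurable number of consecutive expansions that fail to improve the
best merit found.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import _as_binary
from .lb_features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Best-first search settings.

    ``max_stale_expansions``: consecutive non-improving node expansions
    after which the search terminates (default 5).
    """

    max_stale_expansions: int = 5
    correlation_measure: str = "pearson_point_biserial"
    direction: str = "forward"

    def __post_init__(self):
        if self.max_stale_expansions < 1:
            raise ValueError("max_stale_expansions must be >= 1")
        if self.correlation_measure != "pearson_point_biserial":
            raise ValueError(
                f"unknown correlation measure {self.correlation_measure!r}"
            )
        if self.direction != "forward":
            raise ValueError(f"unsupported search direction {self.direction!r}")


def _feature_frame(features) -> pd.DataFrame:
    if isinstance(features, FeatureMatrix):
        return features.values
    return features


def _standardize(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns; constant columns become all-zero
    so every correlation involving them is 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = X - mu
    nz = sd > 0
    Z[:, nz] /= sd[nz]
    Z[:, ~nz] = 0.0
    return Z


def _class_vector(labels) -> np.ndarray:
    y = _as_binary(labels).astype(float)
    sd = y.std()
    if sd == 0:
        return np.zeros_like(y)
    return (y - y.mean()) / sd


def cfs_merit(subset: Sequence[str], features, labels) -> float:
    """CFS merit of a named feature subset.

    For a singleton the formula reduces to the absolute feature-class
    correlation.  Raises on an empty subset.
    """
    names = list(subset)
    if not names:
        raise ValueError("cfs_merit of an empty subset is undefined")
    df = _feature_frame(features)
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise KeyError(f"unknown features: {missing[:5]}")
    Z = _standardize(df[names].to_numpy(dtype=float))
    y = _class_vector(labels)
    n = len(y)
    r_cf = np.abs(Z.T @ y) / n
    k = len(names)
    sum_rcf = float(r_cf.sum())
    if k == 1:
        return sum_rcf
    corr = np.abs(Z.T @ Z) / n
    sum_rff = float((corr.sum() - np.trace(corr)) / 2.0)
    return _merit_from_sums(k, sum_rcf, sum_rff)


def _merit_from_sums(k: int, sum_rcf: float, sum_rff) -> float:
    """merit = k*mean_rcf / sqrt(k + k(k-1)*mean_rff), expressed through
    the raw sums: sum_rcf / sqrt(k + 2*sum_rff)."""
    return sum_rcf / np.sqrt(k + 2.0 * np.asarray(sum_rff, dtype=float))


def best_first_select(
    features, labels, config: SelectionConfig = SelectionConfig()
) -> list[str]:
    """Forward best-first search over feature subsets scored by CFS merit.

    Deterministic: candidate features are processed in lexicographic name
    order and queue ties are broken the same way.  Returns the best-merit
    subset found, as a name list in lexicographic order.  If no feature
    carries any class correlation (e.g. all features constant), an empty
    list is returned with a warning.
    """
    df = _feature_frame(features)
    if df.shape[1] < 1:
        raise ValueError("need at least one feature")
    # lexicographic name order fixes determinism and makes the result
    # invariant to input column permutation
    names = sorted(map(str, df.columns))
    Z = _standardize(df[names].to_numpy(dtype=float))
    y = _class_vector(labels)
    n, F = Z.shape
    r_cf = np.abs(Z.T @ y) / n

    if float(r_cf.max(initial=0.0)) <= 0.0:
        warnings.warn("no feature correlates with the class; empty selection")
        return []

    eps = 1e-12
    # state: (negative merit, member index tuple, sum_rcf, sum_rff)
    open_heap: list[tuple[float, tuple[int, ...], float, float]] = [
        (0.0, (), 0.0, 0.0)
    ]
    closed: set[tuple[int, ...]] = set()
    best_merit = 0.0
    best_subset: tuple[int, ...] = ()
    stale = 0

    while open_heap and stale < config.max_stale_expansions:
        neg_merit, members, sum_rcf, sum_rff = heapq.heappop(open_heap)
        if members in closed:
            continue
        closed.add(members)

        k = len(members)
        member_mask = np.zeros(F, dtype=bool)
        member_mask[list(members)] = True
        if k:
            # |corr| of every feature with each current member, via one matmul
            cross = np.abs(Z.T @ Z[:, list(members)]) / n  # (F, k)
            cross_sum = cross.sum(axis=1)
        else:
            cross_sum = np.zeros(F)

        improved = False
        for j in np.flatnonzero(~member_mask):
            child = tuple(sorted(members + (int(j),)))
            if child in closed:
                continue
            c_sum_rcf = sum_rcf + float(r_cf[j])
            c_sum_rff = sum_rff + float(cross_sum[j])
            merit = float(_merit_from_sums(k + 1, c_sum_rcf, c_sum_rff))
            heapq.heappush(open_heap, (-merit, child, c_sum_rcf, c_sum_rff))
            if merit > best_merit + eps:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1

    return [names[i] for i in best_subset]


def write_selection(names: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(names) + ("\n" if names else ""))


def read_selection(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
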