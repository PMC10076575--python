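"""Applicability domain (AD) assessment by a four-method consensus.

A prediction is trusted only for compounds that resemble the training
data.  Four complementary criteria are evaluated per test compound:

1. **similarity** — nearest-neighbor Tanimoto on ECFP6-style 1024-bit
   fingerprints strictly greater than a cutoff (default 0.7);
2. **range** — the compound's first two standardized PCA scores fall
   inside the training min/max box (closed intervals);
3. **Euclidean distance** — distance to the training centroid in
   standardized descriptor space no greater than a training-distance
   percentile (default 95th);
4. **probability density** — Gaussian-kernel density (estimated on the
   first few PCA components) at least the cutoff that covers a given
   fraction of training points (default 95%).

The consensus verdict is positive when at least ``min_methods`` (default
3) of the four criteria hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .lb_features import PCAResult, bulk_tanimoto, chemspace_pca

N_RANGE_COMPONENTS = 2
N_DENSITY_COMPONENTS = 5


@dataclass(frozen=True)
class ADThresholds:
    similarity_cutoff: float = 0.7
    distance_percentile: float = 95.0
    density_coverage: float = 95.0
    min_methods: int = 3

    def __post_init__(self):
        if not (1 <= self.min_methods <= 4):
            raise ValueError("min_methods must be in 1..4")
        if not (0 < self.distance_percentile <= 100):
            raise ValueError("distance_percentile must be in (0, 100]")
        if not (0 < self.density_coverage <= 100):
            raise ValueError("density_coverage must be in (0, 100]")


@dataclass
class ADVerdict:
    """Per-compound outcome of the four AD criteria and their consensus."""

    similarity_ok: bool
    range_ok: bool
    euclidean_ok: bool
    density_ok: bool
    consensus_ok: bool
    nearest_neighbor_tc: float

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.similarity_ok, self.range_ok, self.euclidean_ok, self.density_ok)


@dataclass
class ADReference:
    """Training-set statistics backing the four AD criteria."""

    training_fingerprints: np.ndarray
    pca: PCAResult
    range_low: np.ndarray
    range_high: np.ndarray
    centroid: np.ndarray
    distance_threshold: float
    kde: gaussian_kde
    density_threshold: float
    descriptor_columns: list[str]
    thresholds: ADThresholds = field(default_factory=ADThresholds)


def fit_ad_reference(
    training_fingerprints: np.ndarray,
    training_descriptors: pd.DataFrame,
    thresholds: ADThresholds = ADThresholds(),
) -> ADReference:
    """Fit all four AD criteria on the training set.

    ``training_descriptors`` is the descriptor table the model space is
    defined in (typically the chemical-space panel); it is standardized
    internally and decomposed once, with the range box on the first two
    components and the kernel density on the first five (fewer if the
    panel is smaller), using the default bandwidth plug-in rule.
    """
    fps = np.asarray(training_fingerprints).astype(bool)
    if fps.ndim != 2 or len(fps) == 0:
        raise ValueError("training fingerprints must be a non-empty matrix")
    n_comp = min(N_DENSITY_COMPONENTS, training_descriptors.shape[1], len(training_descriptors))
    pca = chemspace_pca(training_descriptors, n_components=n_comp)
    scores = pca.scores.to_numpy()

    k = min(N_RANGE_COMPONENTS, scores.shape[1])
    range_low = scores[:, :k].min(axis=0)
    range_high = scores[:, :k].max(axis=0)

    Z = pca.scaler.transform(training_descriptors[pca.columns].to_numpy())
    centroid = Z.mean(axis=0)
    train_dist = np.linalg.norm(Z - centroid, axis=1)
    distance_threshold = float(
        np.percentile(train_dist, thresholds.distance_percentile)
    )

    kde = gaussian_kde(scores.T)
    train_density = kde(scores.T)
    density_threshold = float(
        np.percentile(train_density, 100.0 - thresholds.density_coverage)
    )

    return ADReference(
        training_fingerprints=fps,
        pca=pca,
        range_low=range_low,
        range_high=range_high,
        centroid=centroid,
        distance_threshold=distance_threshold,
        kde=kde,
        density_threshold=density_threshold,
        descriptor_columns=list(pca.columns),
        thresholds=thresholds,
    )


def ad_similarity(
    fingerprint: np.ndarray, reference: ADReference
) -> tuple[bool, float]:
    """Inside iff the max Tanimoto to any training fingerprint is
    strictly greater than the cutoff.  Returns (verdict, nearest Tc)."""
    if len(reference.training_fingerprints) == 0:
        raise ValueError("empty training fingerprint set")
    nn = float(bulk_tanimoto(fingerprint, reference.training_fingerprints).max())
    return nn > reference.thresholds.similarity_cutoff, nn


def _pca_scores(descriptor_row: pd.DataFrame | pd.Series, reference: ADReference) -> np.ndarray:
    if isinstance(descriptor_row, pd.Series):
        descriptor_row = descriptor_row.to_frame().T
    return reference.pca.transform(descriptor_row)


def ad_range(descriptor_row, reference: ADReference) -> bool:
    """Inside iff the first two standardized PCA scores lie within the
    training [min, max] box (boundary inclusive)."""
    scores = _pca_scores(descriptor_row, reference)[0]
    k = len(reference.range_low)
    return bool(
        np.all(scores[:k] >= reference.range_low)
        and np.all(scores[:k] <= reference.range_high)
    )


def ad_euclidean(descriptor_row, reference: ADReference) -> bool:
    """Inside iff the standardized-space distance to the training centroid
    does not exceed the fitted percentile threshold."""
    if isinstance(descriptor_row, pd.Series):
        descriptor_row = descriptor_row.to_frame().T
    z = reference.pca.scaler.transform(
        descriptor_row[reference.descriptor_columns].to_numpy()
    )[0]
    return bool(np.linalg.norm(z - reference.centroid) <= reference.distance_threshold)


def ad_density(descriptor_row, reference: ADReference) -> bool:
    """Inside iff the kernel-density estimate at the compound's PCA
    coordinates reaches the training-coverage cutoff."""
    scores = _pca_scores(descriptor_row, reference)[0]
    dens = float(reference.kde(scores.reshape(-1, 1))[0])
    return dens >= reference.density_threshold


def ad_consensus(flags: Sequence[bool], min_methods: int = 3) -> bool:
    """Inside the domain iff at least ``min_methods`` of the four
    criteria hold."""
    if len(flags) != 4:
        raise ValueError(f"expected exactly 4 method flags, got {len(flags)}")
    return int(np.sum(np.asarray(flags, dtype=bool))) >= min_methods


def assess(
    fingerprints: np.ndarray,
    descriptors: pd.DataFrame,
    reference: ADReference,
) -> list[ADVerdict]:
    """Evaluate all four criteria and the consensus for each compound."""
    fps = np.asarray(fingerprints)
    if len(fps) != len(descriptors):
        raise ValueError("fingerprint / descriptor row count mismatch")
    scores = reference.pca.transform(descriptors)
    Z = reference.pca.scaler.transform(
        descriptors[reference.descriptor_columns].to_numpy()
    )
    dist = np.linalg.norm(Z - reference.centroid, axis=1)
    dens = reference.kde(scores.T)
    k = len(reference.range_low)
    verdicts = []
    for i in range(len(fps)):
        sim_ok, nn = ad_similarity(fps[i], reference)
        rng_ok = bool(
            np.all(scores[i, :k] >= reference.range_low)
            and np.all(scores[i, :k] <= reference.range_high)
        )
        euc_ok = bool(dist[i] <= reference.distance_threshold)
        den_ok = bool(dens[i] >= reference.density_threshold)
        flags = (sim_ok, rng_ok, euc_ok, den_ok)
        verdicts.append(
            ADVerdict(
                *flags,
                consensus_ok=ad_consensus(flags, reference.thresholds.min_methods),
                nearest_neighbor_tc=nn,
            )
        )
    return verdicts


def verdicts_to_frame(verdicts: Sequence[ADVerdict], index=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "similarity_ok": [v.similarity_ok for v in verdicts],
            "range_ok": [v.range_ok for v in verdicts],
            "euclidean_ok": [v.euclidean_ok for v in verdicts],
            "density_ok": [v.density_ok for v in verdicts],
            "consensus_ok": [v.consensus_ok for v in verdicts],
            "nearest_neighbor_tc": [v.nearest_neighbor_tc for v in verdicts],
        },
        index=index,
    )


def trend_report(
    nearest_neighbor_tc: Sequence[float],
    truth: Sequence,
    predicted: Sequence,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Accuracy binned by nearest-neighbor Tanimoto to the training set.

    Bins cover [0, 1] with the given width (the last bin is closed at 1).
    Empty bins are reported with ``n=0`` and ``accuracy=NaN``.
    """
    tc = np.asarray(nearest_neighbor_tc, dtype=float)
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if not (len(tc) == len(t) == len(p)):
        raise ValueError("input lengths differ")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    rows = []
    correct = t == p
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi >= 1.0 - 1e-12
        mask = (tc >= lo) & ((tc <= hi) if last else (tc < hi))
        n = int(mask.sum())
        acc = float(correct[mask].mean()) if n else float("nan")
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "bin_mid": (lo + hi) / 2,
                "n": n,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)
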