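"""Bag-of-visual-words features: k-means vocabulary, histogram encoding,
chi-square feature scoring and top-k selection.

A vocabulary is k centroids (default k=100) clustered from the pooled
training-split descriptors; each image becomes a length-k histogram of
nearest-word assignments.  Binary ORB descriptors are unpacked to 0/1
vectors before clustering so centroids live in the same real-valued
space for both methods.  Chi-square scores each histogram column against
the class labels (class-wise column mass vs the mass expected under
label independence), and selection keeps the top-scoring columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .exceptions import EncodingError, ScoringError, SelectionError, VocabularyError
from .keypoints import DescriptorSet

__all__ = [
    "Vocabulary",
    "FeatureTable",
    "Chi2Result",
    "build_vocabulary",
    "encode",
    "encode_table",
    "chi2_score",
    "select_top_k",
]


@dataclass(frozen=True)
class Vocabulary:
    """k visual words (k-means centroids) in descriptor space."""

    centroids: np.ndarray
    method: str
    k: int
    seed: int
    training_hash: str

    @property
    def width(self) -> int:
        return int(self.centroids.shape[1])

    def save(self, directory: str | Path) -> Path:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / f"vocab_{self.method}.csv", self.centroids, delimiter=",")
        meta = {"method": self.method, "k": self.k, "seed": self.seed, "training_hash": self.training_hash}
        (directory / f"vocab_{self.method}.json").write_text(json.dumps(meta, indent=2))
        return directory / f"vocab_{self.method}.csv"


@dataclass(frozen=True)
class FeatureTable:
    """Per-image BoW histograms with labels.

    ``rows`` is (n_images, n_features); ``normalization`` is "count"
    (rows sum to the image's descriptor count) or "frequency"
    (L1-normalized; an image with no keypoints keeps an all-zero row).
    ``groups`` carries the source-signal id per row so splits can keep
    all epochs of a signal together.
    """

    rows: np.ndarray
    labels: np.ndarray
    normalization: str = "frequency"
    image_ids: tuple[str, ...] | None = None
    groups: np.ndarray | None = None
    selected_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "labels", labels)
        if rows.ndim != 2 or labels.shape[0] != rows.shape[0]:
            raise EncodingError("labels and histogram rows disagree in length")
        if np.any(rows < 0):
            raise EncodingError("histogram entries must be nonnegative")

    @property
    def n_features(self) -> int:
        return int(self.rows.shape[1])

    def __len__(self) -> int:
        return int(self.rows.shape[0])

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return replace(
            self,
            rows=self.rows[idx],
            labels=self.labels[idx],
            image_ids=tuple(np.asarray(self.image_ids, dtype=object)[idx]) if self.image_ids else None,
            groups=self.groups[idx] if self.groups is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"word_{i:03d}" for i in range(self.n_features)]
        df = pd.DataFrame(self.rows, columns=cols)
        df["label"] = self.labels
        if self.image_ids is not None:
            df["image_id"] = list(self.image_ids)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class Chi2Result:
    """Per-feature chi-square statistics against the labels."""

    scores: np.ndarray
    p_values: np.ndarray
    ranking: np.ndarray


def _pool_descriptors(descriptor_sets: Sequence[DescriptorSet]) -> tuple[np.ndarray, str]:
    if not descriptor_sets:
        raise VocabularyError("no descriptor sets supplied")
    methods = {d.method for d in descriptor_sets}
    if len(methods) > 1:
        raise VocabularyError(f"cannot mix descriptor methods {sorted(methods)}")
    mats = [d.descriptors_as_float() for d in descriptor_sets if len(d) > 0]
    if not mats:
        raise VocabularyError("all descriptor sets are empty")
    pool = np.vstack(mats)
    # Sort rows lexicographically: makes the build invariant to the order in
    # which descriptor sets are supplied (the seeded k-means++ is the only
    # remaining source of ordering).
    order = np.lexsort(pool.T[::-1])
    pool = pool[order]
    digest = hashlib.sha256(np.ascontiguousarray(pool).tobytes()).hexdigest()[:16]
    return pool, digest


def build_vocabulary(
    descriptor_sets: Sequence[DescriptorSet],
    k: int = 100,
    seed: int = 0,
    max_train_descriptors: int | None = None,
) -> Vocabulary:
    """Cluster pooled training descriptors into k visual words.

    Lloyd's algorithm with k-means++ seeding and a fixed seed; empty
    descriptor sets contribute nothing.  ``max_train_descriptors``
    optionally subsamples the pool (seeded) to bound clustering cost.
    """
    pool, digest = _pool_descriptors(descriptor_sets)
    if max_train_descriptors is not None and pool.shape[0] > max_train_descriptors:
        rng = np.random.default_rng(seed)
        sel = rng.choice(pool.shape[0], size=max_train_descriptors, replace=False)
        pool = pool[np.sort(sel)]
    if pool.shape[0] < k:
        raise VocabularyError(
            f"{pool.shape[0]} pooled descriptors < k={k}; use a smaller vocabulary"
        )
    if pool.shape[0] < 10 * k:
        import warnings

        warnings.warn(
            f"descriptor pool ({pool.shape[0]}) is small for a k={k} vocabulary; "
            "words may be undersampled",
            UserWarning,
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, algorithm="lloyd", random_state=seed)
    km.fit(pool)
    return Vocabulary(
        centroids=km.cluster_centers_,
        method=descriptor_sets[0].method,
        k=k,
        seed=seed,
        training_hash=digest,
    )


def encode(
    dset: DescriptorSet, vocab: Vocabulary, normalization: str = "frequency"
) -> np.ndarray:
    """Encode one image's descriptors as a length-k word histogram.

    Each descriptor is assigned to the nearest centroid in Euclidean
    distance (ties to the lowest index).  Count mode sums to the
    descriptor count; frequency mode L1-normalizes; an image with no
    descriptors yields the all-zero row.
    """
    if normalization not in ("count", "frequency"):
        raise EncodingError(f"unknown normalization {normalization!r}")
    if len(dset) == 0:
        return np.zeros(vocab.k)
    desc = dset.descriptors_as_float()
    if desc.shape[1] != vocab.width:
        raise EncodingError(
            f"descriptor width {desc.shape[1]} does not match vocabulary width {vocab.width}"
        )
    assign = pairwise_distances_argmin(desc, vocab.centroids)
    hist = np.bincount(assign, minlength=vocab.k).astype(np.float64)
    if normalization == "frequency":
        hist /= hist.sum()
    return hist


def encode_table(
    descriptor_sets: Sequence[DescriptorSet],
    vocab: Vocabulary,
    labels: Sequence,
    normalization: str = "frequency",
    groups: Sequence | None = None,
) -> FeatureTable:
    """Encode a batch of descriptor sets into a labelled feature table."""
    rows = np.stack([encode(d, vocab, normalization) for d in descriptor_sets])
    return FeatureTable(
        rows=rows,
        labels=np.asarray(labels),
        normalization=normalization,
        image_ids=tuple(d.image_id for d in descriptor_sets),
        groups=np.asarray(groups) if groups is not None else None,
    )


def chi2_score(table: FeatureTable) -> Chi2Result:
    """Chi-square statistic of each feature column against the labels.

    For feature f, the observed class-c mass is the sum of f over rows of
    class c; the expected mass under independence is the feature total
    times the class share n_c/n.  The statistic is
    ``sum_c (obs - exp)^2 / exp`` with classes-1 degrees of freedom.
    Features with zero total mass score 0 (p-value 1).
    """
    classes = np.unique(table.labels)
    if classes.size < 2:
        raise ScoringError("chi-square scoring requires at least two classes")
    n = len(table)
    obs = np.stack([table.rows[table.labels == c].sum(axis=0) for c in classes])
    totals = obs.sum(axis=0)
    shares = np.array([(table.labels == c).sum() / n for c in classes])
    exp = np.outer(shares, totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    scores = contrib.sum(axis=0)
    dof = classes.size - 1
    p_values = np.where(totals > 0, chi2_dist.sf(scores, dof), 1.0)
    ranking = np.lexsort((np.arange(scores.size), -scores))
    return Chi2Result(scores=scores, p_values=p_values, ranking=ranking)


def select_top_k(result: Chi2Result, table: FeatureTable, k_select: int = 10) -> FeatureTable:
    """Retain the k_select highest-scoring feature columns (ties to lower index).

    The kept columns stay in their original order; their indices are
    recorded in ``selected_idx`` so held-out tables can be reduced
    identically.
    """
    if not 1 <= k_select <= table.n_features:
        raise SelectionError(
            f"k_select={k_select} out of range [1, {table.n_features}]"
        )
    keep = np.sort(result.ranking[:k_select])
    return replace(table, rows=table.rows[:, keep], selected_idx=keep)
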