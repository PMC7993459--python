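"""Community classes from beta-diversity.

Samples are clustered on a beta-diversity dissimilarity matrix
(average-linkage hierarchy, number of classes picked by maximum mean
silhouette) and the candidate partition is accepted only if within-class
distances are *significantly* smaller than between-class distances under a
label-permutation test. Unstructured data fall back to a single class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from ._rng import spawn
from .containers import AbundanceTable, ValidationError

METRICS = ("bray_curtis", "jaccard")


@dataclass
class DistanceMatrix:
    """Symmetric sample dissimilarities in [0, 1]."""

    ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-9:
            raise ValidationError("distances must lie in [0, 1]")
        self.data = d

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    @property
    def n(self) -> int:
        return len(self.ids)


def beta_distance(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Bray-Curtis (on relative abundances) or Jaccard (presence/absence)."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(table.samples) < 2:
        raise ValidationError("need at least 2 samples")
    depths = table.depths
    if (depths == 0).any():
        bad = list(depths.index[depths == 0])
        raise ValidationError(f"all-zero samples: {bad}")
    if metric == "bray_curtis":
        rel = table.relative().to_numpy().T
        condensed = pdist(rel, metric="braycurtis")
    else:
        pres = table.presence().to_numpy().T.astype(bool)
        condensed = pdist(pres, metric="jaccard")
    return DistanceMatrix(list(table.samples), squareform(condensed), metric)


@dataclass
class ClassPartition:
    """Sample -> class assignment with its supporting evidence."""

    labels: dict[str, str]
    k: int
    silhouette: dict[str, float] | None
    p_value: float | None
    status: str  # "ok", "no_structure", "undecidable"

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def samples_of(self, cls: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == cls]


def _within_between(data: np.ndarray, labels: np.ndarray) -> float:
    """Mean between-class distance minus mean within-class distance."""
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = data[iu][same[iu]]
    between = data[iu][~same[iu]]
    if between.size == 0:
        return float("nan")
    if within.size == 0:
        return float(between.mean())
    return float(between.mean() - within.mean())


def class_significance(
    dist: DistanceMatrix, partition, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for within-class beta-diversity coherence.

    Statistic: mean between-class minus mean within-class distance; labels
    are permuted across samples; p = (1 + #{permuted >= observed}) /
    (1 + n_perm).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    mapping = dict(getattr(partition, "labels", partition))
    try:
        labels = np.array([str(mapping[s]) for s in dist.ids])
    except KeyError as exc:
        raise ValidationError(f"partition missing sample {exc.args[0]!r}") from None
    k = len(set(labels))
    if k < 2:
        raise ValidationError("significance test needs at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in set(labels)}
    if min(counts.values()) < 2:
        warnings.warn(
            "class of size 1: statistic uses between-class terms only",
            stacklevel=2,
        )
    obs = _within_between(dist.data, labels)
    rng = spawn(seed, "classperm", n_perm)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _within_between(dist.data, perm) >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def find_classes(
    dist: DistanceMatrix,
    k_range: range | tuple = range(2, 9),
    linkage_method: str = "average",
    n_perm: int = 999,
    alpha: float = 0.05,
    min_silhouette: float = 0.25,
    seed: int = 0,
) -> ClassPartition:
    """Detect community classes, falling back to a single class.

    Average-linkage hierarchical clustering; k chosen by maximum mean
    silhouette over ``k_range``; the winning partition must clear a
    cluster-strength floor (mean silhouette >= ``min_silhouette``, guarding
    the post-selection permutation test) and the permutation test at
    ``alpha``, otherwise k = 1.
    """
    n = dist.n
    if n < 4:
        return ClassPartition(
            {s: "C1" for s in dist.ids}, 1, None, None, status="undecidable"
        )
    z = linkage(dist.condensed(), method=linkage_method)
    best = None  # (mean_sil, k, labels, sil_samples)
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        sil = silhouette_samples(dist.data, labels, metric="precomputed")
        mean_sil = float(sil.mean())
        if best is None or mean_sil > best[0]:
            best = (mean_sil, k, labels, sil)
    one_class = ClassPartition(
        {s: "C1" for s in dist.ids}, 1, None, None, status="no_structure"
    )
    if best is None or best[0] < min_silhouette:
        return one_class
    mean_sil, _, raw_labels, sil = best
    # deterministic class names in order of first appearance
    seen: dict[int, str] = {}
    labels = {}
    for s, lab in zip(dist.ids, raw_labels):
        if lab not in seen:
            seen[lab] = f"C{len(seen) + 1}"
        labels[s] = seen[lab]
    p = class_significance(dist, labels, n_perm=n_perm, seed=seed)
    if p > alpha:
        return one_class
    return ClassPartition(
        labels,
        k=len(seen),
        silhouette=dict(zip(dist.ids, (float(x) for x in sil))),
        p_value=p,
        status="ok",
    )
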