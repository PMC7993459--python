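"""Phylogenetic core group (PCG) detection.

A PCG is a cluster of marker sequences that is present (summed member
counts >= min_count) in *every* sample of a sample set, fixed at the highest
identity threshold at which this holds. The search walks a descending ladder
of identity thresholds, clustering only the sequences not yet assigned at a
higher threshold; whatever survives the whole ladder is reported as the
non-core residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import AbundanceTable, SequenceSet, ValidationError

#: Descending identity ladder; 0.97 is the conventional OTU level.
DEFAULT_LADDER: tuple[float, ...] = (1.00, 0.99, 0.97, 0.95, 0.92, 0.90)

_EPS = 1e-9


def pairwise_identity(seqs: SequenceSet) -> pd.DataFrame:
    """Fraction of matching positions for every pair of (aligned) sequences.

    Sequences must be equal length and ungapped (the aligned-input
    contract); identity = matches / length, symmetric, unit diagonal.
    """
    mat = seqs.matrix
    n = len(seqs)
    out = np.empty((n, n))
    for i in range(n):
        out[i] = (mat == mat[i]).mean(axis=1)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=seqs.ids, columns=seqs.ids)


def cluster_at_threshold(seqs: SequenceSet, t: float) -> list[set[str]]:
    """Complete-linkage clusters in which every pair has identity >= t.

    The threshold is a guaranteed within-cluster identity floor (complete
    linkage cut at distance 1 - t). The partition is invariant to input
    order: sequences are processed in lexicographic id order.
    """
    if not 0 < t <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {t}")
    order = sorted(seqs.ids)
    if len(order) == 1:
        return [{order[0]}]
    ident = pairwise_identity(seqs.subset(order)).to_numpy()
    dist = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="complete")
    labels = fcluster(z, t=(1.0 - t) + _EPS, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for sid, lab in zip(order, labels):
        clusters.setdefault(int(lab), set()).add(sid)
    return sorted(clusters.values(), key=lambda c: min(c))


@dataclass(frozen=True)
class PCG:
    """A sequence cluster found in all samples of its sample set."""

    pcg_id: str
    threshold: float
    members: tuple[str, ...]
    representative: str
    per_sample_presence: dict[str, bool] = field(hash=False, compare=False, default_factory=dict)


@dataclass
class PCGResult:
    pcgs: list[PCG]
    residual: list[str]
    unreliable: bool = False

    @property
    def assigned(self) -> set[str]:
        return {m for p in self.pcgs for m in p.members}


def pcg_search(
    seqs: SequenceSet,
    table: AbundanceTable,
    thresholds: tuple[float, ...] = DEFAULT_LADDER,
    min_count: int = 1,
) -> PCGResult:
    """Run the descending-ladder PCG search over one set of samples.

    At each rung the *unassigned* sequences are clustered; a cluster whose
    summed counts reach ``min_count`` in every sample becomes a PCG at that
    rung and its members are removed. Sequences surviving the whole ladder
    are the non-phylogenetic-core residual.
    """
    thresholds = tuple(thresholds)
    if not thresholds or any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError(f"threshold ladder must be strictly descending: {thresholds}")
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    missing = [s for s in seqs.ids if s not in set(table.taxa)]
    if missing:
        raise ValidationError(f"sequences absent from abundance table: {sorted(missing)}")

    unassigned = sorted(seqs.ids)
    pcgs: list[PCG] = []
    for t in thresholds:
        if not unassigned:
            break
        for cluster in cluster_at_threshold(seqs.subset(unassigned), t):
            members = tuple(sorted(cluster))
            sums = table.df.loc[list(members)].sum(axis=0)
            if bool((sums >= min_count).all()):
                pcgs.append(
                    PCG(
                        pcg_id=f"PCG{len(pcgs) + 1:03d}",
                        threshold=t,
                        members=members,
                        representative=members[0],
                        per_sample_presence={s: True for s in table.samples},
                    )
                )
        assigned = {m for p in pcgs for m in p.members}
        unassigned = [s for s in unassigned if s not in assigned]
    return PCGResult(pcgs=pcgs, residual=unassigned)


def pcg_per_class(
    seqs: SequenceSet,
    table: AbundanceTable,
    partition,
    thresholds: tuple[float, ...] = DEFAULT_LADDER,
    min_count: int = 1,
) -> dict[str, PCGResult]:
    """Independent PCG search within each community class.

    ``partition`` is a sample -> class-label mapping (or an object with a
    ``labels`` attribute holding one). Classes with fewer than two samples
    are still searched but flagged unreliable.
    """
    labels: dict[str, str] = dict(getattr(partition, "labels", partition))
    missing = [s for s in table.samples if s not in labels]
    if missing:
        raise ValidationError(f"partition does not cover samples: {missing}")
    out: dict[str, PCGResult] = {}
    for cls in sorted({str(v) for v in labels.values()}):
        samples = [s for s in table.samples if str(labels[s]) == cls]
        sub = table.subset_samples(samples)
        res = pcg_search(seqs, sub, thresholds, min_count)
        res.unreliable = len(samples) < 2
        out[cls] = res
    return out
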