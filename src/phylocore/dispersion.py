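"""Phylogenetic dispersion: MNTD, NTI and its between-community variant.

The mean nearest-taxon distance (MNTD) of the taxa present in a community
is compared with a randomization null (uniform draws of equally many tips
from a species pool); the z-score of the observed value is the NTI as
reported here (raw z of distances: significantly *negative* = taxa closer
than expected = phylogenetic clustering; positive = overdispersion). The
between-community variant scores the nearest-taxon turnover distance
between two memberships: significantly negative indicates a homogeneous
selective environment, positive a heterogeneous one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from ._rng import spawn
from .containers import ValidationError
from .tree import LabeledTree

#: |z| beyond which dispersion is called significant.
Z_THRESHOLD = 2.0


@dataclass
class DispersionResult:
    mntd_observed: float
    null_mean: float
    null_sd: float
    z: float
    call: str  # clustered / overdispersed / random / undefined
    n_null: int
    kind: str = "nti"


def _submatrix(tree: LabeledTree, names: list[str]) -> np.ndarray:
    dmat = tree.patristic()
    missing = [t for t in names if t not in dmat.index]
    if missing:
        raise ValidationError(f"unknown tips: {sorted(missing)}")
    return dmat.loc[names, names].to_numpy(copy=True)


def mntd(taxa, tree: LabeledTree) -> float:
    """Mean over members of the patristic distance to the nearest co-occurring taxon."""
    names = sorted(set(taxa))
    if len(names) < 2:
        raise ValidationError("mntd needs at least 2 taxa")
    sub = _submatrix(tree, names)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mntd_from(sub: np.ndarray) -> float:
    s = sub.copy()
    np.fill_diagonal(s, np.inf)
    return float(s.min(axis=1).mean())


def _finish(obs: float, null: np.ndarray, kind: str, z_threshold: float) -> DispersionResult:
    mean = float(null.mean())
    sd = float(null.std())
    if sd == 0:
        return DispersionResult(obs, mean, 0.0, float("nan"), "undefined", len(null), kind)
    z = (obs - mean) / sd
    if z <= -z_threshold:
        call = "clustered"
    elif z >= z_threshold:
        call = "overdispersed"
    else:
        call = "random"
    return DispersionResult(obs, mean, sd, float(z), call, len(null), kind)


def nti(
    taxa,
    tree: LabeledTree,
    pool=None,
    n_null: int = 999,
    seed: int = 0,
    method: str = "auto",
    z_threshold: float = Z_THRESHOLD,
) -> DispersionResult:
    """NTI of one community against a taxa-shuffle null over the pool.

    The null draws ``len(taxa)`` tips uniformly without replacement from
    the pool. With ``method="auto"`` the null is enumerated exhaustively
    whenever there are no more than ``n_null`` distinct subsets, otherwise
    sampled. ``taxa == pool`` leaves a degenerate null (call "undefined").
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    names = sorted(set(taxa))
    pool_names = sorted(set(pool)) if pool is not None else sorted(tree.tip_labels)
    if len(names) < 2:
        raise ValidationError("nti needs at least 2 taxa")
    if not set(names) <= set(pool_names):
        raise ValidationError("taxa must be a subset of the pool")
    poolmat = _submatrix(tree, pool_names)
    index = {t: i for i, t in enumerate(pool_names)}
    obs_idx = [index[t] for t in names]
    obs = _mntd_from(poolmat[np.ix_(obs_idx, obs_idx)])

    k, npool = len(names), len(pool_names)
    if k == npool:
        return DispersionResult(obs, obs, 0.0, float("nan"), "undefined", 0, "nti")
    n_comb = comb(npool, k)
    if method == "exhaustive" or (method == "auto" and n_comb <= n_null):
        draws = itertools.combinations(range(npool), k)
        null = np.array([_mntd_from(poolmat[np.ix_(c, c)]) for c in draws])
    elif method in ("auto", "sample"):
        rng = spawn(seed, "nti", k, npool, n_null)
        null = np.empty(n_null)
        for i in range(n_null):
            c = rng.choice(npool, size=k, replace=False)
            null[i] = _mntd_from(poolmat[np.ix_(c, c)])
    else:
        raise ValidationError(f"unknown method {method!r}")
    return _finish(obs, null, "nti", z_threshold)


def _between_mntd(sub_ab: np.ndarray, sub_ba: np.ndarray) -> float:
    # directed nearest-taxon distances in both directions, averaged jointly
    return float(np.concatenate([sub_ab.min(axis=1), sub_ba.min(axis=1)]).mean())


def beta_nti(
    taxa_a,
    taxa_b,
    tree: LabeledTree,
    pool=None,
    n_null: int = 999,
    seed: int = 0,
    z_threshold: float = Z_THRESHOLD,
) -> DispersionResult:
    """Between-community nearest-taxon dispersion.

    Observed statistic: each member's patristic distance to its nearest
    taxon in the *other* community (shared taxa contribute zero), averaged
    over both directions. The null redraws both memberships (same sizes)
    uniformly from the pool. Sign convention: significantly positive z
    indicates heterogeneous selection ("overdispersed"), significantly
    negative homogeneous selection ("clustered").
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    a = sorted(set(taxa_a))
    b = sorted(set(taxa_b))
    if not a or not b:
        raise ValidationError("both memberships must be nonempty")
    pool_names = sorted(set(pool)) if pool is not None else sorted(tree.tip_labels)
    if not set(a) <= set(pool_names) or not set(b) <= set(pool_names):
        raise ValidationError("memberships must be subsets of the pool")
    poolmat = _submatrix(tree, pool_names)
    index = {t: i for i, t in enumerate(pool_names)}
    ia = [index[t] for t in a]
    ib = [index[t] for t in b]
    obs = _between_mntd(poolmat[np.ix_(ia, ib)], poolmat[np.ix_(ib, ia)])

    npool = len(pool_names)
    if len(a) == npool and len(b) == npool:
        return DispersionResult(obs, obs, 0.0, float("nan"), "undefined", 0, "beta_nti")
    rng = spawn(seed, "betanti", len(a), len(b), npool, n_null)
    null = np.empty(n_null)
    for i in range(n_null):
        ca = rng.choice(npool, size=len(a), replace=False)
        cb = rng.choice(npool, size=len(b), replace=False)
        null[i] = _between_mntd(poolmat[np.ix_(ca, cb)], poolmat[np.ix_(cb, ca)])
    return _finish(obs, null, "beta_nti", z_threshold)
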