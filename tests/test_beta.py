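"""Beta-diversity distances, community classes, permutation significance."""

import numpy as np
import pandas as pd
import pytest

import phylocore as pc
from phylocore.beta import DistanceMatrix, beta_distance, class_significance, find_classes
from phylocore.containers import AbundanceTable, ValidationError


def table_from(counts: dict) -> AbundanceTable:
    return AbundanceTable(pd.DataFrame(counts))


class TestBetaDistance:
    def test_identical_samples_distance_zero(self):
        t = table_from({"s1": [3, 5, 2], "s2": [3, 5, 2]})
        for metric in ("bray_curtis", "jaccard"):
            assert beta_distance(t, metric).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        t = table_from({"s1": [4, 4, 0, 0], "s2": [0, 0, 4, 4]})
        for metric in ("bray_curtis", "jaccard"):
            assert beta_distance(t, metric).data[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        # relative (1/2,1/2,0) vs (0,1/2,1/2): BC = 1 - 2*(1/2)/2 = 0.5
        t = table_from({"s1": [2, 2, 0], "s2": [0, 2, 2]})
        assert beta_distance(t, "bray_curtis").data[0, 1] == pytest.approx(0.5)

    def test_all_zero_sample_rejected_by_name(self):
        t = table_from({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValidationError, match="empty"):
            beta_distance(t)

    def test_unknown_metric_rejected(self):
        t = table_from({"s1": [1], "s2": [2]})
        with pytest.raises(ValidationError, match="metric"):
            beta_distance(t, "euclidean")


def two_block_matrix(n_per: int, rng) -> DistanceMatrix:
    n = 2 * n_per
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_per) == (j < n_per)
            d[i, j] = d[j, i] = rng.uniform(0.1, 0.3) if same else rng.uniform(0.7, 0.9)
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "synthetic")


def exchangeable_matrix(n: int, rng) -> DistanceMatrix:
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = rng.uniform(0.2, 0.8, size=len(iu[0]))
    d[iu] = vals
    d += d.T
    return DistanceMatrix([f"s{i}" for i in range(n)], d, "synthetic")


class TestFindClasses:
    def test_two_block_recovered(self):
        rng = np.random.default_rng(0)
        part = find_classes(two_block_matrix(8, rng), n_perm=199, seed=1)
        assert part.k == 2
        left = {part.labels[f"s{i}"] for i in range(8)}
        right = {part.labels[f"s{i}"] for i in range(8, 16)}
        assert len(left) == 1 and len(right) == 1 and left != right
        assert part.p_value == pytest.approx(1 / 200)

    def test_flat_matrix_gives_single_class(self):
        ids = [f"s{i}" for i in range(10)]
        d = np.full((10, 10), 0.5)
        np.fill_diagonal(d, 0.0)
        part = find_classes(DistanceMatrix(ids, d, "flat"), n_perm=99, seed=0)
        assert part.k == 1

    def test_neutral_community_data_usually_single_class(self):
        """Samples of one metacommunity carry no class structure."""
        hits = 0
        for s in range(10):
            table, _, _ = pc.neutral_dataset(n_taxa=60, n_samples=24, depth=1000,
                                             m=0.1, seed=s)
            part = find_classes(beta_distance(table), n_perm=99, seed=s)
            hits += part.k > 1
        assert hits <= 2

    def test_too_few_samples_undecidable(self):
        rng = np.random.default_rng(2)
        part = find_classes(exchangeable_matrix(3, rng), seed=0)
        assert part.status == "undecidable"
        assert part.k == 1

    def test_partition_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        dm = two_block_matrix(6, rng)
        perm = np.random.default_rng(9).permutation(dm.n)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm], dm.data[np.ix_(perm, perm)], dm.metric)
        p1 = find_classes(dm, n_perm=99, seed=4)
        p2 = find_classes(dm2, n_perm=99, seed=4)
        groups1 = {frozenset(p1.samples_of(c)) for c in p1.classes}
        groups2 = {frozenset(p2.samples_of(c)) for c in p2.classes}
        assert groups1 == groups2


class TestClassSignificance:
    def test_perfect_separation_attains_minimal_p(self):
        rng = np.random.default_rng(1)
        dm = two_block_matrix(6, rng)
        labels = {f"s{i}": ("a" if i < 6 else "b") for i in range(12)}
        p = class_significance(dm, labels, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_nonpositive_statistic_gives_large_p(self):
        # inverted blocks: within-distance larger than between
        rng = np.random.default_rng(1)
        dm = two_block_matrix(6, rng)
        labels = {f"s{i}": ("a" if i % 2 == 0 else "b") for i in range(12)}
        p = class_significance(dm, labels, n_perm=199, seed=0)
        assert p > 0.5

    def test_type_i_error_calibrated(self):
        """Random labels on exchangeable matrices reject at about alpha."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            dm = exchangeable_matrix(14, rng)
            labels = {s: ("a" if v < 0.5 else "b") for s, v in zip(dm.ids, rng.random(14))}
            if len(set(labels.values())) < 2:
                labels[dm.ids[0]] = "a"
                labels[dm.ids[1]] = "b"
            p = class_significance(dm, labels, n_perm=99, seed=rep)
            rejections += p <= 0.05
        assert 0.005 <= rejections / n_rep <= 0.12

    def test_singleton_class_flagged(self):
        rng = np.random.default_rng(4)
        dm = exchangeable_matrix(6, rng)
        labels = {s: ("solo" if i == 0 else "rest") for i, s in enumerate(dm.ids)}
        with pytest.warns(UserWarning, match="size 1"):
            class_significance(dm, labels, n_perm=99, seed=0)

    def test_requires_enough_permutations_and_classes(self):
        rng = np.random.default_rng(4)
        dm = exchangeable_matrix(6, rng)
        with pytest.raises(ValidationError):
            class_significance(dm, {s: "one" for s in dm.ids}, n_perm=99)
        with pytest.raises(ValidationError):
            class_significance(dm, {s: ("a" if i else "b") for i, s in enumerate(dm.ids)}, n_perm=10)
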