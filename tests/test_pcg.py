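"""Pairwise identity, threshold clustering, and the PCG ladder search."""

import numpy as np
import pytest

import phylocore as pc
from phylocore.containers import SequenceSet, ValidationError
from phylocore.pcg import (
    DEFAULT_LADDER,
    cluster_at_threshold,
    pairwise_identity,
    pcg_per_class,
    pcg_search,
)


class TestPairwiseIdentity:
    def test_identical_and_partial(self):
        seqs = SequenceSet({"a": "ACGT", "b": "ACGT", "c": "ACGA"})
        ident = pairwise_identity(seqs)
        assert ident.loc["a", "b"] == pytest.approx(1.0)
        assert ident.loc["a", "c"] == pytest.approx(0.75)
        assert np.allclose(ident.to_numpy(), ident.to_numpy().T)
        assert np.allclose(np.diag(ident.to_numpy()), 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            SequenceSet({"a": "ACGT", "b": "ACG"})

    def test_matches_jc_expectation_at_distance(self):
        d = 0.1
        tree = pc.LabeledTree.from_newick(f"(A:{d / 2},B:{d / 2});")
        seqs = pc.evolve_sequences(tree, 1000, seed=8)
        expected = pc.jc_expected_identity(d)
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(pairwise_identity(seqs).loc["A", "B"] - expected) < 3 * se


def brute_force_complete_linkage(ident, ids, t):
    """Naive O(n^3) agglomeration: the independent clustering oracle."""
    clusters = [{i} for i in ids]

    def dist(c1, c2):
        return max(1 - ident.loc[a, b] for a in c1 for b in c2)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > (1 - t) + 1e-9:
            break
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        clusters.pop(j)
    return sorted(map(frozenset, clusters), key=min)


class TestClusterAtThreshold:
    def test_exact_duplicates_at_unity(self):
        seqs = SequenceSet({"a": "AAAA", "b": "AAAA", "c": "AAAT", "d": "AAAT", "e": "TTTT"})
        parts = cluster_at_threshold(seqs, 1.0)
        assert sorted(map(frozenset, parts), key=min) == [
            frozenset({"a", "b"}), frozenset({"c", "d"}), frozenset({"e"}),
        ]

    def test_fig_fixture_genus_threshold(self, fig_a):
        parts = cluster_at_threshold(fig_a.sequences, fig_a.thresholds["genus"])
        assert sorted(map(frozenset, parts), key=min) == [
            frozenset({"SA", "SB"}), frozenset({"SC", "SD"}),
        ]
        fam = cluster_at_threshold(fig_a.sequences, fig_a.thresholds["family"])
        assert [set(c) for c in fam] == [{"SA", "SB", "SC", "SD"}]

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle_on_six_sequences(self, trial):
        rng = np.random.default_rng(trial)
        base = rng.integers(0, 4, size=60).astype(np.uint8)
        mat = np.stack([base.copy() for _ in range(6)])
        for i in range(1, 6):
            mask = rng.random(60) < 0.25 * i / 6
            mat[i][mask] = (mat[i][mask] + rng.integers(1, 4, int(mask.sum()))) % 4
        seqs = SequenceSet.from_matrix([f"s{i}" for i in range(6)], mat)
        ident = pairwise_identity(seqs)
        for t in (1.0, 0.99, 0.95, 0.9, 0.8, 0.7):
            mine = sorted(map(frozenset, cluster_at_threshold(seqs, t)), key=min)
            assert mine == brute_force_complete_linkage(ident, seqs.ids, t)

    def test_invalid_threshold_rejected(self, fig_a):
        with pytest.raises(ValidationError):
            cluster_at_threshold(fig_a.sequences, 0.0)


class TestClusterProperties:
    """Hypothesis-driven invariants of the threshold clustering."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _seqset(draw_ints, n, length):
        mat = (np.asarray(draw_ints, dtype=np.uint8).reshape(n, length)) % 4
        return SequenceSet.from_matrix([f"q{i}" for i in range(n)], mat)

    @given(
        data=st.lists(st.integers(0, 3), min_size=5 * 30, max_size=5 * 30),
        t=st.sampled_from([1.0, 0.95, 0.85, 0.6]),
        perm_seed=st.integers(0, 100),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_partition_covers_disjointly_and_ignores_order(self, data, t, perm_seed):
        seqs = self._seqset(data, 5, 30)
        parts = cluster_at_threshold(seqs, t)
        flat = [sid for c in parts for sid in c]
        assert sorted(flat) == sorted(seqs.ids)  # a true partition
        ident = pairwise_identity(seqs)
        for c in parts:  # within-cluster identity floor
            for a in c:
                for b in c:
                    assert ident.loc[a, b] >= t - 1e-9
        order = list(np.random.default_rng(perm_seed).permutation(seqs.ids))
        parts2 = cluster_at_threshold(seqs.subset(order), t)
        assert sorted(map(frozenset, parts), key=min) == sorted(
            map(frozenset, parts2), key=min
        )


class TestPcgSearch:
    def test_scenario1_family_pcg(self):
        ds = pc.generate_scenario(1, "A", seed=0)
        res = pcg_search(ds.sequences, ds.table)
        assert len(res.pcgs) == 1
        assert set(res.pcgs[0].members) == {"SA", "SB", "SC", "SD"}
        assert res.pcgs[0].threshold == pytest.approx(0.92)
        assert res.residual == []

    @pytest.mark.parametrize("scenario,expected", [(2, {"SA", "SB"}), (3, {"SC", "SD"})])
    def test_scenario_2_3_genus_pcgs(self, scenario, expected):
        ds = pc.generate_scenario(scenario, "A", seed=0)
        res = pcg_search(ds.sequences, ds.table)
        assert len(res.pcgs) == 1
        assert set(res.pcgs[0].members) == expected

    def test_scenario4_pooled_vs_split(self):
        ds = pc.generate_scenario(4, "A", seed=0)
        pooled = pcg_search(ds.sequences, ds.table)
        assert [set(p.members) for p in pooled.pcgs] == [{"SA", "SB", "SC", "SD"}]
        per = pcg_per_class(ds.sequences, ds.table, ds.truth.class_of_sample)
        sets = sorted((tuple(sorted(p.members)) for r in per.values() for p in r.pcgs))
        assert sets == [("SA", "SB"), ("SC", "SD")]

    def test_single_class_split_equals_pooled(self):
        ds = pc.generate_scenario(1, "A", seed=3)
        pooled = pcg_search(ds.sequences, ds.table)
        per = pcg_per_class(ds.sequences, ds.table,
                            {s: "C1" for s in ds.table.samples})
        assert [p.members for p in per["C1"].pcgs] == [p.members for p in pooled.pcgs]

    def test_members_disjoint_and_presence_complete(self):
        ds = pc.generate_scenario(1, "A", seed=7)
        res = pcg_search(ds.sequences, ds.table)
        seen = set()
        for p in res.pcgs:
            assert not seen & set(p.members)
            seen |= set(p.members)
            sums = ds.table.df.loc[list(p.members)].sum(axis=0)
            assert (sums >= 1).all()

    def test_order_invariance(self):
        ds = pc.generate_scenario(1, "A", seed=5)
        res1 = pcg_search(ds.sequences, ds.table)
        reversed_seqs = ds.sequences.subset(list(reversed(ds.sequences.ids)))
        res2 = pcg_search(reversed_seqs, ds.table)
        assert [set(p.members) for p in res1.pcgs] == [set(p.members) for p in res2.pcgs]

    def test_ladder_coarsening_never_splits(self):
        ds = pc.generate_scenario(1, "A", seed=5)
        full = pcg_search(ds.sequences, ds.table, DEFAULT_LADDER)
        coarse = pcg_search(ds.sequences, ds.table, (1.00, 0.97, 0.90))
        for f in (set(p.members) for p in full.pcgs):
            for c in (set(p.members) for p in coarse.pcgs):
                assert not (f & c) or f <= c

    def test_small_class_flagged_unreliable(self):
        ds = pc.generate_scenario(1, "A", seed=2)
        labels = {s: ("solo" if i == 0 else "rest")
                  for i, s in enumerate(ds.table.samples)}
        per = pcg_per_class(ds.sequences, ds.table, labels)
        assert per["solo"].unreliable
        assert not per["rest"].unreliable

    def test_bad_inputs_rejected(self, fig_a):
        ds = pc.generate_scenario(1, "A", seed=0)
        with pytest.raises(ValidationError, match="descending"):
            pcg_search(ds.sequences, ds.table, thresholds=(0.9, 0.97))
        with pytest.raises(ValidationError, match="absent"):
            pcg_search(fig_a.sequences, ds.table.subset_samples(ds.table.samples[:3])
                       .drop_taxa([ds.table.taxa[0]]))
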