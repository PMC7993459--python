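"""Fig-style fixtures and scenario dataset generation."""

import numpy as np
import pytest

import phylocore as pc
from phylocore.containers import ValidationError
from phylocore.pcg import pairwise_identity
from phylocore.simulate import ScenarioParams


class TestFigFixture:
    def test_case_a_trait_layout(self, fig_a):
        traits = fig_a.traits
        assert traits.species_with_trait("rectangle") == {"SA", "SB", "SC", "SD"}
        assert traits.species_with_trait("triangle") == {"SA", "SB"}
        assert traits.species_with_trait("diamond") == {"SC", "SD"}

    def test_case_b_star_traits(self, fig_b):
        stars = fig_b.traits.df[fig_b.traits.df.function_id == "yellow"]
        assert len(stars) == 4
        assert stars.trait_id.nunique() == 4
        sb = stars[stars.species == "SB"].iloc[0]
        assert sb.origin == "hgt"
        assert sb.origin_branch == "SC"
        assert set(stars[stars.origin == "convergent"].species) == {"SA", "SC", "SD"}

    def test_identity_hierarchy(self, fig_a):
        ident = pairwise_identity(fig_a.sequences)
        within = min(ident.loc["SA", "SB"], ident.loc["SC", "SD"])
        cross = max(ident.loc[a, b] for a in ("SA", "SB") for b in ("SC", "SD"))
        assert within > cross > fig_a.thresholds["family"]
        assert within >= fig_a.thresholds["genus"]

    def test_unknown_case_rejected(self):
        with pytest.raises(ValidationError, match="case"):
            pc.fig1_fixture("C")

    def test_deterministic(self):
        a = pc.fig1_fixture("A", seed=3)
        b = pc.fig1_fixture("A", seed=3)
        assert a.sequences.to_dict() == b.sequences.to_dict()


class TestGenerateScenario:
    def test_scenario1_truth_and_eligibility(self):
        ds = pc.generate_scenario(1, "A", seed=0)
        assert ds.truth.niche_type == "neutral_phylo_niche"
        assert set(ds.table.taxa) <= {"SA", "SB", "SC", "SD"}

    def test_scenario2_samples_only_one_genus(self):
        ds = pc.generate_scenario(2, "A", seed=0)
        assert set(ds.table.taxa) <= {"SA", "SB"}

    def test_scenario4_disjoint_genus_occupancy(self):
        ds = pc.generate_scenario(4, "A", seed=1)
        classes = ds.truth.class_of_sample
        n1 = [s for s, c in classes.items() if c == "N1"]
        n2 = [s for s, c in classes.items() if c == "N2"]
        t = ds.table.df
        g1 = [x for x in ("SA", "SB") if x in t.index]
        g2 = [x for x in ("SC", "SD") if x in t.index]
        assert t.loc[g2, n1].to_numpy().sum() == 0
        assert t.loc[g1, n2].to_numpy().sum() == 0

    def test_scenario6_marks_departing_taxon(self):
        ds = pc.generate_scenario(6, "B", seed=0)
        assert "SA" in ds.truth.departing_taxa
        assert ds.truth.niche_type == "mixed_neutral_selective"
        assert "SA" in ds.table.taxa

    def test_case_requirements_enforced(self):
        with pytest.raises(ValidationError, match="case B"):
            pc.generate_scenario(5, "A", seed=0)
        with pytest.raises(ValidationError, match="case B"):
            pc.generate_scenario(6, "A", seed=0)
        with pytest.raises(ValidationError, match="scenario"):
            pc.generate_scenario(7, "A", seed=0)

    def test_sequences_match_table(self):
        ds = pc.generate_scenario(3, "A", seed=2)
        assert sorted(ds.sequences.ids) == sorted(ds.table.taxa)

    def test_regional_mode_embeds_family_in_pool(self, regional_params):
        ds = pc.generate_scenario(1, "A", regional_params, seed=0)
        assert ds.tree.n_tips == 256
        fam = set(ds.tree.clade_tips("F"))
        assert set(ds.table.taxa) <= fam
        assert 0.2 * 256 <= len(fam) <= 0.6 * 256

    def test_regional_determinism(self, regional_params):
        a = pc.generate_scenario(4, "A", regional_params, seed=9)
        b = pc.generate_scenario(4, "A", regional_params, seed=9)
        assert a.table.df.equals(b.table.df)
        assert a.tree.to_newick() == b.tree.to_newick()

    def test_selective_scenario_truth(self):
        ds = pc.generate_scenario("selective", "B", seed=0)
        assert ds.truth.niche_type == "selective_phylo_niche"
        fam = set(ds.tree.clade_tips("F"))
        assert set(ds.table.taxa) <= fam

    def test_niche_construction_spans_distant_clades(self):
        ds = pc.generate_scenario("niche_construction", "B", seed=0)
        assert ds.truth.niche_type == "other_interactions"
        assert ds.truth.ambiguous
        left = set(ds.tree.clade_tips(ds.tree.root.children[0].name or "root"))
        # taxa drawn from across the pool, not one clade
        fam = set(ds.tree.clade_tips("F"))
        assert not set(ds.table.taxa) <= fam


def test_esv_variants_split_counts(fig_a):
    niche = pc.NicheSpec(frozenset({"rectangle"}))
    table = pc.assemble_samples(fig_a.tree, fig_a.traits, niche, 6, 200, 0.01, seed=0)
    seqs = fig_a.sequences.subset(table.taxa)
    s2, t2 = pc.simulate.add_esv_variants(seqs, table, k=3, seed=1)
    assert len(s2) == 3 * len(table.taxa)
    # per-sample totals preserved
    np.testing.assert_array_equal(t2.depths.to_numpy(), table.depths.to_numpy())
    ident = pairwise_identity(s2)
    for taxon in table.taxa:
        sub = ident.loc[[f"{taxon}.v1", f"{taxon}.v2", f"{taxon}.v3"],
                        [f"{taxon}.v1", f"{taxon}.v2", f"{taxon}.v3"]]
        assert sub.to_numpy().min() >= 1 - 4 / seqs.length
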