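"""Sloan neutral-model occupancy predictions, fitting and departure calls."""

import numpy as np
import pytest

import phylocore as pc
from phylocore.containers import ValidationError
from phylocore.neutral import (
    detection_probability,
    predicted_occupancy,
    refit_excluding,
    sloan_fit,
)


class TestPredictedOccupancy:
    def test_limits_and_symmetry(self):
        assert predicted_occupancy(0.0, 1000, 0.1, 0.001) == 0.0
        assert predicted_occupancy(1.0, 1000, 0.1, 0.001) == 1.0
        assert predicted_occupancy(0.3, 1000, 0.1, 0.0) == 1.0
        # Beta(5,5) is symmetric about 1/2
        assert predicted_occupancy(0.5, 20, 0.5, 0.5) == pytest.approx(0.5)

    def test_monotone_in_p(self):
        ps = np.linspace(0.001, 0.999, 50)
        occ = predicted_occupancy(ps, 500, 0.05, 1 / 500)
        assert np.all(np.diff(occ) >= -1e-12)

    def test_matches_beta_monte_carlo(self):
        """Survival-function values vs direct Beta sampling on a grid."""
        rng = np.random.default_rng(0)
        n_mc = 40_000
        for p, nm, d in [(0.01, 20, 0.001), (0.1, 50, 0.01), (0.5, 10, 0.5)]:
            n, m = 1000, nm / 1000
            draws = rng.beta(nm * p, nm * (1 - p), size=n_mc)
            mc = (draws > d).mean()
            se = np.sqrt(mc * (1 - mc) / n_mc)
            assert abs(predicted_occupancy(p, n, m, d) - mc) < 3 * max(se, 1e-4)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            predicted_occupancy(0.5, 100, 0.0, 0.01)
        with pytest.raises(ValidationError):
            predicted_occupancy(0.5, 100, 0.5, 1.5)


class TestDetectionProbability:
    def test_matches_read_sampling_monte_carlo(self):
        """P(>=1 read) vs Beta draw followed by binomial read sampling."""
        rng = np.random.default_rng(1)
        n_mc = 40_000
        for p, m, depth in [(0.005, 0.05, 1000), (0.05, 0.01, 500), (0.2, 0.2, 200)]:
            x = rng.beta(depth * m * p, depth * m * (1 - p), size=n_mc)
            detected = rng.binomial(depth, x) > 0
            mc = detected.mean()
            se = np.sqrt(mc * (1 - mc) / n_mc)
            assert abs(detection_probability(p, depth, m) - mc) < 3 * max(se, 1e-4)


class TestSloanFit:
    def test_recovers_migration_rate(self):
        table, p, _ = pc.neutral_dataset(n_taxa=150, n_samples=200, depth=2000,
                                         m=0.1, seed=0)
        fit = sloan_fit(table)
        assert abs(fit.m_hat - 0.1) <= 0.03
        assert fit.verdict == "neutral"
        assert fit.fit_quality > 0.9

    def test_occupancy_prediction_monotone_in_result(self):
        table, _, _ = pc.neutral_dataset(n_taxa=80, n_samples=100, depth=1000,
                                         m=0.05, seed=3)
        fit = sloan_fit(table)
        ordered = fit.per_taxon.sort_values("p")
        assert np.all(np.diff(ordered["predicted"]) >= -1e-12)
        assert ((fit.per_taxon["predicted"] >= 0) & (fit.per_taxon["predicted"] <= 1)).all()

    def test_calls_consistent_with_cis(self):
        table, _, _ = pc.neutral_dataset(n_taxa=80, n_samples=100, depth=1000,
                                         m=0.05, seed=4)
        fit = sloan_fit(table)
        pt = fit.per_taxon
        above = pt[pt.call == "above"]
        below = pt[pt.call == "below"]
        assert (above.occupancy > above.ci_high).all()
        assert (below.occupancy < below.ci_low).all()

    def test_advantaged_taxon_called_above(self):
        ds = pc.generate_scenario(6, "B", pc.ScenarioParams(n_advantaged=1), seed=0)
        fit = sloan_fit(ds.table)
        assert fit.per_taxon.loc["SA", "call"] == "above"

    def test_pooled_niches_depart(self, regional_params):
        ds = pc.generate_scenario(4, "A", regional_params, seed=0)
        fit = sloan_fit(ds.table)  # both niches pooled into one metacommunity
        assert fit.verdict != "neutral"

    def test_minimum_size_enforced(self):
        import pandas as pd

        from phylocore.containers import AbundanceTable

        tiny = AbundanceTable(pd.DataFrame(
            {"s1": [5, 5], "s2": [2, 8], "s3": [7, 3], "s4": [5, 5], "s5": [1, 9]},
            index=["t1", "t2"],
        ))
        with pytest.raises(ValidationError, match="taxa"):
            sloan_fit(tiny)


class TestRefitExcluding:
    def test_excluding_nothing_is_identity(self):
        table, _, _ = pc.neutral_dataset(n_taxa=60, n_samples=80, depth=800,
                                         m=0.05, seed=5)
        a = sloan_fit(table)
        b = refit_excluding(table, [])
        assert a.m_hat == b.m_hat
        assert a.verdict == b.verdict
        assert a.per_taxon.equals(b.per_taxon)

    def test_scenario6_neutral_after_excluding_advantaged(self):
        ds = pc.generate_scenario(6, "B", pc.ScenarioParams(n_advantaged=1), seed=1)
        refit = refit_excluding(ds.table, ["SA"])
        assert refit.verdict == "neutral"

    def test_excluding_departers_reduces_departing_fraction(self):
        ds = pc.generate_scenario(6, "B", seed=2)
        fit = sloan_fit(ds.table)
        assert fit.verdict == "subset_departure"
        refit = refit_excluding(ds.table, fit.departing_taxa)
        assert refit.departing_fraction < fit.departing_fraction

    def test_undecidable_when_too_few_taxa_remain(self):
        table, _, _ = pc.neutral_dataset(n_taxa=6, n_samples=50, depth=500,
                                         m=0.05, seed=6)
        refit = refit_excluding(table, table.taxa[:4])
        assert refit.verdict == "undecidable"
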