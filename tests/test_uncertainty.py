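"""Pedigree GSD, lognormal sampling and Monte Carlo propagation."""

import math

import numpy as np
import pandas as pd
import pytest

from spudlca.energy import Inventory
from spudlca.impact import CATEGORIES, CharacterizationModel
from spudlca.pathways import PathwayID
from spudlca.uncertainty import (
    PedigreeScores,
    cv,
    monte_carlo_impacts,
    pedigree_gsd,
    percentile_bounds,
    sample_lognormal,
    sensitivity,
)


def passthrough_model(flow="a"):
    """One flow feeding the first category with factor 1."""
    mid = pd.DataFrame(0.0, index=[flow], columns=list(CATEGORIES))
    mid.iloc[0, 0] = 1.0
    ep = pd.DataFrame(
        1.0, index=list(CATEGORIES), columns=["human_health", "ecosystems", "resources"]
    )
    refs = pd.Series(1.0, index=list(CATEGORIES))
    return CharacterizationModel(mid, ep, refs)


class TestPedigreeGsd:
    def test_perfect_scores_no_uncertainty(self):
        assert pedigree_gsd(PedigreeScores()) == pytest.approx(1.0)

    def test_single_indicator_passthrough(self):
        scores = PedigreeScores(reliability=2)  # factor 1.05
        assert pedigree_gsd(scores) == pytest.approx(1.05)

    def test_two_indicators_with_basic(self):
        # U = 1.05 (reliability 2), 1.10 (temporal 3), basic 1.05
        scores = PedigreeScores(reliability=2, temporal=3, basic_uncertainty=1.05)
        expected = math.exp(
            math.sqrt(
                math.log(1.05) ** 2 + math.log(1.10) ** 2 + math.log(1.05) ** 2
            )
        )
        assert pedigree_gsd(scores) == pytest.approx(expected)
        assert expected == pytest.approx(1.125, abs=1e-3)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PedigreeScores(reliability=6)


class TestSampleLognormal:
    def test_degenerate_gsd_returns_median(self):
        samples = sample_lognormal(3.0, 1.0, 100, seed=0)
        assert (samples == 3.0).all()

    def test_moment_recovery(self):
        samples = sample_lognormal(1.0, 1.2, 100_000, seed=42)
        sample_gsd = np.exp(np.log(samples).std(ddof=1))
        assert sample_gsd == pytest.approx(1.2, rel=0.01)
        assert np.exp(np.log(samples).mean()) == pytest.approx(1.0, rel=0.01)

    def test_seed_reproducibility(self):
        a = sample_lognormal(2.0, 1.3, 1000, seed=7)
        b = sample_lognormal(2.0, 1.3, 1000, seed=7)
        assert (a == b).all()

    def test_invalid_gsd_rejected(self):
        with pytest.raises(ValueError):
            sample_lognormal(1.0, 0.9, 10, seed=0)


class TestCv:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(4.96e-2, 3.06e-3, 6.17), (5.0, 0.0, 0.0), (5.38e-1, 3.79e-2, 7.04)],
    )
    def test_printed_rows(self, mean, sd, expected):
        assert cv(mean=mean, sd=sd) == pytest.approx(expected, abs=0.005)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv(mean=0.0, sd=1.0)

    def test_from_samples(self):
        samples = [1.0, 2.0, 3.0]
        assert cv(samples) == pytest.approx(100.0 * 1.0 / 2.0)


class TestPercentileBounds:
    def test_linear_interpolation_oracle(self):
        samples = np.arange(1, 101, dtype=float)
        lo, hi = percentile_bounds(samples)
        assert lo == pytest.approx(5.95)
        assert hi == pytest.approx(95.05)

    def test_constant_samples(self):
        lo, hi = percentile_bounds([4.0, 4.0, 4.0])
        assert lo == hi == 4.0

    def test_bounds_widen_with_gsd(self):
        widths = []
        for gsd in (1.05, 1.2, 1.5, 2.0):
            s = sample_lognormal(1.0, gsd, 2000, seed=11)
            lo, hi = percentile_bounds(s)
            widths.append(hi - lo)
        assert widths == sorted(widths)


class TestMonteCarlo:
    def test_gsd_one_collapses_to_deterministic(self):
        model = passthrough_model()
        inv = Inventory(PathwayID.parse("RW-US"), {"a": 2.0}, {"a": "kg"})
        pedigree = {"a": PedigreeScores()}  # gsd exactly 1
        frame, summaries = monte_carlo_impacts(inv, model, pedigree, n=100, seed=0)
        first = summaries[0]
        assert first.sd == 0.0
        assert first.cv_pct == 0.0
        assert (frame[CATEGORIES[0]] == 2.0).all()

    def test_single_flow_passthrough_distribution(self):
        model = passthrough_model()
        inv = Inventory(PathwayID.parse("RW-US"), {"a": 1.0}, {"a": "kg"})
        gsd = 1.25
        pedigree = {"a": PedigreeScores(reliability=5, temporal=4, basic_uncertainty=1.05)}
        from spudlca.uncertainty import pedigree_gsd

        g = pedigree_gsd(pedigree["a"])
        frame, _ = monte_carlo_impacts(inv, model, pedigree, n=20_000, seed=3)
        got = np.quantile(frame[CATEGORIES[0]], [0.1, 0.25, 0.5, 0.75, 0.9])
        # analytic lognormal quantiles with the same median/gsd
        from scipy.stats import norm

        expected = np.exp(np.log(g) * norm.ppf([0.1, 0.25, 0.5, 0.75, 0.9]))
        assert np.allclose(got, expected, rtol=0.03)

    def test_summary_deterministic_under_seed(self, model, pedigree):
        inv = Inventory(
            PathwayID.parse("BL-FG", 2),
            {"potato": 1.07, "electricity": 1.06, "tap water": 1.9},
            {"potato": "kg", "electricity": "kWh", "tap water": "kg"},
        )
        _, s1 = monte_carlo_impacts(inv, model, pedigree, n=500, seed=9)
        _, s2 = monte_carlo_impacts(inv, model, pedigree, n=500, seed=9)
        assert [(x.mean, x.sd, x.lower, x.upper) for x in s1] == [
            (x.mean, x.sd, x.lower, x.upper) for x in s2
        ]

    def test_cv_stable_across_seeds(self, model):
        inv = Inventory(
            PathwayID.parse("BL-FG", 2),
            {"potato": 1.07, "electricity": 1.06, "tap water": 1.9},
            {"potato": "kg", "electricity": "kWh", "tap water": "kg"},
        )
        # moderate pedigree typical of measured foreground data
        pedigree = {
            f: PedigreeScores(reliability=2, completeness=2, temporal=2,
                              basic_uncertainty=1.05)
            for f in inv.flows
        }
        cvs = []
        for seed in range(20):
            _, summaries = monte_carlo_impacts(inv, model, pedigree, n=1000, seed=seed)
            cvs.append(summaries[0].cv_pct)
        assert np.std(cvs) < 0.5  # percentage points

    def test_mean_matches_lognormal_identity(self):
        # E[X] = median * exp(ln(gsd)^2 / 2) for a median-preserving lognormal
        model = passthrough_model()
        inv = Inventory(PathwayID.parse("RW-US"), {"a": 1.0}, {"a": "kg"})
        pedigree = {"a": PedigreeScores(technological=4, basic_uncertainty=1.1)}
        from spudlca.uncertainty import pedigree_gsd

        g = pedigree_gsd(pedigree["a"])
        frame, _ = monte_carlo_impacts(inv, model, pedigree, n=100_000, seed=1)
        expected = math.exp(math.log(g) ** 2 / 2.0)
        assert frame[CATEGORIES[0]].mean() == pytest.approx(expected, rel=0.01)


class TestSensitivity:
    @staticmethod
    def linear_run(params):
        # midpoint scores proportional to the electricity parameter
        base = pd.Series(np.arange(1.0, 19.0), index=list(CATEGORIES))
        return base * params["electricity"]

    def test_linear_passthrough_is_responsive_at_boundary(self):
        table = sensitivity(self.linear_run, {"electricity": 1.0}, "electricity")
        up = table[table.delta_pct > 0]
        assert np.allclose(up.change_pct, 10.0)
        assert up.responsive.all()

    def test_zero_weight_parameter(self):
        def run(params):
            return pd.Series(1.0, index=list(CATEGORIES))

        table = sensitivity(run, {"oil": 2.0}, "oil")
        assert (table.change_pct == 0.0).all()
        assert not table.responsive.any()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            sensitivity(self.linear_run, {"electricity": 1.0}, "frobnication")

    def test_share_weighted_sensitivity_oracle(self, model):
        """Perturbing one flow moves each category by its contribution
        share times the perturbation."""
        from spudlca.impact import characterize, contribution_table
        from spudlca.energy import Inventory

        flows = dict(zip(model.midpoint_factors.index, [1.0, 2.0, 0.5, 0.1, 3.0]))
        units = {f: "kg" for f in flows}
        inv = Inventory(PathwayID.parse("RW-US"), flows, units)
        shares = contribution_table(inv, model, cutoff=0.0)
        target = list(flows)[1]

        def run(params):
            f = dict(flows)
            f[target] = params["x"]
            return characterize(
                Inventory(PathwayID.parse("RW-US"), f, units), model
            ).score

        table = sensitivity(run, {"x": flows[target]}, "x", top_k=18)
        up = table[table.delta_pct > 0].set_index("category")
        for cat in CATEGORIES:
            expected = 10.0 * shares.loc[target, cat]
            assert up.loc[cat, "change_pct"] == pytest.approx(expected, abs=1e-8)
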