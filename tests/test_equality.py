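"""Gini/G' arithmetic, collinearity pruning, and trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from equirep import (UndefinedEqualityError, compute_equality, equality_index,
                     gini, kendall_tau, prune_collinear, territory_equality,
                     trajectory)
from equirep.equality import ecoregion_equality, protection_extent_pct
from equirep.representation import RepresentationHistogram

from conftest import toy_cell_table


def gini_mean_abs_difference(values):
    """Independent oracle: G = sum_ab |x_a - x_b| / (2 n^2 mean)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())


class TestGini:
    def test_constant_vector_max_equality(self):
        assert equality_index([5.0] * 10) == pytest.approx(1.0, abs=1e-12)

    def test_single_nonzero_bin_floor_is_one_over_n(self):
        # the rank formula bottoms out at G = (n-1)/n, so G' = 1/n, not 0
        assert gini([0.0] * 9 + [8.0]) == pytest.approx(0.9, abs=1e-12)
        assert equality_index([10.0] + [0.0] * 9) == pytest.approx(0.1, abs=1e-12)

    def test_rank_formula_matches_mean_abs_difference_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 30)
            x = rng.uniform(0, 100, n)
            assert abs(gini(x) - gini_mean_abs_difference(x)) < 1e-12

    def test_scale_invariance_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, 10)
        assert gini(3.7 * x) == pytest.approx(gini(x), abs=1e-12)
        assert gini(rng.permutation(x)) == pytest.approx(gini(x), abs=1e-12)

    def test_all_zero_raises_not_zero(self):
        with pytest.raises(UndefinedEqualityError):
            gini([0.0] * 10)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=10).filter(
        lambda v: sum(v) > 0))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, values):
        n = len(values)
        g = gini(values)
        assert -1e-12 <= g <= (n - 1) / n + 1e-12
        assert 1 / n - 1e-12 <= equality_index(values) <= 1 + 1e-12


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, -x) == pytest.approx(-1.0)

    def test_one_discordant_pair_of_three(self):
        # pairs: (1,2)+(1,3) concordant, (2,3) discordant -> (2-1)/3 = 1/3
        assert kendall_tau([1, 2, 3], [1, 3, 2]) == pytest.approx(1 / 3)

    def test_constant_margin_undefined(self):
        with pytest.raises(ValueError, match="constant margin"):
            kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPruning:
    def make_values(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {f"v{i}": rng.normal(size=n) for i in range(1, 6)}
        )

    def test_independent_variables_all_retained(self):
        vals = self.make_values()
        retained, report = prune_collinear(vals, threshold=0.55)
        assert retained == list(vals.columns)
        assert all(d["eliminated"] is None for d in report.decisions)

    def test_duplicated_neighbor_eliminates_the_earlier(self):
        vals = self.make_values()
        vals["v2"] = vals["v1"]  # tau(v1, v2) = 1
        retained, report = prune_collinear(vals, threshold=0.55)
        assert retained == ["v2", "v3", "v4", "v5"]
        assert report.decisions[0]["eliminated"] == "v1"

    def test_chain_elimination_hand_trace(self):
        vals = self.make_values(seed=1)
        vals["v1"] = vals["v2"] + 0.1 * np.random.default_rng(2).normal(
            size=len(vals))  # |tau(1,2)| > 0.55, v2 vs v3 independent
        retained, _ = prune_collinear(vals, threshold=0.55)
        assert retained == ["v2", "v3", "v4", "v5"]

    def test_deterministic_report(self):
        vals = self.make_values(seed=3)
        r1, rep1 = prune_collinear(vals)
        r2, rep2 = prune_collinear(vals)
        assert r1 == r2
        pd.testing.assert_frame_equal(rep1.tau_matrix, rep2.tau_matrix)

    def test_single_survivor_warns(self):
        vals = self.make_values()
        for c in ["v2", "v3", "v4", "v5"]:
            vals[c] = vals["v1"] + 1e-6 * np.random.default_rng(4).normal(
                size=len(vals))
        with pytest.warns(UserWarning, match="fewer than 2"):
            retained, _ = prune_collinear(vals, threshold=0.55)
        assert len(retained) == 1


def hist(pex, territory="T1", variable="elevation", period=2016):
    pex = np.asarray(pex, dtype=float)
    area = np.ones_like(pex)
    return RepresentationHistogram(territory, variable, period,
                                   np.arange(len(pex) + 1.0), area, area * pex / 100)


class TestTerritoryEquality:
    def test_mean_of_retained_gprimes(self):
        hists = {"a": hist([10.0] * 10, variable="a"),
                 "b": hist([30.0] + [0.0] * 9, variable="b")}
        res = territory_equality(hists, ["a", "b"], extent_pct=5.0)
        assert res.per_variable["a"] == pytest.approx(1.0)
        assert res.per_variable["b"] == pytest.approx(0.1)
        assert res.mean_gprime == pytest.approx(0.55)

    def test_all_zero_variable_reported_undefined_with_warning(self):
        hists = {"a": hist([10.0] * 10, variable="a"),
                 "b": hist([0.0] * 10, variable="b")}
        res = territory_equality(hists, ["a", "b"], extent_pct=5.0)
        assert res.per_variable["b"] is None
        assert res.mean_gprime == pytest.approx(1.0)
        assert any("undefined" in w for w in res.warnings)

    def test_single_ecoregion_territory_is_undefined(self):
        tab = pd.DataFrame({"ecoregion": ["E1"], "area_km2": [10.0],
                            "protected_km2": [1.0], "pex_pct": [10.0]})
        res = ecoregion_equality(tab, "T1", 2016, extent_pct=10.0)
        assert res.mean_gprime is None
        assert any("single biogeographical unit" in w for w in res.warnings)


class TestTrajectory:
    def make_table(self, protected_by_period):
        frames = []
        n = 60
        rng = np.random.default_rng(0)
        elev = rng.uniform(0, 10, n)
        temp = rng.uniform(5, 30, n)
        for period, frac in protected_by_period.items():
            prot = np.zeros(n)
            k = int(frac * n)
            prot[:k] = 1.0
            frames.append(toy_cell_table(np.ones(n), prot,
                                         {"elevation": elev, "temperature": temp},
                                         period=period))
        return pd.concat(frames, ignore_index=True)

    def test_frozen_network_keeps_points_identical_and_efficiency_undefined(self):
        tab = self.make_table({1960: 0.1, 1980: 0.2, 2000: 0.2, 2016: 0.2})
        pts = trajectory(tab, "T1", n_bins=5,
                         variables=("temperature", "elevation"))
        assert pts[1].extent_pct == pts[2].extent_pct == pts[3].extent_pct
        assert pts[2].mean_gprime == pytest.approx(pts[1].mean_gprime)
        assert pts[2].efficiency is None and pts[3].efficiency is None

    def test_extent_nondecreasing(self):
        tab = self.make_table({1960: 0.05, 1980: 0.1, 2000: 0.3, 2016: 0.5})
        pts = trajectory(tab, "T1", n_bins=5,
                         variables=("temperature", "elevation"))
        extents = [p.extent_pct for p in pts]
        assert extents == sorted(extents)

    def test_uniform_infill_growth_has_nonnegative_efficiency(self, landscape):
        """A network that grows by uniform infill never loses equality."""
        from equirep import (PlacementScenario, build_cell_table,
                             generate_protected_network)
        scenario = PlacementScenario("uniform", total_protected_fraction=0.2,
                                     n_units=10)
        records, _ = generate_protected_network(landscape, scenario, seed=9)
        tab = build_cell_table(landscape, records)
        for terr in ("T1", "T2"):
            for pt in trajectory(tab, terr):
                if pt.efficiency is not None:
                    assert pt.efficiency >= -1e-9


def test_extent_percent_arithmetic():
    tab = toy_cell_table([6.0, 4.0], [3.0, 1.0], {"elevation": [0.1, 0.9]})
    assert protection_extent_pct(tab, "T1", 2016) == pytest.approx(40.0)
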