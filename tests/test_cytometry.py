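"""DEFAC cytometry: gating, geometric MFI, the flux statistic, level comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from defac.cytometry import (
    GateConfig,
    assign_levels,
    compare_levels,
    compute_flux,
    defac_analysis,
    exclude_dead,
    geometric_mfi,
    quench_control,
)
from defac.simulate import DEFAULT_GATE, DefacSimSpec, gen_defac_events


class TestExcludeDead:
    def test_dye_positive_events_removed(self, table_factory):
        df = pd.DataFrame(
            {
                "gfp": np.ones(10),
                "lc3": np.ones(10),
                "viability": [10.0] * 7 + [5000.0] * 3,
            }
        )
        out = exclude_dead(table_factory(df), threshold=1000.0)
        assert len(out) == 7

    def test_threshold_above_max_is_identity(self, table_factory, tiny_events):
        out = exclude_dead(table_factory(tiny_events), threshold=1e9)
        assert len(out) == len(tiny_events)

    def test_all_dead_raises(self, table_factory):
        df = pd.DataFrame({"gfp": [1.0], "lc3": [1.0], "viability": [5000.0]})
        with pytest.raises(ValueError, match="no viable"):
            exclude_dead(table_factory(df), threshold=1000.0)

    def test_dead_fraction_matches_binomial_expectation(self, table_factory):
        rng = np.random.default_rng(11)
        n, dead_frac = 10000, 0.2
        dead = rng.random(n) < dead_frac
        df = pd.DataFrame(
            {
                "gfp": np.ones(n),
                "lc3": np.ones(n),
                "viability": np.where(dead, 5000.0, 100.0),
            }
        )
        out = exclude_dead(table_factory(df), threshold=1000.0)
        retained_frac = len(out) / n
        tol = 3 * np.sqrt(dead_frac * (1 - dead_frac) / n)
        assert abs(retained_frac - (1 - dead_frac)) < tol


class TestAssignLevels:
    def test_extremes_and_boundary_convention(self, table_factory, gate):
        df = pd.DataFrame(
            {
                "gfp": [10.0, 1e6, 1000.0],  # below first, above last, exactly boundary 2
                "lc3": [1.0] * 3,
                "viability": [1.0] * 3,
            }
        )
        levels = assign_levels(table_factory(df), gate)
        assert list(levels) == [0, 4, 2]  # boundary value goes to the higher level

    def test_levels_partition_events(self, table_factory, gate):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "gfp": rng.lognormal(8, 2, 5000),
                "lc3": np.ones(5000),
                "viability": np.ones(5000),
            }
        )
        levels = assign_levels(table_factory(df), gate)
        assert sum((levels == lv).sum() for lv in range(5)) == 5000

    def test_non_monotone_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            GateConfig(viability_threshold=1.0, gfp_boundaries=(10, 5, 20, 30))


class TestGeometricMfi:
    def test_two_point_value(self):
        assert geometric_mfi([10.0, 1000.0]) == pytest.approx(100.0)

    def test_constant_identity(self):
        assert geometric_mfi([7.0, 7.0, 7.0]) == pytest.approx(7.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=50),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_homogeneity(self, values, scale):
        base = geometric_mfi(values)
        scaled = geometric_mfi([v * scale for v in values])
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    def test_empty_flagged_not_raised(self):
        assert np.isnan(geometric_mfi([]))

    def test_nonpositive_names_transform_policy(self):
        with pytest.raises(ValueError, match="transform"):
            geometric_mfi([1.0, 0.0])


class TestComputeFlux:
    @pytest.mark.parametrize(
        "bafa1,untreated,expected", [(100, 100, 0.0), (100, 0, 100.0), (200, 150, 25.0)]
    )
    def test_formula_values(self, bafa1, untreated, expected):
        assert compute_flux(bafa1, untreated) == pytest.approx(expected)

    def test_nonpositive_bafa1_rejected(self):
        with pytest.raises(ValueError):
            compute_flux(0.0, 10.0)

    def test_negative_flux_reported_not_clipped(self):
        assert compute_flux(100.0, 150.0) == pytest.approx(-50.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mfi_b=st.floats(min_value=1.0, max_value=1e5),
        mfi_u=st.floats(min_value=0.0, max_value=1e5),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_invariant_under_common_rescaling(self, mfi_b, mfi_u, scale):
        assert compute_flux(mfi_b * scale, mfi_u * scale) == pytest.approx(
            compute_flux(mfi_b, mfi_u), abs=1e-9
        )

    def test_same_formula_applies_to_densitometry_pairs(self):
        # western-blot LC3-II band intensities: one formula, two data sources
        lc3ii_bafa1, lc3ii_untreated = 2.4, 0.9
        assert compute_flux(lc3ii_bafa1, lc3ii_untreated) == pytest.approx(62.5)


class TestDefacAnalysis:
    def test_table_against_itself_is_exactly_zero(self, table_factory):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "gfp": rng.lognormal(8, 1.5, 3000),
                "lc3": rng.lognormal(7, 0.5, 3000),
                "viability": np.full(3000, 100.0),
            }
        )
        t_u = table_factory(df, treatment="untreated")
        t_b = table_factory(df.copy(), treatment="bafa1")
        table = defac_analysis(t_u, t_b, DEFAULT_GATE)
        defined = table.summary[table.summary["flux_defined"]]
        assert (defined["flux_pct"] == 0.0).all()

    def test_flux_invariant_under_lc3_rescaling(self, table_factory):
        spec = DefacSimSpec(seed=7, n_events=5000, n_replicates=1)
        (unt, baf), = gen_defac_events(spec)
        base = defac_analysis(unt, baf, spec.gate)
        unt2 = unt.with_events(unt.events.assign(lc3=unt.events["lc3"] * 3.7))
        baf2 = baf.with_events(baf.events.assign(lc3=baf.events["lc3"] * 3.7))
        scaled = defac_analysis(unt2, baf2, spec.gate)
        np.testing.assert_allclose(
            base.summary["flux_pct"], scaled.summary["flux_pct"], rtol=1e-9
        )

    def test_recovers_generator_truth_within_5_points(self):
        spec = DefacSimSpec(seed=42, n_events=20000, n_replicates=3)
        pairs = gen_defac_events(spec)
        table = defac_analysis([u for u, _ in pairs], [b for _, b in pairs], spec.gate)
        for lv, truth in enumerate(spec.true_flux_by_level):
            assert table.flux(lv) == pytest.approx(truth, abs=5.0)

    def test_mock_construct_yields_null_flux(self):
        spec = DefacSimSpec(seed=8, true_flux_by_level=(0, 0, 0, 0, 0), construct="mock")
        pairs = gen_defac_events(spec)
        table = defac_analysis([u for u, _ in pairs], [b for _, b in pairs], spec.gate)
        for lv in range(5):
            assert table.flux(lv) == pytest.approx(0.0, abs=3.0)

    def test_replicate_mismatch_rejected(self, table_factory, tiny_events):
        t1 = table_factory(tiny_events, replicate=1)
        t2 = table_factory(tiny_events, treatment="bafa1", replicate=2)
        with pytest.raises(ValueError, match="replicate"):
            defac_analysis([t1], [t2], DEFAULT_GATE)

    def test_sparse_level_flagged_not_reported(self, table_factory):
        # all events in level 0; levels 1-4 below min_events threshold
        df = pd.DataFrame(
            {"gfp": np.full(500, 10.0), "lc3": np.full(500, 100.0), "viability": np.ones(500)}
        )
        gate = GateConfig(
            viability_threshold=1000.0, gfp_boundaries=(200, 1000, 5000, 25000), min_events_per_level=100
        )
        t_u = table_factory(df)
        t_b = table_factory(df.copy(), treatment="bafa1")
        table = defac_analysis(t_u, t_b, gate)
        assert table.summary.loc[table.summary["level"] == 0, "flux_defined"].iloc[0]
        assert not table.summary.loc[table.summary["level"] == 4, "flux_defined"].iloc[0]
        assert np.isnan(table.flux(4))


class TestQuenchControl:
    def test_identical_tables_pass(self, table_factory, tiny_events):
        t = table_factory(tiny_events)
        ok, ratio = quench_control(t, table_factory(tiny_events, treatment="bafa1"))
        assert ok and ratio == pytest.approx(1.0)

    def test_halved_gfp_fails_at_tolerance(self, table_factory, tiny_events):
        t_u = table_factory(tiny_events)
        t_b = table_factory(tiny_events.assign(gfp=tiny_events["gfp"] * 0.5), treatment="bafa1")
        ok, ratio = quench_control(t_u, t_b, tolerance=0.2)
        assert not ok and ratio == pytest.approx(0.5)

    def test_simulated_quench_free_pairs_pass(self):
        spec = DefacSimSpec(seed=13, n_events=10000, n_replicates=1)
        (unt, baf), = gen_defac_events(spec)
        ok, _ = quench_control(unt, baf, tolerance=0.1)
        assert ok


class TestCompareLevels:
    def _table_from_fluxes(self, fluxes_by_level):
        rows = []
        for lv, fluxes in enumerate(fluxes_by_level):
            for rep, f in enumerate(fluxes, 1):
                rows.append(
                    {"level": lv, "replicate": rep, "flux_pct": f, "flux_defined": True}
                )
        per_rep = pd.DataFrame(rows)
        summary = pd.DataFrame({"level": range(5), "flux_pct": [np.mean(f) for f in fluxes_by_level]})
        from defac.cytometry import LevelFluxTable

        return LevelFluxTable(summary=summary, per_replicate=per_rep, baseline_lc3=0.0)

    def test_identical_replicates_give_p_one(self):
        a = self._table_from_fluxes([[10, 10, 10]] * 5)
        res = compare_levels(a, a)
        assert (res["p"] == 1.0).all()

    def test_separated_groups_highly_significant(self):
        jitter = [0.01, -0.01, 0.005]
        a = self._table_from_fluxes([[10 + j for j in jitter]] * 5)
        b = self._table_from_fluxes([[50 + j for j in jitter]] * 5)
        res = compare_levels(a, b)
        assert (res["p"] < 0.001).all()
        assert (res["stars"] == "***").all()

    def test_null_vs_active_construct_significant_at_expressed_levels(self):
        ld = DefacSimSpec(seed=21, n_events=8000, true_flux_by_level=(0, 0, 0, 0, 0), construct="LD")
        wt = DefacSimSpec(seed=22, n_events=8000, true_flux_by_level=(0, 60, 60, 60, 60), construct="WT")
        t_ld = defac_analysis(*map(list, zip(*gen_defac_events(ld))), ld.gate)
        t_wt = defac_analysis(*map(list, zip(*gen_defac_events(wt))), wt.gate)
        res = compare_levels(t_ld, t_wt)
        for lv in range(1, 5):
            assert res.loc[res["level"] == lv, "p"].iloc[0] < 0.05

    def test_single_replicate_flagged_untestable(self):
        a = self._table_from_fluxes([[10]] * 5)
        res = compare_levels(a, a)
        assert not res["testable"].any()
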