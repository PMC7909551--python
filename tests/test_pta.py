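import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amikpk import (
    CovariateModel,
    DiscretePopulation,
    ExposureSamples,
    MICDistribution,
    Regimen,
    TargetDefinition,
    fta,
    pta,
    pta_table,
    simulate_exposures,
)


@pytest.fixture
def typical_point_population():
    """Degenerate population: all mass at the final-model means."""
    return DiscretePopulation(
        support=np.array([[2.25, 18.0]]),
        probabilities=np.array([1.0]),
        covariate_model=CovariateModel(),
    )


class TestSimulateExposures:
    def test_degenerate_population_matches_closed_form(
        self, typical_point_population
    ):
        s = simulate_exposures(
            typical_point_population, Regimen(800.0, 24.0), ccr=52.9,
            n=50, seed=0,
        )
        np.testing.assert_allclose(s.cmax, 40.47, atol=0.005)
        np.testing.assert_allclose(s.cmin, 2.43, atol=0.005)

    def test_cmax_linear_in_dose(self, typical_point_population):
        s1 = simulate_exposures(
            typical_point_population, Regimen(800.0, 24.0), 52.9, 20, seed=3
        )
        s2 = simulate_exposures(
            typical_point_population, Regimen(1600.0, 24.0), 52.9, 20, seed=3
        )
        np.testing.assert_allclose(s2.cmax, 2 * s1.cmax, rtol=1e-12)

    def test_fixed_seed_reproducible(self, population):
        a = simulate_exposures(population, Regimen(800.0, 48.0), 40.0, 100, 7)
        b = simulate_exposures(population, Regimen(800.0, 48.0), 40.0, 100, 7)
        np.testing.assert_array_equal(a.cmax, b.cmax)
        np.testing.assert_array_equal(a.cmin, b.cmin)

    def test_interval_restricted(self):
        with pytest.raises(ValueError):
            Regimen(800.0, 36.0)


class TestPTA:
    def test_counts_match_hand_enumeration(self):
        cmax = np.array([40, 30, 65, 80, 10, 33, 64, 12, 90, 31.9])
        cmin = np.array([1, 5, 2, 3.9, 4.1, 0.5, 4.0, 2, 3, 1])
        samples = ExposureSamples(cmax, cmin)
        eff, safe, joint = pta(samples, mic=4.0)
        # Cmax/4 >= 8 <=> Cmax >= 32: indices 0,2,3,5(33),6,9? 31.9 no ->
        # {40,65,80,33,64,90} = 6 of 10
        assert eff == 60.0
        # Cmin < 4: all but 5 (cmin=5), 4.1 and 4.0 -> 7 of 10
        assert safe == 70.0
        # joint: rows 0,2,3,5,8 -> 50%... row by row:
        # (40,1)y (30,5)n (65,2)y (80,3.9)y (10,4.1)n (33,0.5)y
        # (64,4.0)n (12,2)n (90,3)y (31.9,1)n -> 5
        assert joint == 50.0

    def test_degenerate_all_pass(self):
        samples = ExposureSamples(np.full(10, 100.0), np.full(10, 1.0))
        assert pta(samples, 4.0) == (100.0, 100.0, 100.0)

    def test_joint_never_exceeds_components(self, population):
        s = simulate_exposures(population, Regimen(1000.0, 48.0), 50.0, 500, 1)
        for mic in (4.0, 8.0, 16.0):
            eff, safe, joint = pta(s, mic)
            assert joint <= min(eff, safe)

    def test_doubling_mic_never_raises_efficacy(self, population):
        s = simulate_exposures(population, Regimen(1200.0, 24.0), 60.0, 500, 2)
        for mic in (1.0, 2.0, 4.0, 8.0, 16.0):
            assert pta(s, 2 * mic)[0] <= pta(s, mic)[0]

    def test_safety_comparison_configurable(self):
        samples = ExposureSamples(np.array([100.0]), np.array([4.0]))
        assert pta(samples, 4.0)[1] == 0.0  # strict: 4.0 < 4 fails
        loose = TargetDefinition(safety_strict=False)
        assert pta(samples, 4.0, loose)[1] == 100.0

    def test_invalid_mic(self):
        samples = ExposureSamples(np.array([10.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            pta(samples, 0.0)


class TestFTA:
    def test_single_mic_equals_its_pta(self):
        dist = MICDistribution(np.array([8.0]), np.array([1.0]))
        assert fta({8.0: 73.5}, dist) == 73.5

    def test_convex_combination(self):
        dist = MICDistribution(np.array([4.0, 8.0]), np.array([0.5, 0.5]))
        assert fta({4.0: 80.0, 8.0: 100.0}, dist) == pytest.approx(90.0)

    @given(
        ptas=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=6),
        raw_freqs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    def test_bounded_by_min_and_max_pta(self, ptas, raw_freqs):
        k = min(len(ptas), len(raw_freqs))
        ptas, raw = ptas[:k], np.array(raw_freqs[:k])
        freqs = raw / raw.sum()
        freqs[-1] = 1.0 - freqs[:-1].sum()  # exact normalization
        mics = np.array([2.0**i for i in range(k)])
        dist = MICDistribution(mics, freqs)
        value = fta(dict(zip(mics, ptas)), dist)
        assert min(ptas) - 1e-9 <= value <= max(ptas) + 1e-9

    def test_missing_mic_entry_rejected(self):
        dist = MICDistribution(np.array([4.0, 8.0]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            fta({4.0: 80.0}, dist)

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError):
            MICDistribution(np.array([4.0, 8.0]), np.array([0.5, 0.6]))

    def test_bundled_example_distribution_loads(self):
        dist = MICDistribution.example_pseudomonas()
        assert dist.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.mics) > 0)


@pytest.fixture(scope="module")
def grid():
    from amikpk import ParametricPopulation

    return pta_table(
        ParametricPopulation(),
        doses=(400.0, 800.0, 1200.0),
        ccr_values=(20.0, 50.0, 80.0),
        n=400,
        seed=11,
    )


class TestPTATable:
    def test_shape_full_factorial(self, grid):
        # 3 CCr x 3 intervals x 3 doses x 3 MICs
        assert len(grid.table) == 81
        assert grid.wide(8.0, interval_h=24.0).shape == (3, 3)

    def test_joint_bounded_by_components_everywhere(self, grid):
        t = grid.table
        assert (t["joint_pct"] <= t["efficacy_pct"] + 1e-12).all()
        assert (t["joint_pct"] <= t["safety_pct"] + 1e-12).all()
        assert t[["efficacy_pct", "safety_pct", "joint_pct"]].min().min() >= 0
        assert t[["efficacy_pct", "safety_pct", "joint_pct"]].max().max() <= 100

    def test_joint_non_increasing_in_mic_within_cell(self, grid):
        for _, cell in grid.table.groupby(["ccr", "dose_mg", "interval_h"]):
            vals = cell.sort_values("mic")["joint_pct"].to_numpy()
            assert np.all(np.diff(vals) <= 0)

    def test_monotonicities_under_shared_draws(self, population):
        """With common random numbers, efficacy rises with dose and
        safety falls with dose, rises with CCr and interval."""
        doses = (400.0, 800.0, 1600.0)
        eff = [
            pta(simulate_exposures(population, Regimen(d, 24.0), 50.0, 400, 5),
                8.0)[0]
            for d in doses
        ]
        safe = [
            pta(simulate_exposures(population, Regimen(d, 24.0), 50.0, 400, 5),
                8.0)[1]
            for d in doses
        ]
        assert np.all(np.diff(eff) >= 0)
        assert np.all(np.diff(safe) <= 0)
        safe_ccr = [
            pta(simulate_exposures(population, Regimen(800.0, 24.0), c, 400, 5),
                8.0)[1]
            for c in (20.0, 50.0, 80.0)
        ]
        assert np.all(np.diff(safe_ccr) >= 0)
        safe_int = [
            pta(simulate_exposures(population, Regimen(800.0, iv), 30.0, 400, 5),
                8.0)[1]
            for iv in (24.0, 48.0, 72.0)
        ]
        assert np.all(np.diff(safe_int) >= 0)

    def test_zero_variability_gives_indicator_pta(
        self, typical_point_population
    ):
        s = simulate_exposures(
            typical_point_population, Regimen(800.0, 24.0), 52.9, 200, 1
        )
        for mic in (4.0, 8.0, 16.0):
            assert pta(s, mic)[2] in (0.0, 100.0)
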