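"""Cell cycle, necrosis, volume dynamics, and division."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hepamet import phenotype as ph
from hepamet.params import PhenotypeParams
from hepamet.population import (
    PHASE_APOPTOTIC,
    PHASE_KI67_NEG,
    PHASE_KI67_POST,
    PHASE_KI67_PRE,
    PHASE_NECROTIC,
    TYPE_PARENCHYMA,
    TYPE_TUMOR,
    CellPopulation,
)


class TestRates:
    def test_oxygen_multiplier_boundaries(self, phen_params):
        assert ph.oxygen_multiplier(phen_params.sigma_H, phen_params) == 0.0
        assert ph.oxygen_multiplier(phen_params.sigma_sat, phen_params) == 1.0
        assert ph.oxygen_multiplier(100.0, phen_params) == 1.0
        mid = 0.5 * (phen_params.sigma_H + phen_params.sigma_sat)
        assert ph.oxygen_multiplier(mid, phen_params) == pytest.approx(0.5)

    def test_cycle_arrest_above_p2(self, phen_params):
        for sigma in (10.0, 38.0, 60.0):
            assert ph.cycle_entry_rate(sigma, 1.0, phen_params) == 0.0
            assert ph.cycle_entry_rate(sigma, 1.7, phen_params) == 0.0

    def test_no_restriction_below_p1(self, phen_params):
        r = ph.cycle_entry_rate(60.0, 0.0, phen_params)
        assert r == pytest.approx(phen_params.r01_max)

    def test_linear_pressure_interpolation(self, phen_params):
        r = ph.cycle_entry_rate(60.0, 0.5, phen_params)
        assert r == pytest.approx(0.5 * phen_params.r01_max)

    def test_rate_factorizes(self, phen_params):
        """Entry rate = oxygen factor x pressure factor, each in [0, max]."""
        rng = np.random.default_rng(0)
        sig = rng.uniform(0, 80, 50)
        p = rng.uniform(0, 2, 50)
        got = ph.cycle_entry_rate(sig, p, phen_params)
        expected = (
            phen_params.r01_max
            * ph.oxygen_multiplier(sig, phen_params)
            * ph.pressure_multiplier(p, phen_params)
        )
        np.testing.assert_allclose(got, expected)
        assert (got >= 0).all() and (got <= phen_params.r01_max).all()

    def test_necrosis_rate_ramp(self, phen_params):
        assert ph.necrosis_rate(phen_params.sigma_H, phen_params) == 0.0
        assert ph.necrosis_rate(10.0, phen_params) == 0.0
        assert ph.necrosis_rate(0.0, phen_params) == pytest.approx(
            phen_params.r_N_max
        )
        assert ph.necrosis_rate(2.5, phen_params) == pytest.approx(
            0.5 * phen_params.r_N_max
        )


def _tumor_cells(n: int, radius: float = 8.4) -> CellPopulation:
    pop = CellPopulation(thickness=30.0)
    pop.add(np.zeros((n, 2)), TYPE_TUMOR, radius)
    return pop


class TestAdvancePhase:
    def test_zero_rate_keeps_quiescent(self, phen_params):
        pop = _tumor_cells(50)
        pop.oxygen[:] = 0.0  # below the hypoxic threshold: no entry
        rng = np.random.default_rng(0)
        for _ in range(100):
            ph.advance_phase(pop, 6.0, phen_params, rng)
        assert (pop.phase == PHASE_KI67_NEG).all()

    def test_premitotic_divides_after_T_K1(self, phen_params):
        pop = _tumor_cells(1)
        pop.phase[0] = PHASE_KI67_PRE
        pop.phase_clock[0] = 0.0
        rng = np.random.default_rng(0)
        n_steps = int(phen_params.T_K1 / 6.0)
        dividing = np.zeros(0)
        for _ in range(n_steps + 1):
            dividing = ph.advance_phase(pop, 6.0, phen_params, rng)
            if len(dividing):
                break
        assert len(dividing) == 1

    def test_postmitotic_returns_to_quiescence(self, phen_params):
        pop = _tumor_cells(1)
        pop.phase[0] = PHASE_KI67_POST
        rng = np.random.default_rng(0)
        for _ in range(int(phen_params.T_K2 / 6.0) + 1):
            ph.advance_phase(pop, 6.0, phen_params, rng)
        assert pop.phase[0] == PHASE_KI67_NEG

    def test_mean_quiescent_dwell_time(self):
        """Exponential waiting: mean dwell ~ 1/r01 within 3 standard errors."""
        params = PhenotypeParams(r01_max=1.0 / 120.0)
        n = 4000
        pop = _tumor_cells(n)
        pop.oxygen[:] = params.sigma_sat
        pop.pressure[:] = 0.0
        rng = np.random.default_rng(12345)
        dt = 1.0
        waits = np.full(n, np.nan)
        for k in range(1, 2001):
            quiesc_before = pop.phase == PHASE_KI67_NEG
            ph.advance_phase(pop, dt, params, rng)
            entered = quiesc_before & (pop.phase == PHASE_KI67_PRE)
            waits[entered & np.isnan(waits)] = k * dt
            # freeze entered cells so they are not re-counted
            pop.phase[pop.phase != PHASE_KI67_NEG] = PHASE_KI67_PRE
            pop.phase_clock[pop.phase == PHASE_KI67_PRE] = -1e9
        waits = waits[~np.isnan(waits)]
        assert len(waits) > 3000
        se = waits.std(ddof=1) / np.sqrt(len(waits))
        # discrete-time sampling adds ~dt/2 to the observed mean
        assert abs(waits.mean() - dt / 2 - 120.0) < 3 * se + dt

    def test_parenchyma_never_cycles(self, phen_params):
        pop = CellPopulation(thickness=30.0)
        pop.add(np.zeros((20, 2)), TYPE_PARENCHYMA, 15.0, anchored=True)
        pop.oxygen[:] = 60.0
        rng = np.random.default_rng(0)
        for _ in range(200):
            ph.advance_phase(pop, 6.0, phen_params, rng)
        assert (pop.phase == PHASE_KI67_NEG).all()


class TestNecrosis:
    def test_no_necrosis_above_threshold(self, phen_params):
        pop = _tumor_cells(200)
        pop.oxygen[:] = phen_params.sigma_H + 1.0
        rng = np.random.default_rng(0)
        for _ in range(100):
            ph.necrosis_check(pop, 6.0, phen_params, rng)
        assert not (pop.phase == PHASE_NECROTIC).any()

    def test_anoxia_necroses_at_max_rate(self, phen_params):
        pop = _tumor_cells(4000)
        pop.oxygen[:] = 0.0
        rng = np.random.default_rng(1)
        ph.necrosis_check(pop, 60.0, phen_params, rng)
        frac = (pop.phase == PHASE_NECROTIC).mean()
        expected = 1.0 - np.exp(-phen_params.r_N_max * 60.0)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected / 4000))

    def test_necrotic_shrinks_and_is_removed(self, phen_params):
        pop = _tumor_cells(1)
        pop.phase[0] = PHASE_NECROTIC
        pop.target_volume[0] = 0.0
        vols = []
        for _ in range(int(2 * phen_params.T_lysis / 6.0)):
            ph.update_volume(pop, 6.0, phen_params)
            if len(pop) and pop.phase[0] == PHASE_NECROTIC:
                vols.append(pop.volume[0])
            ph.remove_dead(pop)
            if len(pop) == 0:
                break
        assert (np.diff(vols) < 0).all()
        assert len(pop) == 0


class TestVolumeAndDivision:
    def test_resting_cell_volume_unchanged(self, phen_params):
        pop = _tumor_cells(1)
        v0 = pop.volume[0]
        ph.update_volume(pop, 6.0, phen_params)
        assert pop.volume[0] == v0

    def test_apoptotic_below_5pct_after_duration(self, phen_params):
        pop = _tumor_cells(1)
        v0 = pop.volume[0]
        ph.trigger_apoptosis(pop, np.array([0]))
        n = int(round(phen_params.T_apop / 6.0))
        for _ in range(n):
            ph.update_volume(pop, 6.0, phen_params)
        assert pop.volume[0] < 0.05 * v0

    def test_premitotic_grows_toward_double_volume(self, phen_params):
        pop = _tumor_cells(1)
        v0 = pop.volume[0]
        pop.phase[0] = PHASE_KI67_PRE
        pop.target_volume[0] = 2 * v0
        for _ in range(int(round(phen_params.T_K1 / 6.0))):
            ph.update_volume(pop, 6.0, phen_params)
        assert pop.volume[0] == pytest.approx(2 * v0, rel=0.06)

    def test_division_conserves_volume_and_centroid(self, phen_params):
        pop = _tumor_cells(1)
        pop.phase[0] = PHASE_KI67_PRE
        pop.volume[0] = 2 * pop.resting_volume[0]
        center = pop.position[0].copy()
        total = pop.volume[0]
        rng = np.random.default_rng(3)
        ph.divide(pop, np.array([0]), rng)
        assert len(pop) == 2
        np.testing.assert_allclose(pop.position.mean(axis=0), center, atol=1e-12)
        assert pop.volume.sum() == pytest.approx(total)
        assert (pop.phase == PHASE_KI67_POST).all()
        assert len(np.unique(pop.ids)) == 2

    def test_division_axis_reproducible(self, phen_params):
        outs = []
        for _ in range(2):
            pop = _tumor_cells(1)
            pop.phase[0] = PHASE_KI67_PRE
            ph.divide(pop, np.array([0]), np.random.default_rng(77))
            outs.append(pop.position.copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_dead_phases_never_reenter_cycle(self, phen_params):
        pop = _tumor_cells(10)
        ph.trigger_apoptosis(pop, np.arange(5))
        pop.phase[5:] = PHASE_NECROTIC
        pop.oxygen[:] = 60.0
        rng = np.random.default_rng(0)
        for _ in range(50):
            ph.advance_phase(pop, 6.0, phen_params, rng)
        assert not pop.is_viable.any()


class TestPopulationGrowth:
    def test_exponential_growth_rate_matches_euler_lotka(self):
        """Unconstrained growth rate solves 2 E[e^{-a tau}] = 1.

        With deterministic Ki67+ phases and exponential quiescence the
        generation time is tau = T_K2 + Exp(r01) + T_K1, giving
        2 e^{-a (T_K1 + T_K2)} r01 / (r01 + a) = 1; the simulated
        population's fitted log-slope must agree with that root.
        """
        params = PhenotypeParams(r01_max=1.0 / 60.0, T_K1=120.0, T_K2=60.0)
        pop = _tumor_cells(1)
        pop.oxygen[:] = params.sigma_sat
        rng = np.random.default_rng(2024)
        dt = 2.0
        times, counts = [], []
        t = 0.0
        while len(pop) < 3000:
            pop.oxygen[:] = params.sigma_sat
            pop.pressure[:] = 0.0
            dividing = ph.advance_phase(pop, dt, params, rng)
            if len(dividing):
                ph.divide(pop, dividing, rng)
            t += dt
            times.append(t)
            counts.append(len(pop))

        def euler_lotka(a):
            r01 = params.r01_max
            return 2 * np.exp(-a * (params.T_K1 + params.T_K2)) * r01 / (r01 + a) - 1

        alpha = brentq(euler_lotka, 1e-6, 0.1)
        # fit on the late, asymptotic portion of the curve
        times = np.asarray(times)
        counts = np.asarray(counts, dtype=float)
        sel = counts > 100
        slope = np.polyfit(times[sel], np.log(counts[sel]), 1)[0]
        assert slope == pytest.approx(alpha, rel=0.10)
        # and the mean cycle time composes as 1/r01 + T_K1 + T_K2
        assert 1 / params.r01_max + params.T_K1 + params.T_K2 == pytest.approx(240.0)
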