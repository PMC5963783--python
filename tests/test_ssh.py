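"""Kinetics of suppression subtractive hybridization.

The closed-form single-strand decay is checked against direct numerical
integration of the second-order rate equations; the emergent properties —
normalization of equally expressed species, enrichment of tester-specific
species, and their dependence on driver excess and PEG — are asserted on
the composed pipeline.
"""

import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from legoscreen import (
    HybridParams,
    SpeciesPool,
    ValidationError,
    first_hybridization,
    run_ssh,
    second_hybridization,
    suppression_pcr,
)
from legoscreen.ssh import SingleStrandPool


def ode_single_strand(t0: float, c0: float, k: float, tau: float) -> float:
    """Oracle: integrate ds/dt = -k·s·c, dc/dt = -k·c² numerically."""
    sol = solve_ivp(
        lambda _, y: [-k * y[0] * y[1], -k * y[1] ** 2],
        (0.0, tau),
        [t0, c0],
        rtol=1e-12,
        atol=1e-14,
        dense_output=False,
    )
    return sol.y[0, -1]


def make_pool(tester, driver):
    tester = np.asarray(tester, float)
    ids = tuple(f"sp{i}" for i in range(tester.size))
    return SpeciesPool(ids, tester, np.asarray(driver, float))


class TestFirstHybridization:
    def test_zero_time_changes_nothing(self):
        pool = make_pool([5.0, 1.0, 0.3], [5.0, 0.0, 0.3])
        res = first_hybridization(pool, HybridParams(rate_k=1.0, t1_hours=0.0))
        np.testing.assert_allclose(res.ss_A.conc, pool.tester)
        np.testing.assert_allclose(res.duplexed_A, 0.0)

    def test_closed_form_matches_ode_on_grid(self):
        grid = list(itertools.product([0.05, 0.5, 2.0, 10.0], [0.1, 1.0, 8.0], [1.0, 6.0, 20.0, 45.0]))
        checked = 0
        for k, t0, tau in grid:
            for excess in (1.0, 10.0, 60.0):
                c0 = t0 * (1.0 + excess)
                pool = make_pool([t0], [t0])
                res = first_hybridization(pool, HybridParams(rate_k=k, t1_hours=tau, driver_excess=excess))
                expected = ode_single_strand(t0, c0, k, tau)
                np.testing.assert_allclose(res.ss_A.conc[0], expected, rtol=1e-6)
                checked += 1
        assert checked >= 100

    def test_normalization_ratio_approaches_one(self):
        # t proportional to d, strong annealing: abundant/scarce ratio -> 1
        pool = make_pool([100.0, 1.0], [100.0, 1.0])
        res = first_hybridization(pool, HybridParams(rate_k=50.0, t1_hours=45.0, driver_excess=60.0))
        ratio = res.ss_A.conc[0] / res.ss_A.conc[1]
        assert 1.0 <= ratio < 1.01

    def test_tester_specific_species_retains_more(self):
        pool = make_pool([2.0, 2.0], [0.0, 2.0])  # equally expressed in tester
        for tau in (0.5, 5.0, 45.0):
            res = first_hybridization(pool, HybridParams(rate_k=1.0, t1_hours=tau))
            assert res.ss_A.conc[0] > res.ss_A.conc[1]

    def test_mass_conservation(self, rng):
        pool = make_pool(rng.uniform(0.01, 10, 50), rng.uniform(0, 10, 50))
        res = first_hybridization(pool, HybridParams(rate_k=0.7))
        np.testing.assert_allclose(res.ss_A.conc + res.duplexed_A, pool.tester, rtol=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            HybridParams(t1_hours=-1.0)

    def test_cv_of_equally_expressed_species_non_increasing_in_time(self):
        # abundances differ across species but tester == driver per species
        tester = np.array([20.0, 5.0, 1.0, 0.2, 0.05])
        pool = make_pool(tester, tester)
        cvs = []
        for tau in np.linspace(0.0, 45.0, 40):
            res = first_hybridization(pool, HybridParams(rate_k=0.5, t1_hours=float(tau)))
            s = res.ss_A.conc
            cvs.append(s.std() / s.mean())
        assert all(b <= a + 1e-12 for a, b in zip(cvs, cvs[1:]))


class TestSecondHybridization:
    @staticmethod
    def _halves(conc):
        ids = tuple(f"sp{i}" for i in range(len(conc)))
        return SingleStrandPool(ids, np.array(conc, float))

    def test_without_peg_no_duplexes(self):
        a, b = self._halves([1.0, 2.0]), self._halves([1.0, 2.0])
        y = second_hybridization(a, b, HybridParams(rate_k=1.0, peg_rate_multiplier=0.0))
        np.testing.assert_allclose(y.conc, 0.0)

    def test_symmetric_in_a_and_b(self):
        a, b = self._halves([1.0, 0.2]), self._halves([0.5, 0.9])
        params = HybridParams(rate_k=1.0)
        y_ab = second_hybridization(a, b, params)
        y_ba = second_hybridization(b, a, params)
        np.testing.assert_allclose(y_ab.conc, y_ba.conc)

    def test_yield_monotone_in_time(self):
        a, b = self._halves([1.0, 0.3]), self._halves([1.0, 0.3])
        yields = [
            second_hybridization(a, b, HybridParams(rate_k=1.0, t2_hours=t)).conc
            for t in (0.0, 1.0, 6.0, 24.0, 100.0)
        ]
        for y0, y1 in zip(yields, yields[1:]):
            assert (y1 >= y0 - 1e-15).all()

    def test_yield_bounded_by_min_strand(self, rng):
        a = self._halves(rng.uniform(0, 3, 30))
        b = self._halves(rng.uniform(0, 3, 30))
        y = second_hybridization(a, b, HybridParams(rate_k=5.0, t2_hours=1e6))
        assert (y.conc <= np.minimum(a.conc, b.conc) + 1e-12).all()

    def test_mismatched_species_sets_rejected(self):
        a = SingleStrandPool(("x",), np.array([1.0]))
        b = SingleStrandPool(("y",), np.array([1.0]))
        with pytest.raises(ValidationError):
            second_hybridization(a, b, HybridParams(rate_k=1.0))


class TestSuppressionPcr:
    def test_single_species_is_whole_library(self):
        comp = suppression_pcr(SingleStrandPool(("a",), np.array([0.3])))
        assert comp.to_list() == [1.0]

    def test_composition_sums_to_one_and_preserves_rank(self, rng):
        y = rng.uniform(0, 1, 40)
        comp = suppression_pcr(SingleStrandPool(tuple(f"s{i}" for i in range(40)), y))
        assert comp.sum() == pytest.approx(1.0)
        assert (np.argsort(comp.to_numpy()) == np.argsort(y)).all()

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError, match="empty subtracted library"):
            suppression_pcr(SingleStrandPool(("a",), np.array([0.0])))


class TestEndToEnd:
    def test_repressed_in_driver_species_enriched(self):
        # species 0 repressed 4-fold in driver; 1 and 2 equally expressed
        pool = make_pool([2.0, 2.0, 8.0], [0.5, 2.0, 8.0])
        comp = run_ssh(pool)
        tester_share = pool.tester / pool.tester.sum()
        assert comp.iloc[0] > tester_share[0]

    def test_normalization_reduces_cv_of_equal_species(self):
        tester = np.array([30.0, 10.0, 3.0, 1.0, 0.3])
        pool = make_pool(tester, tester)
        comp = run_ssh(pool).to_numpy()
        cv_before = tester.std() / tester.mean()
        cv_after = comp.std() / comp.mean()
        assert cv_after < cv_before

    @pytest.mark.parametrize("rate_k", [0.05, 0.5])
    def test_enrichment_monotone_in_driver_excess(self, rate_k):
        pool = make_pool([1.0, 5.0, 2.0], [0.0, 5.0, 2.0])  # species 0 tester-specific
        shares = []
        for excess in (1.0, 35.0, 60.0):
            params = HybridParams(rate_k=rate_k, driver_excess=excess)
            shares.append(run_ssh(pool, params).iloc[0])
        assert shares[0] < shares[1] < shares[2]
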