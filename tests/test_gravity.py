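import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from huffgap import (FacilityAttraction, ModelParams, StudyRegion,
                     expected_volumes, market_shares, predict, utility_matrix)


def naive_prediction(params, region, attraction):
    """Scalar per-pair evaluation of the adjusted gravity model.

    Independent double-loop oracle: bracket term, attraction products,
    exponential distance decay, Huff normalization, market-size scaling.
    """
    I, J = region.n_areas, region.n_facilities
    aa = np.zeros((I, J))
    for i in range(I):
        for j in range(J):
            bracket = 1.0
            if attraction.availability[j] == 1:
                prod = 1.0
                for name, g in params.gamma_partial.items():
                    prod *= attraction.partial[name][j] ** g
                bracket = params.benchmark * prod
            util = bracket
            for name, g in params.gamma.items():
                util *= attraction.complete[name][j] ** g
            aa[i, j] = util * np.exp(-region.distances[i, j] * params.decay)
    shares = aa / aa.sum(axis=1, keepdims=True)
    vols = shares * np.asarray(region.market_sizes, dtype=float)[:, None]
    return aa, shares, vols


class TestModelParamsValidation:
    def test_benchmark_bounds(self):
        with pytest.raises(ValueError):
            ModelParams(benchmark=0.0)
        with pytest.raises(ValueError):
            ModelParams(benchmark=1.5)

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(decay=-0.1)

    def test_nonfinite_exponent_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(gamma={"beds": np.inf})


class TestWorkedExample:
    """Hand-evaluated 1-area, 2-facility instance.

    A = (2, 2) with exponent 1, facility 0 has a partial value 4 with
    exponent 0.5 and BM = 0.5, both at zero distance:
    AA = (0.5 * 4^0.5 * 2, 2) = (2, 2), shares (0.5, 0.5).
    """

    def test_bracket_levels_the_field(self, toy_region):
        att = FacilityAttraction(
            complete={"size": np.array([2.0, 2.0])},
            partial={"rep": np.array([4.0, 1.0])},
            availability=np.array([1, 0]))
        params = ModelParams(gamma={"size": 1.0}, gamma_partial={"rep": 0.5},
                             decay=0.0, benchmark=0.5)
        aa = utility_matrix(params, toy_region, att)
        np.testing.assert_allclose(aa, [[2.0, 2.0]], rtol=1e-12)
        np.testing.assert_allclose(market_shares(aa), [[0.5, 0.5]], rtol=1e-12)

    def test_all_unavailable_reduces_to_classic_model(self, toy_region):
        att_none = FacilityAttraction(
            complete={"size": np.array([3.0, 5.0])},
            partial={"rep": np.array([4.0, 9.0])},
            availability=np.array([0, 0]))
        params = ModelParams(gamma={"size": 0.9}, gamma_partial={"rep": 0.7},
                             decay=0.1, benchmark=0.3)
        classic = ModelParams(gamma={"size": 0.9}, decay=0.1)
        att_classic = FacilityAttraction(complete={"size": np.array([3.0, 5.0])})
        np.testing.assert_allclose(
            utility_matrix(params, toy_region, att_none),
            utility_matrix(classic, toy_region, att_classic), rtol=1e-12)

    def test_full_availability_unit_partials_reduce_to_classic(self, toy_region):
        att = FacilityAttraction(
            complete={"size": np.array([3.0, 5.0])},
            partial={"rep": np.ones(2)},
            availability=np.array([1, 1]))
        params = ModelParams(gamma={"size": 0.9}, gamma_partial={"rep": 0.7},
                             decay=0.1, benchmark=1.0)
        classic = ModelParams(gamma={"size": 0.9}, decay=0.1)
        att_classic = FacilityAttraction(complete={"size": np.array([3.0, 5.0])})
        np.testing.assert_allclose(
            utility_matrix(params, toy_region, att),
            utility_matrix(classic, toy_region, att_classic), rtol=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_vectorized_matches_double_loop(self, seed, random_instance):
        rng = np.random.default_rng(seed)
        region, attraction, params = random_instance(rng, 5, 7)
        aa_o, shares_o, vols_o = naive_prediction(params, region, attraction)
        pred = predict(params, region, attraction)
        np.testing.assert_allclose(pred.numerators, aa_o, rtol=1e-12)
        np.testing.assert_allclose(pred.shares, shares_o, rtol=1e-12)
        np.testing.assert_allclose(pred.expected_volumes, vols_o, rtol=1e-12)
        np.testing.assert_allclose(pred.shares.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(pred.expected_volumes.sum(axis=1),
                                   region.market_sizes.astype(float), rtol=1e-9)


class TestShares:
    def test_uniform_when_equal(self):
        np.testing.assert_allclose(market_shares(np.full((3, 4), 2.5)), 0.25)

    def test_single_facility_share_is_one(self):
        np.testing.assert_allclose(market_shares(np.array([[7.0]])), 1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1e-6, 1e6), st.integers(0, 99))
    def test_row_rescaling_invariance(self, c, seed):
        aa = np.random.default_rng(seed).uniform(0.1, 10.0, (3, 5))
        np.testing.assert_allclose(market_shares(aa * c), market_shares(aa),
                                   rtol=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            market_shares(np.array([[1.0, 0.0]]))


class TestMonotonicityProperties:
    @settings(deadline=None, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 9999))
    def test_benchmark_strictly_increases_available_shares(self, random_instance, seed):
        rng = np.random.default_rng(seed)
        region, attraction, params = random_instance(rng, 3, 6)
        if not (0 < attraction.availability.sum() < 6):
            attraction.availability[:3] = 1
            attraction.availability[3:] = 0
        # mild decay keeps every share well away from float saturation,
        # so strict monotonicity is visible at machine precision
        lo = ModelParams(params.gamma, params.gamma_partial, 0.02, 0.3)
        hi = ModelParams(params.gamma, params.gamma_partial, 0.02, 0.9)
        s_lo = predict(lo, region, attraction).shares
        s_hi = predict(hi, region, attraction).shares
        avail = attraction.availability == 1
        assert np.all(s_hi[:, avail] > s_lo[:, avail])
        assert np.all(s_hi[:, ~avail] < s_lo[:, ~avail])

    @settings(deadline=None, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 9999))
    def test_distance_strictly_decreases_share(self, random_instance, seed):
        rng = np.random.default_rng(seed)
        region, attraction, params = random_instance(rng, 3, 6)
        params = ModelParams(params.gamma, params.gamma_partial, 0.2,
                             params.benchmark)
        before = predict(params, region, attraction).shares[0, 0]
        region.distances[0, 0] += 25.0
        after = predict(params, region, attraction).shares[0, 0]
        assert after < before

    @settings(deadline=None, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 9999))
    def test_partial_values_ignored_where_unavailable(self, random_instance, seed):
        rng = np.random.default_rng(seed)
        region, attraction, params = random_instance(rng, 3, 6)
        attraction.availability[0] = 0
        base = predict(params, region, attraction).shares
        attraction.partial["reputation"][0] = 12345.0  # placeholder must not matter
        np.testing.assert_array_equal(
            predict(params, region, attraction).shares, base)


class TestExpectedVolumes:
    def test_uniform_shares(self):
        vols, totals = expected_volumes(np.full((1, 4), 0.25), np.array([100]))
        np.testing.assert_allclose(vols, 25.0)
        np.testing.assert_allclose(totals, 25.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 9999))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        shares = rng.dirichlet(np.ones(5), size=4)
        sizes = rng.integers(0, 1000, 4)
        vols, totals = expected_volumes(shares, sizes)
        np.testing.assert_allclose(vols.sum(axis=1), sizes, rtol=1e-9)
        assert totals.sum() == pytest.approx(sizes.sum())

    def test_rejects_nonstochastic(self):
        with pytest.raises(ValueError):
            expected_volumes(np.array([[0.5, 0.4]]), np.array([10]))
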