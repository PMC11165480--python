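"""Rate laws, mass balances and simulation of the GlcNAc pathway model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.integrate import simpson

import phoskin as pk
from phoskin.errors import ConfigError, DataError, InvalidInputError
from phoskin.pathway import REGULATED_REACTIONS, STOICHIOMETRY

from conftest import make_params


class TestCoreRates:
    def test_zero_state_only_uptake(self, simple_params):
        v = pk.core_rates(np.zeros(8), simple_params)
        assert v[0] == simple_params.vmax[0]
        assert np.all(v[1:] == 0.0)

    def test_half_saturation_v3_and_v12(self):
        params = make_params(km=np.arange(1.0, 13.0))
        x = np.zeros(8)
        x[1] = params.km[2]  # x2 = Km3
        assert pk.core_rates(x, params)[2] == pytest.approx(params.vmax[2] / 2)
        x = np.zeros(8)
        x[4] = params.km[11]  # x5 = Km12
        assert pk.core_rates(x, params)[11] == pytest.approx(params.vmax[11] / 2)

    def test_negative_state_rejected(self, simple_params):
        state = np.zeros(8)
        state[3] = -1e-3
        with pytest.raises(InvalidInputError):
            pk.core_rates(state, simple_params)

    def test_v10_substrate_modes(self):
        x = np.zeros(8)
        x[3], x[7] = 2.0, 0.5  # GlcN6P and GlcNAc differ
        p_x4 = make_params(v10_substrate="x4")
        p_x8 = make_params(v10_substrate="x8")
        v4 = pk.core_rates(x, p_x4)[9]
        v8 = pk.core_rates(x, p_x8)[9]
        assert v4 == pytest.approx(0.8 * 2 / 3)
        assert v8 == pytest.approx(0.8 * 0.5 / 1.5)


class TestRegulatedRates:
    def test_zero_inducer_leaves_basal_only(self, simple_params):
        x = np.zeros(8)
        x[1] = simple_params.km[4]  # x2 = Km5, half saturation
        v = pk.regulated_rates(x, simple_params)
        assert v[4] == pytest.approx(simple_params.reg_basal[0] / 2)

    def test_transport_half_inhibition(self, simple_params):
        # phosphosugar pool == Ki -> v1 = v1max/2 for any n_t > 0
        for nt in (0.5, 1.0, 3.0):
            params = make_params(transport_n=nt)
            x = np.zeros(8)
            x[1] = params.ki
            v = pk.regulated_rates(x, params)
            assert v[0] == pytest.approx(params.vmax[0] / 2)

    def test_full_induction_asymptote(self, simple_params):
        """x7 >> Ka drives the prefactor to p + vmax."""
        x = np.zeros(8)
        x[6] = 1e6 * simple_params.reg_ka[3]
        v = pk.regulated_rates(x, simple_params)
        km11, x7 = simple_params.km[10], x[6]
        expected = (simple_params.reg_basal[3] + simple_params.vmax[10]) * x7 / (km11 + x7)
        assert v[10] == pytest.approx(expected, rel=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(x7a=st.floats(0, 10), x7b=st.floats(0, 10), n=st.floats(0.1, 4))
    def test_monotone_regulation_in_x7(self, x7a, x7b, n):
        """The Hill prefactor is non-decreasing in the inducer GlcNAc6P."""
        params = make_params(reg_n=np.full(4, n))
        lo, hi = sorted((x7a, x7b))
        base = np.zeros(8)
        base[3] = 1.0  # keep v7's substrate fixed
        xa, xb = base.copy(), base.copy()
        xa[6], xb[6] = lo, hi
        va = pk.regulated_rates(xa, params)[6]
        vb = pk.regulated_rates(xb, params)[6]
        assert va <= vb + 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(pa=st.floats(0, 10), pb=st.floats(0, 10))
    def test_uptake_nonincreasing_in_pressure(self, pa, pb):
        params = make_params()
        lo, hi = sorted((pa, pb))
        xa, xb = np.zeros(8), np.zeros(8)
        xa[1], xb[1] = lo, hi
        assert pk.regulated_rates(xa, params)[0] >= pk.regulated_rates(xb, params)[0] - 1e-12

    def test_zero_hill_reduces_to_constant_prefactor(self):
        """n = 0: regulated rates equal MM rates with prefactor p + vmax/2."""
        params = make_params(reg_n=np.zeros(4), transport_n=1.0)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.uniform(0, 2, size=8)
            v = pk.regulated_rates(x, params)
            core = pk.core_rates(x, params)
            for k, rxn in enumerate(REGULATED_REACTIONS):
                i = rxn - 1
                sat = core[i] / params.vmax[i]
                expected = (params.reg_basal[k] + params.vmax[i] * 0.5) * sat
                assert v[i] == pytest.approx(expected, rel=1e-12)


class TestMassBalance:
    def test_uptake_only(self):
        v = np.zeros(12)
        v[0] = 1.0
        dx = pk.mass_balance(v)
        assert dx[0] == 1.0 and np.all(dx[1:] == 0.0)

    def test_single_conversion(self):
        v = np.zeros(12)
        v[1] = 1.0
        dx = pk.mass_balance(v)
        assert dx[0] == -1.0 and dx[1] == 1.0
        assert np.all(np.delete(dx, [0, 1]) == 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(v=arrays(float, 12, elements=st.floats(0, 10)))
    def test_total_mass_derivative_equals_uptake(self, v):
        """Sum of all state derivatives is exactly v1 (conservation with source)."""
        assert pk.mass_balance(v).sum() == pytest.approx(v[0], abs=1e-12)

    def test_column_sums_identity(self):
        # every reaction except uptake conserves total mass
        sums = STOICHIOMETRY.sum(axis=0)
        assert sums[0] == 1.0 and np.all(sums[1:] == 0.0)


class TestSimulate:
    def test_pure_accumulation(self):
        params = make_params(vmax=np.r_[0.5, np.zeros(11)])
        traj = pk.simulate(params, horizon=10.0, regulated=False, store_rates=False)
        assert traj.state("glucose")[-1] == pytest.approx(5.0, abs=1e-6)
        assert np.all(traj.states[-1][1:] == 0.0)

    def test_product_requires_v11(self, base_draw, ratios):
        params = pk.build_variant_params(ratios, base_draw, "WT")
        params.vmax[10] = 0.0
        params.reg_basal[3] = 0.0
        traj = pk.simulate(params, horizon=50.0, store_rates=False)
        assert np.all(traj.state("glcnac") == 0.0)

    def test_literal_v10_mode_dead_product_branch(self, base_draw, ratios):
        """With v10 saturating on x8 and an empty pathway, GlcNAc6P and
        GlcNAc can never rise (the printed form's structural consequence)."""
        params = pk.build_variant_params(ratios, base_draw, "WT", v10_substrate="x8")
        traj = pk.simulate(params, horizon=50.0, store_rates=False)
        assert np.all(traj.state("glcnac6p") == 0.0)
        assert np.all(traj.state("glcnac") == 0.0)

    def test_mass_balance_quadrature(self, wt_params):
        """Total mass gained equals the time integral of the uptake flux."""
        traj = pk.simulate(wt_params, horizon=200.0)
        gained = traj.states[-1].sum() - traj.states[0].sum()
        uptake = simpson(traj.rates[:, 0], x=traj.times)
        assert gained == pytest.approx(uptake, rel=1e-4)

    def test_nonnegative_states(self, wt_params):
        traj = pk.simulate(wt_params, horizon=200.0, store_rates=False)
        assert np.all(traj.states >= 0.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_invalid_horizon(self, wt_params):
        with pytest.raises(ConfigError):
            pk.simulate(wt_params, horizon=0.0)


class TestBuildVariantParams:
    def test_wt_anchor(self, base_draw):
        import pandas as pd
        from phoskin.pathway import VariantRatioTable

        ones = VariantRatioTable(
            pd.DataFrame(
                {
                    "variant": "WT",
                    "substrate": ["Glc6P", "Fru6P", "GlcN6P", "GlcNAc6P"],
                    "vmax_ratio": 1.0,
                    "km_ratio": 1.0,
                    "provenance": "measured",
                }
            )
        )
        params = pk.build_variant_params(ones, base_draw, "WT")
        assert params.vmax[4] == 0.5  # v5max anchored exactly
        assert params.km[4] == base_draw.km_wt_glc6p

    def test_vmax_ratio_two_doubles_v11(self, base_draw):
        import pandas as pd
        from phoskin.pathway import VariantRatioTable

        table = VariantRatioTable(
            pd.DataFrame(
                {
                    "variant": "X",
                    "substrate": ["Glc6P", "Fru6P", "GlcN6P", "GlcNAc6P"],
                    "vmax_ratio": [1.0, 1.0, 1.0, 2.0],
                    "km_ratio": 1.0,
                    "provenance": "measured",
                }
            )
        )
        params = pk.build_variant_params(table, base_draw, "X")
        assert params.vmax[10] == pytest.approx(1.0)

    def test_unmeasured_variant_errors_naming_pairs(self, ratios, base_draw):
        with pytest.raises(DataError) as err:
            pk.build_variant_params(ratios, base_draw, "M4")
        assert "(M4, Fru6P)" in str(err.value)
        assert "(M4, GlcN6P)" in str(err.value)

    def test_basal_is_scaled_vmax(self, ratios, base_draw):
        params = pk.build_variant_params(ratios, base_draw, "M3")
        for k, rxn in enumerate(REGULATED_REACTIONS):
            assert params.reg_basal[k] == pytest.approx(params.vmax[rxn - 1])
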