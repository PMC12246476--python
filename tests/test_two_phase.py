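"""Two-phase rate-ratio model, dense-phase inference and diagnostics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasekin.kinetics import MichaelisMentenParams, mm_rate
from phasekin.synthetic import NoiseModel, gen_ratio_dataset
from phasekin.two_phase import (
    REFERENCE_PARAMS,
    TwoPhaseParams,
    fit_dense_phase_constants,
    fraction_product_dense,
    heterogeneous_rate,
    product_partition_ratio,
    rate_ratio,
    transport_diagnostics,
)
from tests.conftest import S_LEVELS


def _params(**kw) -> TwoPhaseParams:
    base = dict(phi_D=1.7e-4, K_E=73_000.0, kcat_I=4.3, KM_I=713.0,
                kcat_II=6.9, KM_II=334.0)
    base.update(kw)
    return TwoPhaseParams(**base)


random_params = st.builds(
    _params,
    phi_D=st.floats(1e-6, 0.01),
    K_E=st.floats(1.0, 1e5),
    kcat_I=st.floats(0.1, 100.0),
    KM_I=st.floats(10.0, 5000.0),
    kcat_II=st.floats(0.1, 100.0),
    KM_II=st.floats(10.0, 5000.0),
)


class TestRateRatio:
    def test_no_dense_phase_is_identity(self):
        p = _params(phi_D=0.0)
        S = np.linspace(0.0, 1000.0, 50)
        np.testing.assert_allclose(rate_ratio(p, S), 1.0, rtol=1e-12)

    def test_indistinguishable_phases_is_identity(self):
        p = _params(K_E=1.0, kcat_II=4.3, KM_II=713.0)
        S = np.linspace(0.0, 1000.0, 50)
        np.testing.assert_allclose(rate_ratio(p, S), 1.0, rtol=1e-12)

    def test_reference_value_at_250(self, ref_params):
        """The fitted parameter set predicts a ~2.5-fold overall rate
        enhancement at 250 µM substrate (~3-fold observed)."""
        assert rate_ratio(ref_params, 250.0) == pytest.approx(2.523, abs=2e-3)

    @given(params=random_params, S=st.floats(0.0, 2000.0))
    @settings(max_examples=200, derandomize=True)
    def test_dense_dilute_decomposition_matches_product_ratio(self, params, S):
        """The dense/dilute term ratio of the rate equation equals the
        product-localization ratio: the two equations are one model."""
        x = params.xi
        dilute_term = x * (1 - params.phi_D)
        total = rate_ratio(params, S)
        dense_term = total - dilute_term
        assert dense_term / dilute_term == pytest.approx(
            product_partition_ratio(params, S), rel=1e-9)

    @given(params=random_params, S=st.floats(0.0, 2000.0),
           bump=st.floats(1.01, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_dense_constants(self, params, S, bump):
        r0 = rate_ratio(params, S)
        assert rate_ratio(replace(params, kcat_II=params.kcat_II * bump), S) > r0
        assert rate_ratio(replace(params, KM_II=params.KM_II * bump), S) < r0
        # in K_E only when the dense phase is actually enhancing: the
        # K_E-enriched dense term must outweigh the xi dilution it causes
        enhancement = (params.kcat_II / params.kcat_I
                       * (params.KM_I + S) / (params.KM_eff_II + S))
        if enhancement > 1 + 1e-9:
            assert rate_ratio(replace(params, K_E=params.K_E * bump), S) > r0
        elif enhancement < 1 - 1e-9:
            assert rate_ratio(replace(params, K_E=params.K_E * bump), S) < r0


class TestDensePhaseFit:
    def test_noiseless_recovery(self, ref_params):
        df = gen_ratio_dataset(ref_params, S_LEVELS, noise=NoiseModel(scale=0.0))
        res = fit_dense_phase_constants(
            list(df[["S_uM", "ratio"]].itertuples(index=False, name=None)),
            known=ref_params, kcat_II_0=1.0, KM_eff_II_0=50.0)
        assert res.kcat_II == pytest.approx(6.9, rel=1e-3)
        assert res.KM_eff_II == pytest.approx(334.0, rel=1e-3)
        # under the equilibrium closure the fitted group is KM_II itself
        assert res.params.KM_II == pytest.approx(res.KM_eff_II, rel=1e-12)

    def test_two_points_flagged_unvalidated(self, ref_params):
        df = gen_ratio_dataset(ref_params, [62.5, 250.0],
                               noise=NoiseModel(scale=0.0))
        res = fit_dense_phase_constants(
            list(df[["S_uM", "ratio"]].itertuples(index=False, name=None)),
            known=ref_params)
        assert np.allclose(res.residuals, 0.0, atol=1e-9)
        assert any("unvalidated" in f for f in res.flags)

    def test_vanishing_dense_phase_flagged_non_identifiable(self, ref_params):
        tiny = replace(ref_params, phi_D=1e-12)
        df = gen_ratio_dataset(tiny, S_LEVELS, noise=NoiseModel(scale=0.0))
        res = fit_dense_phase_constants(
            list(df[["S_uM", "ratio"]].itertuples(index=False, name=None)),
            known=tiny)
        assert any("non-identifiable" in f for f in res.flags)

    def test_single_level_rejected(self, ref_params):
        with pytest.raises(ValueError, match=">= 2 distinct"):
            fit_dense_phase_constants([(250.0, 2.5), (250.0, 2.6)],
                                      known=ref_params)

    def test_coverage_of_95ci_under_noise(self, ref_params):
        """5% replicate noise, 200 simulations: truth inside the 95% CIs
        in >= 90% of fits."""
        n_sim, cov_k, cov_m = 200, 0, 0
        for i in range(n_sim):
            df = gen_ratio_dataset(
                ref_params, S_LEVELS, n_reps=4,
                noise=NoiseModel(scale=0.05, seed=1000 + i))
            res = fit_dense_phase_constants(
                list(df[["S_uM", "ratio", "ratio_se"]].itertuples(
                    index=False, name=None)),
                known=ref_params, kcat_II_0=3.0, KM_eff_II_0=100.0)
            ci = res.ci95()
            cov_k += ci["kcat_II"][0] <= 6.9 <= ci["kcat_II"][1]
            cov_m += ci["KM_eff_II"][0] <= 334.0 <= ci["KM_eff_II"][1]
        assert cov_k / n_sim >= 0.90
        assert cov_m / n_sim >= 0.90


class TestProductLocalization:
    def test_no_dense_phase(self):
        assert product_partition_ratio(_params(phi_D=0.0), 100.0) == 0.0
        assert fraction_product_dense(_params(phi_D=0.0), 100.0) == 0.0

    def test_large_substrate_limit(self, ref_params):
        """As S -> inf the ratio tends to phi/(1-phi) * (kcat ratio) * K_E
        ~ 19.9, i.e. ~95.2% of product formed in the dense phase."""
        limit = (1.7e-4 / (1 - 1.7e-4)) * (6.9 / 4.3) * 73_000
        assert limit == pytest.approx(19.92, abs=5e-3)
        r_far = product_partition_ratio(ref_params, 1e9)
        assert r_far == pytest.approx(limit, rel=1e-4)
        assert limit / (1 + limit) == pytest.approx(0.952, abs=5e-4)

    def test_reference_value_at_250(self, ref_params):
        assert product_partition_ratio(ref_params, 250.0) == pytest.approx(
            32.84, abs=0.05)
        assert fraction_product_dense(ref_params, 250.0) == pytest.approx(
            0.970, abs=2e-3)

    def test_minimum_dense_fraction_on_grid(self, ref_params):
        """Dense-phase product fraction stays >= 95.2% over all substrate
        concentrations (the minimum is the S -> inf limit)."""
        S = np.linspace(0.0, 1000.0, 201)
        frac = fraction_product_dense(ref_params, S)
        assert frac.min() >= 0.952
        # monotone decreasing in S since KM_eff_II < KM_I
        assert np.all(np.diff(frac) < 0)

    def test_symmetric_phases_give_phi(self):
        p = _params(phi_D=0.3, K_E=1.0, kcat_II=4.3, KM_II=713.0)
        assert fraction_product_dense(p, 100.0) == pytest.approx(0.3, rel=1e-12)

    @given(params=random_params, S=st.floats(0.0, 2000.0),
           bump=st.floats(1.01, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_fraction_bounded_and_monotone(self, params, S, bump):
        f = fraction_product_dense(params, S)
        assert 0.0 < f < 1.0
        assert fraction_product_dense(replace(params, K_E=params.K_E * bump),
                                      S) > f
        assert fraction_product_dense(
            replace(params, phi_D=min(params.phi_D * bump, 0.5)), S) > f


class TestHeterogeneousRate:
    def test_reduces_to_homogeneous_without_condensates(self):
        p = _params(phi_D=0.0, kcat_I=4.2, KM_I=713.0)
        hom = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        assert heterogeneous_rate(p, 250.0, hom) == pytest.approx(
            mm_rate(hom, 250.0), rel=1e-9)

    def test_zero_substrate(self):
        p = _params(kcat_I=4.2)
        hom = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        assert heterogeneous_rate(p, 0.0, hom) == 0.0

    def test_reference_composition(self, ref_params):
        # consistent pairing: homogeneous v_max = kcat_I * E0 = 4.3*0.5
        hom = MichaelisMentenParams(v_max=2.15, K_M=713.0, enzyme_0=0.5)
        expected = rate_ratio(ref_params, 250.0) * mm_rate(hom, 250.0)
        got = heterogeneous_rate(ref_params, 250.0, hom)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.409, abs=5e-3)

    def test_inconsistent_constants_rejected(self, ref_params):
        hom = MichaelisMentenParams(v_max=2.1, K_M=713.0, enzyme_0=0.5)
        with pytest.raises(ValueError, match="inconsistent kcat_I"):
            heterogeneous_rate(ref_params, 250.0, hom)  # 4.2 vs 4.3


class TestTransportDiagnostics:
    def test_reference_droplet(self):
        """D = 1.015 µm²/s across a 1 µm droplet: tau_diff 985 ms, and
        t_react = 1/6.9 s = 145 ms -- same order of magnitude."""
        d = transport_diagnostics(1.015, 1.0, 6.9)
        assert d.tau_diff == pytest.approx(0.985, abs=5e-4)
        assert d.t_react == pytest.approx(0.145, abs=5e-4)
        assert d.verdict == "same order of magnitude"
        assert d.damkohler_like_ratio == pytest.approx(
            d.tau_diff / d.t_react, rel=1e-12)

    def test_unit_ratio_construction(self):
        d = transport_diagnostics(2.0**2 * 6.9, 2.0, 6.9)
        assert d.damkohler_like_ratio == pytest.approx(1.0, rel=1e-12)

    def test_faster_diffusion(self):
        d = transport_diagnostics(4.06, 1.0, 6.9)
        assert d.tau_diff == pytest.approx(0.246, abs=5e-4)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            transport_diagnostics(0.0, 1.0, 6.9)


class TestClosure:
    def test_closure_sets_gamma(self):
        p = _params()
        assert p.gamma_S_II * p.K_S == pytest.approx(1.0, rel=1e-12)
        assert p.KM_eff_II == pytest.approx(p.KM_II, rel=1e-12)

    def test_explicit_override(self):
        p = TwoPhaseParams(
            phi_D=1.7e-4, K_E=73_000.0, kcat_I=4.3, KM_I=713.0,
            kcat_II=6.9, KM_II=334.0, K_S=4.0, gamma_S_II=0.5,
            use_equilibrium_closure=False)
        assert p.KM_eff_II == pytest.approx(334.0 / 2.0)

    def test_inconsistent_closure_rejected(self):
        with pytest.raises(ValueError, match="closure"):
            TwoPhaseParams(
                phi_D=1.7e-4, K_E=73_000.0, kcat_I=4.3, KM_I=713.0,
                kcat_II=6.9, KM_II=334.0, K_S=4.0, gamma_S_II=0.5,
                use_equilibrium_closure=True)
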