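"""Tests of the Flory-Huggins/collapse theory module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnacondense import (
    DNAChain,
    MixtureState,
    SolventCondition,
    alpha_stationarity_residual,
    binodal_point,
    chemical_potentials,
    expansion_alpha,
    free_energy_intensive,
    make_chain,
    phase_diagram,
)
from dnacondense.polymer_model import (
    DomainError,
    b3_default,
    concentration_to_phi,
    critical_chi,
    free_energy_extensive,
    internal_free_energy,
    phi_to_concentration,
)

from conftest import grid_search_alpha


class TestMakeChain:
    def test_descriptors_match_hand_computed_power_laws(self):
        # frozen values from an independent evaluation of
        # <h0^2> = 4e-15 * (650 * bp)^{8/7} cm^2
        chain = make_chain(200)
        assert chain.molecular_weight == pytest.approx(130000.0)
        assert chain.h0_squared == pytest.approx(2.7961900094309104e-09, rel=1e-12)
        lam = make_chain(48500)
        assert lam.h0_squared / chain.h0_squared == pytest.approx(
            531.3550947820048, rel=1e-12
        )
        # omega scales as M^{-5/7}: omega ~ M / <h0^2>^{3/2} ~ M^{1-12/7}
        assert lam.omega / chain.omega == pytest.approx(
            0.019798599445859343, rel=1e-12
        )

    def test_segment_number_proportional_to_length(self):
        n1 = make_chain(1000).segment_number_N
        n2 = make_chain(2000).segment_number_N
        assert n2 == pytest.approx(2.0 * n1)
        assert n1 > 0

    @pytest.mark.parametrize("bad", [0, -5, 2.5])
    def test_invalid_length_raises(self, bad):
        with pytest.raises(DomainError):
            make_chain(bad)

    def test_all_fields_finite_positive(self):
        for bp in (1, 12, 200, 48500, 249_000_000):
            c = make_chain(bp)
            for v in (c.molecular_weight, c.segment_number_N, c.omega, c.h0_squared):
                assert math.isfinite(v) and v > 0


class TestFreeEnergy:
    def test_pure_solvent_is_zero(self, chain_200bp, poor_solvent):
        assert free_energy_intensive(
            MixtureState(phi_dna=0.0, alpha=1.0), chain_200bp, poor_solvent
        ) == 0.0

    def test_reduces_to_mixing_terms_without_virial_contributions(self, chain_200bp):
        # with alpha = 1 and both virial coefficients switched off the
        # internal part collapses to N (chi - 1), i.e. f - phi (chi - 1)
        # equals the bare Flory-Huggins mixing free energy
        solvent = SolventCondition(chi=0.5, b2_override=0.0, b3_override=0.0)
        n = chain_200bp.segment_number_N
        for phi in (0.01, 0.3, 0.8):
            f = free_energy_intensive(
                MixtureState(phi_dna=phi, alpha=1.0), chain_200bp, solvent
            )
            mixing = (
                (1 - phi) * math.log(1 - phi)
                + phi / n * math.log(phi)
                + 0.5 * phi * (1 - phi)
            )
            assert f - phi * (0.5 - 1.0) == pytest.approx(mixing, rel=1e-12)

    def test_matches_independent_rederivation(self, rng):
        # term-by-term re-implementation of the printed expression,
        # written here independently of the module
        for _ in range(50):
            bp = int(rng.integers(50, 100000))
            phi = float(rng.uniform(1e-6, 0.95))
            alpha = float(rng.uniform(0.05, 1.5))
            chi = float(rng.uniform(0.3, 1.2))
            chain = make_chain(bp)
            solvent = SolventCondition(chi=chi)
            n, w = chain.segment_number_N, chain.omega
            b2 = 0.5 - chi
            b3 = 1.0 + chi**2 / 20.0 - chi**3 / 600.0
            expected = (
                (1 - phi) * math.log(1 - phi)
                + phi / n * math.log(phi)
                + chi * phi * (1 - phi)
                + phi
                / n
                * (
                    n
                    * (
                        (chi - 1)
                        + b2 * w / (2**1.5 * alpha**3)
                        + b3 * w**2 / (2 * 3**2.5 * alpha**6)
                    )
                    + 1.5 * (alpha**2 - 1)
                    - math.log(alpha**3)
                )
            )
            got = free_energy_intensive(
                MixtureState(phi_dna=phi, alpha=alpha), chain, solvent
            )
            assert got == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("phi,alpha", [(1.0, 1.0), (1.2, 1.0), (0.5, 0.0), (0.5, -1.0)])
    def test_domain_errors(self, chain_200bp, poor_solvent, phi, alpha):
        with pytest.raises(DomainError):
            free_energy_intensive(
                MixtureState(phi_dna=phi, alpha=alpha), chain_200bp, poor_solvent
            )


class TestStationarity:
    def test_residual_vanishes_at_unperturbed_state_without_virials(self, chain_200bp):
        solvent = SolventCondition(chi=0.7, b2_override=0.0, b3_override=0.0)
        assert alpha_stationarity_residual(1.0, chain_200bp, solvent) == pytest.approx(0.0)

    def test_residual_direct_arithmetic(self, chain_200bp):
        solvent = SolventCondition(chi=0.7, b2_override=0.0, b3_override=0.0)
        assert alpha_stationarity_residual(0.5, chain_200bp, solvent) == pytest.approx(
            -0.03515625
        )

    def test_solver_matches_grid_search_oracle(self):
        lengths = [200, 1000, 2500, 10000, 48500]
        chis = np.linspace(0.5, 1.5, 21)
        for bp in lengths:
            chain = make_chain(bp)
            for chi in chis:
                solvent = SolventCondition(chi=float(chi))
                a_solver = expansion_alpha(chain, solvent)
                a_grid = grid_search_alpha(chain, solvent)
                assert abs(a_solver - a_grid) <= 1e-4, (bp, chi)


class TestExpansionAlpha:
    def test_theta_solvent_without_virials_gives_unity(self, chain_200bp):
        solvent = SolventCondition(chi=0.5, b2_override=0.0, b3_override=0.0)
        assert expansion_alpha(chain_200bp, solvent) == pytest.approx(1.0, abs=1e-9)

    def test_longer_chains_collapse_more_easily(self):
        # in the collapse-sensitive range the longer chain is at least as
        # compact as the shorter one
        short, long_ = make_chain(2500), make_chain(48500)
        for chi in (0.6, 0.7, 0.9, 1.2):
            solvent = SolventCondition(chi=chi)
            assert expansion_alpha(long_, solvent) <= expansion_alpha(short, solvent) + 1e-12

    def test_alpha_non_increasing_in_chi(self, chain_2500bp):
        chis = np.linspace(0.5, 2.0, 31)
        alphas = [
            expansion_alpha(chain_2500bp, SolventCondition(chi=float(c))) for c in chis
        ]
        assert all(b <= a + 1e-10 for a, b in zip(alphas, alphas[1:]))


class TestChemicalPotentials:
    def test_solvent_potential_vanishes_at_infinite_dilution(self, chain_200bp, poor_solvent):
        mu_d, mu_s = chemical_potentials(
            MixtureState(phi_dna=1e-12, alpha=1.0), chain_200bp, poor_solvent
        )
        assert abs(mu_s) < 1e-11
        assert mu_d < 0  # ln(phi) dominates

    def test_matches_finite_difference_of_extensive_form(self, rng):
        # central differences with one Richardson extrapolation step
        def numeric_mu(chain, solvent, phi, alpha):
            n = chain.segment_number_N
            n_dna = 1.0
            n_solv = n * (1.0 - phi) / phi

            def g_of(ns, nd):
                return free_energy_extensive(ns, nd, alpha, chain, solvent)

            def central(f, x, h):
                return (f(x + h) - f(x - h)) / (2 * h)

            def richardson(f, x, h):
                return (4 * central(f, x, h / 2) - central(f, x, h)) / 3.0

            h_s = max(1e-6 * n_solv, 1e-9)
            h_d = 1e-7
            mu_s = richardson(lambda x: g_of(x, n_dna), n_solv, h_s)
            mu_d = richardson(lambda x: g_of(n_solv, x), n_dna, h_d)
            return mu_d, mu_s

        failures = 0
        for _ in range(100):
            bp = int(rng.integers(100, 20000))
            phi = float(rng.uniform(0.01, 0.9))
            alpha = float(rng.uniform(0.2, 1.4))
            chi = float(rng.uniform(0.4, 1.2))
            chain = make_chain(bp)
            solvent = SolventCondition(chi=chi)
            mu_d, mu_s = chemical_potentials(
                MixtureState(phi_dna=phi, alpha=alpha), chain, solvent
            )
            nd, ns = numeric_mu(chain, solvent, phi, alpha)
            scale_d = max(abs(mu_d), 1.0)
            scale_s = max(abs(mu_s), 1e-3)
            if abs(mu_d - nd) / scale_d > 1e-4 or abs(mu_s - ns) / scale_s > 1e-4:
                failures += 1
        assert failures == 0

    def test_dna_potential_non_monotonic_above_critical(self, chain_lambda):
        # a necessary condition for coexistence: mu_DNA(phi) has interior
        # extrema at chi = 0.7 for lambda DNA
        solvent = SolventCondition(chi=0.7)
        alpha = expansion_alpha(chain_lambda, solvent)
        phis = np.logspace(-8, -0.05, 300)
        mu = [
            chemical_potentials(MixtureState(phi_dna=float(p), alpha=alpha), chain_lambda, solvent)[0]
            for p in phis
        ]
        signs = np.sign(np.diff(mu))
        assert len(set(signs[signs != 0])) == 2

    def test_boundary_phi_raises(self, chain_200bp, poor_solvent):
        for phi in (0.0, 1.0):
            with pytest.raises(DomainError):
                chemical_potentials(
                    MixtureState(phi_dna=phi, alpha=1.0), chain_200bp, poor_solvent
                )


class TestBinodal:
    def test_worked_concentrations_at_chi_07(self, chain_200bp, chain_2500bp):
        # 200 bp: ~160 mg/mL; 2.5 kb: ~0.3 ug/mL (within a factor of two)
        p200 = binodal_point(chain_200bp, 0.7)
        c200_mg = p200.c_dilute * 1e3
        assert 80.0 <= c200_mg <= 320.0
        p2500 = binodal_point(chain_2500bp, 0.7)
        c2500_ug = p2500.c_dilute * 1e6
        assert 0.15 <= c2500_ug <= 0.6

    def test_coexistence_structure_and_residuals(self, chain_2500bp):
        for chi in (0.6, 0.7, 0.9):
            p = binodal_point(chain_2500bp, chi)
            assert p is not None
            assert 0 < p.phi_dilute < p.phi_dense < 1
            assert abs(p.residual_mu_solvent) < 1e-8
            assert abs(p.residual_mu_dna) < 1e-8
            assert p.c_dilute == pytest.approx(p.phi_dilute * 1.8)
            assert p.c_dense == pytest.approx(p.phi_dense * 1.8)

    def test_theta_solvent_has_no_coexistence(self, chain_200bp):
        assert binodal_point(chain_200bp, 0.5) is None

    def test_below_critical_chi_has_no_coexistence(self, chain_200bp):
        chi_c = critical_chi(chain_200bp)
        assert binodal_point(chain_200bp, chi_c * 0.99) is None

    def test_dense_alpha_unity_switch(self, chain_2500bp):
        p = binodal_point(chain_2500bp, 0.7, dense_alpha_unity=True)
        assert p is not None and p.alpha_dense == 1.0

    def test_dilute_alpha_is_collapse_solution(self, chain_2500bp):
        p = binodal_point(chain_2500bp, 0.7)
        assert p.alpha_dilute == pytest.approx(
            expansion_alpha(chain_2500bp, SolventCondition(chi=0.7))
        )

    def test_chromosome_scale_solved_in_log_space(self):
        p = binodal_point(make_chain(249_000_000), 0.7)
        assert p is not None
        assert p.log10_phi_dilute < -1000  # far below float underflow
        assert math.isfinite(p.log10_phi_dilute)


class TestPhaseDiagram:
    CAPTION_LENGTHS = [200, 2500, 48500, 249_000_000]

    def test_dilute_branch_ordered_by_length_at_fixed_chi(self):
        logs = [
            binodal_point(make_chain(bp), 0.7).log10_phi_dilute
            for bp in self.CAPTION_LENGTHS
        ]
        assert all(b < a for a, b in zip(logs, logs[1:]))

    def test_collapse_chi_decreases_with_length(self):
        grid = np.arange(0.5, 1.3001, 0.01)
        collapse = [
            phase_diagram(make_chain(bp), grid).collapse_chi
            for bp in self.CAPTION_LENGTHS
        ]
        assert all(c is not None for c in collapse)
        assert all(b < a for a, b in zip(collapse, collapse[1:]))

    def test_subcritical_grid_has_no_coexistence(self, chain_200bp):
        grid = np.linspace(0.2, 0.45, 6)
        pd_ = phase_diagram(chain_200bp, grid)
        assert all(p is None for p in pd_.binodal_points)

    def test_empty_or_unsorted_grid_raises(self, chain_200bp):
        with pytest.raises(DomainError):
            phase_diagram(chain_200bp, [])
        with pytest.raises(DomainError):
            phase_diagram(chain_200bp, [0.7, 0.6])

    def test_dataframe_shape(self, chain_2500bp):
        df = phase_diagram(chain_2500bp, np.linspace(0.55, 0.9, 8)).to_dataframe()
        assert len(df) == 8
        assert {"chi", "alpha_dilute", "coexists", "c_dilute_g_per_mL"} <= set(df.columns)


class TestConversions:
    @given(phi=st.floats(min_value=1e-12, max_value=0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_phi_concentration_roundtrip(self, phi):
        assert concentration_to_phi(phi_to_concentration(phi)) == pytest.approx(
            phi, rel=1e-14
        )

    def test_b3_positive_over_working_range(self):
        for chi in np.linspace(0.0, 3.0, 50):
            assert b3_default(float(chi), 10.0) > 0
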