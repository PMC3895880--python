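import numpy as np
import pytest

import eigenlocal as el
from eigenlocal import localization_theory as lt
from eigenlocal.network_models import GradientSelfCouplingParams
from .conftest import FIG3_STRONG

MU_F, MU_B = FIG3_STRONG["mu_f"], FIG3_STRONG["mu_b"]
DELTA_R, L_C = FIG3_STRONG["delta_r"], FIG3_STRONG["l_c"]


class TestRelativeKernel:
    def test_round_trip_recovers_matrix(self, fig3_strong_net):
        kern = lt.relative_kernel(fig3_strong_net)
        assert np.allclose(kern.to_matrix(), fig3_strong_net.W)

    def test_feedforward_offset_two(self, fig3_strong_net):
        kern = lt.relative_kernel(fig3_strong_net)
        expected = MU_F * np.exp(-2 / L_C)
        for j in (5, 40, 80):
            assert kern(j, 2) == pytest.approx(expected)

    def test_ring_kernel_is_position_independent(self, ring100):
        kern = lt.relative_kernel(ring100)
        spread = kern.table.max(axis=0) - kern.table.min(axis=0)
        assert spread.max() < 1e-12


class TestLocalEigenvalue:
    def test_zero_frequency_gives_row_sum(self, fig3_strong_net):
        kern = lt.relative_kernel(fig3_strong_net)
        lam = lt.local_eigenvalue(kern, 30, 0.0)
        assert lam == pytest.approx(fig3_strong_net.W[30].sum())

    def test_exact_on_ring_dft_grid(self, ring100, ring100_dec):
        kern = lt.relative_kernel(ring100)
        eigs = np.sort_complex(ring100_dec.eigenvalues())
        for k in (0, 3, 17, 50):
            lam = lt.local_eigenvalue(kern, 10, 2 * np.pi * k / 100)
            assert np.min(np.abs(eigs - lam)) < 1e-8

    def test_decay_slows_along_the_gradient(self, fig3_strong_net):
        kern = lt.relative_kernel(fig3_strong_net)
        res = [lt.local_eigenvalue(kern, j0, np.pi).real
               for j0 in range(30, 71, 10)]
        assert np.all(np.diff(res) > 0)


class TestAlphaSquared:
    def test_translation_invariance_yields_delocalized_signal(self, ring100):
        kern = lt.relative_kernel(ring100)
        assert lt.alpha_squared(kern, 50, 0.3) is lt.DELOCALIZED
        assert lt.alpha_squared_twist(kern, 50, 0.3) is lt.DELOCALIZED

    def test_matches_closed_form_for_gradient_model(self):
        for l_c in (2.0, 4.0, 8.0):
            # interior means far from both ends in units of l_c
            N = max(100, int(20 * l_c))
            p = GradientSelfCouplingParams(mu0=-1.9, delta_r=DELTA_R,
                                           mu_f=MU_F, mu_b=MU_B, l_c=l_c)
            net = el.build_gradient_self_coupling(N, p)
            kern = lt.relative_kernel(net)
            closed = lt.gradient_model_alpha_sq(MU_F, MU_B, DELTA_R, l_c)
            for j0 in (N // 2 - 5, N // 2, N // 2 + 5):
                a2 = lt.alpha_squared(kern, j0, np.pi)
                assert abs(a2 - closed) / closed < 0.05

    def test_twist_condition_agrees_on_interior_grid(self, fig3_strong_net):
        kern = lt.relative_kernel(fig3_strong_net)
        n_pts = 0
        for j0 in range(35, 66, 5):
            for omega in np.pi + np.linspace(-0.3, 0.3, 5):
                a = lt.alpha_squared(kern, j0, omega)
                b = lt.alpha_squared_twist(kern, j0, omega)
                assert abs(a - b) / abs(a) < 0.01
                n_pts += 1
        assert n_pts >= 20

    def test_width_inversely_proportional_to_gradient(self):
        p2 = GradientSelfCouplingParams(mu0=-1.9, delta_r=2 * DELTA_R,
                                        mu_f=MU_F, mu_b=MU_B, l_c=L_C)
        net2 = el.build_gradient_self_coupling(100, p2)
        a_single = lt.alpha_squared_twist(
            lt.relative_kernel(el.build_gradient_self_coupling(
                100, GradientSelfCouplingParams(mu0=-1.9, delta_r=DELTA_R,
                                                mu_f=MU_F, mu_b=MU_B,
                                                l_c=L_C))), 50, np.pi)
        a_double = lt.alpha_squared_twist(lt.relative_kernel(net2), 50, np.pi)
        assert abs(a_double / a_single - 0.5) < 0.01


class TestClosedForm:
    def test_published_parameter_value(self):
        a2 = lt.gradient_model_alpha_sq(MU_F, MU_B, DELTA_R, L_C)
        assert a2 == pytest.approx(
            0.1 / (0.02 * (1 + np.cosh(0.25))), rel=1e-12)
        assert a2 == pytest.approx(2.461, abs=5e-4)
        assert np.sqrt(a2) == pytest.approx(1.569, abs=1e-3)

    def test_vanishes_when_projections_balance(self):
        assert lt.gradient_model_alpha_sq(0.2, 0.2, 0.01, 4.0) == 0.0

    def test_no_gradient_means_no_localization(self):
        assert lt.gradient_model_alpha_sq(0.2, 0.1, 0.0, 4.0) is lt.DELOCALIZED

    def test_halving_gradient_doubles_width(self):
        a = lt.gradient_model_alpha_sq(MU_F, MU_B, DELTA_R, L_C)
        b = lt.gradient_model_alpha_sq(MU_F, MU_B, DELTA_R / 2, L_C)
        assert b == pytest.approx(2 * a)


class TestGaussianMode:
    def test_real_width_gives_real_gaussian(self):
        v = lt.gaussian_mode(40.0, 0.0, 9.0, 100)
        assert np.allclose(v.imag, 0.0)
        assert np.abs(v).max() == pytest.approx(1.0)
        assert np.argmax(np.abs(v)) == 40

    def test_negative_real_width_is_rejected(self):
        with pytest.raises(lt.RejectedSolutionError):
            lt.gaussian_mode(40.0, 0.0, -2.0 + 1.0j, 100)

    def test_magnitude_depends_only_on_real_inverse_width(self):
        # |e^{-x^2/(2 a2)}| = e^{-x^2 Re(1/a2)/2}
        a2 = 4.0 + 3.0j
        v = lt.gaussian_mode(50.0, 0.7, a2, 100)
        x = np.arange(100) - 50.0
        expected = np.exp(-x ** 2 * np.real(1 / a2) / 2)
        assert np.allclose(np.abs(v), expected / expected.max(), atol=1e-12)

    def test_matches_numerical_gradient_modes(self, fig3_strong_dec):
        sims = []
        for m in fig3_strong_dec.modes:
            if m.edge:
                continue
            pred = lt.predict_gaussian_for_mode(m, MU_F, MU_B, DELTA_R, L_C,
                                                100)
            sims.append(lt.match_prediction(m, pred)["similarity"])
        assert np.median(sims) >= 0.98


class TestLocalizationRegion:
    def test_ring_region_is_empty(self, ring100):
        kern = lt.relative_kernel(ring100)
        region = lt.localization_region(kern,
                                        omega_grid=np.linspace(0.1, 3.0, 8),
                                        j0_grid=np.arange(40, 60, 5))
        assert not (region["re_alpha_sq"] > 0).any()

    def test_strong_gradient_encloses_all_nonedge_eigenvalues(
            self, fig3_strong_net, fig3_strong_dec):
        kern = lt.relative_kernel(fig3_strong_net)
        region = lt.localization_region(kern, j0_grid=np.arange(25, 75))
        lams = np.array([m.lam for m in fig3_strong_dec.modes if not m.edge])
        assert lt.region_membership(region, lams).all()

    def test_weak_gradient_region_separates_pr(self, fig3_weak_net,
                                               fig3_weak_dec):
        import scipy.stats
        kern = lt.relative_kernel(fig3_weak_net)
        region = lt.localization_region(kern, j0_grid=np.arange(25, 75))
        inside = lt.region_membership(region, fig3_weak_dec.eigenvalues())
        prs = np.array([m.pr for m in fig3_weak_dec.modes])
        assert 0 < inside.sum() < len(inside)
        p = scipy.stats.mannwhitneyu(prs[inside], prs[~inside],
                                     alternative="less").pvalue
        assert p < 0.01


class TestAiry:
    def test_published_beta2_value(self):
        _, beta2 = lt.airy_coefficients(0.2, 0.19, DELTA_R, 4.0)
        assert beta2 == pytest.approx((0.01 / 0.39) / np.tanh(0.125),
                                      rel=1e-12)
        assert beta2 == pytest.approx(0.206, abs=5e-4)

    def test_beta2_vanishes_at_symmetry(self):
        _, beta2 = lt.airy_coefficients(0.2, 0.2, DELTA_R, 4.0)
        assert beta2 == 0.0

    def test_beta2_grows_with_asymmetry(self):
        vals = [lt.airy_coefficients(0.2, mu_b, DELTA_R, 4.0)[1]
                for mu_b in (0.19, 0.15, 0.1, 0.05)]
        assert np.all(np.diff(vals) > 0)

    def test_steep_envelope_limit_is_gaussian(self):
        # when beta2 >> beta1^(1/3) the peak is Gaussian with
        # alpha^2 = 2 beta2 / beta1
        beta1, beta2 = 0.5, 4.0
        v = np.abs(lt.airy_mode(100.0, 0.0, beta1, beta2, 201))
        a2 = 2 * beta2 / beta1
        x = np.arange(201) - 100.0
        gauss = np.exp(-x ** 2 / (2 * a2))
        core = np.abs(x) <= np.sqrt(a2)
        assert np.max(np.abs(v[core] - gauss[core]) / gauss[core]) < 0.05

    def test_flat_envelope_shows_airy_ripples(self):
        v = np.abs(lt.airy_mode(80.0, 0.0, 1.0, 0.0, 100))
        interior = v[1:-1]
        peaks = np.sum((interior > v[:-2]) & (interior > v[2:])
                       & (interior > 0.01))
        assert peaks >= 3

    def test_matches_numerical_modes_across_sweep(self):
        sims = {}
        for mu_b in (0.125, 0.15, 0.175, 0.19):
            p = GradientSelfCouplingParams(mu0=-1.9, delta_r=DELTA_R,
                                           mu_f=0.2, mu_b=mu_b, l_c=4.0)
            dec = el.decompose(el.build_gradient_self_coupling(100, p))
            m = min((m for m in dec.modes if not m.edge),
                    key=lambda m: abs(m.center - 50))
            pred = lt.predict_airy_for_mode(m, 0.2, mu_b, DELTA_R, 4.0, 100)
            sims[mu_b] = lt.match_prediction(m, pred)["similarity"]
        assert all(s >= 0.9 for s in sims.values())


class TestMatchPrediction:
    def test_mode_matches_itself_perfectly(self, fig3_strong_dec):
        m = fig3_strong_dec.modes[10]
        pred = lt.LocalizationPrediction(j0=m.center, omega=m.omega,
                                         lam=m.lam, profile=m.v,
                                         order="first")
        rep = lt.match_prediction(m, pred)
        assert rep["similarity"] == pytest.approx(1.0)
        assert rep["peak_offset"] == 0.0

    def test_narrow_gaussian_overlaps_little_with_uniform_ring_mode(
            self, ring100_dec):
        m = ring100_dec.modes[0]
        a2 = lt.gradient_model_alpha_sq(MU_F, MU_B, DELTA_R, L_C)
        pred = lt.LocalizationPrediction(
            j0=50.0, omega=0.0, lam=m.lam, order="first",
            profile=lt.gaussian_mode(50.0, 0.0, a2, 100))
        rep = lt.match_prediction(m, pred)
        assert rep["similarity"] < 0.9
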