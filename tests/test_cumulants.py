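"""Cumulant tensors: moment formulas, symmetries, invariants, truncation."""

import numpy as np
import pytest

from noddida_dde.cumulants import (
    axisym_dk,
    c_invariants,
    cumulant_signal,
    full_tensors,
    invariants_from_tensors,
    reconstruct_from_invariants,
    watson_moments,
)
from noddida_dde.encoding import BTensor
from noddida_dde.forward_model import ModelParams, noddida_signal, sphere_quadrature
from noddida_dde.watson import WatsonODF, h2, watson_pdf

from conftest import random_feasible_params


def minor_major_symmetry_error(C: np.ndarray) -> float:
    return max(
        np.abs(C - np.einsum("jikl->ijkl", C)).max(),
        np.abs(C - np.einsum("ijlk->ijkl", C)).max(),
        np.abs(C - np.einsum("klij->ijkl", C)).max(),
    )


def symmetric_part_error(tensors) -> float:
    """Residual of Dbar^2 W = 3 C_(ijkl)."""
    C = tensors.C
    sym = C + np.einsum("ikjl->ijkl", C) + np.einsum("iljk->ijkl", C)
    return np.abs(sym - tensors.D_mean**2 * tensors.W).max()


class TestWatsonMoments:
    def test_isotropic(self):
        h2t, h4t = watson_moments(WatsonODF(np.array([0.0, 0.0, 1.0]), 0.0))
        assert np.allclose(h2t, np.eye(3) / 3, atol=1e-14)
        assert h4t[0, 0, 0, 0] == pytest.approx(0.2, abs=1e-14)
        assert h4t[0, 0, 1, 1] == pytest.approx(1.0 / 15.0, abs=1e-14)

    def test_h2_diagonal_in_fiber_frame(self):
        kappa = 6.0
        h2t, _ = watson_moments(WatsonODF(np.array([0.0, 0.0, 1.0]), kappa))
        assert h2t[2, 2] == pytest.approx(h2(1.0, kappa), abs=1e-13)
        assert h2t[0, 0] == pytest.approx(h2(0.0, kappa), abs=1e-13)
        assert np.trace(h2t) == pytest.approx(1.0, abs=1e-13)

    def test_against_spherical_quadrature(self, mu_oblique):
        odf = WatsonODF(mu_oblique, 8.0)
        pts, w = sphere_quadrature(degree=59)
        dens = w * watson_pdf(pts, odf)
        h2_o = np.einsum("q,qi,qj->ij", dens, pts, pts)
        h4_o = np.einsum("q,qi,qj,qk,ql->ijkl", dens, pts, pts, pts, pts)
        h2t, h4t = watson_moments(odf)
        assert np.abs(h2t - h2_o).max() < 1e-10
        assert np.abs(h4t - h4_o).max() < 1e-10


class TestAxisymDK:
    def test_reference_example(self, params_row1):
        dk = axisym_dk(params_row1)
        assert np.round(dk.as_array(), 3).tolist() == [1.503, 0.195, 1.456, 0.291, 0.926]

    def test_single_aligned_compartment(self):
        p = ModelParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.3, kappa=1e9)
        dk = axisym_dk(p)
        assert dk.D_par == pytest.approx(2.0, abs=1e-8)
        assert dk.D_perp == pytest.approx(0.0, abs=1e-8)
        assert np.allclose([dk.W_par, dk.W_perp, dk.W_mean], 0.0, atol=1e-6)

    def test_against_small_b_cumulant_oracle(self, params_row1):
        """D(xi), W(xi) are the first two log-signal cumulants in b."""
        from noddida_dde.encoding import AcquisitionScheme, Measurement

        dk = axisym_dk(params_row1)
        mu = params_row1.mu
        perp = np.array([1.0, 0.0, 0.0])
        for axis, d_true, w_true in ((mu, dk.D_par, dk.W_par), (perp, dk.D_perp, dk.W_perp)):
            b1, b2 = 1e-4, 2e-4
            ms = [Measurement(BTensor.linear(b, axis)) for b in (b1, b2)]
            s = noddida_signal(AcquisitionScheme(ms), params_row1).values
            y1, y2 = np.log(s[0]), np.log(s[1])
            # solve y = -b D + b^2 Dbar^2 W / 6 from two points
            A = np.array([[-b1, b1**2 / 6], [-b2, b2**2 / 6]])
            d_est, w_est = np.linalg.solve(A, [y1, y2])
            assert d_est == pytest.approx(d_true, abs=1e-3)
            assert w_est / dk.D_mean**2 == pytest.approx(w_true, abs=1e-3)

    def test_mean_diffusivity_consistency(self, params_row1):
        dk = axisym_dk(params_row1)
        assert dk.D_mean == pytest.approx((2 * dk.D_perp + dk.D_par) / 3, abs=1e-15)


class TestFullTensors:
    def test_no_dispersion_single_compartment_has_zero_C(self):
        p = ModelParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.3, kappa=1e9)
        t = full_tensors(p)
        assert np.abs(t.C).max() < 1e-6

    def test_minor_major_symmetries(self, params_row1, mu_oblique):
        for mu in (params_row1.mu, mu_oblique):
            p = ModelParams(f=0.73, Da=2.0, De_par=1.0, De_perp=0.3, kappa=8.0, mu=mu)
            t = full_tensors(p)
            assert minor_major_symmetry_error(t.C) < 1e-12

    def test_symmetric_part_is_kurtosis(self, params_row1):
        assert symmetric_part_error(full_tensors(params_row1)) < 1e-10

    def test_d_matches_axisym_values_in_fiber_frame(self, params_row1):
        t = full_tensors(params_row1)
        dk = axisym_dk(params_row1)
        assert t.D[2, 2] == pytest.approx(dk.D_par, abs=1e-12)
        assert t.D[0, 0] == pytest.approx(dk.D_perp, abs=1e-12)
        assert abs(t.D[0, 1]) < 1e-14

    def test_against_discrete_mixture_oracle(self, mu_oblique):
        """C as the covariance of per-orientation diffusion tensors.

        Treats quadrature nodes as discrete Gaussian compartments with
        Watson weights: D = <D_u>, C = <D_u (x) D_u> - D (x) D.
        """
        p = ModelParams(f=0.37, Da=2.1, De_par=1.4, De_perp=0.5, kappa=3.0, mu=mu_oblique)
        pts, w = sphere_quadrature(degree=59)
        dens = w * watson_pdf(pts, WatsonODF(p.mu, p.kappa))
        eye = np.eye(3)
        # stick tensor Da u u^T; zeppelin De_perp I + (De_par - De_perp) u u^T
        uu = np.einsum("qi,qj->qij", pts, pts)
        d_stick = p.Da * uu
        d_zepp = p.De_perp * eye + p.delta_e * uu
        frac = np.concatenate([p.f * dens, (1 - p.f) * dens])
        tens = np.concatenate([d_stick, d_zepp])
        D_o = np.einsum("q,qij->ij", frac, tens)
        C_o = np.einsum("q,qij,qkl->ijkl", frac, tens, tens) - np.einsum(
            "ij,kl->ijkl", D_o, D_o
        )
        t = full_tensors(p)
        assert np.abs(t.D - D_o).max() < 1e-10
        assert np.abs(t.C - C_o).max() < 1e-10

    def test_isotropic_odf_keeps_compartment_variance(self):
        # kappa = 0: W and C are isotropic but nonzero through the
        # stick/zeppelin diffusivity spread
        p = ModelParams(f=0.5, Da=2.0, De_par=1.0, De_perp=0.2, kappa=0.0)
        t = full_tensors(p)
        assert np.allclose(t.D, t.D[0, 0] * np.eye(3), atol=1e-12)
        assert np.abs(t.C).max() > 1e-3
        inv = c_invariants(p)
        inv_t = invariants_from_tensors(t, p.mu)
        assert inv.cxxyy_minus_cxyxy == pytest.approx(inv_t.cxxyy_minus_cxyxy, abs=1e-12)


class TestCInvariants:
    def test_reference_example(self, params_row1):
        inv = c_invariants(params_row1)
        assert round(inv.cxxyy_minus_cxyxy, 3) == -0.006
        assert round(abs(inv.cross_combo), 3) == 0.210

    def test_closed_form_matches_tensor_antisymmetrization(self, mu_oblique):
        for kappa in (0.5, 8.0, 50.0):
            p = ModelParams(f=0.6, Da=1.9, De_par=1.2, De_perp=0.4, kappa=kappa, mu=mu_oblique)
            a = c_invariants(p)
            b = invariants_from_tensors(full_tensors(p), p.mu)
            assert a.cxxyy_minus_cxyxy == pytest.approx(b.cxxyy_minus_cxyxy, abs=1e-10)
            assert a.cross_combo == pytest.approx(b.cross_combo, abs=1e-10)

    def test_zeta_scalings(self, params_row1):
        inv = c_invariants(params_row1)
        assert inv.zeta2 == pytest.approx(inv.cxxyy_minus_cxyxy * 2 / 3, rel=1e-12)
        assert inv.zeta1 == pytest.approx(inv.cross_combo * 4 / 3, rel=1e-12)

    def test_vanish_for_single_aligned_compartment(self):
        p = ModelParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.3, kappa=1e9)
        inv = c_invariants(p)
        assert abs(inv.cxxyy_minus_cxyxy) < 1e-8
        assert abs(inv.cross_combo) < 1e-8


class TestReconstruction:
    def test_tensor_forms_reproduce_full_tensors(self):
        rng = np.random.default_rng(11)
        for p in random_feasible_params(rng, 8):
            dk = axisym_dk(p)
            inv = c_invariants(p)
            rec = reconstruct_from_invariants(dk, inv, mu=p.mu)
            t = full_tensors(p)
            assert np.abs(rec.D - t.D).max() < 1e-10
            assert np.abs(rec.W - t.W).max() < 1e-10
            assert np.abs(rec.C - t.C).max() < 1e-10


class TestCumulantSignal:
    def test_b0(self, params_row1):
        t = full_tensors(params_row1)
        assert cumulant_signal(BTensor.zero(), t, S0=3.3) == pytest.approx(3.3)

    def test_matches_directional_dk_form_for_linear_tensors(self, params_row1):
        # log(S/S0) = -b D(xi) + b^2 Dbar^2 W(xi)/6 for linear encodings
        t = full_tensors(params_row1)
        dk = axisym_dk(params_row1)
        from noddida_dde.watson import h4 as h4f

        for xi in (1.0, 0.5, 0.0):
            axis = np.array([np.sqrt(1 - xi**2), 0.0, xi])
            b = 1.7
            B = BTensor.linear(b, axis)
            s = cumulant_signal(B, t)
            d_xi = float(axis @ t.D @ axis)
            w_xi = float(np.einsum("ijkl,i,j,k,l->", t.W, axis, axis, axis, axis))
            expect = np.exp(-b * d_xi + b * b * t.D_mean**2 * w_xi / 6.0)
            assert s == pytest.approx(expect, rel=1e-12)

    def test_truncation_error_scales_as_b_cubed(self, params_row1):
        """Richardson check: halving b divides the O(b^3) residual by ~8."""
        t = full_tensors(params_row1)
        from noddida_dde.encoding import AcquisitionScheme, Measurement

        axis = np.array([0.6, 0.0, 0.8])
        errs = []
        for b in (0.2, 0.1):
            B = BTensor.linear(b, axis)
            exact = noddida_signal(
                AcquisitionScheme([Measurement(B)]), params_row1
            ).values[0]
            approx = cumulant_signal(B, t)
            errs.append(abs(np.log(exact) - np.log(approx)))
        ratio = errs[0] / errs[1]
        assert 6.5 < ratio < 9.5
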