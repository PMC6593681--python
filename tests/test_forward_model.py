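"""Forward signal model: quadrature, fast path, limits, noise."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from noddida_dde.encoding import BTensor, build_scheme
from noddida_dde.forward_model import (
    ModelParams,
    add_rician_noise,
    kernel_signal,
    noddida_signal,
    sphere_quadrature,
)
from noddida_dde.watson import WatsonODF, watson_pdf


class TestKernel:
    def test_unweighted(self):
        p = ModelParams(f=0.5, Da=2.0, De_par=1.0, De_perp=0.5, kappa=3.0)
        assert kernel_signal(BTensor.zero(), [0, 0, 1], p) == pytest.approx(1.0)

    def test_stick_invisible_perpendicular(self):
        p = ModelParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.5, kappa=3.0)
        B = BTensor.linear(2.0, [0, 0, 1])
        assert kernel_signal(B, [1, 0, 0], p) == pytest.approx(1.0, abs=1e-14)

    def test_isotropic_zeppelin(self):
        p = ModelParams(f=0.0, Da=2.0, De_par=0.7, De_perp=0.7, kappa=3.0)
        B = BTensor.linear(1.5, [0, 1, 0])
        for u in ([1, 0, 0], [0, 0, 1], [0.6, 0.8, 0]):
            assert kernel_signal(B, u, p) == pytest.approx(np.exp(-1.5 * 0.7), rel=1e-12)


class TestSignal:
    def test_b0_returns_s0(self, scheme_dde3030, params_set_a):
        sig = noddida_signal(scheme_dde3030, params_set_a)
        b0 = scheme_dde3030.bvalues <= 1e-12
        assert np.allclose(sig.values[b0], params_set_a.S0, atol=1e-12)

    def test_aligned_limit(self, scheme_sde):
        mu = np.array([0.0, 0.0, 1.0])
        p = ModelParams(f=0.6, Da=2.2, De_par=1.4, De_perp=0.4, kappa=1e6, mu=mu)
        sig = noddida_signal(scheme_sde, p).values
        for m, s in zip(scheme_sde, sig):
            bmm = mu @ m.btensor.matrix @ mu
            b = m.btensor.b
            expect = 0.6 * np.exp(-2.2 * bmm) + 0.4 * np.exp(-b * 0.4 - 1.0 * bmm)
            assert s == pytest.approx(expect, abs=1e-6)

    def test_fast_path_matches_quadrature(self, scheme_dde3030, mu_oblique):
        for kappa in (0.0, 0.3, 8.0, 64.0):
            p = ModelParams(f=0.4, Da=2.2, De_par=1.5, De_perp=0.4, kappa=kappa, mu=mu_oblique)
            sq = noddida_signal(scheme_dde3030, p, method="quadrature").values
            sf = noddida_signal(scheme_dde3030, p, method="fast").values
            assert np.allclose(sq, sf, atol=1e-12)

    def test_quadrature_degree_convergence(self, scheme_dde3030, mu_oblique):
        # once the rule resolves the ODF bandwidth, doubling it is a no-op;
        # kappa = 64 needs degree ~120 for that (degree 59 leaves ~1e-6)
        for kappa, degree in ((8.0, 59), (64.0, 119)):
            p = ModelParams(f=0.4, Da=2.2, De_par=1.5, De_perp=0.4, kappa=kappa, mu=mu_oblique)
            a = noddida_signal(scheme_dde3030, p, method="quadrature", degree=degree).values
            b = noddida_signal(scheme_dde3030, p, method="quadrature", degree=2 * degree + 1).values
            assert np.abs(a - b).max() < 1e-9

    def test_rotation_invariance(self, scheme_dde3030):
        p = ModelParams(f=0.45, Da=1.8, De_par=1.2, De_perp=0.3, kappa=12.0,
                        mu=np.array([0.0, 0.0, 1.0]))
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7]).as_matrix()
        p_rot = ModelParams(f=0.45, Da=1.8, De_par=1.2, De_perp=0.3, kappa=12.0,
                            mu=rot @ p.mu)
        a = noddida_signal(scheme_dde3030.rotated(rot), p_rot).values
        b = noddida_signal(scheme_dde3030, p).values
        assert np.abs(a - b).max() < 1e-10

    def test_antipodal_fiber_direction(self, scheme_dde3030, mu_oblique):
        pa = ModelParams(f=0.4, Da=2.0, De_par=1.0, De_perp=0.4, kappa=9.0, mu=mu_oblique)
        pb = ModelParams(f=0.4, Da=2.0, De_par=1.0, De_perp=0.4, kappa=9.0, mu=-mu_oblique)
        assert np.allclose(noddida_signal(scheme_dde3030, pa).values,
                           noddida_signal(scheme_dde3030, pb).values, atol=1e-13)

    def test_monotone_decreasing_in_b(self, mu_oblique):
        p = ModelParams(f=0.4, Da=2.0, De_par=1.0, De_perp=0.4, kappa=9.0, mu=mu_oblique)
        from noddida_dde.encoding import AcquisitionScheme, Measurement

        axis = np.array([0.5, 0.5, np.sqrt(0.5)])
        bs = np.linspace(0.0, 4.0, 9)
        for maker in (BTensor.linear, BTensor.planar):
            ms = [Measurement(maker(b, axis) if b else BTensor.zero()) for b in bs]
            sig = noddida_signal(AcquisitionScheme(ms), p).values
            assert np.all(np.diff(sig) < 0)

    def test_parallel_pair_equals_sde(self, params_set_a):
        # same b-tensor => identical signal, exactly
        from noddida_dde.encoding import AcquisitionScheme, Measurement, btensor_from_pair

        n = np.array([0.6, 0.0, 0.8])
        pair = Measurement(btensor_from_pair(1.0, n, 1.0, n))
        sde = Measurement(BTensor.linear(2.0, n))
        sig = noddida_signal(AcquisitionScheme([pair, sde]), params_set_a).values
        assert sig[0] == sig[1]

    def test_monte_carlo_oracle_set_a(self, scheme_dde3030, params_set_a):
        """Spherical-convolution signal vs direct Monte-Carlo integration."""
        p = params_set_a
        rng = np.random.default_rng(42)
        n = 1_000_000
        # inverse-CDF sampling of the axial cosine of the Watson density
        t_grid = np.linspace(-1, 1, 20001)
        pdf_t = np.exp(p.kappa * (t_grid**2 - 1.0))
        cdf = np.cumsum(pdf_t)
        cdf /= cdf[-1]
        t = np.interp(rng.uniform(size=n), cdf, t_grid)
        phi = rng.uniform(0, 2 * np.pi, size=n)
        st = np.sqrt(1 - t**2)
        u_local = np.column_stack([st * np.cos(phi), st * np.sin(phi), t])
        # rotate local z to mu
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, p.mu)
        c = z @ p.mu
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1 + c)
        u = u_local @ R.T

        sig = noddida_signal(scheme_dde3030, p).values
        for idx in (5, 20, 40, 64):
            B = scheme_dde3030.measurements[idx].btensor
            buu = np.einsum("ij,ni,nj->n", B.matrix, u, u)
            k = p.f * np.exp(-p.Da * buu) + (1 - p.f) * np.exp(
                -B.b * p.De_perp - p.delta_e * buu
            )
            mc, se = k.mean(), k.std(ddof=1) / np.sqrt(n)
            assert abs(sig[idx] - p.S0 * mc) < 3 * max(se, 1e-7)


class TestQuadratureRule:
    def test_weights_sum_to_sphere_area(self):
        for degree in (11, 59):
            pts, w = sphere_quadrature(degree)
            assert w.sum() == pytest.approx(4 * np.pi, rel=1e-12)
            assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_exact_for_even_polynomials(self):
        # integral of z^2 over the sphere is 4 pi / 3
        pts, w = sphere_quadrature(degree=7)
        assert np.sum(w * pts[:, 2] ** 2) == pytest.approx(4 * np.pi / 3, rel=1e-12)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            sphere_quadrature(-1)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, scheme_sde, params_set_a):
        sig = noddida_signal(scheme_sde, params_set_a)
        noisy = add_rician_noise(sig, snr=1e12, seed=0)
        assert np.allclose(noisy.values, sig.values, atol=1e-9)

    def test_reproducible(self, scheme_sde, params_set_a):
        sig = noddida_signal(scheme_sde, params_set_a)
        a = add_rician_noise(sig, snr=50, seed=5, n_reps=3)
        b = add_rician_noise(sig, snr=50, seed=5, n_reps=3)
        assert np.array_equal(a.values, b.values)

    def test_moments_match_rician_expansion(self, scheme_sde, params_set_a):
        """b0 sample mean ~ S0 (1 + 1/(4 snr^2)), variance ~ sigma^2."""
        sig = noddida_signal(scheme_sde, params_set_a)
        snr = 50.0
        reps = add_rician_noise(sig, snr=snr, seed=9, n_reps=100_000)
        b0 = scheme_sde.bvalues <= 1e-12
        vals = reps.values[b0].ravel()
        s0 = params_set_a.S0
        sigma = s0 / snr
        se_mean = sigma / np.sqrt(vals.size)
        assert abs(vals.mean() - s0 * (1 + 1 / (4 * snr**2))) < 4 * se_mean
        assert np.isclose(vals.var(ddof=1), sigma**2, rtol=0.03)

    def test_positive_after_corruption(self, scheme_sde, params_set_a):
        sig = noddida_signal(scheme_sde, params_set_a)
        noisy = add_rician_noise(sig, snr=5, seed=1, n_reps=50)
        assert np.all(noisy.values >= 0)

    def test_rejects_bad_snr(self, scheme_sde, params_set_a):
        sig = noddida_signal(scheme_sde, params_set_a)
        with pytest.raises(ValueError):
            add_rician_noise(sig, snr=0.0, seed=0)
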