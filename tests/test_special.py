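"""Cross products, eigenfunctions, Lommel functions and classical polynomials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shellmodes import special as sp
from shellmodes.special import (
    LommelPoleError,
    bessel_cross,
    boundary_value_outer,
    classical_polynomial,
    gegenbauer_A,
    lommel_S,
    lommel_S_deriv,
    lommel_s_small,
    neumann_O,
    radial_eigenfunction,
    schlafli_S,
)


class TestCrossProduct:
    def test_cyl_even_in_lambda(self):
        assert bessel_cross("cyl", 2, 5.0, 3.0) == pytest.approx(
            bessel_cross("cyl", 2, 5.0, -3.0), rel=1e-13
        )

    def test_sph_odd_in_lambda(self):
        assert bessel_cross("sph", 2, 5.0, 3.0) == pytest.approx(
            -bessel_cross("sph", 2, 5.0, -3.0), rel=1e-13
        )

    def test_cyl_even_in_order(self):
        for lam in (0.7, 2.3, 6.1):
            assert bessel_cross("cyl", 1.3, 5.0, lam) == pytest.approx(
                bessel_cross("cyl", -1.3, 5.0, lam), rel=1e-12
            )

    def test_sph_order_symmetry_about_minus_half(self):
        # g at nu - 1/2 equals g at -nu - 1/2
        for lam in (0.9, 2.2):
            assert bessel_cross("sph", 1.3 - 0.5, 5.0, lam) == pytest.approx(
                bessel_cross("sph", -1.3 - 0.5, 5.0, lam), rel=1e-12
            )

    def test_conjugation_symmetry_complex_order(self, rng):
        nu = 2 + 1j
        for _ in range(20):
            lam = complex(rng.uniform(0.5, 6.0), rng.uniform(-1.0, 1.0))
            lhs = bessel_cross("cyl", np.conj(nu), 5.0, np.conj(lam))
            rhs = np.conj(bessel_cross("cyl", nu, 5.0, lam))
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_first_root_bracketed_by_dense_sign_scan(self):
        lam = np.arange(0.1, 2.0, 1e-3)
        vals = bessel_cross("cyl", 2, 5.0, lam)
        flips = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        assert flips.size >= 1
        lo, hi = lam[flips[0]], lam[flips[0] + 1]
        assert lo < 0.6069449 < hi

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bessel_cross("cyl", 2, 0.5, 1.0)
        with pytest.raises(ValueError):
            bessel_cross("sph", 2, 5.0, 0.0)

    def test_real_for_real_inputs(self):
        assert np.isrealobj(bessel_cross("cyl", 2.5, 5.0, np.array([1.0, 2.0])))


class TestEigenfunctions:
    def test_inner_boundary_wronskian_value(self, cyl_modes10, sph_modes10):
        # Abel's identity pins the value at rho=1: 2/(pi lam) resp. 1/lam^2
        for e in cyl_modes10.entries[:3]:
            assert radial_eigenfunction("cyl", 2, e.lam, 1.0) == pytest.approx(
                2.0 / (math.pi * e.lam), rel=1e-12
            )
        for e in sph_modes10.entries[:3]:
            assert radial_eigenfunction("sph", 2, e.lam, 1.0) == pytest.approx(
                1.0 / e.lam**2, rel=1e-12
            )

    def test_neumann_condition_at_inner_wall(self, cyl_modes10):
        lam = cyl_modes10.lams[0]
        h = 1e-6
        d = (radial_eigenfunction("cyl", 2, lam, 1.0 + h)
             - radial_eigenfunction("cyl", 2, lam, 1.0 + 1e-12)) / h
        val = radial_eigenfunction("cyl", 2, lam, 1.0)
        assert abs(d) < 1e-4 * abs(val)  # one-sided difference, O(h) * curvature

    @pytest.mark.parametrize("dim", ["cyl", "sph"])
    def test_outer_boundary_value_matches_direct_evaluation(self, dim, cyl_modes10,
                                                            sph_modes10):
        table = cyl_modes10 if dim == "cyl" else sph_modes10
        lam = table.lams[0]
        bv = boundary_value_outer(dim, 2, lam, 5.0)
        direct = radial_eigenfunction(dim, 2, lam, 5.0)
        assert bv == pytest.approx(direct, rel=1e-10)

    def test_outer_boundary_degenerate_shell(self):
        assert boundary_value_outer("cyl", 2, 1.7, 1.0) == pytest.approx(
            2.0 / (math.pi * 1.7)
        )

    def test_outer_boundary_rejects_non_zero(self):
        with pytest.raises(ValueError, match="disagree"):
            boundary_value_outer("cyl", 2, 1.0, 5.0)  # 1.0 is not a zero


class TestSphericalCylindricalBridge:
    def test_function_and_derivative_relations(self, rng):
        # Psi_{mu+1/2}(z) = sqrt(2z/pi) psi_mu(z) and the derivative analogue
        A, B, mu = 0.3, 0.7, 2
        for _ in range(5):
            z = rng.uniform(0.3, 8.0)
            Psi = A * sp.cyl_bessel("j", mu + 0.5, z) + B * sp.cyl_bessel("y", mu + 0.5, z)
            psi = A * sp.sph_bessel("j", mu, z) + B * sp.sph_bessel("y", mu, z)
            assert Psi == pytest.approx(math.sqrt(2 * z / math.pi) * psi, rel=1e-12)
            dPsi = A * sp.cyl_bessel_deriv("j", mu + 0.5, z) + B * sp.cyl_bessel_deriv("y", mu + 0.5, z)
            dpsi = A * sp.sph_bessel_deriv("j", mu, z) + B * sp.sph_bessel_deriv("y", mu, z)
            assert dPsi == pytest.approx(
                (psi + 2 * z * dpsi) / math.sqrt(2 * math.pi * z), rel=1e-12
            )


class TestLommelFirstKind:
    def test_small_argument_leading_factor(self):
        kappa, nu = 1.2, 0.4
        z = 1e-4
        lead = lommel_s_small(kappa, nu, z) / z ** (kappa + 1)
        assert lead == pytest.approx(1.0 / ((kappa + 1) ** 2 - nu**2), rel=1e-7)

    def test_even_in_order(self):
        assert lommel_s_small(1.2, 0.7, 2.0) == pytest.approx(
            lommel_s_small(1.2, -0.7, 2.0), rel=1e-14
        )

    def test_against_brute_force_series(self):
        # 500-term partial sum of 1F2 computed independently
        kappa, nu, z = 1, 0, 2.0
        a, b = (kappa - nu + 3) / 2, (kappa + nu + 3) / 2
        w = -z**2 / 4
        total, term = 1.0, 1.0
        for k in range(1, 500):
            term *= w / ((a + k - 1) * (b + k - 1))
            total += term
        expected = z ** (kappa + 1) / ((kappa + 1) ** 2 - nu**2) * total
        assert lommel_s_small(kappa, nu, z) == pytest.approx(expected, rel=1e-14)

    def test_pole_error(self):
        with pytest.raises(LommelPoleError):
            lommel_s_small(1.0, 2.0, 1.0)  # (kappa+1)^2 == nu^2


class TestLommelSecondKind:
    @pytest.mark.parametrize("z", [0.5, 2.5, 7.0])
    def test_S_1_0_is_constant_one(self, z):
        assert lommel_S(1, 0, z, route="series") == pytest.approx(1.0, abs=1e-12)

    def test_printed_power_law_cases(self):
        for z in (0.8, 2.0, 5.5):
            assert lommel_S(-1, 2, z) == pytest.approx(1.0 / z**2, rel=1e-12)
            assert lommel_S(-2.5, 3.5, z) == pytest.approx(z**-3.5, rel=1e-12)
            assert lommel_S(-1.5, 2.5, z) == pytest.approx(z**-2.5, rel=1e-12)

    def test_kappa_recurrence_identity(self):
        kappa, nu, z = 0.3, 1.7, 2.4
        lhs = lommel_S(kappa + 2, nu, z)
        rhs = z ** (kappa + 1) - ((kappa + 1) ** 2 - nu**2) * lommel_S(kappa, nu, z)
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_closed_form_matches_recurrence_shifted_series(self):
        # S_{-1,2} is reachable by one kappa-shift into a pole-free series;
        # S_{0,1} and S_{1,2} sit on the (kappa+1)^2 = nu^2 manifold and are
        # covered by the ODE check below instead
        for z in (1.3, 3.1):
            closed = lommel_S(-1, 2, z, route="closed_form")
            shifted = sp._lommel_S_recur(-1, 2, z)
            assert closed == pytest.approx(shifted, rel=1e-10)

    @pytest.mark.parametrize("kappa,nu", [(1, 2), (-1, 2), (0, 1), (1, 0)])
    def test_closed_forms_satisfy_inhomogeneous_bessel_ode(self, kappa, nu):
        # z^2 S'' + z S' + (z^2 - nu^2) S = z^(kappa+1), central differences
        z, h = 2.7, 1e-5
        f = lambda x: complex(lommel_S(kappa, nu, x)).real
        d1 = (f(z + h) - f(z - h)) / (2 * h)
        d2 = (f(z + h) - 2 * f(z) + f(z - h)) / h**2
        lhs = z**2 * d2 + z * d1 + (z**2 - nu**2) * f(z)
        assert lhs == pytest.approx(z ** (kappa + 1), rel=1e-5)

    def test_derivative_recurrence_vs_finite_difference(self):
        kappa, nu, z, h = 0.3, 1.7, 2.4, 1e-6
        fd = (complex(lommel_S(kappa, nu, z + h)) - complex(lommel_S(kappa, nu, z - h))) / (2 * h)
        assert complex(lommel_S_deriv(kappa, nu, z)) == pytest.approx(fd, rel=1e-8)

    def test_exceptional_pair_errors(self):
        with pytest.raises(LommelPoleError):
            lommel_S(-1, 0, 2.0)

    @pytest.mark.parametrize("kappa,nu", [(-2.5, 3.5), (-1.5, 2.5), (0.5, 2.5)])
    def test_series_agrees_with_closed_form_where_both_defined(self, kappa, nu):
        # odd kappa+nu (Gegenbauer closed form) with a pole-free 1F2 series
        for z in (0.9, 3.3):
            assert complex(lommel_S(kappa, nu, z, route="series")) == pytest.approx(
                complex(lommel_S(kappa, nu, z, route="closed_form")), rel=1e-10
            )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        kappa=st.floats(-0.8, 2.0),
        nu=st.floats(0.1, 1.9),
        z=st.floats(0.5, 8.0),
    )
    def test_recurrence_identity_property(self, kappa, nu, z):
        denom = (kappa + 1) ** 2 - nu**2
        if abs(denom) < 0.05:  # stay clear of the exceptional manifold
            return
        lhs = complex(lommel_S(kappa + 2, nu, z, route="series"))
        rhs = z ** (kappa + 1) - denom * complex(lommel_S(kappa, nu, z, route="series"))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestClassicalPolynomials:
    def test_printed_neumann_polynomials(self):
        z = 2.3
        assert neumann_O(0, z) == pytest.approx(1.0 / z)
        assert neumann_O(1, z) == pytest.approx(1.0 / z**2)
        assert neumann_O(2, z) == pytest.approx(1.0 / z + 4.0 / z**3)

    def test_printed_schlafli_polynomials(self):
        z = 2.3
        assert schlafli_S(0, z) == 0
        assert schlafli_S(1, z) == pytest.approx(2.0 / z)
        assert schlafli_S(2, z) == pytest.approx(4.0 / z**2)

    def test_dispatch(self):
        assert classical_polynomial("neumann_O", 0, 1.7) == pytest.approx(1 / 1.7)
        assert classical_polynomial("schlafli_S", 1, 1.7) == pytest.approx(2 / 1.7)
        with pytest.raises(ValueError):
            classical_polynomial("bogus", 1, 1.0)

    def test_neumann_polynomial_links_to_lommel(self):
        # S_{1,2m}(z) = z O_{2m}(z) at m=1
        z = 3.1
        assert lommel_S(1, 2, z) == pytest.approx(z * neumann_O(2, z), rel=1e-13)

    def test_gegenbauer_low_orders(self):
        nu, z = 1.4, 1.7
        assert gegenbauer_A(0, nu, z) == pytest.approx(
            math.gamma(nu + 1) * 2**nu / z, rel=1e-13
        )
        assert gegenbauer_A(1, nu, z) == pytest.approx(
            math.gamma(nu + 2) * 2 ** (nu + 1) / z**2, rel=1e-13
        )

    def test_gegenbauer_index_shift_relation(self):
        # A_{2p, 1-g}(z) = z A_{2p+1, -g}(z) at p=1, g=0.4
        p, g, z = 1, 0.4, 1.7
        assert gegenbauer_A(2 * p, 1 - g, z) == pytest.approx(
            z * gegenbauer_A(2 * p + 1, -g, z), rel=1e-12
        )
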