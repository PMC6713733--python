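import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taudecor import (
    EquilibriumCoverages,
    ModelParams,
    dilute_coverage,
    gap_model,
    insertion_probability,
    insertion_probability_general,
    portrait,
    saturation_line,
    solve_equilibrium,
)
from taudecor.model_core import _portrait_residual


def cov(rho_p, rho_h, params):
    return EquilibriumCoverages.from_rhos(rho_p, rho_h, params)


class TestInsertionProbability:
    def test_empty_lattice_is_one(self, sigma1_params):
        assert insertion_probability(cov(0, 0, sigma1_params), sigma1_params, "p") == 1.0
        assert insertion_probability(cov(0, 0, sigma1_params), sigma1_params, "h") == 1.0

    def test_zero_on_saturation_line(self, sigma1_params):
        c = cov(0.2, 0.3, sigma1_params)  # 1 - 2*0.2 - 2*0.3 = 0
        assert insertion_probability(c, sigma1_params, "p") == 0.0
        assert insertion_probability(c, sigma1_params, "h") == 0.0

    def test_direct_arithmetic(self, sigma1_params):
        # A = 0.5, (1 - rho_p)= 0.75 -> 0.25/0.75 = 1/3
        c = cov(0.25, 0.0, sigma1_params)
        assert insertion_probability(c, sigma1_params, "p") == pytest.approx(1 / 3)

    def test_point_particle_convention(self):
        # sigma = 0: Phi reduces to the availability itself
        p = ModelParams(sigma_p=0, sigma_h=0, k_eq_p=1, k_eq_h=1, x=1)
        assert insertion_probability(cov(0.3, 0.2, p), p, "p") == pytest.approx(0.5)

    def test_domain_error_names_constraint(self, sigma1_params):
        with pytest.raises(ValueError, match="saturation"):
            insertion_probability(_force(0.3, 0.3, sigma1_params), sigma1_params, "p")

    def test_monotone_decreasing_on_grid(self, sigma1_params):
        # Phi_i decreases in each coverage throughout the triangle
        grid = np.linspace(0.0, 0.49, 25)
        for mode in ("p", "h"):
            for rho_h in grid:
                vals = [
                    insertion_probability(cov(rp, rho_h, sigma1_params), sigma1_params, mode)
                    for rp in grid
                    if 1 - 2 * rp - 2 * rho_h > 0
                ]
                assert np.all(np.diff(vals) <= 1e-12)


def _force(rho_p, rho_h, params):
    """Coverages outside the triangle, bypassing the container validation."""
    c = EquilibriumCoverages.from_rhos(0.0, 0.0, params)
    object.__setattr__(c, "rho_p", rho_p)
    object.__setattr__(c, "rho_h", rho_h)
    return c


class TestGapModel:
    def test_direct_arithmetic(self, sigma1_params):
        gm = gap_model(cov(0.25, 0.0, sigma1_params), sigma1_params, "parallel")
        assert gm.u == pytest.approx(0.5 / 0.75)
        assert not gm.empty_lattice

    def test_geometric_normalization(self, sigma1_params):
        gm = gap_model(cov(0.1, 0.15, sigma1_params), sigma1_params, "perp")
        g = np.arange(2000)
        assert gm.pmf(g).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_lattice_flagged(self, sigma1_params):
        gm = gap_model(cov(0.0, 0.0, sigma1_params), sigma1_params, "parallel")
        assert gm.empty_lattice
        with pytest.raises(ValueError, match="empty lattice"):
            gm.pmf(3)

    def test_saturation_collapses_to_zero_gaps(self, sigma1_params):
        gm = gap_model(cov(0.5, 0.0, sigma1_params), sigma1_params, "parallel")
        assert gm.u == 0.0
        assert gm.pmf(0) == pytest.approx(1.0)


class TestFiniteLatticeInsertion:
    def test_converges_to_closed_form(self, sigma1_params):
        c = cov(0.1, 0.1, sigma1_params)
        closed = insertion_probability(c, sigma1_params, "p")
        general = insertion_probability_general(c, sigma1_params, "p", 10**6)
        assert abs(general - closed) < 1e-4

    def test_empty_finite_lattice_single_gap(self, sigma1_params):
        # one gap of size ell: Phi = (1/ell)(ell - sigma) -> 1 as ell grows
        c = cov(0.0, 0.0, sigma1_params)
        for ell in (10, 100, 10_000):
            f = np.zeros(ell + 1)
            f[ell] = 1.0
            phi = insertion_probability_general(c, sigma1_params, "p", ell, gap_pmf=f)
            assert phi == pytest.approx((ell - 1) / ell)

    def test_gaps_too_small_give_zero(self, sigma1_params):
        c = cov(0.2, 0.0, sigma1_params)
        f = np.zeros(2)
        f[1] = 1.0  # all gaps of size 1 < 1 + sigma_p
        assert insertion_probability_general(c, sigma1_params, "p", 100, gap_pmf=f) == 0.0

    def test_rejects_unnormalized_pmf(self, sigma1_params):
        c = cov(0.1, 0.0, sigma1_params)
        with pytest.raises(ValueError, match="normalized"):
            insertion_probability_general(c, sigma1_params, "p", 100, gap_pmf=[0.5, 0.2])

    @pytest.mark.parametrize("sigma_p,sigma_h", [(1, 1), (2, 0), (0, 2), (3, 1)])
    def test_geometric_gap_model_reproduces_closed_form(self, sigma_p, sigma_h):
        # infinite-lattice gap sum == closed form, to near machine precision,
        # across a 20x20 coverage grid and both modes
        params = ModelParams(sigma_p=sigma_p, sigma_h=sigma_h, k_eq_p=1, k_eq_h=1, x=1)
        sat_p, sat_h = 1 / (1 + sigma_p), 1 / (1 + sigma_h)
        for rp in np.linspace(0, sat_p, 20, endpoint=False):
            for rh in np.linspace(0, sat_h, 20, endpoint=False):
                if 1 - (1 + sigma_p) * rp - (1 + sigma_h) * rh <= 1e-6:
                    continue
                if rp == 0 and rh == 0:
                    continue
                c = cov(rp, rh, params)
                for mode in ("p", "h"):
                    closed = insertion_probability(c, params, mode)
                    general = insertion_probability_general(c, params, mode, np.inf)
                    assert abs(general - closed) < 1e-12


class TestSolveEquilibrium:
    def test_single_mode_low_and_high_coverage(self):
        # the two reference configurations of the sigma=1, k_eq=3 isotherm
        lo = solve_equilibrium(ModelParams(k_eq_p=3, k_eq_h=0, x=0.15))
        assert lo.rho == pytest.approx(0.10, abs=0.01)
        hi = solve_equilibrium(ModelParams(k_eq_p=3, k_eq_h=0, x=10))
        assert hi.rho == pytest.approx(0.45, abs=0.01)

    def test_equal_constants_give_equal_coverages(self):
        c = solve_equilibrium(ModelParams(k_eq_p=1.5, k_eq_h=1.5, x=3.0))
        assert c.rho_p == pytest.approx(c.rho_h, abs=1e-14)

    def test_kappa2_saturation_limit(self):
        # large x drives the kappa=2 system to the saturation intersection
        c = solve_equilibrium(ModelParams(k_eq_p=2e4, k_eq_h=1e4, x=1e4))
        assert c.rho_p == pytest.approx((np.sqrt(3) - 1) / 2, abs=2e-3)
        assert c.rho_h == pytest.approx((2 - np.sqrt(3)) / 2, abs=2e-3)

    def test_monotone_in_x_and_k(self):
        rhos = [
            solve_equilibrium(ModelParams(k_eq_p=2, k_eq_h=1, x=x)).rho
            for x in np.geomspace(0.01, 50, 12)
        ]
        assert np.all(np.diff(rhos) > 0)
        rhos_k = [
            solve_equilibrium(ModelParams(k_eq_p=2 * k, k_eq_h=k, x=1.0)).rho
            for k in np.geomspace(0.01, 100, 12)
        ]
        assert np.all(np.diff(rhos_k) > 0)

    def test_single_mode_limit_of_two_mode_solver(self):
        pinned = solve_equilibrium(ModelParams(k_eq_p=3, k_eq_h=0, x=0.5))
        assert pinned.rho_h == 0.0
        nearly = solve_equilibrium(ModelParams(k_eq_p=3, k_eq_h=1e-11, x=0.5))
        assert nearly.rho_p == pytest.approx(pinned.rho_p, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.01, 50.0),
        keff=st.floats(0.01, 1e3),
        frac=st.floats(0.05, 0.95),
        sigma_p=st.integers(0, 3),
        sigma_h=st.integers(0, 3),
    )
    def test_solution_is_physical(self, x, keff, frac, sigma_p, sigma_h):
        params = ModelParams(
            sigma_p=sigma_p, sigma_h=sigma_h,
            k_eq_p=keff * frac, k_eq_h=keff * (1 - frac), x=x,
        )
        c = solve_equilibrium(params)
        assert c.rho_p >= 0 and c.rho_h >= 0
        assert c.availability >= -1e-12
        assert params.x - c.rho >= 0  # mass balance: free Tau never negative
        assert c.residual < 1e-10


class TestDiluteCoverage:
    def test_vanishes_with_x(self):
        p = ModelParams(k_eq_p=3, k_eq_h=0, x=1e-12)
        assert dilute_coverage(p, "p") == pytest.approx(0.0, abs=1e-10)

    def test_strong_binding_limit(self):
        # k_eq -> inf: rho -> min(x, 1/(1+2 sigma))
        p = ModelParams(k_eq_p=1e14, k_eq_h=0, x=0.05)
        assert dilute_coverage(p, "p") == pytest.approx(0.05, rel=1e-5)
        p2 = ModelParams(sigma_p=2, k_eq_p=1e14, k_eq_h=0, x=10)
        assert dilute_coverage(p2, "p") == pytest.approx(1 / 5, rel=1e-5)

    def test_matches_full_solver_when_dilute(self):
        p = ModelParams(k_eq_p=3, k_eq_h=0, x=0.01)
        full = solve_equilibrium(p).rho
        assert dilute_coverage(p, "p") == pytest.approx(full, rel=0.01)


class TestPortrait:
    def test_kappa_one_equal_sizes_is_diagonal(self):
        pts = portrait(ModelParams(k_eq_p=1, k_eq_h=1, x=1), n_points=40)
        assert np.allclose(pts[:, 0], pts[:, 1], atol=1e-9)

    def test_unequal_sizes_end_at_high_stoichiometry_corner(self):
        p = ModelParams(sigma_p=2, sigma_h=0, k_eq_p=1, k_eq_h=1, x=1)
        pts = portrait(p, n_points=60)
        assert pts[-1] == pytest.approx([0.0, 1.0], abs=1e-9)
        # the curve is bi-valued in rho_p: it must turn back toward rho_p = 0
        assert pts[:, 0].max() > 0.02

    def test_kappa2_endpoint(self):
        pts = portrait(ModelParams(k_eq_p=2, k_eq_h=1, x=1), n_points=30)
        assert pts[-1, 0] == pytest.approx((np.sqrt(3) - 1) / 2, abs=1e-10)
        assert pts[-1, 1] == pytest.approx((2 - np.sqrt(3)) / 2, abs=1e-10)

    def test_interior_points_satisfy_relation(self):
        for kappa in (0.3, 2.0, 7.0):
            p = ModelParams(k_eq_p=kappa, k_eq_h=1.0, x=1)
            pts = portrait(p, n_points=50)
            for rp, rh in pts[1:-1]:
                assert abs(_portrait_residual(rp, rh, 1, 1, kappa)) < 1e-10

    def test_mirror_symmetry_between_kappa_and_inverse(self):
        # rho_h(rho_p; kappa) = rho_p(rho_h; 1/kappa) for equal sizes:
        # swapped points of the kappa portrait lie on the 1/kappa portrait
        kappa = 2.5
        pts = portrait(ModelParams(k_eq_p=kappa, k_eq_h=1, x=1), n_points=40)
        for rp, rh in pts[1:-1]:
            assert abs(_portrait_residual(rh, rp, 1, 1, 1 / kappa)) < 1e-10

    def test_degenerate_kappa_returns_axis(self):
        on_axis = portrait(ModelParams(k_eq_p=1, k_eq_h=0, x=1), n_points=5)
        assert np.all(on_axis[:, 1] == 0) and on_axis[-1, 0] == 0.5
        other = portrait(ModelParams(k_eq_p=0, k_eq_h=1, x=1), n_points=5)
        assert np.all(other[:, 0] == 0) and other[-1, 1] == 0.5

    def test_two_points_gives_endpoints_only(self):
        pts = portrait(ModelParams(k_eq_p=2, k_eq_h=1, x=1), n_points=2)
        assert pts.shape == (2, 2)
        assert pts[0] == pytest.approx([0.0, 0.0])


class TestSaturationLine:
    def test_equal_sizes(self, sigma1_params):
        line = saturation_line(sigma1_params)
        assert line(0.0) == pytest.approx(0.5)
        assert line(0.5) == pytest.approx(0.0)
        assert line(0.25) == pytest.approx(0.25)

    def test_point_degenerate_case(self):
        # sigma_p=2, sigma_h=0: the saturation locus hits rho_h = 1 at rho_p = 0
        p = ModelParams(sigma_p=2, sigma_h=0, k_eq_p=1, k_eq_h=1, x=1)
        assert saturation_line(p)(0.0) == pytest.approx(1.0)
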