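"""Oxygen diffusion-consumption model: closed-form oracle, invariants."""

import numpy as np
import pytest
import sympy
from shapely.geometry import Point, box

from capdomain import (
    CapillaryMap,
    OxygenParams,
    ValidationError,
    hypoxic_fraction,
    krogh_erlang_reference,
    solve_domain,
    solve_frame,
    tessellate,
)
from capdomain.oxygen import EXERCISE_PARAMS, params_for_mode

EX_ZERO_ORDER = OxygenParams(M0=1.5e-3, P50=1e-3, mode="exercise")


def disc_grid_radii(domain, h, grid):
    ny, nx = grid.shape
    minx, miny = domain.bounds[0], domain.bounds[1]
    xc = minx + (np.arange(nx) + 0.5) * h
    yc = miny + (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xc, yc)
    return np.hypot(XX, YY)


class TestKroghErlangReference:
    def test_boundary_condition_at_capillary_wall(self):
        p = EXERCISE_PARAMS
        assert krogh_erlang_reference(p.r_cap, 17.6, p) == pytest.approx(p.P_cap)

    def test_no_flux_at_outer_radius_symbolically(self):
        r, rc, R, M0, D, a, Pc = sympy.symbols(
            "r r_c R M_0 D alpha P_c", positive=True
        )
        P = Pc + (M0 / (2 * D * a)) * ((r**2 - rc**2) / 2 - R**2 * sympy.log(r / rc))
        assert sympy.simplify(sympy.diff(P, r).subs(r, R)) == 0

    def test_rim_value_matches_ode_quadrature_oracle(self):
        """P(R) from the formula agrees with an independent BVP solve."""
        from scipy.integrate import solve_bvp

        p = OxygenParams(M0=1.5e-3, mode="exercise")
        R = 17.6
        formula = krogh_erlang_reference(R, R, p)
        assert formula == pytest.approx(36.3627, abs=1e-3)  # frozen oracle value

        def rhs(r, y):
            return np.vstack([y[1], p.M0 / (p.D * p.alpha) - y[1] / r])

        def bc(ya, yb):
            return np.array([ya[0] - p.P_cap, yb[1]])

        mesh = np.linspace(p.r_cap, R, 100)
        sol = solve_bvp(
            rhs, bc, mesh,
            np.vstack([np.full_like(mesh, p.P_cap), np.zeros_like(mesh)]),
            tol=1e-10,
        )
        assert sol.status == 0 or sol.status == 1
        assert formula == pytest.approx(sol.y[0][-1], rel=1e-6)

    def test_anoxic_parameters_flagged(self):
        p = OxygenParams(M0=1.5e-2, mode="exercise")
        with pytest.raises(ValidationError, match="anoxic"):
            krogh_erlang_reference(100.0, 100.0, p)


class TestSolveDomain:
    def test_zero_consumption_gives_uniform_pcap(self):
        p = OxygenParams(M0=0.0)
        dom = box(0, 0, 30, 30)
        grid = solve_domain(dom, np.array([15.0, 15.0]), p, h=1.0)
        vals = grid[np.isfinite(grid)]
        np.testing.assert_allclose(vals, p.P_cap, atol=1e-8)

    def test_disc_matches_krogh_erlang_within_2pct(self):
        R = 17.6
        disc = Point(0, 0).buffer(R, quad_segs=256)
        grid = solve_domain(disc, np.array([0.0, 0.0]), EX_ZERO_ORDER, h=0.5)
        rr = disc_grid_radii(disc, 0.5, grid)
        mask = np.isfinite(grid) & (rr >= EX_ZERO_ORDER.r_cap) & (rr <= R - 0.5)
        ref = krogh_erlang_reference(rr[mask], R, EX_ZERO_ORDER)
        assert np.max(np.abs(grid[mask] - ref) / ref) < 0.02

    def test_doubling_m0_strictly_lowers_mean_po2(self):
        dom = Point(0, 0).buffer(15.0, quad_segs=64)
        means = []
        for m0 in (5e-4, 1e-3):
            p = OxygenParams(M0=m0)
            g = solve_domain(dom, np.array([0.0, 0.0]), p, h=1.0)
            means.append(np.nanmean(g))
        assert means[1] < means[0]

    def test_maximum_principle(self):
        dom = Point(2, -3).buffer(14.0, quad_segs=64)
        p = EXERCISE_PARAMS
        g = solve_domain(dom, np.array([2.0, -3.0]), p, h=1.0)
        vals = g[np.isfinite(g)]
        assert vals.max() <= p.P_cap + 1e-9
        assert vals.min() >= 0.0

    def test_capillary_outside_domain_rejected(self):
        with pytest.raises(ValidationError):
            solve_domain(box(0, 0, 10, 10), np.array([50.0, 50.0]),
                         OxygenParams(), h=1.0)

    def test_h_larger_than_rcap_rejected(self):
        with pytest.raises(ValidationError):
            solve_domain(box(0, 0, 10, 10), np.array([5.0, 5.0]),
                         OxygenParams(r_cap=2.5), h=3.0)


class TestSolveFrame:
    @pytest.fixture(scope="class")
    def small_map(self):
        rng = np.random.default_rng(5)
        return CapillaryMap(120, 120, rng.uniform(5, 115, size=(12, 2)))

    def test_symmetric_domains_get_identical_subfields(self):
        m = CapillaryMap(100, 200, np.array([[50.0, 50.0], [50.0, 150.0]]))
        field = solve_frame(tessellate(m), m, EXERCISE_PARAMS, h=1.0)
        top = field.grid[100:, :]
        bottom = field.grid[:100, :]
        # permuted sparse factorisations agree to rounding, not bitwise
        np.testing.assert_allclose(bottom, top[::-1, :], rtol=0, atol=1e-9)

    def test_denser_map_has_higher_mean_po2(self):
        rng = np.random.default_rng(11)
        sparse_pts = rng.uniform(5, 145, size=(8, 2))
        dense_pts = np.vstack([sparse_pts, rng.uniform(5, 145, size=(16, 2))])
        p = EXERCISE_PARAMS
        f_sparse = solve_frame(
            tessellate(CapillaryMap(150, 150, sparse_pts)),
            CapillaryMap(150, 150, sparse_pts), p, h=1.5,
        )
        m_dense = CapillaryMap(150, 150, dense_pts)
        f_dense = solve_frame(tessellate(m_dense), m_dense, p, h=1.5)
        assert f_dense.mean_PO2 > f_sparse.mean_PO2

    def test_mean_po2_increases_with_pcap(self, small_map):
        tess = tessellate(small_map)
        lo = solve_frame(tess, small_map, params_for_mode("exercise", P_cap=30.0), h=1.5)
        hi = solve_frame(tess, small_map, params_for_mode("exercise", P_cap=40.0), h=1.5)
        assert hi.mean_PO2 > lo.mean_PO2

    def test_hypoxic_fraction_threshold_zero_is_zero(self, small_map):
        tess = tessellate(small_map)
        field = solve_frame(tess, small_map, params_for_mode("rest"), h=1.5)
        assert hypoxic_fraction(field, threshold=0.0) == 0.0

    def test_hypoxic_fraction_extremes(self, small_map):
        tess = tessellate(small_map)
        field = solve_frame(tess, small_map, params_for_mode("rest"), h=1.5)
        assert hypoxic_fraction(field, threshold=1000.0) == 100.0
        # constructed half/half field
        field.grid[field.tissue_mask] = 10.0
        idx = np.flatnonzero(field.tissue_mask.ravel())
        half = idx[: idx.size // 2]
        field.grid.ravel()[half] = 0.5
        expected = 100.0 * half.size / idx.size
        assert hypoxic_fraction(field, threshold=1.0) == pytest.approx(expected)

    def test_summary_bounds(self, small_map):
        tess = tessellate(small_map)
        field = solve_frame(tess, small_map, EXERCISE_PARAMS, h=1.5)
        assert 0.0 <= field.min_PO2 <= field.mean_PO2 <= EXERCISE_PARAMS.P_cap


class TestParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            OxygenParams(D=-1.0)
        with pytest.raises(ValidationError):
            OxygenParams(P_cap=0.5, hypoxia_threshold=1.0)
        with pytest.raises(ValidationError):
            params_for_mode("sprint")
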