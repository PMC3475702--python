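import numpy as np
import pytest
import sympy as sp

from budkit import (
    DimensionlessParams,
    MembraneParams,
    bud_radius,
    budding_pathway,
    cap_energy,
    cap_energy_by_quadrature,
    corner_energies,
    coupling_window,
    edge_path_barrier,
    global_minimum,
    hessian_sign_scan,
    minimum_morphology,
    phase_diagram,
)


def random_dp(rng, p_g_range=(-3.0, 3.0)):
    return DimensionlessParams(
        p_sigma=float(rng.uniform(0.2, 12.0)),
        p_w=float(rng.uniform(0.0, 45.0)),
        p_g=float(rng.uniform(*p_g_range)),
        length_scale=1.0,
    )


class TestCapEnergy:
    def test_flat_limit_both_cases(self, rng):
        """At x = 0 the bud vanishes: only line tension and binding remain."""
        for _ in range(5):
            dp = random_dp(rng)
            for phi in (0.0, 0.4, 1.0):
                expected = 2 * np.pi * dp.p_sigma - dp.p_w * phi
                assert cap_energy(0.0, phi, dp, "I") == pytest.approx(expected)
                assert cap_energy(0.0, phi, dp, "II") == pytest.approx(expected)

    def test_bending_only_is_8pi_x(self):
        dp = DimensionlessParams(0.0, 0.0, 0.0, 1.0)
        for x in (0.1, 0.5, 0.9):
            assert cap_energy(x, 0.5, dp, "I") == pytest.approx(8 * np.pi * x)

    def test_cases_coincide_on_phi_zero_edge(self, rng):
        for _ in range(5):
            dp = random_dp(rng)
            for x in (0.2, 0.6, 1.0):
                assert cap_energy(x, 0.0, dp, "I") == pytest.approx(
                    cap_energy(x, 0.0, dp, "II"), rel=1e-12)

    def test_out_of_square_rejected(self, unit_dp):
        with pytest.raises(ValueError):
            cap_energy(1.2, 0.5, unit_dp)

    def test_matches_functional_quadrature(self, rng):
        """Central oracle: closed-form cap energies equal direct quadrature
        of the shape functional on the exact cap contours."""
        for _ in range(3):
            dp = random_dp(rng)
            for x in np.linspace(0, 1, 5):
                for phi in np.linspace(0, 1, 5):
                    for case in ("I", "II"):
                        closed = cap_energy(x, phi, dp, case)
                        quad = cap_energy_by_quadrature(x, phi, dp, case)
                        assert abs(closed - quad.e_total) < 1e-6


class TestCorners:
    def test_flat_corner_linear_in_binding(self, unit_dp):
        e = [corner_energies(DimensionlessParams(1.0, pw, 1.0, 1.0))["flat"].energy
             for pw in (0.0, 5.0, 10.0)]
        assert e[0] - e[1] == pytest.approx(5.0)
        assert e[1] - e[2] == pytest.approx(5.0)

    def test_flat_coated_crossing_unique(self):
        """With w = dkg = 0 the flat and coated corners cross at one sigma."""
        from scipy.optimize import brentq

        def diff(ps):
            c = corner_energies(DimensionlessParams(ps, 0.0, 0.0, 1.0))
            return c["flat"].energy - c["coated_bud"].energy

        root = brentq(diff, 0.1, 20.0)
        assert root == pytest.approx(4.0, rel=1e-10)
        assert diff(root - 1) * diff(root + 1) < 0

    def test_corners_match_cap_energy(self, rng):
        for _ in range(5):
            dp = random_dp(rng)
            for state in corner_energies(dp).values():
                assert state.energy == pytest.approx(
                    cap_energy(state.x, state.phi, dp, state.case_label),
                    rel=1e-12, abs=1e-12)


class TestHessian:
    def test_negative_determinant_everywhere(self, rng):
        for _ in range(20):
            dp = DimensionlessParams(
                float(rng.uniform(0.5, 12)), float(rng.uniform(0.5, 45)),
                float(rng.uniform(0.2, 3)), 1.0)
            for case in ("I", "II"):
                signs = hessian_sign_scan(dp, grid_n=21, case_label=case)
                assert np.all(signs < 0)

    def test_degenerate_case_flagged(self):
        """All couplings zero: E_I = 8*pi*x is Hessian-singular."""
        dp = DimensionlessParams(0.0, 0.0, 0.0, 1.0)
        signs = hessian_sign_scan(dp, grid_n=5, case_label="I")
        assert np.all(signs == 0)

    def test_matches_symbolic_determinant(self):
        """Finite differences agree with symbolic Hessian of Case I."""
        x, phi, ps, pw, pg = sp.symbols("x phi ps pw pg", positive=True)
        e1 = (8 * sp.pi * x - 4 * sp.pi * pg * x * (1 - phi)
              + 2 * sp.pi * ps * sp.sqrt(1 - x) - pw * phi)
        det = sp.hessian(e1, (x, phi)).det()
        dp = DimensionlessParams(3.0, 10.0, 1.5, 1.0)
        subs = {ps: 3.0, pw: 10.0, pg: 1.5}
        for xv, pv in [(0.3, 0.3), (0.5, 0.7), (0.8, 0.2), (0.25, 0.9),
                       (0.66, 0.5)]:
            sym = float(det.subs({x: xv, phi: pv, **subs}))
            e = lambda a, b: cap_energy(a, b, dp, "I")
            h = 1e-5
            exx = (e(xv + h, pv) - 2 * e(xv, pv) + e(xv - h, pv)) / h**2
            epp = (e(xv, pv + h) - 2 * e(xv, pv) + e(xv, pv - h)) / h**2
            exp_ = (e(xv + h, pv + h) - e(xv + h, pv - h)
                    - e(xv - h, pv + h) + e(xv - h, pv - h)) / (4 * h**2)
            assert exx * epp - exp_**2 == pytest.approx(sym, rel=1e-3)


class TestGlobalMinimum:
    def test_small_tension_flat(self):
        st = global_minimum(DimensionlessParams(0.5, 10.0, 1.0, 1.0))
        assert (st.x, st.phi) == (0.0, 1.0)

    def test_large_tension_large_binding_coated(self):
        assert minimum_morphology(
            DimensionlessParams(9.0, 40.0, 1.0, 1.0)) == "coated_bud"

    def test_large_tension_small_binding_coatless(self):
        st = global_minimum(DimensionlessParams(9.0, 4.0, 1.0, 1.0))
        assert (st.x, st.phi) == (1.0, 0.0)

    def test_corner_is_global_on_dense_grid(self, rng):
        """Minima sit on the corners for 50 random non-degenerate sets."""
        for _ in range(50):
            dp = DimensionlessParams(
                float(rng.uniform(0.5, 12)), float(rng.uniform(0.5, 45)),
                float(rng.uniform(0.2, 3)), 1.0)
            global_minimum(dp)  # raises if an interior point undercuts


class TestPhaseDiagram:
    def test_three_regions_at_midwindow_coupling(self):
        diag = phase_diagram(np.linspace(1, 11, 10), np.linspace(2, 26, 10),
                             p_g=1.0)
        labels = set(diag.labels.ravel())
        assert labels == {"flat", "coated_bud", "coatless_bud"}
        # flat occupies small sigma, coated large sigma + large w,
        # coatless large sigma + small w
        assert diag.labels[0, 0] == "flat" and diag.labels[0, -1] == "flat"
        assert diag.labels[-1, -1] == "coated_bud"
        assert diag.labels[-1, 0] == "coatless_bud"

    def test_coexistence_curves_match_closed_form(self):
        p_g = 1.0
        diag = phase_diagram(np.linspace(1, 11, 6), np.linspace(2, 26, 6),
                             p_g=p_g)
        # coated/coatless coexistence: p_w = 4*pi*p_g
        assert diag.coexistence_coated_coatless.size > 0
        assert np.allclose(diag.coexistence_coated_coatless[:, 1],
                           4 * np.pi * p_g, rtol=1e-10)
        # flat/bud coexistence above the triple point: p_sigma = 4
        cw = diag.coexistence_flat_bud
        assert cw.size > 0
        above = cw[cw[:, 1] > 4 * np.pi * p_g + 1e-9]
        assert above.size > 0
        assert np.allclose(above[:, 0], 4.0, rtol=1e-9)
        # below the triple point the flat/coatless line is sloped:
        # 2*pi*p_sigma - p_w = 8*pi - 4*pi*p_g
        below = cw[cw[:, 1] < 4 * np.pi * p_g - 1e-9]
        assert below.size > 0
        assert np.allclose(2 * np.pi * below[:, 0] - below[:, 1],
                           8 * np.pi - 4 * np.pi * p_g, rtol=1e-9)

    def test_spinodal_inside_budded_region(self):
        diag = phase_diagram(np.linspace(1, 11, 6), np.linspace(2, 26, 6),
                             p_g=1.0)
        assert diag.spinodal.size > 0
        ps_spin = diag.spinodal[0, 0]
        assert ps_spin == pytest.approx(8.0, abs=1e-6)
        assert np.all(ps_spin > diag.coexistence_flat_bud[:, 0])


class TestPathway:
    def make_params(self, dkg, w=0.005, kappa=10.0, sigma=2.0):
        return MembraneParams(kappa=kappa, delta_kappa_g=dkg, sigma=sigma,
                              w=w, area_omega=np.pi)

    def test_three_stage_above_spinodal_is_barrier_free(self):
        p = self.make_params(dkg=10.0)
        report = budding_pathway(p, domain_radius=1.2 * 8 * p.kappa / p.sigma)
        assert report.pathway == "three_stage"
        assert report.barrier == pytest.approx(0.0, abs=1e-9)
        assert report.stages == ("flat", "coated_bud", "neck_escrt_bud")

    def test_below_spinodal_has_barrier(self):
        p = self.make_params(dkg=10.0)
        report = budding_pathway(p, domain_radius=0.5 * 8 * p.kappa / p.sigma)
        assert report.pathway == "three_stage"
        assert report.barrier > 0

    def test_large_coupling_gives_mini_bud_without_coated_stage(self):
        p = self.make_params(dkg=25.0)  # above the 2*kappa window edge
        report = budding_pathway(p, domain_radius=5.0)
        assert report.pathway == "mini_bud"
        assert "coated_bud" not in report.stages
        assert report.barrier == pytest.approx(0.0, abs=1e-9)

    def test_small_coupling_gives_no_neck_route(self):
        p = self.make_params(dkg=0.001, w=1.0)
        report = budding_pathway(p, domain_radius=5.0)
        assert report.pathway == "none"

    def test_critical_radius_ratio_is_scale_free(self, rng):
        """R_spin / R_coex = 2 across kappa and sigma."""
        for _ in range(10):
            p = MembraneParams(
                kappa=float(rng.uniform(1, 50)), delta_kappa_g=1.0,
                sigma=float(rng.uniform(0.1, 10)), w=0.001, area_omega=1.0)
            report = budding_pathway(p, domain_radius=1.0)
            assert report.r_spin / report.r_coex == pytest.approx(2.0,
                                                                  rel=1e-12)
            assert report.r_spin > report.r_coex

    def test_window_bounds(self):
        lo, hi = coupling_window(kappa=10.0, w=0.5, area=4 * np.pi)
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(20.0)


class TestBudRadius:
    def test_inverse_in_sigma(self):
        assert bud_radius(10.0, 2.0) == pytest.approx(
            2 * bud_radius(10.0, 4.0))

    def test_linear_in_kappa(self):
        assert bud_radius(20.0, 1.0) == pytest.approx(2 * bud_radius(10.0, 1.0))

    def test_matches_spinodal_cap_minimum(self):
        """Minimizing the cap energy at the spinodal domain radius produces
        a complete bud whose radius equals the bud-radius law to < 1%."""
        kappa, sigma = 10.0, 2.0
        a_spin = 8 * kappa / sigma
        p = MembraneParams(kappa=kappa, delta_kappa_g=kappa, sigma=sigma,
                           w=1e-6, area_omega=np.pi * a_spin**2)
        st = global_minimum(p)
        assert st.x == pytest.approx(1.0)
        r_bud = np.sqrt(p.area_omega / (4 * np.pi))  # complete-bud radius
        assert r_bud == pytest.approx(bud_radius(kappa, sigma), rel=0.01)

    def test_rejects_nonpositive_tension(self):
        with pytest.raises(ValueError):
            bud_radius(10.0, 0.0)


def test_edge_path_barrier_nonnegative_and_vanishes_past_spinodal():
    assert edge_path_barrier(DimensionlessParams(9.0, 1.0, 1.0, 1.0)) == 0.0
    assert edge_path_barrier(DimensionlessParams(5.0, 1.0, 1.0, 1.0)) > 0.0
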