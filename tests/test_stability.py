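"""Fixed points, instability conditions, dispersion and bifurcations."""

import numpy as np
import pytest

import hesnotch as hn
from hesnotch import ode_grid, stability as st
from hesnotch.params import sample_perturbed_parameters
from hesnotch.reduction import compute_ab


class TestHomogeneousFixedPoint:
    def test_closed_form_without_repression(self):
        # b = 0, k = 1: x (a + x) = 1 has the root (-a + sqrt(a^2+4))/2
        for a in (0.05, 0.5, 2.0):
            x0 = st.homogeneous_fixed_point(a, 1e-300, 1, 4)
            assert x0 == pytest.approx((-a + np.sqrt(a * a + 4)) / 2, rel=1e-10)

    def test_residual_at_defaults(self, ab):
        a, b = ab
        x0 = st.homogeneous_fixed_point(a, b, 1, 4)
        fn = st._Funcs(a, b, 1, 4)
        assert abs(fn.phi(x0) - x0) < 1e-12
        assert 0 < x0 < 1

    def test_monotone_decreasing_in_a(self, ab):
        _, b = ab
        roots = [st.homogeneous_fixed_point(a, b, 1, 4) for a in np.geomspace(0.01, 5, 12)]
        assert np.all(np.diff(roots) < 0)

    def test_unique_root_from_perturbed_brackets(self, ab):
        # bisection from randomised initial brackets always lands on the
        # same root
        a, b = ab
        from scipy.optimize import brentq

        fn = st._Funcs(a, b, 1, 4)
        x_ref = st.homogeneous_fixed_point(a, b, 1, 4)
        rng = np.random.default_rng(1)
        for _ in range(100):
            lo = rng.uniform(0, x_ref * 0.99)
            hi = rng.uniform(x_ref * 1.01, 1.0)
            root = brentq(lambda x: fn.phi(x) - x, lo, hi, xtol=1e-13)
            assert root == pytest.approx(x_ref, abs=1e-10)


class TestTwoCellInstability:
    def test_stable_without_repression(self):
        # b -> 0 removes g', leaving -f' g which cannot cross -1 from above
        cond = st.instability_reduced_2cell(0.1, 1e-300, 1, 4)
        assert not cond.unstable

    def test_defaults_are_unstable(self, params, ab):
        assert st.instability_reduced_2cell(*ab, 1, 4).unstable
        assert st.instability_full_2cell(params).unstable

    def test_margin_sign_matches_jacobian_eigenvalues(self, ab):
        a, b = ab
        cond = st.instability_reduced_2cell(a, b, 1, 4)
        J = st.reduced_two_cell_jacobian(cond.x0, cond.x0, a, b, 1, 4)
        assert (np.max(np.real(np.linalg.eigvals(J))) > 0) == cond.unstable

    def test_reduced_and_full_margins_identical(self, params):
        # the reduction preserves the constant term of the characteristic
        # polynomial: both conditions evaluate to the same number
        for s in (1.0, 30.0, 200.0):
            ps = params.scale_alpha_N(s)
            a, b = compute_ab(ps)
            m_red = st.instability_reduced_2cell(a, b, ps.k, ps.h).value
            m_full = st.instability_full_2cell(ps).value
            assert m_full == pytest.approx(m_red, rel=1e-9)


class TestNonhomogeneousPair:
    def test_exists_iff_unstable(self, params):
        for s in (1.0, 40.0):
            ps = params.scale_alpha_N(s)
            a, b = compute_ab(ps)
            cond = st.instability_reduced_2cell(a, b, 1, 4)
            pair = st.nonhomogeneous_pair(a, b, 1, 4)
            if cond.unstable:
                assert pair is not None
            x0 = cond.x0
            if pair is not None:
                assert pair[0] < x0 < pair[1]

    def test_absent_without_repression(self):
        assert st.nonhomogeneous_pair(0.1, 1e-300, 1, 4) is None

    def test_cyclic_consistency(self, ab):
        a, b = ab
        x1, x2 = st.nonhomogeneous_pair(a, b, 1, 4)
        fn = st._Funcs(a, b, 1, 4)
        assert fn.gamma(x1) == pytest.approx(x2, abs=1e-10)
        assert fn.gamma(x2) == pytest.approx(x1, abs=1e-10)

    def test_stable_whenever_it_exists(self, ab):
        a, b = ab
        pair = st.nonhomogeneous_pair(a, b, 1, 4)
        assert not st.pair_stability(pair, a, b, 1, 4).unstable

    def test_stability_matches_eigenvalues_on_random_draws(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            a = 10 ** rng.uniform(-2, 0)
            b = 10 ** rng.uniform(1, 6)
            pair = st.nonhomogeneous_pair(a, b, 1, 4)
            if pair is None:
                continue
            cond = st.pair_stability(pair, a, b, 1, 4)
            J = st.reduced_two_cell_jacobian(*pair, a, b, 1, 4)
            eig_stable = np.max(np.real(np.linalg.eigvals(J))) < st.EIG_TOL
            assert eig_stable == (not cond.unstable)
            assert eig_stable  # stable whenever it exists
            checked += 1

    def test_full_model_pair_is_stable_too(self, params, ab):
        # 10-dimensional Jacobian of the two-cell full model at the mapped
        # patterned state has no eigenvalue in the right half plane
        pair = st.nonhomogeneous_pair(*ab, 1, 4)
        state = st.full_pair_state(*pair, params)
        J = st.full_two_cell_jacobian(state, params)
        assert np.max(np.real(np.linalg.eigvals(J))) < 1e-6


class TestSignEquivalenceAcrossDraws:
    def test_reduced_full_and_eigenvalues_agree(self, params):
        # across parameter draws and feedback scalings, the reduced
        # condition, the protein-unit condition and the numeric spectrum of
        # the 10-dimensional two-cell Jacobian flip together
        both_signs = set()
        for seed in range(20):
            draw = sample_perturbed_parameters(params, seed)
            for s in (1.0, 60.0, 400.0):
                ps = draw.scale_alpha_N(s)
                a, b = compute_ab(ps)
                c_red = st.instability_reduced_2cell(a, b, ps.k, ps.h)
                c_full = st.instability_full_2cell(ps)
                h0 = ode_grid.homogeneous_stationary_state(ps)
                state = np.tile([h0[sp] for sp in hn.SPECIES], (2, 1))
                J = st.full_two_cell_jacobian(state, ps)
                eig_unstable = np.max(np.real(np.linalg.eigvals(J))) > 1e-9
                assert c_red.unstable == c_full.unstable == eig_unstable
                both_signs.add(c_red.unstable)
        assert both_signs == {True, False}


class TestDispersion:
    def test_1d_most_unstable_at_half(self, ab):
        res = st.dispersion(*ab, 1, 4, "1d", 10)
        assert res.most_unstable == (5,)
        # the s/N = 1/2 growth rate equals minus the two-cell condition margin
        cond = st.instability_reduced_2cell(*ab, 1, 4)
        assert res.growth[5] == pytest.approx(-cond.margin, abs=1e-12)

    def test_2d_most_unstable_at_third(self, ab):
        res = st.dispersion(*ab, 1, 4, "2d-hex", (9, 9))
        assert res.most_unstable == (3, 3)
        assert res.max_growth > 0

    def test_zero_mode_is_stable(self, ab):
        # the spatially uniform mode decays: phi'(x0) - 1 < 0 at the root
        res1 = st.dispersion(*ab, 1, 4, "1d", 8)
        assert res1.growth[0] < 0
        res2 = st.dispersion(*ab, 1, 4, "2d-hex", (6, 6))
        assert res2.growth[0, 0] < 0

    def test_maxima_locations_across_random_unstable_draws(self):
        rng = np.random.default_rng(3)
        found = 0
        while found < 20:
            a = 10 ** rng.uniform(-2, 0)
            b = 10 ** rng.uniform(2, 6)
            if not st.instability_reduced_2cell(a, b, 1, 4).unstable:
                continue
            r1 = st.dispersion(a, b, 1, 4, "1d", 12)
            assert r1.most_unstable == (6,)
            r2 = st.dispersion(a, b, 1, 4, "2d-hex", (12, 12))
            assert r2.most_unstable in {(4, 4), (8, 8)}  # +-N/3 are degenerate
            found += 1


class TestThreeCellSystem:
    def test_two_pairs_one_stable_at_defaults(self, ab):
        sols = st.three_cell_stationary(*ab, 1, 4)
        patterned = [s for s in sols if not s.homogeneous]
        assert len(patterned) == 2
        assert sum(s.stable for s in patterned) == 1
        homog = [s for s in sols if s.homogeneous]
        assert len(homog) == 1 and not homog[0].stable

    def test_stationary_relations_hold(self, ab):
        a, b = ab
        fn = st._Funcs(a, b, 1, 4)
        for sol in st.three_cell_stationary(a, b, 1, 4):
            assert fn.hfun(sol.x1) == pytest.approx(float(fn.g(sol.x2)), abs=1e-10)
            assert fn.Hfun(sol.x2) == pytest.approx(float(fn.g(sol.x1)) / 2, abs=1e-10)

    def test_w2_coupling_misclassifies_near_homogeneous_pair(self, ab):
        # the two-cell generic coupling admits a spurious stable
        # near-homogeneous solution that the three-cell system rejects
        w3 = {round(s.x1, 6): s.stable for s in st.three_cell_stationary(*ab, 1, 4)}
        w2 = {round(s.x1, 6): s.stable for s in st.three_cell_stationary(*ab, 1, 4, system="W2")}
        assert set(w3) == set(w2)
        assert sum(w2.values()) > sum(w3.values())

    def test_existence_boundary_brackets_solution_count(self, params):
        s_star = st.existence_boundary(params)
        a_lo, b_lo = compute_ab(params.scale_alpha_N(0.95 * s_star))
        a_hi, b_hi = compute_ab(params.scale_alpha_N(1.05 * s_star))
        below = [s for s in st.three_cell_stationary(a_lo, b_lo, 1, 4) if not s.homogeneous]
        above = [s for s in st.three_cell_stationary(a_hi, b_hi, 1, 4) if not s.homogeneous]
        assert len(below) == 2 and len(above) == 0

    def test_branches_merge_at_boundary(self, params):
        # just below the fold the stable and unstable patterned branches are
        # close and the double-root condition is near one
        s_star = st.existence_boundary(params)
        a, b = compute_ab(params.scale_alpha_N(0.995 * s_star))
        sols = [s for s in st.three_cell_stationary(a, b, 1, 4) if not s.homogeneous]
        xs = sorted(s.x1 for s in sols)
        assert abs(xs[1] - xs[0]) < 0.05
        stable = next(s for s in sols if s.stable)
        assert st.eq36_lhs((stable.x1, stable.x2), a, b, 1, 4) == pytest.approx(1.0, abs=0.25)

    def test_boundary_exceeds_homogeneous_instability_threshold(self, params):
        # a window exists where the homogeneous state is already stable on
        # the hexagonal lattice yet patterned three-cell solutions persist
        s_star = st.existence_boundary(params)
        from scipy.optimize import brentq

        def margin30(s):
            a, b = compute_ab(params.scale_alpha_N(s))
            fn = st._Funcs(a, b, 1, 4)
            x0 = st.homogeneous_fixed_point(a, b, 1, 4)
            return float(fn.f(x0) * fn.gp(x0) / 2 - fn.fp(x0) * fn.g(x0)) + 1.0

        s30 = brentq(margin30, 0.5, s_star)
        assert s30 < s_star


@pytest.fixture(scope="module")
def scan(params):
    return st.bifurcation_scan(params, np.geomspace(0.5, 50, 40), system="2cell-full")


class TestBifurcationScan:
    def test_homogeneous_branch_everywhere(self, scan):
        homog = scan[scan.kind == "homogeneous"]
        assert len(homog) == 40
        assert homog["x"].between(0, 1).all()

    def test_stability_flips_at_condition_margin(self, scan):
        homog = scan[scan.kind == "homogeneous"]
        assert (homog["stable"] == (homog["margin_reduced"] > 0)).all()

    def test_patterned_pair_present_and_stable_at_defaults(self, params):
        scan = st.bifurcation_scan(params, np.array([1.0]), system="2cell-full")
        pat = scan[scan.kind == "patterned"]
        assert len(pat) == 2
        assert pat["stable"].all()
        assert (pat["P"] > 0).all()

    def test_three_cell_scan_has_fold(self, params):
        scan = st.bifurcation_scan(params, np.geomspace(20, 60, 25), system="3cell-reduced")
        counts = scan[scan.kind == "patterned"].groupby("s").size()
        assert counts.max() == 4 and set(scan[scan.kind == "patterned"]["stable"]) == {True, False}
        # patterned branches disappear at large s
        last_s = scan["s"].max()
        assert len(scan[(scan.s == last_s) & (scan.kind == "patterned")]) == 0
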