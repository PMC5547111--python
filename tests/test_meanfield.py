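import numpy as np
import pytest

from cyclicomp import meanfield as mf
from cyclicomp.models import cyclic_shift, make_model


def fd_jacobian(model, point, h=1e-6):
    """Central finite-difference oracle for the analytic Jacobian."""
    point = np.asarray(point, dtype=float)
    n = len(point)
    out = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        out[:, j] = (
            mf._rhs(point + e, model.mu, model.sigma,
                    np.asarray(model.p), model.predator_matrix)
            - mf._rhs(point - e, model.mu, model.sigma,
                      np.asarray(model.p), model.predator_matrix)
        ) / (2 * h)
    return out


class TestRHS:
    def test_symmetric_point_balances(self):
        m = make_model("rps", p=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(
            mf.ode_rhs(m, (0.25, 0.25, 0.25)), np.zeros(3), atol=1e-15
        )

    def test_extinction_invariant(self, rps_pair):
        np.testing.assert_array_equal(
            mf.ode_rhs(rps_pair, np.zeros(3)), np.zeros(3)
        )

    def test_interior_point_is_equilibrium(self, rps_coexist):
        fp = mf.rps_interior_point(rps_coexist.p)
        assert np.abs(mf.ode_rhs(rps_coexist, fp)).max() < 1e-12

    def test_negative_density_rejected(self, rps_coexist):
        with pytest.raises(ValueError):
            mf.ode_rhs(rps_coexist, (-0.1, 0.2, 0.2))

    def test_zero_component_stays_zero(self, rpsls_template, rng):
        state = rng.uniform(0, 0.2, size=5)
        state[2] = 0.0
        assert mf.ode_rhs(rpsls_template, state)[2] == 0.0


class TestFixedPoints:
    def test_closed_forms_match_enumeration(self, rng):
        """Numeric support-wise solves agree with the closed forms to 1e-10."""
        for _ in range(100):
            p = rng.uniform(0.0, 5.0, size=3)
            m = make_model("rps", p=p)
            fps = {fp.support: fp for fp in mf.find_fixed_points(m)}
            for i, single in enumerate(mf.rps_single_points(p)):
                np.testing.assert_allclose(
                    fps[frozenset({i})].densities, single, atol=1e-10
                )
            for pair_name, support in [
                ("AB", {0, 1}), ("AC", {0, 2}), ("BC", {1, 2})
            ]:
                expect = mf.rps_pair_points(p)[pair_name]
                if np.all(expect > 1e-8):
                    np.testing.assert_allclose(
                        fps[frozenset(support)].densities, expect, atol=1e-10
                    )
            interior = mf.rps_interior_point(p)
            if np.all(interior > 1e-8):
                np.testing.assert_allclose(
                    fps[frozenset({0, 1, 2})].densities, interior, atol=1e-10
                )

    @pytest.mark.parametrize(
        "p,expected",
        [
            ((2.5, 1.0, 0.5), (2 / 4.5, 0, 0)),
            ((5.2, 1.0, 0.5), (2 / 13.6, 3.2 * 2 / 13.6, 0)),
            ((2.5, 1.0, 0.5), (0.19417476, 0.33009709, 0.11650485)),
            ((0.0, 0.0, 0.0), (0.25, 0.25, 0.25)),
        ],
    )
    def test_reference_points(self, p, expected):
        m = make_model("rps", p=p)
        fps = mf.find_fixed_points(m)
        best = min(
            np.abs(np.asarray(fp.densities) - expected).max() for fp in fps
        )
        assert best < 1e-6

    def test_pair_existence_onset(self, rng):
        """The AB pair point exists (nonnegative) iff p_a > 2 at p_b=1."""
        for pa in np.linspace(0.2, 6.0, 30):
            m = make_model("rps", p=(pa, 1.0, 0.5))
            pairs = [fp for fp in mf.find_fixed_points(m) if fp.kind == "pair"]
            assert bool(pairs) == (pa > 2)


class TestJacobian:
    @pytest.mark.parametrize("kind,n", [("rps", 3), ("erps", 5), ("rpsls", 5)])
    def test_matches_finite_differences(self, kind, n, rng):
        for _ in range(10):
            m = make_model(kind, p=rng.uniform(0, 5, size=n))
            x = rng.uniform(0, 0.3, size=n)
            jac = mf.jacobian(m, x)
            ref = fd_jacobian(m, x)
            scale = max(1.0, np.abs(ref).max())
            assert np.abs(jac - ref).max() / scale < 1e-6

    def test_table_eigenvalues_at_pair_point(self, rng):
        """Computed spectrum at AB matches the closed-form eigenvalues."""
        for _ in range(50):
            pa = rng.uniform(2.1, 8.0)
            pb = rng.uniform(0.1, 1.9)
            pc = rng.uniform(0.1, 5.0)
            m = make_model("rps", p=(pa, pb, pc))
            w1 = 2 / (pa * pb + 2 * (pa + pb) - 4)
            point = w1 * np.array([pb, pa - 2, 0.0])
            eig = np.sort(np.linalg.eigvals(mf.jacobian(m, point)).real)
            expect = np.sort(mf.rps_pair_eigenvalues((pa, pb, pc), "AB"))
            np.testing.assert_allclose(eig, expect, atol=1e-8)

    def test_empty_state_spectrum_is_mu(self, rps_coexist):
        eig = np.linalg.eigvals(mf.jacobian(rps_coexist, np.zeros(3)))
        np.testing.assert_allclose(sorted(eig.real), [1.0] * 3, atol=1e-12)

    def test_ab_stability_boundary_is_analytic(self):
        # p_a(p_b - 2) + 4 < 0  <=>  p_a > 4 / (2 - p_b) for p_b < 2
        pb = 1.0
        boundary = 4 / (2 - pb)
        lo = mf.rps_pair_eigenvalues((boundary - 1e-6, pb, 0.5), "AB")[0]
        hi = mf.rps_pair_eigenvalues((boundary + 1e-6, pb, 0.5), "AB")[0]
        assert lo > 0 > hi


class TestStability:
    def test_single_points_are_saddles(self, rps_heteroclinic):
        singles = [
            fp for fp in mf.find_fixed_points(rps_heteroclinic)
            if fp.kind == "single"
        ]
        assert len(singles) == 3
        assert all(fp.stability == "saddle" for fp in singles)

    def test_interior_stable_in_coexistence_regime(self, rps_coexist):
        assert mf.interior_fixed_point(rps_coexist).stability == "stable"

    def test_pair_stable_in_two_species_regime(self, rps_pair):
        pairs = [
            fp for fp in mf.find_fixed_points(rps_pair) if fp.kind == "pair"
        ]
        assert len(pairs) == 1 and pairs[0].stability == "stable"

    def test_classifier_labels(self):
        assert mf.classify_stability(np.array([-1.0, -0.5])) == "stable"
        assert mf.classify_stability(np.array([1.0, 2.0])) == "unstable"
        assert mf.classify_stability(np.array([-1.0, 2.0])) == "saddle"
        assert mf.classify_stability(np.array([1e-12, -1.0])) == "marginal"


class TestHeteroclinic:
    def test_attracting_below_threshold(self, rps_heteroclinic):
        assert mf.heteroclinic_cycle_stable(rps_heteroclinic) is True

    def test_not_attracting_in_coexistence_regime(self, rps_coexist):
        assert mf.heteroclinic_cycle_stable(rps_coexist) is False

    def test_criteria_flip_together(self):
        """Cycle attractiveness flips where the interior point's leading
        eigenvalue crosses zero (within 0.05 in p_a)."""
        def cycle_flip():
            lo, hi = 1.0, 2.5
            while hi - lo > 1e-4:
                mid = 0.5 * (lo + hi)
                m = make_model("rps", p=(mid, 1.0, 0.5))
                if mf.heteroclinic_cycle_stable(m):
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        def interior_flip():
            lo, hi = 1.0, 2.5
            while hi - lo > 1e-4:
                mid = 0.5 * (lo + hi)
                m = make_model("rps", p=(mid, 1.0, 0.5))
                if mf.interior_leading_eigenvalue(m) > 0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        assert abs(cycle_flip() - interior_flip()) < 0.05


class TestIntegration:
    def test_coexistence_attractor(self, rps_coexist):
        traj = mf.integrate(rps_coexist, (0.3, 0.3, 0.3), 2000, dt_out=10)
        assert np.all(traj.final > 0.05)
        np.testing.assert_allclose(
            traj.final, mf.rps_interior_point(rps_coexist.p), atol=1e-6
        )

    def test_pair_attractor_extinguishes_one(self, rps_pair):
        traj = mf.integrate(rps_pair, (0.3, 0.3, 0.3), 2000, dt_out=10)
        assert traj.final[2] < 1e-6
        assert np.all(traj.final[:2] > 0.05)

    def test_single_species_logistic_limit(self):
        m = make_model("rps", p=(2.5, 1.0, 0.5))
        traj = mf.integrate(m, (0.0, 0.0, 0.5), 500, dt_out=5)
        assert traj.final[2] == pytest.approx(2 / 2.5, abs=1e-8)

    def test_simplex_forward_invariance(self, rng):
        m = make_model("rps", p=(1.7, 0.3, 4.0))
        for _ in range(100):
            init = rng.dirichlet([1, 1, 1, 1])[:3]
            traj = mf.integrate(m, init, 50, dt_out=5)
            assert np.all(traj.densities >= 0)
            assert np.all(traj.densities <= 1)
            assert np.all(traj.total_density <= 1 + 1e-9)

    def test_bad_initial_state_rejected(self, rps_coexist):
        with pytest.raises(ValueError):
            mf.integrate(rps_coexist, (0.6, 0.6, 0.3), 10)


class TestScan:
    def test_rps_phase_sequence(self):
        template = make_model("rps", p=(1.0, 1.0, 0.5))
        scan = mf.scan_bifurcation(template, "p_a", np.arange(0.1, 8.01, 0.1))
        assert scan.phase_pairs == [(0, 3), (3, 2)]
        assert scan.thresholds[0] == pytest.approx(1.5, abs=5e-3)
        assert scan.thresholds[1] == pytest.approx(4.0, abs=5e-3)

    def test_scan_commutes_with_relabeling(self):
        """Scanning p_b for the shifted template reproduces the p_a scan."""
        grid = np.arange(0.5, 6.01, 0.1)
        base = make_model("rps", p=(1.0, 1.0, 0.5))
        s1 = mf.scan_bifurcation(base, "p_a", grid)
        shifted = cyclic_shift(base, 1)  # p -> (0.5, p_a slot, 1.0)
        s2 = mf.scan_bifurcation(shifted, "p_b", grid)
        np.testing.assert_array_equal(s1.phase, s2.phase)
        np.testing.assert_allclose(s1.thresholds, s2.thresholds, atol=1e-3)

    def test_short_grid_rejected(self, rps_coexist):
        with pytest.raises(ValueError):
            mf.scan_bifurcation(rps_coexist, "p_a", [1.0, 2.0])


class TestLimits:
    def test_pair_point_limit(self):
        template = make_model("rps", p=(1.0, 1.0, 0.5))
        limit = mf.limit_fixed_point(template, "p_a", 1e6)
        np.testing.assert_allclose(limit, [0, 2 / 3, 0], atol=1e-4)

    def test_limit_depends_only_on_prey_rate(self):
        template = make_model("rps", p=(1.0, 0.5, 1.0))
        limit = mf.limit_fixed_point(template, "p_a", 1e6)
        np.testing.assert_allclose(limit, [0, 0.8, 0], atol=1e-4)

    def test_finite_large_parameter(self):
        m = make_model("rps", p=(100.0, 1.0, 0.5))
        pair = [
            fp for fp in mf.find_fixed_points(m)
            if fp.kind == "pair" and fp.stability == "stable"
        ][0]
        assert pair.densities[1] == pytest.approx(2 * 98 / 298, abs=1e-10)


class TestSubTournament:
    def test_rps_full_cycle(self, rps_coexist):
        assert mf.sub_tournament(rps_coexist, {0, 1, 2}) == "cyclic"

    def test_erps_pair_is_mixed_or_edge(self, erps_template):
        # adjacent pair has one edge (total order on two vertices)
        assert mf.sub_tournament(erps_template, {0, 1}) == "transitive"
        # non-adjacent pair has no edge at all
        assert mf.sub_tournament(erps_template, {0, 2}) == "mixed"

    def test_too_small_support_rejected(self, rps_coexist):
        with pytest.raises(ValueError):
            mf.sub_tournament(rps_coexist, {0})
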