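"""Kinematics of the four swim modes and the scene-level features."""

import math

import numpy as np
import pytest

from casabench import swim


class TestCircular:
    def test_head_at_time_zero(self):
        p = swim.CircularParams(r_c=10.0, a=2.0, C_xc=0.0, C_yc=0.0)
        assert swim.circular_head(0.0, p) == pytest.approx((10.0, 0.0))

    def test_quarter_cycle_pure_circle(self):
        p = swim.CircularParams(r_c=10.0, a=0.0, f_c=1.0, C_xc=5.0, C_yc=5.0)
        assert swim.circular_head(0.25, p) == pytest.approx((5.0, 15.0), abs=1e-9)

    def test_radius_term_with_benchmark_values(self):
        # direct evaluation oracle: r_c + a*sin(2 pi f_s t) at t = 1/(4 f_s)
        p = swim.CircularParams(r_c=80.0, a=3.0, f_s=4.0, f_c=50 / 360,
                                C_xc=0.0, C_yc=0.0)
        x, y = swim.circular_head(0.0625, p)
        assert np.hypot(x, y) == pytest.approx(83.0, rel=1e-12)

    def test_head_stays_within_modulated_radius(self):
        p = swim.CircularParams(r_c=80.0, a=3.0, f_s=4.0)
        for t in np.linspace(0, 7, 211):
            x, y = swim.circular_head(t, p)
            assert np.hypot(x, y) <= 83.0 + 1e-9

    def test_amplitude_profile_substitutions(self):
        # b(k) = a(alpha*lambda*k/M + beta): b(M) = 6.4 px for a=4, lambda=40
        p = swim.CircularParams(a=4.0, lambda_=40.0)
        b = lambda k: p.a * (p.alpha * p.lambda_ * k / p.M + p.beta)
        assert b(p.M) == pytest.approx(6.4)
        assert b(0) == pytest.approx(0.8 * p.a)

    def test_tail_endpoint_and_root(self):
        p = swim.CircularParams(r_c=80.0, a=4.0, lambda_=40.0)
        head = swim.circular_head(0.3, p)
        tail = swim.circular_tail(0.3, head, p)
        assert tail.shape == (p.M, 2)
        assert np.linalg.norm(tail[0] - head) < 1e-6  # root on the head
        # endpoint lies lambda px from the head along the local tail axis
        # (plus the perpendicular beat offset), so its distance is at least
        # lambda and at most hypot(lambda, b(M)+b(0))
        d = np.linalg.norm(tail[-1] - head)
        assert p.lambda_ - 1e-9 <= d <= np.hypot(p.lambda_, 2 * 6.4)

    def test_deg_per_s_conversion(self):
        assert swim.CircularParams.deg_per_s(50.0) == pytest.approx(50 / 360)


class TestRibbonConstant:
    def test_zero_harmonic_ratio(self):
        assert swim.ribbon_constant(0.0) == 1.0

    def test_value_against_dense_grid_oracle(self):
        # max of sin(t)+0.1 sin(3t) equals 0.9 (attained at pi/2)
        assert swim.ribbon_constant(0.1) == pytest.approx(1.0 / 0.9, abs=1e-9)

    def test_ribbon_vertical_amplitude_is_half_width(self):
        p = swim.LinearParams(r_h=12.0, A_har=0.1, f_l=3.0)
        t = np.linspace(0, 1 / 3, 200001)
        ph = 2 * np.pi * 3.0 * t
        py = (p.r_h * p.A_c / 2) * (np.sin(ph) + 0.1 * np.sin(3 * ph))
        assert py.max() == pytest.approx(6.0, abs=1e-6)


class TestLinear:
    def test_head_at_time_zero_is_start(self):
        p = swim.LinearParams(C_xL=7.0, C_yL=9.0)
        assert swim.linear_head(0.0, p) == pytest.approx((7.0, 9.0), abs=1e-12)

    def test_ribbon_free_limit_is_straight_line(self):
        p = swim.LinearParams(V=50.0, theta_r=0.0, r_h=0.0, r_v=0.0,
                              C_xL=3.0, C_yL=4.0)
        assert swim.linear_head(1.0, p) == pytest.approx((53.0, 4.0), abs=1e-12)

    def test_benchmark_values_match_independent_evaluation(self):
        # independent re-derivation of the ribbon path at t = 1/(4 f_l)
        p = swim.LinearParams(V=50.0, theta_r=0.7, f_l=3.0, r_h=12.0, r_v=8.0,
                              A_har=0.1, C_xL=10.0, C_yL=20.0)
        t = 1.0 / (4 * 3.0)
        a_c = 1.0 / max(np.sin(th) + 0.1 * np.sin(3 * th)
                        for th in np.linspace(0, 2 * np.pi, 2000001))
        px = (8.0 / 2) * math.sin(4 * math.pi * 3.0 * t)
        py = (12.0 * a_c / 2) * (math.sin(2 * math.pi * 3 * t)
                                 + 0.1 * math.sin(6 * math.pi * 3 * t))
        c, s = math.cos(0.7), math.sin(0.7)
        expect = (50 * c * t + 10 + c * px - s * py,
                  50 * s * t + 20 + s * px + c * py)
        assert swim.linear_head(t, p) == pytest.approx(expect, abs=1e-6)

    def test_head_distance_from_line_bounded(self):
        # perpendicular distance from the straight-line path is the ribbon's
        # vertical component, bounded by r_h/2 thanks to A_c
        p = swim.LinearParams(V=50.0, theta_r=0.4, r_h=12.0, r_v=8.0, A_har=0.1)
        for t in np.linspace(0, 2, 301):
            x, y = swim.linear_head(t, p)
            cx = 50 * math.cos(0.4) * t + p.C_xL
            cy = 50 * math.sin(0.4) * t + p.C_yL
            perp = abs(-math.sin(0.4) * (x - cx) + math.cos(0.4) * (y - cy))
            assert perp <= 12.0 / 2 + 1e-9

    def test_ribbon_free_path_is_exactly_the_line(self):
        p = swim.LinearParams(V=30.0, theta_r=0.4, r_h=0.0, r_v=0.0)
        for t in np.linspace(0, 2, 51):
            x, y = swim.linear_head(t, p)
            assert y * math.cos(0.4) == pytest.approx(x * math.sin(0.4),
                                                      abs=1e-9)

    def test_shaping_function_substitutions(self):
        p = swim.LinearParams()
        b1 = lambda k: 1 / (1 + math.exp(p.alpha * k / p.M + p.beta))
        b2 = lambda k: math.exp(-p.gamma1 * k / p.M)
        b3 = lambda k: 1 - math.exp(-p.gamma2 * k / p.M)
        assert b1(0) == pytest.approx(1 / (1 + math.exp(-2)))
        assert b2(p.M) == pytest.approx(math.exp(-5))
        assert b3(0) == 0.0

    def test_tail_root_attached_to_head(self):
        p = swim.LinearParams(theta_r=1.1, C_xL=50.0, C_yL=60.0)
        for t in [0.0, 0.21, 1.7]:
            head = swim.linear_head(t, p)
            tail = swim.linear_tail(t, head, p)
            assert tail.shape == (p.M, 2)
            assert np.linalg.norm(tail[0] - head) < 1e-6


class TestHyperactive:
    def test_zero_diffusion_is_stationary(self, rng):
        p = swim.HyperactiveParams(sigma_b=0.0, T=1 / 15)
        pos = (5.0, 5.0)
        for _ in range(50):
            pos = swim.hyperactive_head(pos, p, rng)
        assert pos == pytest.approx((5.0, 5.0))

    def test_increment_variance_matches_normal_law(self, rng):
        # Monte-Carlo against N(0, sigma_b^2 T): 1e4 steps, fixed seed
        p = swim.HyperactiveParams(sigma_b=10.0, T=1 / 15)
        pos = np.zeros(2)
        steps = []
        for _ in range(10_000):
            new = swim.hyperactive_head(tuple(pos), p, rng)
            steps.append([new[0] - pos[0], new[1] - pos[1]])
            pos = np.asarray(new)
        steps = np.asarray(steps)
        target = 100.0 / 15.0
        assert abs(steps[:, 0].var() - target) / target < 0.05
        assert abs(steps[:, 1].var() - target) / target < 0.05
        assert abs(steps.mean()) < 3 * math.sqrt(target / 10_000)

    def test_increments_uncorrelated_across_steps(self, rng):
        p = swim.HyperactiveParams(sigma_b=10.0, T=1 / 15)
        pos = (0.0, 0.0)
        xs = []
        for _ in range(10_000):
            new = swim.hyperactive_head(pos, p, rng)
            xs.append(new[0] - pos[0])
            pos = new
        xs = np.asarray(xs)
        r = np.corrcoef(xs[:-1], xs[1:])[0, 1]
        assert abs(r) < 0.05

    def test_rms_displacement_scales_as_sqrt_time(self, rng):
        # 1e4 independent cells, displacement RMS after t and 4t differ by ~2x
        p = swim.HyperactiveParams(sigma_b=10.0, T=0.1)
        n = 10_000
        pos = np.zeros((n, 2))
        rms = {}
        for step in range(1, 41):
            pos += 10.0 * rng.normal(0, math.sqrt(0.1), size=(n, 2))
            if step in (10, 40):
                rms[step] = np.sqrt((pos**2).sum(axis=1).mean())
        assert rms[40] / rms[10] == pytest.approx(2.0, rel=0.05)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            swim.HyperactiveParams(sigma_b=-1.0)


class TestTrailingTail:
    def test_single_point_history_collapses(self):
        tail = swim.trailing_tail([(3.0, 4.0)], n=3, M=200)
        assert tail.shape == (200, 2)
        assert np.allclose(tail, [3.0, 4.0])

    def test_collinear_history_equally_spaced(self):
        hist = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0)]
        tail = swim.trailing_tail(hist, n=3, M=7)
        assert np.allclose(tail[:, 1], 0.0)
        assert np.allclose(np.diff(tail[:, 0]), -0.5)
        assert tail[0, 0] == 3.0  # newest end at the head

    def test_resampling_matches_dense_polyline_oracle(self):
        hist = [(0.0, 0.0), (2.0, 1.0), (3.0, 3.0), (1.0, 4.0)]
        tail = swim.trailing_tail(hist, n=3, M=50)
        # oracle: dense sampling of the same polyline then arc-length lookup
        pts = np.asarray(hist[::-1])
        dense = np.concatenate([
            np.linspace(pts[i], pts[i + 1], 20001)[:-1] for i in range(3)
        ] + [pts[-1:]])
        s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0),
                                                          axis=1))])
        q = np.linspace(0, s[-1], 50)
        idx = np.searchsorted(s, q).clip(0, len(dense) - 1)
        assert np.abs(tail - dense[idx]).max() < 1e-3

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            swim.trailing_tail([], 3, 10)


class TestImmotileAndModes:
    def test_immotile_state_frozen(self):
        st = swim.CellState(id=0, mode="immotile", head=(5.0, 5.0),
                            tail=np.zeros((200, 2)), params=None)
        assert swim.immotile_state(st, 10.0) is st

    def test_identity_transition_matrix_absorbing(self, rng):
        tm = swim.TransitionModel(np.eye(4))
        st = swim.CellState(id=0, mode="linear", head=(0.0, 0.0),
                            tail=np.zeros((200, 2)), params=swim.LinearParams())
        for _ in range(100):
            swim.step_mode(st, tm, rng)
        assert st.mode == "linear"

    def test_transition_frequencies_match_row(self, rng):
        # row: 85% stay linear, 10% -> circular, 5% -> hyperactive
        m = np.array([[1, 0, 0, 0],
                      [0.10, 0.85, 0.05, 0.0],
                      [0, 0, 1, 0],
                      [0, 0, 0, 1.0]])
        tm = swim.TransitionModel(m)
        counts = {"linear": 0, "circular": 0, "hyperactive": 0, "immotile": 0}
        for _ in range(10_000):
            st = swim.CellState(id=0, mode="linear", head=(0.0, 0.0),
                                tail=np.zeros((200, 2)),
                                params=swim.LinearParams())
            swim.step_mode(st, tm, rng)
            counts[st.mode] += 1
        for mode, p in [("linear", 0.85), ("circular", 0.10),
                        ("hyperactive", 0.05), ("immotile", 0.0)]:
            sd = math.sqrt(p * (1 - p) * 10_000)
            assert abs(counts[mode] - p * 10_000) <= max(3 * sd, 1)

    def test_transition_preserves_position(self, rng):
        tm = swim.TransitionModel(np.array([[0, 1, 0, 0]] + [[1, 0, 0, 0]] * 3,
                                           dtype=float))
        st = swim.CellState(id=0, mode="circular", head=(40.0, 50.0),
                            tail=np.zeros((200, 2)),
                            params=swim.CircularParams(), heading=0.3)
        swim.step_mode(st, tm, rng, t=2.0)
        assert st.mode == "linear"
        assert st.params.theta_r == pytest.approx(0.3)
        assert (st.params.C_xL, st.params.C_yL) == pytest.approx((40.0, 50.0))

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            swim.TransitionModel(np.full((4, 4), 0.3))


class TestJitter:
    def test_zero_sigma_identity(self, rng):
        assert swim.jitter_position((1.0, 2.0), 0.0, rng) == (1.0, 2.0)

    def test_sample_std_matches_sigma(self, rng):
        draws = np.array([swim.jitter_position((0.0, 0.0), 2.5, rng)
                          for _ in range(10_000)])
        assert abs(draws[:, 0].std() - 2.5) / 2.5 < 0.05
        assert abs(draws[:, 1].std() - 2.5) / 2.5 < 0.05

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            swim.jitter_position((0.0, 0.0), -1.0, rng)
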