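"""End-stopped stage: gated lateral inhibition and shunting dynamics."""

import numpy as np
import pytest

from mtpattern.config import default_config
from mtpattern.endstopped import (endstopped_step, inhibition_kernel,
                                  lateral_inhibition, run_endstopped)


def brute_force_gamma(v_cx, mu, rho, gate_radius):
    """Direct double-loop evaluation of the gated inhibition sum.

    Replicate boundary handling (indices clipped to the lattice) to match
    the production convolution.
    """
    h, w, nd = v_cx.shape
    r = mu.shape[0] // 2
    out = np.zeros_like(v_cx)
    for d in range(nd):
        sl = v_cx[..., d]
        for y in range(h):
            for x in range(w):
                gate = 0.0
                for i in range(-gate_radius, gate_radius + 1):
                    for j in range(-gate_radius, gate_radius + 1):
                        gate = max(gate, sl[np.clip(y + i, 0, h - 1),
                                            np.clip(x + j, 0, w - 1)])
                if gate <= rho:
                    continue
                acc = 0.0
                for i in range(-r, r + 1):
                    for j in range(-r, r + 1):
                        acc += mu[r + i, r + j] * sl[np.clip(y + i, 0, h - 1),
                                                     np.clip(x + j, 0, w - 1)]
                out[y, x, d] = acc
    return out


class TestInhibitionKernel:
    def test_symmetric_with_central_hole(self):
        mu = inhibition_kernel(8, hole=3)
        assert mu.shape == (17, 17)
        np.testing.assert_array_equal(mu, np.rot90(mu, 2))
        assert (mu[8 - 3:8 + 4, 8 - 3:8 + 4] == 0).all()
        # peak weight: 1/sigma Gaussian evaluated just outside the hole
        assert mu.max() == pytest.approx(np.exp(-16.0 / 32.0) / 4.0)

    def test_hole_must_fit(self):
        with pytest.raises(ValueError):
            inhibition_kernel(4, hole=5)


class TestLateralInhibition:
    def test_all_subthreshold_gives_zero(self):
        cfg = default_config()
        mu = inhibition_kernel(cfg.es_inhib_radius, cfg.es_gate_radius)
        v = np.full((16, 16, 8), 0.05)  # below c_cx = 0.12
        assert lateral_inhibition(v, mu, cfg.c_cx, cfg.es_gate_radius).max() == 0

    def test_matches_brute_force_one_hot(self):
        cfg = default_config()
        mu = inhibition_kernel(cfg.es_inhib_radius, cfg.es_gate_radius)
        v = np.zeros((16, 16, 2))
        v[7, 9, 0] = 0.8
        got = lateral_inhibition(v, mu, cfg.c_cx, cfg.es_gate_radius)
        want = brute_force_gamma(v, mu, cfg.c_cx, cfg.es_gate_radius)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_matches_brute_force_uniform_field(self):
        cfg = default_config()
        mu = inhibition_kernel(cfg.es_inhib_radius, cfg.es_gate_radius)
        v = np.full((16, 16, 1), 0.5)
        got = lateral_inhibition(v, mu, cfg.c_cx, cfg.es_gate_radius)
        want = brute_force_gamma(v, mu, cfg.c_cx, cfg.es_gate_radius)
        np.testing.assert_allclose(got, want, atol=1e-10)
        # away from borders the sum equals the full kernel mass times a
        assert got[8, 8, 0] == pytest.approx(0.5 * mu.sum())

    def test_matches_brute_force_random_field(self):
        rng = np.random.default_rng(7)
        cfg = default_config()
        mu = inhibition_kernel(cfg.es_inhib_radius, cfg.es_gate_radius)
        v = rng.uniform(0, 1, (16, 16, 2))
        got = lateral_inhibition(v, mu, cfg.c_cx, cfg.es_gate_radius)
        want = brute_force_gamma(v, mu, cfg.c_cx, cfg.es_gate_radius)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestDynamics:
    def test_quiescence_is_fixed_point(self):
        cfg = default_config()
        z = np.zeros((8, 8, 8))
        out = endstopped_step(z, z, z, cfg)
        assert out.max() == 0.0

    def test_shunting_upper_bound(self):
        cfg = default_config()
        v = np.ones((4, 4, 8))
        out = endstopped_step(v, np.ones_like(v), np.zeros_like(v), cfg)
        assert out.max() <= 1.0

    def test_steady_state_closed_form(self):
        # with no inhibition: v* = G1 v_cx / (G1 v_cx + tau_es)
        cfg = default_config()
        v_cx = np.full((4, 4, 1), 0.5)
        v = np.zeros_like(v_cx)
        gamma = np.zeros_like(v_cx)
        for _ in range(10_000):
            v = endstopped_step(v, v_cx, gamma, cfg)
        expected = (cfg.G_escx1 * 0.5) / (cfg.G_escx1 * 0.5 + cfg.tau_es)
        assert expected == pytest.approx(1.0 / 1.01)
        np.testing.assert_allclose(v, expected, atol=1e-4)

    def test_bounded_for_random_bounded_inputs(self):
        rng = np.random.default_rng(3)
        cfg = default_config()
        v = np.zeros((12, 12, 8))
        for _ in range(200):
            v_cx = rng.uniform(0, 1, v.shape)
            gamma = rng.uniform(0, 5, v.shape)
            v = endstopped_step(v, v_cx, gamma, cfg)
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_stronger_inhibition_never_raises_steady_state(self):
        cfg = default_config()
        rng = np.random.default_rng(11)
        v_cx_traj = np.repeat(rng.uniform(0, 1, (1, 12, 12, 8)), 5, axis=0)
        lo = run_endstopped(v_cx_traj, cfg.replace(G_escx2=1.0), n_settle=400)
        hi = run_endstopped(v_cx_traj, cfg.replace(G_escx2=6.0), n_settle=400)
        assert (hi[-1] <= lo[-1] + 1e-12).all()

    def test_zero_input_trajectory_stays_zero(self):
        cfg = default_config()
        out = run_endstopped(np.zeros((5, 10, 10, 8)), cfg, n_settle=50)
        assert out.max() == 0.0

    def test_invalid_dt(self):
        cfg = default_config()
        z = np.zeros((2, 2, 1))
        with pytest.raises(ValueError):
            endstopped_step(z, z, z, cfg, dt=0.0)
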