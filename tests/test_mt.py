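"""Recurrent MT stage: kernels, lateral terms, stepping, full simulation."""

import numpy as np
import pytest

from mtpattern.config import default_config
from mtpattern.mt import (MTState, lateral_terms, mt_kernels, mt_step,
                          simulate)
from mtpattern.stimuli import StimulusMovie


@pytest.fixture()
def small_cfg():
    return default_config(grid_shape=(12, 12))


def make_state(cfg, shape=(12, 12)):
    return MTState.zeros(shape, cfg.N_dir, cfg.delay_steps)


class TestKernels:
    def test_geometry_and_masses(self, config):
        k = mt_kernels(config)
        assert k["center_pool"].sum() == pytest.approx(1.0)
        assert k["center"].sum() == pytest.approx(config.lambda_mass)
        assert k["annulus"].sum() == pytest.approx(1.0)
        assert k["annulus_zeta"].sum() == pytest.approx(config.zeta_mass)
        # centre kernel spans the MT RF (7 lattice steps across)
        assert k["center"].shape == (9, 9)
        # annulus is hollow
        c = k["annulus"].shape[0] // 2
        assert k["annulus"][c, c] == 0.0

    def test_center_excludes_self(self, config):
        k = mt_kernels(config)
        c = k["center"].shape[0] // 2
        assert k["center"][c, c] == 0.0


class TestLateralTerms:
    def test_all_zero_state_gives_zero_terms(self, small_cfg):
        cfg = small_cfg
        z = np.zeros((12, 12, 8))
        terms = lateral_terms(z, z, z, mt_kernels(cfg), cfg.directions(), cfg)
        for t in terms:
            assert np.max(np.abs(t)) == 0.0

    def test_one_hot_integration_field(self, small_cfg):
        cfg = small_cfg
        dirs = cfg.directions()
        ker = mt_kernels(cfg)
        v = np.zeros((12, 12, 8))
        v[6, 6, 2] = 0.8  # above c_ig
        lam, gam, zet, eta, chi_e, chi_i = lateral_terms(
            v, v, np.zeros_like(v), ker, dirs, cfg)
        c = ker["center"].shape[0] // 2
        # same-direction neighbour excitation equals the kernel weight
        assert lam[6, 7, 2] == pytest.approx(0.8 * ker["center"][c, c - 1])
        assert lam[6, 6, 2] == 0.0  # self excluded
        # inter-directional inhibition at the same location, other channels
        assert gam[6, 6, 3] == pytest.approx(0.8 / 7.0)
        assert gam[6, 6, 2] == 0.0
        # long-range inhibition confined to the annulus
        assert zet[6, 6, 2] == 0.0
        assert zet[6, 10, 2] > 0.0
        # direction-pooled drive onto segmentation
        assert eta[6, 6] > 0.0

    def test_subthreshold_units_do_not_contribute(self, small_cfg):
        cfg = small_cfg
        v = np.full((12, 12, 8), cfg.c_ig * 0.9)
        lam, gam, zet, *_ = lateral_terms(v, v, np.zeros_like(v),
                                          mt_kernels(cfg), cfg.directions(),
                                          cfg)
        assert lam.max() == 0.0 and gam.max() == 0.0 and zet.max() == 0.0

    def test_uniform_single_direction_silences_opposite_surround(self,
                                                                 small_cfg):
        cfg = small_cfg
        v_sg = np.zeros((12, 12, 8))
        v_sg[..., 1] = 0.5
        z = np.zeros_like(v_sg)
        *_, chi_e, chi_i = lateral_terms(z, z, v_sg, mt_kernels(cfg),
                                         cfg.directions(), cfg)
        assert chi_e[..., 1].max() > 0.0
        assert chi_i[..., 1].max() == 0.0  # opposite slice empty

    def test_empty_history_rejected(self, small_cfg):
        cfg = small_cfg
        z = np.zeros((12, 12, 8))
        with pytest.raises(ValueError):
            lateral_terms(z, None, z, mt_kernels(cfg), cfg.directions(), cfg)


class TestStepping:
    def test_zero_input_zero_state_is_fixed_point(self, small_cfg):
        cfg = small_cfg
        st = make_state(cfg)
        z = np.zeros((12, 12, 8))
        out = mt_step(st, z, z, z, cfg)
        assert out.v_ig.max() == 0.0 and out.v_sg.max() == 0.0

    def test_bounded_under_random_input(self, small_cfg):
        cfg = small_cfg
        rng = np.random.default_rng(cfg.seed)
        st = make_state(cfg)
        ker = mt_kernels(cfg)
        for _ in range(1000):
            v_cx = rng.uniform(0, 1, (12, 12, 8))
            v_es = rng.uniform(0, 1, (12, 12, 8))
            kap = rng.uniform(0, 1, (12, 12, 8))
            st = mt_step(st, v_cx, v_es, kap, cfg, ker)
        assert st.v_ig.min() >= 0.0 and st.v_ig.max() <= 1.0
        assert st.v_sg.min() >= 0.0 and st.v_sg.max() <= 1.0

    def test_nan_input_aborts_with_diagnostic(self, small_cfg):
        cfg = small_cfg
        st = make_state(cfg)
        bad = np.zeros((12, 12, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="integration"):
            mt_step(st, bad, np.zeros_like(bad), np.zeros_like(bad), cfg)

    def test_delay_buffer_length(self, small_cfg):
        st = make_state(small_cfg)
        assert len(st.history) == small_cfg.delay_steps == 10


class TestSimulate:
    def test_blank_movie_gives_identically_zero_trajectories(self, config):
        movie = StimulusMovie(np.ones((8, 24, 24)), 0.01)
        sim = simulate(movie, config, n_settle=40)
        assert sim.v_ig_final.max() == 0.0
        assert sim.v_sg_final.max() == 0.0
        assert sim.v_es_final.max() == 0.0
        assert sim.v_cx_final.max() == 0.0

    def test_deterministic(self, config):
        movie = StimulusMovie(np.ones((8, 16, 16)), 0.01)
        a = simulate(movie, config, n_settle=20)
        b = simulate(movie, config, n_settle=20)
        np.testing.assert_array_equal(a.v_ig_final, b.v_ig_final)

    def test_probe_off_grid_rejected(self, config):
        movie = StimulusMovie(np.ones((8, 16, 16)), 0.01)
        with pytest.raises(ValueError):
            simulate(movie, config, n_settle=5, probes=[(99, 0)])

    def test_propagation_extent_non_decreasing(self, pattern_timecourse):
        """Supra-threshold upward activity only grows during the run."""
        sim = pattern_timecourse["sim"]
        cfg = sim.config
        # probe trace is monotone non-decreasing (ratchet dynamics)
        for tr in sim.probe_traces.values():
            assert (np.diff(tr[:, 2]) >= -1e-12).all()

    def test_activity_bounds_on_real_run(self, pattern_timecourse):
        sim = pattern_timecourse["sim"]
        for arr in (sim.v_ig_final, sim.v_sg_final, sim.v_es_final,
                    sim.kappa_final):
            assert arr.min() >= 0.0 and arr.max() <= 1.0
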