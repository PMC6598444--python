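"""Crossing-bar stimulus rendering, occlusion, and contrast variants."""

import numpy as np
import pytest

from mtpattern.stimuli import (BarSpec, StimulusMovie, contrast_variant,
                               default_bars, occlude_intrinsic_terminators,
                               preset_movie, render_bar_frame,
                               render_crossing_bars)


def make_pair(c1=1.0, c2=1.0, **kw):
    b1, b2 = default_bars(**kw)
    import dataclasses
    return (dataclasses.replace(b1, contrast=c1),
            dataclasses.replace(b2, contrast=c2))


class TestRenderCrossingBars:
    def test_overlap_is_saturated_minimum(self):
        b1, b2 = make_pair()
        m = render_crossing_bars(b1, b2, (64, 64), 10, 0.01)
        # equal full-contrast bars: overlap pixels are black, same as bars
        assert m.frames.min() == 0.0
        ex = m.annotations["extrinsic"][0, 0]
        y, x = int(round(ex[0])), int(round(ex[1]))
        assert m.frames[0, y, x] == 0.0

    def test_extrinsic_annotation_moves_straight_up(self):
        b1, b2 = make_pair()
        m = render_crossing_bars(b1, b2, (64, 64), 20, 0.01)
        ex = m.annotations["extrinsic"][:, 0, :]
        assert np.all(np.diff(ex[:, 0]) > 0)          # y strictly increasing
        np.testing.assert_allclose(np.diff(ex[:, 1]), 0.0, atol=1e-9)

    def test_single_bar_degenerate_no_extrinsic(self):
        b1, b2 = make_pair(c2=0.0)
        m = render_crossing_bars(b1, b2, (64, 64), 10, 0.01)
        assert "extrinsic" not in m.annotations
        assert m.frames.min() == 0.0  # bar 1 still drawn

    def test_never_intersecting_bars_rejected(self):
        b1 = BarSpec(orientation=45.0, center=(10.0, 10.0), length=10.0)
        b2 = BarSpec(orientation=135.0, center=(54.0, 54.0), length=10.0,
                     direction=180.0)
        with pytest.raises(ValueError, match="extrinsic"):
            render_crossing_bars(b1, b2, (64, 64), 5, 0.01)

    def test_rigid_translation_integer_speed(self):
        # one lattice step per frame: each frame is the previous one shifted
        bar = BarSpec(orientation=90.0, direction=0.0, speed=100.0,
                      length=20.0, width=3.0, center=(32.0, 20.0))
        ghost = BarSpec(contrast=0.0, center=(32.0, 40.0))
        m = render_crossing_bars(bar, ghost, (64, 64), 6, 0.01)
        for k in range(1, 6):
            np.testing.assert_array_equal(m.frames[k, :, 1:],
                                          m.frames[k - 1, :, :-1])

    def test_mirror_symmetry(self):
        b1, b2 = make_pair()
        m = render_crossing_bars(b1, b2, (64, 64), 8, 0.01)
        mm = m.mirrored()
        np.testing.assert_array_equal(mm.frames, m.frames[:, :, ::-1])
        # mirroring twice restores the movie and its annotations
        np.testing.assert_allclose(mm.mirrored().frames, m.frames)


class TestOcclusion:
    def test_crop_hides_intrinsic_keeps_extrinsic(self):
        m = preset_movie("pattern")
        assert "intrinsic" not in m.annotations
        assert "extrinsic" in m.annotations
        ex = m.annotations["extrinsic"]
        assert (ex[..., 0] >= 0).all() and (ex[..., 0] < m.shape[0]).all()
        assert m.occluded_margin > 0

    def test_window_missing_extrinsic_rejected(self):
        b1, b2 = make_pair(length=60.0)
        full = render_crossing_bars(b1, b2, (64, 64), 10, 0.01)
        with pytest.raises(ValueError):
            occlude_intrinsic_terminators(full, (2, 12, 2, 12))

    def test_window_containing_intrinsic_rejected(self):
        b1, b2 = make_pair(length=30.0)
        full = render_crossing_bars(b1, b2, (64, 64), 10, 0.01)
        with pytest.raises(ValueError, match="intrinsic"):
            occlude_intrinsic_terminators(full, (4, 60, 4, 60))

    def test_interior_mask_geometry(self):
        m = preset_movie("pattern")
        mask = m.interior_mask()
        k = m.occluded_margin
        assert not mask[0].any() and not mask[:, 0].any()
        assert mask[k:-k, k:-k].all()


class TestContrastVariant:
    def test_low_contrast_bar_in_front_at_overlap(self):
        b1, b2 = make_pair()
        m = contrast_variant(b1, b2, 1.0, 0.4, (64, 64), 10, 0.01)
        ex = m.annotations["extrinsic"][0, 0]
        y, x = int(round(ex[0])), int(round(ex[1]))
        assert m.frames[0, y, x] == pytest.approx(0.6)

    def test_equal_contrast_reduces_to_plain_rendering(self):
        b1, b2 = make_pair()
        plain = render_crossing_bars(b1, b2, (64, 64), 8, 0.01)
        var = contrast_variant(b1, b2, 1.0, 1.0, (64, 64), 8, 0.01)
        np.testing.assert_array_equal(plain.frames, var.frames)

    def test_zero_contrast_gives_single_bar(self):
        b1, b2 = make_pair()
        m = contrast_variant(b1, b2, 1.0, 0.0, (64, 64), 8, 0.01)
        assert "extrinsic" not in m.annotations

    def test_both_zero_rejected(self):
        b1, b2 = make_pair()
        with pytest.raises(ValueError):
            contrast_variant(b1, b2, 0.0, 0.0)


class TestStimulusMovieValidation:
    def test_luminance_range_enforced(self):
        with pytest.raises(ValueError):
            StimulusMovie(np.full((3, 8, 8), 1.5))

    def test_minimum_two_frames(self):
        with pytest.raises(ValueError):
            StimulusMovie(np.ones((1, 8, 8)))

    def test_reversed_intensity(self):
        m = StimulusMovie(np.zeros((2, 4, 4)))
        np.testing.assert_allclose(m.reversed_intensity(), 1.0)

    def test_bar_spec_validation(self):
        with pytest.raises(ValueError):
            BarSpec(speed=0.0)
        with pytest.raises(ValueError):
            BarSpec(contrast=1.5)
        with pytest.raises(ValueError):
            BarSpec(orientation=200.0)
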