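"""Frame selection, ΔA, M-mode excursion and B-mode apex displacement."""

import numpy as np
import pytest

from diamotion import (
    Bounds,
    BreathCycle,
    CineClip,
    Contour,
    DomeModel,
    RenderConfig,
    ScanLine,
    b_mode_apex_displacement,
    delta_area,
    dome_contour,
    m_mode_excursion,
    render_cine,
    select_extreme_frames,
)


def flat_contours(depths, frame0=0):
    return [
        Contour(points=np.array([[0.0, d], [5.0, d], [10.0, d]]), frame_index=i)
        for i, d in enumerate(depths, start=frame0)
    ]


class TestSelectExtremeFrames:
    def test_monotone_caudal_drift(self, bounds):
        contours = flat_contours([4.0, 5.0, 6.0, 7.0])
        assert select_extreme_frames(bounds, contours) == (3, 0)

    def test_single_breath_extremes_at_phase_peaks(self, bounds):
        phases = 0.5 * (1 - np.cos(2 * np.pi * np.arange(9) / 8))
        contours = flat_contours(4.0 + 2.0 * phases)
        i_max, i_min = select_extreme_frames(bounds, contours)
        assert i_max == 4  # phase 1 at mid-clip
        assert i_min == 0  # tie (phase 0 at both ends) breaks earliest

    def test_constant_clip_warns_and_returns_first_frame(self, bounds):
        with pytest.warns(UserWarning, match="no diaphragm motion"):
            assert select_extreme_frames(bounds, flat_contours([5.0, 5.0, 5.0])) == (0, 0)


class TestDeltaArea:
    def test_piston_is_width_times_displacement(self, bounds):
        res = delta_area(bounds, flat_contours([4.0, 6.0]))
        assert res.delta_area == pytest.approx(20.0, rel=1e-12)
        assert res.area_max_contraction == pytest.approx(60.0, rel=1e-12)
        assert res.frame_max == 1 and res.frame_min == 0

    def test_zero_motion_gives_zero(self, bounds):
        with pytest.warns(UserWarning):
            res = delta_area(bounds, flat_contours([5.0, 5.0]))
        assert res.delta_area == 0.0

    def test_delta_area_invariants(self, bounds):
        res = delta_area(bounds, flat_contours([4.0, 5.5, 4.8]))
        assert res.delta_area == pytest.approx(
            res.area_max_contraction - res.area_min_contraction
        )
        assert res.delta_area >= 0

    def test_invariant_under_vertical_translation(self, bounds):
        base = [4.0, 5.5, 4.8]
        d0 = delta_area(bounds, flat_contours(base)).delta_area
        d1 = delta_area(bounds, flat_contours([d + 2.0 for d in base])).delta_area
        assert d0 == pytest.approx(d1, rel=1e-12)

    def test_scales_linearly_with_window_width_for_piston(self):
        for w in (5.0, 10.0, 20.0):
            contours = [
                Contour(points=np.array([[0.0, d], [w / 2, d], [w, d]]))
                for d in (4.0, 6.0)
            ]
            res = delta_area(Bounds(w, 12.0), contours)
            assert res.delta_area == pytest.approx(2.0 * w, rel=1e-12)

    def test_frame_order_does_not_change_delta_area(self, bounds, dome_model):
        phases = np.linspace(0, 1, 7)
        contours = [dome_contour(dome_model, p) for p in phases]
        d0 = delta_area(bounds, contours).delta_area
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = rng.permutation(len(contours))
            d1 = delta_area(bounds, [contours[i] for i in perm]).delta_area
            assert d1 == pytest.approx(d0, rel=1e-12)

    def test_monotone_in_amplitude(self, dome_model):
        deltas = []
        for amp in (1.0, 2.0, 4.0, 6.0, 9.0):
            m = dome_model.with_amplitude(amp)
            contours = [dome_contour(m, p) for p in (0.0, 0.5, 1.0)]
            deltas.append(delta_area(m.bounds, contours).delta_area)
        assert all(a < b for a, b in zip(deltas, deltas[1:]))


class TestMModeExcursion:
    @staticmethod
    def _synthetic_clip(depths_cm, n_rows=160, n_cols=120, spacing=0.05):
        """Bright horizontal band at the given depth per frame."""
        rows = (np.arange(n_rows) + 0.5) * spacing
        frames = [
            0.1 + np.exp(-0.5 * ((rows[:, None] - d) / 0.1) ** 2)
            * np.ones((1, n_cols))
            for d in depths_cm
        ]
        return CineClip(np.stack(frames).astype(np.float32),
                        spacing=(spacing, spacing))

    def test_sinusoidal_depth_gives_twice_amplitude(self):
        a, d0 = 1.5, 4.0
        t = np.linspace(0, 2 * np.pi, 16)
        clip = self._synthetic_clip(d0 + a * np.sin(t))
        res = m_mode_excursion(clip, ScanLine.vertical(3.0))
        assert res.excursion == pytest.approx(2 * a, abs=clip.spacing[0])

    def test_static_clip_gives_zero(self):
        clip = self._synthetic_clip([4.0, 4.0, 4.0])
        res = m_mode_excursion(clip, ScanLine.vertical(3.0))
        assert res.excursion == pytest.approx(0.0, abs=1e-6)

    def test_speckled_phantom_recovered_within_one_pixel(self):
        model = DomeModel(amplitude=3.0)
        clip, truth = render_cine(
            model, BreathCycle(), RenderConfig(speckle_strength=0.25, seed=4)
        )
        res = m_mode_excursion(clip, ScanLine.vertical(truth.mmode_line_x))
        assert res.excursion == pytest.approx(
            truth.mmode_excursion, abs=clip.spacing[0]
        )

    def test_invisible_diaphragm_rejected(self):
        rng = np.random.default_rng(0)
        frames = 0.4 + 0.02 * rng.standard_normal((6, 160, 120))
        clip = CineClip(frames.astype(np.float32), spacing=(0.05, 0.05))
        with pytest.raises(ValueError, match="not visualized"):
            m_mode_excursion(clip, ScanLine.vertical(3.0))

    def test_line_missing_the_image_rejected(self, rendered_clip):
        _, clip, _ = rendered_clip
        with pytest.raises(ValueError, match="does not intersect"):
            m_mode_excursion(clip, ScanLine(origin=(-5.0, -5.0),
                                            direction=(0.0, -1.0)))


class TestBModeApexDisplacement:
    def test_rigid_translation_displacement_equals_shift(self, dome_model):
        contours = [dome_contour(dome_model, p) for p in (0.0, 1.0)]
        res = b_mode_apex_displacement(dome_model.bounds, contours)
        assert res.displacement == pytest.approx(dome_model.amplitude, rel=1e-9)

    def test_static_contours_give_zero(self, dome_model):
        contours = [dome_contour(dome_model, 0.5)] * 3
        res = b_mode_apex_displacement(dome_model.bounds, contours)
        assert res.displacement == 0.0

    def test_apex_near_top_border_warns(self, bounds):
        near_top = Contour(
            points=np.array([[0, 3], [5, 0.01], [10, 3.0]]), spacing=(0.05, 0.05)
        )
        low = Contour(
            points=np.array([[0, 5], [5, 3.0], [10, 5.0]]), spacing=(0.05, 0.05)
        )
        with pytest.warns(UserWarning, match="apex clipped"):
            b_mode_apex_displacement(bounds, [near_top, low])


class TestPistonAgreement:
    def test_all_three_methods_agree_for_piston(self):
        """Pure piston: ΔA/width = M-mode excursion = apex displacement."""
        model = DomeModel(window_width=10.0, window_depth=12.0, chord=10.0,
                          apex_height=0.0, baseline_depth=5.0, amplitude=2.0)
        clip, truth = render_cine(model, BreathCycle(), RenderConfig())
        from diamotion import detect_contours

        contours = detect_contours(clip)
        px = clip.spacing[0]
        da = delta_area(clip, contours).delta_area / model.window_width
        mm = m_mode_excursion(clip, ScanLine.vertical(truth.mmode_line_x)).excursion
        bm = b_mode_apex_displacement(clip, contours).displacement
        assert abs(da - mm) <= px
        assert abs(mm - bm) <= px
        assert da == pytest.approx(model.amplitude, abs=px)
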