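import numpy as np
import pytest

from scatterbmd.phantom import (
    MaterialSpec,
    PhantomSpec,
    ScanParams,
    default_qrm_efp,
)
from scatterbmd.simulate import (
    HU_MAX,
    HU_MIN,
    StreakParams,
    _draw_streaks,
    expected_streak_count,
    render_base_image,
    render_streak_artifacts,
    simulate_stack,
)


class TestBaseImage:
    def test_material_placement(self, qrm50, small_scan):
        base = render_base_image(qrm50, small_scan)
        n = small_scan.matrix_size
        # insert at the center (50 mg HA -> 70 HU), air at the corner
        assert base.pixels[n // 2, n // 2] == 70
        assert base.pixels[0, 0] == -1000
        # wall midline pixel: radius outer - wall/2 = 9.4 mm along +x
        offset = round(9.4 / small_scan.pixel_spacing_mm)
        assert base.pixels[n // 2, n // 2 + offset] == 1120

    def test_body_is_water(self, qrm50, small_scan):
        base = render_base_image(qrm50, small_scan)
        n = small_scan.matrix_size
        # between periosteal surface (10 mm) and body edge (20 mm)
        offset = round(15.0 / small_scan.pixel_spacing_mm)
        assert base.pixels[n // 2, n // 2 + offset] == 0

    def test_deterministic(self, qrm50, small_scan):
        a = render_base_image(qrm50, small_scan)
        b = render_base_image(qrm50, small_scan)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_phantom_must_fit_fov(self, qrm50):
        small_fov = ScanParams(matrix_size=64, pixel_spacing_mm=0.25)  # 16 mm
        with pytest.raises(ValueError):
            render_base_image(qrm50, small_fov)

    def test_hu_range_respected(self, qrm50, small_scan):
        base = render_base_image(qrm50, small_scan)
        assert base.pixels.min() >= HU_MIN and base.pixels.max() <= HU_MAX


class TestStreakRendering:
    def test_negligible_density_yields_base_image(self, small_scan):
        phantom = default_qrm_efp(0.0, trabecular_rho_e=1e-9)
        params = StreakParams(gain=10.0, seed=3)
        base = render_base_image(phantom, small_scan)
        out = render_streak_artifacts(base, phantom, small_scan, params)
        # gain * I_s rounds to zero streaks: legal, image unchanged
        assert expected_streak_count(phantom, small_scan, params) == 0
        np.testing.assert_array_equal(out.pixels, base.pixels)

    def test_same_seed_same_image(self, qrm50, small_scan):
        params = StreakParams(gain=10.0, seed=11)
        base = render_base_image(qrm50, small_scan)
        a = render_streak_artifacts(base, qrm50, small_scan, params)
        b = render_streak_artifacts(base, qrm50, small_scan, params)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_streak_count_follows_scatter_model(self, small_scan):
        # interior radius 1 cm, explicit mu 0.2 and rho_e 2, S = 3:
        # I_s = 2 * 3 * e^-0.2 = 4.9124 -> 49 streaks at gain 10
        phantom = PhantomSpec(
            outer_radius_mm=11.2,
            cortical_wall_mm=1.2,
            trabecular=MaterialSpec("custom", rho_e=2.0, mu=0.2),
        )
        scan = ScanParams(
            matrix_size=128, pixel_spacing_mm=0.5, s_per_electron=3.0
        )
        params = StreakParams(gain=10.0)
        assert expected_streak_count(phantom, scan, params) == 49
        base = render_base_image(phantom, scan)
        _, angles = _draw_streaks(
            base.pixels, phantom, scan, params, np.random.default_rng(0)
        )
        assert len(angles) == 49
        assert len(np.unique(angles)) == 49

    def test_interior_untouched(self, qrm50, small_scan):
        params = StreakParams(gain=50.0, seed=5)
        base = render_base_image(qrm50, small_scan)
        out = render_streak_artifacts(base, qrm50, small_scan, params)
        n = small_scan.matrix_size
        yy, xx = np.mgrid[0:n, 0:n]
        r_mm = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) * small_scan.pixel_spacing_mm
        inside = r_mm <= qrm50.outer_radius_mm
        np.testing.assert_array_equal(out.pixels[inside], base.pixels[inside])
        # and something was drawn outside
        assert (out.pixels != base.pixels).any()

    def test_output_hu_clamped(self, qrm50, small_scan):
        params = StreakParams(gain=80.0, seed=9)
        base = render_base_image(qrm50, small_scan)
        out = render_streak_artifacts(base, qrm50, small_scan, params)
        assert out.pixels.min() >= HU_MIN and out.pixels.max() <= HU_MAX


class TestSimulateStack:
    def test_stack_length_and_indices(self, qrm50, small_scan, streaks):
        stack = simulate_stack(qrm50, small_scan, streaks, n_slices=40, seed=1)
        assert len(stack) == 40
        assert [sl.slice_index for sl in stack] == list(range(40))

    def test_invalid_slice_count(self, qrm50, small_scan, streaks):
        with pytest.raises(ValueError):
            simulate_stack(qrm50, small_scan, streaks, n_slices=0, seed=1)

    def test_master_seed_reproducibility(self, qrm50, small_scan, streaks):
        a = simulate_stack(qrm50, small_scan, streaks, n_slices=4, seed=42)
        b = simulate_stack(qrm50, small_scan, streaks, n_slices=4, seed=42)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)

    def test_seeds_change_streaks_not_base(self, qrm50, small_scan, streaks):
        a = simulate_stack(qrm50, small_scan, streaks, n_slices=2, seed=1)
        b = simulate_stack(qrm50, small_scan, streaks, n_slices=2, seed=2)
        assert any((sa.pixels != sb.pixels).any() for sa, sb in zip(a, b))
        base = render_base_image(qrm50, small_scan)
        n = small_scan.matrix_size
        yy, xx = np.mgrid[0:n, 0:n]
        r_mm = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2) * small_scan.pixel_spacing_mm
        inside = r_mm <= qrm50.outer_radius_mm
        for sl in (*a, *b):
            np.testing.assert_array_equal(sl.pixels[inside], base.pixels[inside])

    def test_mean_count_monotone_in_electron_density(self, small_scan):
        # expected artifact abundance rises with rho_e, averaged over seeds
        from scatterbmd.pipeline import count_artifact_pixels

        params = StreakParams(gain=10.0)
        means = []
        for rho_e in (1.0, 1.3):
            phantom = default_qrm_efp(0.0, trabecular_rho_e=rho_e)
            totals = []
            for seed in range(5):
                stack = simulate_stack(phantom, small_scan, params, 5, seed=seed)
                totals.append(sum(count_artifact_pixels(stack, 500)))
            means.append(np.mean(totals))
        assert means[1] > means[0]
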