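"""Imaging tests: calibration, skin suppression, DAS reconstruction, slicing."""

import numpy as np
import pytest

from radarperm import (
    DASReconstructor,
    GridSpec,
    ImageGrid,
    Phantom,
    Pulse,
    RadarScan,
    Scatterer,
    circular_array,
    das_reconstruct,
    simulate_scan,
    slice_image,
    subtract_calibration,
    suppress_skin,
)


class TestSubtractCalibration:
    def test_identical_traces_cancel(self, noiseless_scan):
        scan = RadarScan(
            array=noiseless_scan.array,
            time_axis=noiseless_scan.time_axis,
            traces=noiseless_scan.traces,
            calibration_traces=noiseless_scan.traces.copy(),
        )
        out = subtract_calibration(scan)
        assert np.all(out.traces == 0)
        assert out.calibration_traces is None

    def test_empty_phantom_residual_far_below_skin_echo(self):
        # empty-scanner reflections cancel; what remains is the skin echo
        arr = circular_array(6, 52.0)
        scan = simulate_scan(Phantom(), arr, Pulse(), noise_level=0.0)
        out = subtract_calibration(scan)
        skinless = simulate_scan(Phantom(), arr, Pulse(), noise_level=0.0,
                                 skin_echo_amplitude=0.0)
        residual = subtract_calibration(skinless)
        assert (
            np.sqrt(np.mean(residual.traces**2))
            < 1e-6 * np.sqrt(np.mean(out.traces**2))
        )

    def test_missing_calibration_rejected(self, processed_scan):
        with pytest.raises(ValueError):
            subtract_calibration(processed_scan)


class TestSuppressSkin:
    def test_identical_traces_nearly_cancelled_in_window(self):
        # skin echo only: every trace identical, so the neighbour average
        # reproduces the target and the window residual is ~0
        arr = circular_array(8, 52.0)
        scan = subtract_calibration(
            simulate_scan(Phantom(), arr, Pulse(), noise_level=0.0)
        )
        out = suppress_skin(scan)
        from radarperm.imaging import _skin_window

        start, stop = _skin_window(scan.traces[0], 9, 0.1)
        assert np.abs(out.traces[:, start:stop]).max() < 1e-10
        # the tapered margins keep only the echo's negligible tails
        assert np.abs(out.traces).max() < 1e-2 * np.abs(scan.traces).max()

    def test_samples_after_window_untouched(self, single_phantom):
        scan = subtract_calibration(
            simulate_scan(single_phantom, circular_array(8, 52.0), Pulse(),
                          noise_level=0.0)
        )
        out = suppress_skin(scan)
        late = scan.time_axis > 0.3e-9  # beyond the skin window + pad
        np.testing.assert_array_equal(out.traces[:, late], scan.traces[:, late])

    def test_skin_energy_cut_while_scatterer_echo_retained(self, single_phantom):
        # oracle: the same simulation with the skin echo toggled off
        arr = circular_array(20, 52.0)
        with_skin = subtract_calibration(
            simulate_scan(single_phantom, arr, Pulse(), noise_level=0.0)
        )
        without_skin = subtract_calibration(
            simulate_scan(single_phantom, arr, Pulse(), noise_level=0.0,
                          skin_echo_amplitude=0.0)
        )
        filtered = suppress_skin(with_skin)
        skin_before = with_skin.traces - without_skin.traces
        skin_after = filtered.traces - without_skin.traces
        assert np.sum(skin_after**2) < np.sum(skin_before**2) / 10.0
        peak_true = np.abs(without_skin.traces).max()
        peak_kept = np.abs(
            filtered.traces[np.abs(without_skin.traces) > 0.5 * peak_true]
        ).max()
        assert peak_kept > peak_true / np.sqrt(2)  # within 3 dB

    def test_too_few_traces_rejected(self, noiseless_scan):
        small = RadarScan(
            array=circular_array(3, 52.0),
            time_axis=noiseless_scan.time_axis,
            traces=noiseless_scan.traces[:3],
        )
        with pytest.raises(ValueError):
            suppress_skin(small, k_neighbors=4)


class TestDASReconstruct:
    def test_zero_traces_give_zero_image(self, processed_scan, single_phantom):
        zero = RadarScan(
            array=processed_scan.array,
            time_axis=processed_scan.time_axis,
            traces=np.zeros_like(processed_scan.traces),
        )
        img = das_reconstruct(zero, GridSpec(), 2.5, 25.0, single_phantom)
        assert np.all(img.intensities == 0)

    def test_argmax_near_scatterer_at_true_permittivities(
        self, reconstructor
    ):
        img = reconstructor.reconstruct(2.5, 25.0)
        assert np.linalg.norm(img.argmax_position() - [25.0, 0.0]) <= 5.0

    def test_masked_exterior_pixels_exactly_zero(self, reconstructor, single_phantom):
        img = reconstructor.reconstruct(2.5, 25.0)
        assert np.all(img.intensities[~img.mask] == 0)
        # mask is the interior of the skin contour
        x = img.pixel_centers(0)
        r = np.hypot(x[:, None], x[None, :])
        np.testing.assert_array_equal(img.mask, r < single_phantom.interior_radius)

    def test_linear_in_traces(self, processed_scan, single_phantom):
        gs = GridSpec(extent=50.0, spacing=2.0)
        rng = np.random.default_rng(0)
        other = RadarScan(
            array=processed_scan.array,
            time_axis=processed_scan.time_axis,
            traces=rng.normal(size=processed_scan.traces.shape),
        )
        combo = RadarScan(
            array=processed_scan.array,
            time_axis=processed_scan.time_axis,
            traces=3.0 * processed_scan.traces + other.traces,
        )
        i1 = das_reconstruct(processed_scan, gs, 2.5, 25.0, single_phantom)
        i2 = das_reconstruct(other, gs, 2.5, 25.0, single_phantom)
        i3 = das_reconstruct(combo, gs, 2.5, 25.0, single_phantom)
        np.testing.assert_allclose(
            i3.intensities, 3.0 * i1.intensities + i2.intensities, atol=1e-12
        )

    def test_matched_permittivity_maximises_peak_height(self, reconstructor):
        # matched-filter property: forward and reconstruction speeds agree
        peaks = {
            eps: np.abs(reconstructor.reconstruct(eps, 25.0).intensities).max()
            for eps in [1.5, 2.0, 2.5, 3.0, 4.0, 6.0]
        }
        assert max(peaks, key=peaks.get) == 2.5

    def test_wrong_permittivity_broadens_and_lowers_response(self, reconstructor):
        good = reconstructor.reconstruct(2.5, 25.0)
        bad = reconstructor.reconstruct(7.5, 25.0)  # 3x the true value
        assert np.abs(bad.intensities).max() < np.abs(good.intensities).max()
        # breadth: pixel count above half the image's own peak
        area = lambda im: np.sum(
            np.abs(im.intensities) > 0.5 * np.abs(im.intensities).max()
        )
        assert area(bad) > area(good)

    def test_permittivity_below_one_rejected(self, reconstructor):
        with pytest.raises(ValueError):
            reconstructor.reconstruct(0.5, 25.0)


class TestSliceImage:
    @staticmethod
    def _volume():
        data = np.zeros((10, 10, 10))
        data[3, 4, 5] = 1.0
        return ImageGrid(
            intensities=data,
            origin=np.array([-5.0, -5.0, -5.0]),
            pixel_spacing=np.ones(3),
            mask=np.ones_like(data, dtype=bool),
        )

    def test_slice_through_peak_plane(self):
        vol = self._volume()
        # z centre of voxel index 5 is -5 + 5.5 = 0.5
        sl = slice_image(vol, axis=2, coordinate=0.5)
        assert sl.ndim == 2
        idx = np.unravel_index(np.argmax(sl.intensities), sl.intensities.shape)
        assert idx == (3, 4)

    def test_constant_volume_slices_constant(self):
        vol = self._volume()
        vol.intensities[:] = 2.0
        sl = slice_image(vol, axis=0, coordinate=0.0)
        assert np.all(sl.intensities == 2.0)

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(ValueError):
            slice_image(self._volume(), axis=2, coordinate=40.0)

    def test_2d_input_rejected(self, reconstructor):
        img = reconstructor.reconstruct(2.5, 25.0)
        with pytest.raises(ValueError):
            slice_image(img, axis=0, coordinate=0.0)
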