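"""Volumes, PSF simulation, convolution oracle, Wiener and Gold deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holovol import (
    OpticalConfig,
    Volume3D,
    build_measured_volume,
    convolve3d,
    gold_deconvolve,
    simulate_psf,
    wiener_deconvolve,
)
from holovol.deconv import GOLD_ITER_CAP, InvalidVolume, match_minmax
from holovol.simulate import make_beads, render_field

CFG = OpticalConfig()
PITCH = CFG.highres_pitch


def _vol(data, z0=0.0, dz=1.0, mode="amplitude", pitch=1.0):
    nz = data.shape[0]
    return Volume3D(data, pitch, z0 + dz * np.arange(nz), mode)


def _delta_psf(shape, pitch=1.0):
    d = np.zeros(shape)
    d[shape[0] // 2, shape[1] // 2, shape[2] // 2] = 1.0
    return _vol(d, pitch=pitch)


def _direct_circular_convolve(obj, kern_centered):
    """Triple-loop direct-sum circular convolution oracle (origin at centre)."""
    nz, ny, nx = obj.shape
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    out = np.zeros_like(obj, dtype=float)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                acc = 0.0
                for w in range(nz):
                    for v in range(ny):
                        for u in range(nx):
                            acc += (
                                obj[w, v, u]
                                * kern_centered[(z - w + cz) % nz, (y - v + cy) % ny, (x - u + cx) % nx]
                            )
                out[z, y, x] = acc
    return out


class TestVolume3D:
    def test_non_uniform_z_rejected(self, rng):
        with pytest.raises(InvalidVolume):
            Volume3D(rng.random((3, 4, 4)), 1.0, [0.0, 1.0, 3.0])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidVolume):
            Volume3D(-np.ones((2, 4, 4)), 1.0, [0.0, 1.0], "amplitude")


class TestBuildMeasuredVolume:
    def test_single_z_matches_plain_backpropagation(self, rng):
        from holovol.wave import ComplexField2D, propagate_array

        data = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        holo = ComplexField2D(data, PITCH, CFG.wavelength)
        vol = build_measured_volume(holo, [500.0], mode="complex")
        direct = propagate_array(data, PITCH, CFG.wavelength, -500.0)
        assert np.allclose(vol.data[0], direct)

    def test_bead_focus_plane_holds_global_maximum(self):
        """With DC background removed, the scattered amplitude peaks at the
        bead's focus plane of the stack (reference geometry: 721 um)."""
        scene = make_beads(1, 2.0, [721.0], seed=5, shape=(128, 128), pitch=PITCH)
        holo = render_field(scene, CFG, 800.0)
        # plane depths are relative to the detector at 800; bead focus at 721
        z = np.arange(661.0, 781.0 + 1e-9, 10.0)
        vol = build_measured_volume(holo, z, mode="amplitude", background="dc")
        k_max = int(np.argmax(vol.data)) // (128 * 128)
        assert z[k_max] == pytest.approx(721.0, abs=vol.z_step)


@pytest.fixture(scope="module")
def psf():
    return simulate_psf(CFG, (64, 64), np.arange(650.0, 770.0 + 1e-9, 10.0))


class TestSimulatePSF:
    def test_total_magnitude_normalized(self, psf):
        assert np.sum(np.abs(psf.data)) == pytest.approx(1.0, abs=1e-12)

    def test_central_plane_peaks_at_lateral_centre(self, psf):
        nz, ny, nx = psf.shape
        plane = np.abs(psf.data[nz // 2])
        assert np.unravel_index(int(np.argmax(plane)), plane.shape) == (ny // 2, nx // 2)

    def test_axial_profile_maximal_at_central_plane(self, psf):
        nz, ny, nx = psf.shape
        axial = np.abs(psf.data[:, ny // 2, nx // 2])
        assert axial[nz // 2] > axial[0] and axial[nz // 2] > axial[-1]

    def test_centre_of_mass_within_one_voxel_of_centre(self, psf):
        from scipy import ndimage

        com = ndimage.center_of_mass(np.abs(psf.data))
        centre = tuple(s // 2 for s in psf.shape)
        assert all(abs(c - g) <= 1.0 for c, g in zip(com, centre))

    def test_mismatched_source_kind_rejected(self):
        with pytest.raises(InvalidVolume):
            simulate_psf(CFG, (16, 16), [1.0, 2.0], source_kind="laser")


class TestConvolve3D:
    def test_delta_kernel_is_identity(self, rng):
        obj = _vol(rng.random((4, 8, 8)))
        out = convolve3d(obj, _delta_psf((4, 8, 8)))
        assert np.allclose(out.data, obj.data, atol=1e-12)

    def test_matches_direct_sum_oracle(self, rng):
        obj = rng.random((4, 8, 8))
        kern = rng.random((4, 8, 8))
        kern /= kern.sum()
        out = convolve3d(_vol(obj), _vol(kern))
        expect = _direct_circular_convolve(obj, kern)
        assert np.linalg.norm(out.data - expect) / np.linalg.norm(expect) < 1e-10

    def test_normalized_kernel_preserves_constants(self, rng):
        obj = _vol(np.ones((4, 8, 8)))
        kern = rng.random((4, 8, 8))
        kern /= kern.sum()
        out = convolve3d(obj, _vol(kern))
        assert np.allclose(out.data, 1.0, atol=1e-10)

    def test_padded_mode_emulates_linear_convolution(self):
        obj = np.zeros((4, 8, 8))
        obj[0, 0, 0] = 1.0  # mass at the corner wraps circularly, not linearly
        kern = np.zeros((4, 8, 8))
        kern[2, 4, 4] = 0.5
        kern[1, 3, 4] = 0.5  # offset (-1,-1,0) from centre
        circ = convolve3d(_vol(obj), _vol(kern), pad=False)
        lin = convolve3d(_vol(obj), _vol(kern), pad=True)
        assert circ.data[3, 7, 0] == pytest.approx(0.5)  # wrapped
        assert lin.data[3, 7, 0] == pytest.approx(0.0)  # suppressed by padding
        assert lin.data[0, 0, 0] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(InvalidVolume):
            convolve3d(_vol(rng.random((4, 8, 8))), _vol(rng.random((4, 6, 6))))


class TestWiener:
    def test_delta_kernel_scales_by_one_over_one_plus_beta(self, rng):
        M = _vol(rng.random((4, 8, 8)) + 0.5)
        out = wiener_deconvolve(M, _delta_psf((4, 8, 8)), beta=0.25)
        assert np.allclose(out.data, M.data / 1.25, atol=1e-12)

    def test_noiseless_forward_then_invert_recovers_object(self, rng):
        """Forward-convolve a random 16x16x8 volume, invert with tiny beta."""
        O_true = rng.random((8, 16, 16)) + 0.5
        kern = np.zeros((8, 16, 16))
        kern[4, 8, 8] = 1.0
        kern += 0.3 * rng.random((8, 16, 16))
        kern /= kern.sum()
        psf = _vol(kern)
        spectrum = np.abs(np.fft.fftn(kern))
        assert spectrum.min() > 1e-6  # well-conditioned by construction
        M = convolve3d(_vol(O_true), psf)
        out = wiener_deconvolve(M, psf, beta=1e-12)
        assert np.linalg.norm(out.data - O_true) / np.linalg.norm(O_true) < 1e-6

    def test_reference_operating_point_accepted(self, rng):
        M = _vol(rng.random((4, 8, 8)))
        out = wiener_deconvolve(M, _delta_psf((4, 8, 8)), beta=0.001)
        assert np.all(np.isfinite(out.data))

    def test_beta_zero_with_singular_spectrum_rejected(self):
        kern = np.zeros((4, 8, 8))
        kern[2, 4, 4] = 0.5
        kern[2, 4, 5] = 0.5  # two-point kernel: spectral zeros
        M = _vol(np.ones((4, 8, 8)))
        with pytest.raises(InvalidVolume, match="beta"):
            wiener_deconvolve(M, _vol(kern), beta=0.0)


class TestGold:
    def test_delta_kernel_fixed_point(self, rng):
        M_data = rng.random((4, 8, 8)) + 0.5
        M = _vol(M_data)
        out, residuals = gold_deconvolve(M, _delta_psf((4, 8, 8)), beta=1e-6, n_iter=1)
        tol = 1e-6 / float(M_data.min() ** 2)
        assert np.all(np.abs(out.data - M_data) / M_data <= tol)
        assert residuals[0] == pytest.approx(0.0, abs=1e-12)

    def test_nonnegativity_preserved(self, rng):
        M = _vol(rng.random((4, 8, 8)))
        kern = rng.random((4, 8, 8))
        kern /= kern.sum()
        out, _ = gold_deconvolve(M, _vol(kern), beta=0.001, n_iter=5)
        assert np.all(out.data >= 0)

    def test_minmax_matching_idempotent(self, rng):
        ref = rng.random((3, 6, 6)) * 4.0
        v = rng.random((3, 6, 6))
        matched = match_minmax(v, ref)
        assert np.allclose(match_minmax(matched, ref), matched, atol=1e-12)
        assert matched.min() == pytest.approx(ref.min())
        assert matched.max() == pytest.approx(ref.max())

    def test_minmax_matching_preserves_phase(self, rng):
        ref = rng.random((2, 4, 4)) + 0.5
        v = (rng.random((2, 4, 4)) + 0.5) * np.exp(1j * rng.random((2, 4, 4)))
        matched = match_minmax(v, ref)
        assert np.allclose(np.angle(matched), np.angle(v), atol=1e-12)

    def test_excessive_iterations_warn(self, rng):
        M = _vol(rng.random((2, 4, 4)) + 0.5)
        with pytest.warns(UserWarning, match="over-fit"):
            gold_deconvolve(M, _delta_psf((2, 4, 4)), beta=0.01, n_iter=GOLD_ITER_CAP + 1)

    def test_residual_history_recorded_per_iteration(self, rng):
        M = _vol(rng.random((2, 4, 4)) + 0.5)
        kern = rng.random((2, 4, 4))
        kern /= kern.sum()
        _, residuals = gold_deconvolve(M, _vol(kern), beta=0.001, n_iter=7)
        assert len(residuals) == 7 and np.all(np.isfinite(residuals))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_minmax_matching_idempotence_property(seed):
    r = np.random.default_rng(seed)
    ref = r.random((2, 3, 3)) * (1 + r.random())
    v = r.random((2, 3, 3))
    m1 = match_minmax(v, ref)
    assert np.allclose(match_minmax(m1, ref), m1, atol=1e-12)
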