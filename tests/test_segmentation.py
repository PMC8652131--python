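"""Directional ridge filtering and string extraction on toy images."""

import numpy as np
import pytest

from vwfstrings import build_kernel_bank, count_long_strings, directional_response, extract_strings
from vwfstrings.segmentation import (
    StringRecord,
    angular_deviation_deg,
    ridge_kernel,
    skeleton_chain_length_px,
)


def _line_image(shape=(64, 64), row=32, x0=8, x1=56, value=100.0):
    img = np.zeros(shape)
    img[row, x0:x1] = value
    return img


def test_single_orientation_bank_sits_at_flow_angle():
    bank = build_kernel_bank(12.5, n_orientations=1, max_deviation_deg=0.0)
    assert bank.orientations_deg == [12.5]
    bank7 = build_kernel_bank(0.0, n_orientations=7, max_deviation_deg=15.0)
    assert len(bank7.kernels) == 7
    assert bank7.orientations_deg[0] == -15.0 and bank7.orientations_deg[-1] == 15.0


def test_kernels_give_zero_response_on_constant_image():
    bank = build_kernel_bank(0.0)
    flat = np.full((64, 64), 37.0)
    resp = directional_response(flat, bank)
    assert np.allclose(resp, 0.0, atol=1e-9)


def test_isotropic_bank_rejected():
    with pytest.raises(ValueError):
        build_kernel_bank(0.0, length_px=3, width_px=3.0)


def test_aligned_line_outresponds_perpendicular_line():
    k = ridge_kernel(0.0, 21, 1.5)
    horiz = _line_image()
    vert = horiz.T.copy()
    from scipy.signal import fftconvolve

    r_h = fftconvolve(horiz, k, mode="same")[32, 32]
    r_v = fftconvolve(vert, k, mode="same")[32, 32]
    assert r_h / max(r_v, 1e-12) > 3


def test_response_peaks_on_line_not_off_line():
    bank = build_kernel_bank(0.0)
    img = _line_image()
    resp = directional_response(img, bank)
    on_line = resp[32, 16:48].min()
    off = np.delete(resp, np.s_[28:37], axis=0).max()
    assert on_line > off


def test_blob_suppressed_relative_to_line_of_equal_peak():
    # agglomerate-suppression mechanism: a wide isotropic blob responds far
    # less than a line of the same peak intensity
    bank = build_kernel_bank(0.0)
    yy, xx = np.mgrid[:64, :64]
    blob = 100.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 8.0**2))
    line = _line_image()
    assert directional_response(blob, bank).max() < 0.5 * directional_response(line, bank).max()


def test_rotating_line_monotonically_loses_response():
    from skimage.transform import rotate

    bank = build_kernel_bank(0.0)
    img = _line_image()
    peaks = []
    for ang in (0, 15, 30, 60, 90):
        rot = rotate(img, ang, preserve_range=True)
        peaks.append(directional_response(rot, bank).max())
    assert all(a > b for a, b in zip(peaks, peaks[1:]))


def test_blank_response_yields_no_strings():
    assert extract_strings(np.zeros((64, 64)), pixel_size_um=0.25) == []


def test_straight_line_length_measured_within_half_micron():
    # 101-px horizontal component, 3 px wide, 0.25 μm/px -> 25 μm skeleton
    resp = np.zeros((64, 128))
    resp[31:34, 10:111] = 10.0
    recs = extract_strings(resp, response_threshold=1.0, pixel_size_um=0.25)
    assert len(recs) == 1
    assert recs[0].skeleton_length_um == pytest.approx(25.0, abs=0.5)
    assert abs(recs[0].orientation_deg) < 2.0


def test_disk_rejected_by_elongation_filter():
    resp = np.zeros((80, 160))
    resp[39:42, 10:111] = 10.0  # 25 μm line at 0.25 μm/px
    yy, xx = np.mgrid[:80, :160]
    resp[(yy - 50) ** 2 + (xx - 130) ** 2 <= 20**2] = 10.0  # 5 μm radius disk
    recs = extract_strings(resp, response_threshold=1.0, pixel_size_um=0.25)
    assert len(recs) == 1
    assert recs[0].skeleton_length_um == pytest.approx(25.0, abs=1.0)


def test_off_axis_component_rejected_by_orientation_filter():
    resp = np.zeros((128, 128))
    for i in range(60):  # 45-degree line
        resp[20 + i, 20 + i] = 10.0
        resp[21 + i, 20 + i] = 10.0
    recs = extract_strings(
        resp, response_threshold=1.0, pixel_size_um=0.25, max_orientation_dev_deg=20.0
    )
    assert recs == []


def test_skeleton_chain_length_counts_diagonals_sqrt2():
    s = np.zeros((10, 10), bool)
    for i in range(6):
        s[i, i] = True
    assert skeleton_chain_length_px(s) == pytest.approx(5 * np.sqrt(2))
    s2 = np.zeros((5, 20), bool)
    s2[2, 3:15] = True
    assert skeleton_chain_length_px(s2) == 11


def test_count_long_strings_strict_cutoff_and_loop_oracle(rng):
    def rec(l):
        return StringRecord(np.array([[0, 0]]), l, 0.0, 1.0)

    assert count_long_strings([rec(10), rec(25), rec(26)], 25) == 1
    assert count_long_strings([], 25) == 0
    lengths = rng.uniform(0, 60, size=100)
    recs = [rec(l) for l in lengths]
    oracle = sum(1 for l in lengths if l > 25.0)
    assert count_long_strings(recs, 25.0) == oracle


def test_angular_deviation_wraps_mod_180():
    assert angular_deviation_deg(179.0, -1.0) == pytest.approx(0.0)
    assert angular_deviation_deg(90.0, 0.0) == pytest.approx(90.0)
    assert angular_deviation_deg(-80.0, 80.0) == pytest.approx(20.0)
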