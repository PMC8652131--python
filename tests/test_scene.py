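"""Synthetic scene generator: construction contracts and truth invariants."""

import dataclasses
import math

import numpy as np
import pytest

from vwfstrings import ConditionEffects, SceneParams, generate_fov, generate_sample_set
from vwfstrings.scene import CHANNEL_CD41, CHANNEL_VWF, add_agglomerates


def test_empty_scene_is_all_zero(small_params):
    p = dataclasses.replace(
        small_params,
        string_count_mean=0.0,
        n_agglomerates=0,
        platelet_density_per_um_string=0.0,
        platelet_background_count=0.0,
        background_level=0.0,
        gaussian_noise_sd=0.0,
    )
    stack, truth = generate_fov(p)
    assert not truth.strings and not truth.agglomerates and not truth.platelets
    assert stack.channel(CHANNEL_VWF).max() == 0
    assert stack.channel(CHANNEL_CD41).max() == 0


def test_single_horizontal_string_has_exact_arclength(small_params):
    # one deterministic-length 25 μm string: sigma=0 makes the lognormal a
    # point mass at exp(mu); zero jitter keeps it horizontal
    p = dataclasses.replace(
        small_params,
        pixel_size_um=0.25,
        fixed_string_count=1,
        string_length_um_lognormal_mu_sigma=(math.log(25.0), 0.0),
        string_angle_jitter_deg=0.0,
        n_agglomerates=0,
    )
    _, truth = generate_fov(p)
    assert len(truth.strings) == 1
    s = truth.strings[0]
    poly = np.asarray(s.polyline)
    arc_px = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum()
    assert s.arclength_um == pytest.approx(arc_px * 0.25, abs=1e-6)
    assert s.arclength_um == pytest.approx(25.0, abs=0.3)  # 1-px step rounding
    assert abs(s.orientation_deg) < 1e-6


def test_same_seed_is_bit_identical(small_params):
    a, ta = generate_fov(small_params)
    b, tb = generate_fov(small_params)
    for ch in (CHANNEL_VWF, CHANNEL_CD41):
        assert np.array_equal(a.channel(ch), b.channel(ch))
    assert len(ta.strings) == len(tb.strings)
    for sa, sb in zip(ta.strings, tb.strings):
        assert np.array_equal(sa.polyline, sb.polyline)


def test_truth_arclength_matches_polyline(small_params):
    _, truth = generate_fov(small_params)
    assert truth.strings
    for s in truth.strings:
        poly = np.asarray(s.polyline)
        arc = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1)).sum()
        assert s.arclength_um == pytest.approx(arc * small_params.pixel_size_um, abs=1e-6)
        assert (poly >= 0).all()
        assert (poly[:, 0] <= small_params.fov_shape_px[0] - 1).all()
        assert (poly[:, 1] <= small_params.fov_shape_px[1] - 1).all()


def test_platelets_inside_fov(small_params):
    _, truth = generate_fov(dataclasses.replace(small_params, seed=3))
    h, w = small_params.fov_shape_px
    for (cy, cx), _r in truth.platelets:
        assert 0 <= cy <= h - 1 and 0 <= cx <= w - 1


def test_sample_set_counts_match_poisson_mean(small_params):
    n_fov = 35
    fovs = generate_sample_set(small_params, n_fov, "control_vehicle", seed=5)
    assert len(fovs) == n_fov
    counts = [len(t.strings) for _, t in fovs]
    lam = small_params.string_count_mean
    se = math.sqrt(lam / n_fov)
    assert np.mean(counts) == pytest.approx(lam, abs=4 * se)


def test_count_multiplier_doubles_total_strings(small_params):
    n_fov = 35
    a = generate_sample_set(small_params, n_fov, "control_vehicle", seed=5)
    doubled = dataclasses.replace(small_params, count_multiplier=2.0)
    b = generate_sample_set(doubled, n_fov, "control_vehicle", seed=6)
    na = sum(len(t.strings) for _, t in a)
    nb = sum(len(t.strings) for _, t in b)
    ratio = nb / na
    se = ratio * math.sqrt(1 / na + 1 / nb)
    assert ratio == pytest.approx(2.0, abs=3 * se)


def test_length_multiplier_monotone_in_truth(small_params):
    # expected total true arclength strictly increases with the multiplier
    totals = []
    for mult in (1.0, 1.5, 2.5):
        p = dataclasses.replace(small_params, length_multiplier=mult)
        fovs = generate_sample_set(p, 20, "control_vehicle", seed=9)
        totals.append(sum(t.total_length_um for _, t in fovs))
    assert totals[0] < totals[1] < totals[2]


def test_condition_effects_apply_expected_multipliers():
    eff = ConditionEffects()
    base = SceneParams()
    ttp = eff.apply(base, "ttp_vehicle")
    assert ttp.length_multiplier == pytest.approx(eff.ttp_length_multiplier)
    assert ttp.count_multiplier == pytest.approx(eff.ttp_count_multiplier)
    both = eff.apply(base, "ttp_fluva")
    assert both.length_multiplier == pytest.approx(
        eff.ttp_length_multiplier * eff.fluva_length_multiplier
    )
    with pytest.raises(ValueError):
        eff.apply(base, "nonsense")


def test_generate_sample_set_rejects_bad_args(small_params):
    with pytest.raises(ValueError):
        generate_sample_set(small_params, 0, "control_vehicle", seed=1)
    with pytest.raises(ValueError):
        generate_fov(dataclasses.replace(small_params, pixel_size_um=0.0))
    with pytest.raises(ValueError):
        generate_fov(dataclasses.replace(small_params, platelet_density_per_um_string=-1))


def test_add_agglomerates_keeps_other_channels_and_strings(small_params):
    p = dataclasses.replace(small_params, n_agglomerates=0)
    stack, truth = generate_fov(p)
    stack2, blobs = add_agglomerates(stack, p, 5, seed=77)
    assert len(blobs) == 5
    assert np.array_equal(stack.channel(CHANNEL_CD41), stack2.channel(CHANNEL_CD41))
    # blob layer only adds intensity
    assert (
        stack2.channel(CHANNEL_VWF).astype(int) - stack.channel(CHANNEL_VWF).astype(int)
    ).min() >= 0
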