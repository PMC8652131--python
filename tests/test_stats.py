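"""Metric aggregation, paired normalization and the statistical tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vwfstrings import (
    normalize_to_control,
    run_comparison,
    summarize_sample,
    t_unpaired,
    wilcoxon_paired,
)
from vwfstrings.particles import ParticleSummary
from vwfstrings.segmentation import StringRecord
from vwfstrings.stats import METRICS, SampleSummary


def _rec(length, fov="f0"):
    return StringRecord(np.array([[0, 0]]), length, 0.0, 1.0, fov_id=fov)


def _part(frac, channel, fov="f0"):
    return ParticleSummary(1, frac * 100.0, frac, fov_id=fov, channel_name=channel)


def test_summary_of_three_strings():
    s = summarize_sample([_rec(10.0), _rec(20.0), _rec(30.0)], [], "s1", "control_vehicle")
    assert s.total_string_length_um == pytest.approx(60.0)
    assert s.median_string_length_um == pytest.approx(20.0)
    assert s.n_strings == 3 and s.n_long_strings == 1


def test_summary_without_strings_flags_and_averages_fractions():
    parts = [_part(0.1, "CD41", "f0"), _part(0.3, "CD41", "f1")]
    s = summarize_sample([], parts, "s1", "control_vehicle")
    assert s.total_string_length_um == 0.0
    assert s.median_string_length_um == 0.0 and s.no_strings
    assert s.platelet_area_fraction == pytest.approx(0.2)


def test_summary_matches_loop_oracle(rng):
    lengths = rng.uniform(1, 60, size=500)
    s = summarize_sample([_rec(l) for l in lengths], [], "s", "ttp_vehicle")
    assert s.total_string_length_um == pytest.approx(float(np.sum(lengths)))
    assert s.median_string_length_um == pytest.approx(float(np.median(lengths)))
    assert s.n_long_strings == sum(1 for l in lengths if l > 25)


def _summary(total=100.0, **kw):
    base = dict(
        sample_id="s",
        condition="ttp_vehicle",
        total_string_length_um=total,
        median_string_length_um=10.0,
        n_strings=10,
        n_long_strings=2,
        platelet_area_fraction=0.01,
        vwf_area_fraction=0.02,
        n_fov=3,
    )
    base.update(kw)
    return SampleSummary(**base)


def test_fold_change_of_sample_against_itself_is_one():
    s = _summary()
    for m in METRICS:
        assert normalize_to_control(s, s, m).fold_change == pytest.approx(1.0)


@pytest.mark.parametrize("patient,expected", [(389.0, 3.89), (147.0, 1.47)])
def test_fold_change_simple_ratios(patient, expected):
    r = normalize_to_control(_summary(total=patient), _summary(total=100.0), "total_string_length_um")
    assert r.fold_change == pytest.approx(expected)


def test_zero_control_metric_reports_missing():
    r = normalize_to_control(_summary(), _summary(total=0.0), "total_string_length_um")
    assert r.fold_change is None


def test_wilcoxon_identical_samples_degenerate_p_one():
    r = wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert r.p_value == 1.0 and r.degenerate


def test_wilcoxon_six_uniform_signs_exact_p():
    # all six differences positive: two-sided exact p = 2/2^6
    r = wilcoxon_paired([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
    assert r.p_value == pytest.approx(2 / 64)
    assert r.n == 6


def _wilcoxon_enumeration_oracle(a, b):
    """Brute-force two-sided exact signed-rank p over all sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    w_min = min(w_obs, ranks.sum() - w_obs)
    return min(1.0, 2 * np.mean(ws <= w_min + 1e-9))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_wilcoxon_matches_full_enumeration_oracle(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(5, 11))
    a = r.normal(0.3, 1.0, size=n).round(1)  # rounding provokes ties/zeros
    b = r.normal(0.0, 1.0, size=n).round(1)
    if np.all(a == b):
        return
    ours = wilcoxon_paired(a, b)
    assert ours.p_value == pytest.approx(_wilcoxon_enumeration_oracle(a, b))


def test_wilcoxon_agrees_with_scipy_exact_when_no_ties():
    a = [1.1, 2.7, 0.4, 5.2, 3.3, 2.1, 0.9, 4.4]
    b = [0.8, 3.1, 0.2, 4.0, 3.9, 1.0, 1.6, 4.1]
    d = np.array(a) - np.array(b)
    assert len(np.unique(np.abs(d))) == len(d)  # genuinely untied
    ours = wilcoxon_paired(a, b)
    ref = sps.wilcoxon(a, b, mode="exact")
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_wilcoxon_requires_five_pairs():
    with pytest.raises(ValueError):
        wilcoxon_paired([1, 2, 3], [4, 5, 6])


def test_t_identical_groups_statistic_zero_p_one():
    r = t_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_welch_t_matches_textbook_formula(rng):
    a = rng.normal(1.0, 1.0, size=3)
    b = rng.normal(0.0, 2.0, size=3)
    r = t_unpaired(a, b, variant="welch")
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
    p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
    assert r.statistic == pytest.approx(t_hand)
    assert r.p_value == pytest.approx(p_hand)


def test_student_t_matches_pooled_formula(rng):
    a = rng.normal(0.5, 1.0, size=4)
    b = rng.normal(0.0, 1.0, size=5)
    r = t_unpaired(a, b, variant="student")
    sp2 = ((3 * a.var(ddof=1)) + (4 * b.var(ddof=1))) / 7
    t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 5))
    assert r.statistic == pytest.approx(t_hand)


def _study_frame(scale=1.0):
    rows = []
    for exp in (1, 2):
        for pid, cond in [
            ("control", "control_vehicle"),
            ("patient1", "ttp_vehicle"),
            ("patient2", "ttp_vehicle"),
        ]:
            rows.append(
                {
                    "sample_id": f"{pid}_{cond}_e{exp}",
                    "patient_id": pid,
                    "condition": cond,
                    "experiment": exp,
                    **{
                        m: (100.0 + 10 * exp) * (scale if pid != "control" else 1.0)
                        for m in METRICS
                    },
                }
            )
    return pd.DataFrame(rows)


def test_run_comparison_self_identical_gives_unit_folds():
    res = run_comparison(_study_frame(scale=1.0))
    assert np.allclose(res.folds["fold_change"], 1.0)
    assert not res.warnings


def test_run_comparison_recovers_embedded_two_fold():
    res = run_comparison(_study_frame(scale=2.0))
    assert np.allclose(res.normalized["fold_change_mean"], 2.0)


def test_run_comparison_excludes_unpaired_patient_with_warning():
    df = _study_frame()
    df = df[df["patient_id"] != "control"]
    res = run_comparison(df)
    assert res.folds.empty
    assert any("no paired control" in w for w in res.warnings)
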