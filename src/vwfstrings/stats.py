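"""Per-sample metric aggregation, paired-control normalization, and tests.

The study design pairs every patient-plasma run with a pooled-control run from
the same session and fluvastatin status; each metric of a patient sample is
reported both in absolute terms and as a fold change over its paired control.
Significance follows the original analysis: a two-sided paired signed-rank
(Wilcoxon) test across patient/control sample pairs, and a two-sided unpaired
t-test (Welch by default) across independent experiments.  The signed-rank
test is exact (full sign enumeration) up to n=15 pairs and uses the
tie-corrected normal approximation above that.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .particles import ParticleSummary
from .segmentation import StringRecord, count_long_strings

METRICS = (
    "total_string_length_um",
    "median_string_length_um",
    "n_strings",
    "n_long_strings",
    "platelet_area_fraction",
    "vwf_area_fraction",
)

LONG_STRING_CUTOFF_UM = 25.0


@dataclass
class SampleSummary:
    """The six per-sample metrics, aggregated over a sample's FOVs."""

    sample_id: str
    condition: str
    total_string_length_um: float
    median_string_length_um: float
    n_strings: int
    n_long_strings: int
    platelet_area_fraction: float
    vwf_area_fraction: float
    n_fov: int
    no_strings: bool = False  # flagged when the median fell back to 0

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise ValueError(f"unknown metric {name!r}")
        return float(getattr(self, name))


@dataclass
class NormalizedResult:
    patient_id: str
    metric_name: str
    fold_change: float | None  # None when the control metric is 0 (undefined)
    replicate_values: list[float] = field(default_factory=list)
    mean: float = math.nan
    sem: float = math.nan


@dataclass
class TestResult:
    test_name: str  # "wilcoxon_paired" | "t_unpaired"
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def summarize_sample(
    strings: list[StringRecord],
    particles: list[ParticleSummary],
    sample_id: str,
    condition: str,
) -> SampleSummary:
    """Aggregate per-FOV strings and particle summaries into sample metrics.

    String lengths are pooled over the sample's FOVs (sum, median, counts);
    area fractions are means over FOVs per channel.
    """
    lengths = np.array([s.skeleton_length_um for s in strings], dtype=float)
    fovs = {p.fov_id for p in particles} or {s.fov_id for s in strings}
    plate = [p.area_fraction for p in particles if p.channel_name == "CD41"]
    vwf = [p.area_fraction for p in particles if p.channel_name == "VWF"]
    return SampleSummary(
        sample_id=sample_id,
        condition=condition,
        total_string_length_um=float(lengths.sum()),
        median_string_length_um=float(np.median(lengths)) if lengths.size else 0.0,
        n_strings=int(lengths.size),
        n_long_strings=count_long_strings(strings, LONG_STRING_CUTOFF_UM),
        platelet_area_fraction=float(np.mean(plate)) if plate else 0.0,
        vwf_area_fraction=float(np.mean(vwf)) if vwf else 0.0,
        n_fov=len(fovs),
        no_strings=lengths.size == 0,
    )


def normalize_to_control(
    patient: SampleSummary, control: SampleSummary, metric_name: str
) -> NormalizedResult:
    """Fold change of one metric: patient value / paired control value.

    A zero control value makes the fold change undefined; it is reported as
    missing (``fold_change=None``) and excluded from downstream tests.
    """
    c = control.metric(metric_name)
    p = patient.metric(metric_name)
    fold = None if c == 0 else p / c
    return NormalizedResult(
        patient_id=patient.sample_id, metric_name=metric_name, fold_change=fold
    )


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ = sum of positive ranks over all sign flips.

    Ranks may be half-integers from mid-ranking; everything is doubled to
    stay integral.  Returns (support of 2*W, counts).
    """
    doubled = np.round(ranks * 2).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return np.arange(total + 1), counts


def wilcoxon_paired(a: list[float], b: list[float]) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences are mid-ranked.
    Exact sign-enumeration p-value for n <= 15 non-zero pairs; tie-corrected
    normal approximation with continuity correction above.  All differences
    zero is degenerate and reports p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon_paired", 0.0, 1.0, 0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks.sum() - w_pos)
    if n <= 15:
        # two-sided exact p doubles the lower tail of min(W+, W-), the
        # standard convention of statistics packages
        support2, counts = _signed_rank_distribution(ranks)
        total = counts.sum()
        w2 = int(round(min(w_pos, w_neg) * 2))
        p = min(1.0, 2.0 * counts[: w2 + 1].sum() / total)
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    p = max(p, np.finfo(float).tiny)
    return TestResult("wilcoxon_paired", w_pos, float(p), int(n))


def t_unpaired(
    a: list[float], b: list[float], variant: str = "welch"
) -> TestResult:
    """Two-sided unpaired t-test; Welch (unequal variances) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("t_unpaired", 0.0, 1.0, int(a.size + b.size), degenerate=True)
        return TestResult(
            "t_unpaired",
            math.inf if a.mean() > b.mean() else -math.inf,
            float(np.finfo(float).tiny),
            int(a.size + b.size),
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    p = max(float(res.pvalue), float(np.finfo(float).tiny))
    return TestResult("t_unpaired", float(res.statistic), p, int(a.size + b.size))


# ---------------------------------------------------------------------------
# study-level comparison


@dataclass
class ComparisonResult:
    """Tidy tables of a full four-condition comparison."""

    summaries: pd.DataFrame  # one row per sample x experiment
    folds: pd.DataFrame  # per patient x experiment x metric fold changes
    normalized: pd.DataFrame  # per patient x metric: replicate folds, mean, sem
    tests: pd.DataFrame  # per metric (x arm): Wilcoxon and t results
    warnings: list[str] = field(default_factory=list)


def _arm_of(condition: str) -> str:
    return "fluva" if condition.endswith("fluva") else "vehicle"


def _is_control(condition: str) -> bool:
    return condition.startswith("control")


def run_comparison(
    summaries: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    t_variant: str = "welch",
) -> ComparisonResult:
    """Normalize patient samples to paired controls and run the study tests.

    ``summaries`` must hold one row per sample per experiment with columns
    ``sample_id, patient_id, condition, experiment`` plus the metric columns.
    Within each (experiment, fluvastatin arm) the control row is the paired
    reference for every patient row; patients lacking a paired control are
    excluded with a logged warning.  Per-patient fold changes are computed per
    experiment then averaged; the paired Wilcoxon runs across patient/control
    pairs of per-patient experiment means; the unpaired t-test compares each
    patient's per-experiment values against its paired control's.
    """
    required = {"sample_id", "patient_id", "condition", "experiment"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    warnings: list[str] = []
    fold_rows = []
    for (exp, arm), grp in summaries.groupby(
        [summaries["experiment"], summaries["condition"].map(_arm_of)]
    ):
        ctrl = grp[grp["condition"].map(_is_control)]
        pats = grp[~grp["condition"].map(_is_control)]
        if ctrl.empty:
            if not pats.empty:
                warnings.append(
                    f"experiment {exp} arm {arm}: no paired control; "
                    f"{len(pats)} patient sample(s) excluded"
                )
            continue
        crow = ctrl.iloc[0]
        for _, prow in pats.iterrows():
            for m in metrics:
                c = float(crow[m])
                fold_rows.append(
                    {
                        "patient_id": prow["patient_id"],
                        "experiment": exp,
                        "arm": arm,
                        "metric": m,
                        "patient_value": float(prow[m]),
                        "control_value": c,
                        "fold_change": (float(prow[m]) / c) if c != 0 else np.nan,
                    }
                )
                if c == 0:
                    warnings.append(
                        f"patient {prow['patient_id']} exp {exp} arm {arm}: "
                        f"control {m} is 0, fold change undefined"
                    )
    folds = pd.DataFrame(fold_rows)

    norm_rows = []
    test_rows = []
    if not folds.empty:
        for (pid, arm, m), grp in folds.groupby(["patient_id", "arm", "metric"]):
            reps = grp["fold_change"].dropna().tolist()
            mean = float(np.mean(reps)) if reps else math.nan
            sem = (
                float(np.std(reps, ddof=1) / math.sqrt(len(reps)))
                if len(reps) > 1
                else math.nan
            )
            norm_rows.append(
                {
                    "patient_id": pid,
                    "arm": arm,
                    "metric": m,
                    "n_experiments": len(reps),
                    "fold_change_mean": mean,
                    "fold_change_sem": sem,
                    "replicates": ",".join(f"{v:.6g}" for v in reps),
                }
            )
            pa = grp["patient_value"].to_numpy(float)
            cb = grp["control_value"].to_numpy(float)
            if pa.size >= 2 and (pa.var() > 0 or cb.var() > 0):
                tr = t_unpaired(pa, cb, variant=t_variant)
                test_rows.append(
                    {
                        "metric": m,
                        "arm": arm,
                        "scope": f"patient:{pid}",
                        "test_name": tr.test_name,
                        "statistic": tr.statistic,
                        "p_value": tr.p_value,
                        "n": tr.n,
                        "degenerate": tr.degenerate,
                    }
                )
        # paired Wilcoxon across patients (per arm) on per-patient means
        for (arm, m), grp in folds.groupby(["arm", "metric"]):
            per_pat = grp.groupby("patient_id")[["patient_value", "control_value"]].mean()
            if len(per_pat) >= 5:
                wr = wilcoxon_paired(
                    per_pat["patient_value"].to_numpy(),
                    per_pat["control_value"].to_numpy(),
                )
                test_rows.append(
                    {
                        "metric": m,
                        "arm": arm,
                        "scope": "all_patients",
                        "test_name": wr.test_name,
                        "statistic": wr.statistic,
                        "p_value": wr.p_value,
                        "n": wr.n,
                        "degenerate": wr.degenerate,
                    }
                )
    normalized = pd.DataFrame(norm_rows)
    tests = pd.DataFrame(test_rows)
    return ComparisonResult(summaries, folds, normalized, tests, warnings)
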