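"""Self-validation experiments: ground-truth recovery, effect recovery, null calibration.

These run the full simulate→quantify pipeline on ground-truthed synthetic
studies and score it against the truth.  They back both the test suite and
the reproduction script; problem sizes (FOV count, FOV size, z-slices) are
arguments so cost can be scaled without touching the study conditions
(densities, lengths, noise, multipliers).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import stats
from .config import RunConfig
from .preprocess import max_z_projection
from .scene import (
    CHANNEL_VWF,
    SceneParams,
    add_agglomerates,
    fov_seed_stream,
    generate_fov,
    generate_sample_set,
)
from .segmentation import build_kernel_bank, directional_response, extract_strings
from .pipeline import quantify_sample, quantify_stack
from .validation import match_truth, pool_stats


def _scaled_scene(scene: SceneParams, fov_shape_px=None, n_z_slices=None) -> SceneParams:
    kw = {}
    if fov_shape_px is not None:
        kw["fov_shape_px"] = tuple(fov_shape_px)
    if n_z_slices is not None:
        kw["n_z_slices"] = n_z_slices
    return dataclasses.replace(scene, **kw) if kw else scene


def recovery_experiment(cfg: RunConfig, n_fov: int, seed: int) -> dict:
    """Segmentation ground-truth recovery over ``n_fov`` default-SNR FOVs.

    Returns recall of true strings at or above the minimum length, and the
    relative error of summed measured length vs summed rendered truth length.
    """
    per_fov = []
    for s in fov_seed_stream(seed, n_fov):
        stack, truth = generate_fov(dataclasses.replace(cfg.scene, seed=int(s)))
        q = quantify_stack(stack, cfg)
        per_fov.append(
            match_truth(truth, q.strings, stack.shape_yx, min_length_um=cfg.min_length_um)
        )
    pooled = pool_stats(per_fov)
    return {
        "recall": pooled.recall,
        "length_relative_error": pooled.length_relative_error,
        "n_true": pooled.n_true,
        "n_detected": pooled.n_detected,
        "n_fov": n_fov,
    }


def agglomerate_experiment(cfg: RunConfig, n_fov: int, n_blobs: int, seed: int) -> dict:
    """Add ``n_blobs`` isotropic agglomerates per FOV to otherwise identical
    scenes and difference the string measurements at fixed thresholds."""
    scene = dataclasses.replace(cfg.scene, n_agglomerates=0)
    bank = build_kernel_bank(
        scene.flow_angle_deg,
        length_px=cfg.kernel_length_px,
        width_px=cfg.kernel_width_px,
        max_deviation_deg=cfg.max_deviation_deg,
        n_orientations=cfg.n_orientations,
    )
    count_change = 0
    len_base = len_blob = 0.0
    for s in fov_seed_stream(seed, n_fov):
        stack, _ = generate_fov(dataclasses.replace(scene, seed=int(s)))
        blobbed, _ = add_agglomerates(stack, scene, n_blobs, seed=int(s) + 1)
        proj = max_z_projection(stack, CHANNEL_VWF).astype(float)
        resp = directional_response(proj, bank)
        thr = float(threshold_otsu(resp))  # frozen, then reused on the blobbed scene
        kw = dict(
            response_threshold=thr,
            min_length_um=cfg.min_length_um,
            min_axis_ratio=cfg.min_axis_ratio,
            pixel_size_um=scene.pixel_size_um,
            flow_angle_deg=scene.flow_angle_deg,
            max_orientation_dev_deg=cfg.max_orientation_dev_deg,
        )
        base = extract_strings(resp, **kw)
        resp2 = directional_response(
            max_z_projection(blobbed, CHANNEL_VWF).astype(float), bank
        )
        with_blobs = extract_strings(resp2, **kw)
        count_change += len(with_blobs) - len(base)
        len_base += sum(r.skeleton_length_um for r in base)
        len_blob += sum(r.skeleton_length_um for r in with_blobs)
    return {
        "count_change": count_change,
        "length_relative_change": (len_blob - len_base) / len_base if len_base else 0.0,
        "n_fov": n_fov,
        "n_blobs": n_blobs,
    }


def _sample_metrics(cfg: RunConfig, scene: SceneParams, n_fov: int, condition: str, seed: int):
    fovs = generate_sample_set(scene, n_fov, condition, seed, effects=cfg.effects)
    summary, _ = quantify_sample([st for st, _ in fovs], cfg, condition, condition)
    truth_total = sum(t.total_length_um for _, t in fovs)
    truth_n = sum(len(t.strings) for _, t in fovs)
    return summary, truth_total, truth_n


def effect_recovery_experiment(
    cfg: RunConfig,
    multipliers: Sequence[float] = (1.5, 2.0, 4.0),
    n_experiments: int = 3,
    n_fov: int = 32,
    seed: int = 0,
    fov_shape_small=(384, 384),
    fov_shape_large=(768, 768),
    n_z_slices: int = 5,
) -> list[dict]:
    """Fold-change recovery of embedded condition effects.

    For each multiplier m, a TTP-like condition is generated with length and
    count multipliers both m; the measured fold changes of total string
    length (nominal m*m) and string count (nominal m) vs a control sample
    are averaged over ``n_experiments`` independent experiments.  Long
    conditions use the large FOV so strings are not clipped by the frame.
    """
    out = []
    root = np.random.SeedSequence(seed)
    for mi, mult in enumerate(multipliers):
        shape = fov_shape_large if mult > 2 else fov_shape_small
        scene = _scaled_scene(cfg.scene, fov_shape_px=shape, n_z_slices=n_z_slices)
        len_folds, cnt_folds = [], []
        for exp in range(n_experiments):
            s_c, s_t = np.random.SeedSequence((seed, mi, exp)).generate_state(2) % 2**31
            ctrl, _, _ = _sample_metrics(cfg, scene, n_fov, "control_vehicle", int(s_c))
            ttp_scene = dataclasses.replace(
                scene, length_multiplier=mult, count_multiplier=mult
            )
            ttp, _, _ = _sample_metrics(cfg, ttp_scene, n_fov, "control_vehicle", int(s_t))
            len_folds.append(ttp.total_string_length_um / ctrl.total_string_length_um)
            cnt_folds.append(ttp.n_strings / ctrl.n_strings)
        out.append(
            {
                "multiplier": mult,
                "nominal_length_fold": mult * mult,
                "nominal_count_fold": mult,
                "measured_length_fold": float(np.mean(len_folds)),
                "measured_count_fold": float(np.mean(cnt_folds)),
                "n_experiments": n_experiments,
                "n_fov": n_fov,
            }
        )
    return out


def fluva_monotonicity_experiment(
    cfg: RunConfig,
    n_replicates: int = 10,
    n_fov: int = 10,
    seed: int = 0,
    fov_shape=(384, 384),
    n_z_slices: int = 5,
) -> dict:
    """Directional fluvastatin effect: treated-TTP fold changes (vs the
    vehicle control) must fall below untreated-TTP fold changes.

    Returns, per metric, the fraction of replicates with the correct
    ordering."""
    scene = _scaled_scene(cfg.scene, fov_shape_px=fov_shape, n_z_slices=n_z_slices)
    below = {m: 0 for m in stats.METRICS}
    for rep in range(n_replicates):
        seeds = np.random.SeedSequence((seed, rep)).generate_state(3) % 2**31
        rows = {}
        for cond, s in zip(("control_vehicle", "ttp_vehicle", "ttp_fluva"), seeds):
            fovs = generate_sample_set(scene, n_fov, cond, int(s), effects=cfg.effects)
            rows[cond], _ = quantify_sample([st for st, _ in fovs], cfg, cond, cond)
        for m in stats.METRICS:
            ctrl = rows["control_vehicle"].metric(m)
            if ctrl == 0:
                continue
            if rows["ttp_fluva"].metric(m) / ctrl < rows["ttp_vehicle"].metric(m) / ctrl:
                below[m] += 1
    return {
        "fraction_below": {m: below[m] / n_replicates for m in stats.METRICS},
        "n_replicates": n_replicates,
        "n_fov": n_fov,
    }


def null_calibration_experiment(
    cfg: RunConfig,
    seed: int,
    n_patients: int = 5,
    n_experiments: int = 3,
    n_fov_control: int = 200,
    n_fov_patient: int = 40,
    fov_shape=(224, 224),
    n_z_slices: int = 3,
) -> dict:
    """Four-condition study with all multipliers at 1: fold changes should
    sit near 1 and the paired Wilcoxon should not reject.

    Controls get more FOVs than patient runs because every patient fold in an
    arm shares the one pooled-control denominator.  Fold changes per metric
    and arm are condition-pooled (per-FOV rates of the patient pool over the
    control pool); the Wilcoxon pairs per-patient experiment means with their
    paired control values.
    """
    null_effects = dataclasses.replace(
        cfg.effects,
        ttp_length_multiplier=1.0,
        ttp_count_multiplier=1.0,
        ttp_platelet_density_multiplier=1.0,
        fluva_length_multiplier=1.0,
        fluva_count_multiplier=1.0,
    )
    cfg = dataclasses.replace(cfg, effects=null_effects)
    scene = _scaled_scene(cfg.scene, fov_shape_px=fov_shape, n_z_slices=n_z_slices)
    rows = []
    i = 0
    seeds = fov_seed_stream(seed, n_experiments * 2 * (n_patients + 1))
    for exp in range(1, n_experiments + 1):
        for arm, cond_c, cond_p in (
            ("vehicle", "control_vehicle", "ttp_vehicle"),
            ("fluva", "control_fluva", "ttp_fluva"),
        ):
            members = [("control", cond_c, n_fov_control)] + [
                (f"patient{p}", cond_p, n_fov_patient) for p in range(1, n_patients + 1)
            ]
            for pid, cond, nf in members:
                fovs = generate_sample_set(scene, nf, cond, int(seeds[i]), effects=cfg.effects)
                i += 1
                summary, _ = quantify_sample(
                    [st for st, _ in fovs], cfg, f"{pid}_{cond}_e{exp}", cond
                )
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "experiment": exp,
                        "n_fov": nf,
                        **{m: summary.metric(m) for m in stats.METRICS},
                    }
                )
    df = pd.DataFrame(rows)

    per_fov_metrics = (
        "total_string_length_um",
        "n_strings",
        "n_long_strings",
    )
    folds: dict[tuple[str, str], float] = {}
    p_values: dict[tuple[str, str], float] = {}
    for arm, grp in df.groupby("arm"):
        ctrl = grp[grp["patient_id"] == "control"]
        pats = grp[grp["patient_id"] != "control"]
        for m in stats.METRICS:
            if m in per_fov_metrics:  # pooled per-FOV rates
                fold = (pats[m].sum() / pats["n_fov"].sum()) / (
                    ctrl[m].sum() / ctrl["n_fov"].sum()
                )
            else:  # already per-FOV-normalized quantities: plain pooled means
                fold = pats[m].mean() / ctrl[m].mean()
            folds[(arm, m)] = float(fold)
            per_pat = pats.groupby("patient_id")[m].mean().sort_index()
            if len(per_pat) >= 5:
                ctrl_mean = ctrl[m].mean()
                res = stats.wilcoxon_paired(
                    per_pat.to_numpy(), np.full(len(per_pat), ctrl_mean)
                )
                p_values[(arm, m)] = res.p_value
    return {
        "folds": folds,
        "p_values": p_values,
        "max_abs_fold_deviation": max(abs(v - 1.0) for v in folds.values()),
        "min_p_value": min(p_values.values()) if p_values else math.nan,
        "n_patients": n_patients,
        "n_fov_control": n_fov_control,
        "n_fov_patient": n_fov_patient,
    }
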