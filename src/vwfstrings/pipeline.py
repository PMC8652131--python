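"""End-to-end workflows: simulate a four-condition study, quantify stacks.

The quantification of one FOV is: maximum-intensity Z-projection per channel,
per-channel binarization and particle analysis (platelet and total-VWF
coverage), then directional ridge filtering of the VWF projection and
flow-aligned string extraction.  Samples aggregate their FOVs into the six
study metrics; the study-level comparison lives in :mod:`vwfstrings.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, stats
from .config import RunConfig
from .particles import ParticleSummary, analyze_particles
from .preprocess import binarize, max_z_projection
from .scene import (
    CHANNEL_CD41,
    CHANNEL_VWF,
    CONDITIONS,
    ImageStack,
    SceneTruth,
    fov_seed_stream,
    generate_sample_set,
)
from .segmentation import StringRecord, build_kernel_bank, directional_response, extract_strings
from .stats import ComparisonResult, SampleSummary, summarize_sample


@dataclass
class FovQuant:
    """Everything measured on one FOV."""

    fov_id: str
    strings: list[StringRecord]
    vwf_particles: ParticleSummary
    cd41_particles: ParticleSummary


def quantify_stack(stack: ImageStack, cfg: RunConfig, fov_id: str = "") -> FovQuant:
    """Project, threshold, segment and measure one two-channel stack."""
    vwf_proj = max_z_projection(stack, CHANNEL_VWF).astype(np.float64)
    cd41_proj = max_z_projection(stack, CHANNEL_CD41).astype(np.float64)

    vwf_mask = binarize(
        vwf_proj,
        method=cfg.threshold_method,
        fixed_value=cfg.threshold_value,
        pixel_size_um=stack.pixel_size_um,
        channel_name=CHANNEL_VWF,
    )
    cd41_mask = binarize(
        cd41_proj,
        method=cfg.threshold_method,
        fixed_value=cfg.threshold_value,
        pixel_size_um=stack.pixel_size_um,
        channel_name=CHANNEL_CD41,
    )
    vwf_particles = analyze_particles(
        vwf_mask, cfg.vwf_min_area_um2, cfg.vwf_max_area_um2, fov_id=fov_id
    )
    cd41_particles = analyze_particles(
        cd41_mask, cfg.platelet_min_area_um2, cfg.platelet_max_area_um2, fov_id=fov_id
    )

    bank = build_kernel_bank(
        stack.flow_angle_deg,
        length_px=cfg.kernel_length_px,
        width_px=cfg.kernel_width_px,
        max_deviation_deg=cfg.max_deviation_deg,
        n_orientations=cfg.n_orientations,
    )
    response = directional_response(vwf_proj, bank)
    strings = extract_strings(
        response,
        response_threshold=cfg.response_threshold,
        min_length_um=cfg.min_length_um,
        min_axis_ratio=cfg.min_axis_ratio,
        pixel_size_um=stack.pixel_size_um,
        flow_angle_deg=stack.flow_angle_deg,
        max_orientation_dev_deg=cfg.max_orientation_dev_deg,
        intensity_image=vwf_proj,
        closing_radius_px=cfg.closing_radius_px,
        fov_id=fov_id,
    )
    return FovQuant(fov_id, strings, vwf_particles, cd41_particles)


def quantify_sample(
    stacks: list[ImageStack],
    cfg: RunConfig,
    sample_id: str,
    condition: str,
    fov_ids: list[str] | None = None,
) -> tuple[SampleSummary, list[FovQuant]]:
    fov_ids = fov_ids or [f"{sample_id}_fov{i:02d}" for i in range(len(stacks))]
    quants = [quantify_stack(s, cfg, fid) for s, fid in zip(stacks, fov_ids)]
    strings = [rec for q in quants for rec in q.strings]
    particles = [p for q in quants for p in (q.vwf_particles, q.cd41_particles)]
    return summarize_sample(strings, particles, sample_id, condition), quants


# ---------------------------------------------------------------------------
# in-memory study simulation


@dataclass
class SimulatedSample:
    sample_id: str
    patient_id: str
    condition: str
    experiment: int
    seed: int
    fovs: list[tuple[ImageStack, SceneTruth]] = field(default_factory=list)


def simulate_study(
    cfg: RunConfig,
    n_patients: int,
    seed: int,
    n_fov: int | None = None,
    n_experiments: int | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> list[SimulatedSample]:
    """Simulate the paired study layout in memory.

    Each experiment (session) holds one pooled-control run per fluvastatin
    arm plus one run per patient per arm, mirroring the one-control-per-run
    pairing of the assay.  Every sample gets its own deterministic substream
    of ``seed``.
    """
    n_fov = n_fov or cfg.n_fov
    n_experiments = n_experiments or cfg.n_experiments
    samples: list[SimulatedSample] = []
    layout: list[tuple[str, str, str]] = []  # (patient_id, condition, sample kind)
    for cond in conditions:
        if cond.startswith("control"):
            layout.append(("control", cond, "control"))
        else:
            for p in range(1, n_patients + 1):
                layout.append((f"patient{p}", cond, "patient"))
    n_per_exp = len(layout)
    sample_seeds = fov_seed_stream(seed, n_per_exp * n_experiments)
    i = 0
    for exp in range(1, n_experiments + 1):
        for patient_id, cond, _kind in layout:
            s = int(sample_seeds[i])
            i += 1
            sid = f"{patient_id}_{cond}_exp{exp}"
            fovs = generate_sample_set(cfg.scene, n_fov, cond, s, effects=cfg.effects)
            samples.append(SimulatedSample(sid, patient_id, cond, exp, s, fovs))
    return samples


def quantify_study(
    samples: list[SimulatedSample], cfg: RunConfig
) -> tuple[pd.DataFrame, dict[str, list[FovQuant]]]:
    """Quantify every simulated sample; returns the tidy summary table."""
    rows = []
    quants: dict[str, list[FovQuant]] = {}
    for s in samples:
        summary, q = quantify_sample(
            [stack for stack, _ in s.fovs], cfg, s.sample_id, s.condition
        )
        quants[s.sample_id] = q
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "condition": s.condition,
                "experiment": s.experiment,
                **{m: summary.metric(m) for m in stats.METRICS},
                "n_fov": summary.n_fov,
            }
        )
    return pd.DataFrame(rows), quants


def compare_study(summaries: pd.DataFrame, cfg: RunConfig) -> ComparisonResult:
    return stats.run_comparison(summaries, t_variant=cfg.t_test_variant)


def run_comparison_from_manifest(
    manifest: pd.DataFrame, cfg: RunConfig
) -> tuple[ComparisonResult, dict[str, pd.DataFrame], list[dict]]:
    """File-driven quantification: read every manifest FOV, then compare.

    Unreadable FOVs are recorded (never silently dropped) and the run
    continues; an all-FOV failure raises.
    """
    rows = []
    string_rows = []
    particle_rows = []
    errors: list[dict] = []
    n_total = 0
    for (sample_id, patient_id, condition, experiment), grp in manifest.groupby(
        ["sample_id", "patient_id", "condition", "experiment"], sort=True
    ):
        strings: list[StringRecord] = []
        particles: list[ParticleSummary] = []
        for _, r in grp.iterrows():
            n_total += 1
            try:
                stack = io.read_fov_tiff(r["path"])
                q = quantify_stack(stack, cfg, fov_id=str(r["fov_id"]))
            except (OSError, ValueError, KeyError) as exc:
                errors.append(
                    {"fov_id": str(r["fov_id"]), "path": r["path"], "error": str(exc)}
                )
                continue
            strings.extend(q.strings)
            particles.extend([q.vwf_particles, q.cd41_particles])
            for rec in q.strings:
                string_rows.append(
                    {
                        "fov_id": rec.fov_id,
                        "sample_id": sample_id,
                        "length_um": rec.skeleton_length_um,
                        "orientation_deg": rec.orientation_deg,
                        "n_pixels": len(rec.pixel_set),
                        "mean_intensity": rec.mean_intensity,
                    }
                )
            for p in (q.vwf_particles, q.cd41_particles):
                particle_rows.append(
                    {
                        "fov_id": p.fov_id,
                        "sample_id": sample_id,
                        "channel": p.channel_name,
                        "n_particles": p.n_particles,
                        "total_area_um2": p.total_area_um2,
                        "area_fraction": p.area_fraction,
                    }
                )
        summary = summarize_sample(strings, particles, str(sample_id), str(condition))
        rows.append(
            {
                "sample_id": sample_id,
                "patient_id": patient_id,
                "condition": condition,
                "experiment": experiment,
                **{m: summary.metric(m) for m in stats.METRICS},
                "n_fov": summary.n_fov,
            }
        )
    if n_total and len(errors) == n_total:
        raise RuntimeError("all FOVs failed to quantify")
    summaries = pd.DataFrame(rows)
    result = stats.run_comparison(summaries, t_variant=cfg.t_test_variant)
    detail = {
        "strings": pd.DataFrame(string_rows),
        "particles": pd.DataFrame(particle_rows),
    }
    return result, detail, errors
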