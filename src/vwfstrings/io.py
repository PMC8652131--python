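"""File formats: multi-page TIFF stacks, sample manifests, truth files.

One TIFF per FOV, pages ordered channel-major (all VWF z-slices, then all
CD41 z-slices), 16-bit unsigned, with a JSON ImageDescription carrying pixel
size, flow angle and channel layout so stacks round-trip losslessly.  The
manifest is a TSV pairing each FOV with its sample, condition and experiment;
ground truth is serialized to JSON per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scene import ImageStack, SceneTruth, TrueString

MANIFEST_COLUMNS = [
    "fov_id",
    "path",
    "sample_id",
    "patient_id",
    "condition",
    "experiment",
    "seed",
]


def write_fov_tiff(stack: ImageStack, path: str | Path) -> None:
    names = list(stack.channels)
    arrs = [stack.channels[n] for n in names]
    n_z = arrs[0].shape[0]
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "flow_angle_deg": stack.flow_angle_deg,
        "n_z": n_z,
        "channels": names,
        "page_order": "channel_major",
    }
    pages = np.concatenate(arrs, axis=0).astype(np.uint16)
    tifffile.imwrite(str(path), pages, description=json.dumps(meta))


def read_fov_tiff(
    path: str | Path,
    channels: list[str] | None = None,
    n_z: int | None = None,
    pixel_size_um: float | None = None,
    flow_angle_deg: float | None = None,
) -> ImageStack:
    """Read a FOV stack; metadata from the file unless overridden.

    For generic z-stack TIFFs without our JSON description, pass the channel
    order, slice count and pixel size explicitly.
    """
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    channels = channels or meta.get("channels")
    n_z = n_z or meta.get("n_z")
    pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
    flow_angle_deg = (
        flow_angle_deg if flow_angle_deg is not None else meta.get("flow_angle_deg", 0.0)
    )
    if channels is None or n_z is None or pixel_size_um is None:
        raise ValueError(
            f"{path}: missing stack metadata; pass channels, n_z and pixel_size_um"
        )
    if pages.ndim == 2:
        pages = pages[None]
    expected = n_z * len(channels)
    if pages.shape[0] != expected:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages, expected {expected} "
            f"({len(channels)} channels x {n_z} slices)"
        )
    chans = {
        name: pages[i * n_z : (i + 1) * n_z] for i, name in enumerate(channels)
    }
    return ImageStack(chans, pixel_size_um=float(pixel_size_um), flow_angle_deg=float(flow_angle_deg))


def write_mask_tiff(mask, path: str | Path) -> None:
    """Export a binary mask as an 8-bit TIFF (0/255), ImageJ-style."""
    tifffile.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    """Export a 2-D intensity/response/label image for audit."""
    tifffile.imwrite(str(path), np.asarray(image))


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fov_id": str, "sample_id": str, "patient_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def truth_to_dict(truth: SceneTruth) -> dict:
    return {
        "condition_label": truth.condition_label,
        "strings": [
            {
                "polyline": np.asarray(s.polyline).round(3).tolist(),
                "arclength_um": round(float(s.arclength_um), 6),
                "orientation_deg": round(float(s.orientation_deg), 3),
            }
            for s in truth.strings
        ],
        "agglomerates": [
            {"center": [round(c[0], 3), round(c[1], 3)], "radius_um": r}
            for c, r in truth.agglomerates
        ],
        "platelets": [
            {"center": [round(c[0], 3), round(c[1], 3)], "radius_um": r}
            for c, r in truth.platelets
        ],
    }


def truth_from_dict(d: dict) -> SceneTruth:
    return SceneTruth(
        strings=[
            TrueString(
                polyline=np.asarray(s["polyline"], dtype=float),
                arclength_um=float(s["arclength_um"]),
                orientation_deg=float(s["orientation_deg"]),
            )
            for s in d.get("strings", [])
        ],
        agglomerates=[
            ((a["center"][0], a["center"][1]), a["radius_um"])
            for a in d.get("agglomerates", [])
        ],
        platelets=[
            ((p["center"][0], p["center"][1]), p["radius_um"])
            for p in d.get("platelets", [])
        ],
        condition_label=d.get("condition_label", "control_vehicle"),
    )


def write_truth(truths: dict[str, SceneTruth], path: str | Path) -> None:
    payload = {fov_id: truth_to_dict(t) for fov_id, t in truths.items()}
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> dict[str, SceneTruth]:
    payload = json.loads(Path(path).read_text())
    return {fov_id: truth_from_dict(d) for fov_id, d in payload.items()}
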