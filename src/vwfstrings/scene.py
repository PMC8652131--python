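"""Synthetic two-channel confocal scene generator for VWF flow-assay images.

Emulates endpoint-fixed flow-chamber fields of view: histamine-stimulated
endothelial monolayers release von Willebrand factor (VWF) that unfurls into
flow-aligned strings; platelets (CD41 label) decorate the strings; round VWF
agglomerates (exocytosed, non-string material) dot the surface.  Each field of
view (FOV) is rendered as a two-channel z-stack with point-spread blur, Poisson
shot noise and Gaussian read noise, and is returned together with its exact
ground truth so that downstream segmentation can be validated.

Condition labels follow the four-arm study design: plasma source
(control / TTP) crossed with endothelial pretreatment (vehicle / fluvastatin).
TTP plasma raises string number and length; fluvastatin pretreatment lowers
both, on top of whichever plasma is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

CONDITIONS = ("control_vehicle", "control_fluva", "ttp_vehicle", "ttp_fluva")

CHANNEL_VWF = "VWF"
CHANNEL_CD41 = "CD41"


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic FOV.

    Geometry defaults mimic a spinning-disk confocal tile: a square FOV at
    0.22 μm/px with a 30 μm z-range sampled every 2 μm (15 slices).  String
    lengths are lognormal with a control median of ~10 μm and a tail past
    25 μm; all distributional choices are stand-ins for undeposited data and
    are fully parameterized.
    """

    fov_shape_px: tuple[int, int] = (768, 768)
    n_z_slices: int = 15
    pixel_size_um: float = 0.22
    flow_angle_deg: float = 0.0
    string_count_mean: float = 10.0
    string_length_um_lognormal_mu_sigma: tuple[float, float] = (math.log(10.0), 0.7)
    length_multiplier: float = 1.0
    count_multiplier: float = 1.0
    n_agglomerates: int = 6
    agglomerate_radius_um: tuple[float, float] = (1.5, 4.0)
    platelet_density_per_um_string: float = 0.15
    platelet_density_multiplier: float = 1.0
    platelet_radius_um: float = 1.0
    platelet_background_count: float = 10.0
    psf_sigma_um: float = 0.3
    background_level: float = 8.0
    gaussian_noise_sd: float = 3.0
    poisson_scaling: float = 1.0
    string_intensity: float = 600.0
    agglomerate_intensity: float = 110.0
    platelet_intensity: float = 150.0
    string_angle_jitter_deg: float = 5.0
    fixed_string_count: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.fov_shape_px[0] < 64 or self.fov_shape_px[1] < 64:
            raise ValueError("fov_shape_px must be at least (64, 64)")
        if self.n_z_slices < 1:
            raise ValueError("n_z_slices must be >= 1")
        if self.length_multiplier <= 0 or self.count_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if self.string_count_mean < 0:
            raise ValueError("string_count_mean must be >= 0")
        if self.platelet_density_per_um_string < 0:
            raise ValueError("platelet densities must be >= 0")
        if self.platelet_background_count < 0:
            raise ValueError("platelet_background_count must be >= 0")
        if self.n_agglomerates < 0:
            raise ValueError("n_agglomerates must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.poisson_scaling <= 0:
            raise ValueError("poisson_scaling must be > 0")


@dataclass(frozen=True)
class ConditionEffects:
    """Multiplicative condition effects applied on top of base parameters.

    Defaults reproduce the qualitative study outcome: TTP plasma roughly
    doubles total cumulative string length (length x count fold ~2.1) and
    raises platelet recruitment more strongly than string length alone (plasma
    UL-VWF thickening is folded into the platelet linear density), while
    fluvastatin pretreatment pushes string length and number down far enough
    that the treated TTP arm falls below the untreated control arm.
    """

    ttp_length_multiplier: float = 1.4
    ttp_count_multiplier: float = 1.5
    ttp_platelet_density_multiplier: float = 1.8
    fluva_length_multiplier: float = 0.6
    fluva_count_multiplier: float = 0.65

    def apply(self, base: SceneParams, condition: str) -> SceneParams:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        length = base.length_multiplier
        count = base.count_multiplier
        pdens = base.platelet_density_multiplier
        if condition.startswith("ttp"):
            length *= self.ttp_length_multiplier
            count *= self.ttp_count_multiplier
            pdens *= self.ttp_platelet_density_multiplier
        if condition.endswith("fluva"):
            length *= self.fluva_length_multiplier
            count *= self.fluva_count_multiplier
        return replace(
            base,
            length_multiplier=length,
            count_multiplier=count,
            platelet_density_multiplier=pdens,
        )


@dataclass
class TrueString:
    polyline: np.ndarray  # (n, 2) float, (y, x) pixel coordinates, in-FOV
    arclength_um: float
    orientation_deg: float


@dataclass
class SceneTruth:
    """Exact ground truth of one rendered FOV (pre-noise, pre-blur)."""

    strings: list[TrueString]
    agglomerates: list[tuple[tuple[float, float], float]]  # ((y, x), radius_um)
    platelets: list[tuple[tuple[float, float], float]]
    condition_label: str = "control_vehicle"

    @property
    def total_length_um(self) -> float:
        return float(sum(s.arclength_um for s in self.strings))


@dataclass
class ImageStack:
    """A two-channel confocal z-stack with pixel-size metadata.

    ``channels`` maps channel name to a (z, y, x) uint16 array; all channels
    share shape and pixel size.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    flow_angle_deg: float = 0.0

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ValueError(f"unknown channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]

    @property
    def shape_yx(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1], arr.shape[2]


def _anchor_interval(span: float, delta: float) -> tuple[float, float]:
    # Anchor range keeping both endpoints inside [0, span] when the string
    # fits; if it cannot fit, the swapped interval makes it span the FOV.
    lo, hi = max(0.0, -delta), min(span, span - delta)
    if hi < lo:
        lo, hi = hi, lo
    return lo, hi


def _walk_string(
    rng: np.random.Generator, params: SceneParams, length_px: float
) -> np.ndarray | None:
    """Random-walk polyline of ~unit-pixel steps, jittered about the flow axis.

    Returns the in-FOV portion as an (n, 2) array of (y, x) positions, or
    None when nothing lands inside the FOV (essentially never happens with
    containment anchoring; treated as a retry by the caller).
    """
    h, w = params.fov_shape_px
    n_steps = max(1, int(round(length_px)))
    theta0 = math.radians(params.flow_angle_deg)
    jitter = np.deg2rad(
        rng.normal(0.0, params.string_angle_jitter_deg, size=n_steps)
    )
    angles = theta0 + jitter
    dx = np.cos(angles)
    dy = np.sin(angles)
    # Anchor so the string fits inside the FOV whenever its length allows.
    total_dx = length_px * math.cos(theta0)
    total_dy = length_px * math.sin(theta0)
    x_lo, x_hi = _anchor_interval(w - 1.0, total_dx)
    y_lo, y_hi = _anchor_interval(h - 1.0, total_dy)
    # Small margin against jitter wander where there is room for one.
    pad = min(4.0, (y_hi - y_lo) / 2.0)
    x0 = rng.uniform(x_lo, x_hi)
    y0 = rng.uniform(y_lo + pad, y_hi - pad) if y_hi - y_lo > 2 * pad else rng.uniform(y_lo, y_hi)
    xs = np.concatenate(([x0], x0 + np.cumsum(dx)))
    ys = np.concatenate(([y0], y0 + np.cumsum(dy)))
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not inside.any():
        return None
    # Longest contiguous in-FOV run (jitter may briefly cross the border).
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = ends - starts
    k = int(np.argmax(runs))
    sel = idx[starts[k] : ends[k] + 1]
    if sel.size < 2:
        return None
    return np.column_stack((ys[sel], xs[sel]))


def _polyline_arclength_px(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def _deposit_polyline(img: np.ndarray, poly: np.ndarray, amplitude: float) -> None:
    iy = np.clip(np.round(poly[:, 0]).astype(int), 0, img.shape[0] - 1)
    ix = np.clip(np.round(poly[:, 1]).astype(int), 0, img.shape[1] - 1)
    # unique pixels along the path so overlapping steps do not double-deposit
    flat = iy * img.shape[1] + ix
    uniq = np.unique(flat)
    img.ravel()[uniq] += amplitude


def _deposit_blob(img: np.ndarray, center: tuple[float, float], sigma_px: float, amplitude: float) -> None:
    cy, cx = center
    r = max(2, int(math.ceil(3.0 * sigma_px)))
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2)
    )


def _deposit_disk(img: np.ndarray, center: tuple[float, float], radius_px: float, amplitude: float) -> None:
    cy, cx = center
    r = int(math.ceil(radius_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(img.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(img.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * (
        (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    )


def _z_weights(n_z: int) -> tuple[np.ndarray, np.ndarray]:
    """Slice indices and weights for surface-bound structures.

    Strings and platelets lie on the apical cell surface, so their signal is
    confined to (up to) three adjacent slices around the stack centre.
    """
    center = n_z // 2
    if n_z >= 3:
        idx = np.array([center - 1, center, center + 1])
        idx = np.clip(idx, 0, n_z - 1)
        w = np.array([0.25, 0.5, 0.25])
    else:
        idx = np.arange(n_z)
        w = np.full(n_z, 1.0 / n_z)
    return idx, w


def generate_fov(params: SceneParams) -> tuple[ImageStack, SceneTruth]:
    """Render one synthetic FOV and return (image stack, ground truth).

    Ground truth describes the scene before blur and noise; identical
    parameters (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.fov_shape_px
    px = params.pixel_size_um

    mu, sigma = params.string_length_um_lognormal_mu_sigma
    mu = mu + math.log(params.length_multiplier)

    if params.fixed_string_count is not None:
        n_strings = int(params.fixed_string_count)
    else:
        lam = params.string_count_mean * params.count_multiplier
        n_strings = int(rng.poisson(lam)) if lam > 0 else 0

    vwf_plane = np.zeros((h, w), dtype=np.float64)
    cd41_plane = np.zeros((h, w), dtype=np.float64)

    strings: list[TrueString] = []
    platelets: list[tuple[tuple[float, float], float]] = []
    for _ in range(n_strings):
        length_um = float(rng.lognormal(mu, sigma)) if sigma > 0 else math.exp(mu)
        poly = None
        for _attempt in range(4):
            poly = _walk_string(rng, params, length_um / px)
            if poly is not None:
                break
        if poly is None:  # pragma: no cover - containment anchoring prevents this
            continue
        arclength = _polyline_arclength_px(poly) * px
        dy, dx = poly[-1] - poly[0]
        orientation = math.degrees(math.atan2(dy, dx))
        strings.append(TrueString(poly, arclength, orientation))
        _deposit_polyline(vwf_plane, poly, params.string_intensity)

        # platelets decorate the string at a linear density per μm
        lam_p = (
            params.platelet_density_per_um_string
            * params.platelet_density_multiplier
            * arclength
        )
        n_p = int(rng.poisson(lam_p)) if lam_p > 0 else 0
        if n_p > 0:
            ts = rng.integers(0, poly.shape[0], size=n_p)
            offs = rng.normal(0.0, 1.0, size=(n_p, 2))
            for t, off in zip(ts, offs):
                c = poly[t] + off
                cy = float(np.clip(c[0], 0, h - 1))
                cx = float(np.clip(c[1], 0, w - 1))
                platelets.append(((cy, cx), params.platelet_radius_um))
                _deposit_disk(
                    cd41_plane,
                    (cy, cx),
                    params.platelet_radius_um / px,
                    params.platelet_intensity,
                )

    agglomerates: list[tuple[tuple[float, float], float]] = []
    r_lo, r_hi = params.agglomerate_radius_um
    for _ in range(params.n_agglomerates):
        radius_um = float(rng.uniform(r_lo, r_hi))
        cy = float(rng.uniform(0, h - 1))
        cx = float(rng.uniform(0, w - 1))
        agglomerates.append(((cy, cx), radius_um))
        _deposit_blob(
            vwf_plane, (cy, cx), radius_um / px / 1.5, params.agglomerate_intensity
        )

    # background scatter of unbound platelets
    n_bg = (
        int(rng.poisson(params.platelet_background_count))
        if params.platelet_background_count > 0
        else 0
    )
    for _ in range(n_bg):
        cy = float(rng.uniform(0, h - 1))
        cx = float(rng.uniform(0, w - 1))
        platelets.append(((cy, cx), params.platelet_radius_um))
        _deposit_disk(
            cd41_plane, (cy, cx), params.platelet_radius_um / px, params.platelet_intensity
        )

    zi, zw = _z_weights(params.n_z_slices)
    psf_sigma_px = params.psf_sigma_um / px
    ps = params.poisson_scaling
    bg = params.background_level
    channels: dict[str, np.ndarray] = {}
    for name, plane in ((CHANNEL_VWF, vwf_plane), (CHANNEL_CD41, cd41_plane)):
        if psf_sigma_px > 0 and plane.any():
            blurred = gaussian_filter(plane, psf_sigma_px, mode="reflect")
        else:
            blurred = plane
        # Shot noise: scalar-rate Poisson for the (dominant) uniform
        # background, array-rate only on signal pixels of the signal slices.
        stack = rng.poisson(bg * ps, size=(params.n_z_slices, h, w)).astype(np.float32)
        if ps != 1.0:
            stack /= np.float32(ps)
        sig_idx = np.flatnonzero(blurred > 1e-6)
        if sig_idx.size:
            sig = blurred.ravel()[sig_idx]
            for i, wt in zip(zi, zw):
                stack[i].ravel()[sig_idx] = (
                    rng.poisson((bg + wt * sig) * ps) / ps
                ).astype(np.float32)
        if params.gaussian_noise_sd > 0:
            noise = rng.standard_normal(stack.shape, dtype=np.float32)
            np.multiply(noise, np.float32(params.gaussian_noise_sd), out=noise)
            np.add(stack, noise, out=stack)
        np.rint(stack, out=stack)
        np.clip(stack, 0, 65535, out=stack)
        channels[name] = stack.astype(np.uint16)

    truth = SceneTruth(strings, agglomerates, platelets)
    stack_out = ImageStack(channels, pixel_size_um=px, flow_angle_deg=params.flow_angle_deg)
    return stack_out, truth


def add_agglomerates(
    stack: ImageStack,
    params: SceneParams,
    n: int,
    seed: int,
) -> tuple[ImageStack, list[tuple[tuple[float, float], float]]]:
    """Return a copy of ``stack`` with ``n`` extra VWF agglomerates rendered in.

    The blob layer carries its own Poisson shot noise and is added to the
    existing image; since independent Poisson counts are additive, the result
    is distributed exactly like a scene rendered with the blobs present,
    while every other structure (and its noise) stays bit-identical.  Used to
    probe agglomerate rejection on otherwise unchanged scenes.
    """
    rng = np.random.default_rng(seed)
    h, w = stack.shape_yx
    px = stack.pixel_size_um
    plane = np.zeros((h, w), dtype=np.float64)
    blobs: list[tuple[tuple[float, float], float]] = []
    r_lo, r_hi = params.agglomerate_radius_um
    for _ in range(n):
        radius_um = float(rng.uniform(r_lo, r_hi))
        cy = float(rng.uniform(0, h - 1))
        cx = float(rng.uniform(0, w - 1))
        blobs.append(((cy, cx), radius_um))
        _deposit_blob(plane, (cy, cx), radius_um / px / 1.5, params.agglomerate_intensity)
    psf_sigma_px = params.psf_sigma_um / px
    if psf_sigma_px > 0 and plane.any():
        plane = gaussian_filter(plane, psf_sigma_px, mode="reflect")
    zi, zw = _z_weights(params.n_z_slices)
    vwf = stack.channels[CHANNEL_VWF].astype(np.float64)
    ps = params.poisson_scaling
    sig_idx = np.flatnonzero(plane > 1e-6)
    sig = plane.ravel()[sig_idx]
    for i, wt in zip(zi, zw):
        vwf[i].ravel()[sig_idx] += rng.poisson(wt * sig * ps) / ps
    channels = dict(stack.channels)
    channels[CHANNEL_VWF] = np.clip(np.rint(vwf), 0, 65535).astype(np.uint16)
    return (
        ImageStack(channels, pixel_size_um=px, flow_angle_deg=stack.flow_angle_deg),
        blobs,
    )


def generate_sample_set(
    base: SceneParams,
    n_fov: int,
    condition: str,
    seed: int,
    effects: ConditionEffects | None = None,
) -> list[tuple[ImageStack, SceneTruth]]:
    """Generate ``n_fov`` FOVs of one sample under a study condition.

    Condition multipliers are applied on top of the base parameters; each FOV
    gets an independent substream of the given seed.
    """
    if n_fov < 1:
        raise ValueError("n_fov must be >= 1")
    effects = effects or ConditionEffects()
    params = effects.apply(base, condition)
    fov_seeds = fov_seed_stream(seed, n_fov)
    out = []
    for s in fov_seeds:
        stack, truth = generate_fov(replace(params, seed=int(s)))
        truth.condition_label = condition
        out.append((stack, truth))
    return out


def fov_seed_stream(seed: int, n: int) -> np.ndarray:
    """Deterministic per-FOV seeds (each < 2**31) derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) % (2**31)
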