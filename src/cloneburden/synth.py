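"""Synthetic midgut generator with full ground truth.

No imaging dataset accompanies the assay this package reimplements, so the
generator is the test bed: it draws clone and nucleus populations from the
condition presets, places them in an idealised midgut, rasterises them into a
calibrated multi-channel image, and records every true area and mask.  The
measurement pipeline (:mod:`cloneburden.quant`, :mod:`cloneburden.classify`)
is then validated by parameter recovery against that ground truth.

Structure and noise are drawn from two independent seeded streams, so the
same gut can be re-rendered with different z-plane counts or noise without
changing clone/nucleus geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .images import CalibratedImage, write_tiff
from .presets import (
    TUMOUR_AREA_THRESHOLD_UM2,
    ConditionPreset,
    MidgutGeometry,
    RenderConfig,
)

__all__ = [
    "PlacementError",
    "GroundTruthClone",
    "GroundTruthNucleus",
    "GroundTruth",
    "generate_midgut",
    "generate_batch",
    "derive_gut_seed",
    "sample_luciferase",
    "sample_survival",
]

_PLACEMENT_RETRIES = 200
_NUCLEUS_RETRIES = 60
_MASK_GAP_PX = 2  # minimum clearance between rendered objects


class PlacementError(RuntimeError):
    """A clone could not be placed inside the gut after bounded retries."""


@dataclass
class GroundTruthClone:
    clone_id: int
    area_um2: float  # rasterised (mask pixel count x pixel area)
    sampled_area_um2: float  # value drawn from the preset law
    centroid_x_px: float
    centroid_y_px: float
    anterior: bool
    component: str  # "base" or "merged"


@dataclass
class GroundTruthNucleus:
    nucleus_id: int
    clone_id: int  # 0 = outside any clone (background epithelium)
    area_um2: float
    centroid_x_px: float
    centroid_y_px: float


@dataclass
class GroundTruth:
    """Generator-side record of everything that was rendered."""

    preset_name: str
    seed: int
    pixel_size_um: float
    clones: list[GroundTruthClone]
    nuclei: list[GroundTruthNucleus]
    clone_labels: np.ndarray  # int32, 0 = background
    nucleus_labels: np.ndarray
    gut_mask: np.ndarray  # bool
    gut_area_um2: float
    anterior_boundary_x_px: float  # clones left of this are anterior
    gut_x_bounds_px: tuple[int, int]

    def clone_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "area_um2": c.area_um2,
                    "sampled_area_um2": c.sampled_area_um2,
                    "centroid_x_px": c.centroid_x_px,
                    "centroid_y_px": c.centroid_y_px,
                    "anterior": c.anterior,
                    "component": c.component,
                }
                for c in self.clones
            ],
            columns=[
                "clone_id",
                "area_um2",
                "sampled_area_um2",
                "centroid_x_px",
                "centroid_y_px",
                "anterior",
                "component",
            ],
        )

    def nucleus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus_id": n.nucleus_id,
                    "clone_id": n.clone_id,
                    "area_um2": n.area_um2,
                    "centroid_x_px": n.centroid_x_px,
                    "centroid_y_px": n.centroid_y_px,
                }
                for n in self.nuclei
            ],
            columns=["nucleus_id", "clone_id", "area_um2", "centroid_x_px", "centroid_y_px"],
        )

    def total_clone_area_um2(self) -> float:
        return float(sum(c.area_um2 for c in self.clones))


# ---------------------------------------------------------------------------
# Rasterisation helpers


def _blob_mask(rng: np.random.Generator, area_px: float, irregularity: float = 0.10):
    """Rasterise a mildly irregular blob of (approximately) ``area_px`` pixels.

    The boundary is a circle perturbed by three low-frequency harmonics; one
    corrective rescale brings the rasterised pixel count within ~1% of the
    target so that hard area truncations in the presets survive rendering.
    Returns (mask, r_max) with the mask centred in its own bounding array.
    """
    r0 = math.sqrt(area_px / math.pi)
    amps = rng.uniform(-irregularity, irregularity, size=3)
    phases = rng.uniform(0, 2 * math.pi, size=3)

    def rasterise(scale: float):
        r_theta_max = scale * r0 * (1.0 + np.abs(amps).sum())
        half = int(math.ceil(r_theta_max)) + 1
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        rr = np.hypot(yy, xx)
        theta = np.arctan2(yy, xx)
        boundary = scale * r0 * (
            1.0
            + amps[0] * np.cos(2 * theta + phases[0])
            + amps[1] * np.cos(3 * theta + phases[1])
            + amps[2] * np.cos(5 * theta + phases[2])
        )
        return rr <= boundary, r_theta_max

    mask, r_max = rasterise(1.0)
    actual = mask.sum()
    if actual > 0:
        mask, r_max = rasterise(math.sqrt(area_px / actual))
    return mask, r_max


def _ellipse_mask(area_px: float, aspect: float, theta: float):
    """Rasterise an ellipse of ``area_px`` pixels, aspect ratio >= 1, tilt theta."""

    def rasterise(scale: float):
        a = scale * math.sqrt(area_px * aspect / math.pi)
        b = a / aspect
        half = int(math.ceil(a)) + 1
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        u = xx * math.cos(theta) + yy * math.sin(theta)
        v = -xx * math.sin(theta) + yy * math.cos(theta)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    mask = rasterise(1.0)
    actual = mask.sum()
    if actual > 0:
        mask = rasterise(math.sqrt(area_px / actual))
    return mask


def _paint(canvas: np.ndarray, mask: np.ndarray, cy: int, cx: int, value) -> None:
    h, w = mask.shape
    y0, x0 = cy - h // 2, cx - w // 2
    sub = canvas[y0 : y0 + h, x0 : x0 + w]
    sub[mask] = value


def _region_overlaps(occupancy: np.ndarray, mask: np.ndarray, cy: int, cx: int) -> bool:
    h, w = mask.shape
    y0, x0 = cy - h // 2, cx - w // 2
    if y0 < 0 or x0 < 0 or y0 + h > occupancy.shape[0] or x0 + w > occupancy.shape[1]:
        return True
    return bool(np.any(occupancy[y0 : y0 + h, x0 : x0 + w] & mask))


def _dilate(mask: np.ndarray, gap: int) -> np.ndarray:
    if gap <= 0:
        return mask
    return ndi.binary_dilation(mask, iterations=gap)


# ---------------------------------------------------------------------------
# Gut geometry realisation


def _realise_gut(
    geometry: MidgutGeometry, render: RenderConfig, rng: np.random.Generator
):
    """Draw one gut's realised shape and rasterise its mask."""
    px = render.pixel_size_um
    length = geometry.length_um * (1.0 + rng.uniform(-geometry.length_jitter, geometry.length_jitter))
    length = min(length, MidgutGeometry.MAX_LENGTH_UM)
    width_scale = 1.0 + rng.uniform(-geometry.width_jitter, geometry.width_jitter)
    bulge_phase = rng.uniform(0, 2 * math.pi)
    curve_phase = rng.uniform(0, 2 * math.pi)
    curve_amp = geometry.curvature_amplitude_um * rng.uniform(0.5, 1.0)

    length_px = int(round(length / px))
    margin = render.margin_px
    t = (np.arange(length_px) + 0.5) / length_px
    half_width_px = geometry.half_width_um(t, bulge_phase) * width_scale / px
    centre_y_um = curve_amp * np.sin(2 * math.pi * t + curve_phase)

    height_px = int(2 * math.ceil(half_width_px.max() + curve_amp / px) + 2 * margin)
    width_canvas = length_px + 2 * margin
    centre_y_px = height_px / 2.0 + centre_y_um / px

    mask = np.zeros((height_px, width_canvas), dtype=bool)
    yy = np.arange(height_px)[:, None]
    mask[:, margin : margin + length_px] = (
        np.abs(yy - centre_y_px[None, :]) <= half_width_px[None, :]
    )
    return mask, (margin, margin + length_px)


# ---------------------------------------------------------------------------
# Main entry points


def generate_midgut(
    preset: ConditionPreset,
    geometry: MidgutGeometry | None = None,
    render: RenderConfig | None = None,
    seed: int = 0,
    image_id: str = "",
) -> tuple[CalibratedImage, GroundTruth]:
    """Generate one synthetic midgut image plus its ground truth.

    Deterministic in ``seed``: identical arguments give bit-identical pixel
    arrays and ground truth.  Raises :class:`PlacementError` if a clone
    cannot be fitted into the gut after bounded retries (e.g. clone areas
    far too large for the supplied geometry).
    """
    geometry = geometry or MidgutGeometry()
    render = render or RenderConfig()
    ss = np.random.SeedSequence(seed)
    rng_structure, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    px = render.pixel_size_um
    px_area = px * px

    gut_mask, (x_lo, x_hi) = _realise_gut(geometry, render, rng_structure)
    gut_area_um2 = float(gut_mask.sum()) * px_area
    anterior_x = x_lo + geometry.anterior_fraction * (x_hi - x_lo)

    dt_gut = ndi.distance_transform_edt(gut_mask)

    # --- clones -----------------------------------------------------------
    draws: list[tuple[float, str]] = []
    for component in preset.clone_components:
        label = "merged" if component.area_law.lower >= TUMOUR_AREA_THRESHOLD_UM2 else "base"
        n = component.count_law.sample(rng_structure)
        for area in component.area_law.sample(rng_structure, n):
            draws.append((float(area), label))
    draws.sort(key=lambda d: -d[0])  # place big clones first

    clone_labels = np.zeros(gut_mask.shape, dtype=np.int32)
    clone_occupancy = np.zeros(gut_mask.shape, dtype=bool)
    clones: list[GroundTruthClone] = []
    clone_intensity_factor: dict[int, float] = {}
    for clone_id, (area_um2, component_name) in enumerate(draws, start=1):
        area_px = area_um2 / px_area
        mask, r_max = _blob_mask(rng_structure, area_px)
        footprint = _dilate(mask, _MASK_GAP_PX)
        candidates = dt_gut > (r_max + 1.0)
        if preset.anterior_restricted:
            xs = np.arange(gut_mask.shape[1])
            candidates = candidates & (xs[None, :] + r_max <= anterior_x)
        cand_idx = np.flatnonzero(candidates.ravel())
        if cand_idx.size == 0:
            raise PlacementError(
                f"no valid position for clone of {area_um2:.0f} um^2 "
                f"(gut too small or anterior region too narrow)"
            )
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            flat = int(rng_structure.choice(cand_idx))
            cy, cx = divmod(flat, gut_mask.shape[1])
            if not _region_overlaps(clone_occupancy, footprint, cy, cx):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place clone of {area_um2:.0f} um^2 after "
                f"{_PLACEMENT_RETRIES} retries (gut too crowded)"
            )
        _paint(clone_labels, mask, cy, cx, clone_id)
        _paint(clone_occupancy, footprint, cy, cx, True)
        clone_intensity_factor[clone_id] = rng_structure.uniform(0.9, 1.1)
        clones.append(
            GroundTruthClone(
                clone_id=clone_id,
                area_um2=float(mask.sum()) * px_area,
                sampled_area_um2=area_um2,
                centroid_x_px=float(cx),
                centroid_y_px=float(cy),
                anterior=bool(cx <= anterior_x),
                component=component_name,
            )
        )

    # --- nuclei -----------------------------------------------------------
    nucleus_labels = np.zeros(gut_mask.shape, dtype=np.int32)
    nucleus_occupancy = np.zeros(gut_mask.shape, dtype=bool)
    nuclei: list[GroundTruthNucleus] = []
    nucleus_id = 0

    def place_nucleus(area_um2: float, clone_id: int, cand_idx: np.ndarray) -> None:
        nonlocal nucleus_id
        area_px = area_um2 / px_area
        aspect = rng_structure.uniform(1.0, 1.6)
        theta = rng_structure.uniform(0, math.pi)
        mask = _ellipse_mask(area_px, aspect, theta)
        footprint = _dilate(mask, _MASK_GAP_PX)
        for _ in range(_NUCLEUS_RETRIES):
            flat = int(rng_structure.choice(cand_idx))
            cy, cx = divmod(flat, gut_mask.shape[1])
            if not _region_overlaps(nucleus_occupancy, footprint, cy, cx):
                nucleus_id += 1
                _paint(nucleus_labels, mask, cy, cx, nucleus_id)
                _paint(nucleus_occupancy, footprint, cy, cx, True)
                nuclei.append(
                    GroundTruthNucleus(
                        nucleus_id=nucleus_id,
                        clone_id=clone_id,
                        area_um2=float(mask.sum()) * px_area,
                        centroid_x_px=float(cx),
                        centroid_y_px=float(cy),
                    )
                )
                return
        # densely packed clone: the nucleus is skipped, realized density
        # saturates below the nominal law (documented behaviour)

    for clone in clones:
        clone_px_idx = np.flatnonzero((clone_labels == clone.clone_id).ravel())
        n_nuclei = rng_structure.poisson(
            preset.nuclei_density_per_1000um2 * clone.area_um2 / 1000.0
        )
        areas = preset.nuclear_area_law.sample(rng_structure, n_nuclei)
        for area in np.sort(areas)[::-1]:
            place_nucleus(float(area), clone.clone_id, clone_px_idx)

    # Sparse small background nuclei outside clones (ordinary epithelium);
    # these exercise the pipeline's nucleus-to-clone exclusion rule.
    bg_candidates = np.flatnonzero((gut_mask & ~clone_occupancy).ravel())
    n_bg = rng_structure.poisson(0.2 * gut_area_um2 / 1000.0)
    if bg_candidates.size:
        for area in rng_structure.uniform(30.0, 90.0, size=n_bg):
            place_nucleus(float(area), 0, bg_candidates)

    # --- render -----------------------------------------------------------
    green = np.full(gut_mask.shape, render.green_background, dtype=np.float32)
    green[gut_mask] = render.green_gut_background
    for clone in clones:
        sel = clone_labels == clone.clone_id
        green[sel] = render.clone_intensity * clone_intensity_factor[clone.clone_id]
    red = np.full(gut_mask.shape, render.red_background, dtype=np.float32)
    red[gut_mask] = render.gut_red_intensity
    blue = np.full(gut_mask.shape, render.blue_background, dtype=np.float32)
    blue[nucleus_labels > 0] = render.nucleus_intensity

    top = float(2**render.bit_depth - 1)
    planes = np.empty((render.n_zplanes, 3) + gut_mask.shape, dtype=render.dtype)
    for z in range(render.n_zplanes):
        for c, signal in enumerate((green, red, blue)):
            jitter = 1.0 + rng_noise.normal(0.0, render.zplane_intensity_jitter)
            plane = signal * jitter
            sigma = np.sqrt(render.read_noise_sd**2 + plane / render.photon_gain)
            plane = plane + rng_noise.normal(0.0, 1.0, size=plane.shape).astype(np.float32) * sigma
            planes[z, c] = np.clip(plane, 0.0, top).astype(render.dtype)

    image = CalibratedImage(
        data=planes,
        pixel_size_um=px,
        channel_names=("green", "red", "blue"),
        image_id=image_id or f"{preset.name}_seed{seed}",
    )
    truth = GroundTruth(
        preset_name=preset.name,
        seed=int(seed),
        pixel_size_um=px,
        clones=clones,
        nuclei=nuclei,
        clone_labels=clone_labels,
        nucleus_labels=nucleus_labels,
        gut_mask=gut_mask,
        gut_area_um2=gut_area_um2,
        anterior_boundary_x_px=float(anterior_x),
        gut_x_bounds_px=(int(x_lo), int(x_hi)),
    )
    return image, truth


def derive_gut_seed(batch_seed: int, index: int) -> int:
    """Deterministic per-gut seed derived from a batch seed (stays < 2**31)."""
    state = np.random.SeedSequence([int(batch_seed), int(index)]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def generate_batch(
    preset: ConditionPreset,
    n_guts: int,
    out_dir,
    seed: int,
    geometry: MidgutGeometry | None = None,
    render: RenderConfig | None = None,
    write_label_images: bool = True,
) -> pd.DataFrame:
    """Write ``n_guts`` synthetic images plus ground-truth tables to a folder.

    Per-gut seeds are derived deterministically from the batch seed (see
    :func:`derive_gut_seed`), so gut ``i`` of a batch is bit-identical to
    ``generate_midgut(..., seed=derive_gut_seed(seed, i))``.  Returns the
    batch manifest (one row per gut).
    """
    if n_guts < 1:
        raise ValueError(f"n_guts must be >= 1, got {n_guts}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    clone_frames = []
    nucleus_frames = []
    for i in range(n_guts):
        gut_seed = derive_gut_seed(seed, i)
        name = f"{preset.name}_gut{i:03d}"
        image, truth = generate_midgut(
            preset, geometry=geometry, render=render, seed=gut_seed, image_id=name
        )
        image_path = out_dir / f"{name}.tif"
        write_tiff(image, image_path)
        if write_label_images:
            labels = CalibratedImage(
                truth.clone_labels.astype(np.uint16)[None, None],
                pixel_size_um=image.pixel_size_um,
                channel_names=("labels",),
                image_id=f"{name}_clone_labels",
            )
            write_tiff(labels, out_dir / f"{name}_clone_labels.tif")
        ct = truth.clone_table()
        ct.insert(0, "image_id", name)
        clone_frames.append(ct)
        nt = truth.nucleus_table()
        nt.insert(0, "image_id", name)
        nucleus_frames.append(nt)
        manifest_rows.append(
            {
                "image_id": name,
                "path": image_path.name,
                "seed": gut_seed,
                "preset": preset.name,
                "gut_area_um2": truth.gut_area_um2,
                "n_clones": len(truth.clones),
                "total_clone_area_um2": truth.total_clone_area_um2(),
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.concat(clone_frames, ignore_index=True).to_csv(
        out_dir / "ground_truth_clones.csv", index=False
    )
    pd.concat(nucleus_frames, ignore_index=True).to_csv(
        out_dir / "ground_truth_nuclei.csv", index=False
    )
    return manifest


def sample_luciferase(
    preset: ConditionPreset, week: int, n_flies: int, seed: int
) -> np.ndarray:
    """Per-fly luciferase activities (relative light units) for one arm/week.

    Readings are lognormal — strictly positive with the large between-fly
    variability characteristic of the assay.  Week must be one the preset
    parameterises (2 or 3 for the built-ins).
    """
    if n_flies < 1:
        raise ValueError(f"n_flies must be >= 1, got {n_flies}")
    if week not in preset.luciferase_laws:
        raise ValueError(
            f"week {week} not parameterised for preset {preset.name!r} "
            f"(have {sorted(preset.luciferase_laws)})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(week)]))
    return preset.luciferase_laws[week].sample(rng, n_flies)


def sample_survival(
    preset: ConditionPreset,
    n_flies: int,
    n_days: int,
    seed: int,
    hazard: float | None = None,
) -> pd.DataFrame:
    """Simulate per-fly survival under a constant daily death hazard.

    Returns a table with columns ``fly_id``, ``day`` (death day, or the final
    observation day for survivors) and ``died``.  Each fly dies on day ``d``
    with probability ``hazard * (1 - hazard)**(d-1)``.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    if n_flies < 1:
        raise ValueError(f"n_flies must be >= 1, got {n_flies}")
    h = preset.daily_death_hazard if hazard is None else hazard
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"hazard must be in [0, 1], got {h}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    if h == 0.0:
        days = np.full(n_flies, n_days, dtype=int)
        died = np.zeros(n_flies, dtype=bool)
    else:
        u = rng.uniform(size=n_flies)
        if h == 1.0:
            death_day = np.ones(n_flies, dtype=int)
        else:
            death_day = np.ceil(np.log(u) / np.log1p(-h)).astype(int)
            death_day = np.maximum(death_day, 1)
        died = death_day <= n_days
        days = np.where(died, death_day, n_days)
    return pd.DataFrame(
        {
            "fly_id": np.arange(n_flies),
            "day": days,
            "died": died,
            "condition": preset.name,
        }
    )
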