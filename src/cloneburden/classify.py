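"""Tumour-like clone classification and nuclear morphometry.

A clone counts as tumour-like when its area strictly exceeds the
7,800 um^2 threshold — in this midgut model such clones arise only in the
Apc/Ras tumour condition, never in control or merely over-proliferating
(Snail) clones, which makes clone area a robust screening readout.
Nuclear morphometry (maximal nuclear cross-section per clone, nucleus
count and density) provides the finer discrimination between control
(max 420 um^2), tumour-like (up to 980 um^2) and drug-treated tumour
(~680 um^2) clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, segmentation

from . import assays
from .images import CalibratedImage
from .presets import TUMOUR_AREA_THRESHOLD_UM2
from .quant import CloneLabelMap, CloneMeasurement, _auto_threshold

__all__ = [
    "CloneClass",
    "NucleusMeasurement",
    "CloneMorphometry",
    "MissingChannelError",
    "MorphometryConsistencyError",
    "classify_clones",
    "count_tumour_like",
    "segment_nuclei_in_clones",
    "nuclei_to_frame",
    "clone_morphometry",
    "condition_summary",
]

DEFAULT_MIN_NUCLEUS_SIZE_UM2 = 20.0


class MissingChannelError(ValueError):
    """The image lacks the channel an operation needs (e.g. no DAPI)."""


class MorphometryConsistencyError(ValueError):
    """A nucleus references a clone id absent from the clone list."""


@dataclass(frozen=True)
class CloneClass:
    clone_id: int
    area_um2: float
    tumour_like: bool
    threshold_um2: float
    image_id: str = ""


@dataclass(frozen=True)
class NucleusMeasurement:
    nucleus_id: int
    clone_id: int
    area_um2: float
    centroid_x_um: float
    centroid_y_um: float
    image_id: str = ""


@dataclass(frozen=True)
class CloneMorphometry:
    clone_id: int
    max_nuclear_area_um2: float  # NaN when the clone holds no nucleus
    nuclei_count: int
    nuclei_density_per_1000um2: float


def classify_clones(
    measurements,
    threshold_um2: float = TUMOUR_AREA_THRESHOLD_UM2,
) -> list[CloneClass]:
    """Classify clones by the strict ``area > threshold`` rule.

    Accepts a list of :class:`~cloneburden.quant.CloneMeasurement` or a
    DataFrame with ``clone_id`` and ``area_um2`` columns.  A clone of
    exactly the threshold area is *not* tumour-like ("over" is strict).
    """
    if threshold_um2 <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold_um2}")
    if isinstance(measurements, pd.DataFrame):
        records = [
            (int(r.clone_id), float(r.area_um2), getattr(r, "image_id", ""))
            for r in measurements.itertuples()
        ]
    else:
        records = [(m.clone_id, m.area_um2, m.image_id) for m in measurements]
    return [
        CloneClass(
            clone_id=cid,
            area_um2=area,
            tumour_like=area > threshold_um2,
            threshold_um2=threshold_um2,
            image_id=img,
        )
        for cid, area, img in records
    ]


def count_tumour_like(classes: list[CloneClass]) -> int:
    return sum(c.tumour_like for c in classes)


def _split_touching(region_mask: np.ndarray, min_distance_px: float):
    """Separate touching nuclei in one connected component.

    Marker-based watershed on the distance transform: markers are the
    connected blobs where the distance map exceeds 0.85 of its maximum.
    A single convex nucleus always yields one marker (superlevel sets of
    the distance transform over a convex region are connected), while two
    fused nuclei pinched at a waist yield two and are split.
    """
    dt = ndi.distance_transform_edt(np.pad(region_mask, 1))[1:-1, 1:-1]
    markers = measure.label(dt > 0.85 * dt.max(), connectivity=2)
    if markers.max() <= 1:
        return region_mask.astype(np.int32)
    return segmentation.watershed(-dt, markers, mask=region_mask).astype(np.int32)


def segment_nuclei_in_clones(
    image: CalibratedImage,
    labels: CloneLabelMap,
    nuclei_channel: str = "blue",
    threshold_value: float | None = None,
    min_size_um2: float = DEFAULT_MIN_NUCLEUS_SIZE_UM2,
) -> list[NucleusMeasurement]:
    """Segment nuclei and assign each to the clone containing its centroid.

    The nuclei (DAPI) channel is thresholded (Otsu by default), touching
    nuclei are separated by distance-transform watershed, and nuclei whose
    centroid falls outside every clone are excluded.  Raises
    :class:`MissingChannelError` when the channel is absent; a blank
    channel yields an empty list.
    """
    if not image.has_channel(nuclei_channel):
        raise MissingChannelError(
            f"image has no {nuclei_channel!r} channel; cannot segment nuclei"
        )
    plane = image.channel(nuclei_channel)
    if threshold_value is None:
        threshold = _auto_threshold(plane, None)
        if threshold is None:
            return []
    else:
        threshold = float(threshold_value)
    mask = plane > threshold
    if not mask.any():
        return []

    px = image.pixel_size_um
    px_area = px * px
    min_px = max(1.0, min_size_um2 / px_area)

    components = measure.label(mask, connectivity=2)
    out: list[NucleusMeasurement] = []
    nucleus_id = 0
    for comp in measure.regionprops(components):
        if comp.area < min_px:
            continue
        sub = _split_touching(comp.image, min_distance_px=np.sqrt(comp.area / np.pi))
        y0, x0, _, _ = comp.bbox
        for nucleus in measure.regionprops(sub):
            if nucleus.area < min_px:
                continue
            cy, cx = nucleus.centroid
            gy, gx = int(round(cy)) + y0, int(round(cx)) + x0
            clone_id = int(labels.labels[gy, gx])
            if clone_id == 0:
                continue  # background-epithelium nucleus, outside any clone
            nucleus_id += 1
            out.append(
                NucleusMeasurement(
                    nucleus_id=nucleus_id,
                    clone_id=clone_id,
                    area_um2=float(nucleus.area) * px_area,
                    centroid_x_um=(cx + x0) * px,
                    centroid_y_um=(cy + y0) * px,
                    image_id=image.image_id,
                )
            )
    return out


def nuclei_to_frame(nuclei: list[NucleusMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nucleus_id": n.nucleus_id,
                "clone_id": n.clone_id,
                "area_um2": n.area_um2,
                "centroid_x_um": n.centroid_x_um,
                "centroid_y_um": n.centroid_y_um,
                "image_id": n.image_id,
            }
            for n in nuclei
        ],
        columns=[
            "nucleus_id",
            "clone_id",
            "area_um2",
            "centroid_x_um",
            "centroid_y_um",
            "image_id",
        ],
    )


def clone_morphometry(
    nuclei: list[NucleusMeasurement], clones: list[CloneMeasurement]
) -> list[CloneMorphometry]:
    """Per-clone nuclear summaries: maximal nuclear area, count, density.

    Density is nuclei per 1,000 um^2 of clone area.  A clone with no
    nucleus reports NaN maximal area and zero count; a nucleus referencing
    an unknown clone raises :class:`MorphometryConsistencyError`.
    """
    clone_areas = {m.clone_id: m.area_um2 for m in clones}
    per_clone: dict[int, list[float]] = {cid: [] for cid in clone_areas}
    for n in nuclei:
        if n.clone_id not in clone_areas:
            raise MorphometryConsistencyError(
                f"nucleus {n.nucleus_id} references unknown clone {n.clone_id}"
            )
        per_clone[n.clone_id].append(n.area_um2)
    out = []
    for cid, areas in per_clone.items():
        out.append(
            CloneMorphometry(
                clone_id=cid,
                max_nuclear_area_um2=max(areas) if areas else float("nan"),
                nuclei_count=len(areas),
                nuclei_density_per_1000um2=len(areas) / (clone_areas[cid] / 1000.0),
            )
        )
    return out


def condition_summary(
    clones: pd.DataFrame,
    guts: pd.DataFrame,
    nuclei: pd.DataFrame | None = None,
    threshold_um2: float = TUMOUR_AREA_THRESHOLD_UM2,
    conditions: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition summary plus pairwise tests on supra-threshold counts.

    ``clones`` needs columns ``image_id, condition, area_um2``; ``guts``
    needs ``image_id, condition, gut_area_um2``; ``nuclei`` (optional)
    needs ``condition, area_um2``.  Returns ``(summary, comparisons)``:
    one summary row per condition, and Kruskal–Wallis (with Holm-corrected
    Mann–Whitney pairs when more than two conditions) on the per-gut number
    of supra-threshold clones.
    """
    labels = sorted(guts["condition"].unique())
    if conditions is not None:
        unknown = set(labels) - set(conditions)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    rows = []
    supra_by_condition: dict[str, np.ndarray] = {}
    for cond in labels:
        gut_rows = guts[guts["condition"] == cond]
        clone_rows = clones[clones["condition"] == cond] if len(clones) else clones
        supra = []
        for image_id in gut_rows["image_id"]:
            if len(clone_rows):
                areas = clone_rows.loc[clone_rows["image_id"] == image_id, "area_um2"]
                supra.append(int((areas > threshold_um2).sum()))
            else:
                supra.append(0)
        supra_by_condition[cond] = np.asarray(supra)
        max_nuc = float("nan")
        if nuclei is not None and len(nuclei):
            sel = nuclei[nuclei["condition"] == cond]["area_um2"]
            if len(sel):
                max_nuc = float(sel.max())
        rows.append(
            {
                "condition": cond,
                "n_guts": len(gut_rows),
                "n_clones": int(len(clone_rows)) if len(clone_rows) else 0,
                "n_supra_clones": int(np.sum(supra)),
                "mean_supra_per_gut": float(np.mean(supra)) if supra else 0.0,
                "mean_gut_area_um2": float(gut_rows["gut_area_um2"].mean()),
                "max_nuclear_area_um2": max_nuc,
            }
        )
    summary = pd.DataFrame(rows)

    comparisons = pd.DataFrame(
        columns=["comparison", "test", "statistic", "pvalue", "p_adjusted"]
    )
    testable = {c: v for c, v in supra_by_condition.items() if len(v) >= 2}
    if len(testable) >= 2:
        overall = assays.compare_groups(testable, test="kruskal_wallis")
        comp_rows = [
            {
                "comparison": "all",
                "test": "kruskal_wallis",
                "statistic": overall.statistic,
                "pvalue": overall.pvalue,
                "p_adjusted": overall.pvalue,
            }
        ]
        if len(testable) > 2:
            posthoc = assays.pairwise_posthoc(testable)
            for r in posthoc.itertuples():
                comp_rows.append(
                    {
                        "comparison": r.comparison,
                        "test": "mann_whitney",
                        "statistic": r.statistic,
                        "pvalue": r.pvalue,
                        "p_adjusted": r.p_adjusted,
                    }
                )
        comparisons = pd.DataFrame(comp_rows, columns=comparisons.columns)
    return summary, comparisons
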