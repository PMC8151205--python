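"""End-to-end orchestration: simulate -> quantify -> classify -> statistics.

The two entry points are :func:`analyze_synthetic_batch` (generate guts in
memory and push them through the measurement pipeline, the workhorse for
parameter-recovery studies) and :func:`run_pipeline`, which builds a full
:class:`RunReport` from a validated :class:`RunConfig` — either from a
folder of TIFFs or from synthetic presets — and can write every table to
disk with complete provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assays, classify, quant, synth
from .presets import ConditionPreset, MidgutGeometry, RenderConfig, get_preset

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunReport",
    "analyze_synthetic_batch",
    "run_pipeline",
    "write_tables",
    "read_tables",
]

logger = logging.getLogger(__name__)

PER_IMAGE_COLUMNS = quant.BATCH_COLUMNS + ["condition"]
CLONE_COLUMNS = [
    "image_id",
    "condition",
    "clone_id",
    "area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "tumour_like",
]
NUCLEUS_COLUMNS = ["image_id", "condition", "nucleus_id", "clone_id", "area_um2"]
LUCIFERASE_COLUMNS = ["condition", "week", "activity", "pool_size", "is_remainder"]
SURVIVAL_COLUMNS = ["condition", "day", "percent_survival", "n_at_risk"]


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every violated field."""


@dataclass
class RunConfig:
    """One run's inputs and parameters.

    Exactly one input source must be set: ``input_dir`` (a folder of
    calibrated TIFFs) or ``presets`` (synthetic arms to simulate, which
    then requires a ``seed``).
    """

    input_dir: str | None = None
    presets: tuple[str, ...] = ()
    n_guts: int = 10
    seed: int | None = None
    pixel_size_um: float | None = None
    threshold_mode: str = "auto"
    threshold_value: float | None = None
    anterior_fraction: float = 0.4
    tumour_threshold_um2: float = 7800.0
    min_clone_size_um2: float = 10.0
    min_nucleus_size_um2: float = 20.0
    luciferase_week: int = 3
    n_flies: int = 30
    pool_size: int = 10
    survival_days: int = 21
    out_dir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        errors = []
        if bool(self.input_dir) == bool(self.presets):
            errors.append("exactly one of input_dir / presets must be set")
        if self.presets and self.seed is None:
            errors.append("seed: required for any synthetic stage")
        if self.n_guts < 1:
            errors.append(f"n_guts: must be >= 1, got {self.n_guts}")
        if self.threshold_mode not in ("auto", "fixed"):
            errors.append(f"threshold_mode: unknown mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            errors.append("threshold_value: required in fixed threshold mode")
        if not (0.0 < self.anterior_fraction < 1.0):
            errors.append(f"anterior_fraction: must be in (0, 1), got {self.anterior_fraction}")
        if self.tumour_threshold_um2 <= 0:
            errors.append("tumour_threshold_um2: must be > 0")
        if self.luciferase_week not in (2, 3):
            errors.append(f"luciferase_week: must be 2 or 3, got {self.luciferase_week}")
        if self.pool_size < 1:
            errors.append(f"pool_size: must be >= 1, got {self.pool_size}")
        if self.survival_days < 1:
            errors.append(f"survival_days: must be >= 1, got {self.survival_days}")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["presets"] = list(self.presets)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    """All result tables of one run plus provenance."""

    per_image: pd.DataFrame
    clones: pd.DataFrame
    nuclei: pd.DataFrame
    condition_summary: pd.DataFrame
    comparisons: pd.DataFrame
    luciferase: pd.DataFrame
    survival: pd.DataFrame
    provenance: dict


def analyze_synthetic_batch(
    preset: str | ConditionPreset,
    n_guts: int,
    seed: int,
    geometry: MidgutGeometry | None = None,
    render: RenderConfig | None = None,
    anterior_fraction: float | None = None,
    tumour_threshold_um2: float = 7800.0,
    min_clone_size_um2: float = 10.0,
    min_nucleus_size_um2: float = 20.0,
    segment_nuclei: bool = True,
) -> dict[str, pd.DataFrame]:
    """Generate ``n_guts`` synthetic midguts and measure them in memory.

    Each gut is rendered (per-gut seed derived from ``seed``), max-projected
    and quantified; nuclei are segmented within clone masks.  Returns a dict
    of DataFrames: ``per_image``, ``clones`` (with tumour classification),
    ``nuclei``, and the generator ground truth ``gt_clones`` / ``gt_nuclei``
    / ``gt_guts`` for parameter-recovery comparisons.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if anterior_fraction is None:
        anterior_fraction = (geometry or MidgutGeometry()).anterior_fraction

    rows, clone_frames, nucleus_frames = [], [], []
    gt_clone_frames, gt_nucleus_frames, gt_gut_rows = [], [], []
    for i in range(n_guts):
        gut_seed = synth.derive_gut_seed(seed, i)
        name = f"{preset.name}_gut{i:03d}"
        image, truth = synth.generate_midgut(
            preset, geometry=geometry, render=render, seed=gut_seed, image_id=name
        )
        row, labels, gut, measurements = quant.quantify_image(
            image,
            anterior_fraction=anterior_fraction,
            min_size_um2=min_clone_size_um2,
        )
        row["condition"] = preset.name
        rows.append(row)

        classes = classify.classify_clones(measurements, tumour_threshold_um2)
        cf = quant.measurements_to_frame(measurements)
        cf["condition"] = preset.name
        cf["tumour_like"] = [c.tumour_like for c in classes]
        clone_frames.append(cf)

        if segment_nuclei:
            nuclei = classify.segment_nuclei_in_clones(
                image, labels, min_size_um2=min_nucleus_size_um2
            )
            nf = classify.nuclei_to_frame(nuclei)
            nf["condition"] = preset.name
            nucleus_frames.append(nf)

        gt_c = truth.clone_table()
        gt_c.insert(0, "image_id", name)
        gt_c["condition"] = preset.name
        gt_clone_frames.append(gt_c)
        gt_n = truth.nucleus_table()
        gt_n.insert(0, "image_id", name)
        gt_n["condition"] = preset.name
        gt_nucleus_frames.append(gt_n)
        gt_gut_rows.append(
            {
                "image_id": name,
                "condition": preset.name,
                "seed": gut_seed,
                "gut_area_um2": truth.gut_area_um2,
                "total_clone_area_um2": truth.total_clone_area_um2(),
                "n_clones": len(truth.clones),
            }
        )

    def cat(frames):
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame()
        )

    return {
        "per_image": pd.DataFrame(rows),
        "clones": cat(clone_frames),
        "nuclei": cat(nucleus_frames),
        "gt_clones": cat(gt_clone_frames),
        "gt_nuclei": cat(gt_nucleus_frames),
        "gt_guts": pd.DataFrame(gt_gut_rows),
    }


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run described by ``config`` and return its report.

    Deterministic for fixed config + seed.  Synthetic runs add luciferase
    pools and survival curves per arm; folder runs carry image-derived
    tables only.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    per_image = _empty(PER_IMAGE_COLUMNS)
    clones = _empty(CLONE_COLUMNS)
    nuclei = _empty(NUCLEUS_COLUMNS)
    luciferase = _empty(LUCIFERASE_COLUMNS)
    survival = _empty(SURVIVAL_COLUMNS)

    if config.presets:
        per_image_frames, clone_frames, nucleus_frames = [], [], []
        luci_frames, survival_events = [], []
        for arm_index, preset_name in enumerate(config.presets):
            preset = get_preset(preset_name)
            arm_seed = synth.derive_gut_seed(config.seed, 10_000 + arm_index)
            result = analyze_synthetic_batch(
                preset,
                n_guts=config.n_guts,
                seed=arm_seed,
                anterior_fraction=config.anterior_fraction,
                tumour_threshold_um2=config.tumour_threshold_um2,
                min_clone_size_um2=config.min_clone_size_um2,
                min_nucleus_size_um2=config.min_nucleus_size_um2,
            )
            per_image_frames.append(result["per_image"])
            clone_frames.append(result["clones"])
            nucleus_frames.append(result["nuclei"])

            per_fly = synth.sample_luciferase(
                preset, config.luciferase_week, config.n_flies, seed=arm_seed
            )
            pools = assays.pool_homogenates(per_fly, config.pool_size)
            pools.insert(0, "week", config.luciferase_week)
            pools.insert(0, "condition", preset.name)
            luci_frames.append(pools)

            survival_events.append(
                synth.sample_survival(
                    preset, config.n_flies, config.survival_days, seed=arm_seed
                )
            )
        per_image = pd.concat(per_image_frames, ignore_index=True)
        clones = pd.concat([f for f in clone_frames if len(f)], ignore_index=True) if any(
            len(f) for f in clone_frames
        ) else clones
        nuclei = pd.concat([f for f in nucleus_frames if len(f)], ignore_index=True) if any(
            len(f) for f in nucleus_frames
        ) else nuclei
        luciferase = pd.concat(luci_frames, ignore_index=True)[LUCIFERASE_COLUMNS]
        survival = assays.survival_curve(
            pd.concat(survival_events, ignore_index=True), n_days=config.survival_days
        )
    else:
        per_image = quant.batch_quantify(
            config.input_dir,
            pixel_size_um=config.pixel_size_um,
            threshold_mode=config.threshold_mode,
            threshold_value=config.threshold_value,
            anterior_fraction=config.anterior_fraction,
            min_size_um2=config.min_clone_size_um2,
        )
        per_image["condition"] = "unspecified"

    if len(clones):
        guts = per_image.loc[per_image["status"] == "ok", ["image_id", "condition", "gut_area_um2"]]
        summary, comparisons = classify.condition_summary(
            clones, guts, nuclei if len(nuclei) else None, config.tumour_threshold_um2
        )
    elif len(per_image):
        guts = per_image.loc[per_image["status"] == "ok", ["image_id", "condition", "gut_area_um2"]]
        summary = pd.DataFrame(
            [
                {
                    "condition": cond,
                    "n_guts": len(rows_),
                    "n_clones": 0,
                    "n_supra_clones": 0,
                    "mean_supra_per_gut": 0.0,
                    "mean_gut_area_um2": float(rows_["gut_area_um2"].mean()),
                    "max_nuclear_area_um2": float("nan"),
                }
                for cond, rows_ in guts.groupby("condition")
            ]
        )
        comparisons = _empty(["comparison", "test", "statistic", "pvalue", "p_adjusted"])
    else:
        summary = _empty(
            [
                "condition",
                "n_guts",
                "n_clones",
                "n_supra_clones",
                "mean_supra_per_gut",
                "mean_gut_area_um2",
                "max_nuclear_area_um2",
            ]
        )
        comparisons = _empty(["comparison", "test", "statistic", "pvalue", "p_adjusted"])

    provenance = {
        "software": "cloneburden",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "schema_version": 1,
    }
    return RunReport(
        per_image=per_image[ [c for c in PER_IMAGE_COLUMNS if c in per_image.columns] ],
        clones=clones[[c for c in CLONE_COLUMNS if c in clones.columns]] if len(clones) else _empty(CLONE_COLUMNS),
        nuclei=nuclei[[c for c in NUCLEUS_COLUMNS if c in nuclei.columns]] if len(nuclei) else _empty(NUCLEUS_COLUMNS),
        condition_summary=summary,
        comparisons=comparisons,
        luciferase=luciferase,
        survival=survival,
        provenance=provenance,
    )


_TABLE_NAMES = (
    "per_image",
    "clones",
    "nuclei",
    "condition_summary",
    "comparisons",
    "luciferase",
    "survival",
)


def write_tables(report: RunReport, out_dir) -> dict[str, Path]:
    """Write every report table as CSV plus a JSON provenance/summary file.

    Stable column order and no timestamps in the tables, so re-running the
    same config + seed reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in _TABLE_NAMES:
        path = out_dir / f"{name}.csv"
        getattr(report, name).to_csv(path, index=False)
        paths[name] = path
    report_json = {
        "provenance": report.provenance,
        "tables": {name: f"{name}.csv" for name in _TABLE_NAMES},
        "n_images": int(len(report.per_image)),
        "n_clones": int(len(report.clones)),
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report_json, indent=2, sort_keys=True))
    paths["report"] = json_path
    return paths


def read_tables(out_dir) -> dict[str, pd.DataFrame]:
    """Re-read the CSV tables written by :func:`write_tables`."""
    out_dir = Path(out_dir)
    return {name: pd.read_csv(out_dir / f"{name}.csv") for name in _TABLE_NAMES}
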