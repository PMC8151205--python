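"""Condition presets, midgut geometry and rendering configuration.

The synthetic generator emulates four experimental arms of the adult
*Drosophila* midgut clone model:

``control``
    wild-type GFP clones — small, dispersed, never tumour-like.
``snail``
    Snail-overexpressing clones — over-proliferating (more and larger clones,
    denser nuclei) but never crossing the tumour-like clone-area threshold.
``apcras``
    Apc/Apc2-mutant, Ras(V12)-overexpressing clones — the colorectal-cancer
    model.  A subset of clones merge into large tumour-like masses above the
    7,800 um^2 threshold, nuclei reach 980 um^2, and clones are confined to
    the anterior portion of the midgut.
``apcras_treated``
    the tumour model after chemotherapy — expected total clone coverage is
    exactly half of ``apcras`` at the parameter level, the supra-threshold
    clone component is absent, and the maximal nuclear area drops to 680 um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .laws import BinomialCount, CountLaw, LogNormalLaw, PoissonCount, TruncatedLogNormal

__all__ = [
    "TUMOUR_AREA_THRESHOLD_UM2",
    "CloneComponent",
    "ConditionPreset",
    "MidgutGeometry",
    "RenderConfig",
    "default_presets",
    "get_preset",
    "preset_to_dict",
    "preset_from_dict",
    "load_preset",
    "save_preset",
]

#: Clone area (um^2) above which a clone is called tumour-like.
TUMOUR_AREA_THRESHOLD_UM2 = 7800.0

PRESET_NAMES = ("control", "snail", "apcras", "apcras_treated")


@dataclass(frozen=True)
class CloneComponent:
    """One sub-population of clones: how many per gut, and their area law."""

    count_law: CountLaw
    area_law: TruncatedLogNormal

    def expected_total_area(self) -> float:
        return self.count_law.mean() * self.area_law.mean()


@dataclass(frozen=True)
class ConditionPreset:
    """All generator parameters for one experimental condition.

    ``clone_components`` is the clone-count/clone-area law (a mixture of
    sub-populations; ``apcras`` carries a separate heavy "merged" component
    whose areas exceed the tumour threshold).  ``luciferase_laws`` maps week
    (2 or 3) to the per-fly activity law.  ``nuclei_density_per_1000um2`` is
    the nominal nucleus count per 1,000 um^2 of clone cross-section.
    """

    name: str
    clone_components: tuple[CloneComponent, ...]
    nuclear_area_law: TruncatedLogNormal
    nuclei_density_per_1000um2: float
    anterior_restricted: bool
    coverage_scale: float
    luciferase_laws: dict[int, LogNormalLaw]
    daily_death_hazard: float

    def __post_init__(self) -> None:
        if not self.clone_components:
            raise ValueError("preset needs at least one clone component")
        if self.nuclei_density_per_1000um2 < 0:
            raise ValueError("nuclei density must be >= 0")
        if not (0.0 <= self.daily_death_hazard <= 1.0):
            raise ValueError("daily_death_hazard must be in [0, 1]")
        if self.coverage_scale <= 0:
            raise ValueError("coverage_scale must be > 0")

    @property
    def nuclear_area_max_um2(self) -> float:
        return self.nuclear_area_law.upper

    def expected_total_clone_area_um2(self) -> float:
        """Expected summed clone area per gut, exact at the parameter level."""
        return sum(c.expected_total_area() for c in self.clone_components)

    def supra_threshold_mass(self) -> float:
        """Expected number of clones per gut above the tumour threshold."""
        return sum(
            c.count_law.mean() * c.area_law.tail_mass_above(TUMOUR_AREA_THRESHOLD_UM2)
            for c in self.clone_components
        )

    def validate(self) -> None:
        """Check the condition-specific invariants the presets are built around."""
        if self.name in ("control", "snail"):
            for c in self.clone_components:
                if c.area_law.upper >= TUMOUR_AREA_THRESHOLD_UM2:
                    raise ValueError(
                        f"{self.name}: clone-area truncation must stay below "
                        f"{TUMOUR_AREA_THRESHOLD_UM2} um^2"
                    )
            if self.nuclear_area_max_um2 != 420.0:
                raise ValueError(f"{self.name}: nuclear truncation must be 420 um^2")
        elif self.name == "apcras":
            if self.supra_threshold_mass() <= 0:
                raise ValueError("apcras: clone-area law needs mass above the threshold")
            if self.nuclear_area_max_um2 != 980.0:
                raise ValueError("apcras: nuclear truncation must be 980 um^2")
            if not self.anterior_restricted:
                raise ValueError("apcras: clones must be anterior-restricted")
        elif self.name == "apcras_treated":
            if self.supra_threshold_mass() > 1e-9:
                raise ValueError("apcras_treated: supra-threshold mass must be ~0")
            if self.nuclear_area_max_um2 != 680.0:
                raise ValueError("apcras_treated: nuclear truncation must be 680 um^2")


@dataclass(frozen=True)
class MidgutGeometry:
    """Idealised midgut shape: an elongated, gently curved, tapered band.

    ``length_um`` defaults to 5,000 um (real midguts run up to ~6 mm, the
    hard cap enforced here).  The anterior region — where tumour-like clones
    concentrate — is the first ``anterior_fraction`` of the axial length.
    Per-gut biological variation enters through the jitter fractions.
    """

    length_um: float = 5000.0
    width_um: float = 280.0
    anterior_fraction: float = 0.4
    length_jitter: float = 0.05
    width_jitter: float = 0.07
    curvature_amplitude_um: float = 60.0
    bulge_amplitude: float = 0.12

    MAX_LENGTH_UM = 6000.0

    def __post_init__(self) -> None:
        if not (0 < self.length_um <= self.MAX_LENGTH_UM):
            raise ValueError(
                f"length_um must be in (0, {self.MAX_LENGTH_UM}], got {self.length_um}"
            )
        if not (0.0 < self.anterior_fraction < 1.0):
            raise ValueError("anterior_fraction must be in (0, 1)")
        if self.width_um <= 0:
            raise ValueError("width_um must be > 0")

    def half_width_um(self, t: np.ndarray, bulge_phase: float = 0.0) -> np.ndarray:
        """Half-width profile at relative axial position ``t`` in [0, 1].

        Tapered at both ends, widest mid-organ, with a low-frequency bulge
        modulation whose phase varies gut to gut.
        """
        base = 0.5 * self.width_um * (0.6 + 0.5 * np.sin(np.pi * np.asarray(t)))
        modulation = 1.0 + self.bulge_amplitude * np.sin(3.0 * np.pi * np.asarray(t) + bulge_phase)
        return base * modulation


@dataclass(frozen=True)
class RenderConfig:
    """How ground-truth geometry becomes pixels.

    Defaults: 1.0 um/px, 3 z-planes, 16-bit, crisp (unblurred) structures
    with mild noise so that segmentation accuracy — not denoising — is what
    downstream tests exercise.  Noise per pixel is one Gaussian draw with
    variance ``read_noise_sd^2 + signal/photon_gain`` (Gaussian shot-noise
    approximation, accurate at the default signal levels).
    """

    pixel_size_um: float = 1.0
    n_zplanes: int = 3
    margin_px: int = 40
    bit_depth: int = 16
    # Foreground / background intensity levels (16-bit scale).
    clone_intensity: float = 12000.0
    gut_red_intensity: float = 8000.0
    nucleus_intensity: float = 9000.0
    green_gut_background: float = 600.0
    red_background: float = 500.0
    green_background: float = 300.0
    blue_background: float = 300.0
    read_noise_sd: float = 60.0
    photon_gain: float = 2.0
    zplane_intensity_jitter: float = 0.03

    channel_names = ("green", "red", "blue")  # clones, gut outline, nuclei

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_zplanes < 1:
            raise ValueError("n_zplanes must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        top = 2**self.bit_depth - 1
        for name in ("clone_intensity", "gut_red_intensity", "nucleus_intensity"):
            if not (0 < getattr(self, name) <= top):
                raise ValueError(f"{name} must fit in {self.bit_depth}-bit range")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16


def _luciferase(week2: float, week3: float, sigma: float = 0.8) -> dict[int, LogNormalLaw]:
    return {2: LogNormalLaw(median=week2, sigma=sigma), 3: LogNormalLaw(median=week3, sigma=sigma)}


def default_presets() -> dict[str, ConditionPreset]:
    """The four built-in experimental arms.

    Parameter choices: clone-area truncation maxima and nuclear maxima encode
    the published hard limits (7,800 um^2 clone threshold reached only in the
    tumour arm; nuclear maxima 420 / 980 / 680 um^2); luciferase medians put
    the tumour arm well above control at week 3 and overlapping at week 2;
    daily death hazards give the mild 21-day survival differences seen in the
    model.  The treated arm's clone-count rate is solved from the analytic
    law means so its expected coverage is exactly half the untreated arm's.
    """
    control = ConditionPreset(
        name="control",
        clone_components=(
            CloneComponent(
                PoissonCount(15.0),
                TruncatedLogNormal(median=700.0, sigma=0.8, upper=6000.0, lower=50.0),
            ),
        ),
        nuclear_area_law=TruncatedLogNormal(median=140.0, sigma=0.6, upper=420.0, lower=30.0),
        nuclei_density_per_1000um2=2.2,
        anterior_restricted=False,
        coverage_scale=1.0,
        luciferase_laws=_luciferase(week2=950.0, week3=1050.0),
        daily_death_hazard=0.004,
    )
    snail = ConditionPreset(
        name="snail",
        clone_components=(
            CloneComponent(
                PoissonCount(25.0),
                TruncatedLogNormal(median=1100.0, sigma=0.8, upper=6500.0, lower=50.0),
            ),
        ),
        nuclear_area_law=TruncatedLogNormal(median=150.0, sigma=0.6, upper=420.0, lower=30.0),
        nuclei_density_per_1000um2=2.6,
        anterior_restricted=False,
        coverage_scale=1.0,
        luciferase_laws=_luciferase(week2=1000.0, week3=1400.0),
        daily_death_hazard=0.005,
    )
    apcras_base_law = TruncatedLogNormal(median=800.0, sigma=0.6, upper=7000.0, lower=50.0)
    apcras = ConditionPreset(
        name="apcras",
        clone_components=(
            CloneComponent(PoissonCount(45.0), apcras_base_law),
            # Merged tumour masses: a handful per gut, all above threshold.
            CloneComponent(
                BinomialCount(8, 0.75),
                TruncatedLogNormal(median=9500.0, sigma=0.12, upper=13000.0, lower=8000.0),
            ),
        ),
        nuclear_area_law=TruncatedLogNormal(median=120.0, sigma=1.0, upper=980.0, lower=30.0),
        nuclei_density_per_1000um2=3.0,
        anterior_restricted=True,
        coverage_scale=1.0,
        luciferase_laws=_luciferase(week2=1300.0, week3=6500.0),
        daily_death_hazard=0.022,
    )
    # Treated arm: same base clone-area law, no merged component; the count
    # rate is derived so expected total coverage is exactly half of apcras.
    target_total = 0.5 * apcras.expected_total_clone_area_um2()
    treated_rate = target_total / apcras_base_law.mean()
    apcras_treated = ConditionPreset(
        name="apcras_treated",
        clone_components=(CloneComponent(PoissonCount(treated_rate), apcras_base_law),),
        nuclear_area_law=TruncatedLogNormal(median=120.0, sigma=1.0, upper=680.0, lower=30.0),
        nuclei_density_per_1000um2=3.0,
        anterior_restricted=True,
        coverage_scale=0.5,
        luciferase_laws=_luciferase(week2=1300.0, week3=1900.0),
        daily_death_hazard=0.012,
    )
    presets = {p.name: p for p in (control, snail, apcras, apcras_treated)}
    for p in presets.values():
        p.validate()
    return presets


_PRESETS_CACHE: dict[str, ConditionPreset] | None = None


def get_preset(name: str) -> ConditionPreset:
    global _PRESETS_CACHE
    if _PRESETS_CACHE is None:
        _PRESETS_CACHE = default_presets()
    try:
        return _PRESETS_CACHE[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None


# ---------------------------------------------------------------------------
# Serialisation (YAML/JSON-friendly dicts) so presets are user-editable.

def _law_to_dict(law) -> dict:
    if isinstance(law, TruncatedLogNormal):
        return {
            "type": "truncated_lognormal",
            "median": law.median,
            "sigma": law.sigma,
            "upper": law.upper,
            "lower": law.lower,
        }
    if isinstance(law, LogNormalLaw):
        return {"type": "lognormal", "median": law.median, "sigma": law.sigma}
    if isinstance(law, PoissonCount):
        return {"type": "poisson", "rate": law.rate}
    if isinstance(law, BinomialCount):
        return {"type": "binomial", "n": law.n, "p": law.p}
    raise TypeError(f"cannot serialise law {law!r}")


def _law_from_dict(d: dict):
    kind = d["type"]
    if kind == "truncated_lognormal":
        return TruncatedLogNormal(d["median"], d["sigma"], d["upper"], d.get("lower", 0.0))
    if kind == "lognormal":
        return LogNormalLaw(d["median"], d["sigma"])
    if kind == "poisson":
        return PoissonCount(d["rate"])
    if kind == "binomial":
        return BinomialCount(d["n"], d["p"])
    raise ValueError(f"unknown law type {kind!r}")


def preset_to_dict(preset: ConditionPreset) -> dict:
    return {
        "name": preset.name,
        "clone_components": [
            {"count_law": _law_to_dict(c.count_law), "area_law": _law_to_dict(c.area_law)}
            for c in preset.clone_components
        ],
        "nuclear_area_law": _law_to_dict(preset.nuclear_area_law),
        "nuclei_density_per_1000um2": preset.nuclei_density_per_1000um2,
        "anterior_restricted": preset.anterior_restricted,
        "coverage_scale": preset.coverage_scale,
        "luciferase_laws": {
            str(week): _law_to_dict(law) for week, law in preset.luciferase_laws.items()
        },
        "daily_death_hazard": preset.daily_death_hazard,
    }


def preset_from_dict(d: dict) -> ConditionPreset:
    return ConditionPreset(
        name=d["name"],
        clone_components=tuple(
            CloneComponent(_law_from_dict(c["count_law"]), _law_from_dict(c["area_law"]))
            for c in d["clone_components"]
        ),
        nuclear_area_law=_law_from_dict(d["nuclear_area_law"]),
        nuclei_density_per_1000um2=float(d["nuclei_density_per_1000um2"]),
        anterior_restricted=bool(d["anterior_restricted"]),
        coverage_scale=float(d["coverage_scale"]),
        luciferase_laws={
            int(week): _law_from_dict(law) for week, law in d["luciferase_laws"].items()
        },
        daily_death_hazard=float(d["daily_death_hazard"]),
    )


def save_preset(preset: ConditionPreset, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(preset_to_dict(preset), fh, sort_keys=False)


def load_preset(path) -> ConditionPreset:
    with open(path) as fh:
        return preset_from_dict(yaml.safe_load(fh))
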