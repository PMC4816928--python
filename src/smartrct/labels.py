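"""Digital nutrition-label engine.

Computes the five front- and back-of-pack label formats used across the
two country profiles:

* ``DIG``  — Daily Intake Guide: percent of reference daily intake per
  serving for energy, fat, saturated fat, sugars, sodium.
* ``TLL``  — Traffic Lights: GREEN / AMBER / RED per nutrient, from
  low/high cutoffs per 100 g (foods) or 100 mL (beverages).
* ``HSR``  — Health Star Rating: 0.5–5.0 stars from a points algorithm
  (baseline risk points minus modifying points, mapped to stars).
* ``NIP``  — Nutrition Information Panel: the plain tabular declaration
  per 100 g/mL and per serving; the control arm, deliberately free of
  any interpretive element.
* ``WARNING`` — threshold-triggered warning flags per nutrient.

All cutoffs, point bands, and reference intakes are configuration data
loaded from the country profile, never code constants; the shipped
defaults are editable transcriptions in the style of the public
Australian/UK labelling guides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional, TYPE_CHECKING

from .errors import ConfigError, LabelingError
from .food_db import Product

if TYPE_CHECKING:  # pragma: no cover
    from .config import TrialConfig

ARM_DIG = "DIG"
ARM_TLL = "TLL"
ARM_HSR = "HSR"
ARM_NIP = "NIP"
ARM_WARNING = "WARNING"

#: Nutrients covered by traffic-light and warning schemes (per 100 g/mL).
TL_NUTRIENTS = {
    "fat": "fat_g_100",
    "satfat": "satfat_g_100",
    "sugars": "sugars_g_100",
    "sodium": "sodium_mg_100",
}

#: Components shown on the Daily Intake Guide (per serving).
DIG_COMPONENTS = {
    "energy": "energy_kj_100",
    "fat": "fat_g_100",
    "satfat": "satfat_g_100",
    "sugars": "sugars_g_100",
    "sodium": "sodium_mg_100",
}

#: The seven panel rows of the control-arm NIP.
NIP_ROWS = [
    ("energy_kj", "energy_kj_100"),
    ("protein_g", "protein_g_100"),
    ("fat_g", "fat_g_100"),
    ("satfat_g", "satfat_g_100"),
    ("carbohydrate_g", "carb_g_100"),
    ("sugars_g", "sugars_g_100"),
    ("sodium_mg", "sodium_mg_100"),
]


class Color(str, Enum):
    GREEN = "GREEN"
    AMBER = "AMBER"
    RED = "RED"


@dataclass(frozen=True)
class Label:
    """One rendered label: the arm tag plus its format-specific payload."""

    arm: str
    payload: dict

    def to_json(self) -> str:
        return json.dumps({"arm": self.arm, "payload": self.payload}, sort_keys=True)


@dataclass
class TrafficLightThresholds:
    """Low/high cutoffs per nutrient, separately for foods and beverages.

    ``foods`` and ``beverages`` map nutrient name -> (low, high) on the
    per-100 g/mL scale (grams, except sodium in milligrams).
    """

    foods: dict[str, tuple[float, float]]
    beverages: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for table in (self.foods, self.beverages):
            for nutrient, (low, high) in table.items():
                if not (0 < low < high):
                    raise ConfigError(f"traffic-light cutoffs for {nutrient}: need 0 < low < high")

    def for_product(self, product: Product) -> dict[str, tuple[float, float]]:
        return self.beverages if product.is_beverage else self.foods


@dataclass
class DailyIntakeReferences:
    """Reference daily intakes for the Daily Intake Guide components."""

    energy_kj: float
    fat_g: float
    satfat_g: float
    sugars_g: float
    sodium_mg: float

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ConfigError(f"daily-intake reference {name} must be > 0")

    def reference(self, component: str) -> float:
        return {
            "energy": self.energy_kj, "fat": self.fat_g, "satfat": self.satfat_g,
            "sugars": self.sugars_g, "sodium": self.sodium_mg,
        }[component]


def _band_points(value: float, thresholds: list[float]) -> int:
    """Points for a band table given as ascending strict thresholds.

    Points equal the count of thresholds strictly below the value, so
    the bands partition [0, inf) exhaustively and monotonically.
    """
    return sum(1 for t in thresholds if value > t)


@dataclass
class HsrTables:
    """Point-band tables and star mapping for the Health Star Rating.

    ``baseline`` maps each risk component (energy, saturated fat, total
    sugars, sodium) to an ascending threshold list: the points awarded
    equal the number of thresholds the per-100 g/mL amount exceeds.
    ``modifying`` does the same for the protective components (fvnl
    percentage, protein, fibre). ``star_cutoffs`` is an ascending list
    of final-score cutoffs; each one exceeded costs half a star off 5.0,
    flooring at 0.5 — so stars are monotone non-increasing in the score.
    """

    baseline: dict[str, list[float]]
    modifying: dict[str, list[float]]
    star_cutoffs: list[float]

    def __post_init__(self) -> None:
        for name, bands in {**self.baseline, **self.modifying}.items():
            if sorted(bands) != list(bands):
                raise ConfigError(f"HSR band table {name} not ascending")
        if sorted(self.star_cutoffs) != list(self.star_cutoffs):
            raise ConfigError("HSR star cutoffs not ascending")

    def stars(self, score: float) -> float:
        return max(0.5, 5.0 - 0.5 * _band_points(score, self.star_cutoffs))


@dataclass
class WarningRule:
    """Per-nutrient warning thresholds (per 100 g/mL), strict exceedance."""

    thresholds: dict[str, float]
    text: str = "HIGH IN"

    def __post_init__(self) -> None:
        for nutrient, t in self.thresholds.items():
            if t <= 0:
                raise ConfigError(f"warning threshold for {nutrient} must be > 0")


def _round1(x: float) -> float:
    """Round to one decimal place, half away from zero (display rule)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def traffic_light(product: Product, thresholds: TrafficLightThresholds) -> Label:
    """Color fat, saturated fat, sugars and sodium per 100 g/mL.

    GREEN if amount <= low, AMBER if low < amount <= high, RED above.
    """
    table = thresholds.for_product(product)
    colors: dict[str, str] = {}
    amounts: dict[str, float] = {}
    for nutrient, attr in TL_NUTRIENTS.items():
        if nutrient not in table:
            raise LabelingError(f"no traffic-light cutoffs for {nutrient}")
        value = getattr(product, attr)
        if value is None:
            raise LabelingError(f"missing nutrient {nutrient} on {product.barcode}")
        low, high = table[nutrient]
        if value <= low:
            color = Color.GREEN
        elif value <= high:
            color = Color.AMBER
        else:
            color = Color.RED
        colors[nutrient] = color.value
        amounts[nutrient] = value
    return Label(ARM_TLL, {"colors": colors, "per_100": amounts})


def daily_intake(product: Product, refs: DailyIntakeReferences) -> Label:
    """Percent of reference daily intake per serving, one decimal place."""
    pct: dict[str, float] = {}
    per_serving: dict[str, float] = {}
    for component, attr in DIG_COMPONENTS.items():
        amount = product.per_serving(attr)
        per_serving[component] = amount
        pct[component] = _round1(amount / refs.reference(component) * 100.0)
    return Label(ARM_DIG, {"pct_di": pct, "per_serving": per_serving,
                           "serving_size": product.serving_size})


#: Product attribute behind each HSR component name.
_HSR_ATTRS = {
    "energy": "energy_kj_100", "satfat": "satfat_g_100",
    "sugars": "sugars_g_100", "sodium": "sodium_mg_100",
    "fvnl": "fvnl_pct", "protein": "protein_g_100", "fibre": "fibre_g_100",
}


def health_star(product: Product, tables: HsrTables) -> Label:
    """Health Star Rating: baseline points minus modifying points, to stars.

    Optional components (fibre, fvnl) missing from the product record
    contribute zero modifying points, the conservative convention.
    """
    baseline_pts = {}
    for name, bands in tables.baseline.items():
        value = getattr(product, _HSR_ATTRS[name])
        if value is None:
            raise LabelingError(f"missing baseline nutrient {name} on {product.barcode}")
        baseline_pts[name] = _band_points(value, bands)
    modifying_pts = {}
    for name, bands in tables.modifying.items():
        value = getattr(product, _HSR_ATTRS[name])
        modifying_pts[name] = 0 if value is None else _band_points(value, bands)
    score = sum(baseline_pts.values()) - sum(modifying_pts.values())
    return Label(ARM_HSR, {
        "stars": tables.stars(score), "final_score": score,
        "baseline_points": baseline_pts, "modifying_points": modifying_pts,
    })


def nip(product: Product) -> Label:
    """Nutrition Information Panel: 7 rows x (per 100 g/mL, per serving).

    The control label: no colors, stars, %DI or warnings, replicating
    the mandatory back-of-pack declaration.
    """
    rows = {}
    for row_name, attr in NIP_ROWS:
        value = getattr(product, attr)
        if value is None:
            raise LabelingError(f"missing required nutrient {row_name} on {product.barcode}")
        rows[row_name] = {"per_100": value, "per_serving": product.per_serving(attr)}
    return Label(ARM_NIP, {"rows": rows, "serving_size": product.serving_size})


def warning(product: Product, rule: WarningRule) -> Label:
    """Flag each nutrient whose per-100 amount strictly exceeds its threshold."""
    flags = sorted(
        nutrient for nutrient, t in rule.thresholds.items()
        if (getattr(product, TL_NUTRIENTS[nutrient]) or 0.0) > t
    )
    return Label(ARM_WARNING, {"flags": flags, "text": rule.text})


def label_for(product: Product, arm: str, config: "TrialConfig") -> Label:
    """Render the label a participant in ``arm`` sees for ``product``.

    Dispatches on the randomization allocation using the scheme tables
    of the trial configuration.
    """
    if arm not in config.arms:
        raise ConfigError(f"arm {arm!r} not in configured arms {config.arms}")
    schemes = config.schemes
    if arm == ARM_TLL:
        return traffic_light(product, schemes.traffic_light)
    if arm == ARM_DIG:
        return daily_intake(product, schemes.daily_intake)
    if arm == ARM_HSR:
        tables = schemes.hsr_beverages if product.is_beverage else schemes.hsr_foods
        return health_star(product, tables)
    if arm == ARM_NIP:
        return nip(product)
    if arm == ARM_WARNING:
        if schemes.warning is None:
            raise ConfigError("WARNING arm configured but no warning rule present")
        return warning(product, schemes.warning)
    raise ConfigError(f"no label scheme for arm {arm!r}")


@dataclass
class SchemeTables:
    """Bundle of all label-scheme tables for one country profile."""

    traffic_light: TrafficLightThresholds
    daily_intake: DailyIntakeReferences
    hsr_foods: HsrTables
    hsr_beverages: HsrTables
    warning: Optional[WarningRule] = None
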