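"""Trial configuration: country profiles, durations, schemes, screening.

A :class:`TrialConfig` holds everything the engine needs to run one
country's trial: the arm list, phase durations, the run-in threshold,
stratification factor definitions, block sizes for the allocator, the
label-scheme tables, and the screening predicate. Two profiles ship
with the package (``australia``: 5 arms, no stratification;
``new_zealand``: 3 arms, stratified by ethnicity and interest in
healthy eating); any YAML/JSON file with the same shape can be loaded.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, ScreeningError
from .labels import (
    DailyIntakeReferences,
    HsrTables,
    SchemeTables,
    TrafficLightThresholds,
    WarningRule,
)

#: Stratum = tuple of factor levels, in factor-definition order.
Stratum = tuple[str, ...]


@dataclass
class ScreeningCriteria:
    """First-stage eligibility predicate over screening-questionnaire answers.

    The trial protocols keep the actual criteria; here they are an
    opaque configurable predicate: every key in ``required_true`` must
    be present and truthy in the answers.
    """

    required_true: list[str] = field(default_factory=list)

    def evaluate(self, answers: dict) -> bool:
        missing = [k for k in self.required_true if k not in answers]
        if missing:
            raise ScreeningError(f"incomplete screening answers, missing: {missing}")
        return all(bool(answers[k]) for k in self.required_true)


@dataclass
class TrialConfig:
    country: str
    arms: list[str]
    schemes: SchemeTables
    baseline_days: int = 7
    intervention_days: int = 28
    run_in_min_items: int = 15
    run_in_grace_days: int = 7
    recruitment_window_days: int = 540
    block_sizes: list[int] = field(default_factory=list)
    stratification: dict[str, list[str]] = field(default_factory=dict)
    screening: ScreeningCriteria = field(default_factory=ScreeningCriteria)

    def __post_init__(self) -> None:
        if not self.arms:
            raise ConfigError("arms must be non-empty")
        if len(set(self.arms)) != len(self.arms):
            raise ConfigError("duplicate arm tags")
        if self.baseline_days <= 0 or self.intervention_days <= 0:
            raise ConfigError("phase durations must be > 0")
        if self.run_in_min_items < 0:
            raise ConfigError("run_in_min_items must be >= 0")
        if not self.block_sizes:
            self.block_sizes = [len(self.arms), 2 * len(self.arms)]
        for size in self.block_sizes:
            if size <= 0 or size % len(self.arms) != 0:
                raise ConfigError(f"block size {size} is not a positive multiple of {len(self.arms)} arms")

    @property
    def total_days(self) -> int:
        return self.baseline_days + self.intervention_days

    def strata(self) -> list[Stratum]:
        """All strata as level tuples; a single empty tuple if unstratified."""
        if not self.stratification:
            return [()]
        level_sets = list(self.stratification.values())
        return [tuple(combo) for combo in itertools.product(*level_sets)]

    def stratum_for(self, factors: dict[str, str]) -> Stratum:
        """Build the stratum tuple for a participant's factor levels."""
        if not self.stratification:
            return ()
        stratum = []
        for factor, levels in self.stratification.items():
            level = factors.get(factor)
            if level not in levels:
                raise ConfigError(f"unknown level {level!r} for stratification factor {factor!r}")
            stratum.append(level)
        return tuple(stratum)


def _parse_hsr(raw: dict) -> HsrTables:
    return HsrTables(
        baseline={k: list(v) for k, v in raw["baseline"].items()},
        modifying={k: list(v) for k, v in raw["modifying"].items()},
        star_cutoffs=list(raw["star_cutoffs"]),
    )


def _parse_schemes(raw: dict) -> SchemeTables:
    try:
        tl = raw["traffic_light"]
        thresholds = TrafficLightThresholds(
            foods={k: tuple(v) for k, v in tl["foods"].items()},
            beverages={k: tuple(v) for k, v in tl["beverages"].items()},
        )
        refs = DailyIntakeReferences(**raw["daily_intake"])
        hsr_foods = _parse_hsr(raw["hsr"]["foods"])
        hsr_bev = _parse_hsr(raw["hsr"]["beverages"])
    except KeyError as exc:
        raise ConfigError(f"missing scheme table: {exc}") from exc
    warn = None
    if "warning" in raw:
        warn = WarningRule(thresholds=dict(raw["warning"]["thresholds"]),
                           text=raw["warning"].get("text", "HIGH IN"))
    return SchemeTables(traffic_light=thresholds, daily_intake=refs,
                        hsr_foods=hsr_foods, hsr_beverages=hsr_bev, warning=warn)


def config_from_dict(raw: dict) -> TrialConfig:
    try:
        schemes = _parse_schemes(raw["schemes"])
        return TrialConfig(
            country=raw["country"],
            arms=list(raw["arms"]),
            schemes=schemes,
            baseline_days=int(raw.get("baseline_days", 7)),
            intervention_days=int(raw.get("intervention_days", 28)),
            run_in_min_items=int(raw.get("run_in_min_items", 15)),
            run_in_grace_days=int(raw.get("run_in_grace_days", 7)),
            recruitment_window_days=int(raw.get("recruitment_window_days", 540)),
            block_sizes=list(raw.get("block_sizes", [])),
            stratification={k: list(v) for k, v in raw.get("stratification", {}).items()},
            screening=ScreeningCriteria(required_true=list(
                raw.get("screening", {}).get("required_true", []))),
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration field: {exc}") from exc


def load_config(path: str | Path) -> TrialConfig:
    """Load a trial configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return config_from_dict(raw)


def load_profile(name: str) -> TrialConfig:
    """Load a bundled country profile (``australia`` or ``new_zealand``)."""
    ref = resources.files("smartrct").joinpath(f"profiles/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown profile {name!r}") from exc
    return config_from_dict(raw)
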