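"""Age-conditioned environmental weight tables and ammonia class bins.

Suitability scoring rests on lookup tables: for each environmental variable
(dry-bulb temperature ``T``, relative humidity ``RH``, air velocity ``AV``)
and each recorded broiler age (21, 28, 35, 42 days), a sequence of half-open
value bins, each carrying a :class:`~broilerenv.quality.QualityClass` and an
integer weight 1-10; plus, per age, three ascending ammonia cutpoints mapping
NH3 concentration to a quality class.

The tables ship as editable YAML.  The published bins contain gaps, one
duplicated interval and one mislabelled row; :func:`load_weight_config`
canonicalizes them with explicit, logged repairs so that after loading every
in-domain value falls into exactly one bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .quality import QualityClass

__all__ = [
    "RECORDED_AGES",
    "ENV_VARIABLES",
    "WeightBin",
    "WeightConfig",
    "ValidationReport",
    "ConfigError",
    "load_weight_config",
    "validate_weight_config",
    "nearest_recorded_age",
    "lookup_env_weight",
    "lookup_ammonia_class",
]

#: Broiler ages (days) at which the tables are defined.
RECORDED_AGES: tuple[int, ...] = (21, 28, 35, 42)

#: Environmental variables covered by the weight bins.
ENV_VARIABLES: tuple[str, ...] = ("T", "RH", "AV")

#: Default ARC multiplier per ammonia quality class.
DEFAULT_ARC_MULTIPLIERS: dict[QualityClass, float] = {
    QualityClass.EXCELLENT: 1.0,
    QualityClass.GOOD: 0.75,
    QualityClass.MODERATE: 0.5,
    QualityClass.INADEQUATE: 0.25,
}

#: Default cutpoints discretizing ARC into the final label ARCf.
DEFAULT_ARCF_CUTPOINTS: tuple[float, ...] = (4.0, 6.0, 8.0)


class ConfigError(ValueError):
    """Raised for malformed or inconsistent weight-table configuration."""


@dataclass(frozen=True)
class WeightBin:
    """One half-open value interval ``[lower, upper)`` with its grade and weight."""

    lower: float
    upper: float  # may be +inf (open top bin)
    quality: QualityClass
    weight: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError(f"bin bounds must satisfy lower < upper, got {self}")
        if not 1 <= int(self.weight) <= 10:
            raise ConfigError(f"bin weight must be in [1, 10], got {self.weight}")

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


@dataclass
class ValidationReport:
    """Gaps, overlaps and repairs discovered while checking a config."""

    gaps: list[tuple[str, int, tuple[float, float]]] = field(default_factory=list)
    overlaps: list[tuple[str, int, tuple[float, float], str]] = field(default_factory=list)
    repairs_applied: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.gaps and not self.overlaps


@dataclass
class WeightConfig:
    """Canonicalized weight tables plus the ARC multiplier/cutpoint constants.

    ``env_bins`` maps ``(variable, recorded_age)`` to an ordered,
    non-overlapping list of :class:`WeightBin`; ``ammonia_cutpoints`` maps a
    recorded age to three ascending NH3 cutpoints; ``arc_multipliers`` scales
    RC by the ammonia class; ``arcf_cutpoints`` discretize ARC into ARCf.
    """

    env_bins: dict[tuple[str, int], list[WeightBin]]
    ammonia_cutpoints: dict[int, tuple[float, float, float]]
    arc_multipliers: dict[QualityClass, float] = field(
        default_factory=lambda: dict(DEFAULT_ARC_MULTIPLIERS)
    )
    arcf_cutpoints: tuple[float, ...] = DEFAULT_ARCF_CUTPOINTS
    validation: ValidationReport = field(default_factory=ValidationReport, compare=False)

    def __post_init__(self) -> None:
        cuts = self.arcf_cutpoints
        if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
            raise ConfigError(f"arcf_cutpoints must be strictly ascending, got {cuts}")
        if cuts and (cuts[0] < 0 or cuts[-1] > 10):
            raise ConfigError(f"arcf_cutpoints must lie inside [0, 10], got {cuts}")
        mults = [self.arc_multipliers[c] for c in QualityClass]
        if any(a <= b for a, b in zip(mults, mults[1:])):
            raise ConfigError(
                f"arc_multipliers must be strictly decreasing in severity, got {mults}"
            )
        for age, c in self.ammonia_cutpoints.items():
            if list(c) != sorted(c) or len(set(c)) != len(c):
                raise ConfigError(
                    f"ammonia_cutpoints[{age}] must be strictly ascending, got {c}"
                )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "env_bins": {
                var: {
                    age: [
                        [b.lower, b.upper, b.quality.label, b.weight]
                        for b in self.env_bins[(var, age)]
                    ]
                    for age in RECORDED_AGES
                    if (var, age) in self.env_bins
                }
                for var in ENV_VARIABLES
            },
            "ammonia_cutpoints": {
                age: list(c) for age, c in sorted(self.ammonia_cutpoints.items())
            },
            "arc_multipliers": {c.label: m for c, m in self.arc_multipliers.items()},
            "arcf_cutpoints": list(self.arcf_cutpoints),
        }

    def to_yaml(self, path: str | Path) -> None:
        """Write the canonical config; loading it back reproduces this config."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=None)
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _parse_bin(raw, context: str) -> WeightBin:
    if not isinstance(raw, (list, tuple)) or len(raw) != 4:
        raise ConfigError(
            f"{context}: each bin must be [lower, upper, quality, weight], got {raw!r}"
        )
    lower, upper, quality, weight = raw
    try:
        lower = float(lower)
        upper = float(upper)
        weight = int(weight)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: non-numeric bin entry in {raw!r}") from exc
    return WeightBin(lower, upper, QualityClass.from_label(quality), weight)


def _parse_mapping(doc: Mapping, key: str) -> Mapping:
    value = doc.get(key)
    if not isinstance(value, Mapping):
        raise ConfigError(f"config key '{key}' must be a mapping, got {type(value).__name__}")
    return value


def _read_yaml(source: str | Path) -> dict:
    text = Path(source).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {source}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {source} must contain a mapping at top level")
    return doc


def _packaged(name: str) -> dict:
    with resources.files("broilerenv.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _config_from_doc(doc: Mapping) -> tuple[WeightConfig, list[dict]]:
    """Build an (uncanonicalized) config from a merged YAML document."""
    env_bins: dict[tuple[str, int], list[WeightBin]] = {}
    raw_env = _parse_mapping(doc, "env_bins")
    for var, by_age in raw_env.items():
        if var not in ENV_VARIABLES:
            raise ConfigError(f"env_bins: unknown variable '{var}' (expected {ENV_VARIABLES})")
        if not isinstance(by_age, Mapping):
            raise ConfigError(f"env_bins['{var}'] must map ages to bin lists")
        for age, bins in by_age.items():
            age = int(age)
            if age not in RECORDED_AGES:
                raise ConfigError(
                    f"env_bins['{var}']: unknown age {age} (expected {RECORDED_AGES})"
                )
            env_bins[(var, age)] = [
                _parse_bin(b, f"env_bins['{var}'][{age}]") for b in bins
            ]
    missing = [
        (v, a) for v in ENV_VARIABLES for a in RECORDED_AGES if (v, a) not in env_bins
    ]
    if missing:
        raise ConfigError(f"env_bins: missing (variable, age) cells {missing}")

    raw_cuts = _parse_mapping(doc, "ammonia_cutpoints")
    ammonia = {}
    for age, cuts in raw_cuts.items():
        age = int(age)
        if not isinstance(cuts, (list, tuple)) or len(cuts) != 3:
            raise ConfigError(
                f"ammonia_cutpoints[{age}] must list exactly three cutpoints, got {cuts!r}"
            )
        ammonia[age] = tuple(float(c) for c in cuts)
    for age in RECORDED_AGES:
        if age not in ammonia:
            raise ConfigError(f"ammonia_cutpoints: missing age {age}")

    mults = dict(DEFAULT_ARC_MULTIPLIERS)
    if "arc_multipliers" in doc:
        for label, m in _parse_mapping(doc, "arc_multipliers").items():
            mults[QualityClass.from_label(label)] = float(m)

    arcf = DEFAULT_ARCF_CUTPOINTS
    if "arcf_cutpoints" in doc:
        arcf = tuple(float(c) for c in doc["arcf_cutpoints"])

    patches = list(doc.get("patches") or [])
    cfg = WeightConfig(
        env_bins=env_bins,
        ammonia_cutpoints=ammonia,
        arc_multipliers=mults,
        arcf_cutpoints=arcf,
    )
    return cfg, patches


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------


def _apply_patches(
    cfg: WeightConfig, patches: Iterable[Mapping], report: ValidationReport
) -> None:
    for p in patches:
        key = (str(p["variable"]), int(p["age"]))
        lower = float(p["lower"])
        bins = cfg.env_bins.get(key)
        if bins is None:
            raise ConfigError(f"patch refers to unknown cell {key}")
        hit = False
        for i, b in enumerate(bins):
            if math.isclose(b.lower, lower):
                fields = {}
                if "quality" in p:
                    fields["quality"] = QualityClass.from_label(p["quality"])
                if "weight" in p:
                    fields["weight"] = int(p["weight"])
                bins[i] = replace(b, **fields)
                shown = {
                    k: (v.label if isinstance(v, QualityClass) else v)
                    for k, v in fields.items()
                }
                report.repairs_applied.append(
                    f"patch {key} bin [{b.lower}, {b.upper}): "
                    f"{', '.join(f'{k}={v}' for k, v in shown.items())}"
                    + (f" ({p['note']})" if "note" in p else "")
                )
                hit = True
                break
        if not hit:
            raise ConfigError(f"patch target bin with lower={lower} not found in {key}")


def _canonicalize_cell(
    key: tuple[str, int], bins: list[WeightBin], report: ValidationReport
) -> list[WeightBin]:
    """Sort, truncate overlaps (first bin wins) and close gaps (extend below)."""
    var, age = key
    out: list[WeightBin] = []
    for b in sorted(bins, key=lambda b: (b.lower, b.upper)):
        if not out:
            out.append(b)
            continue
        prev = out[-1]
        if b.lower < prev.upper:  # overlap: keep the earlier bin's claim
            clipped = (b.lower, min(b.upper, prev.upper))
            report.repairs_applied.append(
                f"overlap at ({var}, {age}) {clipped}: bin "
                f"[{b.lower}, {b.upper}) ({b.quality.label}, {b.weight}) truncated"
            )
            if b.upper <= prev.upper:
                continue  # fully shadowed -> dropped
            b = replace(b, lower=prev.upper)
        if b.lower > prev.upper:  # gap: absorb into the preceding bin
            report.repairs_applied.append(
                f"gap at ({var}, {age}) ({prev.upper}, {b.lower}): bin "
                f"[{prev.lower}, {prev.upper}) extended to [{prev.lower}, {b.lower})"
            )
            out[-1] = replace(prev, upper=b.lower)
        out.append(b)
    return out


def load_weight_config(
    source: str | Path | None = None, *, repair: bool = True
) -> WeightConfig:
    """Load the weight tables from YAML, or the packaged defaults.

    Parameters
    ----------
    source
        Path to a YAML file containing ``env_bins`` and ``ammonia_cutpoints``
        (plus optional ``arc_multipliers``, ``arcf_cutpoints`` and ``patches``).
        ``None`` loads the packaged default tables.
    repair
        When true (default), point patches are applied and overlaps/gaps are
        canonicalized; every repair is logged in ``config.validation``.
        ``repair=False`` returns the tables verbatim, useful for auditing the
        shipped defaults with :func:`validate_weight_config`.
    """
    if source is None:
        doc = _packaged("table2_env_weights.yaml")
        doc.update(_packaged("table3_ammonia.yaml"))
    else:
        doc = _read_yaml(source)
    cfg, patches = _config_from_doc(doc)
    if repair:
        report = cfg.validation
        _apply_patches(cfg, patches, report)
        for key in list(cfg.env_bins):
            cfg.env_bins[key] = _canonicalize_cell(key, cfg.env_bins[key], report)
    return cfg


def validate_weight_config(cfg: WeightConfig) -> ValidationReport:
    """Report every gap and overlap in ``cfg`` relative to each cell's domain.

    Pure function: ``cfg`` is not modified.  The domain of a (variable, age)
    cell is the span from its lowest ``lower`` to its highest ``upper``.
    """
    report = ValidationReport()
    for (var, age), bins in sorted(cfg.env_bins.items()):
        ordered = sorted(bins, key=lambda b: (b.lower, b.upper))
        for prev, b in zip(ordered, ordered[1:]):
            if b.lower < prev.upper:
                report.overlaps.append(
                    (
                        var,
                        age,
                        (b.lower, min(b.upper, prev.upper)),
                        f"[{prev.lower}, {prev.upper}) ({prev.quality.label}, {prev.weight}) vs "
                        f"[{b.lower}, {b.upper}) ({b.quality.label}, {b.weight})",
                    )
                )
            elif b.lower > prev.upper:
                report.gaps.append((var, age, (prev.upper, b.lower)))
    return report


# ---------------------------------------------------------------------------
# Lookups
# ---------------------------------------------------------------------------


def nearest_recorded_age(age_days: int) -> int:
    """Map an arbitrary age in days onto the nearest recorded age; ties go younger."""
    age_days = int(age_days)
    if age_days < 1:
        raise ValueError(f"age_days must be >= 1, got {age_days}")
    return min(RECORDED_AGES, key=lambda a: (abs(age_days - a), a))


def lookup_env_weight(
    cfg: WeightConfig, variable: str, age_days: int, value: float
) -> tuple[QualityClass, int]:
    """Resolve ``value`` of ``variable`` at ``age_days`` to its (class, weight).

    Values below the lowest bin clamp into it; values at or above the highest
    bin's upper bound fall into the highest bin (field sensors occasionally
    read outside the tabled ranges).
    """
    if variable not in ENV_VARIABLES:
        raise ValueError(f"unknown variable '{variable}' (expected one of {ENV_VARIABLES})")
    value = float(value)
    if math.isnan(value):
        raise ValueError(f"value for {variable} is NaN")
    bins = cfg.env_bins[(variable, nearest_recorded_age(age_days))]
    if value < bins[0].lower:
        b = bins[0]
    elif value >= bins[-1].upper:
        b = bins[-1]
    else:
        b = next(b for b in bins if b.contains(value))
    return b.quality, b.weight


def lookup_ammonia_class(cfg: WeightConfig, age_days: int, nh3: float) -> QualityClass:
    """Grade an ammonia concentration (mg/m3) at the given age.

    Monotone: a higher concentration never yields a more favourable class.
    """
    nh3 = float(nh3)
    if math.isnan(nh3) or nh3 < 0:
        raise ValueError(f"nh3 must be a non-negative number, got {nh3}")
    cuts = cfg.ammonia_cutpoints[nearest_recorded_age(age_days)]
    rank = int(np.searchsorted(np.asarray(cuts), nh3, side="right"))
    return QualityClass(rank)
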