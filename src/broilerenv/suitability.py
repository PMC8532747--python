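"""Rearing-condition scoring: RC, the ammonia correction ARC, and ARCf.

Each environmental record (dry-bulb temperature, relative humidity, air
velocity, ammonia, at a broiler age) is scored in three steps:

1. *RC* — each of T, RH and AV is resolved through its age-conditioned weight
   bin and RC is the mean of the three bin weights, so ``RC in [1, 10]``.
   The aggregator is pluggable; the mean is the default because it is the
   reading under which the score stays on the 0-10 scale that the final
   discretization assumes.
2. *ARC* — RC is scaled by the ammonia-class multiplier
   (Excellent x1, Good x0.75, Moderate x0.5, Inadequate x0.25).
3. *ARCf* — ARC is discretized: ``< 4`` Inadequate, ``[4, 6)`` Moderate,
   ``[6, 8)`` Good, ``>= 8`` Excellent.

The labeling function is deterministic and piecewise constant on axis-aligned
boxes of (T, RH, AV, NH3, age) space — exactly the structure an axis-aligned
decision tree can represent without error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .quality import CLASS_LABELS, QualityClass
from .weight_tables import WeightConfig, lookup_ammonia_class, lookup_env_weight

__all__ = [
    "EnvRecord",
    "ScoredRecord",
    "rearing_condition",
    "ammonia_correction",
    "discretize_arc",
    "label_record",
    "label_dataset",
    "read_records_csv",
    "LOCATIONS",
    "RECORD_COLUMNS",
    "SCORED_COLUMNS",
]

logger = logging.getLogger(__name__)

#: In-house measurement locations along the tunnel-ventilation axis.
LOCATIONS: tuple[str, ...] = ("intake", "center", "exhaust")

#: CSV schema for raw environmental records.
RECORD_COLUMNS = ("house_id", "location", "age_days", "t_db_c", "rh_pct", "av_ms", "nh3_mgm3")

#: Columns appended by :func:`label_dataset`.
SCORED_COLUMNS = ("wt", "wrh", "wav", "rc", "nh3_class", "arc", "arcf")


@dataclass(frozen=True)
class EnvRecord:
    """One timed measurement of the four environmental variables."""

    house_id: str
    location: str
    age_days: int
    t_db: float  # dry-bulb temperature, degC
    rh: float  # relative humidity, %
    av: float  # air velocity, m/s
    nh3: float  # ammonia concentration, mg/m3

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if int(self.age_days) < 1:
            raise ValueError(f"age_days must be >= 1, got {self.age_days}")
        for name in ("t_db", "rh", "av", "nh3"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0 <= self.rh <= 100:
            raise ValueError(f"rh must lie in [0, 100], got {self.rh}")
        if self.av < 0:
            raise ValueError(f"av must be >= 0, got {self.av}")
        if self.nh3 < 0:
            raise ValueError(f"nh3 must be >= 0, got {self.nh3}")


@dataclass(frozen=True)
class ScoredRecord:
    """An :class:`EnvRecord` together with every intermediate score."""

    record: EnvRecord
    wt: int
    wrh: int
    wav: int
    rc: float
    nh3_class: QualityClass
    arc: float
    arcf: QualityClass


Aggregator = Callable[[Sequence[float]], float]


def _mean(weights: Sequence[float]) -> float:
    return sum(weights) / len(weights)


def rearing_condition(
    cfg: WeightConfig, rec: EnvRecord, aggregator: Aggregator = _mean
) -> tuple[int, int, int, float]:
    """Look up the three variable weights and aggregate them into RC."""
    _, wt = lookup_env_weight(cfg, "T", rec.age_days, rec.t_db)
    _, wrh = lookup_env_weight(cfg, "RH", rec.age_days, rec.rh)
    _, wav = lookup_env_weight(cfg, "AV", rec.age_days, rec.av)
    return wt, wrh, wav, float(aggregator((wt, wrh, wav)))


def ammonia_correction(rc: float, nh3_class: QualityClass, cfg: WeightConfig) -> float:
    """Scale RC by the multiplier of the record's ammonia class."""
    if not 0 <= rc <= 10:
        raise ValueError(f"rc must lie in [0, 10], got {rc}")
    return rc * cfg.arc_multipliers[nh3_class]


def discretize_arc(arc: float, cfg: WeightConfig) -> QualityClass:
    """Map an ARC value onto the final four-level label ARCf."""
    if not 0 <= arc <= 10:
        raise ValueError(f"arc must lie in [0, 10], got {arc}")
    cuts = np.asarray(cfg.arcf_cutpoints)
    # index counts cutpoints <= arc: 0 -> worst region, len(cuts) -> best
    idx = int(np.searchsorted(cuts, arc, side="right"))
    return QualityClass(len(cuts) - idx)


def label_record(cfg: WeightConfig, rec: EnvRecord, aggregator: Aggregator = _mean) -> ScoredRecord:
    """Score one record end to end (RC -> ammonia class -> ARC -> ARCf)."""
    wt, wrh, wav, rc = rearing_condition(cfg, rec, aggregator)
    nh3_class = lookup_ammonia_class(cfg, rec.age_days, rec.nh3)
    arc = ammonia_correction(rc, nh3_class, cfg)
    return ScoredRecord(rec, wt, wrh, wav, rc, nh3_class, arc, discretize_arc(arc, cfg))


def _records_to_frame(records: Iterable[EnvRecord]) -> pd.DataFrame:
    rows = [
        (r.house_id, r.location, r.age_days, r.t_db, r.rh, r.av, r.nh3) for r in records
    ]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def label_dataset(
    cfg: WeightConfig,
    records: pd.DataFrame | Iterable[EnvRecord],
    aggregator: Aggregator = _mean,
) -> pd.DataFrame:
    """Score a whole dataset, preserving row order.

    ``records`` is either a DataFrame with the :data:`RECORD_COLUMNS` schema
    or an iterable of :class:`EnvRecord`.  Returns a copy with the
    :data:`SCORED_COLUMNS` appended; logs the ARCf class frequencies.
    """
    if not isinstance(records, pd.DataFrame):
        records = _records_to_frame(records)
    if records.empty:
        raise ValueError("cannot label an empty dataset")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"input is missing required columns {missing}")

    out = records.reset_index(drop=True).copy()
    n = len(out)
    wt = np.empty(n, dtype=int)
    wrh = np.empty(n, dtype=int)
    wav = np.empty(n, dtype=int)
    rc = np.empty(n)
    arc = np.empty(n)
    nh3_cls: list[str] = []
    arcf: list[str] = []
    for i, row in enumerate(out.itertuples(index=False)):
        rec = EnvRecord(
            house_id=str(row.house_id),
            location=str(row.location),
            age_days=int(row.age_days),
            t_db=float(row.t_db_c),
            rh=float(row.rh_pct),
            av=float(row.av_ms),
            nh3=float(row.nh3_mgm3),
        )
        s = label_record(cfg, rec, aggregator)
        wt[i], wrh[i], wav[i] = s.wt, s.wrh, s.wav
        rc[i], arc[i] = s.rc, s.arc
        nh3_cls.append(s.nh3_class.label)
        arcf.append(s.arcf.label)

    out["wt"], out["wrh"], out["wav"] = wt, wrh, wav
    out["rc"] = rc
    out["nh3_class"] = nh3_cls
    out["arc"] = arc
    out["arcf"] = arcf

    freq = out["arcf"].value_counts().reindex(CLASS_LABELS, fill_value=0)
    logger.info(
        "labeled %d records; ARCf frequencies: %s",
        n,
        ", ".join(f"{lbl}={int(c)}" for lbl, c in freq.items()),
    )
    return out


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read an environmental-records CSV and check its schema."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
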