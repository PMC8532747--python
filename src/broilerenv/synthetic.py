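"""Synthetic broiler-house microclimate datasets.

The generator emulates the distributional structure of the study conditions:
per recorded age (21/28/35/42 d), each of the four environmental variables is
drawn from a truncated normal with the published per-age mean and standard
deviation, independently within a record (no covariances are published; a
correlation-matrix hook is provided and defaults to identity).  Records are
laid out as a full factorial design of 4 houses x 3 in-house locations x
4 ages x 52 replicates = 2496 rows, the shape of the original dataset; the
factorization into 52 replicates per cell is a reconstruction that reproduces
the published total.

Truncation (RH in [0, 100], AV >= 0, NH3 >= 0, T unbounded) is enforced by
rejection resampling, so the nominal mean/SD are the parameters of the parent
normal, not the moments of the truncated draw — material only for AV, whose
lower bound sits ~1-2 SD below the mean (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .suitability import RECORD_COLUMNS
from .weight_tables import RECORDED_AGES

__all__ = [
    "GENERATOR_VARIABLES",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_generator_config",
    "stress_generator_config",
    "generate_records",
    "summarize",
]

#: Generator variable names, in dataset-column order.
GENERATOR_VARIABLES: tuple[str, ...] = ("T", "RH", "AV", "NH3")

_VAR_TO_COLUMN = {"T": "t_db_c", "RH": "rh_pct", "AV": "av_ms", "NH3": "nh3_mgm3"}

#: Per (variable, age) mean and SD of the study conditions.
DEFAULT_MOMENTS: dict[tuple[str, int], tuple[float, float]] = {
    ("T", 21): (25.3, 3.4), ("T", 28): (25.6, 2.7), ("T", 35): (25.2, 1.9), ("T", 42): (24.2, 2.7),
    ("RH", 21): (63.1, 12.2), ("RH", 28): (69.8, 14.5), ("RH", 35): (67.8, 12.0), ("RH", 42): (70.6, 12.3),
    ("AV", 21): (0.5, 0.4), ("AV", 28): (0.8, 0.5), ("AV", 35): (1.0, 0.4), ("AV", 42): (1.0, 0.5),
    ("NH3", 21): (4.0, 0.8), ("NH3", 28): (4.3, 1.5), ("NH3", 35): (4.0, 1.5), ("NH3", 42): (4.2, 0.8),
}

#: Physical truncation bounds per variable.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "T": (-math.inf, math.inf),
    "RH": (0.0, 100.0),
    "AV": (0.0, math.inf),
    "NH3": (0.0, math.inf),
}


@dataclass
class GeneratorConfig:
    """Parameters of the factorial truncated-normal generator."""

    moments: dict[tuple[str, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS)
    )
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    houses: int = 4
    locations: tuple[str, ...] = ("intake", "center", "exhaust")
    ages: tuple[int, ...] = RECORDED_AGES
    replicates_per_cell: int = 52
    seed: int = 0
    #: Optional 4x4 correlation matrix over (T, RH, AV, NH3); None = identity.
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError(f"replicates_per_cell must be >= 1, got {self.replicates_per_cell}")
        if self.houses < 1:
            raise ValueError(f"houses must be >= 1, got {self.houses}")
        for (var, age), (mean, sd) in self.moments.items():
            if sd <= 0:
                raise ValueError(f"sd for ({var}, {age}) must be > 0, got {sd}")
        for var in GENERATOR_VARIABLES:
            for age in self.ages:
                if (var, age) not in self.moments:
                    raise ValueError(f"moments: missing cell ({var}, {age})")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (4, 4) or not np.allclose(c, c.T):
                raise ValueError("correlation must be a symmetric 4x4 matrix")
            self.correlation = c

    @property
    def n_records(self) -> int:
        return self.houses * len(self.locations) * len(self.ages) * self.replicates_per_cell

    def to_dict(self) -> dict:
        return {
            "moments": {
                var: {age: list(self.moments[(var, age)]) for age in self.ages}
                for var in GENERATOR_VARIABLES
            },
            "bounds": {
                var: [_bound_repr(lo), _bound_repr(hi)]
                for var, (lo, hi) in self.bounds.items()
            },
            "houses": self.houses,
            "locations": list(self.locations),
            "ages": list(self.ages),
            "replicates_per_cell": self.replicates_per_cell,
            "seed": self.seed,
            "correlation": None if self.correlation is None else self.correlation.tolist(),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _bound_repr(x: float) -> float | str:
    if x == math.inf:
        return ".inf"
    if x == -math.inf:
        return "-.inf"
    return x


def _bound_parse(x) -> float:
    if x in (".inf", "inf"):
        return math.inf
    if x in ("-.inf", "-inf"):
        return -math.inf
    return float(x)


def default_generator_config(**overrides) -> GeneratorConfig:
    """The study conditions: published per-age moments, 2496-row factorial."""
    return GeneratorConfig(**overrides)


def _config_from_doc(doc: Mapping, **overrides) -> GeneratorConfig:
    kwargs: dict = {}
    if "moments" in doc:
        moments = dict(DEFAULT_MOMENTS)
        for var, by_age in doc["moments"].items():
            for age, pair in by_age.items():
                moments[(str(var), int(age))] = (float(pair[0]), float(pair[1]))
        kwargs["moments"] = moments
    if "bounds" in doc:
        bounds = dict(DEFAULT_BOUNDS)
        for var, (lo, hi) in doc["bounds"].items():
            bounds[str(var)] = (_bound_parse(lo), _bound_parse(hi))
        kwargs["bounds"] = bounds
    for key in ("houses", "replicates_per_cell", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    if "locations" in doc:
        kwargs["locations"] = tuple(doc["locations"])
    if "ages" in doc:
        kwargs["ages"] = tuple(int(a) for a in doc["ages"])
    if doc.get("correlation") is not None:
        kwargs["correlation"] = np.asarray(doc["correlation"], dtype=float)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def load_generator_config(source: str | Path, **overrides) -> GeneratorConfig:
    """Load a generator config from YAML; unspecified fields keep defaults."""
    doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, Mapping):
        raise ValueError(f"generator config {source} must be a mapping")
    return _config_from_doc(doc, **overrides)


def stress_generator_config(**overrides) -> GeneratorConfig:
    """Packaged scenario with inflated ammonia (all four NH3 classes populated)."""
    with resources.files("broilerenv.data").joinpath("stress_nh3.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return _config_from_doc(doc, **overrides)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated records plus the provenance needed to regenerate them."""

    records: pd.DataFrame
    provenance: tuple[str, int]  # (config hash, seed)


def _draw_cell(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    sds: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    chol: np.ndarray | None,
) -> np.ndarray:
    """Draw n rows of the 4 variables, rejection-resampling out-of-bounds rows."""

    def sample(k: int) -> np.ndarray:
        z = rng.standard_normal((k, 4))
        if chol is not None:
            z = z @ chol.T
        return means + sds * z

    x = sample(n)
    bad = np.any((x < lows) | (x > highs), axis=1)
    while bad.any():
        x[bad] = sample(int(bad.sum()))
        bad = np.any((x < lows) | (x > highs), axis=1)
    return x


def generate_records(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate the full factorial dataset; bit-for-bit reproducible from (cfg, seed)."""
    if cfg is None:
        cfg = default_generator_config()
    rng = np.random.default_rng(cfg.seed)
    chol = None
    if cfg.correlation is not None and not np.allclose(cfg.correlation, np.eye(4)):
        chol = np.linalg.cholesky(cfg.correlation)

    lows = np.array([cfg.bounds[v][0] for v in GENERATOR_VARIABLES])
    highs = np.array([cfg.bounds[v][1] for v in GENERATOR_VARIABLES])

    frames = []
    n_cell = cfg.houses * len(cfg.locations) * cfg.replicates_per_cell
    for age in cfg.ages:
        means = np.array([cfg.moments[(v, age)][0] for v in GENERATOR_VARIABLES])
        sds = np.array([cfg.moments[(v, age)][1] for v in GENERATOR_VARIABLES])
        x = _draw_cell(rng, n_cell, means, sds, lows, highs, chol)
        idx = pd.MultiIndex.from_product(
            [
                [f"house_{h + 1}" for h in range(cfg.houses)],
                list(cfg.locations),
                range(cfg.replicates_per_cell),
            ],
            names=["house_id", "location", "replicate"],
        )
        frame = pd.DataFrame(
            x, columns=[_VAR_TO_COLUMN[v] for v in GENERATOR_VARIABLES]
        )
        frame.insert(0, "house_id", idx.get_level_values("house_id"))
        frame.insert(1, "location", idx.get_level_values("location"))
        frame.insert(2, "age_days", age)
        frames.append(frame)

    records = pd.concat(frames, ignore_index=True)
    # canonical row order: house x location x age x replicate
    records["_rep"] = records.groupby(["house_id", "location", "age_days"]).cumcount()
    records = (
        records.sort_values(["house_id", "location", "age_days", "_rep"], kind="mergesort")
        .drop(columns="_rep")
        .reset_index(drop=True)
    )
    records = records[list(RECORD_COLUMNS)]
    return SyntheticDataset(records=records, provenance=(cfg.config_hash(), cfg.seed))


def summarize(ds: SyntheticDataset | pd.DataFrame) -> pd.DataFrame:
    """Per-age mean/SD table of the four variables (variables x (age, stat)).

    A cell with a single record reports its SD as NaN.
    """
    df = ds.records if isinstance(ds, SyntheticDataset) else ds
    if df.empty:
        raise ValueError("cannot summarize an empty dataset")
    ages = sorted(df["age_days"].unique())
    data = {}
    for age in ages:
        sub = df[df["age_days"] == age]
        for stat in ("mean", "sd"):
            col = []
            for var in GENERATOR_VARIABLES:
                values = sub[_VAR_TO_COLUMN[var]]
                col.append(values.mean() if stat == "mean" else values.std(ddof=1))
            data[(age, stat)] = col
    out = pd.DataFrame(data, index=list(GENERATOR_VARIABLES))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["age_days", "stat"])
    return out
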