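"""Readers, writers, configuration and fixtures.

CSV is the only tabular interchange format.  Configuration is YAML with
strict key checking: every field defaults to the study configuration
(life-history table, reference-model priors, estimator settings) and any
unknown key is an error rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .com_estimators import CmsyConfig, OcomConfig, SscomConfig
from .operating_model import FleetSpec, LifeHistory, ObservationSpec
from .truth_spm import MCMCSettings, SPMConfig

__all__ = [
    "CatchSeries",
    "read_catch_csv",
    "write_catch_csv",
    "RunConfig",
    "load_config",
    "make_anchovy_fixture",
    "write_results",
]

logger = logging.getLogger(__name__)


@dataclass
class CatchSeries:
    """An annual catch series (tonnes), optionally with an abundance index."""

    years: np.ndarray
    catch: np.ndarray
    index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.catch = np.asarray(self.catch, dtype=float)
        if self.index is not None:
            self.index = np.asarray(self.index, dtype=float)
            if len(self.index) != len(self.years):
                raise ValueError("index length must match years")
        if len(self.years) != len(self.catch):
            raise ValueError("years and catch must have equal length")
        if len(self.years) == 0:
            raise ValueError("empty series")
        diffs = np.diff(self.years)
        if np.any(diffs == 0):
            dup = self.years[:-1][diffs == 0]
            raise ValueError(f"duplicate years: {dup.tolist()}")
        if np.any(diffs != 1):
            gaps = self.years[:-1][diffs > 1]
            raise ValueError(f"years must be gap-free; gaps after {gaps.tolist()}")
        if np.any(self.catch <= 0):
            bad = self.years[self.catch <= 0]
            raise ValueError(f"non-positive catch in years {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.years)


def read_catch_csv(path) -> CatchSeries:
    """Read and validate a catch CSV with ``year`` and ``catch`` columns.

    An optional ``index`` column is carried along.  Rows out of order are
    sorted with a warning; gaps, duplicate years or non-positive catches
    raise a validation error naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "year" not in cols or "catch" not in cols:
        raise ValueError(f"{path}: expected 'year' and 'catch' columns, found {list(df.columns)}")
    year_raw = df[cols["year"]]
    catch_raw = df[cols["catch"]]
    for name, col in (("year", year_raw), ("catch", catch_raw)):
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(
                f"{path}: column '{name}' is not numeric; comma-decimal or "
                "thousands-separator dialects are not supported"
            )
    years = year_raw.to_numpy()
    if np.any(years != np.floor(years)):
        raise ValueError(f"{path}: non-integer year labels")
    order = np.argsort(years, kind="stable")
    if not np.all(order == np.arange(len(order))):
        logger.warning("%s: rows out of order; sorting by year", path)
        df = df.iloc[order]
    idx = df[cols["index"]].to_numpy() if "index" in cols else None
    return CatchSeries(
        years=df[cols["year"]].to_numpy().astype(int),
        catch=df[cols["catch"]].to_numpy().astype(float),
        index=idx,
    )


def write_catch_csv(series: CatchSeries, path) -> None:
    data = {"year": series.years, "catch": series.catch}
    if series.index is not None:
        data["index"] = series.index
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationConfig:
    n_replicates: int = 500
    methods: tuple[str, ...] = ("cmsy13", "cmsy17", "ocom", "sscom")
    reference: str = "spm"  # or "om"
    shape_from_om: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of a simulation-testing run."""

    life_history: LifeHistory = field(default_factory=LifeHistory)
    fleet: FleetSpec = field(default_factory=FleetSpec)
    observation: ObservationSpec = field(default_factory=ObservationSpec)
    truth_spm: SPMConfig = field(default_factory=SPMConfig)
    cmsy13: CmsyConfig = field(default_factory=CmsyConfig)
    cmsy17: CmsyConfig = field(default_factory=lambda: CmsyConfig(variant="2017"))
    ocom: OcomConfig = field(default_factory=OcomConfig)
    sscom: SscomConfig = field(default_factory=SscomConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 1234
    scale: str = "full"  # or "test"
    out_dir: str = "results"


class ConfigError(ValueError):
    pass


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if dataclasses.is_dataclass(_resolve_nested(cls, key)):
            kwargs[key] = _build_dataclass(_resolve_nested(cls, key), value, f"{path}.{key}")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        base = cls()
    except TypeError as exc:
        raise ConfigError(f"{path}: cannot default-construct {cls.__name__}") from exc
    try:
        return dataclasses.replace(base, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _resolve_nested(cls, key):
    for f in dataclasses.fields(cls):
        if f.name == key:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING \
                else f.default
            return type(default) if dataclasses.is_dataclass(default) else None
    return None


def load_config(path=None) -> RunConfig:
    """Load a YAML run configuration; absent file/None means all defaults.

    Unknown keys and type mismatches are errors.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _build_dataclass(RunConfig, raw, "config")
    if cfg.scale not in ("full", "test"):
        raise ConfigError(f"config.scale must be 'full' or 'test', got {cfg.scale!r}")
    return cfg


def config_to_dict(cfg) -> dict:
    """Recursively serialise a (nested) config dataclass to plain types."""
    if dataclasses.is_dataclass(cfg):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (tuple, list)):
        return [config_to_dict(v) for v in cfg]
    if isinstance(cfg, np.generic):
        return cfg.item()
    return cfg


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_anchovy_fixture(seed: int = 0) -> CatchSeries:
    """Synthetic 1990-2021 anchovy-like catch series (tonnes).

    A stand-in for the regional catch statistics used in the original
    assessment, which are not publicly deposited; only summary anchors
    are reproduced: a geometric rise to the 2003 maximum of 179,854 t, a
    geometric decline to 20,000 t in 2019, 49,000 t in 2021, a long-term
    (1990-2021) mean near 79,000 t and a 2017-2021 mean near 33,000 t.
    Non-anchor years carry a small seeded lognormal wiggle.  This is NOT
    the real catch series; it exists for smoke tests and demos.
    """
    years = np.arange(1990, 2022)
    peak, y_peak = 179_854.0, 2003
    c2019, c2021 = 20_000.0, 49_000.0
    rise = 1.115  # annual factor 1990 -> 2003
    fall = (c2019 / peak) ** (1.0 / 16.0)  # 2003 -> 2019
    catch = np.empty(len(years))
    for i, y in enumerate(years):
        if y <= y_peak:
            catch[i] = peak * rise ** (y - y_peak)
        elif y <= 2019:
            catch[i] = peak * fall ** (y - y_peak)
        else:
            catch[i] = c2019 * (c2021 / c2019) ** ((y - 2019) / 2.0)
    rng = np.random.default_rng(seed)
    wiggle = np.exp(rng.normal(0.0, 0.03, len(years)))
    anchors = np.isin(years, (y_peak, 2019, 2021))
    catch = np.where(anchors, catch, catch * wiggle)
    return CatchSeries(years=years, catch=catch)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(result, out_dir, config: dict | None = None,
                  timings: dict | None = None) -> dict:
    """Write experiment tables and a JSON manifest; returns the manifest.

    Outputs: records.csv, failures.csv, summary.csv, classification.csv
    and manifest.json.  Re-running with identical inputs produces
    byte-identical CSVs; wall-clock timings live under the manifest's
    ``timing`` key only.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    files = {}
    for name, df in (("records", result.records), ("failures", result.failures),
                     ("summary", result.summary), ("classification", result.classification)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        files[name] = p.name
    manifest = {
        "package": "comsim",
        "version": __version__,
        "seed": result.seed,
        "refs": {k: float(v) for k, v in result.refs.items()},
        "config": config if config is not None else result.config,
        "files": files,
        "n_records": int(len(result.records)),
        "n_failures": int(len(result.failures)),
    }
    if timings:
        manifest["timing"] = timings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str))
    return manifest
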