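"""Run configuration loading, resolution, and manifests.

A run is described by a small YAML or JSON document::

    strategy: prio_maxwait        # fifo | prio | prio_maxwait | perfect
    n_days: 200
    t_max: 360                    # minutes; prio_maxwait only
    seeds: {master: 7}            # or the four named stream seeds
    catalog: catalog.csv          # optional; default = embedded catalog
    operating_point: lowFPR       # preset name or CSV path
    roc: roc.csv                  # optional; default derived from lowFPR
    timing:                       # optional; default = calibrated synthetic
      synthetic: {day_mean_arrival_delta: 12, ...}
      # or: {arrival_csv: a.csv, reporting_csv: r.csv}

Every omitted section falls back to the embedded defaults (institutional
catalog, bundled operating points, calibrated synthetic timing), so the
minimal config is just a strategy, a day count, and a seed.  A
``RunSpec`` is the fully resolved, serializable form; its manifest plus
the package version suffices to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .catalog import FindingCatalog, default_catalog
from .classifier import (
    OperatingPoint,
    ROCModel,
    default_roc_model,
    low_fnr_preset,
    low_fpr_preset,
)
from .simulate import STRATEGIES, SimulationConfig, StreamSeeds
from .timing import (
    DEFAULT_HIST_SEED,
    SyntheticTimingParams,
    TimeOfDayHistogram,
    default_histograms,
    synth_histogram,
)

__all__ = ["ConfigError", "RunSpec", "load_run_spec", "load_config", "write_manifest"]

OPERATING_POINT_PRESETS = {"lowFPR": low_fpr_preset, "lowFNR": low_fnr_preset}

_STREAMS = ("arrival", "labels", "classifier", "service")


class ConfigError(ValueError):
    """Configuration problem; the message names the offending key."""


@dataclass
class RunSpec:
    """Fully resolved run description (serializable)."""

    strategy: str
    n_days: int
    seeds: dict
    t_max: float | None = None
    catalog: str | None = None  # CSV path or None for embedded default
    operating_point: str | None = None  # preset name, CSV path, or None
    roc: str | None = None
    timing: dict | None = None  # {"synthetic": {...}} or {"*_csv": path}

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    # -- resolution into runnable objects ---------------------------------

    def resolved_seeds(self) -> StreamSeeds:
        seeds = self.seeds
        if "master" in seeds:
            return StreamSeeds.from_master(int(seeds["master"]))
        missing = [s for s in _STREAMS if s not in seeds]
        if missing:
            raise ConfigError(
                f"seeds: provide 'master' or all named streams; missing {missing}"
            )
        return StreamSeeds(**{s: int(seeds[s]) for s in _STREAMS})

    def resolved_catalog(self) -> FindingCatalog:
        if self.catalog is None:
            return default_catalog()
        return FindingCatalog.from_csv(self.catalog)

    def resolved_operating_point(self) -> OperatingPoint | None:
        if self.strategy not in ("prio", "prio_maxwait"):
            return None
        name = self.operating_point or "lowFPR"
        if name in OPERATING_POINT_PRESETS:
            return OPERATING_POINT_PRESETS[name]()
        return OperatingPoint.from_csv(name)

    def resolved_roc(self) -> ROCModel:
        if self.roc is None:
            return default_roc_model()
        return ROCModel.from_csv(self.roc)

    def resolved_histograms(self) -> tuple[TimeOfDayHistogram, TimeOfDayHistogram]:
        timing = self.timing
        if timing is None:
            return default_histograms()
        if "arrival_csv" in timing or "reporting_csv" in timing:
            missing = [
                k for k in ("arrival_csv", "reporting_csv") if k not in timing
            ]
            if missing:
                raise ConfigError(f"timing: missing {missing}")
            return (
                TimeOfDayHistogram.from_csv(timing["arrival_csv"], kind="arrival"),
                TimeOfDayHistogram.from_csv(timing["reporting_csv"], kind="reporting"),
            )
        if "synthetic" in timing:
            try:
                params = SyntheticTimingParams(**timing["synthetic"])
            except TypeError as exc:
                raise ConfigError(f"timing.synthetic: {exc}") from exc
            return default_histograms(params, seed=timing.get("hist_seed", DEFAULT_HIST_SEED))
        raise ConfigError(
            "timing: expected 'synthetic' params or 'arrival_csv'/'reporting_csv'"
        )

    def build(self) -> SimulationConfig:
        arrival_hist, reporting_hist = self.resolved_histograms()
        return SimulationConfig(
            strategy=self.strategy,
            n_days=self.n_days,
            catalog=self.resolved_catalog(),
            arrival_hist=arrival_hist,
            reporting_hist=reporting_hist,
            operating_point=self.resolved_operating_point(),
            t_max=self.t_max,
            seeds=self.resolved_seeds(),
        )

    # -- parsing -----------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "RunSpec":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(raw) - {
            "strategy",
            "n_days",
            "t_max",
            "seeds",
            "catalog",
            "operating_point",
            "roc",
            "timing",
        }
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "strategy" not in raw:
            raise ConfigError("missing required key 'strategy'")
        strategy = raw["strategy"]
        if strategy not in STRATEGIES:
            raise ConfigError(
                f"strategy: unknown value {strategy!r}; choose from {STRATEGIES}"
            )
        if "n_days" not in raw:
            raise ConfigError("missing required key 'n_days'")
        n_days = int(raw["n_days"])
        if n_days < 1:
            raise ConfigError("n_days: must be at least 1")
        if "seeds" not in raw:
            raise ConfigError("missing required key 'seeds'")
        t_max = raw.get("t_max")
        if strategy == "prio_maxwait":
            if t_max is None:
                raise ConfigError("t_max: required for strategy 'prio_maxwait'")
            t_max = float(t_max)
            if t_max <= 0:
                raise ConfigError("t_max: must be positive")
        elif t_max is not None:
            t_max = float(t_max)
        spec = cls(
            strategy=strategy,
            n_days=n_days,
            seeds=dict(raw["seeds"]),
            t_max=t_max,
            catalog=raw.get("catalog"),
            operating_point=raw.get("operating_point"),
            roc=raw.get("roc"),
            timing=raw.get("timing"),
        )
        spec.resolved_seeds()  # validate eagerly
        return spec


def load_run_spec(path) -> RunSpec:
    """Parse and validate a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    return RunSpec.from_dict(raw)


def load_config(path) -> SimulationConfig:
    """Load a run configuration file into a runnable simulation config."""
    return load_run_spec(path).build()


def write_manifest(
    spec: RunSpec, out_paths: dict[str, str], path, extra: dict | None = None
) -> None:
    """Write the JSON run manifest (resolved config + version + outputs)."""
    manifest = {
        "package": "worklistsim",
        "version": __version__,
        "config": spec.to_dict(),
        "resolved_seeds": asdict(spec.resolved_seeds()),
        "outputs": out_paths,
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
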