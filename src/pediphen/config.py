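"""Run configuration: YAML config files with flag override and validation.

Config files are flat key/value YAML mirroring the CLI flags 1:1.  Unknown
keys are an error (never silently ignored); flags take precedence over file
values, which take precedence over documented defaults.  The fully resolved
configuration is echoed to the log for reproducibility.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .codesets import AlgorithmVersion, CodeCatalog, default_catalog, load_catalog
from .engine import DEFAULT_INDEX_DATE, AlgorithmConfig

logger = logging.getLogger(__name__)

_ALGO_KEYS = {
    "version", "index_date", "insulin_window_days", "glucose_threshold_mgdl",
    "hba1c_threshold_pct", "threshold_strict", "ratio_counting",
}
_OTHER_KEYS = {"catalog", "log_level"}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    algorithm: AlgorithmConfig
    catalog_path: str | None = None
    log_level: str = "INFO"

    def load_catalog(self) -> CodeCatalog:
        if self.catalog_path:
            return load_catalog(self.catalog_path)
        return default_catalog()


def _parse_version(value) -> AlgorithmVersion:
    try:
        return AlgorithmVersion(str(value))
    except ValueError:
        allowed = [v.value for v in AlgorithmVersion]
        raise ConfigError(f"invalid version {value!r}; allowed: {allowed}") from None


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        raise ConfigError(f"invalid index_date {value!r}; expected YYYY-MM-DD") from None


def build_run_config(
    config_path: str | Path | None = None, **overrides
) -> RunConfig:
    """Merge defaults, an optional config file and flag overrides.

    ``overrides`` values of None mean "not given on the command line".
    """
    file_values: dict = {}
    if config_path is not None:
        with open(config_path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a key/value mapping")
        unknown = set(raw) - _ALGO_KEYS - _OTHER_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        file_values = raw

    merged = dict(file_values)
    for key, value in overrides.items():
        if value is not None:
            if key not in _ALGO_KEYS | _OTHER_KEYS:
                raise ConfigError(f"unknown override {key!r}")
            merged[key] = value

    algo_kwargs = {}
    if "version" in merged:
        algo_kwargs["version"] = _parse_version(merged["version"])
    if "index_date" in merged:
        algo_kwargs["index_date"] = _parse_date(merged["index_date"])
    for key in ("insulin_window_days",):
        if key in merged:
            algo_kwargs[key] = int(merged[key])
    for key in ("glucose_threshold_mgdl", "hba1c_threshold_pct"):
        if key in merged:
            algo_kwargs[key] = float(merged[key])
    if "threshold_strict" in merged:
        algo_kwargs["threshold_strict"] = bool(merged["threshold_strict"])
    if "ratio_counting" in merged:
        rc = str(merged["ratio_counting"])
        if rc not in ("events", "encounters"):
            raise ConfigError(
                f"invalid ratio_counting {rc!r}; allowed: ['events', 'encounters']"
            )
        algo_kwargs["ratio_counting"] = rc
    try:
        algorithm = AlgorithmConfig(**algo_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    run = RunConfig(
        algorithm=algorithm,
        catalog_path=merged.get("catalog"),
        log_level=str(merged.get("log_level", "INFO")).upper(),
    )
    logger.info("resolved configuration: %s", run)
    return run


def default_run_config() -> RunConfig:
    """Documented defaults: v3, index 2016-12-31, 90-day window, strict thresholds."""
    return RunConfig(algorithm=AlgorithmConfig(), catalog_path=None)


__all__ = ["RunConfig", "ConfigError", "build_run_config", "default_run_config", "DEFAULT_INDEX_DATE"]
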