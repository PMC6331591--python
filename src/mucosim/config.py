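"""Run configuration: strict YAML parsing for the CLI pipeline.

A config file has up to five sections plus scalar keys::

    seed: 1
    log_level: INFO
    transport:      {C0: 1.0e7, Dg: 6.0e-6, ...}
    discretization: {dx_gel: 5.0, dt: 0.01, t_end: 96.0, output_interval: 0.1}
    grid:           {he_levels: [...], kD_levels: [...], kB_levels: [...]}
    nn:             {n_hidden: 10, n_restarts: 10, ...}

Every key is optional (defaults are the standard values); unknown keys are
rejected, and all problems are reported together.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources

import yaml

from .cohort import VariationGrid, build_variation_grid
from .neuralnet import MLPConfig
from .params import (Discretization, ParamError, TransportParams,
                     default_discretization, make_output_times)

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_text"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


class ConfigError(ValueError):
    """Raised with a message naming every invalid or unknown key."""


@dataclass
class RunConfig:
    transport: TransportParams
    disc: Discretization
    grid: VariationGrid
    nn: MLPConfig
    seed: int = 0
    log_level: str = "INFO"
    split_fractions: tuple = (0.8, 0.2)
    n_test_cases: int = 40
    raw: dict = field(default_factory=dict)

    @property
    def sha256(self) -> str:
        """Stable short digest of the fully-resolved configuration."""
        payload = {
            "transport": self.transport.to_dict(),
            "disc": self.disc.to_dict(),
            "grid": {"he_levels": self.grid.he_levels,
                     "kD_levels": self.grid.kD_levels,
                     "kB_levels": self.grid.kB_levels},
            "nn": {f.name: getattr(self.nn, f.name)
                   for f in fields(self.nn)},
            "seed": self.seed,
            "split_fractions": list(self.split_fractions),
            "n_test_cases": self.n_test_cases,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _check_unknown(section: str, given: dict, allowed, errors: list) -> None:
    unknown = sorted(set(given) - set(allowed))
    for key in unknown:
        errors.append(f"{section}: unknown key '{key}'")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration (or the built-in defaults).

    All validation failures are collected and raised together in a single
    :class:`ConfigError` naming each offending key.
    """
    if path is None:
        data = yaml.safe_load(default_config_text())
    else:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    data = data or {}
    if overrides:
        data.update(overrides)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    errors: list[str] = []
    _check_unknown("config", data,
                   ("seed", "log_level", "split_fractions", "n_test_cases",
                    "transport", "discretization", "grid", "nn"), errors)

    transport = _build_section(
        "transport", data.get("transport") or {},
        TransportParams.from_dict, errors)
    disc = _build_disc(data.get("discretization") or {}, errors)
    grid = _build_section(
        "grid", data.get("grid") or {}, build_variation_grid, errors)
    nn = _build_nn(data.get("nn") or {}, errors)

    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer (got {seed!r})")
    log_level = str(data.get("log_level", "INFO")).upper()
    if log_level not in _LOG_LEVELS:
        errors.append(f"log_level: must be one of {_LOG_LEVELS}")
    split = tuple(data.get("split_fractions", (0.8, 0.2)))
    if len(split) != 2:
        errors.append("split_fractions: must be a pair (train, test)")
    n_test = data.get("n_test_cases", 40)
    if not isinstance(n_test, int) or n_test < 0:
        errors.append(f"n_test_cases: must be a non-negative integer "
                      f"(got {n_test!r})")

    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return RunConfig(transport=transport, disc=disc, grid=grid, nn=nn,
                     seed=seed, log_level=log_level,
                     split_fractions=split, n_test_cases=n_test, raw=data)


def _build_section(name, section, builder, errors):
    if not isinstance(section, dict):
        errors.append(f"{name}: must be a mapping")
        return None
    try:
        return builder(section)
    except (ParamError, TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def _build_disc(section, errors):
    if not isinstance(section, dict):
        errors.append("discretization: must be a mapping")
        return None
    allowed = ("dx_gel", "dx_epi", "dx_stroma", "dt", "t_end",
               "output_interval")
    _check_unknown("discretization", section, allowed, errors)
    kwargs = {k: section[k] for k in allowed[:-1] if k in section}
    try:
        interval = section.get("output_interval", 0.1)
        t_end = kwargs.get("t_end", 96.0)
        kwargs["output_times"] = make_output_times(t_end, interval)
        return Discretization(**kwargs)
    except (ParamError, TypeError, ValueError) as exc:
        errors.append(f"discretization: {exc}")
        return None


def _build_nn(section, errors):
    if not isinstance(section, dict):
        errors.append("nn: must be a mapping")
        return None
    allowed = [f.name for f in fields(MLPConfig)]
    _check_unknown("nn", section, allowed, errors)
    try:
        return MLPConfig(**{k: v for k, v in section.items() if k in allowed})
    except (TypeError, ValueError) as exc:
        errors.append(f"nn: {exc}")
        return None


def default_config_text() -> str:
    """The shipped default configuration file, as text."""
    return (resources.files("mucosim.data") / "default_config.yaml").read_text()
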