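"""Run configuration: flat ``key = value`` files with dotted sections.

Every tunable of the simulator lives under one of the sections ``model.*``,
``lattice.*``, ``inoculum.*``, ``schedule.*``, ``sweep.*``, ``output.*``
plus the top-level ``seed``.  Unknown keys are rejected (typo safety);
missing keys fall back to documented defaults.  A resolved config
round-trips losslessly through :func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .experiments import InoculumSpec
from .lattice import ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Malformed configuration file or invalid key/value."""


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "yes", "1", "on"):
        return True
    if t in ("false", "no", "0", "off"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_float_list(text: str) -> list[float]:
    return [float(tok) for tok in text.replace(",", " ").split()]


def _opt_int(text: str) -> int | None:
    t = text.strip().lower()
    return None if t in ("none", "") else int(t)


# key -> (default, parser).  Defaults encode the canonical protocol:
# 51x51 periodic lattice, radius-5 diluted inoculum, 200 iterations.
DEFAULTS: dict[str, tuple[object, object]] = {
    "model.r_s": (0.1, float),
    "model.r_a": (0.1, float),
    "model.D_s": (0.01, float),
    "model.D_a": (0.01, float),
    "model.K_a": (0.08, float),
    "model.hill_n": (4.0, float),
    "model.alpha": (1.5, float),
    "model.beta": (1.5, float),
    "lattice.rows": (51, int),
    "lattice.cols": (51, int),
    "lattice.boundary": ("periodic", str),
    "inoculum.radius": (5.0, float),
    "inoculum.kind": ("mixed", str),
    "inoculum.s_max": (0.2, float),
    "inoculum.rho": (0.0, float),
    "schedule.n_iterations": (200, int),
    "schedule.record_every": (1, int),
    "schedule.snapshot_every": (50, _opt_int),
    "sweep.rho_values": ([0.1, 0.25, 0.5, 0.75, 1.0, 2.0], _parse_float_list),
    "sweep.replicates": (10, int),
    "sweep.resistant_factor": (0.9, float),
    "sweep.compare_resistant": (False, _parse_bool),
    "output.dir": ("colonycml_out", str),
    "output.format": ("tsv", str),
    "output.png": (False, _parse_bool),
    "seed": (1, int),
}


@dataclass
class RunConfig:
    """Resolved configuration for any CLI entry point."""

    values: dict[str, object] = field(
        default_factory=lambda: {k: v for k, (v, _) in DEFAULTS.items()}
    )

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    def override(self, key: str, value: object) -> None:
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key: {key!r}")
        self.values[key] = value

    def model_params(self) -> ModelParams:
        v = self.values
        return ModelParams(
            r_s=v["model.r_s"], r_a=v["model.r_a"],
            D_s=v["model.D_s"], D_a=v["model.D_a"],
            K_a=v["model.K_a"], hill_n=v["model.hill_n"],
            alpha=v["model.alpha"], beta=v["model.beta"],
        )

    def lattice_shape(self) -> tuple[int, int]:
        return (int(self.values["lattice.rows"]), int(self.values["lattice.cols"]))

    def inoculum_spec(self, seed: int | None = None) -> InoculumSpec:
        v = self.values
        return InoculumSpec(
            radius=v["inoculum.radius"],
            kind=v["inoculum.kind"],
            s_max=v["inoculum.s_max"],
            rho=v["inoculum.rho"],
            seed=v["seed"] if seed is None else seed,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse a flat key=value config file; ``None`` gives pure defaults.

    Lines are ``key = value``; blank lines and ``#`` comments are ignored.
    Unknown keys and unparseable values raise :class:`ConfigError` naming
    the offending key.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        if key not in DEFAULTS:
            raise ConfigError(f"line {lineno}: unknown config key: {key!r}")
        parser = DEFAULTS[key][1]
        try:
            cfg.values[key] = parser(value)
        except (ValueError, TypeError) as exc:
            raise ConfigError(
                f"line {lineno}: bad value for {key!r}: {exc}"
            ) from exc
    return cfg


def _format_value(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, list):
        return ", ".join(repr(float(v)) for v in value)
    if value is None:
        return "none"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration, one key per line."""
    lines = [f"{k} = {_format_value(cfg.values[k])}" for k in DEFAULTS]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
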