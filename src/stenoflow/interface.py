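"""Configuration, parameter sweeps and tabular output.

Configuration is a flat ``key = value`` file (``#`` comments allowed); the
defaults are the canonical converging-artery configuration used throughout
the model study::

    phi = -0.05, eps = 0.1, gamma = 0.5, Gamma = 0.5, rc = 0.1,
    N = 0.75, m = 50, Q = 1, u = 0.01

``phi`` and ``zeta`` are alternative ways to state the taper; supplying both
is rejected as overdetermined.  Sweeps take the cartesian product of one or
more named parameter axes and record impedance, wall shear stress at the
extremum stations, and/or the extrema report, one row per combination;
per-row failures are recorded in an ``error`` column rather than aborting
the sweep.  Re-running a sweep with the same configuration byte-reproduces
the CSV: there is no hidden randomness anywhere in the model.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import GeometryParams, stenosis_extrema
from .hemodynamics import FlowConditions, impedance
from .station_solver import FluidParams

__all__ = [
    "DEFAULTS",
    "ConfigError",
    "ModelConfig",
    "SweepSpec",
    "load_config",
    "config_from_mapping",
    "run_sweep",
    "write_table",
]

logger = logging.getLogger("stenoflow")

DEFAULTS: dict[str, float] = {
    "phi": -0.05,
    "eps": 0.1,
    "gamma": 0.5,
    "Gamma": 0.5,
    "rc": 0.1,
    "N": 0.75,
    "m": 50.0,
    "Q": 1.0,
    "u": 0.01,
}

_GEOM_KEYS = ("zeta", "eps", "gamma", "Gamma", "rc")
_FLUID_KEYS = ("N", "m")
_FLOW_KEYS = ("Q", "u")
_ALL_KEYS = frozenset(("phi",) + _GEOM_KEYS + _FLUID_KEYS + _FLOW_KEYS)

#: outputs a sweep can record
SWEEP_OUTPUTS = ("impedance", "wss", "extrema")

#: CSV float formatting: 10 significant digits, reproducibility over prettiness
FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Unparseable, unknown or inconsistent configuration input."""


@dataclass(frozen=True)
class ModelConfig:
    """Full parameter set: geometry + fluid + flow conditions."""

    geom: GeometryParams
    fluid: FluidParams
    flow: FlowConditions

    def as_dict(self) -> dict[str, float]:
        return {
            "zeta": self.geom.zeta, "eps": self.geom.eps,
            "gamma": self.geom.gamma, "Gamma": self.geom.Gamma,
            "rc": self.geom.rc, "N": self.fluid.N, "m": self.fluid.m,
            "Q": self.flow.Q, "u": self.flow.u,
        }

    def replace(self, **changes) -> "ModelConfig":
        merged = self.as_dict()
        if "phi" in changes:
            if "zeta" in changes:
                raise ConfigError("phi and zeta are alternatives; give one")
            merged["zeta"] = math.tan(float(changes.pop("phi")))
        unknown = set(changes) - set(merged)
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        merged.update({k: float(v) for k, v in changes.items()})
        return config_from_mapping(merged)


def config_from_mapping(mapping: dict) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a flat mapping.

    Missing keys take the canonical defaults; unknown keys and a
    ``phi``/``zeta`` conflict are rejected before any computation.
    """
    unknown = set(mapping) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
    if "phi" in mapping and "zeta" in mapping:
        raise ConfigError(
            "phi and zeta both given: the taper is overdetermined"
        )
    values = dict(mapping)
    if "zeta" not in values:
        phi = float(values.pop("phi", DEFAULTS["phi"]))
        values["zeta"] = math.tan(phi)
    else:
        values.pop("phi", None)
        values["zeta"] = float(values["zeta"])
    for key, default in DEFAULTS.items():
        if key == "phi":
            continue
        values.setdefault(key, default)

    def _f(key: str) -> float:
        try:
            return float(values[key])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"parameter {key!r}: not a number "
                              f"({values[key]!r})") from exc

    try:
        geom = GeometryParams(zeta=_f("zeta"), eps=_f("eps"),
                              gamma=_f("gamma"), Gamma=_f("Gamma"),
                              rc=_f("rc"))
        fluid = FluidParams(N=_f("N"), m=_f("m"))
        flow = FlowConditions(Q=_f("Q"), u=_f("u"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    cfg = ModelConfig(geom=geom, fluid=fluid, flow=flow)
    logger.info("resolved configuration: %s", cfg.as_dict())
    return cfg


def load_config(path=None, overrides: dict | None = None) -> ModelConfig:
    """Read a flat ``key = value`` config file (``key: value`` also accepted).

    ``path = None`` or an empty file yields the canonical defaults.
    ``overrides`` are applied on top of the file, with the same validation.
    """
    mapping: dict[str, str] = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    break
            else:
                raise ConfigError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}"
                )
            key = key.strip()
            if key in mapping:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            mapping[key] = val.strip()
    if overrides:
        for key, val in overrides.items():
            mapping[key] = val
    return config_from_mapping(mapping)


@dataclass(frozen=True)
class SweepSpec:
    """A cartesian parameter sweep around a base configuration.

    ``axes`` maps parameter names (any config key, including ``phi``) to the
    values each axis takes; the product of all axes is evaluated in
    deterministic axis order.  ``outputs`` selects which quantity groups to
    record.  The product size is capped to keep runs desk-scale.
    """

    base: ModelConfig
    axes: dict[str, list] = field(default_factory=dict)
    outputs: tuple[str, ...] = ("impedance",)
    max_rows: int = 100_000

    def __post_init__(self) -> None:
        for name in self.axes:
            if name not in _ALL_KEYS:
                raise ConfigError(f"unknown sweep axis {name!r}")
        for out in self.outputs:
            if out not in SWEEP_OUTPUTS:
                raise ConfigError(
                    f"unknown output {out!r}; choose from {SWEEP_OUTPUTS}"
                )
        n = 1
        for vals in self.axes.values():
            n *= max(len(vals), 1)
        if n > self.max_rows:
            raise ConfigError(
                f"sweep size {n} exceeds the cap of {self.max_rows} rows"
            )


def _evaluate_row(cfg: ModelConfig, outputs: tuple[str, ...]) -> dict:
    row: dict[str, float] = {}
    if "extrema" in outputs or "wss" in outputs:
        rep = stenosis_extrema(cfg.geom)
        if "extrema" in outputs:
            row.update(rep.as_dict())
    if "impedance" in outputs or "wss" in outputs:
        res = impedance(cfg.geom, cfg.fluid, cfg.flow)
        if "impedance" in outputs:
            row["lam"] = res.lam
            row["dp"] = res.dp
        if "wss" in outputs:
            for name in ("zL", "zC", "zR"):
                row[f"tw_{name}"] = res.tw_at[name]
    return row


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; one row per parameter combination.

    Failures (e.g. a catheter radius that closes the annulus somewhere along
    the sweep) are recorded per row in the ``error`` column and leave the
    output columns NaN.

    Raises
    ------
    RuntimeError
        If every row failed.
    """
    names = list(spec.axes)
    grids = [spec.axes[n] for n in names]
    rows: list[dict] = []
    for combo in itertools.product(*grids) if names else [()]:
        point = dict(zip(names, combo))
        row: dict = {k: float(v) for k, v in point.items()}
        try:
            cfg = spec.base.replace(**point)
            row.update(_evaluate_row(cfg, spec.outputs))
            row["error"] = ""
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("sweep row %s failed: %s", point, row["error"])
        else:
            logger.info("sweep row %s done", point)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and (df["error"] != "").all():
        raise RuntimeError("every sweep row failed; first error: "
                           f"{df['error'].iloc[0]}")
    return df


def write_table(df: pd.DataFrame, path, fmt: str = "csv",
                metadata: dict | None = None) -> None:
    """Write a result table plus a JSON run-metadata sidecar.

    CSV floats use 10 significant digits.  The sidecar (``<path>.meta.json``)
    records the parameters, tolerances and version needed to re-run the
    computation.
    """
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", double_precision=10,
                                   indent=2))
    else:
        raise ConfigError(f"unknown format {fmt!r}; choose csv or json")
    sidecar = {
        "stenoflow_version": __version__,
        "quadrature_tol": 1e-9,
        "boundary_residual_tol": 1e-10,
        "numpy_version": np.__version__,
        "format": fmt,
    }
    if metadata:
        sidecar.update(metadata)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2,
                                                         sort_keys=True))
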