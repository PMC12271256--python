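"""Structured run configuration (YAML, schema version 1, strictly validated).

A config names either a registry scenario or an inline parameter block
(dimensional or dimensionless), plus optional grid/solver/output overrides.
Unknown keys anywhere are rejected rather than ignored so that a typo cannot
silently change a run.

Schema::

    schema: 1                # optional, must be 1 if present
    scenario: fig2_L1=0.5    # XOR with `parameters`
    parameters:
      dimensionless: {D_n: 0.47, Lambda1: 0.5, ...}   # or
      dimensional:   {D_n: ..., D_g: ..., alpha: ..., ...}
      cell_diffusion: degenerate | linear
    scale: scaled | full
    grid:    {dx: 0.5, x_max: 100, y_half_width: 25}
    solver:  {safety: 0.2, front_threshold: 0.05}
    t_end: 150
    snapshot_interval: 5
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .model import DimensionalParameters, DimensionlessParameters, nondimensionalize
from .scenarios import Scenario, get_scenario

__all__ = ["ConfigError", "RunConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid or unparsable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """A validated configuration, resolvable to a runnable Scenario."""

    scenario_name: str | None
    inline_params: DimensionlessParameters | None
    cell_diffusion: str
    scale: str
    grid_overrides: dict
    solver_overrides: dict
    t_end: float | None
    snapshot_interval: float | None
    space_scale: float | None = None  # set when input was dimensional
    time_scale: float | None = None

    def resolve(self) -> Scenario:
        """Build the Scenario this config describes, defaults filled in."""
        if self.scenario_name is not None:
            sc = get_scenario(self.scenario_name, scale=self.scale)
            if self.inline_params is not None:  # pragma: no cover - guarded earlier
                raise ConfigError("scenario and inline parameters are exclusive")
        else:
            sc = get_scenario("fig2", scale=self.scale).replace(
                name="inline", description="inline parameter block",
                params=self.inline_params, sweep_param=None, sweep_values=None,
            )
        sc = sc.replace(cell_diffusion=self.cell_diffusion or sc.cell_diffusion)
        changes = {}
        if self.t_end is not None:
            changes["t_end"] = self.t_end
        if self.snapshot_interval is not None:
            changes["snapshot_interval"] = self.snapshot_interval
        for key in ("dx", "x_max", "y_half_width"):
            if key in self.grid_overrides:
                changes[key] = self.grid_overrides[key]
        return sc.replace(**changes) if changes else sc


def _require_mapping(obj, where: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{where} must be a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


_GRID_KEYS = {"dx", "x_max", "y_half_width"}
_SOLVER_KEYS = {"safety", "front_threshold"}
_TOP_KEYS = {"schema", "scenario", "parameters", "scale", "grid", "solver", "t_end", "snapshot_interval"}
_PARAM_BLOCK_KEYS = {"dimensionless", "dimensional", "cell_diffusion"}


def parse_config(data: dict) -> RunConfig:
    """Validate an already-parsed mapping into a RunConfig."""
    data = _require_mapping(data, "config")
    _check_keys(data, _TOP_KEYS, "config")
    if data.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {data['schema']!r} (expected {SCHEMA_VERSION})")

    scenario = data.get("scenario")
    params_block = _require_mapping(data.get("parameters"), "parameters")
    if scenario is not None and params_block:
        raise ConfigError("config must name either 'scenario' or 'parameters', not both")
    if scenario is None and not params_block:
        raise ConfigError("config must name either 'scenario' or 'parameters'")

    inline = None
    cell_diffusion = ""
    space_scale = time_scale = None
    if params_block:
        _check_keys(params_block, _PARAM_BLOCK_KEYS, "parameters")
        cell_diffusion = params_block.get("cell_diffusion", "")
        if cell_diffusion not in ("", "degenerate", "linear"):
            raise ConfigError(f"cell_diffusion must be 'degenerate' or 'linear', got {cell_diffusion!r}")
        has_dimless = "dimensionless" in params_block
        has_dim = "dimensional" in params_block
        if has_dimless == has_dim:
            raise ConfigError("parameters block needs exactly one of 'dimensionless'/'dimensional'")
        try:
            if has_dimless:
                inline = DimensionlessParameters(**_require_mapping(
                    params_block["dimensionless"], "parameters.dimensionless"))
            else:
                nd = nondimensionalize(DimensionalParameters(**_require_mapping(
                    params_block["dimensional"], "parameters.dimensional")))
                inline, space_scale, time_scale = nd.params, nd.space_scale, nd.time_scale
        except TypeError as err:
            raise ConfigError(f"invalid parameter block: {err}") from None
        except ValueError as err:
            raise ConfigError(str(err)) from None

    scale = data.get("scale", "scaled")
    if scale not in ("scaled", "full"):
        raise ConfigError(f"scale must be 'scaled' or 'full', got {scale!r}")

    grid = _require_mapping(data.get("grid"), "grid")
    _check_keys(grid, _GRID_KEYS, "grid")
    solver = _require_mapping(data.get("solver"), "solver")
    _check_keys(solver, _SOLVER_KEYS, "solver")
    for key, rng in (("safety", (0.0, 1.0)), ("front_threshold", (0.0, 1.0))):
        if key in solver and not (rng[0] < float(solver[key]) <= rng[1]):
            raise ConfigError(f"solver.{key} must lie in ({rng[0]}, {rng[1]}]")
    for key in _GRID_KEYS & set(grid):
        if float(grid[key]) <= 0:
            raise ConfigError(f"grid.{key} must be positive")

    t_end = data.get("t_end")
    snap = data.get("snapshot_interval")
    if t_end is not None and float(t_end) <= 0:
        raise ConfigError("t_end must be positive")
    if snap is not None and float(snap) <= 0:
        raise ConfigError("snapshot_interval must be positive")

    return RunConfig(
        scenario_name=scenario,
        inline_params=inline,
        cell_diffusion=cell_diffusion,
        scale=scale,
        grid_overrides={k: float(v) for k, v in grid.items()},
        solver_overrides={k: float(v) for k, v in solver.items()},
        t_end=None if t_end is None else float(t_end),
        snapshot_interval=None if snap is None else float(snap),
        space_scale=space_scale,
        time_scale=time_scale,
    )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as err:
        raise ConfigError(f"could not parse {path}: {err}") from None
    except OSError as err:
        raise ConfigError(f"could not read {path}: {err}") from None
    return parse_config(data if data is not None else {})
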