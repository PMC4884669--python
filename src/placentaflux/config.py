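"""Structured-text configuration: loading, validation, result writing and
randomized test fixtures.

A run configuration is a YAML file mirroring the model's parameter blocks
(``geometry``, ``transporters``, ``concentrations``, ``inputs``,
``scenario``) plus optional ``sweep``, ``fit`` and ``pku`` sections.  All
quantities use the package's internal units (μmol l⁻¹, μmol min⁻¹, ml,
min; flows in ml min⁻¹ g⁻¹).  An empty file is a valid configuration and
yields the packaged physiological reference.  Unknown keys are rejected
with a diagnostic naming the nearest valid key; all violations in a file
are reported at once.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .core import (
    COMPARTMENTS,
    GROUPS,
    BoundaryInputs,
    Geometry,
    SystemState,
    TransporterParams,
    reference_parameters,
)
from .model import TRANSPORTERS, PlacentaModel, ScenarioSpec

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_results",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

_GEOMETRY_KEYS = (
    "total_volume",
    "frac_maternal",
    "frac_syncytio",
    "frac_fetal",
    "flow_maternal",
    "flow_fetal",
)
_TRANSPORTER_KEYS = (
    "V_ac", "V_ex_mvm", "V_ex_bm", "V_fa",
    "K_ac", "K_Na", "K_ex", "K_fa",
    "beta", "delta_psi", "Na_maternal", "Na_syncytio",
    "z", "F_const", "R_const", "T_abs",
)
_SCENARIO_KEYS = (
    "name",
    "active_transporters",
    "clamped_compartments",
    "flow_maternal_enabled",
    "flow_fetal_enabled",
    "activity_multipliers",
)
_TOP_KEYS = (
    "geometry", "transporters", "concentrations", "inputs", "scenario",
    "sweep", "fit", "pku", "output_dir", "seed",
)
_SCENARIO_NAMES = ("full", "mvm_only", "bm_only")


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]) -> None:
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration with defaults filled in.

    ``seed`` only feeds the randomized property-test fixture generator;
    the model itself is deterministic.
    """

    geometry: Geometry
    params: TransporterParams
    inputs: BoundaryInputs
    initial: SystemState
    scenario: ScenarioSpec
    sweep: dict[str, Any] = field(default_factory=dict)
    fit: dict[str, Any] = field(default_factory=dict)
    pku: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0

    def build_model(self) -> PlacentaModel:
        return PlacentaModel(
            geometry=self.geometry,
            params=self.params,
            inputs=self.inputs,
            initial=self.initial,
            scenario=self.scenario,
        )


def _suggest(key: str, valid: tuple[str, ...]) -> str:
    close = difflib.get_close_matches(key, valid, n=1)
    hint = f" (did you mean {close[0]!r}?)" if close else ""
    return f"unknown key {key!r}{hint}; valid keys: {', '.join(valid)}"


def _check_keys(section: Mapping, valid: tuple[str, ...], where: str, errors: list[str]) -> None:
    for key in section:
        if key not in valid:
            errors.append(f"{where}: " + _suggest(str(key), valid))


def _conc_block(
    raw: Mapping, names: tuple[str, ...], where: str, errors: list[str]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    _check_keys(raw, names, where, errors)
    for comp, per_group in raw.items():
        if comp not in names:
            continue
        if not isinstance(per_group, Mapping):
            errors.append(f"{where}.{comp}: expected a mapping of group -> concentration")
            continue
        _check_keys(per_group, GROUPS, f"{where}.{comp}", errors)
        block = {}
        for g, v in per_group.items():
            if g not in GROUPS:
                continue
            if not isinstance(v, (int, float)) or v < 0:
                errors.append(f"{where}.{comp}.{g}: must be a non-negative number")
            else:
                block[g] = float(v)
        out[comp] = block
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``path=None`` (or an empty file) gives the pure reference
    configuration.  ``overrides`` is an optional mapping merged on top of
    the file content (used by CLI flags).  Raises :class:`ConfigError`
    listing *all* violations at once.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError([f"{path}: top level must be a mapping"])
        raw = loaded
    if overrides:
        raw = _deep_merge(raw, dict(overrides))

    errors: list[str] = []
    _check_keys(raw, _TOP_KEYS, "config", errors)

    geometry_ref, params_ref, inputs_ref, initial_ref = reference_parameters()

    geo_raw = raw.get("geometry", {}) or {}
    _check_keys(geo_raw, _GEOMETRY_KEYS, "geometry", errors)
    try:
        geometry = replace(
            geometry_ref, **{k: float(v) for k, v in geo_raw.items() if k in _GEOMETRY_KEYS}
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"geometry: {exc}")
        geometry = geometry_ref

    par_raw = raw.get("transporters", {}) or {}
    _check_keys(par_raw, _TRANSPORTER_KEYS, "transporters", errors)
    try:
        params = replace(
            params_ref, **{k: float(v) for k, v in par_raw.items() if k in _TRANSPORTER_KEYS}
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"transporters: {exc}")
        params = params_ref

    conc_raw = raw.get("concentrations", {}) or {}
    conc = _conc_block(conc_raw, COMPARTMENTS, "concentrations", errors)
    initial_arr = initial_ref.conc.copy()
    for comp, per_group in conc.items():
        j = COMPARTMENTS.index(comp)
        for g, v in per_group.items():
            initial_arr[GROUPS.index(g), j] = v
    try:
        initial = SystemState(initial_arr)
    except ValueError as exc:
        errors.append(f"concentrations: {exc}")
        initial = initial_ref

    in_raw = raw.get("inputs", {}) or {}
    in_blocks = _conc_block(in_raw, ("maternal", "fetal"), "inputs", errors)
    in_m = inputs_ref.in_maternal.copy()
    in_f = inputs_ref.in_fetal.copy()
    for g, v in in_blocks.get("maternal", {}).items():
        in_m[GROUPS.index(g)] = v
    for g, v in in_blocks.get("fetal", {}).items():
        in_f[GROUPS.index(g)] = v
    try:
        inputs = BoundaryInputs(in_m, in_f)
    except ValueError as exc:
        errors.append(f"inputs: {exc}")
        inputs = inputs_ref

    sc_raw = raw.get("scenario", {}) or {}
    _check_keys(sc_raw, _SCENARIO_KEYS, "scenario", errors)
    scenario = _build_scenario(sc_raw, errors)

    for section in ("sweep", "fit", "pku"):
        val = raw.get(section, {}) or {}
        if not isinstance(val, Mapping):
            errors.append(f"{section}: expected a mapping")
            raw[section] = {}

    if errors:
        raise ConfigError(errors)

    return RunConfig(
        geometry=geometry,
        params=params,
        inputs=inputs,
        initial=initial,
        scenario=scenario,
        sweep=dict(raw.get("sweep", {}) or {}),
        fit=dict(raw.get("fit", {}) or {}),
        pku=dict(raw.get("pku", {}) or {}),
        output_dir=str(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )


def _build_scenario(sc_raw: Mapping, errors: list[str]) -> ScenarioSpec:
    name = sc_raw.get("name", "full")
    if name not in _SCENARIO_NAMES:
        errors.append("scenario.name: " + _suggest(str(name), _SCENARIO_NAMES))
        name = "full"
    base: ScenarioSpec = getattr(ScenarioSpec, name)()
    kw: dict[str, Any] = {}
    if "active_transporters" in sc_raw:
        kw["active_transporters"] = frozenset(sc_raw["active_transporters"])
    if "clamped_compartments" in sc_raw:
        kw["clamped_compartments"] = frozenset(sc_raw["clamped_compartments"])
    for k in ("flow_maternal_enabled", "flow_fetal_enabled"):
        if k in sc_raw:
            kw[k] = bool(sc_raw[k])
    if "activity_multipliers" in sc_raw:
        mult = sc_raw["activity_multipliers"]
        if not isinstance(mult, Mapping):
            errors.append("scenario.activity_multipliers: expected a mapping")
        else:
            _check_keys(mult, TRANSPORTERS, "scenario.activity_multipliers", errors)
            kw["activity_multipliers"] = {
                k: float(v) for k, v in mult.items() if k in TRANSPORTERS
            }
    try:
        return replace(base, **kw)
    except ValueError as exc:
        errors.append(f"scenario: {exc}")
        return base


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _deep_merge(dict(out[k]), dict(v))
        else:
            out[k] = v
    return out


def dump_config(config: RunConfig) -> str:
    """Serialise a configuration back to YAML (round-trips exactly)."""
    doc = {
        "geometry": {k: getattr(config.geometry, k) for k in _GEOMETRY_KEYS},
        "transporters": {k: getattr(config.params, k) for k in _TRANSPORTER_KEYS},
        "concentrations": config.initial.to_dict(),
        "inputs": {
            "maternal": dict(zip(GROUPS, map(float, config.inputs.in_maternal))),
            "fetal": dict(zip(GROUPS, map(float, config.inputs.in_fetal))),
        },
        "scenario": {
            "name": config.scenario.name,
            "active_transporters": sorted(config.scenario.active_transporters),
            "clamped_compartments": sorted(config.scenario.clamped_compartments),
            "flow_maternal_enabled": config.scenario.flow_maternal_enabled,
            "flow_fetal_enabled": config.scenario.flow_fetal_enabled,
            "activity_multipliers": dict(config.scenario.activity_multipliers),
        },
        "sweep": config.sweep,
        "fit": config.fit,
        "pku": config.pku,
        "output_dir": config.output_dir,
        "seed": config.seed,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def write_results(
    result,
    directory: str | Path,
    config: RunConfig | None = None,
    extra_tables: Mapping[str, Any] | None = None,
) -> list[Path]:
    """Write a run's outputs as diff-able comma-separated tables + metadata.

    ``result`` may be a :class:`~placentaflux.model.SimulationResult`, a
    :class:`~placentaflux.fitting.FitResult` or a plain ``DataFrame`` (a
    sweep table).  Returns the list of files written.
    """
    from .fitting import FitResult
    from .model import SimulationResult

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_frame(frame, name: str) -> None:
        p = directory / name
        frame.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    metadata: dict[str, Any] = {"package": "placentaflux"}
    if isinstance(result, SimulationResult):
        if result.trajectory.shape[0] > 1:
            _write_frame(result.trajectory_frame(), "trajectory.csv")
        _write_frame(result.summary_frame(), "steady_state.csv")
        metadata.update(
            scenario=result.scenario.name,
            converged=bool(result.converged),
            va_difference_umol_per_l=result.va_difference,
            net_transfer_umol_per_min=result.net_transfer,
        )
    elif isinstance(result, FitResult):
        _write_frame(result.to_frame(), "fit_predictions.csv")
        _write_frame(result.trace_frame(), "fit_trace.csv")
        (directory / "fit_report.txt").write_text(result.summary() + "\n")
        written.append(directory / "fit_report.txt")
        metadata.update(
            fitted_V_umol_per_min=result.fitted_V,
            multipliers=result.multipliers,
            objective=result.objective,
            converged=result.converged,
            n_evaluations=result.n_evaluations,
        )
    else:
        _write_frame(result, "sweep.csv")
        metadata.update(rows=int(len(result)))

    for name, frame in (extra_tables or {}).items():
        _write_frame(frame, f"{name}.csv")

    if config is not None:
        (directory / "run_config.yaml").write_text(dump_config(config))
        written.append(directory / "run_config.yaml")
        metadata["seed"] = config.seed

    meta_path = directory / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=float))
    written.append(meta_path)
    logger.info("wrote %d files to %s", len(written), directory)
    return written


def generate_fixture(
    seed: int,
    conc_range: tuple[float, float] = (0.1, 10.0),
    rate_range: tuple[float, float] = (0.1, 10.0),
) -> dict[str, Any]:
    """Reproducible randomized parameter/state set for property tests.

    Concentrations are drawn per group per compartment within
    ``conc_range`` × their physiological values; kinetic V and K constants
    within ``rate_range`` × their reference values; the membrane potential
    uniformly in ±42 mV and β in [0, 1].  Same seed → identical fixture,
    and every draw satisfies the domain-type invariants by construction.
    """
    lo, hi = conc_range
    rlo, rhi = rate_range
    if not (0 < lo <= hi and 0 < rlo <= rhi):
        raise ValueError("ranges must be positive with low ≤ high")
    rng = np.random.default_rng(seed)
    _, params_ref, _, initial_ref = reference_parameters()

    conc = initial_ref.conc * rng.uniform(lo, hi, size=initial_ref.conc.shape)
    scale = {
        k: float(getattr(params_ref, k)) * float(rng.uniform(rlo, rhi))
        for k in ("V_ac", "V_ex_mvm", "V_ex_bm", "V_fa", "K_ac", "K_Na", "K_ex", "K_fa")
    }
    params = replace(
        params_ref,
        **scale,
        beta=float(rng.uniform(0.0, 1.0)),
        delta_psi=float(rng.uniform(-0.042, 0.042)),
        Na_maternal=params_ref.Na_maternal * float(rng.uniform(lo, hi)),
        Na_syncytio=params_ref.Na_syncytio * float(rng.uniform(lo, hi)),
    )
    return {"state": SystemState(conc), "params": params, "seed": int(seed)}
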