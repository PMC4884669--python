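"""In-silico sensitivity experiments on the full placental transfer model.

Each sweep varies one or two quantities around the physiological
reference, solves the full model to steady state at every grid point, and
reports per-group umbilical venous−arterial differences (μmol l⁻¹) and
net transfer rates (μmol min⁻¹) in a long-format table.  Grid points are
independent, so sweep output is deterministic and order-independent; every
default grid includes the factor 1 (reference) point.

Sweepable quantities:

* ``V_ac``, ``V_ex_mvm``, ``V_ex_bm``, ``V_fa`` — multiplicative factors
  on the carrier activities,
* ``F_m``, ``F_f`` — factors on maternal/fetal flow,
* ``maternal_conc_scale``, ``fetal_conc_scale`` — factors applied jointly
  to the initial and arterial input concentrations of one side,
* ``maternal_ExF_add`` — absolute μmol l⁻¹ added to maternal ExF
  (the phenylketonuria axis: excess phenylalanine, an ExF member).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GROUP_INDEX, GROUPS, SystemState
from .model import PlacentaModel, SteadyStateError

__all__ = [
    "SweepSpec",
    "default_grid",
    "run_sweep",
    "activity_sweep",
    "flow_sweep",
    "concentration_sweep",
    "pku_scenario",
]

logger = logging.getLogger(__name__)

_ACTIVITY_KEYS = {
    "V_ac": "accumulative_mvm",
    "V_ex_mvm": "exchanger_mvm",
    "V_ex_bm": "exchanger_bm",
    "V_fa": "facilitative_bm",
}
_VALID_PARAMETERS = tuple(_ACTIVITY_KEYS) + (
    "F_m",
    "F_f",
    "maternal_conc_scale",
    "fetal_conc_scale",
    "maternal_ExF_add",
)


def default_grid(n: int = 25, lo: float = 1e-2, hi: float = 1e2) -> np.ndarray:
    """Log-spaced multiplicative factors including the exact reference 1.0."""
    grid = np.geomspace(lo, hi, n)
    # snap the midpoint to exactly 1 so the reference point is bit-identical
    grid[np.argmin(np.abs(np.log(grid)))] = 1.0
    return grid


@dataclass(frozen=True)
class SweepSpec:
    """One- or two-axis sweep definition.

    ``varied_parameters`` lists one or two quantity names; ``grids`` one
    factor (or addition, for ``maternal_ExF_add``) array per axis.
    """

    varied_parameters: tuple[str, ...]
    grids: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.varied_parameters) <= 2:
            raise ValueError("sweep varies one or two parameters")
        for p in self.varied_parameters:
            if p not in _VALID_PARAMETERS:
                raise ValueError(
                    f"unknown sweep parameter {p!r}; valid: {_VALID_PARAMETERS}"
                )
        grids = self.grids or tuple(
            default_grid() for _ in self.varied_parameters
        )
        grids = tuple(np.asarray(g, dtype=float) for g in grids)
        if len(grids) != len(self.varied_parameters):
            raise ValueError("need one grid per varied parameter")
        for p, g in zip(self.varied_parameters, grids):
            if p == "maternal_ExF_add":
                if np.any(g < 0):
                    raise ValueError("concentration additions must be ≥ 0")
            elif np.any(g <= 0):
                raise ValueError("multiplicative factors must be > 0")
        object.__setattr__(self, "grids", grids)


def _apply_point(base: PlacentaModel, assignment: dict[str, float]) -> PlacentaModel:
    """Model at one grid point: reference model with factors applied."""
    params = base.params
    geometry = base.geometry
    inputs = base.inputs
    initial_conc = base.initial.conc.copy()
    multipliers = dict(base.scenario.activity_multipliers)

    for name, value in assignment.items():
        if name in _ACTIVITY_KEYS:
            key = _ACTIVITY_KEYS[name]
            multipliers[key] = multipliers.get(key, 1.0) * value
        elif name == "F_m":
            geometry = replace(geometry, flow_maternal=geometry.flow_maternal * value)
        elif name == "F_f":
            geometry = replace(geometry, flow_fetal=geometry.flow_fetal * value)
        elif name == "maternal_conc_scale":
            inputs = inputs.scaled(maternal=value)
            initial_conc[:, 0] *= value
        elif name == "fetal_conc_scale":
            inputs = inputs.scaled(fetal=value)
            initial_conc[:, 2] *= value
        elif name == "maternal_ExF_add":
            i = GROUP_INDEX["ExF"]
            in_m = inputs.in_maternal.copy()
            in_m[i] += value
            inputs = replace(inputs, in_maternal=in_m)
            initial_conc[i, 0] += value
        else:  # pragma: no cover
            raise ValueError(name)

    scenario = replace(base.scenario, activity_multipliers=multipliers)
    return base.with_(
        params=params,
        geometry=geometry,
        inputs=inputs,
        initial=SystemState(initial_conc),
        scenario=scenario,
    )


def run_sweep(spec: SweepSpec, base: PlacentaModel | None = None) -> pd.DataFrame:
    """Steady-state outcomes over the sweep grid, long format.

    One row per (grid point, group) with columns for each varied parameter,
    the group, the V−A difference, the net transfer rate and a convergence
    flag.  Non-convergent points are kept (NaN outcome) and logged.
    """
    base = base if base is not None else PlacentaModel()
    rows = []
    for values in itertools.product(*spec.grids):
        assignment = dict(zip(spec.varied_parameters, values))
        point = _apply_point(base, assignment)
        try:
            res = point.steady_state_result()
            ok = True
        except SteadyStateError as exc:
            logger.warning("no steady state at %s: %s", assignment, exc)
            res, ok = None, False
        for g in GROUPS:
            rows.append(
                {
                    **assignment,
                    "group": g,
                    "va_difference_umol_per_l": res.va_difference[g] if ok else np.nan,
                    "net_transfer_umol_per_min": res.net_transfer[g] if ok else np.nan,
                    "converged": ok,
                }
            )
        logger.debug("sweep point %s converged=%s", assignment, ok)
    return pd.DataFrame(rows)


def activity_sweep(
    spec: SweepSpec | str | Sequence[str],
    base: PlacentaModel | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sweep one or two carrier activities around the reference.

    ``spec`` may be a full :class:`SweepSpec`, a single activity name
    (``"V_ac"``, ``"V_ex_mvm"``, ``"V_ex_bm"``, ``"V_fa"``) or a pair.
    """
    if not isinstance(spec, SweepSpec):
        names = (spec,) if isinstance(spec, str) else tuple(spec)
        for n in names:
            if n not in _ACTIVITY_KEYS:
                raise ValueError(f"{n!r} is not a carrier activity")
        grids = (grid,) * len(names) if grid is not None else ()
        spec = SweepSpec(names, grids)
    return run_sweep(spec, base)


def flow_sweep(
    f_m_factors: np.ndarray | None = None,
    f_f_factors: np.ndarray | None = None,
    base: PlacentaModel | None = None,
) -> pd.DataFrame:
    """Sweep maternal and fetal flow factors simultaneously."""
    spec = SweepSpec(
        ("F_m", "F_f"),
        (
            np.asarray(f_m_factors if f_m_factors is not None else default_grid()),
            np.asarray(f_f_factors if f_f_factors is not None else default_grid()),
        ),
    )
    return run_sweep(spec, base)


def concentration_sweep(
    maternal_scales: np.ndarray | None = None,
    fetal_scales: np.ndarray | None = None,
    base: PlacentaModel | None = None,
) -> pd.DataFrame:
    """Scale all maternal and/or fetal amino acid levels (initial + input)
    by common factors and record steady-state transfer."""
    spec = SweepSpec(
        ("maternal_conc_scale", "fetal_conc_scale"),
        (
            np.asarray(maternal_scales if maternal_scales is not None else default_grid()),
            np.asarray(fetal_scales if fetal_scales is not None else default_grid()),
        ),
    )
    return run_sweep(spec, base)


def pku_scenario(
    maternal_phe_excess: np.ndarray | Sequence[float] | None = None,
    base: PlacentaModel | None = None,
) -> pd.DataFrame:
    """Maternal phenylketonuria: excess phenylalanine raises maternal ExF.

    ``maternal_phe_excess`` is the additional phenylalanine (μmol l⁻¹)
    added to the maternal ExF initial and input concentrations; the fetal
    side is left unchanged.  Normal maternal phenylalanine is ~39 μmol l⁻¹
    while classic untreated disease exceeds 1200 μmol l⁻¹.  Returns the
    steady-state transfer of every group across the excess range.
    """
    if maternal_phe_excess is None:
        maternal_phe_excess = np.linspace(0.0, 2400.0, 25)
    spec = SweepSpec(
        ("maternal_ExF_add",), (np.asarray(maternal_phe_excess, dtype=float),)
    )
    return run_sweep(spec, base)
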