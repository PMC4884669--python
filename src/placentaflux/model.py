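"""Three-compartment placental transfer model: ODE assembly, integration,
steady states.

The model couples a maternal intervillous-space compartment, the
syncytiotrophoblast cytosol and the fetal capillary compartment through
four lumped carriers — accumulative and exchange on the maternal-facing
microvillous membrane (MVM), exchange and facilitative on the fetal-facing
basal membrane (BM) — plus constant arterial in/outflow of the maternal and
fetal compartments.  Sodium is a clamped boundary condition (the Na⁺/K⁺
pump holds the transmembrane gradient), not a state variable.

The public surface follows the model/results convention: build a
:class:`PlacentaModel`, then call :meth:`~PlacentaModel.simulate`,
:meth:`~PlacentaModel.steady_state` or :meth:`~PlacentaModel.fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import (
    COMPARTMENTS,
    GROUP_INDEX,
    GROUPS,
    BoundaryInputs,
    Geometry,
    SystemState,
    TransporterParams,
    accumulative_substrates,
    facilitative_substrates,
    reference_parameters,
)
from .kinetics import MembraneSides, accumulative_flux, exchanger_flux, facilitative_flux

__all__ = ["ScenarioSpec", "SimulationResult", "SteadyStateError", "PlacentaModel"]

TRANSPORTERS = ("accumulative_mvm", "exchanger_mvm", "exchanger_bm", "facilitative_bm")

_AC_IDX = np.array([GROUP_INDEX[g] for g in accumulative_substrates()])
_FA_IDX = np.array([GROUP_INDEX[g] for g in facilitative_substrates()])

#: relative concentration change per minute below which the system is
#: considered stationary (spec'd once, used by integration and polish)
STEADY_RTOL = 1e-6
#: hard cap on integrated model time when hunting for a steady state, min
STEADY_T_CAP = 1e6


class SteadyStateError(RuntimeError):
    """Raised when no steady state is reached; carries the last state."""

    def __init__(self, message: str, last_state: SystemState | None = None) -> None:
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ScenarioSpec:
    """Which carriers, flows and clamps are in force during a run.

    Clamped compartments have their concentrations frozen (zero
    derivative).  ``activity_multipliers`` scale the maximum rates of the
    named carriers without touching the base parameter set.
    """

    active_transporters: frozenset[str] = frozenset(TRANSPORTERS)
    clamped_compartments: frozenset[str] = frozenset()
    flow_maternal_enabled: bool = True
    flow_fetal_enabled: bool = True
    activity_multipliers: Mapping[str, float] = field(default_factory=dict)
    name: str = "full"

    def __post_init__(self) -> None:
        unknown = set(self.active_transporters) - set(TRANSPORTERS)
        if unknown:
            raise ValueError(f"unknown transporters: {sorted(unknown)}")
        unknown = set(self.clamped_compartments) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments: {sorted(unknown)}")
        unknown = set(self.activity_multipliers) - set(TRANSPORTERS)
        if unknown:
            raise ValueError(f"unknown activity multipliers: {sorted(unknown)}")
        object.__setattr__(
            self, "active_transporters", frozenset(self.active_transporters)
        )
        object.__setattr__(
            self, "clamped_compartments", frozenset(self.clamped_compartments)
        )
        object.__setattr__(
            self, "activity_multipliers", dict(self.activity_multipliers)
        )

    def multiplier(self, transporter: str) -> float:
        return float(self.activity_multipliers.get(transporter, 1.0))

    @classmethod
    def full(cls, **kw) -> "ScenarioSpec":
        """All four carriers active, maternal and fetal flows on."""
        return cls(name="full", **kw)

    @classmethod
    def mvm_only(cls, **kw) -> "ScenarioSpec":
        """Uptake across the MVM only: BM transport disabled.

        The maternal compartment keeps its arterial flow so it stays near
        arterial composition while the syncytiotrophoblast accumulates.
        """
        return cls(
            active_transporters=frozenset({"accumulative_mvm", "exchanger_mvm"}),
            name="mvm_only",
            **kw,
        )

    @classmethod
    def bm_only(cls, **kw) -> "ScenarioSpec":
        """Delivery across the BM only, with the cytosol clamped at its
        physiological composition and the fetal compartment perfused with
        umbilical-arterial input."""
        return cls(
            active_transporters=frozenset({"exchanger_bm", "facilitative_bm"}),
            clamped_compartments=frozenset({"maternal", "syncytiotrophoblast"}),
            name="bm_only",
            **kw,
        )


@dataclass
class SimulationResult:
    """Trajectory plus steady-state summary of one model run.

    ``va_difference`` is the umbilical venous−arterial concentration
    difference per group, [A]ᶠ − [A]ᶠ_in at the final/steady state (the
    fetal compartment is well mixed, so its concentration is the umbilical
    venous concentration); ``net_transfer`` the corresponding molar rate
    F_f · ΔA in μmol min⁻¹.
    """

    times: np.ndarray
    trajectory: np.ndarray  # (n_times, n_groups, n_compartments)
    steady_state: SystemState
    va_difference: dict[str, float]
    net_transfer: dict[str, float]
    converged: bool
    scenario: ScenarioSpec

    @property
    def final_state(self) -> SystemState:
        return SystemState(self.trajectory[-1])

    def state_at(self, index: int) -> SystemState:
        return SystemState(self.trajectory[index])

    def trajectory_frame(self) -> pd.DataFrame:
        """Long-format table: time, compartment, group, concentration."""
        rows = []
        for k, t in enumerate(self.times):
            for c, j in zip(COMPARTMENTS, range(len(COMPARTMENTS))):
                for g, i in GROUP_INDEX.items():
                    rows.append((float(t), c, g, float(self.trajectory[k, i, j])))
        return pd.DataFrame(
            rows, columns=["time_min", "compartment", "group", "concentration_umol_per_l"]
        )

    def summary_frame(self) -> pd.DataFrame:
        """Steady-state concentrations with V−A difference and net transfer."""
        rows = []
        for c in COMPARTMENTS:
            for g in GROUPS:
                rows.append(
                    {
                        "compartment": c,
                        "group": g,
                        "concentration_umol_per_l": self.steady_state.get(g, c),
                        "va_difference_umol_per_l": self.va_difference[g]
                        if c == "fetal"
                        else np.nan,
                        "net_transfer_umol_per_min": self.net_transfer[g]
                        if c == "fetal"
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)


class PlacentaModel:
    """Compartmental model of amino acid transfer across one cotyledon.

    Parameters default to the packaged physiological reference set.  The
    model is deterministic; all stochasticity in the package lives in the
    test-fixture generator.

    Parameters
    ----------
    geometry, params, inputs, initial :
        Geometry, kinetic constants, arterial inputs and initial state;
        any omitted piece is taken from :func:`reference_parameters`.
    scenario :
        Which carriers/flows/clamps are in force; default: full system.
    denominator_convention :
        Reading of the constant term in the accumulative-carrier
        denominator, ``"dimensional"`` (default) or ``"literal"``.
    """

    def __init__(
        self,
        geometry: Geometry | None = None,
        params: TransporterParams | None = None,
        inputs: BoundaryInputs | None = None,
        initial: SystemState | None = None,
        scenario: ScenarioSpec | None = None,
        denominator_convention: str = "dimensional",
    ) -> None:
        ref = reference_parameters()
        self.geometry = geometry if geometry is not None else ref[0]
        self.params = params if params is not None else ref[1]
        self.inputs = inputs if inputs is not None else ref[2]
        self.initial = initial if initial is not None else ref[3]
        self.scenario = scenario if scenario is not None else ScenarioSpec.full()
        self.denominator_convention = denominator_convention
        self._clamp_mask = np.array(
            [c in self.scenario.clamped_compartments for c in COMPARTMENTS]
        )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_reference(cls, scenario: ScenarioSpec | None = None, **kw) -> "PlacentaModel":
        return cls(scenario=scenario, **kw)

    def with_(self, **kw) -> "PlacentaModel":
        """Copy of the model with some components replaced."""
        out = dict(
            geometry=self.geometry,
            params=self.params,
            inputs=self.inputs,
            initial=self.initial,
            scenario=self.scenario,
            denominator_convention=self.denominator_convention,
        )
        out.update(kw)
        return PlacentaModel(**out)

    # -- right-hand side -----------------------------------------------------

    def _fluxes(self, conc: np.ndarray) -> dict[str, np.ndarray]:
        """Per-group carrier and flow fluxes at a given (4, 3) state."""
        sc, p, g = self.scenario, self.params, self.geometry
        c_m, c_s, c_f = conc[:, 0], conc[:, 1], conc[:, 2]
        z4 = np.zeros(len(GROUPS))

        J_ac = z4.copy()
        if "accumulative_mvm" in sc.active_transporters:
            sides = MembraneSides(
                c_m[_AC_IDX], c_s[_AC_IDX], p.Na_maternal, p.Na_syncytio
            )
            J_ac[_AC_IDX] = accumulative_flux(
                sides,
                p,
                V_ac=p.V_ac * sc.multiplier("accumulative_mvm"),
                denominator_convention=self.denominator_convention,
            )

        J_ex_mvm = z4.copy()
        if "exchanger_mvm" in sc.active_transporters:
            J_ex_mvm = exchanger_flux(
                MembraneSides(c_m, c_s),
                p.V_ex_mvm * sc.multiplier("exchanger_mvm"),
                p.K_ex,
            )

        J_ex_bm = z4.copy()
        if "exchanger_bm" in sc.active_transporters:
            J_ex_bm = exchanger_flux(
                MembraneSides(c_s, c_f),
                p.V_ex_bm * sc.multiplier("exchanger_bm"),
                p.K_ex,
            )

        J_fa = z4.copy()
        if "facilitative_bm" in sc.active_transporters:
            sides = MembraneSides(c_s[_FA_IDX], c_f[_FA_IDX])
            J_fa[_FA_IDX] = facilitative_flux(
                sides, p.V_fa * sc.multiplier("facilitative_bm"), p.K_fa
            )

        J_flow_m = z4.copy()
        if sc.flow_maternal_enabled:
            J_flow_m = g.f_maternal_l_min * (self.inputs.in_maternal - c_m)
        J_flow_f = z4.copy()
        if sc.flow_fetal_enabled:
            J_flow_f = g.f_fetal_l_min * (self.inputs.in_fetal - c_f)

        return {
            "accumulative_mvm": J_ac,
            "exchanger_mvm": J_ex_mvm,
            "exchanger_bm": J_ex_bm,
            "facilitative_bm": J_fa,
            "flow_maternal": J_flow_m,
            "flow_fetal": J_flow_f,
        }

    def _rhs_array(self, conc: np.ndarray) -> np.ndarray:
        J = self._fluxes(conc)
        g = self.geometry
        d = np.empty_like(conc)
        d[:, 0] = (J["flow_maternal"] - J["accumulative_mvm"] - J["exchanger_mvm"]) / g.v_maternal_l
        d[:, 1] = (
            J["accumulative_mvm"] + J["exchanger_mvm"] - J["exchanger_bm"] - J["facilitative_bm"]
        ) / g.v_syncytio_l
        d[:, 2] = (J["flow_fetal"] + J["exchanger_bm"] + J["facilitative_bm"]) / g.v_fetal_l
        d[:, self._clamp_mask] = 0.0
        return d

    def rhs(self, state: SystemState) -> np.ndarray:
        """d[conc]/dt (μmol l⁻¹ min⁻¹), shape (n_groups, n_compartments).

        Maternal balance: flow in/out minus MVM uptake; cytosol: MVM uptake
        minus BM efflux; fetal: flow in/out plus BM efflux.  Clamped
        compartments get a zero derivative.
        """
        if not isinstance(state, SystemState):
            state = SystemState(np.asarray(state, dtype=float))
        return self._rhs_array(state.conc)

    def _ode_rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        # integrator-facing: tolerate the tiny negative excursions RK45
        # probes near zero (fluxes are continuous there)
        conc = np.clip(y, 0.0, None).reshape(len(GROUPS), len(COMPARTMENTS))
        return self._rhs_array(conc).ravel()

    # -- integration ---------------------------------------------------------

    def simulate(
        self,
        t_end: float = 500.0,
        initial: SystemState | None = None,
        n_points: int = 201,
        rtol: float = 1e-8,
        atol: float = 1e-6,
    ) -> SimulationResult:
        """Integrate the system with adaptive 4th/5th-order Runge–Kutta.

        Returns the trajectory on an evenly spaced grid plus a summary at
        the final state (flagged ``converged`` only if the stationarity
        criterion holds there; use :meth:`steady_state` for a guaranteed
        steady state).
        """
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        y0 = (initial or self.initial).conc.ravel()
        sol = solve_ivp(
            self._ode_rhs,
            (0.0, t_end),
            y0,
            method="RK45",
            t_eval=np.linspace(0.0, t_end, n_points),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise SteadyStateError(
                f"integration failed: {sol.message}",
                SystemState(np.clip(sol.y[:, -1], 0, None).reshape(len(GROUPS), -1)),
            )
        traj = np.clip(sol.y.T, 0.0, None).reshape(-1, len(GROUPS), len(COMPARTMENTS))
        final = SystemState(traj[-1])
        return self._result(sol.t, traj, final, self._is_stationary(final.conc))

    def _is_stationary(self, conc: np.ndarray, rtol: float = STEADY_RTOL) -> bool:
        d = self._rhs_array(conc)
        scale = np.maximum(conc, 1.0)
        return bool(np.max(np.abs(d) / scale) < rtol)

    def steady_state(
        self,
        initial: SystemState | None = None,
        polish: bool = True,
        rtol: float = STEADY_RTOL,
        t_cap: float = STEADY_T_CAP,
    ) -> SystemState:
        """Integrate to stationarity, then polish by root-finding on the RHS.

        Stationary means every unclamped concentration changes by less than
        ``rtol`` relative per minute.  Raises :class:`SteadyStateError`
        (carrying the last state) if the cap on model time is exhausted.
        """
        state = (initial or self.initial).copy()

        if polish:
            polished = self._polish(state)
            if polished is not None:
                return polished

        t_chunk, t_total = 200.0, 0.0
        while t_total < t_cap:
            res = self.simulate(t_end=t_chunk, initial=state, n_points=2, rtol=1e-8)
            state = res.final_state
            t_total += t_chunk
            if self._is_stationary(state.conc, rtol):
                if polish:
                    polished = self._polish(state)
                    if polished is not None:
                        return polished
                return state
            t_chunk = min(t_chunk * 2.0, t_cap - t_total) or t_chunk
        raise SteadyStateError(
            f"no steady state within {t_cap:g} min of model time", state
        )

    def _polish(self, state: SystemState) -> SystemState | None:
        """Newton polish of the unclamped concentrations; None on failure."""
        free = ~self._clamp_mask
        if not free.any():
            return state
        base = state.conc.copy()

        def residual(x: np.ndarray) -> np.ndarray:
            conc = base.copy()
            conc[:, free] = np.clip(x.reshape(len(GROUPS), -1), 0.0, None)
            return self._rhs_array(conc)[:, free].ravel()

        sol = root(residual, base[:, free].ravel(), method="hybr", tol=1e-12)
        if not sol.success:
            return None
        conc = base.copy()
        conc[:, free] = sol.x.reshape(len(GROUPS), -1)
        if np.any(conc < -1e-9):
            return None
        conc = np.clip(conc, 0.0, None)
        if not self._is_stationary(conc):
            return None
        return SystemState(conc)

    def steady_state_result(self, **kw) -> SimulationResult:
        """Like :meth:`steady_state` but wrapped in a :class:`SimulationResult`
        (single-point trajectory) carrying the V−A summary."""
        ss = self.steady_state(**kw)
        traj = ss.conc[None, :, :]
        return self._result(np.array([0.0]), traj, ss, True)

    def _result(
        self, times: np.ndarray, traj: np.ndarray, ss: SystemState, converged: bool
    ) -> SimulationResult:
        va = {
            g: float(ss.get(g, "fetal") - self.inputs.in_fetal[GROUP_INDEX[g]])
            for g in GROUPS
        }
        f_f = self.geometry.f_fetal_l_min  # l/min × μmol/l → μmol/min
        net = {g: f_f * va[g] for g in GROUPS}
        return SimulationResult(
            times=times,
            trajectory=traj,
            steady_state=ss,
            va_difference=va,
            net_transfer=net,
            converged=converged,
            scenario=self.scenario,
        )

    # -- fitting -------------------------------------------------------------

    def fit(self, targets=None, **kw):
        """Fit the four carrier activities to umbilical V−A targets.

        Thin wrapper around :func:`placentaflux.fitting.fit_activities`;
        see there for details.  Returns a
        :class:`~placentaflux.fitting.FitResult`.
        """
        from .fitting import fit_activities

        return fit_activities(self, targets=targets, **kw)
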