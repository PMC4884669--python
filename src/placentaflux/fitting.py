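"""Least-squares fitting of the four carrier activities to umbilical
venous−arterial concentration differences.

The four maximum transport rates (accumulative, MVM exchange, BM exchange,
facilitative) are adjusted simultaneously so that the steady-state V−A
difference of each amino acid group matches a per-group target, using an
equally weighted normalised (relative) least-squares criterion minimised
by Nelder–Mead.  Optimisation runs in log-rate space, which enforces
positivity without constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import GROUPS, TransporterParams
from .model import SteadyStateError

__all__ = ["LITERATURE_VA_TARGETS", "FitResult", "fit_objective", "fit_activities"]

#: Published umbilical venous−arterial differences (μmol l⁻¹) per group,
#: the default fitting targets.
LITERATURE_VA_TARGETS: dict[str, float] = {
    "AcEx": 55.0,
    "Ex": 12.0,
    "ExF": 40.0,
    "AcExF": 44.0,
}

_RATE_NAMES = ("V_ac", "V_ex_mvm", "V_ex_bm", "V_fa")
# objective value returned when a candidate admits no steady state
_PENALTY = 1e6


@dataclass
class FitResult:
    """Outcome of an activity fit.

    ``multipliers`` are fitted rates divided by the starting (reference)
    rates; ``trace`` records every objective evaluation.
    """

    fitted_V: dict[str, float]
    multipliers: dict[str, float]
    objective: float
    objective_at_start: float
    predicted_va: dict[str, float]
    targets: dict[str, float]
    converged: bool
    n_evaluations: int
    trace: list[tuple[tuple[float, ...], float]] = field(repr=False, default_factory=list)
    message: str = ""

    def summary(self) -> str:
        """Plain-text report of rates, multipliers and predicted vs target V−A."""
        lines = [
            "Carrier activity fit (normalised least squares, Nelder-Mead)",
            "=" * 62,
            f"{'rate':<10}{'fitted (umol/min)':>20}{'multiplier':>14}",
        ]
        for k in _RATE_NAMES:
            lines.append(f"{k:<10}{self.fitted_V[k]:>20.4g}{self.multipliers[k]:>14.3g}")
        lines.append("")
        lines.append(f"{'group':<8}{'predicted V-A':>16}{'target':>10}{'rel.err %':>12}")
        for g in GROUPS:
            p, t = self.predicted_va[g], self.targets[g]
            lines.append(f"{g:<8}{p:>16.2f}{t:>10.1f}{100*(p-t)/t:>12.1f}")
        lines.append("")
        lines.append(
            f"objective {self.objective:.6g} (start {self.objective_at_start:.6g}), "
            f"{self.n_evaluations} evaluations, "
            f"{'converged' if self.converged else 'NOT converged'}"
        )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(GROUPS),
                "predicted_va_umol_per_l": [self.predicted_va[g] for g in GROUPS],
                "target_va_umol_per_l": [self.targets[g] for g in GROUPS],
            }
        )

    def trace_frame(self) -> pd.DataFrame:
        rows = [dict(zip(_RATE_NAMES, np.exp(x)), objective=f) for x, f in self.trace]
        return pd.DataFrame(rows)


def _as_target_dict(targets) -> dict[str, float]:
    if targets is None:
        return dict(LITERATURE_VA_TARGETS)
    if isinstance(targets, Mapping):
        out = {g: float(targets[g]) for g in GROUPS}
    else:
        seq = list(targets)
        if len(seq) != len(GROUPS):
            raise ValueError("need one target per amino acid group")
        out = dict(zip(GROUPS, map(float, seq)))
    if any(v <= 0 for v in out.values()):
        raise ValueError("targets must be positive (normalised errors divide by them)")
    return out


class _ObjectiveEvaluator:
    """Predicted-V−A objective with steady-state warm starting.

    Each evaluation rebuilds the kinetic parameters with the candidate
    rates, solves for the steady state (seeding the solver with the last
    successful steady state, which keeps Nelder–Mead iterations cheap) and
    returns Σ_g ((predicted − target)/target)².
    """

    def __init__(self, model, targets: dict[str, float]) -> None:
        self.model = model
        self.targets = targets
        self._warm = model.initial
        self.n_calls = 0
        self.trace: list[tuple[tuple[float, ...], float]] = []

    def predicted_va(self, rates: Sequence[float]) -> dict[str, float]:
        from dataclasses import replace

        params = replace(
            self.model.params, **dict(zip(_RATE_NAMES, map(float, rates)))
        )
        candidate = self.model.with_(params=params)
        ss = candidate.steady_state(initial=self._warm)
        self._warm = ss
        return candidate._result(np.array([0.0]), ss.conc[None], ss, True).va_difference

    def __call__(self, log_rates: np.ndarray) -> float:
        self.n_calls += 1
        rates = np.exp(np.asarray(log_rates, dtype=float))
        try:
            va = self.predicted_va(rates)
            value = sum(
                ((va[g] - self.targets[g]) / self.targets[g]) ** 2 for g in GROUPS
            )
        except (SteadyStateError, ValueError, FloatingPointError):
            value = _PENALTY
        self.trace.append((tuple(log_rates), float(value)))
        return float(value)


def fit_objective(V_candidates, model=None, targets=None) -> float:
    """Equally weighted normalised least-squares objective at candidate rates.

    ``V_candidates``: the four maximum rates (μmol min⁻¹) in the order
    accumulative, MVM exchange, BM exchange, facilitative.  A candidate for
    which the steady state cannot be found scores a large finite penalty.
    """
    if model is None:
        from .model import PlacentaModel

        model = PlacentaModel()
    rates = np.asarray(V_candidates, dtype=float)
    if rates.shape != (4,) or np.any(rates <= 0):
        raise ValueError("expected four strictly positive rates")
    ev = _ObjectiveEvaluator(model, _as_target_dict(targets))
    return ev(np.log(rates))


def fit_activities(
    model=None,
    targets=None,
    start: Sequence[float] | None = None,
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxfev: int = 2000,
) -> FitResult:
    """Fit the four carrier activities by Nelder–Mead from the reference start.

    Parameters
    ----------
    model : PlacentaModel, optional
        Base model; default the packaged reference (full scenario).
    targets : mapping or sequence, optional
        Per-group V−A targets (μmol l⁻¹); default the literature values.
    start : sequence of four rates, optional
        Starting rates; default the model's current rates.

    Returns
    -------
    FitResult
        Fitted rates, multipliers relative to the start, predicted V−A at
        the optimum and the full evaluation trace.  If the simplex does not
        meet the tolerances within ``maxfev`` evaluations the best point is
        returned with ``converged=False``.
    """
    if model is None:
        from .model import PlacentaModel

        model = PlacentaModel()
    target_dict = _as_target_dict(targets)
    start_rates = np.asarray(
        start
        if start is not None
        else [getattr(model.params, k) for k in _RATE_NAMES],
        dtype=float,
    )
    if start_rates.shape != (4,) or np.any(start_rates <= 0):
        raise ValueError("start must be four strictly positive rates")

    evaluator = _ObjectiveEvaluator(model, target_dict)
    x0 = np.log(start_rates)
    f0 = evaluator(x0)

    opt = minimize(
        evaluator,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xatol,
            "fatol": fatol,
            "maxfev": maxfev,
            "adaptive": True,
        },
    )
    best_x = opt.x
    fitted = np.exp(best_x)
    predicted = evaluator.predicted_va(fitted)

    return FitResult(
        fitted_V=dict(zip(_RATE_NAMES, map(float, fitted))),
        multipliers=dict(zip(_RATE_NAMES, map(float, fitted / start_rates))),
        objective=float(opt.fun),
        objective_at_start=float(f0),
        predicted_va=predicted,
        targets=target_dict,
        converged=bool(opt.success),
        n_evaluations=evaluator.n_calls,
        trace=evaluator.trace,
        message=str(opt.message),
    )
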