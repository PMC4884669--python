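"""Net flux laws for the three carrier classes and the flow exchange term.

All functions are pure and stateless.  Fluxes are net molecular fluxes from
membrane side I to side II in μmol min⁻¹; concentrations in μmol l⁻¹.

Conventions
-----------
* Each transporter class is represented by a single lumped carrier whose
  substrates share identical binding (K) and translocation (V) constants,
  with symmetric rates on both membrane faces.
* The exchanger is a strict 1:1 antiporter: summed over its substrates the
  net flux is identically zero — it changes composition, never amount.
* The accumulative carrier cotransports 1 Na⁺ per amino acid; sodium binds
  first and only the translocation of the full carrier·Na·substrate complex
  is electrogenic, biased by the membrane potential through the factors
  ε = exp(βzFΔψ/RT) (backward) and ε′ = exp((β−1)zFΔψ/RT) (forward).
  Δψ is the potential of side II relative to side I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TransporterParams

__all__ = [
    "MembraneSides",
    "BiasFactors",
    "bias_factors",
    "exchanger_flux",
    "facilitative_flux",
    "accumulative_flux",
    "flow_flux",
]


@dataclass(frozen=True)
class MembraneSides:
    """Substrate (and optionally sodium) concentrations on both membrane faces.

    ``conc_I``/``conc_II`` hold one concentration per substrate group of the
    transporter being evaluated, in a caller-chosen but consistent order.
    Totals are always recomputed from these vectors, never stored.
    """

    conc_I: np.ndarray
    conc_II: np.ndarray
    na_I: float | None = None
    na_II: float | None = None

    def __post_init__(self) -> None:
        for name in ("conc_I", "conc_II"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise ValueError(f"{name}: concentrations must be finite and ≥ 0")
            object.__setattr__(self, name, arr)
        if self.conc_I.shape != self.conc_II.shape:
            raise ValueError("both sides must list the same substrates")

    @property
    def tot_I(self) -> float:
        return float(self.conc_I.sum())

    @property
    def tot_II(self) -> float:
        return float(self.conc_II.sum())

    def swapped(self) -> "MembraneSides":
        return MembraneSides(self.conc_II, self.conc_I, self.na_II, self.na_I)


@dataclass(frozen=True)
class BiasFactors:
    """Membrane-potential bias on the electrogenic translocation step.

    ``eps`` biases the backward (II→I) and ``eps_prime`` the forward (I→II)
    translocation of the charged carrier complex.  Their ratio is fixed by
    thermodynamics: eps_prime/eps = exp(−zFΔψ/RT), independent of β.
    """

    eps: float
    eps_prime: float


def bias_factors(params: TransporterParams) -> BiasFactors:
    """ε = exp(βzFΔψ/RT), ε′ = exp((β−1)zFΔψ/RT) from the electrogenic constants."""
    x = params.z * params.F_const * params.delta_psi / (params.R_const * params.T_abs)
    return BiasFactors(eps=float(np.exp(params.beta * x)),
                       eps_prime=float(np.exp((params.beta - 1.0) * x)))


def exchanger_flux(
    sides: MembraneSides,
    V_ex: float,
    K_ex: float,
    group: int | None = None,
):
    """Net antiport flux of each substrate from side I to side II.

    For substrate A with counter-substrate pool [R]ⁱ = [Tot]ⁱ − [A]ⁱ::

        J_A = V_ex ([A]ᴵ[R]ᴵᴵ − [A]ᴵᴵ[R]ᴵ)
              ─────────────────────────────────────────
              K_ex ([Tot]ᴵ + [Tot]ᴵᴵ)/2 + [Tot]ᴵ[Tot]ᴵᴵ

    Obligatory 1:1 exchange: a substrate with nothing to swap against on
    the far side has zero flux, and the fluxes of all substrates sum to
    zero identically.  The empty–empty singularity is defined as zero by
    continuity.  Returns the per-substrate flux vector, or a scalar when
    ``group`` (an index into the substrate vectors) is given.
    """
    cI, cII = sides.conc_I, sides.conc_II
    tot_I, tot_II = cI.sum(), cII.sum()
    denom = K_ex * (tot_I + tot_II) / 2.0 + tot_I * tot_II
    if denom == 0.0:
        flux = np.zeros_like(cI)
    else:
        # A_I * (tot_II - A_II) - A_II * (tot_I - A_I) simplifies to
        # A_I * tot_II - A_II * tot_I (the A_I*A_II cross terms cancel).
        flux = V_ex * (cI * tot_II - cII * tot_I) / denom
    return flux if group is None else float(flux[group])


def facilitative_flux(
    sides: MembraneSides,
    V_fa: float,
    K_fa: float,
    group: int | None = None,
):
    """Net facilitative (uniport) flux of each substrate from side I to II.

        J_A = V_fa ( [A]ᴵ/(K_fa + [Tot]ᴵ) − [A]ᴵᴵ/(K_fa + [Tot]ᴵᴵ) )

    [Tot] sums the facilitative substrates only; shared-carrier competition
    enters through the totals in the denominators.
    """
    cI, cII = sides.conc_I, sides.conc_II
    flux = V_fa * (cI / (K_fa + cI.sum()) - cII / (K_fa + cII.sum()))
    return flux if group is None else float(flux[group])


def _denominator_constant(K_ac: float, K_Na: float, convention: str) -> float:
    """Final constant term of the accumulative-carrier denominator.

    The published form of this term is typographically ambiguous.  Every
    other term in the denominator has dimension concentration⁴, which the
    ``"dimensional"`` reading 2·K_ac²·K_Na² preserves; the ``"literal"``
    reading 2·K_ac·K_Na² (concentration³) is kept selectable for
    comparison.  Both are constant offsets ≲ 10 % of the state-dependent
    terms at physiological sodium, so steady-state results barely differ.
    """
    if convention == "dimensional":
        return 2.0 * K_ac * K_ac * K_Na * K_Na
    if convention == "literal":
        return 2.0 * K_ac * K_Na * K_Na
    raise ValueError(f"unknown denominator convention {convention!r}")


def accumulative_flux(
    sides: MembraneSides,
    params: TransporterParams,
    V_ac: float | None = None,
    group: int | None = None,
    denominator_convention: str = "dimensional",
):
    """Net sodium-coupled flux of the two accumulative substrates, side I → II.

    ``sides`` must carry exactly the two accumulative substrate groups
    (call them A and B) plus sodium on both faces.  For substrate A::

        J_A = (2 V_ac / D) [ εε′ Naᴵ Naᴵᴵ ([A]ᴵ[B]ᴵᴵ − [A]ᴵᴵ[B]ᴵ)
                             + K_ac K_Na (ε′ [A]ᴵ Naᴵ − ε [A]ᴵᴵ Naᴵᴵ) ]

    with the shared denominator::

        D = Naᴵ Naᴵᴵ [ ε′ [Tot]ᴵ ([Tot]ᴵᴵ + K_ac) + ε [Tot]ᴵᴵ ([Tot]ᴵ + K_ac) ]
            + K_ac K_Na [ (ε′+1) [Tot]ᴵ Naᴵ + (ε+1) [Tot]ᴵᴵ Naᴵᴵ ]
            + K_ac² K_Na (Naᴵ + Naᴵᴵ) + (constant term)

    The first numerator term is substrate↔substrate exchange through the
    carrier; the second is net sodium-driven pumping, which vanishes when
    [A]ᴵᴵ/[A]ᴵ = (Naᴵ/Naᴵᴵ)·exp(−zFΔψ/RT) — the thermodynamic accumulation
    limit, independent of every kinetic constant.
    """
    if sides.conc_I.shape != (2,):
        raise ValueError("accumulative carrier expects exactly two substrate groups")
    if sides.na_I is None or sides.na_II is None or sides.na_I <= 0 or sides.na_II <= 0:
        raise ValueError("sodium must be present (> 0) on both sides")
    if V_ac is None:
        V_ac = params.V_ac

    bias = bias_factors(params)
    eps, epsp = bias.eps, bias.eps_prime
    na_I, na_II = float(sides.na_I), float(sides.na_II)
    K_ac, K_Na = params.K_ac, params.K_Na
    cI, cII = sides.conc_I, sides.conc_II
    tot_I, tot_II = cI.sum(), cII.sum()

    # cI[::-1] pairs each substrate with the *other* one (its B).
    cross = na_I * na_II * eps * epsp * (cI * cII[::-1] - cII * cI[::-1])
    pump = K_ac * K_Na * (epsp * cI * na_I - eps * cII * na_II)

    D = (
        na_I * na_II * (epsp * tot_I * (tot_II + K_ac) + eps * tot_II * (tot_I + K_ac))
        + K_ac * K_Na * ((epsp + 1.0) * tot_I * na_I + (eps + 1.0) * tot_II * na_II)
        + K_ac * K_ac * K_Na * (na_I + na_II)
        + _denominator_constant(K_ac, K_Na, denominator_convention)
    )
    if D == 0.0:
        raise ZeroDivisionError("accumulative carrier denominator is zero")
    flux = 2.0 * V_ac * (cross + pump) / D
    return flux if group is None else float(flux[group])


def flow_flux(input_conc, compartment_conc, F_ml_min: float):
    """Net molecular flux into a flow-perfused compartment, μmol min⁻¹.

    J = F ([A]_in − [A]); F given in ml min⁻¹, concentrations in μmol l⁻¹.
    """
    if F_ml_min < 0:
        raise ValueError("flow must be ≥ 0")
    return (F_ml_min / 1000.0) * (np.asarray(input_conc, dtype=float)
                                  - np.asarray(compartment_conc, dtype=float))
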