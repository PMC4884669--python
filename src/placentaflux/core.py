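"""Domain types, unit conventions and the packaged reference parameterisation.

The model lumps the neutral amino acids into four generic groups named by
their transporter specificity:

=======  ==============================================  =================
group    transporters that accept it                     example members
=======  ==============================================  =================
AcEx     accumulative + exchange                         glutamine, glycine
Ex       exchange only                                   threonine
ExF      exchange + facilitative                         leucine, phenylalanine
AcExF    accumulative + exchange + facilitative          alanine
=======  ==============================================  =================

Glutamate and aspartate are excluded: they are handled by distinct (EAAT)
systems with negligible interaction with the groups above.

All quantities are held internally in a single unit system:

* concentration  μmol l⁻¹
* molar flux     μmol min⁻¹
* volume         ml (converted to l where fluxes divide by volumes)
* flow           ml min⁻¹ (specific flows in ml min⁻¹ g⁻¹ scale by the
  cotyledon mass, taking tissue density as 1 g ml⁻¹)
* time           min

Published parameter tables mix mmol- and μmol-based units; everything is
converted once, on construction, to avoid factor-of-10³ mistakes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GROUPS",
    "COMPARTMENTS",
    "AminoAcidGroup",
    "GROUP_REGISTRY",
    "accumulative_substrates",
    "facilitative_substrates",
    "SystemState",
    "Geometry",
    "TransporterParams",
    "BoundaryInputs",
    "reference_parameters",
    "group_fraction",
    "diffusion_timescale",
]

#: Canonical ordering of the lumped substrate groups.
GROUPS: tuple[str, ...] = ("AcEx", "Ex", "ExF", "AcExF")

#: Canonical ordering of the compartments: maternal intervillous space,
#: syncytiotrophoblast cytosol, fetal capillaries.
COMPARTMENTS: tuple[str, ...] = ("maternal", "syncytiotrophoblast", "fetal")

GROUP_INDEX: dict[str, int] = {g: i for i, g in enumerate(GROUPS)}
COMPARTMENT_INDEX: dict[str, int] = {c: i for i, c in enumerate(COMPARTMENTS)}


@dataclass(frozen=True)
class AminoAcidGroup:
    """A lumped substrate class with transporter-specificity flags."""

    name: str
    is_accumulative_substrate: bool
    is_exchange_substrate: bool
    is_facilitative_substrate: bool

    def __post_init__(self) -> None:
        if self.name not in GROUPS:
            raise ValueError(f"unknown amino acid group {self.name!r}")
        if not self.is_exchange_substrate:
            raise ValueError("every group is an exchanger substrate")


#: The four groups of the model, keyed by name.
GROUP_REGISTRY: dict[str, AminoAcidGroup] = {
    "AcEx": AminoAcidGroup("AcEx", True, True, False),
    "Ex": AminoAcidGroup("Ex", False, True, False),
    "ExF": AminoAcidGroup("ExF", False, True, True),
    "AcExF": AminoAcidGroup("AcExF", True, True, True),
}


def accumulative_substrates() -> tuple[str, ...]:
    """Names of the groups carried by the accumulative transporter."""
    return tuple(g for g in GROUPS if GROUP_REGISTRY[g].is_accumulative_substrate)


def facilitative_substrates() -> tuple[str, ...]:
    """Names of the groups carried by the facilitative transporter."""
    return tuple(g for g in GROUPS if GROUP_REGISTRY[g].is_facilitative_substrate)


class SystemState:
    """Concentrations of each group in each compartment (μmol l⁻¹).

    Thin wrapper over a ``(n_groups, n_compartments)`` array with named
    accessors.  Rows follow :data:`GROUPS`, columns :data:`COMPARTMENTS`.
    """

    __slots__ = ("conc",)

    def __init__(self, conc: np.ndarray) -> None:
        conc = np.asarray(conc, dtype=float)
        if conc.shape != (len(GROUPS), len(COMPARTMENTS)):
            raise ValueError(
                f"expected shape {(len(GROUPS), len(COMPARTMENTS))}, got {conc.shape}"
            )
        if np.any(conc < 0) or np.any(np.isnan(conc)):
            raise ValueError("concentrations must be non-negative and finite")
        self.conc = conc

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, float]]) -> "SystemState":
        """Build from ``{compartment: {group: conc}}``."""
        arr = np.zeros((len(GROUPS), len(COMPARTMENTS)))
        for comp, per_group in d.items():
            j = COMPARTMENT_INDEX[comp]
            for g, v in per_group.items():
                arr[GROUP_INDEX[g], j] = v
        return cls(arr)

    def compartment(self, name: str) -> np.ndarray:
        """Concentration vector (per group) of one compartment."""
        return self.conc[:, COMPARTMENT_INDEX[name]]

    def get(self, group: str, compartment: str) -> float:
        return float(self.conc[GROUP_INDEX[group], COMPARTMENT_INDEX[compartment]])

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            c: {g: float(self.conc[i, j]) for g, i in GROUP_INDEX.items()}
            for c, j in COMPARTMENT_INDEX.items()
        }

    def to_frame(self):
        """Long-format ``DataFrame`` with compartment, group, concentration."""
        import pandas as pd

        rows = [
            (c, g, float(self.conc[i, j]))
            for c, j in COMPARTMENT_INDEX.items()
            for g, i in GROUP_INDEX.items()
        ]
        return pd.DataFrame(
            rows, columns=["compartment", "group", "concentration_umol_per_l"]
        )

    def copy(self) -> "SystemState":
        return SystemState(self.conc.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"SystemState({self.to_dict()!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SystemState):
            return NotImplemented
        return np.array_equal(self.conc, other.conc)


@dataclass(frozen=True)
class Geometry:
    """Compartment volumes and blood flows for one placental cotyledon.

    ``flow_maternal``/``flow_fetal`` are specific flows in ml min⁻¹ g⁻¹;
    absolute flows scale by the cotyledon mass assuming 1 g ≈ 1 ml of
    tissue, so a 30 ml cotyledon weighs 30 g.
    """

    total_volume: float = 30.0  # ml
    frac_maternal: float = 0.34
    frac_syncytio: float = 0.15
    frac_fetal: float = 0.075
    flow_maternal: float = 2.0  # ml min⁻¹ g⁻¹
    flow_fetal: float = 0.2  # ml min⁻¹ g⁻¹

    def __post_init__(self) -> None:
        if self.total_volume <= 0:
            raise ValueError("total volume must be positive")
        fr = (self.frac_maternal, self.frac_syncytio, self.frac_fetal)
        if any(f <= 0 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ValueError("volume fractions must be positive and sum to ≤ 1")
        if self.flow_maternal <= 0 or self.flow_fetal <= 0:
            raise ValueError("flows must be positive")

    # Absolute volumes, litres (used where flux μmol/min divides by volume).
    @property
    def v_maternal_l(self) -> float:
        return self.total_volume * self.frac_maternal / 1000.0

    @property
    def v_syncytio_l(self) -> float:
        return self.total_volume * self.frac_syncytio / 1000.0

    @property
    def v_fetal_l(self) -> float:
        return self.total_volume * self.frac_fetal / 1000.0

    # Absolute flows, litres per minute (1 g tissue per ml).
    @property
    def f_maternal_l_min(self) -> float:
        return self.flow_maternal * self.total_volume / 1000.0

    @property
    def f_fetal_l_min(self) -> float:
        return self.flow_fetal * self.total_volume / 1000.0

    def volumes_l(self) -> np.ndarray:
        return np.array([self.v_maternal_l, self.v_syncytio_l, self.v_fetal_l])


@dataclass(frozen=True)
class TransporterParams:
    """Kinetic constants of the four lumped transporters.

    Maximum rates V are per cotyledon (μmol min⁻¹); dissociation constants
    K in μmol l⁻¹.  The electrogenic constants parameterise the membrane
    potential bias of the sodium-coupled accumulative carrier:
    ``delta_psi`` is the potential of the cytosolic side relative to the
    maternal side (negative: cytosol negative), ``beta`` apportions the
    bias between forward and backward translocation.
    """

    V_ac: float = 5.0  # μmol min⁻¹  (0.005 mmol min⁻¹)
    V_ex_mvm: float = 5.0
    V_ex_bm: float = 5.0
    V_fa: float = 5.0
    K_ac: float = 2260.0  # μmol l⁻¹  (2.26 mmol l⁻¹)
    K_Na: float = 25070.0  # μmol l⁻¹ (25.07 mmol l⁻¹)
    K_ex: float = 200.0
    K_fa: float = 1000.0
    beta: float = 0.33
    delta_psi: float = -0.021  # V
    Na_maternal: float = 134000.0  # μmol l⁻¹ (134 mmol l⁻¹)
    Na_syncytio: float = 15000.0  # μmol l⁻¹ (15 mmol l⁻¹)
    z: float = 1.0
    F_const: float = 9.65e4  # C mol⁻¹
    R_const: float = 8.314  # V C K⁻¹ mol⁻¹
    T_abs: float = 310.0  # K

    def __post_init__(self) -> None:
        for name in ("V_ac", "V_ex_mvm", "V_ex_bm", "V_fa", "K_ac", "K_Na", "K_ex", "K_fa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.T_abs <= 0:
            raise ValueError("temperature must be positive")

    def with_activities(
        self, *, ac: float = 1.0, ex_mvm: float = 1.0, ex_bm: float = 1.0, fa: float = 1.0
    ) -> "TransporterParams":
        """Return a copy with the four maximum rates scaled."""
        return replace(
            self,
            V_ac=self.V_ac * ac,
            V_ex_mvm=self.V_ex_mvm * ex_mvm,
            V_ex_bm=self.V_ex_bm * ex_bm,
            V_fa=self.V_fa * fa,
        )


@dataclass(frozen=True)
class BoundaryInputs:
    """Arterial input concentrations entering with flow (μmol l⁻¹).

    ``in_maternal`` is the maternal arterial composition, ``in_fetal`` the
    umbilical-artery composition; both are per-group vectors following
    :data:`GROUPS`.
    """

    in_maternal: np.ndarray
    in_fetal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("in_maternal", "in_fetal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(GROUPS),):
                raise ValueError(f"{name} must have one value per group")
            if np.any(arr < 0):
                raise ValueError("input concentrations must be non-negative")
            object.__setattr__(self, name, arr)

    @classmethod
    def from_dict(
        cls, maternal: Mapping[str, float], fetal: Mapping[str, float]
    ) -> "BoundaryInputs":
        return cls(
            in_maternal=np.array([maternal[g] for g in GROUPS], dtype=float),
            in_fetal=np.array([fetal[g] for g in GROUPS], dtype=float),
        )

    def scaled(self, maternal: float = 1.0, fetal: float = 1.0) -> "BoundaryInputs":
        return BoundaryInputs(self.in_maternal * maternal, self.in_fetal * fetal)


# ---------------------------------------------------------------------------
# Reference parameterisation
# ---------------------------------------------------------------------------

# Physiological group-sum concentrations, μmol l⁻¹, rows follow GROUPS,
# columns: maternal plasma, syncytiotrophoblast cytosol, umbilical artery,
# umbilical vein.
_REFERENCE_CONCENTRATIONS = np.array(
    [
        # maternal, syncytio, umb. artery, umb. vein
        [826.0, 4413.0, 1369.0, 1424.0],  # AcEx
        [170.0, 786.0, 258.0, 270.0],  # Ex
        [338.0, 1145.0, 483.0, 523.0],  # ExF
        [215.0, 1987.0, 238.0, 282.0],  # AcExF
    ]
)


def reference_parameters() -> tuple[Geometry, TransporterParams, BoundaryInputs, SystemState]:
    """The packaged physiological reference parameterisation.

    Returns geometry (30 ml cotyledon; 34 % maternal, 15 % syncytiotrophoblast,
    7.5 % fetal-capillary volume; maternal flow 2 and fetal flow
    0.2 ml min⁻¹ g⁻¹), transporter kinetics (all maximum rates
    0.005 mmol min⁻¹), arterial boundary inputs, and the initial state
    whose compartment columns are maternal plasma, syncytiotrophoblast
    cytosol and umbilical-artery concentrations respectively.
    """
    geometry = Geometry()
    params = TransporterParams()
    conc = _REFERENCE_CONCENTRATIONS
    inputs = BoundaryInputs(in_maternal=conc[:, 0].copy(), in_fetal=conc[:, 2].copy())
    initial = SystemState(conc[:, :3].copy())
    return geometry, params, inputs, initial


def group_fraction(
    concentrations: Mapping[str, float] | np.ndarray,
    numerator_groups: Iterable[str],
) -> float:
    """Fraction of total concentration carried by a subset of groups.

    ``concentrations`` is either a per-group mapping or a vector following
    :data:`GROUPS`.  Raises ``ValueError`` when the total is zero (the
    fraction is undefined).
    """
    if isinstance(concentrations, Mapping):
        vec = np.array([concentrations[g] for g in GROUPS], dtype=float)
    else:
        vec = np.asarray(concentrations, dtype=float)
        if vec.shape != (len(GROUPS),):
            raise ValueError("expected one concentration per group")
    total = vec.sum()
    if total <= 0:
        raise ValueError("total concentration is zero; fraction undefined")
    num = sum(vec[GROUP_INDEX[g]] for g in set(numerator_groups))
    return float(num / total)


def diffusion_timescale(h: float = 1e-5, D: float = 1e-9) -> float:
    """Characteristic intra-cell diffusion time T = h²/D, seconds.

    With the syncytiotrophoblast thickness h ≈ 10⁻⁵ m and an aqueous
    amino acid diffusivity D ≈ 10⁻⁹ m² s⁻¹ this is ≈ 0.1 s — orders of
    magnitude faster than membrane transport, which justifies treating the
    cytosol as well mixed rather than resolving spatial gradients.
    """
    if h < 0 or D <= 0:
        raise ValueError("need h ≥ 0 and D > 0")
    return h * h / D
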