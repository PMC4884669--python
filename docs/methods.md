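# Methods

## Model structure and assumptions

The placental cotyledon is represented as three well-mixed compartments —
maternal intervillous space, syncytiotrophoblast cytosol, fetal
capillaries — exchanging neutral amino acids through four lumped carriers:
a sodium-coupled accumulative transporter and an exchanger on the
microvillous membrane (MVM), and an exchanger and a facilitative carrier
on the basal membrane (BM). Blood flow enters and leaves the maternal and
fetal compartments at constant rates with fixed arterial compositions, so
the fetal compartment concentration doubles as the umbilical venous
concentration. The model's state is the concentration of each of four
substrate groups (AcEx, Ex, ExF, AcExF — named by carrier specificity) in
each compartment: twelve ODEs.

Assumptions worth keeping in mind:

* **Lumping.** All members of a group share one set of kinetic constants,
  and each carrier class on a membrane acts as a single representative
  carrier with symmetric translocation and equal binding on both faces.
  Anionic amino acids (glutamate/aspartate, handled by separate EAAT
  systems) are excluded; the flux laws describe neutral substrates only.
* **Clamped sodium.** The Na⁺ gradient (134 mmol l⁻¹ maternal,
  15 mmol l⁻¹ cytosol) and the membrane potential (−21 mV, cytosol
  negative) are boundary conditions, implicitly maintained by the
  Na⁺/K⁺-ATPase; sodium is not a state variable.
* **Well-mixed cytosol.** Intra-cell diffusion over the ~10 μm
  syncytiotrophoblast thickness has timescale T = h²/D ≈ 0.1 s
  (`diffusion_timescale`), orders of magnitude faster than membrane
  transport, so no spatial gradients are resolved.
* **No metabolism, no paracellular leak, non-pulsatile flow.**

## Flux laws

The exchanger law is a strict 1:1 antiport with a shared carrier pool:
its per-substrate fluxes sum to zero identically (asserted to machine
precision in the tests), so exchangers reshape composition but never move
net mass. A substrate with no counter-substrate on the far side has zero
flux (zero-trans behaviour). The facilitative law is a standard
competitive uniporter. The accumulative law is an ordered-binding
(sodium-first) 1:1 cotransport model in which only the loaded-carrier
translocation is electrogenic; the membrane potential enters through the
bias factors ε = exp(βzFΔψ/RT) and ε′ = exp((β−1)zFΔψ/RT). Two exact
properties anchor this law:

* the zero-flux accumulation ratio for a single substrate is
  (Naᴵ/Naᴵᴵ)·exp(−zFΔψ/RT) — independent of every kinetic constant
  (≈ 19.6 at reference conditions, vs ≈ 8.9 from the bare sodium ratio);
* relabelling the membrane sides while flipping the potential **and** the
  bias split (Δψ → −Δψ, β → 1−β) negates the flux exactly. Note that a
  side swap with only the potential flipped is *not* an exact symmetry
  unless β = ½; both statements are property-tested.

One term of the accumulative denominator is implemented behind a single
definition (`kinetics._denominator_constant`) with two selectable
readings, because its printed source is typographically ambiguous. The
default, `2·K_ac²·K_Na²`, is the only reading in which every denominator
term has dimension concentration⁴, matching the concentration⁴ numerator;
the alternative `2·K_ac·K_Na²` ("literal") shifts reference steady-state
V−A differences by up to ~4%. The dimensional reading reproduces the
reference results and is the packaged default.

## Units and parameters

All internal computation uses μmol l⁻¹, μmol min⁻¹, ml and min; published
parameter tables mixing mmol- and μmol-based units are converted once at
construction. Tissue density is taken as 1 g ml⁻¹, so specific flows
(ml min⁻¹ g⁻¹) scale by the 30 g cotyledon to absolute flows
F_m = 60 and F_f = 6 ml min⁻¹. Compartment volumes are 34% / 15% / 7.5%
of the 30 ml total; the remaining ~43.5% (stroma, endothelium, villous
core) stores no free amino acid and is treated as inert, which is what
the balance equations imply. Defaults that matter:

| parameter | default | meaning |
|---|---|---|
| V_ac, V_ex,mvm, V_ex,bm, V_fa | 5 μmol min⁻¹ | maximum carrier rates, deliberately equal so that activity sweeps start from a symmetric reference |
| K_ex, K_fa | 200, 1000 μmol l⁻¹ | exchanger/facilitative dissociation constants |
| K_ac, K_Na | 2260, 25 070 μmol l⁻¹ | amino acid and sodium dissociation constants of the accumulative carrier |
| β | 0.33 | apportioning of the electrical bias between forward and backward translocation |
| Δψ | −21 mV | cytosol relative to maternal side |

Initial and arterial-input concentrations are physiological group sums
(e.g. maternal AcEx 826, cytosolic AcExF 1987, umbilical-arterial Ex
258 μmol l⁻¹), packaged both in code (`reference_parameters`) and as a
YAML config (`placentaflux/data/reference.yaml`).

## Numerics

* **Integration**: adaptive RK45 (`scipy.integrate.solve_ivp`) at relative
  tolerance 10⁻⁸. The integrator-facing right-hand side clips the tiny
  negative excursions adaptive steppers probe near zero; all flux laws are
  continuous there, and trajectories from non-negative states stay
  non-negative.
* **Steady state**: a state is stationary when every unclamped
  concentration changes by < 10⁻⁶ relative per minute. The solver first
  tries a Newton/hybrid root solve of the right-hand side from the
  initial (or caller-supplied warm-start) state, accepting the root only
  if it is non-negative and stationary; otherwise it integrates in
  doubling chunks (cap 10⁶ min of model time) and polishes. Root-first
  makes sweep grids and fitting cheap (each point milliseconds) and
  avoids integrating the stiff fast modes that appear at high carrier
  activities. Steady states are volume-independent (volumes only scale the
  dynamics), and for the full flow-coupled scenario independent of the
  cytosolic initial condition, which is property-tested.
* **Degenerate inputs**: the exchanger's empty-empty denominator is
  defined as zero flux by continuity; fraction computations on an empty
  compartment raise instead of returning NaN.

## Sensitivity experiments

`experiments` sweeps carrier activities, flows, overall maternal/fetal
concentration scales (initial + input jointly) and the maternal-ExF
addition that represents phenylketonuria (excess phenylalanine, an ExF
member; fetal side untouched — steady states do not depend on initial
conditions, so raising only the maternal input is sufficient). Grids
default to 25 log-spaced factors over 10⁻²–10², with the midpoint snapped
to exactly 1.0 so every sweep contains a bit-identical reference point.
Outputs are long-format tables (one row per grid point per group) carrying
both the V−A difference (μmol l⁻¹) and the molar net transfer
(μmol min⁻¹ = F_f × ΔA); heatmap rendering is left to the caller.

## Activity fitting

`fit_activities` adjusts the four maximum rates to match per-group
umbilical V−A targets (defaults 55, 12, 40, 44 μmol l⁻¹ for AcEx, Ex,
ExF, AcExF) by minimising the equally weighted sum of squared relative
errors Σ((predicted−target)/target)² with Nelder–Mead. Optimisation runs
in log-rate space (positivity by construction; tolerances 10⁻⁶ on simplex
and objective, ≤ 2000 evaluations), warm-starting each steady-state solve
from the previous one. Candidates without a steady state score a large
finite penalty. From the reference start the fit converges in ~460
evaluations (seconds) to multipliers (0.61, 2.8, 33, 4.5) with objective
0.386 and predictions (54.0, 8.3, 32.6, 66.2) μmol l⁻¹.

The objective surface deserves a caveat: it has a nearly degenerate
valley in the (BM-exchange, facilitative) plane — between BM multipliers
×33 and ×80 the objective changes by < 0.5% while the facilitative
multiplier compensates. Reported multipliers for those two carriers are
therefore much less identifiable than the predicted V−A values, and
different optimiser implementations can legitimately stop at different
points along the valley; the predicted V−A differences, not the
multipliers, are the quantity to compare across implementations. The
under-determination disappears when targets are exactly attainable, which
is why parameter self-recovery from model-generated targets succeeds to
< 5% (property-tested).

## Scenarios

* **MVM-only** (BM carriers off, maternal flow on): the cytosol
  accumulates both accumulative substrates (driven by the Na⁺
  electrochemical gradient) and, through exchange, the non-accumulative
  groups; equilibrium levels are set by thermodynamics alone, so scaling
  carrier activities changes approach rates but not the equilibrium
  (property-tested to < 10⁻⁴ relative).
* **BM-only** (cytosol clamped at physiological composition, fetal flow
  on): facilitative substrates are delivered while the exchange-only pool
  ends slightly below its arterial input — reverse transport caused by
  the fetal exchange-substrate fraction (0.69) exceeding the cytosolic
  one (0.62).
* **Full system**: all carriers and flows; the reference steady state
  delivers every group (V−A of 46.1, 2.6, 43.5, 67.4 μmol l⁻¹) and the
  cytosolic AcExF fraction falls from 0.24 to 0.109.

## What the synthetic fixtures do and do not cover

`generate_fixture` draws concentrations at 0.1–10× physiological, kinetic
constants at 0.1–10× reference, β ∈ [0, 1] and Δψ ∈ ±42 mV, for
property-testing flux-law invariants (conservation, antisymmetry,
thermodynamic limits) across a wide parameter envelope. These draws probe
the mathematics, not biology: they do not emulate inter-individual
variability, gestational changes, or correlated parameter uncertainty,
so passing them validates structural correctness of the implementation
rather than physiological realism of any particular draw.

## Known limitations

Per-amino-acid resolution, charged-substrate (system y⁺) transport,
placental metabolism, paracellular diffusion, intra-cytosol gradients,
asymmetric carrier kinetics and Na⁺ stoichiometries other than 1:1 are
out of scope. The fitted multipliers inherit the identifiability caveat
above. Steady-state solutions assume the scenario admits one (flows on or
boundaries clamped); closed no-flow systems conserve mass and are handled
by time integration only.
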