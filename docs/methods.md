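# Methods

## Model

`hhsim` simulates the classic conductance-based membrane model of the squid
giant axon as an electrical circuit of self-contained components: a lipid
bilayer (capacitor), a delayed-rectifier potassium channel, a fast sodium
channel, an always-open leak channel, and a current clamp (grounded
extracellular electrode plus constant-current source). All five sit in
parallel between an extracellular and an intracellular node; the gates of
the sodium and potassium channel additionally receive the membrane
temperature through a signal connection from the bilayer.

### Conventions

All internal quantities use the original displacement convention:

* `v` — displacement voltage in mV, `v = v_extracellular − v_intracellular`,
  0 at rest and *negative* during depolarization;
* time in ms, currents in µA/cm², conductances in mS/cm², capacitance in
  µF/cm², rates in 1/ms. In these units the capacitor law is `dv/dt = i/c`
  with no unit prefactor (a mixed seconds/millivolt formulation would need
  a factor of 1000);
* through-current `i` of a two-pin element flows from the intracellular to
  the extracellular pin, so positive `i` is outward current;
* the measured membrane potential is reported alongside `v` as
  `V_m = E_r − v` with resting potential `E_r = −75 mV`, which matches the
  modern sign convention (rest at −75 mV, overshoot above 0 mV).

### Equations

The flattened system has four states `(v, n, m, h)`:

    c dv/dt = −(i_Na + i_K + i_L + i_clamp)
    i_Na = g_Na_max · m³ h · (v − v_Na)
    i_K  = g_K_max  · n⁴   · (v − v_K)
    i_L  = g_L      · (v − v_L)
    dx/dt = φ (α_x(v) (1 − x) − β_x(v) x),  x ∈ {n, m, h}
    φ = q10^((T − T_ref)/10)

The rate functions are expressed through three reusable fits, each a stored
first-class value on its gate:

* exponential: `sy·exp(sx·x)` (β_n, β_m, α_h),
* logistic: `sy/(1 + exp(sx·(x − x0)))` (β_h),
* linoid ("goldman"): `sy·(x − x0)/(exp(sx·(x − x0)) − 1)` (α_n, α_m), whose
  removable singularity at `x = x0` is evaluated as its analytic limit
  `sy/sx`; `expm1` keeps the quotient accurate near the singularity.

Because the gates store their rate functions, each gate's initial value is
*derived* as the steady state `α(0)/(α(0)+β(0))` at the pre-stimulus holding
potential — changing a fit parameter automatically moves the initialization.
A stimulus is a sudden displacement of the membrane voltage to `v_init`
while the gates remain at their holding-potential steady states.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `c` | 1.0 | µF/cm² | membrane capacitance |
| `g_max_na` / `g_max_k` / `g_max_leak` | 120 / 36 / 0.3 | mS/cm² | maximal conductances |
| `v_eq_na` / `v_eq_k` | −115 / +12 | mV | reversal displacements |
| `v_eq_leak` | −10.59892 (computed) | mV | leak reversal, see below |
| `temperature` / `t_ref` / `q10` | 6.3 / 6.3 / 3 | °C, °C, – | gating-rate temperature scaling |
| `e_rest` | −75 | mV | resting potential for `V_m = E_r − v` |
| `v_init` | −15 | mV | canonical suprathreshold stimulus |
| `i_const` | 0 | µA/cm² | clamp current (positive outward) |

Two deliberate choices:

* **Leak reversal.** The commonly printed value −10.613 mV does not make
  v = 0 an equilibrium of the double-precision rate functions (the residual
  ionic current is ≈ 4.3·10⁻³ µA/cm², enough to drift the resting trace by
  several µV). The leak reversal was always *defined* as the value that
  balances the resting currents, so the default is computed exactly from
  the stored fits: `v_L = −(g_Na m∞³h∞ v_Na + g_K n∞⁴ v_K)/g_L ≈ −10.59892 mV`.
  The unstimulated membrane then rests at −75 mV to solver precision.
* **Q10 and T_ref are not per-gate parameters.** They are fixed properties
  of the 1952 rate parameterization, folded into the gate kinetics as
  constructor defaults rather than declared parameters. This keeps the gate
  declaration at the five items a reader actually faces (n, the two stored
  rate functions, the voltage input and the temperature input).

## Circuit flattening

Electrical connections are resolved by a union-find partition of all pins
(model-level connects plus component-internal ones); each equivalence class
is a connection node carrying one potential and a Kirchhoff current law.
Validation requires exactly one ground, every temperature input bound to
exactly one driver, no directly instantiated partial component, and a
current-defining element on every node.

Flattening uses structural causalization rather than general DAE solving:
node potentials are propagated from the ground reference across capacitive
elements, algebraic branch currents are then evaluated from the node
potentials (gates → conductances → currents), and each capacitor's charging
current is recovered from the current law of one of its nodes — the one
whose other element pins are all algebraic branches. This covers the
supported circuit class (capacitive nodes bridged by parallel branches and
sources), which includes the membrane model and its listed extensions.
Structures outside it — series algebraic chains, floating subcircuits,
capacitor pairs sharing both nodes — raise `UnsupportedStructureError`
instead of being solved implicitly. Evaluation order ties are broken by
declaration order, and all pin-set iterations are sorted by qualified name,
so flattening is deterministic down to floating-point summation order.

## Monolithic oracle

`hhsim.monolithic` is a separate, literal transcription of the flat
equation system that shares no evaluation code with the component library
(only the parameter container is shared). Agreement between the two — the
same vector field on 1000 random states to 1e-10 relative tolerance and
voltage traces within 1e-3 mV over a stimulated 50 ms run — is therefore a
genuine cross-check of the flattening machinery, not a tautology.

## Complexity metrics

The understandability proxy is the number of items (variables, parameters,
equations) a reader must hold in working memory at once. Convention, chosen
as the unique one consistent with a 5-variable/1-equation gate, a
≤2-equation/≤5-variable component bound, and a 3-equation two-pin base
class of which two equations are renamings:

* only locally declared items count per class level (inherited items were
  processed with the base class);
* every connector instance (pin or port), every subcomponent instance and
  every stored replaceable function is one variable;
* alias equations (pure renamings) and initialization rules are not
  counted; connect statements are tallied separately;
* the top-level model is one more unit whose variables are its five
  components and whose ten connects are its connect statements.

The model-wide worst case combines the largest local variable/parameter set
(5, the gate) with the largest local equation set (2, the bilayer's
capacitor law plus temperature source): a simultaneous load of 7. The flat
formulation's annotated enumeration (data, not hard-coded totals) counts 15
equations and 33 variables+parameters, i.e. 48 items at once, giving a
reduction factor of 48/7 ≈ 6.86. The enumeration groups the rate-fit
constants by the three functional forms (linoid 3, exponential 2, logistic
2); a tally that counted every numeral separately would give a larger flat
total and a larger factor, so the grouped count is the conservative choice.

## Numerics

* Default solver: adaptive LSODA with rtol 1e-8, atol 1e-10 mV, sampled on
  a uniform 0.01 ms grid over 50 ms (5001 points). The AP upstroke is stiff
  relative to the plateau; LSODA switches automatically.
* A fixed-step classic RK4 (dt = 0.01 ms, substeps tiling each output
  interval exactly) is provided for bitwise-reproducible runs.
* Gate variables are bounded in [0,1] by the dynamics alone (nonnegative
  rates); traces are never clipped post hoc.
* Analytic benchmark circuits (constant-current ramp, RC relaxation) match
  closed forms to better than 1e-8 mV at rtol 1e-10.
* Node current residuals vanish to 1e-12 relative to the total branch
  current magnitude at every evaluated state (exactly at the causalizing
  node, to summation roundoff elsewhere).

## What the built-in experiments do and do not show

The package generates its own inputs — there is no external data. The
standard experiments (rest at 0 mV displacement, a −15 mV suprathreshold
stimulus, temperature steps 6.3 → 16.3 °C) probe the canonical qualitative
physiology: a stable resting potential, an overshooting action potential
with recovery, Q10 acceleration of the upstroke. They validate the
component framework and the published parameter set against the flat
formulation; they do not validate the model against biological recordings,
spatial propagation (cable effects), stimulus trains, or voltage-clamp
protocols, all of which are out of scope. The slow-inactivation extension
ships with placeholder kinetics (reusing the fast-inactivation fits) to
demonstrate the extension mechanism; realistic slow inactivation operates
on a seconds-to-minutes time scale and would need its own fits.

## Known limitations

* The flattener supports one class of circuits (parallel branches around
  capacitive nodes); general index-reduction DAE handling is a non-goal.
* Temperature is resolved to a constant at flatten time; time-varying
  temperature protocols would require re-flattening.
* The item-counting convention reproduces the published totals for this
  declaration; other reasonable groupings of the fitting constants would
  shift the flat total by a few items in either direction.
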