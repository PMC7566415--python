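# hhsim

A component-based simulator of the Hodgkin-Huxley squid-axon membrane.

Conductance-based action-potential models are usually communicated as a
flat list of coupled equations, which is hard to read for novices and hard
to extend for experts. `hhsim` instead mirrors the biology: a lipid bilayer
(capacitor), sodium/potassium/leak channels with voltage-dependent gates,
and a current clamp are declared as small self-contained components with
documented variables, parameters and equations. Components are wired
through electrical pins — connected pins share one potential and satisfy
Kirchhoff's current law automatically — and through a temperature signal
from the bilayer to the gated channels. A flattener turns the connected
circuit into an explicit ODE system that is integrated with a stiff solver.

The library is aimed at electrophysiology teaching and at prototyping
Hodgkin-Huxley-type channel models: channels share base classes
(`TwoPinComponent → IonChannel → GatedIonChannel`), gates store their rate
fits as replaceable values, and extensions (slow sodium inactivation,
steady-state/time-constant gate parameterizations) reuse the same
interfaces.

## The model

In the 1952 displacement convention (v = 0 at rest, negative during
depolarization; ms, mV, µA/cm², mS/cm²):

    c dv/dt = −(i_Na + i_K + i_L + i_clamp)
    i_Na = ḡ_Na m³h (v − v_Na)     i_K = ḡ_K n⁴ (v − v_K)     i_L = ḡ_L (v − v_L)
    dx/dt = φ (α_x(v)(1 − x) − β_x(v) x),   x ∈ {n, m, h}
    φ = q10^((T − 6.3)/10)

with ḡ_Na/ḡ_K/ḡ_L = 120/36/0.3 mS/cm², v_Na/v_K = −115/+12 mV, c = 1 µF/cm²
and the classic α/β rate fits. The leak reversal defaults to the value that
makes v = 0 an exact resting equilibrium (≈ −10.599 mV). Traces report both
v and the measured potential V_m = E_r − v with E_r = −75 mV. An
independent monolithic transcription of the same equations serves as an
oracle: the flattened circuit and the flat system agree to 1e-10 on the
vector field and to better than 1e-3 mV on simulated voltage traces. A
metrics module tallies how many items (variables, parameters, equations) a
reader must hold in working memory per component versus all at once in the
flat formulation.

## Worked example

Simulate an action potential: a membrane held at rest is suddenly displaced
by a 15 mV depolarizing stimulus (`v_init = −15` in the displacement
convention) and left to develop at 6.3 °C:

```bash
$ hhsim run --model modular --v-init -15 --out ap.csv
modular model: 5001 samples over 50.0 ms (stiff solver) -> ap.csv
$ head -3 ap.csv
time_ms,V_mV,Vm_mV,n,m,h,iNa_uAcm2,iK_uAcm2,iL_uAcm2
0,-15,-60,0.317676914,0.0529324853,0.596120754,1.06091928,-9.8994003,-1.32032371
0.01,-14.8998557,-60.1001443,0.318211947,0.0574525182,0.595172643,1.35577031,-9.92929406,-1.29028042
```

The trace starts at V_m = −60 mV (rest −75 mV plus the 15 mV stimulus) with
the gates at their resting steady states n∞ = 0.318, m∞ = 0.053, h∞ = 0.596.
The sodium current activates regeneratively: V_m peaks at **+30.41 mV after
1.16 ms**, then the potassium current repolarizes the membrane back to
−75.00 mV by 50 ms.

The same experiment in Python:

```python
from hhsim import ExperimentConfig, run_modular

trace = run_modular(ExperimentConfig(v_init=-15.0))
print(trace.V_m.max())   # 30.414... (mV, overshoot above 0)
```

Check the modular circuit against the monolithic oracle, and inspect the
cognitive-load accounting:

```bash
$ hhsim compare --duration 50
max_abs_diff=3.286615e-09 mV  rmse=1.398318e-10 mV
$ hhsim metrics | tail -4
monolithic: 15 equations, 33 variables+parameters (total 48)
modular worst-case simultaneous load: 7 (≤5 variables/parameters, ≤2 equations)
reduction factor: 6.857
```

Reading the modular model one component at a time never requires more than
five variables/parameters and two equations simultaneously; the flat
formulation presents all 48 items at once — a reduction factor of about 6.9.
`hhsim dot` exports the five-component topology (solid electrical
connections, dashed red temperature bindings) as Graphviz DOT, and
`hhsim run --config exp.yaml` reads experiment settings and qualified
parameter overrides (e.g. `sodiumChannel.g_max`) from a JSON/YAML file.

## Layout

- `src/hhsim/circuit_core.py` — acausal component/connector framework,
  node partition, validation, flattening
- `src/hhsim/hh_library.py` — fits, gates, bilayer, channels, clamp,
  model builders and extensions
- `src/hhsim/monolithic.py` — independent flat transcription (oracle) and
  its annotated item enumeration
- `src/hhsim/simulation.py` — solvers, traces, output conventions,
  comparison
- `src/hhsim/metrics.py` — item counts, load profile, reduction factor
- `src/hhsim/cli.py` — `hhsim run|compare|metrics|dot`, config files,
  DOT export
- `docs/methods.md` — modeling conventions, counting rules, numerics and
  limitations
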