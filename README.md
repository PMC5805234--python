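# glucoloop

A closed-loop, multi-level ODE simulator of human glucose homeostasis for
systems biologists and physiological modelers.  The package couples a
whole-body hormonal layer — plasma glucose `G`, insulin `I`, incretins `W`,
glucagon `E`, leptin `Y`, ghrelin `Q`, a hunger signal `H`, and glucose
masses in stomach `S`, intestine `L`, liver `C`, muscle `M` and adipose
tissue `A` — to a 27-species mass-action model of the insulin-signaling
cascade in adipocytes, from receptor binding down to GLUT4 translocation.

The loop is closed through appetite: ghrelin (secreted by the empty
stomach) drives hunger, leptin and insulin suppress it, and intake `b9·H`
refills the stomach — so an *in silico* subject feeds itself and the model
self-sustains recurrent meals with no external forcing.  Two condition
presets are provided: normal glucose regulation (**NGR**) and type 2
diabetes (**T2DM**, with reduced insulin effectiveness `e`, increased fat
mass, raised basal glucose/insulin, elevated hepatic glucose production,
and reduced insulin-receptor/GLUT4 pools and mTORC1 feedback).

## Model sketch

Whole-body dynamics (14 ODEs), e.g. plasma glucose and the hunger signal:

    dG/dt = f·b10·L/v + f·b5·C/v − b1·G − b3·I·G
    dH/dt = b17·Q/(b18·Y + 1)·exp(−r·I) − b19·G·H − b9·H

with a Heaviside-gated glucagon secretion term `c1/(c2 + I·e)·(Ge − G)·u(Ge − G)`.
The two layers communicate through interstitial deviations
`dINS_A/dt = −p2U·INS_A + p2U·(I − Ib)⁺` and
`dGt_A/dt = −q1·Gt_A + q2·(G − Gb)⁺`; interstitial insulin drives the
receptor cascade, and glucose uptake returns through saturating GLUT1/GLUT4
transport: `k8·GLUT4m·Gt_A/(KmG4 + Gt_A) + GLUT1·Gt_A/(KmG1 + Gt_A)`.
The cellular layer is pure mass action over ten conserved protein cycles
(receptor, IRS1, X, PKB, mTORC1/2, AS160, GLUT4, S6K, S6); a declarative
reaction network compiles to the same right-hand side and doubles as an
independent oracle and SBML exporter.

Eight whole-body parameters (`b4, b5, b12, b13, b17, b27, c, c3`) are not
stored: they are derived at preset-build time by imposing a fasting steady
state on their equations (see `glucoloop.parameter_workflow`).

## Worked example

```python
import numpy as np
import glucoloop as gl

preset = gl.condition_preset("NGR")
config = gl.SimulationConfig(duration=1000.0)
traj = gl.simulate(preset, config)

meals = gl.detect_meals(traj, variable="S")
print("meal times (min):", np.round(meals).astype(int).tolist())
print("plasma glucose range (mg/dL): %.1f - %.1f"
      % (traj["G"].min(), traj["G"].max()))
print("max conserved-total drift: %.2e"
      % max(traj.metadata["conserved_drift"].values()))

t2dm = gl.simulate(gl.condition_preset("T2DM"), config)
print("NGR vs T2DM glucose excursion (mg/dL): %.1f vs %.1f"
      % (np.ptp(traj["G"]), np.ptp(t2dm["G"])))
```

prints

```
meal times (min): [71, 467, 802]
plasma glucose range (mg/dL): 85.4 - 135.3
max conserved-total drift: 1.44e-10
NGR vs T2DM glucose excursion (mg/dL): 49.9 vs 53.8
```

Three meal episodes emerge over 1000 simulated minutes (detected as
prominent stomach-glucose peaks ~5.5 h apart), plasma glucose stays inside
the normal fasting-to-postprandial band, the ten cellular protein totals
are conserved to ~1e-10 relative, and the matched T2DM run shows the wider
glucose excursion expected under insulin resistance, together with lower
adipose/muscle glucose uptake, lower membrane GLUT4 and higher leptin.

A command-line interface wraps the same calls:

```
glucoloop simulate --condition NGR --duration 1000 --out traj.csv
glucoloop detect-meals --in traj.csv
glucoloop simulate --condition T2DM --duration 500 --out c.csv --clamp INS_A=0
glucoloop estimate-params --condition NGR --seed 17 --out params.json
glucoloop sensitivity --condition NGR --params all-estimated --out sens/
```

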