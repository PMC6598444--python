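# mtpattern

A rate-model simulator of the primate V1 → MT motion pathway that shows how
**pattern** versus **component** motion selectivity can arise in MT neurons
from the relative strength of their V1 inputs, without a hierarchy of
component-to-pattern cells.

When two bars (or gratings) cross and move in different directions, humans
perceive a single coherent "pattern" motion — the motion of the intersection
point (an *extrinsic terminator*).  MT neurons split into *pattern cells*,
tuned to that coherent direction, and *component cells*, tuned to each bar's
own (aperture-limited) direction.  This package implements a network model of
that computation:

- **Complex V1 cells** — opponent motion energy from quadrature Gabor pairs
  and biphasic multi-stage temporal filters
  `g_n(t) = (t/τ_g)^n e^(−t/τ_g) [1/n! − (t/τ_g)²/(n+2)!]` with n = 6 and 9.
- **End-stopped V1 cells** — shunting dynamics
  `dv/dt = (1−v)·G₁v_cx − v·(τ_es + G₂Γ)` with a threshold-gated, discretised
  Gaussian inhibition patch Γ, so activity survives only at line endings
  (terminators).
- **V1-ECRF cells** — orientation-selective form cells with suppressive
  extra-classical surrounds: an oriented difference-of-Gaussians
  `R = A_C e^(−(x²/σ_xc²+y²/σ_yc²)) − A_S e^(−(x²/σ_xs²+y²/σ_ys²))` applied to
  the reversed stimulus intensity and saturated.  Their output gates the
  motion signal (κ), silencing it at extrinsic terminators.
- **MT integration and segmentation populations** — recurrent rate units,
  `dv_ig/dt = h(G_igcx v_cx + G_iges v_es + G_igig2 λ + G_igcs κ − G_igig1 γ −
  G_igig3 ζ − G_igsg v_sg − τ_ig v_ig)` and the analogous segmentation
  equation, stepped with forward Euler.  Integration cells propagate
  terminator motion through facilitatory same-direction surrounds;
  segmentation cells detect motion discontinuities.

Two gains are the experiment levers: `G_igcs` (form-gated complex drive) and
`G_sges` (end-stopped inhibition of segmentation cells).  Their ratio moves
the network between component and pattern selectivity, quantified by the
pattern index `P_I = S_P − S_C`.

## Worked example

```python
import numpy as np
import mtpattern as mp
from mtpattern.experiments import (run_v1_maps, run_timecourse,
                                   PATTERN_EXEMPLAR, COMPONENT_EXEMPLAR)

v1 = run_v1_maps("crossing")
print({k: round(v, 3) for k, v in v1.stats.items()})

tc = run_timecourse(PATTERN_EXEMPLAR)     # G_igcs = 0.1, G_sges = 0.8
print("crossing time:", tc["crossing_time"])
```

prints

```
{'es_terminator_mean': 1.046, 'es_edge_mean': 0.148,
 'es_terminator_edge_ratio': 7.075, 'cx_terminator_edge_ratio': 1.279,
 'cs_extrinsic_mean': 0.075, 'cs_intrinsic_mean': 0.224}
crossing time: 2.94
```

End-stopped activity at the bar terminators is ~7× the activity along the bar
edges (complex cells show no such accentuation: ratio 1.3), and the form
cells are suppressed at the crossing (0.075) relative to the true bar ends
(0.224) — the two cues the MT stage feeds on.  Under pattern-regime gains the
probe on a bar's edge first follows the bar's own oblique direction and is
overtaken by the upward pattern direction after a delay of 2.94 time units;
under component-regime gains (`COMPONENT_EXEMPLAR`) no such crossover occurs.

A gain sweep maps the regimes:

```python
from mtpattern.experiments import run_gain_sweep
sweep = run_gain_sweep((0.0, 0.5, 1.0), (0.0, 0.5, 1.0))
print(sweep.pi_matrix().round(3))
```

```
G_igcs    0.0    0.5    1.0
G_sges
0.0     0.000 -0.307 -0.520
0.5     0.474  0.065 -0.245
1.0     0.819  0.350  0.000
```

The pattern index falls monotonically with the
form-pathway gain and rises with the end-stopped inhibition of segmentation,
changing sign across the grid — positive = pattern-selective, negative =
component-selective.

## Command line

```bash
mtsim stimgen --preset pattern --out stim.h5
mtsim run --stimulus stim.h5 --gigcs 0.1 --gsges 0.8 --out fields.h5
mtsim v1maps --preset crossing --out-dir out/
mtsim sweep --grid 3 --out sweep.csv
mtsim timecourse --regime pattern
```

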