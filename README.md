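# progplan

An open sandbox for **automatic progressive VMAT plan optimization** in
thoracic radiotherapy.  Scripted automatic planning workflows generate
lung-cancer treatment plans by starting from a deliberately loose
objective template and repeatedly *tightening* the conformity-driving
objectives toward what the evolving plan actually achieves.  Evaluating
such a loop normally requires a commercial treatment planning system;
`progplan` re-creates every ingredient in plain scientific Python so the
algorithm itself can be exercised, audited and extended:

* **phantom** — parameterized voxel thorax (body, lungs, heart, spinal
  cord, CTV/PTV) plus the derived optimization structures `ring`
  ((PTV+1.3 cm)\\(PTV+0.3 cm)), `nt` (body\\(PTV+1.3 cm)), `sp0.3`,
  `lung-ptv`;
* **dose_engine** — sparse beamlet influence matrix for six partial arcs
  (182°–230°, 300°–60°, 130°–178° and their opposites) from a simplified
  pencil-beam model (attenuation × inverse square × Gaussian penumbra);
* **objectives** — MinDose/MaxDose, MinDvh/MaxDvh, MinEud/MaxEud
  (gEUD = (mean dᵃ)^{1/a}), and DoseFallOff, each with an analytic
  gradient and a normalized *feedback value*;
* **optimizer** — projected-gradient fluence solve, prescription
  normalization (D95 → Rx), and a sliding-window leaf sequencer;
* **progressive** — the three-phase loop: optimize → normalize →
  evaluate feedback → tighten adaptive targets by 0.98 while feedback
  < 4·10⁻⁴ → converge when the ring/normal-tissue/falloff objectives are
  binding, with a reset after 3 cycles to bound plan complexity;
* **evaluate / report** — DVH metrics (VxGy, Dx%, Dxcc, Dmean), Paddick
  conformity index (TV∩PIV)²/(TV·PIV), homogeneity index
  (D2%−D98%)/D50%, aperture edge-metric complexity
  M = (1/MU)·Σ MUᵢ·yᵢ/Aᵢ, clinical-goal checking, and paired
  Wilcoxon comparison tables.

The prescription is 6000 cGy in 30 fractions; plans are normalized so
95% of the PTV receives 100% of the prescription.

## Worked example

```python
from progplan import workflow

result = workflow.run_standard_case(seed=7)   # a few minutes on one CPU
print(result.log.status)
print(result.goals[["goal", "achieved", "pass"]].to_string())
```

Output (4 mm grid, six arcs at 6° control-point spacing, seed 7):

```
best_effort_after_reset
                               goal     achieved   pass
0               ptv V60Gy (%) >= 95    95.003391   True
1          ptv D0.03cc (cGy) < 6900  6484.114435   True
2                      ptv CI > 0.8     0.950034   True
3              lungs V30Gy (%) < 18    22.402908  False
4              lungs V20Gy (%) < 28    27.672555   True
5               lungs V5Gy (%) < 50    37.208511   True
6          lungs Dmean (cGy) < 1250  1274.494847  False
7              heart V30Gy (%) < 40     2.251407   True
8          heart Dmean (cGy) < 2500   379.570020   True
9  spinal_cord D0.03cc (cGy) < 4500  2665.640806   True
```

Reading this: normalization pins PTV coverage at the prescription
(V60Gy ≥ 95%), the near-maximum dose stays under 115% of the
prescription, and the tightened ring/falloff objectives push the Paddick
conformity index to 0.95.  The lung mid-dose metrics (V30Gy, mean lung
dose) land above their goals at this geometry — all six coplanar arcs
traverse lung — while V20Gy, V5Gy, heart and cord goals are met.  The
`best_effort_after_reset` status means the loop used its
complexity-control branch: after three cycles the plan is reset once and
the best cycle is returned.

The same run is available from a shell:

```bash
progplan run --out results/demo --seed 7
```

which writes the dose grid (NIfTI), apertures (JSON), the cycle-level
run log (JSON lines), metrics (JSON) and the goal table (CSV).

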