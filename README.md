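# vortexhab

Cross-sectional vorticity analysis for fish spawning habitat hydraulics.

*Schizothorax prenanti*, a fish endemic to the mountain rivers of southwestern
China, spawns in "rolling and upwelling" water: compound-channel river
sections carrying strong coherent vortices near the bed. This package
quantifies that preference and turns it into a restoration-assessment tool
for river scientists and ecological engineers:

1. **Vorticity metrics** — per-cell streamwise vorticity of a gridded
   transect velocity field and its cross-sectional summaries,
   `Ω̄ = Γ / A_TOT = Σ |Δv_z/Δy − Δv_y/Δz| ΔyΔz / Σ ΔyΔz`,
   reported for the full section and for the near-bed layer (bed to 1.3 m),
   split into left / middle / right thirds of the wetted width.
2. **Group contrast** — a Wilcoxon rank-sum test (mid-ranks, tie-corrected
   variance, lower-tailed at α = 0.05 by default) comparing the pooled
   cell-level vorticity of spawning vs non-spawning sections, with an exact
   enumeration oracle for small samples.
3. **Vague-set similarity** — a reach's mean vorticity is mapped to a vague
   value `[t, 1−f]` by a piecewise-linear membership family anchored on the
   natural suitable interval 0.17–0.35 s⁻¹ (boundary 0.02–1.0 s⁻¹); two
   reaches are compared with
   `SIM = 1 − |Δt − Δf|/4 − (|Δt| + |Δf|)/4`,
   classified on a five-band scale, and a restoration is *effective* when
   SIM rises by more than 5%.
4. **Synthetic flow generator** — Lamb–Oseen (optionally Rankine) vortices
   over parametric compound / V-shaped / flat bed profiles with an exact
   analytic curl, so every metric can be validated against a closed-form
   oracle without a CFD solver.

## Worked example

Run the demo reach — three spawning, two transition and three non-spawning
synthetic sections, calibrated to section means observed in a natural reach:

```bash
python analysis/02_run_demo_reach.py
```

which ends with

```
Spawning/non-spawning ratio of full-section band means: 2.00
Rank sum: Z = -31.34 (reject H0 at alpha = 0.05, lower-tailed)
```

i.e. spawning sections carry about twice the band-mean vorticity of
non-spawning sections, and the cell-level distributions differ decisively
(the non-spawning group ranks far below, so the lower-tail Z is large and
negative). Scoring a restoration with the vague-set model:

```bash
python analysis/04_score_restoration.py
```

```
Before restoration: mean 0.100 1/s -> SIM 0.569 (Low)
After restoration:  mean 0.177 1/s -> SIM 0.874 (Good)
Rate of SIM increase: +53.7% -> effective (threshold 5%)
```

A degraded reach sitting at the 0.10 s⁻¹ non-spawning baseline is only
"Low"-similar to a natural spawning reach (0.26 s⁻¹); lifting its mean
vorticity to 0.177 s⁻¹ moves it into the "Good" band, a 53.7% SIM increase —
well past the 5% effectiveness threshold.

The same stages are available from the shell via the `vortexhab` CLI
(`generate`, `compute`, `compare`, `score`, `run`), and as a library:

```python
from vortexhab import generate_scenario, build_section_geometry, \
    evaluate_velocity, compute_cell_vorticity, mean_vorticity

spec = generate_scenario("spawning", seed=0)
grid = evaluate_velocity(spec, build_section_geometry(
    spec.bed, spec.ny, spec.nz, spec.water_surface))
field = compute_cell_vorticity(grid)
print(mean_vorticity(field, grid.wet))   # ~0.26 s^-1, inside 0.17-0.35
```

## Analysis scripts

- `analysis/01_reference_tables.py` — recomputes the published reference
  section means from their printed band values (all match at five decimals,
  one cell up to a printed rounding slip) and the 2.64 spawning/non-spawning
  contrast; writes `results/reference_summary.csv`.
- `analysis/02_run_demo_reach.py` — simulates the demo reach end to end;
  writes `results/demo/`.
- `analysis/03_rank_sum_calibration.py` — oracle agreement and null
  rejection rate of the rank-sum test; writes
  `results/ranksum_calibration.json`.
- `analysis/04_score_restoration.py` — similarity sweep and a worked
  before/after restoration case; writes `results/similarity_sweep.csv`.

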