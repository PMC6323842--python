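# breath4d

Simulation toolkit for quantifying how **heterogeneous respiratory
motion** breaks the dose bookkeeping of phase-sorted 4DCT in lung
stereotactic body radiotherapy (SBRT), and for testing a
probability-density-based robust-ITV planning strategy that mitigates
it.

## The problem

A traditional 4DCT sorts the breathing signal into ten phases of a
*single* representative cycle. Treatment plans (here: 60 Gy in 5
fractions prescribed to the ITV, the union of the GTV over the ten
phase positions) are evaluated by accumulating the plan dose over
those ten phases — the "4D dose" D⁴ᴰ. Real patients do not breathe
one cycle: amplitude and period fluctuate, so the tumor regularly
travels beyond the range the planning 4DCT saw, and the dose actually
accumulated over the whole session — the "true dose" Dᵗʳᵘᵉ — can be
lower than D⁴ᴰ suggests.

`breath4d` builds this experiment end to end, in silico:

* **Motion model** — per cycle, SI displacement
  `Z(t) = A (cos⁴(πt/P) − ½)`, with peak-to-peak amplitude
  `A ~ N(μ_A, σ_A)` and period `P ~ N(μ_P, σ_P)` drawn per cycle;
  sessions last ~100 s. Fiducial-like patient traces add 30 Hz
  sampling and Gaussian measurement noise.
* **Phantom** — a 1-mm voxel grid with a spherical GTV (2/3/4 cm) at
  integer SI offsets in [−15, 15] mm; 3 × 31 = 93 phase-tagged sample
  geometries; phase mapping `P = ⌊(i+15)/3⌋` (with `i = 15 → P = 9`).
* **Dose surrogate** — an analytic stand-in for the clinical VMAT
  plan: prescription exactly on the ITV surface, maximum
  `Rx / isodose-level` on an interior plateau, Gaussian penumbra
  outside. All downstream numbers reproduce the *qualitative*
  structure of the clinical study, not its TPS-computed values.
* **Accumulation** — rigid SI shifts of the reference GTV;
  `D(e) = (1/I) Σᵢ d(xᵢ(e))` with I = 10 for D⁴ᴰ (one cycle's phase
  samples) and I ≈ 250 for Dᵗʳᵘᵉ (whole trace at 0.4 s); coverage via
  `D_x`, the largest dose level (% of Rx) covering x% of the GTV.
* **Evaluation** — the per-curve worst-case deviation
  `ΔD̄ₓ = Σⱼ maxₖ |D⁴ᴰₓⱼₖ − Dᵗʳᵘᵉₓⱼ| / (J · Dᵗʳᵘᵉₓⱼ) × 100%`,
  parameter sweeps with linear trend fits, and paired t / Wilcoxon
  comparison of standard vs robust plans.
* **Robust strategy** — extend the phase-position set with every
  integer mm of the central 80% interval of the empirical tumor
  position pdf, rebuild the ITV, and re-evaluate Dᵗʳᵘᵉ per fraction.

## Worked example

```python
import numpy as np
from breath4d import motion, evaluate as ev, workflow

# worst-case 4D-vs-true dose deviation across breathing amplitudes
rows = [
    dict(mean_excursion_mm=a, excursion_cv=0.25, mean_period_s=4.0, period_cv=0.2)
    for a in (5.0, 10.0, 15.0, 20.0)
]
summary, records = ev.run_sweep(rows, replicates=10, base_seed=2)
print(summary[["mean_excursion_mm", "delta_d99_pct", "delta_d95_pct"]].to_string(index=False))

fit = ev.fit_trend(summary["mean_excursion_mm"], summary["delta_d99_pct"])
print(f"linear trend: slope {fit.slope:.3f} %/mm, R^2 {fit.r_squared:.3f}")

# pdf-based robust replanning for the most irregular breather
res = workflow.patient_robust_comparison(
    motion.PATIENT_MOTION_CHARACTERISTICS[3], base_seed=300000
)
comp = res["comparison"]
print("80% position interval:", res["coverage_interval_mm"])
print(f"mean improvement {comp.mean_difference_pct:.2f}% (paired t p = {comp.t_pvalue:.4f})")
```

prints

```
 mean_excursion_mm  delta_d99_pct  delta_d95_pct
               5.0       0.908015       0.829561
              10.0       1.609674       1.471234
              15.0       9.294943       6.063380
              20.0      10.958598       7.866357
linear trend: slope 0.757 %/mm, R^2 0.892
80% position interval: (-9, 7)
mean improvement 0.35% (paired t p = 0.0000)
```

Reading: with a 5-mm mean excursion the ten-phase accumulated dose is
a faithful summary (worst-case D₉₉ deviation < 1% of the true dose),
but at 15–20 mm the worst cycle of a session misrepresents the true
D₉₉ by ~9–11% — heterogeneous motion carries the tumor beyond the
planning ITV, where the dose falls off steeply. For the emulated
irregular breather (≈15 mm excursion, CV ≈ 0.22), extending the ITV to
the central 80% of the measured position distribution (−9 to +7 mm
instead of the planning curve's −7 to +7 mm) raises the true D₉₉ in
every fraction, by 0.35% of prescription on average (paired t,
p < 0.01).

A command-line layer wraps the same pipeline for archived,
reproducible runs:

```bash
breath4d simulate --config run.yaml   # scenario bank of trace CSVs + manifest
breath4d evaluate --config run.yaml   # sweep summary CSV, trend fits, report
breath4d robust   --config run.yaml   # standard-vs-robust paired comparison
breath4d report   --run runs/default  # provenance (config hash, seeds, versions)
```

## Layout

| module | contents |
| --- | --- |
| `breath4d.motion` | cos⁴ cycle model, scenario grid, patient tables, trace generators, CSV I/O |
| `breath4d.processing` | zero-phase low-pass filter, cycle segmentation, phase sampling, position pdf + coverage interval |
| `breath4d.phantom` | voxel grid, sphere masks, phase mapping, ITV, 93-sample bank |
| `breath4d.dose` | plan spec, analytic dose surrogate, pdf-extended robust plan |
| `breath4d.accumulate` | rigid shift sampling, mean-dose accumulation, D_x, DVH |
| `breath4d.evaluate` | ΔD̄ₓ, sweeps, trend fits, paired comparisons |
| `breath4d.workflow` / `breath4d.cli` | configs, archived runs, provenance, CLI |

See `docs/methods.md` for the model assumptions, numerical choices
and known limitations.
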