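# entasis

Analysis toolkit for the energetics of electron transfer at a
metalloprotein active site held in an *entatic* state — a geometry the
protein scaffold pins between the optima of the oxidized and reduced
forms, lowering the reorganization energy and hence speeding electron
transfer. The motivating system is the blue-copper
Cu–S(cys)/Cu–S(met)/Cu–N(his)₂ site, but the operations are generic to
any two-state redox site sampled by simulation.

It is written for computational chemists who already have trajectories
(PDB/XYZ frames) and per-frame two-state energies (TSV), and need the
analysis layer: geometry statistics, linear-response estimators, Marcus
rates, strain energies — plus a synthetic two-state generator to validate
the whole chain without an electronic-structure engine.

## What it computes

Given trajectories sampled on each redox surface with vertical energy
gaps ΔE = E_ox − E_red per frame:

- **Reorganization energy and driving force** (linear response):
  λ = ½(⟨ΔE⟩_red − ⟨ΔE⟩_ox), ΔG = ½(⟨ΔE⟩_red + ⟨ΔE⟩_ox), plus the
  variance diagnostic λ_var = σ²/(2k_BT) whose agreement with λ tests the
  approximation itself.
- **Marcus rate** k_ET = (|V|²/ħ)√(π/λk_BT)·exp[−(λ+ΔG)²/(4λk_BT)] on a
  grid of diabatic couplings |V|.
- **Coordination geometry**: internal-coordinate summary tables (mean and
  RMS fluctuation, circular statistics for angles), the τ4 four-coordination
  index (360° − (α+β))/141°, Kabsch RMSD series, ensemble-average
  structures, and the RMSD–gap Pearson correlation.
- **Strain energy**: site energy at its in-protein (ensemble-average)
  geometry minus at its optimized geometry, on the same surface.
- **Surrogate data**: a two-state displaced-harmonic model with exact
  Boltzmann sampling (or a Metropolis chain with a deliberate
  equilibration transient), closed-form λ/ΔG/strain references, and an
  embedding that emits toy active-site trajectories.

Units throughout: Å, kcal/mol, ps, K.

## Worked example

Trajectory gap means of ⟨ΔE⟩_red = 82.5 kcal/mol and
⟨ΔE⟩_ox = −29.2 kcal/mol (the oxidized mean taken from 3 ps onward to
drop its equilibration transient):

```python
from entasis import GapStatistics, reorganization_energy, driving_force, tau4

red = GapStatistics(mean_delta_e=82.5, sd_delta_e=11.2, n_frames=4000,
                    discarded_before=0.0, state="reduced")
ox = GapStatistics(mean_delta_e=-29.2, sd_delta_e=9.0, n_frames=3700,
                   discarded_before=3.0, state="oxidized")
lam = reorganization_energy(red, ox)
print(f"lambda = {lam:.2f} kcal/mol  (prints as {lam:.1f} at 1 d.p.)")
print(f"delta_G = {driving_force(red, ox):.2f} kcal/mol")
print(f"tau4(reduced site) = {tau4([113.8, 118.3, 103.9, 108.8]):.2f}")
```

```
lambda = 55.85 kcal/mol  (prints as 55.9 at 1 d.p.)
delta_G = 26.65 kcal/mol
tau4(reduced site) = 0.91
```

λ = 55.9 kcal/mol is the mean-gap reorganization energy implied by those
two trajectory averages; τ4 = 0.91 says the reduced coordination cage is
nearly tetrahedral (1 = tetrahedral, 0 = square planar).

The same analysis runs end-to-end from a config. With a surrogate block
(equal force constants 50 kcal mol⁻¹ Å⁻² on 4 coordinates, minima
displaced 0.15 Å, ε = 5 kcal/mol — analytic λ = 2.25 kcal/mol, ΔG = 5):

```sh
entasis run --config config.yaml --out out --seed 1
```

```
INFO entasis: state reduced: sampled 5000 surrogate frames (seed 1)
INFO entasis: state reduced: discard_before=0 ps keeps 5000 of 5000 frames; <dE>=7.287 sd=1.618 kcal/mol
INFO entasis: state oxidized: sampled 5000 surrogate frames (seed 2)
INFO entasis: state oxidized: discard_before=0 ps keeps 5000 of 5000 frames; <dE>=2.727 sd=1.628 kcal/mol
```

and `out/report.json` contains (abridged):

```json
{
  "lambda": 2.27993,
  "lambda_1dp": "2.3",
  "delta_g": 5.00706,
  "surrogate_analytic": {"lambda_eq3": 2.25, "delta_g_mean_based": 5.0},
  "states": {"reduced": {"lambda_var": 2.19507,
                         "tau4": {"per_frame_mean": 1.00041,
                                  "average_structure": 1.00038}}}
}
```

The sampled λ (2.28) and λ_var (2.20) bracket the closed-form 2.25 within
Monte-Carlo error, ΔG recovers ε = 5, and τ4 ≈ 1.00 reflects the
tetrahedral template — the parameter-recovery loop that validates the
estimator chain. `entasis simulate` writes the surrogate trajectories and
gap tables to files; `entasis analyze` consumes files produced by any
engine. The report also carries the experimentally measured λ range for
the blue-copper site (16–28 kcal/mol) as display-only context.

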