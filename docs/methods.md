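# Methods

`entasis` analyses the thermodynamics of electron transfer at a
four-coordinate metalloprotein active site — the blue-copper
(Cu–S(cys)/Cu–S(met)/Cu–N(his)×2) motif is the motivating case — from two
trajectories, one sampled on the oxidized surface and one on the reduced
surface, each carrying per-frame vertical energy gaps ΔE = E_ox − E_red.
The electronic-structure engine that produces coordinates and energies is
out of scope: the package consumes its outputs (PDB/XYZ frames, TSV gap
tables) and, for testing and demonstration, generates statistically
equivalent synthetic data from a two-state harmonic surrogate.

## Model and estimators

**Linear response.** If gap fluctuations are Gaussian with
state-independent variance, the reorganization energy and driving force
follow from the two trajectory means alone:

    λ  = ½(⟨ΔE⟩_red − ⟨ΔE⟩_ox)
    ΔG = ½(⟨ΔE⟩_red + ⟨ΔE⟩_ox)

with the exact algebraic identities λ + ΔG = ⟨ΔE⟩_red and
λ − ΔG = −⟨ΔE⟩_ox. The variance route λ_var = σ²/(2 k_B T) must agree with
the mean route when the approximation holds; the package computes both and
reports the gap between them as a diagnostic, never reconciling them
silently.

**Marcus rate.** k_ET = (|V|²/ħ)·√(π/(λ k_B T))·exp[−(λ+ΔG)²/(4 λ k_B T)].
Constants are fixed in code in the per-mole convention
(k_B = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, ħ = 1.51787×10⁻¹⁴ kcal s mol⁻¹) so
that molar energies and a rate in s⁻¹ are dimensionally consistent. The
diabatic coupling |V| is never estimated by the package; rates are
computed on a user-configured grid of couplings.

**τ4 geometry index.** τ4 = (360° − (α + β))/141° with α, β the two
largest coordination angles (multiset selection: a tied maximum counts
twice). 0 is square planar, 1 tetrahedral. Two evaluation modes exist for
trajectories — mean of per-frame τ4, and τ4 of the ensemble-average
structure — because the two genuinely differ on a fluctuating site; the
report carries both and asserts neither.

**Strain energy.** Energy of the site at its in-protein (ensemble-average)
geometry minus at its freely optimized geometry, on the same surface. The
package performs the subtraction and the ensemble averaging; the two
surface energies themselves must come from an external electronic-structure
calculation (or from the surrogate, where they are closed-form). A
negative strain raises a warning: the "optimized" input was not a minimum.

**Geometry statistics.** Summary tables report, per internal coordinate,
the mean over frames and the population (divide-by-n) RMS fluctuation.
Angles, dihedrals and impropers use circular statistics (mean by
atan2 of averaged sines/cosines, deviations wrapped into (−180°, 180°]),
so a torsion oscillating across the ±180° seam averages to 180°, not 0°.
Gap series use the sample (n−1) standard deviation instead, since there
they estimate a distribution width; the difference is negligible at
trajectory length but both conventions are stated.

**Superposition.** Kabsch SVD with the determinant correction, unweighted,
proper rotations only. The superposition target for ensemble averaging is
frame 0 in a single pass (no iterated mean structure), which keeps the
operation deterministic. Fewer than 3 atoms or a collinear subset is an
error rather than a silently arbitrary rotation.

## The surrogate generator

The synthetic engine is a pair of diagonal quadratic surfaces over n_d
active-site coordinates x (Å):

    E_red(x) = ½ Σ k_red,i x_i²,   E_ox(x) = ½ Σ k_ox,i (x_i − d_i)² + ε

Closed forms used as oracles: λ_red = ½Σk_ox d² (reduced geometry on the
oxidized surface), λ_ox = ½Σk_red d², ΔG at the minima = ε, and at equal
curvature the population value of the mean-gap estimator equals ½Σk d²
exactly, with gap variance Σ(k d)²·k_B T/k, so λ_var agrees too — the
self-consistency the linear-response estimators assume. For unequal
curvatures the mean-gap and variance expressions acquire
temperature-dependent terms; `analytic_reference` implements them (with
the derivation in its docstring) and the tests check them against both a
brute-force 1-D minimization oracle and large-n sampling.

Sampling is exact by default — independent Gaussians with per-coordinate
variance k_B T/k_i about the sampled surface's minimum — so textbook
standard-error formulas apply to every recovery test. A Metropolis
random-walk sampler (step ≈ σ, configurable burn-in and start point) is
provided to exercise equilibration-discard logic: started far from the
minimum with no burn-in it reproduces the "transient then stable" shape
of a real trajectory's early segment. The time axis is fictitious
(dt × sample index, default dt = 0.01 ps): the surrogate has statistics,
not dynamics, and in particular no autocorrelation, which is exactly why
its i.i.d. error bars are valid for the tests. Real QM/MM gap series are
autocorrelated, so passing recovery tests here says the estimators are
implemented correctly, not that 40 ps of correlated dynamics suffices to
converge λ.

Default study conditions: a 4-coordinate site (one stretch per ligand),
force constants chosen so thermal fluctuations √(k_B T/k) at 300 K are
0.05–0.29 Å (stiff equatorial ligands, soft axial thioether), minima
displaced 0.1–0.3 Å between redox states, ε = 5 kcal/mol. The gap-series
generator defaults mirror the reference trajectory statistics
(⟨ΔE⟩_red = 82.5, σ = 11.2; ⟨ΔE⟩_ox = −29.2, σ = 9.0 kcal/mol, with the
oxidized series analysed from 3 ps onward).

The embedding maps sampled coordinates onto a toy Cu site template (bond
stretches along the bond direction, angle bends in the angle's plane) so
the geometry pipeline runs end-to-end; a perturbation driving two atoms
within 0.3 Å is rejected as a collapsed geometry.

## Numerical choices

- One unit system: Å, kcal/mol, ps, K. No conversion layer.
- PDB I/O is fixed-column (simulation frames, not curated depositions):
  no CONECT/occupancy handling, altLoc other than blank/'A' skipped with
  a warning, element inferred from the atom-name leading characters when
  columns 77–78 are absent. Coordinates round-trip at the format's
  3-decimal precision.
- Atom order is the identity key across frames; names are not re-matched.
- Angles are degenerate below 10⁻⁸ Å separation; superposition requires
  rank ≥ 2 of the centered coordinates (relative SVD threshold 10⁻⁹).
- Equilibration discard (`discard_before`, ps) defaults to 0 and is a
  per-state configuration value; λ is always computed from post-discard
  means. Every discard decision and kept-frame count is logged.
- Report floats are formatted at 6 significant digits (λ echoed again at
  1 decimal place), which is what makes re-runs byte-identical.
- Seeds are explicit everywhere; there is no global random state. The
  pipeline derives per-state seeds as seed + {0, 1}.

## Design choices that were genuinely open

- Table statistics are computed per-frame on internal coordinates; the
  ensemble-average structure exists only for the strain workflow. The two
  conventions disagree on nonlinear functions of coordinates, so both are
  exposed (see τ4 above) rather than blessed.
- The experimental reorganization-energy range for the blue-copper site
  (16–28 kcal/mol) is carried in the report as a display band for
  context. It is never an assertion: a linear-response estimate from
  small-QM-region gap data can legitimately fall far outside it.
- The active-site atom selection is fully user-specified (residue
  numbers/names, atom names, element exclusion). No attempt is made to
  guess link-atom or protonation bookkeeping of a QM region.
- The CLI exposes `simulate`, `analyze` and `run`; `run` on a surrogate
  config is equivalent to `simulate` + `analyze` up to the PDB format's
  coordinate rounding, which is tested.

## Problem sizes

Recovery tests use n = 50,000 samples per state for gap statistics
(standard error ≈ 0.007 kcal/mol on the benchmark model), n = 2,000
frames for geometry summaries, and 100 random structure pairs for the
superposition cross-check; all complete in seconds.

## Known limitations

- Diagonal quadratic surfaces only: no mode coupling, no anharmonicity,
  no autocorrelated dynamics, no polarizable environment. Consequences of
  QM-region size on gap energetics are outside the model.
- No mass-weighted RMSD, τ5 or other geometry indices, mmCIF, or binary
  trajectory formats.
- `gap_geometry_correlation` is plain Pearson on the full series; it does
  not separate the equilibration transient from the stationary segment
  (use `discard_before` upstream for that).
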