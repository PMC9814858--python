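# Methods

This note records the statistical models, numerical procedures, and default
parameters implemented in `abfekit`, and their known limitations. Empirical
statements here are the ones computed by the test suite
(`tests/test_acceptance.py`) and by `scripts/acceptance.py`.

## Thermodynamic cycle

The binding free energy is assembled by double decoupling with an
orientational restraint:

```
ΔG_bind = [ΔG_solv,coul + ΔG_solv,vdw]
        + ΔG_restr,analytic
        − [ΔG_complex,restraint + ΔG_complex,coul + ΔG_complex,vdw]
        + ΔG_charge_correction
```

All stage free energies are reported in the λ 0 → 1 direction (decoupling;
restraint-ON for the restraint stage). Stage uncertainties combine in
quadrature. Constants: k_B = 0.0019872041 kcal/mol/K, T = 298.15 K
(RT = 0.5925 kcal/mol), 1 kcal = 4.184 kJ, V° = 1660.54 Å³.

The canonical λ schedules are 11 Coulomb windows (Δλ = 0.1), 21 van der
Waals windows (Δλ = 0.05), and a 12-window non-uniform restraint stage;
`validate_schedule` flags deviations (missing endpoints, non-monotone λ,
restraint stages on solvent legs).

## Estimators

**Statistical inefficiency.** g = 1 + 2 Σ_t (1 − t/N) ρ(t) with the biased
FFT autocovariance, truncated at the first non-positive ρ(t), clamped to
g ≥ 1. Windows are subsampled at stride ⌈g⌉ with a floor of 50 frames. On
AR(1) series (exact g = (1+ρ)/(1−ρ)) of length 10⁶ the estimate is within
10% of the closed form for ρ ∈ {0.5, 0.9, 0.99} (acceptance criterion 4).

**MBAR.** Self-consistent iteration followed by Newton steps on the
reduced free energies, anchored at f₀ = 0, tolerance 1e-8, at most 10⁴
iterations; non-convergence raises an error carrying the residual.
Uncertainties come from the asymptotic covariance evaluated through the
K×K Gram matrix of the weight matrix; the overlap matrix
O_ij = N_j Σ_n W_ni W_nj (rows sum to 1) and its low-overlap pairs
(< 1e-3) are reported as diagnostics. MBAR is invariant to per-sample
constants and, for two states, agrees with BAR to better than 1e-6 kT
(criterion 2). On seeded harmonic legs with analytic answers, the
estimate falls within 3 asymptotic standard errors of truth in ≥ 95/100
runs for both canonical schedule shapes (criterion 1).

**BAR / TI.** BAR solves the Bennett implicit equation by bracketed root
finding on log-Fermi sums, bracketed by the two exponential-averaging
estimates. Trapezoidal TI over the window mean dH/dλ serves as a
secondary cross-check and agrees with MBAR within 2% on dense harmonic
legs (criterion 2).

**Replica aggregation.** Replica means with the sample standard deviation
(ddof = 1) across replicas; a single replica reports no spread.

## Boresch restraints

A restraint is six atoms (L1–L3 ligand, P1–P3 protein) defining one
distance r(L1–P1), two angles θ_A(L2–L1–P1), θ_B(L1–P1–P2), and three
dihedrals φ_A, φ_B, φ_C. The analytic standard-state correction is the
stiff-spring closed form

```
ΔG = −kT ln[ 8π² V° √(Π K_i) / (r0² sinθ_A0 sinθ_B0 (2πkT)³) ]
```

valid away from the sinθ singularities; construction enforces a guard band
of 0.1 rad and positive force constants. The exact scaling laws — −kT ln 2
per doubling of V°, −6 kT ln 2 for quadrupling all six force constants —
hold to machine precision (criterion 3).

**Limitation.** The closed form is an approximation. Against the exact
factorised one-dimensional quadrature (which keeps the r² and sinθ
Jacobians and finite integration ranges), the gap at the default
parameters (all K = 10, r0 = 5 Å, θ = π/2, T = 298.15 K) is
≈ 0.034 kcal/mol, dominated by the Jacobian curvature at these moderate
stiffnesses; the gap shrinks as the force constants grow. The acceptance
test asserting 0.01/0.02 kcal/mol agreement therefore fails by design and
documents this approximation error; `scripts/acceptance.py` reports the
measured gap.

**Selection pipeline.** Ligand anchors are the heavy atoms of lowest RMSF
(stable tie-break by index). Candidate P1 atoms are protein Cα within
8 Å of the anchor in ≥ 50% of frames; P2/P3 are the residue's backbone C
and N, L2/L3 the nearest bonded heavy ligand atoms. Candidates inside the
collinearity guard band are excluded. Each candidate is scored by the sum
of its six coordinate standard deviations, each normalised by the median
standard deviation of its class (bond / angle / dihedral) across
candidates; dihedral statistics are circular. The reference frame
minimises Σ((value − mean)/σ)² with wrapped dihedral deviations. On 20
seeded toy complexes the pipeline recovers the ground-truth anchor and the
exhaustively-scored best restraint in all cases (criterion 6).

## Benchmark statistics

Affinities convert as ΔG = RT ln K (Kd/Ki in molar); censored measurements
("K > bound") carry the bound and a direction and can be excluded.
Metrics: Pearson r, Spearman ρ, Kendall τ-b (tie-corrected; validated
against an O(n²) brute force on 1000 random tied sets, criterion 5), and
RMSE. Uncertainties are paired-bootstrap standard deviations (ligands
resampled with replacement, n_boot ≥ 100; degenerate zero-variance
resamples are skipped for the correlation metrics and counted). At
n_boot = 10⁵ the bootstrap standard errors from independent seeds agree
within 2% (criterion 5).

## Decision evaluation

For each (parent, child) elaboration pair, ΔΔG = ΔG(child) − ΔG(parent)
on both the calculated and experimental side; the calculated error is the
quadrature of the two replica standard deviations. A pair is *supported*
when the signs match and |ΔΔG_calc| strictly exceeds the (configurable,
default 1×) error; a sign mismatch between two nonzero changes is
*direction wrong*; everything else — including experimental ties and zero
calculated change — is *direction correct within error*. A decision (a
named set of pairs) is supported only if every pair is (criterion 7).

## Synthetic generators

All generators are seeded (`np.random.default_rng([seed, stream])`) and
bit-reproducible.

- **Harmonic legs**: per-window Gaussian samples from u(x) = ½K x² + c
  with analytic ΔA = ½ ln(K₁/K₀) + Δc per window pair; foreign-state
  reduced energies are exact transformations of the same samples.
- **AR(1)**: unit-marginal-variance series with exact inefficiency
  (1+ρ)/(1−ρ), generated by a stationary linear filter.
- **Toy complexes**: an MDAnalysis universe with a small ligand whose
  heavy atoms fluctuate with controlled amplitudes (the minimum-amplitude
  atom is the ground-truth anchor) inside a ring of residues, with the
  Cα-within-cutoff set known by construction.
- **Benchmark sets**: defaults mirror a fragment-scale study — 59 ligands
  over 4 systems with per-system offsets, experimental values in
  −13…−4 kcal/mol, replica standard deviations drawn around 0.79 ± 0.38
  kcal/mol, optional censoring at RT ln 10⁻³ ≈ −4.09 kcal/mol, and a
  configurable population correlation between calculated and experimental
  values.

## Limitations

- The Boresch closed form carries the ≈0.03 kcal/mol stiff-spring error
  discussed above at moderate force constants.
- The trapezoidal TI estimator is a cross-check, not the primary
  estimator; it inherits the usual quadrature bias on curved dH/dλ.
- The charge correction hook accepts a precomputed value; no
  Poisson–Boltzmann machinery is included.
- Synthetic generators provide exact ground truth for validation; they do
  not model force-field error or sampling pathologies beyond AR(1)
  autocorrelation.
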