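# Methods

## Free-energy surfaces from energy-gap sampling

The central object is the free-energy surface of an electronic state as a
function of a vertical energy gap ΔE, which acts as a collective reaction
coordinate for molecular and solvent geometry fluctuations. The
construction assumes **linear response**: the equilibrium distribution of
ΔE along a trajectory of a state is Gaussian, equivalently the surface is
quadratic, V(ΔE) = (k_BT/2)((ΔE−μ)/σ)². `fit_gap_distribution` fits μ
(sample mean) and σ (ddof-1 sample SD — the maximum-likelihood normal
scale up to the n/(n−1) factor) and attaches exact confidence intervals:
Student-t for μ, chi-square for σ. Both assume i.i.d. samples; trajectory
frames are treated as independent, appropriate when frame spacing exceeds
the solvent decorrelation time (~1 ps here). Autocorrelation within
trajectories is deliberately not emulated or corrected for.

Two constructions locate the excited-state surface without excited-state
dynamics:

- **companion** (`companion_surface`): on the ΔE = E_ES − E_CS axis,
  V_ES = V_CS + ΔE identically. Closed forms: ES minimum at μ − σ²/k_BT,
  λ = σ²/(2k_BT), ΔA = σ²/(2k_BT) − μ.
- **crossfit** (`crossfit_es_surface`): on the x = E_CS − E_GS axis,
  V_ES = V_CS + a·x + b with (a, b) from OLS of the ES−CS gap against the
  CS−GS gap on the ground-state trajectory. Closed forms: ES minimum at
  μ_x − a σ_x²/k_BT, λ = a²σ_x²/(2k_BT), ΔA = a²σ_x²/(2k_BT) − aμ_x − b.
  When a ≠ 0 the surface is re-expressed on the ES−CS axis through the
  fitted linear map; a = 0 is reported as a non-re-expressible rigid shift
  rather than an error.

Sign convention: ΔA = V_CS(min) − V_ES(min) > 0 means the charge-separated
minimum lies **above** the excited-state minimum (uphill charge
separation). The crossing point reported by `summarize_surface_pair` is the
real root of V_ES − V_CS between the two minima when one exists (the
thermally relevant crossing), else the lower-energy root; identical
surfaces report a crossing height of 0. The Marcus inverted region is
flagged when −ΔA > λ. A surface whose minimum falls outside the sampled
gap range carries a boolean extrapolation flag — no correction is applied.

## Uncertainty propagation

`propagate_uncertainty` evaluates a derived quantity over the Cartesian
product of {lower, point, upper} for every input parameter and returns the
min/max envelope. This "CI-corner scan" is exact for quantities monotone in
each parameter (all quantities here: λ, ΔA, the rate) and is preferred to a
full pipeline bootstrap for transparency; analytic t/chi-square/OLS
intervals are the default, with seeded bootstrap available through the
fitting layer if needed. Corners where the evaluator fails are returned as
flagged records, never silently dropped. The joint envelope is
conservative: it does not model μ–σ correlation (zero for a normal sample)
and attains ~95% simultaneous coverage empirically (the test suite measures
≥90/100 replicates covering both λ and ΔA at n = 500 frames).

## Marcus kinetics

`marcus_rate` evaluates the classical high-temperature expression
k = (2π/ħ)|H|²(4πλk_BT)^(−1/2)exp(−(λ+ΔA)²/(4λk_BT)) with everything in
eV and the result in ns⁻¹. Constants are pinned in `chlquench.constants`
(k_B = 8.617333×10⁻⁵ eV/K, ħ = 6.582120×10⁻¹⁶ eV·s, Coulomb constant
14.3996 eV·Å·e⁻², 1 Ha = 27.2114 eV, 1 bohr = 0.529177 Å); reproducing the
printed rate digits depends on this table. The default temperature is
300 K, and Helmholtz ΔA stands in for ΔG (NVT sampling of a nearly
incompressible system).

With the benchmark 10 Å parameters (H = 0.115 eV, λ = 0.66 eV,
ΔA = 0.39 eV) direct evaluation gives 0.0263 ns⁻¹, printed as 0.03 ns⁻¹ at
one significant figure. The pre-relaxation ("initial") rate uses the same
expression with (λ, ΔA) of the geometry distribution immediately after
photoexcitation; with the rounded inputs λ = 0.63, ΔA = 0.39 eV it also
evaluates to ≈0.03 ns⁻¹ — a rate printed as 0.04 ns⁻¹ elsewhere is not
exactly recoverable from the rounded inputs, and no agreement is forced.

Coupling distance decay: n = √(−2ε) evaluated in atomic units (ε the
smallest-magnitude occupied-orbital energy, negative) and converted to
Å⁻¹; ε = −6.5 eV gives n = 1.3 Å⁻¹, a 13× coupling drop and ~169× rate
drop per additional 2 Å. The working coupling drawn from a sampled
distribution defaults to the **maximum** (policy `max`): a feasibility
analysis asks whether quenching *can* win, so the optimistic value is the
honest default; `mean` and `median` are available for sensitivity.

## Exciton model

`exciton` builds the two-(or more-)site Frenkel Hamiltonian
H = Σ E_i|i⟩⟨i| + Σ V_ij|i⟩⟨j| with V_ij the unscreened Coulomb sum over
transition charges (an optional scalar screening multiplier is exposed;
none is applied by default). Transition charges must be monopole-free to
1e-6 e, and inter-site atoms closer than 0.1 Å are rejected. Oscillator
strength is reported as the dimensionless proxy |Σ c_i μ_i|²/|μ_mono|²
(no energy prefactor — the analysis only needs "dark vs bright").
Thresholds: dark < 0.05 monomer strengths, localized > 0.8 dominance; both
configurable, neither dictated by theory. The pipeline's ensemble uses a
cofacial dimer with 1 e·Å site dipoles 10 Å apart (V ≈ 14 meV) and
Gaussian site-energy disorder of SD 0.05 eV — disorder ≫ |V| — emulating
ring/solvent fluctuations that break the H-aggregate symmetry; the
qualitative output (the lowest state is rarely dark) is insensitive to the
precise dipole model.

## Charge embedding

`correct_ion_charges` applies the per-atom shift q′ = q + (q_ion −
q_neutral), which transfers exactly the net ionic charge by construction.
`assemble_total_energy` sums per-monomer polarized QM energies plus a
direct (non-periodic) Coulomb double sum over every unordered pair of
charge groups; membership lists must be disjoint. Periodic-image
electrostatics (particle-mesh Ewald) belong to the external engine and are
out of scope — the direct sum is exact for the non-periodic desk-scale
systems treated here.

## Pair statistics

For a uniform solution, m = ρ(4/3)πr³ is the mean neighbor count within r.
Three conventions are exposed: `expected_count` (the fraction is m,
clamped to 1 — the back-of-the-envelope convention that yields 25% at
0.1 mol dm⁻³ and ~3.5% ≈ 4% at 0.014 mol dm⁻³ for r = 1 nm), `poisson`
(1 − e^−m, exact for an ideal gas of points), and
`expected_count_free_volume` (density rescaled by the free volume after
excluding 4πr_g³/3 per molecule, r_g = 0.96 nm). How the excluded volume
enters the printed 4%/25% figures is not derivable from their values —
the free-volume variant does *not* reproduce 25% — so the convention is a
method switch with `expected_count` as default, not a hard-coded choice.
Whole-percent rounding happens only at report time.

The Monte-Carlo verifier places hard spheres sequentially in a cubic box
and counts molecules with a neighbor inside the cutoff using **periodic
minimum-image** distances, so the finite box emulates the infinite uniform
medium the analytic estimators assume (a non-periodic box depletes
neighborhoods near walls by ~2 standard errors at the default problem
size). With r_excl = 0 the verifier converges on the `poisson` variant.

## Synthetic generator calibration

The study's empirical gap means and widths are not printed, so the
generator's defaults are back-derived from the benchmark Marcus parameters
through the companion closed forms: σ = √(2k_BTλ) = 0.1847 eV and
μ = λ − ΔA = 0.27 eV for λ = 0.66, ΔA = 0.39 eV at 300 K. The
ground-state-axis defaults (μ_x = 3.26 eV, σ_x = 0.3695 eV, slope −0.5,
intercept 1.9 eV, residual SD 0.02 eV) are chosen so the crossfit route
encodes the same λ and ΔA with a strongly correlated gap relation
(|r| ≈ 0.99). Couplings are log-normal — the simplest strictly positive,
orders-of-magnitude-spread model — with 0.5 decades of spread centered at
10⁻²·⁵ eV so that 500 draws span ~10⁻⁴–10⁻¹ eV with an expected maximum
near 0.11 eV. Pipeline distance scenarios encode (λ, ΔA) of (0.56, 0.25),
(0.66, 0.39), (0.70, 0.46) eV at 8/10/12 Å — values chosen to reproduce
the reconstructed trend of ~2 orders of magnitude rate loss from 8→10 Å
and ~1 further order by 12 Å at constant coupling — and (0.55, 0.84) eV
for the protein-embedded (LH2-like) pair. Each generated artifact carries
one named seed; identical spec + seed is byte-identical.

What passing tests on synthetic data do and do not show: they validate the
**estimators and constructions** (recovery of known parameters, coverage
of envelopes, agreement of analytic and Monte-Carlo routes), not the
physics of any real chlorophyll pair — real gap distributions may be
skewed, heteroscedastic in the inter-gap relation, and autocorrelated,
none of which the generator emulates.

## Numerical choices and problem sizes

- Eigensolves via `numpy.linalg.eigh`; coupling matrices are validated
  symmetric to 1e-12 before diagonalization.
- Crossing roots from the quadratic-difference discriminant; a degenerate
  (equal-curvature) difference falls back to the linear root.
- Recovery/coverage tests use 500-frame trajectories and 100 replicates;
  Monte-Carlo pair verification uses 2,000 molecules × 20 replicates
  (standard error ~0.1 percentage points). These sizes put every
  stochastic check several standard errors clear of its threshold while
  keeping the whole suite in the seconds-to-a-minute range.
- Rejection sampling for placements budgets 10⁴ attempts per molecule and
  raises on exhaustion; the exclusion radius must stay below half the box
  side under the minimum-image convention.

## Known limitations

- Quadratic surfaces are extrapolated beyond the sampled gap range; the
  package flags but does not correct this.
- The corner-scan envelope is conservative rather than a calibrated
  confidence interval for strongly nonlinear functionals (the rate's
  envelope is wide because the exponent amplifies σ uncertainty).
- The exciton layer takes transition charges as given; no electronic
  structure, environment polarization, or charge-transfer-exciton mixing.
- Couplings are inputs (or synthetic); no fragment-orbital DFT.
- No excitation-migration/quenching-yield simulation: pair statistics stop
  at the fraction of close pairs.
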