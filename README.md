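# chlquench

Concentrated chlorophyll solutions lose their fluorescence ("concentration
quenching") while the same pigments, packed just as tightly inside
photosynthetic antenna proteins, do not. The leading explanation is
photoinduced symmetric charge separation: a *statistical pair* of
chlorophylls that happens to sit within ~10 Å undergoes
(Chl–Chl)\* → Chl⁺–Chl⁻ faster than it can fluoresce, and the ion pair
recombines nonradiatively. `chlquench` implements the quantitative analysis
behind that argument for computational (bio)physical chemists: free-energy
surfaces reconstructed from sampled vertical energy gaps, Marcus-theory
rates with confidence-envelope propagation, the coupling's exponential
distance decay, a Frenkel exciton treatment of the competing dark-state
(H-aggregate) hypothesis, and the solution statistics of close pairs.

## The model

Under linear response, the Boltzmann distribution of a vertical energy gap
ΔE sampled along an equilibrium trajectory is Gaussian with mean μ and
width σ, so the free-energy surface in the gap coordinate is quadratic:

    V(ΔE) = (k_B T / 2) · ((ΔE − μ)/σ)²

The excited-state (ES) surface follows on the same axis from the
charge-separated (CS) state's surface as V_ES(ΔE) = V_CS(ΔE) + ΔE
("companion" construction), or — anchored to ground-state sampling — as
V_ES(x) = V_CS(x) + a·x + b on the x = E_CS − E_GS axis, where (a, b) is
the fitted linear relation between the two gaps ("crossfit" construction).
Either way the Marcus parameters follow from the minima:
ΔA = V_CS(min CS) − V_ES(min ES) and λ = V_CS(at ES min) − V_CS(at CS min),
with closed forms λ = σ²/(2k_BT), ΔA = λ − μ for the companion route. The
charge-separation rate is the classical Marcus expression

    k_CS = (2π/ħ) |H_AB|² (4πλk_BT)^(−1/2) · exp(−(λ+ΔA)²/(4λk_BT))

compared against the fluorescence rate k_f = 1/τ_f (τ_f = 5.1 ns in diethyl
ether). Statistical uncertainty in (μ, σ, a, b) is propagated to every
derived quantity as the min/max envelope over the Cartesian product of 95%
confidence-interval endpoints.

Because the MD + semiempirical engine that produced the original per-frame
energy tables is external, the package ships a first-class synthetic
generator (`chlquench.synthetic`) that emulates those tables' statistical
structure — Gaussian gaps, the linear inter-gap relation, log-normally
spread couplings, hard-sphere solution placements — so the entire analysis
is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the study workflow on synthetic
data and write tables under `results/`:

```
python analysis/01_simulate_trajectories.py --seed 0
python analysis/02_reconstruct_surfaces.py
python analysis/03_marcus_rates.py
```

Step 02 prints (seed 0):

```
companion route: lambda = 0.679 [0.602, 0.772] eV, dA = 0.414 [0.321, 0.523] eV
crossfit route:  lambda = 0.618 eV, dA = 0.351 eV (gap relation: slope -0.501, r = -0.995)
route disagreement: |d lambda| = 0.061 eV
```

The generator encodes λ = 0.66 eV and ΔA = 0.39 eV (the 10 Å-pair-in-ether
conditions); both reconstruction routes recover them within the printed 95%
envelopes, and their mutual agreement is the self-consistency check that
justifies extrapolating the quadratic surfaces. Step 03 then prints

```
surface stiffening alone: k(8A)/k(10A) = 140, k(10A)/k(12A) = 12 at constant coupling
at 10 A: k_CS = 0.003 ns^-1 vs k_f = 0.20 ns^-1 (branching 0.01); at 8 A charge
separation dominates (branching 0.64)
```

i.e. the rate collapses by ~2 orders of magnitude between 8 and 10 Å from
the surface stiffening alone, before the coupling's exp(−2nΔR) decay
(~169× per 2 Å with n = 1.3 Å⁻¹) is counted — charge separation switches
from dominant to negligible over a few ångströms, which is why a critical
quenching distance is a good approximation. Steps 04–05 show that
site-energy disorder keeps the lowest exciton state bright (dark lowest
state in only ~11% of dimers at 0.05 eV disorder, against 100% for the
ideal H-dimer) and that 4% / 25% of molecules have a ≤1 nm neighbor at
0.014 / 0.1 mol dm⁻³ — enough statistical pairs to explain 50% / ~100%
quenching once excitation migration feeds them.

A CLI exposes the same operations (`chlquench simulate|fes|rate|exciton|pairs|run`),
e.g.:

```
$ chlquench rate --coupling-ev 0.115 --lambda-ev 0.66 --delta-a-ev 0.39
{
  "k_ns": 0.026301787223312362,
  "marcus_region": "normal"
}
```

## Layout

- `src/chlquench/` — the library: `synthetic` (generators), `fes`
  (surface reconstruction), `marcus` (rates, distance decay), `exciton`
  (Frenkel Hamiltonian), `embedding` (charge correction, energy assembly),
  `pairs` (solution statistics), `pipeline` + `cli`.
- `analysis/` — numbered narrative drivers.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end suites.
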