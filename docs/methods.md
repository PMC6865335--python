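# Model and methods

## The model

`colonycml` simulates the population dynamics of a mixed bacterial colony
containing a **sensitive** strain and an **antagonistic** strain that
secretes a diffusible growth inhibitor.  The growth surface is a regular
square lattice; each compartment holds two continuous state variables,
`s[i,j]` and `a[i,j]`, the local populations of the two strains normalized
to the compartment carrying capacity (1.0 = saturated).  Time is discrete:
the model is a coupled-map lattice, equivalent to a forward-Euler
discretization of Lotka–Volterra competition within compartments plus
nearest-neighbor diffusion, with the time step folded into the rate
constants.

Per iteration, each compartment gains

```
Δs⁺ = r_s / (1 + (N_a / K_a)^n) · (1 − s − α·a) · s
Δa⁺ = r_a · (1 − a − β·s) · a
```

where `N_a` is the antagonist density in the 3×3 neighborhood, averaged
with weights 1/2 (self), 1/12 (each cardinal neighbor) and 1/24 (each
diagonal neighbor).  The Hill factor `1/(1 + (N_a/K_a)^n)` is the
antagonism: nearby antagonists suppress the *rate* of sensitive growth
(they do not change the logistic equilibria).  Antagonist growth has no
such term — the strains' only mechanistic asymmetry is the inhibitor.

Each compartment simultaneously loses a fraction `D·x` of each population
to diffusion, redistributed to the 8 neighbors with weights 1/6 (cardinal)
and 1/12 (diagonal).  Both kernels sum to exactly 1, so uniform fields are
fixed points of both operators and, with growth switched off, total
populations are conserved on a periodic lattice to machine precision.

The update is fully synchronous: all increments are evaluated from a frozen
copy of the state, then applied at once:

```
x ← x + Δ⁺ − Δ⁻ + inflow
```

## Parameters

| symbol | meaning | default | rationale |
|---|---|---|---|
| `r_s`, `r_a` | per-iteration growth rates | 0.1 | strains expand at similar speeds; small enough for the map to track the continuous dynamics |
| `D_s`, `D_a` | diffusing fraction per iteration | 0.01 | `D ≪ r` keeps the colony interior saturated (`s ≈ 1` behind the front) |
| `K_a` | half-inhibition neighborhood density | 0.08 | places the dose-response transition at intermediate inoculum proportions |
| `hill_n` | inhibition steepness | 4 | sharp, threshold-like onset of inhibition |
| `alpha`, `beta` | competition coefficients | 1.5 | see below |

All rates must be ≪ 1; the constructor rejects values outside [0, 0.5] and
warns above 0.2.  Growth rates of exactly 0 are admitted as the degenerate
pure-diffusion case used in conservation diagnostics.

### Why `alpha = beta = 1.5`

The competition coefficients are not fixed by any measurement, and they
select the qualitative regime of the within-compartment dynamics:

* `α, β < 1` — stable coexistence: every compartment relaxes to the same
  mixed equilibrium and no patches form;
* `α = β = 1` — a degenerate neutral case: every state with `s + a = 1` is
  an equilibrium.  Saturated sensitive patches then cannot repel antagonist
  influx, while the inhibitor blocks sensitive regrowth, so antagonists
  slowly erode sensitive territory regardless of the initial mixture and
  the sensitive strain never ends up dominant even at a 10:1 starting
  advantage;
* `α, β > 1` — bistable mutual exclusion: whichever strain locally
  saturates first actively excludes the other.

Real mixed colonies form sharp, mutually exclusive single-strain patches,
which is exactly the exclusion regime.  We therefore default to a
symmetric, moderately supercritical `α = β = 1.5`: symmetric so that the
*only* asymmetry between the strains remains the `K_a` inhibition term, and
moderately above 1 so that exclusion is decisive without overwhelming the
inhibition effect.  With this choice the three canonical outcomes appear in
the expected order as the initial antagonist proportion ρ grows: sensitive
dominance (ρ ≈ 0.1), balanced patchwork (ρ ≈ 0.3), antagonist dominance
(ρ ≥ 1).  Both coefficients are exposed in `ModelParams` and the config
file.

## Initial conditions

Mixed-colony runs start from a "diluted inoculum": inside a disk of radius
5 around the center of a 51×51 periodic lattice (81 compartments; disk
membership is Euclidean distance between compartment centers ≤ radius, ties
included), `s ~ U[0, 0.2]` and `a ~ U[0, 0.2·ρ]` independently per
compartment, zero outside.  ρ is the antagonist proportion of the initial
mixture.  The two layers are drawn from two independent generator streams
spawned from the seed (`numpy` PCG64 via `SeedSequence.spawn`), filling the
disk in row-major order — documented so any inoculum is reproducible from
its seed alone.

Single-colony and two-colony protocols use deterministic saturated disks
(`s = 1` or `a = 1` inside, 0 outside).

## Experiments and metrics

* **Mixed-colony ensembles.**  200 iterations; readout σ = S/(S+A) with
  S = Σs, A = Σa.  Sweeps run 10 replicates per ρ over
  {0.1, 0.25, 0.5, 0.75, 1.0, 2.0} (the experimental mixing proportions
  10–200%).  Replicate seeds derive as `base + replicate + 10⁶ · rank(ρ)`,
  so every cell of the ensemble matrix is independently regenerable.
* **Resistant-strain mode.**  A third, resistant strain (numerous,
  homogeneously spread, unaffected by the inhibitor) is modeled only
  through its effect on the antagonist: forcing antagonists to secrete the
  costly inhibitor everywhere lowers their growth rate.  `resistant_mode`
  multiplies `r_a` by 0.9 (0.1 → 0.09); the factor is a config knob, not a
  calibration from dose.
* **Outcome labels.**  `sensitive_dominant` iff σ ≥ 0.9,
  `antagonist_dominant` iff σ ≤ 0.1, `mixed` otherwise.  The thresholds are
  a convention of this package (the wet-lab classification is by visual
  morphology) and are exposed as arguments.
* **Dose-response midpoint.**  Mean final σ versus ρ is summarized by a
  two-parameter decreasing logistic σ(ρ) = 1/(1 + (ρ/ρ₅₀)^h), fitted by
  least squares (initializer ρ₅₀ = median ρ, h = 2; both positive).  The
  form is a pragmatic midpoint extractor, not a model claim.  Inputs
  without a transition return a flagged degenerate fit rather than raising.
* **Radii.**  The scalar colony radius is area-equivalent,
  `sqrt(n_above/π)` with `n_above` the compartments ≥ threshold (default
  0.5) — rotation-robust on a lattice.  Directional radii (used for the
  two-colony internal/external asymmetry ΔR = external − internal) ray-cast
  from the inoculation center along a lattice axis to the farthest
  above-threshold compartment; when both colonies occupy the same layer the
  internal scan stops at the midline between them so a neighbor's mass is
  never counted as the measuring colony's front.  Two-colony runs use
  absorbing boundaries (radii are ill-defined under wraparound) and
  truncate with a flag once the facing fronts meet.

## Numerical choices

* Neighborhood sums are 3×3 convolutions (`scipy.ndimage.convolve`) with
  `wrap` (periodic) or zero-padded `constant` (absorbing) modes.  Kernels
  are built from integer numerators (/24, /12) and sum to exactly 1.0 in
  IEEE double arithmetic.
* Lattices smaller than 3 in either dimension are rejected under periodic
  boundaries (a compartment would become its own neighbor).
* A compartment value driven below −1e−12 in one step raises (parameter
  regime outside the model's validity); negatives within that tolerance
  are float noise and clamp to 0.
* One iteration is the unit of time; no Δt symbol is carried.
* The `step` function is pure; all randomness enters through explicit
  seeds, and CLI outputs are byte-reproducible given a seed.

## Problem sizes

Default protocol sizes are those of the study conditions: 51×51 periodic
lattice, radius-5 inoculum, 200 iterations, 10 replicates per ρ, and a
151×151 absorbing lattice over 400 iterations for front-speed measurement
(fit window: iterations 100–400, after the initial transient).  The paired
dose-response comparison repeats the full two-condition sweep ensemble 10
times with disjoint seed blocks.

## What the simulations do and do not show

The model reproduces, from one mechanism (a single diffusible inhibitor
with a growth cost), the qualitative phenomenology of mixed-colony plate
experiments: patchy colony structure, a sigmoidal decline of the sensitive
fraction with the initial antagonist proportion, and a protective
right-shift of that curve when antagonists are uniformly slowed.  It does
not model nutrient depletion, colony morphology (wrinkling, opacity),
agar-surface physics, or an explicit resistant population with its own
spatial dynamics; the resistant strain exists only as the `r_a` reduction.
σ is a population fraction, whereas plate-image quantification measures
morphology area fractions — the two are comparable only qualitatively.
The lattice front speed grows with `r` and `D` and the radius grows
linearly in time, but the package records measured speeds without asserting
a specific speed law.  Two antagonist colonies show no mutual front
suppression (ΔR ≈ 0) because the model contains no antagonist–antagonist
inhibition term, a documented divergence from the plate observations.
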