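# Methods

`deltamd` implements, end to end, the Δ-learning route to a high-level
potential-energy surface for a molecular liquid: sample with an
affordable baseline, carve open-boundary clusters from the periodic
snapshots, label them with *energy differences* between a high-level
(HL) and a low-level (LL) theory, fit a short-ranged correction model
on those energies alone, and run constant-pressure and
constant-volume dynamics on the composite surface LL + Δ.  Because
real coupled-cluster labels are out of reach at desk scale, the
package ships a **synthetic two-level theory** whose HL surface *can*
be simulated directly — so every step of the workflow, including its
central transferability assumption, is testable against an exact
reference.

## The synthetic two-level theory

Both surfaces describe flexible water:

* **Shared terms** (bitwise identical in LL and HL): harmonic bonds
  (½·k_b(r−r₀)², k_b = 45 eV/Å², r₀ = 0.9572 Å), harmonic angle
  (k_a = 3.3 eV/rad², θ₀ = 104.52°), and damped shifted-force (DSF,
  Wolf-type) Coulomb electrostatics with SPC/E charges
  (q_O = −0.8476 e), α = 0.2 Å⁻¹ and a 6 Å cutoff.  DSF is used
  instead of Ewald because it is identical between periodic and open
  boundaries — precisely the property the Δ-learning premise needs:
  the long range must live entirely in the baseline.
* **LL**: a switched Lennard-Jones O–O term, ε = 0.00674 eV,
  σ = 3.166 Å, with a C¹ switching function over 3.2–4.0 Å.  (A
  smooth switch rather than a bare energy shift keeps forces
  continuous at the cutoff, which the integrator tests and the 10⁻⁶
  eV/Å finite-difference oracle require.)
* **HL**: the same functional form with perturbed LJ parameters
  (ε = 0.0105 eV, σ = 3.075 Å) plus a Stillinger–Weber-style O–O–O
  three-body term λ₃(cos θ − cos θ₀)²·g(r_ij)g(r_ik) with λ₃ = 0.015 eV,
  cos θ₀ = −1/3, g(r) = exp(−0.15 r²)·f_c(r) and a smooth cosine
  cutoff f_c at 4 Å.

Every term that differs between the levels vanishes smoothly beyond
4 Å, so HL − LL is strictly short-ranged, and the difference contains
both pairwise and genuinely angular content (a radial-only Δ-model
demonstrably underfits — a built-in negative control).

The numerical constants were fixed once, by running 300 ps NPT
simulations of both levels at 298 K / 1 bar: LL equilibrates near
0.874 g/cm³ and HL near 0.932 g/cm³, a density gap of ≈ +7%.  That
satisfies the design contract (two levels differing by 3–10% in
equilibrium density, with the baseline underestimating) and emulates a
baseline functional with a substantial density error.  The gap is
verified by the packaged regression tests at reduced run lengths, not
recomputed at import time.  Density responds strongly to σ and to the
three-body amplitude (tetrahedral ordering opens the network and
*lowers* the density), which is why the HL parameters look close to
the LL ones.

## Cluster carving and cumulative datasets

A cluster of radius r_c around a center molecule contains the center
plus every molecule whose O atom lies within r_c of the center O under
the minimum image (the O site is the unambiguous single heavy atom per
molecule).  Molecules are kept whole, unwrapped into a contiguous
open-boundary geometry with the center O at the origin; no rotational
canonicalization is applied since the descriptors are rotation
invariant.  Cumulative datasets draw (frame, center) pairs uniformly
without replacement per radius, independently across radii, with a
single seed; the validation split is a stratified-by-radius random
10%.  At the experimental density, 5.5 Å clusters hold ≈ 23 molecules.

## The Δ-model

Per-atom descriptors with a 4 Å cosine cutoff: 15 Gaussian radial
basis functions (centers 0.5–4.0 Å, width 0.25 Å) per neighbor element,
plus angular functions (1 + λ cos θ)^ζ·exp(−η(r_ij² + r_ik²)) with
(λ, ζ) ∈ {(±1, 1), (±1, 2)} and η = 0.15 Å⁻² per unordered
neighbor-element pair — 42 features per center element, 84 in total.
λ = ±1 with ζ ≤ 2 spans all quadratics in cos θ, so the three-body
angular shape of HL − LL lies (up to the radial envelope) inside the
model space.

The model is linear: ΔE = Σ_i w_{Z_i}·f_i + b·M with per-element
weight vectors, a per-molecule intercept b (absorbing the
size-proportional part of ΔE without contributing forces), and a
closed-form ridge solution (λ_ridge = 10⁻⁶ by default).  A linear
model rather than a neural network keeps training deterministic and
seconds-fast; the scientific surface being exercised here is the
pipeline, not model capacity.

Two numerical choices matter:

* **No feature standardization.**  Ridge shrinkage acts in the raw
  feature space.  With per-column rescaling the minimum-norm solution
  of the underdetermined small-cluster fits loads weight onto columns
  those clusters barely sample; deployed on a periodic box — whose
  feature vectors lie far outside the cluster manifold — such models
  diverge by orders of magnitude.  Raw-space shrinkage recovers
  weights at the physical scale and reproduces the expected physics:
  a 2.5 Å-only dataset transfers poorly (but finitely) to the bulk,
  while cumulative datasets through 3.5 Å and beyond transfer
  near-exactly.
* **Energy labels only.**  Forces and virial come from the exact
  analytic gradient of the fitted form (chain rule through the radial
  and angular terms), evaluated by a compiled kernel that contracts
  weights and features in one pass.  The weighted angular basis is
  pre-expanded into a polynomial in cos θ and evaluated by Horner's
  rule; Gaussians beyond 5σ of a radial center are dropped identically
  in training and deployment.

## Dynamics

Velocity Verlet (0.5 fs default) with:

* **CSVR thermostat** (canonical sampling through velocity rescaling):
  kinetic energy resampled each step with relaxation time τ_T = 0.1 ps;
  the conserved-quantity accumulator tracks the work exchanged with
  the bath.
* **Stochastic cell rescaling barostat**: overdamped Langevin dynamics
  of ε = ln V, dε = (κ_T/τ_P)(P_inst − P₀)dt + √(2k_BT κ_T/(Vτ_P))dW,
  with τ_P = 1 ps and a compressibility-like mobility parameter
  κ_T = 4.5×10⁻⁵ bar⁻¹.  Volume moves scale molecular centers of mass;
  atoms ride rigidly with their molecule.  P_inst is the atomic
  instantaneous pressure (2K + tr W)/(3V) with the virial
  W = −Σ d ⊗ ∂E/∂d accumulated per interaction term and verified
  against −dE/d ln V.  The ideal-gas equation of state and the 1 bar
  mean pressure of the liquid are recovered within statistical error.
* Degrees of freedom 3N−3 (center-of-mass momentum removed and
  preserved); flexible water, no constraints; positions never wrapped
  (minimum image lives inside the force kernels), so mean-squared
  displacements need no unwrapping bookkeeping.

Neighbor handling is a compiled O(N²) minimum-image double loop rather
than a cell list: at the box sizes in scope (≤ 126 molecules, ≤ 400
atoms) the compiled quadratic loop is faster than list maintenance and
comfortably exceeds the performance target (10 ps of a 378-atom NVT
run takes about a minute on one CPU).

## Observables

* **RDF**: shell-count histogram (0.05 Å bins) normalized per frame
  against the ideal-gas expectation at that frame's density, so NPT
  trajectories average correctly; first-peak height/position by
  quadratic interpolation through the maximum bin and its neighbors.
* **Self-diffusion**: multi-origin MSD of O atoms (origins spaced half
  the maximum lag, capping origin overlap at 50%), D = slope/6 over a
  configurable window (2–10 ps default at production scale), plus the
  Yeh–Hummer cubic-box correction ξ·k_BT/(6πηL), ξ = 2.837297, with a
  user-supplied viscosity (0.896 mPa·s at 298 K by default).
* **Density**: post-equilibration mean (first 20% discarded) with a
  standard error from 10 non-overlapping block means.
* **Isobar**: independent NPT runs per temperature; an interior
  maximum is refined by a quadratic through the top three points.

## The recovery experiment and its scale

The central test: composite LL + Δ dynamics must reproduce direct HL
dynamics — density, first O–O peak, diffusion — with deviations
shrinking as the carve radius grows.  Equilibrium density fluctuations
of a 126-water box are large (30 ps block means scatter by ~1.5%), so
naive independent runs cannot resolve a 1% density criterion at desk
scale.  Two choices make the comparison sharp:

* **Paired replicas**: composite and HL replicas share starting frames
  and random seeds (common thermostat/barostat noise streams).  Since
  the trained Δ is nearly exact, paired trajectories remain
  statistically locked together and the *difference* of observables
  has far smaller variance than either observable alone.  The pairing
  is strengthened by running the production barostat at a reduced
  mobility (κ_T = 1.5×10⁻⁵ bar⁻¹): the stationary NPT ensemble is
  mobility-independent, but slower volume dynamics means the shared
  noise stream dominates each replica's volume trajectory, so paired
  volumes stay locked.  The initial transient from the baseline-liquid
  starting configurations is likewise shared and is discarded (first
  40% of the NPT window).
* **Smoke scale**: the packaged experiment runs 64 waters (the
  smallest box whose edge exceeds twice the 6 Å Coulomb cutoff —
  which is why 64 rather than a smaller box), radii {2.5, 3.5} Å,
  3 replicas, 7 ps NPT + 12 ps NVT per replica, and a short MSD fit
  window (0.5–3 ps) applied identically to both surfaces so that its
  finite-time bias cancels in the comparison.  Problem sizes are the
  package's own defaults for a quick, reproducible experiment;
  everything scales up by changing `ProtocolSettings`.

The error protocol follows the replica convention: observables are
replica means with standard errors from the scatter (9 replicas at
production scale; fewer in the packaged smoke runs).

## What the synthetic setting does and does not show

The generator emulates: a liquid with realistic density, structure and
hydrogen-bond-network physics; a baseline with a several-percent
density error; a strictly short-ranged, angular-content-bearing
difference to the target theory; and energy-only labels.  It does not
emulate: electronic-structure label noise, basis-set incompleteness
(the CBS two-point extrapolation utility implements the arithmetic,
E_CBS = (Y^β E_Y − X^β E_X)/(Y^β − X^β), β = 3 by default, but no real
correlation energies), nuclear quantum effects, or the capacity limits
of neural potentials.  A passing recovery experiment therefore
validates the *pipeline logic* — carving, cumulative datasets,
energy-only Δ-fitting, composite NPT/NVT — not the accuracy of any
particular electronic-structure method.

## Degenerate inputs and tie-breaks

Non-orthorhombic cells, boxes smaller than twice the largest cutoff,
clusters with broken molecules, and carve radii beyond L/2 − extent
are rejected with specific errors.  Monotone g(r) raises a no-peak
error; NVE trajectories are rejected by the density estimator; a
compact-mode count larger than the full count clamps with a warning.
The CSVR bracket is evaluated in its numerically stable squared form;
angle gradients guard the sin θ → 0 limit.  All stochastic stages
(velocity initialization, carving draws, splits, thermostat,
barostat) consume explicit seeds, and per-replica seeds derive
deterministically from a master seed via a seed sequence.

## Known limitations

Cubic cells and pure water only; linear Δ-model capacity; the DSF
baseline's dielectric response differs from Ewald-based water models
(irrelevant to the two-level comparison, which shares electrostatics
exactly); smoke-scale statistics are deliberately minimal — the 1%/
0.05/10% recovery margins at 64 waters rest on the paired-replica
variance reduction described above.
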