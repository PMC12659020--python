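# deltamd

**Δ-learning pipeline for condensed-phase simulation, tested end to end
on a synthetic two-level theory of liquid water.**

Reaching coupled-cluster-quality potential-energy surfaces for liquids
is done today by *Δ-learning*: run an affordable baseline theory
everywhere, and train a small correction model — on gas-phase cluster
energies only — for the difference to the expensive target theory.
The composite surface

```
E(R) = E_baseline(R) + ΔE_model(R),      Δ ≡ E_high − E_low
```

inherits the baseline's long range while the learned Δ is strictly
short-ranged.  Whether that actually works hinges on one assumption:
*energy differences of small open clusters, carved from periodic
snapshots, transfer to the periodic bulk*.

`deltamd` implements the entire workflow — cluster carving, cumulative
datasets, energy-only ridge-regression Δ-models with analytic forces,
NVE/NVT/NPT molecular dynamics (CSVR thermostat, stochastic cell
rescaling barostat), and RDF/diffusion/density analysis — against a
built-in **two-level synthetic theory**: a flexible-water baseline
(LL) and a target (HL) that share their electrostatics exactly and
differ only within 4 Å (perturbed Lennard-Jones plus a
Stillinger–Weber-style three-body term).  Because HL is directly
simulable, every link in the chain can be checked against ground
truth, including the self-consistent convergence of observables with
cluster radius.  The audience is method developers who want a
transparent, fully-testable sandbox for Δ-learning protocol decisions
(dataset quotas, radii, convergence thresholds) before spending
coupled-cluster compute.

## Worked example

Train a Δ-model on clusters and predict periodic-box energy
differences it has never seen (`examples/03_train_delta.py`, ~2 min):

```
trained on 405 clusters, validated on 45
validation RMSE: 0.005 meV per molecule

frame  ΔE predicted   ΔE direct  (eV, whole box)
    0       -1.0028     -1.0037
    1       -0.9466     -0.9474
    2       -1.0154     -1.0163
    ...
```

A model fitted only to open clusters of radius ≤ 3.5 Å reproduces the
whole-box HL−LL energy to fractions of a meV per molecule — the
cluster-to-bulk transfer that justifies the approach.

The locality that makes this possible
(`examples/01_two_level_theory.py`, seconds):

```
 d_OO / Å    E_LL / eV    E_HL / eV   HL−LL / eV
      2.8    -0.103108    -0.108928    -0.005820
      3.6    -0.063544    -0.065181    -0.001637
      4.0    -0.041963    -0.041963     0.000000
      5.5    -0.017422    -0.017422     0.000000
```

Other examples: carving cumulative datasets (`02`), NPT dynamics with
density/RDF/diffusion analysis (`04`), the full blueprint with its
radius-convergence table (`05`), and complete-basis-set extrapolation
arithmetic (`06`).  A thin CLI mirrors the stages:

```bash
deltamd generate --n 126 --density 0.997 --seed 0 --out box.extxyz
deltamd md --start box.extxyz --ensemble npt --level LL --steps 20000 --out run
deltamd analyze density --traj run.extxyz
```

## What is in the box

| module | contents |
|---|---|
| `deltamd.structures`, `deltamd.xyzio`, `deltamd.units` | configurations, topology, minimum image, extended-XYZ I/O, unit system |
| `deltamd.potentials` | the two-level theory (LL, HL, composite) with analytic forces and virial |
| `deltamd.carve` | whole-molecule cluster carving, cumulative datasets, ΔE labelling |
| `deltamd.descriptors`, `deltamd.deltamodel` | invariant descriptors (4 Å cutoff), energy-only ridge Δ-model, analytic force/virial kernels |
| `deltamd.md` | velocity Verlet, CSVR thermostat, stochastic cell rescaling, NVE/NVT/NPT drivers |
| `deltamd.observables` | RDF + first peak, MSD diffusion + Yeh–Hummer correction, block-averaged density, isobars |
| `deltamd.protocol` | radius-convergence workflow, compact-dataset mode, force-scale diagnostic, CBS extrapolation, blueprint driver |

`docs/methods.md` documents the model, parameters, numerical choices
and limitations.

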