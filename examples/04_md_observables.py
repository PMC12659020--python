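"""Constant-pressure dynamics and the standard liquid-water observables.

Runs a short NPT trajectory of the baseline liquid at 298 K / 1 bar,
then NVT from its endpoint, and prints the block-averaged density, the
first O–O RDF peak, and the finite-size-corrected self-diffusion
coefficient.
"""

from deltamd import (RunConfig, calibrate_two_level, density, diffusion,
                     first_peak, generate_water_box, identify_molecules, rdf,
                     run)

theory = calibrate_two_level()
box = generate_water_box(64, 0.997, seed=21)
pot = theory.bind("LL", box.elements, identify_molecules(box))

print("NVT warmup 2 ps, NPT 15 ps, NVT 10 ps (64 waters) ...")
warm = run(pot, box, RunConfig(ensemble="nvt", n_steps=4000, stride=4000, seed=22))
npt = run(pot, None, RunConfig(ensemble="npt", n_steps=30000, stride=100, seed=23),
          state=warm.final_state)
nvt = run(pot, None, RunConfig(ensemble="nvt", n_steps=20000, stride=25, seed=24),
          state=npt.final_state)

rho = density(npt.trajectory)
print(f"density: {rho.mean:.4f} ± {rho.stderr:.4f} g/cm³ "
      f"({rho.n_blocks} blocks, first {rho.equil_fraction:.0%} discarded)")

g = rdf(nvt.trajectory, "O-O", dr=0.05)
height, position = first_peak(g)
print(f"first O–O peak: g = {height:.2f} at r = {position:.2f} Å")

d = diffusion(nvt.trajectory, fit_window_ps=(1.0, 5.0), eta_mPas=0.896)
print(f"diffusion: D_pbc = {d.D_pbc:.3f} Å²/ps, "
      f"finite-size corrected D = {d.D_corrected:.3f} Å²/ps "
      f"(+{d.D_corrected - d.D_pbc:.3f} Yeh–Hummer at L = {d.L:.2f} Å)")
print("\nThe correction term ξ·kB·T/(6πηL) vanishes as the box grows;")
print("at production scale it is ~0.044 Å²/ps for the 15.577 Å box.")
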