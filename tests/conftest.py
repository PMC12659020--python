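"""Shared fixtures: the default theory and equilibrated systems.

Expensive simulations are session-scoped so the whole suite pays for
each one once; several are shared between the engine tests and the
acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from deltamd import (RunConfig, TwoLevelTheory, generate_water_box,
                     identify_molecules, run)


@pytest.fixture(scope="session")
def theory() -> TwoLevelTheory:
    return TwoLevelTheory()


@pytest.fixture(scope="session")
def box126(theory):
    """126-water box at experimental density, generated fresh."""
    return generate_water_box(126, 0.997, seed=11)


@pytest.fixture(scope="session")
def ll_source(theory, box126):
    """Short LL equilibration + sampling of the 126-water box.

    2.5 ps warmup, then 7.5 ps sampled every 125 fs → 60 liquid frames.
    """
    topo = identify_molecules(box126)
    pot = theory.bind("LL", box126.elements, topo)
    eq = run(pot, box126, RunConfig(ensemble="nvt", n_steps=5000, stride=5000, seed=101))
    prod = run(pot, None, RunConfig(ensemble="nvt", n_steps=15000, stride=250, seed=102),
               state=eq.final_state)
    return prod.trajectory[1:]


@pytest.fixture(scope="session")
def labelled_dataset(theory, ll_source):
    """Cumulative 2.5–5.5 Å dataset carved from the LL liquid, ΔE-labelled."""
    from deltamd import CarveSpec, build_cumulative_dataset, label_delta
    spec = CarveSpec(radii=(2.5, 3.5, 4.5, 5.5),
                     counts={2.5: 300, 3.5: 300, 4.5: 300, 5.5: 60}, seed=42)
    return label_delta(build_cumulative_dataset(ll_source, spec), theory)


@pytest.fixture(scope="session")
def delta_model(labelled_dataset):
    from deltamd import train
    model, report = train(labelled_dataset, ridge_lambda=1e-6, seed=0)
    return model


@pytest.fixture(scope="session")
def heldout_frames(theory, ll_source):
    """20 periodic frames from an independent continuation run (not carved from)."""
    frame = ll_source[len(ll_source) - 1]
    topo = identify_molecules(frame)
    pot = theory.bind("LL", frame.elements, topo)
    res = run(pot, frame, RunConfig(ensemble="nvt", n_steps=4000, stride=200, seed=777))
    return res.trajectory[1:]


@pytest.fixture(scope="session")
def small_cluster(theory, ll_source):
    """An open ~20-molecule cluster carved from the liquid."""
    from deltamd import carve_cluster
    return carve_cluster(ll_source[0], center_mol=5, r_c=5.0)


# ---- shared long runs -----------------------------------------------------

@pytest.fixture(scope="session")
def nve_run_126(theory, ll_source):
    """10 ps NVE of the 126-water box at the baseline level."""
    frame = ll_source[10]
    topo = identify_molecules(frame)
    pot = theory.bind("LL", frame.elements, topo)
    return run(pot, frame, RunConfig(ensemble="nve", n_steps=20000, stride=200,
                                     seed=3, T=298.0))


@pytest.fixture(scope="session")
def csvr_run_50ps(theory):
    """50 ps NVT of a 64-water box at the protocol thermostat time (0.1 ps)."""
    box = generate_water_box(64, 0.997, seed=21)
    topo = identify_molecules(box)
    pot = theory.bind("LL", box.elements, topo)
    warm = run(pot, box, RunConfig(ensemble="nvt", n_steps=4000, stride=4000, seed=5))
    return run(pot, None, RunConfig(ensemble="nvt", n_steps=100000, stride=50,
                                    seed=6, tau_T=0.1), state=warm.final_state)


@pytest.fixture(scope="session")
def npt_run_64(theory):
    """40 ps NPT of a 64-water box at 298 K / 1 bar (after 10 ps settling)."""
    box = generate_water_box(64, 0.997, seed=31)
    topo = identify_molecules(box)
    pot = theory.bind("LL", box.elements, topo)
    warm = run(pot, box, RunConfig(ensemble="nvt", n_steps=3000, stride=3000, seed=7))
    settle = run(pot, None, RunConfig(ensemble="npt", n_steps=20000, stride=20000,
                                      seed=8), state=warm.final_state)
    return run(pot, None, RunConfig(ensemble="npt", n_steps=80000, stride=100,
                                    seed=9), state=settle.final_state)


@pytest.fixture(scope="session")
def recovery_table(theory):
    """The Δ-recovery experiment at smoke scale (64 waters, radii 2.5/3.5).

    Builds the cumulative dataset from a baseline NPT sampling run,
    trains per cumulative radius, and runs paired composite vs direct
    high-level NPT+NVT replicas (common seeds and starting frames act
    as common random numbers for the comparison).
    """
    from deltamd import CarveSpec, build_cumulative_dataset, label_delta
    from deltamd.protocol import ProtocolSettings, Thresholds, converge_radius

    box = generate_water_box(64, 0.997, seed=7)
    topo = identify_molecules(box)
    pot = theory.bind("LL", box.elements, topo)
    eq = run(pot, box, RunConfig(ensemble="nvt", n_steps=4000, stride=4000, seed=201))
    prod = run(pot, None, RunConfig(ensemble="npt", n_steps=12000, stride=200,
                                    seed=202), state=eq.final_state)
    source = prod.trajectory[10:]

    spec = CarveSpec(radii=(2.5, 3.5), counts={2.5: 400, 3.5: 200}, seed=42)
    dataset = label_delta(build_cumulative_dataset(source, spec), theory)
    # the slow barostat mobility strengthens the common-random-numbers
    # pairing: paired runs share the volume noise stream, so the paired
    # difference of observables carries far less variance than either
    # observable alone (the stationary NPT ensemble is mobility-independent)
    settings = ProtocolSettings(n_replicas=3, npt_steps=14000, nvt_steps=24000,
                                stride=25, fit_window_ps=(0.5, 3.0),
                                compressibility=1.5e-5,
                                density_equil_fraction=0.4)
    return converge_radius(source, theory, spec, settings, Thresholds(),
                           master_seed=9, dataset=dataset)
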