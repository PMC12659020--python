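"""Cluster carving and cumulative dataset construction.

Whole water molecules are cut out of periodic snapshots around a
center molecule: a molecule belongs to the cluster iff its O atom lies
within the carve radius of the center O (minimum image).  Clusters are
unwrapped to contiguous open-boundary geometries with the center O at
the origin.  Cumulative datasets mix many small clusters with few
large ones — the economy that makes high-level labelling affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structures import AtomicConfiguration, Trajectory, identify_molecules, minimum_image
from .potentials import TwoLevelTheory, evaluate
from .xyzio import write_extxyz, read_extxyz


@dataclass
class CarveSpec:
    """Which radii to carve, how many clusters of each, and the seed."""

    radii: tuple = (2.5, 3.5, 4.5, 5.5)           # Å
    counts: dict = field(default_factory=lambda: {2.5: 1800, 3.5: 1800, 4.5: 1800, 5.5: 1800})
    seed: int = 0
    validation_fraction: float = 0.10
    margin: float = 1.2   # Å of molecular extent beyond the carve radius

    def __post_init__(self):
        radii = tuple(sorted(self.radii))
        if radii != tuple(self.radii):
            raise ValueError("radii must be strictly increasing")
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if any(self.counts.get(r, 0) < 0 for r in self.radii):
            raise ValueError("counts must be non-negative")

    def check_box(self, edge: float) -> None:
        if max(self.radii) + self.margin > edge / 2.0:
            raise ValueError(
                f"carve radius {max(self.radii)} Å (+{self.margin} Å molecular extent) "
                f"exceeds half the box edge {edge / 2.0:.2f} Å")


@dataclass
class LabeledDataset:
    """Open-boundary clusters with ΔE labels and per-cluster provenance."""

    clusters: list                      # AtomicConfiguration, open boundary
    labels: Optional[np.ndarray]        # ΔE = E_HL − E_LL, eV; None until labelled
    radii: np.ndarray                   # carve radius per cluster
    source_frame: np.ndarray            # frame index per cluster
    center_mol: np.ndarray              # center molecule index per cluster
    split: np.ndarray                   # "train" / "val" per cluster

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_molecules(self) -> np.ndarray:
        return np.array([c.n_atoms // 3 for c in self.clusters])

    def subset_max_radius(self, r_max: float) -> "LabeledDataset":
        """Cumulative subset: every cluster with radius ≤ r_max."""
        m = self.radii <= r_max + 1e-9
        return LabeledDataset(
            clusters=[c for c, keep in zip(self.clusters, m) if keep],
            labels=None if self.labels is None else self.labels[m],
            radii=self.radii[m], source_frame=self.source_frame[m],
            center_mol=self.center_mol[m], split=self.split[m])

    def manifest(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "radius": self.radii,
            "source_frame": self.source_frame,
            "center_mol": self.center_mol,
            "n_molecules": self.n_molecules,
            "split": self.split,
        })
        if self.labels is not None:
            df["delta_energy"] = self.labels
        return df

    def save(self, xyz_path, manifest_path) -> None:
        frames = []
        for i, c in enumerate(self.clusters):
            f = c.copy()
            if self.labels is not None:
                f.info["delta_energy"] = float(self.labels[i])
            f.info["radius"] = float(self.radii[i])
            f.info["split"] = str(self.split[i])
            frames.append(f)
        write_extxyz(frames, xyz_path)
        self.manifest().to_csv(manifest_path, index=False)


def load_dataset(xyz_path, manifest_path) -> LabeledDataset:
    traj = read_extxyz(xyz_path)
    df = pd.read_csv(manifest_path)
    labels = df["delta_energy"].to_numpy() if "delta_energy" in df else None
    return LabeledDataset(clusters=list(traj.frames), labels=labels,
                          radii=df["radius"].to_numpy(),
                          source_frame=df["source_frame"].to_numpy(),
                          center_mol=df["center_mol"].to_numpy(),
                          split=df["split"].to_numpy())


def carve_cluster(frame: AtomicConfiguration, center_mol: int, r_c: float,
                  topology=None, margin: float = 1.2) -> AtomicConfiguration:
    """Carve one open-boundary cluster of radius `r_c` around `center_mol`.

    Includes the center molecule and every molecule whose O–O
    minimum-image distance to the center O is ≤ r_c; molecules are kept
    whole, unwrapped relative to the center O, which ends up at the
    origin.  The result has no cell.
    """
    if not frame.periodic:
        raise ValueError("carving requires a periodic frame")
    L = frame.edge
    if r_c + margin > L / 2.0:
        raise ValueError(f"carve radius {r_c} Å too large for box edge {L:.2f} Å")
    topo = topology if topology is not None else identify_molecules(frame)
    o_center = topo.oxygens[center_mol]
    d_o = minimum_image(frame.positions[topo.oxygens] - frame.positions[o_center], frame.cell)
    r_oo = np.linalg.norm(d_o, axis=1)
    members = np.flatnonzero(r_oo <= r_c)

    elements, positions = [], []
    for m in members:
        o = topo.oxygens[m]
        # place the molecule's O by its minimum image, H atoms by their
        # minimum image relative to that O: molecules stay whole
        o_pos = d_o[m]
        elements.append("O")
        positions.append(o_pos)
        for h in topo.hydrogens[m]:
            dh = minimum_image(frame.positions[h] - frame.positions[o], frame.cell)
            elements.append("H")
            positions.append(o_pos + dh)
    return AtomicConfiguration(
        elements=elements, positions=np.array(positions), cell=None,
        info={"radius": float(r_c), "center_mol": int(center_mol)})


def build_cumulative_dataset(frames: Trajectory, spec: CarveSpec) -> LabeledDataset:
    """Draw (frame, center) pairs per radius and carve; union over radii.

    Sampling is uniform without replacement within each radius and
    independent across radii, with a deterministic seed.  The
    train/validation split is a stratified-by-radius random 10%.
    """
    topos = [identify_molecules(f) for f in frames]
    for f in frames:
        spec.check_box(f.edge)
    pool = [(fi, m) for fi, topo in enumerate(topos) for m in range(topo.n_molecules)]
    rng = np.random.default_rng(spec.seed)

    clusters, radii, src, cen = [], [], [], []
    for r in spec.radii:
        n = spec.counts.get(r, 0)
        if n > len(pool):
            raise ValueError(
                f"requested {n} clusters at radius {r} Å but only {len(pool)} "
                f"(frame, center) pairs are available")
        pick = rng.choice(len(pool), size=n, replace=False)
        for idx in pick:
            fi, m = pool[idx]
            clusters.append(carve_cluster(frames[fi], m, r, topology=topos[fi],
                                          margin=spec.margin))
            radii.append(r)
            src.append(fi)
            cen.append(m)

    radii = np.array(radii)
    split = np.full(len(clusters), "train", dtype=object)
    for r in spec.radii:
        idx = np.flatnonzero(radii == r)
        n_val = int(round(spec.validation_fraction * len(idx)))
        if n_val:
            val_idx = rng.permutation(idx)[:n_val]
            split[val_idx] = "val"
    return LabeledDataset(clusters=clusters, labels=None, radii=radii,
                          source_frame=np.array(src), center_mol=np.array(cen),
                          split=split.astype(str))


def label_delta(ds: LabeledDataset, theory: TwoLevelTheory) -> LabeledDataset:
    """Attach energy-only labels ΔE = E_HL − E_LL to every cluster."""
    labels = np.empty(len(ds))
    for i, cluster in enumerate(ds.clusters):
        if cluster.periodic:
            raise ValueError(f"cluster {i} is periodic; labels are defined on open clusters")
        try:
            e_hl = evaluate(theory, "HL", cluster).energy
            e_ll = evaluate(theory, "LL", cluster).energy
        except Exception as exc:
            raise RuntimeError(
                f"labelling failed for cluster {i} "
                f"(radius {ds.radii[i]}, frame {ds.source_frame[i]}, "
                f"center {ds.center_mol[i]}): {exc}") from exc
        labels[i] = e_hl - e_ll
    ds.labels = labels
    return ds
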