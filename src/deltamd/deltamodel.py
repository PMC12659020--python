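"""Energy-only Δ-model: ridge regression on summed invariant descriptors.

The model predicts the difference between the target and baseline
surfaces from *energy labels alone*; forces and virial come from the
exact analytic gradient of the fitted form.  Trained on open-boundary
clusters, deployable unchanged on periodic boxes — the central
transferability assumption of the Δ-learning blueprint.

Model form for a configuration with atoms i and molecule count M:

    ΔE = Σ_i w_{Z_i} · f_i / s  +  b·M

with per-element weight vectors (O, H) fitted by ridge regression in
the raw feature space, and a per-molecule intercept `b` that absorbs
the size-proportional part of ΔE (it contributes no forces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .descriptors import DescriptorSpec, feature_sums, contract
from .structures import AtomicConfiguration
from .potentials import PotentialResult


@dataclass
class TrainReport:
    n_train: int
    n_val: int
    rmse_per_molecule_train: float     # eV
    rmse_per_molecule_val: float       # eV
    per_radius_val_rmse: dict          # radius -> eV per molecule
    ridge_lambda: float
    seed: int


@dataclass
class DeltaModel:
    spec: DescriptorSpec
    weights: np.ndarray                # (n_features,) on scaled columns
    scales: np.ndarray                 # (n_features,)
    intercept_per_molecule: float
    ridge_lambda: float
    report: Optional[TrainReport] = None

    def __post_init__(self):
        if len(self.weights) != self.spec.n_features:
            raise ValueError("weight dimension must equal descriptor dimension")
        d1 = self.spec.n_per_element
        w_eff = self.weights / self.scales
        self._wO = np.ascontiguousarray(w_eff[:d1])
        self._wH = np.ascontiguousarray(w_eff[d1:])
        # pre-expanded kernel inputs, reused every MD step
        from .descriptors import _expand_element_weights, _contract
        self._wradO, self._polyO = _expand_element_weights(self.spec, self._wO)
        self._wradH, self._polyH = _expand_element_weights(self.spec, self._wH)
        self._kernel = _contract

    # ---- low-level evaluator (used inside the MD loop) ----
    def compute(self, positions: np.ndarray, zcode: np.ndarray, L: float):
        mu, width, eta, _, _ = self.spec.arrays()
        e, f, w = self._kernel(np.ascontiguousarray(positions, dtype=float),
                               zcode, L, self.spec.cutoff, mu, width, eta,
                               self._wradO, self._wradH, self._polyO, self._polyH)
        n_mol = int(np.sum(zcode == 0))
        return e + self.intercept_per_molecule * n_mol, f, w

    def predict(self, cfg: AtomicConfiguration) -> PotentialResult:
        """Δ energy, analytic forces and virial for one configuration."""
        unknown = set(cfg.elements) - {"O", "H"}
        if unknown:
            raise ValueError(f"elements outside the training set: {sorted(unknown)}")
        zcode = np.array([0 if el == "O" else 1 for el in cfg.elements], dtype=np.int64)
        L = cfg.edge if cfg.periodic else -1.0
        e, f, w = self.compute(cfg.positions, zcode, L)
        return PotentialResult(energy=e, forces=f, virial=w)

    # ---- serialization ----
    def save(self, path) -> None:
        payload = {
            "cutoff": self.spec.cutoff,
            "radial_centers": self.spec.radial_centers.tolist(),
            "radial_width": self.spec.radial_width,
            "eta_angular": self.spec.eta_angular,
            "angular_set": [list(a) for a in self.spec.angular_set],
            "weights": self.weights.tolist(),
            "scales": self.scales.tolist(),
            "intercept_per_molecule": self.intercept_per_molecule,
            "ridge_lambda": self.ridge_lambda,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DeltaModel":
        d = json.loads(Path(path).read_text())
        spec = DescriptorSpec(cutoff=d["cutoff"],
                              radial_centers=np.array(d["radial_centers"]),
                              radial_width=d["radial_width"],
                              eta_angular=d["eta_angular"],
                              angular_set=tuple((a[0], int(a[1])) for a in d["angular_set"]))
        return cls(spec=spec, weights=np.array(d["weights"]),
                   scales=np.array(d["scales"]),
                   intercept_per_molecule=d["intercept_per_molecule"],
                   ridge_lambda=d["ridge_lambda"])


def zero_model(spec: Optional[DescriptorSpec] = None) -> DeltaModel:
    """A Δ-model that predicts exactly zero everywhere."""
    spec = spec or DescriptorSpec()
    return DeltaModel(spec=spec, weights=np.zeros(spec.n_features),
                      scales=np.ones(spec.n_features), intercept_per_molecule=0.0,
                      ridge_lambda=0.0)


def design_row(cfg: AtomicConfiguration, spec: DescriptorSpec) -> np.ndarray:
    """Per-element feature sums of one configuration, flattened."""
    zcode = np.array([0 if el == "O" else 1 for el in cfg.elements], dtype=np.int64)
    L = cfg.edge if cfg.periodic else -1.0
    return feature_sums(cfg.positions, zcode, L, spec).ravel()


def train(ds, ridge_lambda: float = 1e-6, seed: int = 0,
          spec: Optional[DescriptorSpec] = None) -> tuple[DeltaModel, TrainReport]:
    """Fit the Δ-model on a labelled cluster dataset.

    Uses the dataset's stratified 10% validation split; the
    per-molecule count enters as an unpenalized-in-spirit extra column
    whose coefficient becomes the intercept.  Deterministic:
    closed-form ridge solution.
    """
    if ds.labels is None:
        raise ValueError("dataset must be labelled before training")
    if len(ds) < 2:
        raise ValueError("need at least 2 clusters to train")
    spec = spec or DescriptorSpec()

    X = np.array([design_row(c, spec) for c in ds.clusters])
    nmol = ds.n_molecules.astype(float)
    y = np.asarray(ds.labels, dtype=float)
    is_val = ds.split == "val"
    tr = ~is_val

    # The ridge penalty acts on the raw (unscaled) feature space.  With
    # per-column rescaling, the minimum-norm solution loads weight onto
    # columns the small clusters barely sample and diverges when the
    # model is deployed on bulk boxes, whose features lie far outside
    # the cluster manifold; raw-space shrinkage keeps the effective
    # weights at the physical scale and extrapolation bounded.
    scales = np.ones(X.shape[1])
    Xs = np.column_stack([X, nmol])

    A = Xs[tr].T @ Xs[tr]
    n_p = A.shape[0]
    A[np.diag_indices(n_p)] += ridge_lambda
    b = Xs[tr].T @ y[tr]
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "ridge system is singular; use ridge_lambda > 0") from exc
    if ridge_lambda == 0.0 and not np.all(np.isfinite(theta)):
        raise np.linalg.LinAlgError("ridge system is singular; use ridge_lambda > 0")

    resid = Xs @ theta - y
    per_mol = resid / nmol

    def rmse(mask):
        return float(np.sqrt(np.mean(per_mol[mask] ** 2))) if np.any(mask) else float("nan")

    per_radius = {}
    for r in np.unique(ds.radii):
        m = is_val & (ds.radii == r)
        per_radius[float(r)] = rmse(m)

    report = TrainReport(
        n_train=int(tr.sum()), n_val=int(is_val.sum()),
        rmse_per_molecule_train=rmse(tr), rmse_per_molecule_val=rmse(is_val),
        per_radius_val_rmse=per_radius, ridge_lambda=ridge_lambda, seed=seed)
    model = DeltaModel(spec=spec, weights=theta[:-1], scales=scales,
                       intercept_per_molecule=float(theta[-1]),
                       ridge_lambda=ridge_lambda, report=report)
    return model, report
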