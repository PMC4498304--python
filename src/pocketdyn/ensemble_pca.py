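"""Cartesian-coordinate PCA of a superposed conformational ensemble.

The ensemble is an M x 3N matrix of flattened coordinates of the same N
atoms in M conformations, all superposed onto one reference frame.  The
covariance matrix C_ij = <(r_i - <r_i>)(r_j - <r_j>)> (population form,
normalised by M) is diagonalised; its eigenvectors are the principal
components and each eigenvalue is the ensemble variance along that
component.  Projections of conformations onto the dominant components
give the low-dimensional subspace used for clustering, and per-atom RMSF
profiles summarise local flexibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, PairingError
from .structure_io import CoordinateSet, superpose

__all__ = [
    "EnsembleMatrix",
    "PCModel",
    "PCScores",
    "build_ensemble",
    "covariance",
    "fit_pca",
    "project",
    "rmsf",
]


@dataclass
class EnsembleMatrix:
    """M x 3N matrix of superposed, flattened conformations."""

    X: np.ndarray
    conf_labels: tuple
    atom_labels: tuple

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.conf_labels = tuple(self.conf_labels)
        self.atom_labels = tuple(self.atom_labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (M x 3N)")
        if self.X.shape[1] != 3 * len(self.atom_labels):
            raise ValueError("column count must be 3 * number of atoms")
        if self.X.shape[0] != len(self.conf_labels):
            raise ValueError("row count must match conformation labels")

    @property
    def n_conformations(self) -> int:
        return self.X.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.X.shape[1] // 3

    def mean(self) -> np.ndarray:
        return self.X.mean(axis=0)

    def row_coords(self, i: int) -> np.ndarray:
        return self.X[i].reshape(-1, 3)


@dataclass
class PCModel:
    """Mean conformation + orthonormal principal components.

    ``components`` is 3N x K with columns sorted by descending eigenvalue;
    ``variance_fraction[k] = eigenvalue[k] / trace(C)``.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    atom_labels: tuple
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "schema": "pocketdyn.pcmodel/1",
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "atom_labels": [list(l) for l in self.atom_labels],
            "total_variance": self.total_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PCModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.array(d["mean"]),
            components=np.array(d["components"]),
            eigenvalues=np.array(d["eigenvalues"]),
            variance_fraction=np.array(d["variance_fraction"]),
            atom_labels=tuple(tuple(l) for l in d["atom_labels"]),
            total_variance=float(d["total_variance"]),
        )


@dataclass
class PCScores:
    """M x K projections of conformations onto principal components."""

    scores: np.ndarray
    component_ids: tuple = field(default_factory=tuple)
    conf_labels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if not self.component_ids:
            self.component_ids = tuple(range(1, self.scores.shape[1] + 1))


def build_ensemble(
    sets: list[CoordinateSet],
    reference: CoordinateSet,
    fit_indices=None,
    conf_labels=None,
) -> EnsembleMatrix:
    """Superpose every set onto ``reference`` over the fit subset and stack.

    All sets must be label-compatible with the reference; rows are the
    fitted, flattened coordinates.
    """
    if conf_labels is None:
        conf_labels = tuple(range(len(sets)))
    rows = []
    for cs in sets:
        if cs.labels != reference.labels:
            raise PairingError("ensemble member labels do not match reference")
        _, fitted, _ = superpose(cs, reference, fit_indices)
        rows.append(fitted.flatten())
    return EnsembleMatrix(np.array(rows), conf_labels, reference.labels)


def covariance(e: EnsembleMatrix) -> np.ndarray:
    """Population (1/M) covariance of the flattened coordinates."""
    if e.n_conformations < 2:
        raise InsufficientDataError("covariance needs at least 2 conformations")
    Xc = e.X - e.X.mean(axis=0)
    return Xc.T @ Xc / e.n_conformations


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-|component| entry of each PC positive."""
    out = components.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def fit_pca(
    C: np.ndarray,
    mean: np.ndarray,
    n_components: int,
    atom_labels=(),
) -> PCModel:
    """Diagonalise a covariance matrix and keep the top-K eigenpairs.

    Eigenvalues are clipped at zero (numerical negatives) and sorted
    descending; variance fractions are relative to the full trace.
    """
    C = np.asarray(C, dtype=float)
    dim = C.shape[0]
    if n_components > dim:
        raise ValueError(f"requested {n_components} components from a {dim}-dim matrix")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = float(np.trace(C))
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCModel(
        mean=np.asarray(mean, dtype=float).reshape(-1),
        components=evecs[:, :n_components],
        eigenvalues=evals[:n_components],
        variance_fraction=frac[:n_components],
        atom_labels=tuple(atom_labels),
        total_variance=total,
    )


def project(
    data,
    model: PCModel,
    fit_indices=None,
) -> PCScores:
    """Project conformations onto the model's principal components.

    ``data`` is an :class:`EnsembleMatrix` already in the model frame, or
    a list of CoordinateSets; in the latter case each set is first
    superposed onto the model's mean conformation over ``fit_indices``
    (all atoms when None).  score_k = (x - mean) . component_k.
    """
    if isinstance(data, EnsembleMatrix):
        X = data.X
        conf_labels = data.conf_labels
    else:
        mean_cs = CoordinateSet(
            model.atom_labels or tuple(range(len(model.mean) // 3)),
            model.mean.reshape(-1, 3),
        )
        rows = []
        for cs in data:
            if model.atom_labels and cs.labels != mean_cs.labels:
                raise PairingError("coordinate set labels do not match PC model")
            _, fitted, _ = superpose(
                cs, mean_cs.with_coords(mean_cs.coords), fit_indices
            )
            rows.append(fitted.flatten())
        X = np.array(rows)
        conf_labels = tuple(range(len(rows)))
    scores = (X - model.mean) @ model.components
    return PCScores(scores, conf_labels=conf_labels)


def rmsf(e: EnsembleMatrix) -> np.ndarray:
    """Per-atom RMS fluctuation about the ensemble mean (3-D norm), Å."""
    if e.n_conformations < 2:
        raise InsufficientDataError("rmsf needs at least 2 conformations")
    Xc = e.X - e.X.mean(axis=0)
    per_atom_sq = Xc.reshape(e.n_conformations, e.n_atoms, 3) ** 2
    return np.sqrt(per_atom_sq.sum(axis=2).mean(axis=0))
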