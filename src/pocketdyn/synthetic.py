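"""Deterministic synthetic inputs for every other module.

Three generators:

* **mode ensembles** — conformations built from a base structure plus a
  small number of planted orthonormal deformation modes with Gaussian
  amplitudes and isotropic noise.  This emulates the low-dimensional
  covariance structure that ensemble PCA assumes, with known ground
  truth for recovery tests.  Optional per-cluster amplitude centres
  plant a cluster structure in amplitude space.
* **ideal helices** — C-alpha traces with standard helical geometry, the
  stand-ins for helix segments.
* **cage pockets** — quasi-uniform (Fibonacci-sphere) atom shells with
  an optional conical aperture, plus the analytic solid-angle occlusion
  at the cage centre.  These are the geometry oracles for the
  ray-traced buriedness method.

All randomness flows through one seeded generator per call; identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .structure_io import CoordinateSet, Structure

__all__ = [
    "ModeEnsembleConfig",
    "CagePocketConfig",
    "make_mode_ensemble",
    "make_helix",
    "make_cage_pocket",
    "random_orthonormal_modes",
    "ensemble_to_structures",
    "fibonacci_sphere",
]


def _ca_structure(coords: np.ndarray, res_name: str = "GLY", chain: str = "A",
                  hetero: bool = False, source: str = "synthetic") -> Structure:
    n = len(coords)
    return Structure(
        chain_id=np.full(n, chain, dtype="U4"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, "", dtype="U2"),
        res_name=np.full(n, res_name, dtype="U5"),
        atom_name=np.full(n, "CA", dtype="U6"),
        element=np.full(n, "C", dtype="U2"),
        coords=coords,
        hetero=np.full(n, hetero, dtype=bool),
        source=source,
    )


def make_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
) -> Structure:
    """Ideal-helix C-alpha trace (rise Å/residue, twist deg/residue)."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    i = np.arange(n_residues)
    theta = np.deg2rad(twist) * i
    coords = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * i], axis=1
    )
    return _ca_structure(coords, source="synthetic helix")


def random_orthonormal_modes(n_atoms: int, n_modes: int, seed: int) -> np.ndarray:
    """Random mutually-orthonormal mode vectors, shape (n_modes, 3N)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3 * n_atoms, n_modes))
    Q, R = np.linalg.qr(A)
    # deterministic sign: positive diagonal of R
    return (Q * np.sign(np.diag(R))).T


@dataclass
class ModeEnsembleConfig:
    """Planted-mode ensemble: conformation = base + sum_k a_k v_k + noise.

    ``modes`` is (K, 3N) with mutually orthonormal rows; amplitudes are
    drawn Normal(0, amplitude_sd_k^2), optionally shifted by one of the
    ``cluster_centers`` rows (K columns) to plant clusters in amplitude
    space; noise is isotropic Normal(0, noise_sd^2) per coordinate.
    """

    n_atoms: int
    n_conformations: int
    modes: np.ndarray
    amplitude_sd: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    cluster_centers: np.ndarray | None = None

    def __post_init__(self):
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.amplitude_sd = np.atleast_1d(np.asarray(self.amplitude_sd, dtype=float))
        if self.modes.shape[1] != 3 * self.n_atoms:
            raise ConfigError("modes must have 3*n_atoms columns")
        if len(self.amplitude_sd) != len(self.modes):
            raise ConfigError("one amplitude SD per mode required")
        if np.any(self.amplitude_sd < 0) or self.noise_sd < 0:
            raise ConfigError("SDs must be non-negative")
        G = self.modes @ self.modes.T
        if not np.allclose(G, np.eye(len(self.modes)), atol=1e-10):
            raise ConfigError("planted modes must be mutually orthonormal (1e-10)")
        if self.cluster_centers is not None:
            self.cluster_centers = np.atleast_2d(
                np.asarray(self.cluster_centers, dtype=float)
            )
            if self.cluster_centers.shape[1] != len(self.modes):
                raise ConfigError("cluster_centers must have one column per mode")


def make_mode_ensemble(
    cfg: ModeEnsembleConfig, base: Structure | None = None
):
    """Generate the ensemble plus a ground-truth record.

    Returns ``(coordinate_sets, truth)`` where truth carries the planted
    modes, the drawn amplitudes, the per-conformation cluster
    assignments (when cluster centres are configured) and the base
    coordinates.  Reproducible per seed.
    """
    if base is None:
        base = make_helix(cfg.n_atoms)
    if base.n_atoms != cfg.n_atoms:
        raise ConfigError("base structure size does not match n_atoms")
    rng = np.random.default_rng(cfg.seed)
    base_flat = base.coords.reshape(-1)
    labels = tuple(
        ("base", str(c), int(r), "", str(a))
        for c, r, a in zip(base.chain_id, base.res_id, base.atom_name)
    )
    m, k = cfg.n_conformations, len(cfg.modes)
    if cfg.cluster_centers is not None:
        assign = rng.integers(0, len(cfg.cluster_centers), size=m)
        centers = cfg.cluster_centers[assign]
    else:
        assign = np.zeros(m, dtype=int)
        centers = np.zeros((m, k))
    amplitudes = centers + rng.normal(size=(m, k)) * cfg.amplitude_sd
    noise = rng.normal(size=(m, 3 * cfg.n_atoms)) * cfg.noise_sd
    X = base_flat + amplitudes @ cfg.modes + noise
    sets = [CoordinateSet(labels, X[i].reshape(-1, 3)) for i in range(m)]
    truth = {
        "modes": cfg.modes,
        "amplitudes": amplitudes,
        "assignments": assign,
        "noise_sd": cfg.noise_sd,
        "base": base_flat,
    }
    return sets, truth


def ensemble_to_structures(
    sets: list[CoordinateSet], template: Structure
) -> list[Structure]:
    """Turn generated CoordinateSets back into Structures for PDB output."""
    return [template.with_coords(cs.coords) for cs in sets]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


@dataclass
class CagePocketConfig:
    """Spherical atom cage with an optional conical aperture.

    ``aperture_half_angle`` (degrees) removes shell atoms whose direction
    lies within the cone around ``aperture_axis``; 0 keeps the cage
    closed.  The analytic record gives the exact solid-angle fraction
    blocked at the centre assuming an opaque shell:
    1 - (1 - cos(half_angle)) / 2.
    """

    radius: float = 8.0
    n_shell_atoms: int = 300
    aperture_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    aperture_half_angle: float = 0.0
    element: str = "C"
    ligand_coords: np.ndarray = field(default_factory=lambda: np.zeros((1, 3)))
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.n_shell_atoms < 10:
            raise ConfigError("need positive radius and >= 10 shell atoms")
        self.aperture_axis = np.asarray(self.aperture_axis, dtype=float)
        norm = np.linalg.norm(self.aperture_axis)
        if norm == 0:
            raise ConfigError("aperture axis must be non-zero")
        self.aperture_axis = self.aperture_axis / norm
        if not (0.0 <= self.aperture_half_angle < 180.0):
            raise ConfigError("aperture half-angle must be in [0, 180) degrees")
        self.ligand_coords = np.atleast_2d(np.asarray(self.ligand_coords, dtype=float))


def make_cage_pocket(cfg: CagePocketConfig):
    """Build the cage Structure, ligand CoordinateSet and analytic record.

    Shell atoms sit exactly on the sphere; a seeded random rotation is
    applied to the Fibonacci arrangement so different seeds give
    different (but reproducible) geometries.  Raises when the aperture
    leaves fewer than 10 atoms.
    """
    rng = np.random.default_rng(cfg.seed)
    dirs = fibonacci_sphere(cfg.n_shell_atoms)
    # seeded random rotation (QR of Gaussian, det forced to +1)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    dirs = dirs @ Q.T
    cos_cut = np.cos(np.deg2rad(cfg.aperture_half_angle))
    keep = dirs @ cfg.aperture_axis < cos_cut if cfg.aperture_half_angle > 0 else (
        np.ones(len(dirs), dtype=bool)
    )
    if keep.sum() < 10:
        raise ConfigError("aperture removes too many shell atoms (<10 left)")
    coords = cfg.radius * dirs[keep]
    cage = _ca_structure(coords, res_name="CGE", source="synthetic cage")
    cage = Structure(
        chain_id=cage.chain_id,
        res_id=cage.res_id,
        ins_code=cage.ins_code,
        res_name=cage.res_name,
        atom_name=cage.atom_name,
        element=np.full(len(coords), cfg.element, dtype="U2"),
        coords=coords,
        hetero=cage.hetero,
        source=cage.source,
    )
    lig_labels = tuple(
        ("ligand", "L", i + 1, "", "C") for i in range(len(cfg.ligand_coords))
    )
    ligand = CoordinateSet(
        lig_labels,
        cfg.ligand_coords,
        {"elements": ["C"] * len(cfg.ligand_coords)},
    )
    occluded_fraction = 1.0 - (1.0 - np.cos(np.deg2rad(cfg.aperture_half_angle))) / 2.0
    record = {
        "occluded_fraction": float(occluded_fraction),
        "n_shell_atoms": int(keep.sum()),
        "radius": cfg.radius,
        "aperture_half_angle": cfg.aperture_half_angle,
        "aperture_axis": cfg.aperture_axis.tolist(),
    }
    return cage, ligand, record
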