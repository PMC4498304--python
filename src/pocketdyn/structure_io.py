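"""Structure I/O, atom selection and least-squares superposition.

Protein conformations are read from (possibly multi-model) PDB files into
array-backed :class:`Structure` objects.  Selections pull named residue
segments (e.g. the helices flanking a binding groove) into order-locked
:class:`CoordinateSet` objects, which are the unit of all downstream
numerics: superposition, RMSD, ensemble PCA and hotspot mapping.

Coordinates are Å throughout and are stored exactly as parsed — no
re-centering happens on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateFitError,
    FormatError,
    PairingError,
    SelectionError,
)

__all__ = [
    "Structure",
    "CoordinateSet",
    "ResidueSelection",
    "Transform",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "superpose",
    "rmsd",
]


@dataclass
class Structure:
    """One conformation: parallel per-atom arrays plus provenance.

    ``chain_id``, ``res_id``, ``ins_code``, ``res_name``, ``atom_name``,
    ``element`` are 1-D arrays of equal length; ``coords`` is (n, 3) in Å.
    ``hetero`` flags HETATM records, ``is_hydrogen`` flags H atoms (kept on
    read, but flagged so geometric stages can exclude them).
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    ins_code: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    hetero: np.ndarray
    model_id: int = 1
    source: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all atom coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) == "H"

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def transformed(self, transform: "Transform") -> "Structure":
        return self.with_coords(transform.apply(self.coords))


@dataclass
class CoordinateSet:
    """Ordered atom labels + (N, 3) coordinates; the r_i of the PCA model.

    Labels are tuples ``(segment, chain, res_id, ins_code, atom_name)``
    and are order-locked with the coordinate rows: two CoordinateSets are
    pairable only if their label sequences are identical.
    """

    labels: tuple
    coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coordinate rows must be equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def flatten(self) -> np.ndarray:
        """Row-major 3N vector (x1, y1, z1, x2, ...)."""
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(self.labels, coords, dict(self.meta))

    def subset(self, indices) -> "CoordinateSet":
        idx = np.asarray(indices, dtype=int)
        return CoordinateSet(
            tuple(self.labels[i] for i in idx), self.coords[idx], dict(self.meta)
        )


@dataclass
class ResidueSelection:
    """Named segments mapped to inclusive residue ranges.

    ``segments`` maps a segment name (e.g. ``"alpha2"``) to one or more
    ``(chain, first_res, last_res)`` tuples.  Segment order is the order
    of insertion and fixes the atom order of any selection made with it.
    Segments may not overlap within one selection.
    """

    segments: dict

    def __post_init__(self):
        norm = {}
        covered = set()
        for name, ranges in self.segments.items():
            if isinstance(ranges, tuple) and len(ranges) == 3 and not isinstance(
                ranges[0], tuple
            ):
                ranges = [ranges]
            ranges = [tuple(r) for r in ranges]
            for chain, lo, hi in ranges:
                if hi < lo:
                    raise ValueError(f"segment {name!r}: empty range {lo}-{hi}")
                for r in range(int(lo), int(hi) + 1):
                    key = (str(chain), r)
                    if key in covered:
                        raise ValueError(
                            f"segment {name!r} overlaps another segment at "
                            f"chain {chain} residue {r}"
                        )
                    covered.add(key)
            norm[name] = ranges
        self.segments = norm

    def to_jsonable(self) -> dict:
        return {k: [list(r) for r in v] for k, v in self.segments.items()}

    @classmethod
    def from_jsonable(cls, d: dict) -> "ResidueSelection":
        return cls({k: [tuple(r) for r in v] for k, v in d.items()})


@dataclass
class Transform:
    """Proper rigid motion x -> x @ R.T + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


def _from_atom_array(arr, model_id: int, source: str) -> Structure:
    return Structure(
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        res_id=np.asarray(arr.res_id, dtype=int),
        ins_code=np.asarray(arr.ins_code, dtype="U2"),
        res_name=np.asarray(arr.res_name, dtype="U5"),
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=np.asarray(arr.element, dtype="U2"),
        coords=np.asarray(arr.coord, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        model_id=model_id,
        source=source,
    )


def read_pdb(path) -> list[Structure]:
    """Read a (possibly multi-model) PDB file into one Structure per MODEL.

    Alternate locations are resolved to highest occupancy; hydrogens are
    retained (see :attr:`Structure.is_hydrogen`).  A file without any
    ATOM/HETATM records raises :class:`FormatError`.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    structures = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="occupancy")
        if arr.array_length() == 0:
            raise FormatError(f"{path}: model {m} has no atoms")
        structures.append(_from_atom_array(arr, m, str(path)))
    return structures


def _to_atom_array(s: Structure):
    arr = struc.AtomArray(s.n_atoms)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_id.astype(int)
    arr.ins_code = s.ins_code.astype("U1")
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.hetero = s.hetero.astype(bool)
    arr.coord = s.coords.astype(np.float32)
    return arr


def write_pdb(structures, path) -> None:
    """Write one or more Structures as a (multi-model) PDB file.

    Multi-model output requires all structures to share the same atom
    table (labels in identical order), as for ensemble files.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    arrays = [_to_atom_array(s) for s in structures]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def select_atoms(
    s: Structure, sel: ResidueSelection, atom_names=("CA",)
) -> CoordinateSet:
    """Select atoms by segment and atom name into a CoordinateSet.

    Atoms are ordered by (segment order, residue number, insertion code,
    file order of atoms within a residue).  Residue numbers in a segment
    range with no matching atom are reported in ``meta['missing']``; a
    segment matching zero atoms raises :class:`SelectionError`.
    """
    atom_names = set(atom_names)
    labels, rows, missing = [], [], []
    name_mask = np.isin(s.atom_name, list(atom_names))
    for seg_name, ranges in sel.segments.items():
        seg_count = 0
        for chain, lo, hi in ranges:
            chain_mask = (s.chain_id == str(chain)) & name_mask
            for res in range(int(lo), int(hi) + 1):
                idx = np.nonzero(chain_mask & (s.res_id == res))[0]
                if idx.size == 0:
                    missing.append((seg_name, str(chain), res))
                    continue
                # stable order: insertion code then file order
                order = np.lexsort((idx, s.ins_code[idx]))
                for i in idx[order]:
                    labels.append(
                        (seg_name, str(chain), res, str(s.ins_code[i]), str(s.atom_name[i]))
                    )
                    rows.append(s.coords[i])
                    seg_count += 1
        if seg_count == 0:
            raise SelectionError(
                f"segment {seg_name!r} matched no atoms "
                f"(atom names {sorted(atom_names)})"
            )
    return CoordinateSet(tuple(labels), np.array(rows, dtype=float),
                         {"missing": missing})


def _check_paired(a: CoordinateSet, b: CoordinateSet) -> None:
    if a.n_atoms != b.n_atoms:
        raise PairingError(
            f"coordinate sets differ in length ({a.n_atoms} vs {b.n_atoms})"
        )
    if a.labels != b.labels:
        raise PairingError("coordinate sets have mismatched atom labels")


def _check_fit_points(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise DegenerateFitError("superposition needs >= 3 fit points")
    centered = coords - coords.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateFitError("fit points are (near-)collinear")


def superpose(
    mobile: CoordinateSet,
    reference: CoordinateSet,
    fit_indices=None,
):
    """Least-squares fit ``mobile`` onto ``reference`` over a fit subset.

    Returns ``(transform, fitted, rmsd_fit)``: the optimal proper rigid
    motion (rotation determinant +1), the transform applied to *all*
    mobile atoms, and the RMSD over the fit subset.
    """
    _check_paired(mobile, reference)
    if fit_indices is None:
        fit_indices = np.arange(mobile.n_atoms)
    fit_indices = np.asarray(fit_indices, dtype=int)
    mob_fit = mobile.coords[fit_indices]
    ref_fit = reference.coords[fit_indices]
    _check_fit_points(mob_fit)
    _check_fit_points(ref_fit)

    mob_cen = mob_fit.mean(axis=0)
    ref_cen = ref_fit.mean(axis=0)
    with warnings.catch_warnings():
        # align_vectors warns on exact/near-exact alignments; harmless here
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_fit - ref_cen, mob_fit - mob_cen)
    R = rot.as_matrix()
    t = ref_cen - mob_cen @ R.T
    transform = Transform(R, t)
    fitted = mobile.with_coords(transform.apply(mobile.coords))
    dev = fitted.coords[fit_indices] - ref_fit
    rmsd_fit = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    return transform, fitted, rmsd_fit


def rmsd(
    a: CoordinateSet,
    b: CoordinateSet,
    subset=None,
    fit: bool = False,
) -> float:
    """RMSD between two paired CoordinateSets over ``subset`` (default all).

    With ``fit=True`` the sets are first superposed on the subset, so the
    value is invariant under rigid motion of either input.
    """
    _check_paired(a, b)
    if subset is None:
        subset = np.arange(a.n_atoms)
    subset = np.asarray(subset, dtype=int)
    if fit:
        _, fitted, value = superpose(a, b, subset)
        return value
    dev = a.coords[subset] - b.coords[subset]
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
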