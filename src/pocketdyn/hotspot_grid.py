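"""Grid-based binding-site hotspot mapping.

A uniform lattice (1 Å spacing by default) is anchored at the centre of
mass of a reference ligand placed in the binding site.  The pipeline per
conformation is:

1. *clash pruning* — drop lattice points closer to any protein atom than
   that atom's van der Waals radius plus a margin (1.5 Å default);
2. *site restriction* — keep points within a cutoff (3 Å default) of the
   reference ligand: these define the binding site;
3. *buriedness* — cast 12 rays (icosahedron vertices) from each site
   point against the vdW spheres of nearby protein atoms; a point is
   ray-occluded when at least 10 of 12 rays hit, and *buried* when it is
   occluded and more than three of its 26 lattice neighbours are too
   (this strips the exposed boundary layer);
4. *probe scoring* — a pluggable probe scorer evaluates each buried
   point; the shipped default is a piecewise-linear hydrophobic
   contact-well for a saturated-carbon probe;
5. *hotspot designation* — points whose favourability reaches a quarter
   of the best buried score are candidates; a candidate surrounded by
   more than four candidate neighbours is a hotspot.

For ensembles, every conformation is superposed onto a reference segment
and mapped on one shared lattice, so hotspot occurrences can be counted
per lattice point into a consensus map.  The lattice axes are anchored to
an internal frame of the reference segment, which makes the maps
invariant under a global rigid motion of all inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._elements import atomic_masses, vdw_radii
from .errors import PairingError, PocketdynError
from .structure_io import (
    CoordinateSet,
    ResidueSelection,
    Structure,
    Transform,
    select_atoms,
    superpose,
)

__all__ = [
    "RaySet",
    "SiteGrid",
    "ProbeScorer",
    "HotspotParams",
    "EnsembleHotspotResult",
    "contact_well_scorer",
    "ligand_com",
    "build_site_grid",
    "prune_clashes",
    "restrict_to_site",
    "classify_buried",
    "score_probes",
    "designate_hotspots",
    "select_top_hotspots",
    "map_ensemble",
    "consensus_filter",
]


# ---------------------------------------------------------------------------
# ray set


def _icosahedron_vertices() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v.append((0.0, a, b))
            v.append((a, b, 0.0))
            v.append((b, 0.0, a))
    v = np.array(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass
class RaySet:
    """Unit ray directions plus a finite maximum length (Å).

    The default is the 12 icosahedron vertex directions — the canonical
    centrally-symmetric quasi-uniform 12-direction set.
    """

    directions: np.ndarray
    max_length: float = 10.0

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("ray directions must be unit vectors")
        if len(self.directions) == 0:
            raise ValueError("ray set must not be empty")

    @property
    def n_rays(self) -> int:
        return len(self.directions)

    @classmethod
    def icosahedron(cls, max_length: float = 10.0) -> "RaySet":
        return cls(_icosahedron_vertices(), max_length)


# ---------------------------------------------------------------------------
# grid


_NEIGHBOR_OFFSETS_26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)
_NEIGHBOR_OFFSETS_6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass
class SiteGrid:
    """Uniform lattice anchored at the reference-ligand centre of mass.

    ``lattice`` holds integer lattice coordinates; Cartesian positions
    are exactly ``origin + spacing * lattice @ axes`` (axes rows are an
    orthonormal basis, identity by default).  Boolean flags per point
    respect the hierarchy hotspot => candidate => buried => in_site =>
    not pruned.  ``scores`` holds probe favourability (higher = more
    favourable) for buried points, NaN elsewhere.
    """

    origin: np.ndarray
    spacing: float
    lattice: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    pruned: np.ndarray = None
    in_site: np.ndarray = None
    occluded: np.ndarray = None
    buried: np.ndarray = None
    candidate: np.ndarray = None
    hotspot: np.ndarray = None
    scores: np.ndarray = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.lattice = np.asarray(self.lattice, dtype=int)
        self.axes = np.asarray(self.axes, dtype=float)
        n = len(self.lattice)
        for name in ("pruned", "in_site", "occluded", "buried", "candidate", "hotspot"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=bool))
        if self.scores is None:
            self.scores = np.full(n, np.nan)

    @property
    def n_points(self) -> int:
        return len(self.lattice)

    @property
    def positions(self) -> np.ndarray:
        return self.origin + self.spacing * (self.lattice @ self.axes)

    def neighbor_counts(self, mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
        """Per point, how many lattice neighbours satisfy ``mask``."""
        offsets = _NEIGHBOR_OFFSETS_26 if connectivity == 26 else _NEIGHBOR_OFFSETS_6
        index = {tuple(p): i for i, p in enumerate(self.lattice)}
        counts = np.zeros(self.n_points, dtype=int)
        for i, p in enumerate(self.lattice):
            c = 0
            for off in offsets:
                j = index.get((p[0] + off[0], p[1] + off[1], p[2] + off[2]))
                if j is not None and mask[j]:
                    c += 1
            counts[i] = c
        return counts


def ligand_com(ligand, mass_weighted: bool = True) -> np.ndarray:
    """Centre of mass of a ligand (Structure or CoordinateSet).

    Mass weighting uses standard atomic masses and requires element
    metadata (a Structure); with ``mass_weighted=False`` the unweighted
    mean position is returned.
    """
    if isinstance(ligand, Structure):
        coords = ligand.coords
        elements = ligand.element
    elif isinstance(ligand, CoordinateSet):
        coords = ligand.coords
        elements = ligand.meta.get("elements")
    else:
        coords = np.asarray(ligand, dtype=float)
        elements = None
    if len(coords) == 0:
        raise ValueError("ligand has no atoms")
    if not mass_weighted:
        return coords.mean(axis=0)
    if elements is None:
        raise ValueError("mass-weighted COM needs element metadata")
    m = atomic_masses(elements)
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def build_site_grid(
    origin,
    spacing: float = 1.0,
    half_extent: float = 10.0,
    axes=None,
) -> SiteGrid:
    """All lattice points with |offset| <= half_extent on each axis."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if half_extent <= 0:
        raise ValueError("half_extent must be positive")
    n = int(np.floor(half_extent / spacing + 1e-9))
    r = np.arange(-n, n + 1)
    lattice = np.array(np.meshgrid(r, r, r, indexing="ij")).reshape(3, -1).T
    return SiteGrid(
        origin=np.asarray(origin, dtype=float),
        spacing=float(spacing),
        lattice=lattice,
        axes=np.eye(3) if axes is None else np.asarray(axes, dtype=float),
    )


def _protein_arrays(protein, include_hydrogens: bool = True):
    if isinstance(protein, Structure):
        coords = protein.coords
        elements = protein.element
        if not include_hydrogens:
            keep = ~protein.is_hydrogen
            coords, elements = coords[keep], elements[keep]
    else:
        coords, elements = protein
        coords = np.asarray(coords, dtype=float)
    return coords, vdw_radii(elements)


def prune_clashes(g: SiteGrid, protein, margin: float = 1.5) -> SiteGrid:
    """Prune points closer than (vdW radius + margin) to any protein atom."""
    coords, radii = _protein_arrays(protein)
    pruned = g.pruned.copy()
    if len(coords) > 0:
        tree = cKDTree(g.positions)
        for rad in np.unique(radii):
            centers = coords[radii == rad]
            hit = tree.query_ball_point(centers, r=rad + margin)
            for lst in hit:
                pruned[lst] = True
    return replace(g, pruned=pruned)


def restrict_to_site(g: SiteGrid, ligand_coords, cutoff: float = 3.0) -> SiteGrid:
    """Flag unpruned points within ``cutoff`` of any reference-ligand atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(ligand_coords, (Structure, CoordinateSet)):
        ligand_coords = ligand_coords.coords
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if len(ligand_coords) == 0:
        raise ValueError("ligand has no atoms")
    tree = cKDTree(ligand_coords)
    d, _ = tree.query(g.positions)
    return replace(g, in_site=(~g.pruned) & (d <= cutoff))


def _ray_occluded(
    points: np.ndarray,
    rays: RaySet,
    centers: np.ndarray,
    radii: np.ndarray,
    hit_quota: int,
) -> np.ndarray:
    """Per point: do >= hit_quota rays cross any atom's vdW sphere?

    A ray crosses an atom when the finite segment of length
    ``rays.max_length`` passes within the atom's vdW radius of its
    centre.
    """
    U = rays.directions  # (R, 3)
    L = rays.max_length
    out = np.zeros(len(points), dtype=bool)
    if len(centers) == 0:
        return out
    r2 = radii**2  # (A,)
    for i, p in enumerate(points):
        diff = centers - p  # (A, 3)
        proj = diff @ U.T  # (A, R)
        t = np.clip(proj, 0.0, L)
        d2 = (diff * diff).sum(axis=1)[:, None] - 2.0 * t * proj + t * t
        hits = (d2 <= r2[:, None]).any(axis=0)  # (R,)
        out[i] = int(hits.sum()) >= hit_quota
    return out


def classify_buried(
    g: SiteGrid,
    protein,
    rays: RaySet | None = None,
    hit_quota: int = 10,
    neighbor_quota: int = 3,
    site_atom_cutoff: float = 12.0,
    connectivity: int = 26,
) -> SiteGrid:
    """Two-pass buriedness classification of the in-site points.

    Pass 1 marks a point *ray-occluded* when at least ``hit_quota`` of the
    cast rays cross the vdW sphere of a protein atom near the site (atoms
    within ``site_atom_cutoff`` of any in-site point).  Pass 2 marks it
    *buried* when it is occluded and strictly more than ``neighbor_quota``
    of its lattice neighbours (among unpruned in-site points) are
    occluded; pass 2 reads only pass-1 flags.
    """
    rays = rays or RaySet.icosahedron()
    if not (0 <= hit_quota <= rays.n_rays):
        raise ValueError("hit_quota outside [0, ray count]")
    coords, radii = _protein_arrays(protein)
    site_idx = np.nonzero(g.in_site)[0]
    occluded = np.zeros(g.n_points, dtype=bool)
    if site_idx.size > 0 and len(coords) > 0:
        site_pos = g.positions[site_idx]
        tree = cKDTree(site_pos)
        near = tree.query_ball_point(coords, r=site_atom_cutoff)
        keep = np.array([len(lst) > 0 for lst in near], dtype=bool)
        centers, rad = coords[keep], radii[keep]
        # rays are cast along lattice axes directions in world space
        world_rays = RaySet(rays.directions @ g.axes, rays.max_length)
        occluded[site_idx] = _ray_occluded(
            site_pos, world_rays, centers, rad, hit_quota
        )
    support = g.neighbor_counts(occluded & g.in_site, connectivity)
    buried = occluded & g.in_site & (support > neighbor_quota)
    return replace(g, occluded=occluded, buried=buried)


# ---------------------------------------------------------------------------
# probe scoring


@dataclass
class ProbeScorer:
    """Pluggable probe scorer: (position, atom coords, elements) -> score.

    ``higher_is_better`` records the sign convention; ``favorability``
    maps raw scores onto a scale where larger always means more
    favourable, which is what the quarter-of-best hotspot rule uses.
    """

    name: str
    fn: callable
    higher_is_better: bool = True

    def favorability(self, score):
        return np.asarray(score) if self.higher_is_better else -np.asarray(score)


def _contact_well(d: np.ndarray) -> np.ndarray:
    """Piecewise-linear hydrophobic contact well for a C.3 probe.

    0 below 2.5 Å (clash), rising linearly to 1 at 3.5 Å, flat to
    4.5 Å, falling linearly to 0 at 6.0 Å.
    """
    w = np.zeros_like(d)
    rise = (d >= 2.5) & (d < 3.5)
    w[rise] = d[rise] - 2.5
    flat = (d >= 3.5) & (d <= 4.5)
    w[flat] = 1.0
    fall = (d > 4.5) & (d < 6.0)
    w[fall] = (6.0 - d[fall]) / 1.5
    return w


def contact_well_scorer() -> ProbeScorer:
    """Default surrogate scorer: summed contact well over heavy atoms."""

    def fn(position, coords, elements):
        heavy = np.char.upper(np.asarray(elements, dtype=str)) != "H"
        d = np.linalg.norm(coords[heavy] - position, axis=1)
        return float(_contact_well(d).sum())

    return ProbeScorer("contact_well", fn, higher_is_better=True)


def score_probes(g: SiteGrid, protein, scorer: ProbeScorer | None = None) -> SiteGrid:
    """Evaluate the probe scorer at every buried point.

    ``g.scores`` receives *favourability* values (higher = better);
    non-buried points stay NaN.
    """
    scorer = scorer or contact_well_scorer()
    if isinstance(protein, Structure):
        coords, elements = protein.coords, protein.element
    else:
        coords, elements = protein
        coords = np.asarray(coords, dtype=float)
    scores = np.full(g.n_points, np.nan)
    pos = g.positions
    for i in np.nonzero(g.buried)[0]:
        try:
            raw = scorer.fn(pos[i], coords, elements)
        except Exception as exc:  # propagate with point id per contract
            raise PocketdynError(
                f"probe scorer {scorer.name!r} failed at grid point "
                f"{tuple(g.lattice[i])}: {exc}"
            ) from exc
        scores[i] = float(scorer.favorability(raw))
    return replace(g, scores=scores)


def designate_hotspots(
    g: SiteGrid,
    fraction: float = 0.25,
    support_quota: int = 4,
    connectivity: int = 26,
) -> SiteGrid:
    """Quarter-of-best candidate rule plus candidate-neighbour support.

    A buried point is a *candidate* when its favourability is at least
    ``fraction`` of the best buried favourability; a candidate is a
    *hotspot* when strictly more than ``support_quota`` of its lattice
    neighbours are candidates.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    scored = g.buried & np.isfinite(g.scores)
    if not scored.any():
        warnings.warn("no buried/scored grid points; hotspot set is empty")
        return replace(
            g,
            candidate=np.zeros(g.n_points, dtype=bool),
            hotspot=np.zeros(g.n_points, dtype=bool),
        )
    fmax = g.scores[scored].max()
    candidate = scored & (g.scores >= fraction * fmax)
    support = g.neighbor_counts(candidate, connectivity)
    hotspot = candidate & (support > support_quota)
    return replace(g, candidate=candidate, hotspot=hotspot)


def select_top_hotspots(scores, top_fraction: float = 0.25) -> np.ndarray:
    """Mask of hotspot scores in the most favourable quantile of a pool.

    The threshold is the (1 - top_fraction) quantile of the pooled
    favourability distribution (linear-interpolation estimator); ties at
    the threshold are retained, so equal scores are all kept.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty hotspot score pool")
    thresh = np.quantile(scores, 1.0 - top_fraction)
    return scores >= thresh


# ---------------------------------------------------------------------------
# ensemble mapping


@dataclass
class HotspotParams:
    """Tunables of the per-conformation hotspot pipeline."""

    spacing: float = 1.0
    clash_margin: float = 1.5
    site_cutoff: float = 3.0
    hit_quota: int = 10
    neighbor_quota: int = 3
    support_quota: int = 4
    fraction: float = 0.25
    ray_length: float = 10.0
    site_atom_cutoff: float = 12.0
    connectivity: int = 26
    half_extent: float | None = None  # default: ligand extent + cutoff + spacing

    def to_jsonable(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class EnsembleHotspotResult:
    grids: list
    consensus: np.ndarray
    lattice: np.ndarray
    frame_rotation: np.ndarray
    frame_origin: np.ndarray
    conf_labels: tuple

    def consensus_points(self, min_count: int = 1) -> np.ndarray:
        return self.lattice[self.consensus >= min_count]


def _segment_frame(cs: CoordinateSet):
    """Orthonormal frame anchored to a reference segment.

    Built by Gram–Schmidt from three anchor atoms (first, middle, last of
    the segment selection).  Mapping coordinates into this frame makes
    every lattice quantity a function of internal geometry only, so a
    global rigid motion of all inputs leaves the maps unchanged.
    """
    c = cs.coords
    if len(c) < 3:
        raise ValueError("reference segment needs >= 3 atoms for a frame")
    o = c[0]
    a = c[-1] - o
    b = c[len(c) // 2] - o
    e1 = a / np.linalg.norm(a)
    b_perp = b - (b @ e1) * e1
    n = np.linalg.norm(b_perp)
    if n < 1e-8:
        raise ValueError("frame anchor atoms are collinear")
    e2 = b_perp / n
    e3 = np.cross(e1, e2)
    F = np.stack([e1, e2, e3])  # rows
    return F, o


def _run_single(
    protein: Structure,
    ligand_canon: np.ndarray,
    grid_template: SiteGrid,
    params: HotspotParams,
    scorer: ProbeScorer,
    rays: RaySet,
) -> SiteGrid:
    g = prune_clashes(grid_template, protein, margin=params.clash_margin)
    g = restrict_to_site(g, ligand_canon, cutoff=params.site_cutoff)
    g = classify_buried(
        g,
        protein,
        rays=rays,
        hit_quota=params.hit_quota,
        neighbor_quota=params.neighbor_quota,
        site_atom_cutoff=params.site_atom_cutoff,
        connectivity=params.connectivity,
    )
    g = score_probes(g, protein, scorer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = designate_hotspots(
            g,
            fraction=params.fraction,
            support_quota=params.support_quota,
            connectivity=params.connectivity,
        )
    return g


def map_ensemble(
    conformations: list[Structure],
    reference: Structure,
    reference_segment: ResidueSelection,
    ligand: Structure,
    params: HotspotParams | None = None,
    scorer: ProbeScorer | None = None,
    atom_names=("CA",),
    conf_labels=None,
) -> EnsembleHotspotResult:
    """Run the hotspot pipeline per conformation on one shared lattice.

    Every conformation is superposed onto ``reference_segment`` of the
    reference structure, all coordinates are mapped into the reference
    segment's internal frame, and one lattice (origin at the reference
    ligand's centre of mass) is used throughout, so the consensus map can
    count, per lattice point, in how many conformations it is a hotspot.
    """
    params = params or HotspotParams()
    scorer = scorer or contact_well_scorer()
    rays = RaySet.icosahedron(params.ray_length)
    if conf_labels is None:
        conf_labels = tuple(range(len(conformations)))

    ref_cs = select_atoms(reference, reference_segment, atom_names)
    F, frame_o = _segment_frame(ref_cs)
    to_canon = Transform(F, -F @ frame_o)

    ligand_canon = to_canon.apply(ligand.coords)
    origin = ligand_com(ligand.transformed(to_canon), mass_weighted=True)

    if params.half_extent is not None:
        half_extent = params.half_extent
    else:
        lig_extent = float(
            np.max(np.abs(ligand_canon - origin)) if len(ligand_canon) else 0.0
        )
        half_extent = lig_extent + params.site_cutoff + params.spacing
    grid_template = build_site_grid(origin, params.spacing, half_extent)

    grids = []
    for label, conf in zip(conf_labels, conformations):
        try:
            conf_cs = select_atoms(conf, reference_segment, atom_names)
        except Exception as exc:
            raise PairingError(
                f"conformation {label!r} is missing the reference segment: {exc}"
            ) from exc
        if conf_cs.labels != ref_cs.labels:
            raise PairingError(
                f"conformation {label!r} does not pair with the reference segment"
            )
        transform, _, _ = superpose(conf_cs, ref_cs)
        aligned = conf.transformed(transform).transformed(to_canon)
        grids.append(_run_single(aligned, ligand_canon, grid_template, params, scorer, rays))

    consensus = np.zeros(grid_template.n_points, dtype=int)
    for g in grids:
        consensus += g.hotspot.astype(int)
    return EnsembleHotspotResult(
        grids=grids,
        consensus=consensus,
        lattice=grid_template.lattice,
        frame_rotation=F,
        frame_origin=frame_o,
        conf_labels=tuple(conf_labels),
    )


def consensus_filter(consensus: np.ndarray, min_count: int = 2) -> np.ndarray:
    """Recurrence filter: lattice points hotspot in >= min_count maps.

    The threshold is a parameter because the recurrence rule is a
    reporting choice (e.g. 'in at least two of three subgroup maps').
    """
    return np.asarray(consensus) >= min_count
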