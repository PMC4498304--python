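# Methods

This note documents the models and procedures pocketdyn implements, the
defaults and why, what the synthetic fixtures do and do not emulate, and
the numerical choices a maintainer should know about.

## Superposition and RMSD

Conformations are paired atom-by-atom through order-locked label tuples
(segment, chain, residue, insertion code, atom name); the tool accepts
identical numbering or an explicit residue mapping and deliberately does
**not** perform sequence alignment — establishing residue equivalence
across heterogeneous chains is an input artifact, not a numeric method.

Superposition is a single least-squares rigid fit (via
`scipy.spatial.transform.Rotation.align_vectors`, which solves the
Kabsch/Wahba problem with a guaranteed proper rotation, det = +1) over an
explicit fit subset — typically the structurally invariant core helices —
after which the transform is applied to *all* atoms. No iterated or
core-weighted refitting is used. Fits on fewer than three points, or on
(near-)collinear points (second singular value of the centred fit
coordinates below 1e-8 of the first), raise a degenerate-fit error
rather than returning an ill-conditioned rotation. RMSD with `fit=True`
superposes on the requested subset first and is therefore invariant
under rigid motions of either input.

PDB reading/writing is delegated to biotite; alternate locations resolve
to highest occupancy, hydrogens are kept but flagged, insertion codes are
part of the residue identity, and coordinates are stored in Å exactly as
parsed.

## Ensemble PCA

The ensemble is an M×3N matrix of flattened, superposed coordinates.
The covariance uses the **population normalisation (1/M)**, matching the
expectation form of the covariance definition; variance *fractions* are
identical under either normalisation. Eigen-decomposition uses `eigh`;
eigenvalues are clipped at zero (they can go negative by roundoff),
sorted descending, and each eigenvector's sign is fixed by making its
largest-magnitude entry positive so projections are reproducible across
platforms. The analysis region is a user-supplied residue selection —
nothing is hard-coded, since region choices (e.g. excluding a
domain-swapping helix) are dataset-specific decisions.

Two identities anchor the implementation and are tested: the sum of all
eigenvalues equals the trace of C (total ensemble variance), and the sum
over atoms of RMSF² equals the same trace.

One subtlety the fixtures exposed: superposing ensemble members onto a
reference *before* PCA projects out rigid-body components of any
deformation. Random planted modes contain such components, so recovery
tests stack the generated conformations directly (they are constructed
in a common frame); with superposition enabled the recovered variance of
a random planted mode is systematically low by roughly its rigid-body
content. For real data this is immaterial — superposition is exactly
what removes spurious rigid-body variance — but it matters when
validating against planted ground truth.

## PC-subspace clustering

Agglomerative clustering on Euclidean distances in the PC1–PC2 score
plane, through `scipy.cluster.hierarchy`. **Ward linkage is the
default** (compact, variance-minimising subgroups suit conformational
clusters); complete/average/single are selectable. The tree cut is an
explicit parameter — either a cluster count or a cophenetic height —
recorded in the output metadata; no automatic cut-selection heuristic is
provided. Scores are clustered raw (not variance-scaled); this is a
config-visible choice. Labels are renumbered by first appearance so
identical inputs give identical labels, and permuting the input permutes
the partition consistently.

The representative of a cluster is its *centroid member*: the ensemble
is already in a common frame, so the cluster-average conformation is the
plain mean of member rows and the representative is the member with the
lowest RMSD to it (no re-fitting, which would change the subspace
geometry); ties break to the lowest conformation index.

Population tiers (high/middle/low) are assigned by descending size
thresholds, ordering clusters within a tier by descending size then id.

## Grid-based hotspot mapping

The lattice has 1.0 Å spacing, origin at the mass-weighted centre of the
reference ligand (Bondi-table vdW radii and standard atomic masses;
unknown elements raise rather than defaulting, because a silently wrong
radius corrupts buriedness). The default half-extent is the ligand's
maximum axis offset from its centre of mass plus the site cutoff plus
one spacing, so the site sphere set is never clipped.

Stage by stage:

* **Clash pruning** removes points with centre distance to any protein
  atom below that atom's vdW radius plus a 1.5 Å margin (the only
  dimensionally consistent reading of "within a margin of the vdW
  radius"; the margin is configurable).
* **Site restriction** keeps unpruned points within 3.0 Å of any
  reference-ligand atom.
* **Buriedness** casts **12 rays along the icosahedron vertex
  directions** — the canonical centrally symmetric 12-direction set —
  with a finite maximum length of 10 Å, against the vdW *spheres* (not
  centres) of protein atoms near the site (within 12 Å of any in-site
  point). A ray "crosses" an atom when the finite segment passes within
  the atom's vdW radius of its centre. A point is ray-occluded at ≥10 of
  12 hits, and buried when additionally more than 3 of its lattice
  neighbours are occluded; this second pass uses only first-pass flags
  (no iteration) and strips the exposed boundary layer. The neighbour
  set is the 26-point Chebyshev-1 neighbourhood (a volumetric reading of
  "surrounded by"; the 6-neighbourhood is selectable), counting only
  unpruned in-site points.
* **Probe scoring** is a pluggable seat carrying an explicit sign
  convention; `SiteGrid.scores` always stores *favourability* (higher =
  better) so the downstream rules are scorer-agnostic. The shipped
  default is a parameter-free piecewise-linear hydrophobic contact-well
  for a saturated-carbon probe, summed over protein heavy atoms: 0 below
  2.5 Å, rising to 1 at 3.5 Å, flat to 4.5 Å, falling to 0 at 6.0 Å.
  It is monotone in burial depth and has closed forms for tests; any
  knowledge-based scorer can be plugged in its place.
* **Hotspot designation**: candidates reach ≥¼ of the best buried
  favourability; a candidate with more than 4 candidate neighbours is a
  hotspot. An ensemble-level filter keeps hotspots in the most
  favourable quartile of the pooled score distribution
  (linear-interpolation quantile; ties at the threshold retained).
* **Ensemble mapping** superposes every conformation onto a reference
  segment and evaluates all of them on one shared lattice; the consensus
  map counts per lattice point how many maps mark it a hotspot, and the
  recurrence filter threshold (e.g. "at least 2 of 3 subgroup maps") is
  an explicit parameter.

**Frame anchoring.** The lattice axes are not world axes: all aligned
coordinates are mapped into an orthonormal frame built by Gram–Schmidt
from three anchor atoms of the reference segment (first, middle, last).
Because that frame co-moves with the inputs, applying one rigid motion
to protein, ligand and reference together leaves every lattice flag —
and hence the consensus map — bit-identical (verified away from
classification-threshold boundaries, where floating-point ulps could in
principle flip a comparison).

## aMD boost potential

ΔV = (E_b − V)²/(E_b − V + α) for V < E_b and 0 otherwise;
V* = V + ΔV. Closed-form anchors: ΔV(E_b) = 0, ΔV(E_b − α) = α/2, and
ΔV → (E_b − V) − α in deep wells, so V* saturates just below E_b.
V* is strictly increasing in V (dV*/dV = α²/((E_b−V)+α)² > 0). A single
(E_b, α) pair applies to whichever energy series the user supplies;
dual-boost (separate dihedral/total) bookkeeping and reweighting of
observables are out of scope. `suggest_parameters` derives
E_b = ⟨V⟩ + c_E·n and α = c_α·n from a count basis (atoms or residues);
the shipped "low"/"high" presets are **placeholders** — the appropriate
coefficients are system- and protocol-specific and must be supplied
explicitly for production use.

## Synthetic fixtures

* *Mode ensembles*: conformation = base + Σ_k a_k v_k + ε with
  orthonormal planted modes, Gaussian amplitudes (optionally shifted by
  per-cluster centres to plant a partition) and isotropic noise; the
  ground-truth record returns every draw. Defaults used throughout the
  tests mirror the recovery conditions: M = 200 conformations, amplitude
  SDs 3.0/1.5 Å, noise SD 0.1 Å. They emulate the low-rank covariance
  structure PCA assumes — not bonded geometry, side chains, or
  anisotropic experimental noise — so passing recovery tests show the
  estimator is correct, not that any particular protein's motion is
  low-rank.
* *Cage pockets*: Fibonacci-sphere shells (deterministic, quasi-uniform;
  seeded random rotation for variety) of radius 8 Å with an optional
  conical aperture, plus the exact opaque-shell solid-angle occlusion at
  the centre. They provide geometry oracles for buriedness: fixture
  apertures are chosen so the dense-ray occlusion lands clearly outside
  the 10/12 quota boundary band, where the 12-ray decision must agree
  with a 2000-direction oracle. They emulate enclosure, not the
  irregular, partially open topography of real pockets.
* *Helices*: ideal C-α traces (rise 1.5 Å, twist 100°, radius 2.3 Å).

All generators draw from one seeded `numpy` generator per call; same
config ⇒ bit-identical output.

## Pipeline and problem sizes

`run_pipeline` composes read → superpose → PCA → project → cluster →
representatives → hotspot maps → consensus, writes JSON/CSV/PDB
artifacts plus a manifest of SHA-256 hashes, and re-runs byte-identically
on identical inputs. Stage failures abort with the stage name. The test
and acceptance workloads use deliberately compact problem sizes — 60-
conformation ensembles of ~280-atom cages, 729–4913-point lattices, 24
cage fixtures, 10⁴-point boost grids — chosen as the smallest sizes at
which every statistical check is well-resolved.

## Known limitations

* No sequence alignment, protonation assignment, or trajectory-format
  ingestion beyond multi-model PDB (DCD/NetCDF adapters are an extension
  point); no mmCIF beyond what biotite's PDB path covers.
* The published knowledge-based probe scoring function is not
  reimplemented; the default contact-well is a documented surrogate with
  the same interface, and conclusions about absolute hotspot scores do
  not transfer to it.
* Headline numbers from any particular curated structure set (variance
  fractions, cluster counts of specific trajectory ensembles) depend on
  that dataset and are not reproduced here; the validation is
  property-based on fixtures with known ground truth.
* Multi-model output requires a shared atom table across models.
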