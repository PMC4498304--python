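"""End-to-end pipeline: ensemble -> superpose -> PCA -> cluster -> hotspots.

``run_pipeline`` wires the modules together in the order the analysis
prescribes: read the conformational ensemble, superpose everything onto
the fit segment of a reference conformation, build the Cartesian PCA
over the analysis region, project into the PC1-PC2 plane, cluster there,
pick one centroid representative per cluster, run the grid-based hotspot
pipeline over the representatives on one shared lattice, and write a
consensus map.  All artifacts are written with a manifest carrying the
parameters and SHA-256 hashes, so re-running on identical inputs
reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble_pca import EnsembleMatrix, covariance, fit_pca, project
from .errors import StageError
from .hotspot_grid import HotspotParams, map_ensemble
from .pc_clustering import ClusterResult, cluster_subspace, representatives
from .structure_io import ResidueSelection, read_pdb, select_atoms, write_pdb

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, selections and tunables for one pipeline run."""

    ensemble_path: str
    fit_segment: dict
    pca_segment: dict
    out_dir: str
    reference_path: str | None = None  # default: first ensemble model
    ligand_path: str | None = None  # hotspot stage skipped when absent
    hotspot_segment: dict | None = None  # default: fit segment
    atom_names: tuple = ("CA",)
    n_components: int = 2
    linkage: str = "ward"
    n_clusters: int | None = 2
    cut_height: float | None = None
    frame_stride: int = 1
    hotspot: HotspotParams = field(default_factory=HotspotParams)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "hotspot" in d:
            d["hotspot"] = HotspotParams(**d["hotspot"])
        if "atom_names" in d:
            d["atom_names"] = tuple(d["atom_names"])
        return cls(**d)

    def to_jsonable(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["hotspot"] = self.hotspot.to_jsonable()
        d["atom_names"] = list(self.atom_names)
        return d


@dataclass
class PipelineReport:
    model: object
    scores: object
    clusters: ClusterResult
    representative_structures: list
    hotspot_result: object
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("read")
def _read_inputs(cfg: PipelineConfig):
    conformations = read_pdb(cfg.ensemble_path)[:: max(1, cfg.frame_stride)]
    reference = (
        read_pdb(cfg.reference_path)[0] if cfg.reference_path else conformations[0]
    )
    ligand = read_pdb(cfg.ligand_path)[0] if cfg.ligand_path else None
    return conformations, reference, ligand


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full analysis and write artifacts + manifest to ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    conformations, reference, ligand = _read_inputs(cfg)
    fit_sel = ResidueSelection.from_jsonable(cfg.fit_segment)
    pca_sel = ResidueSelection.from_jsonable(cfg.pca_segment)

    @_stage("pca")
    def _pca():
        ref_fit = select_atoms(reference, fit_sel, cfg.atom_names)
        ref_pca = select_atoms(reference, pca_sel, cfg.atom_names)
        # superpose whole conformations on the fit segment, then take the
        # PCA region from the fitted coordinates
        rows = []
        from .structure_io import superpose

        for conf in conformations:
            cs_fit = select_atoms(conf, fit_sel, cfg.atom_names)
            transform, _, _ = superpose(cs_fit, ref_fit)
            fitted = conf.transformed(transform)
            rows.append(select_atoms(fitted, pca_sel, cfg.atom_names))
        # conformations are already in the fit-segment frame; stack the PCA
        # region directly (no second fit over the analysis region)
        for cs in rows:
            if cs.labels != ref_pca.labels:
                raise StageError("pca", ValueError("PCA region labels differ"))
        X = np.array([cs.flatten() for cs in rows])
        ens = EnsembleMatrix(X, tuple(range(len(rows))), ref_pca.labels)
        C = covariance(ens)
        model = fit_pca(C, ens.mean(), cfg.n_components, ref_pca.labels)
        scores = project(ens, model)
        return ens, model, scores

    ens, model, scores = _pca()

    @_stage("cluster")
    def _cluster():
        labels = cluster_subspace(
            scores,
            method=cfg.linkage,
            n_clusters=cfg.n_clusters,
            height=cfg.cut_height,
        )
        reps = representatives(ens, labels)
        return ClusterResult(
            labels=labels,
            method=cfg.linkage,
            metric="euclidean",
            cut=(
                {"n_clusters": cfg.n_clusters}
                if cfg.n_clusters is not None
                else {"height": cfg.cut_height}
            ),
            representative_indices=reps,
        )

    clusters = _cluster()
    rep_indices = [clusters.representative_indices[c] for c in sorted(clusters.representative_indices)]
    rep_structures = [conformations[i] for i in rep_indices]

    @_stage("hotspots")
    def _hotspots():
        if ligand is None:
            return None
        seg = ResidueSelection.from_jsonable(cfg.hotspot_segment or cfg.fit_segment)
        return map_ensemble(
            rep_structures,
            reference,
            seg,
            ligand,
            params=cfg.hotspot,
            atom_names=cfg.atom_names,
            conf_labels=tuple(rep_indices),
        )

    hotspot_result = _hotspots()

    @_stage("write")
    def _write():
        model.to_json(out / "model.json")
        artifacts["model"] = out / "model.json"

        df = pd.DataFrame(
            scores.scores,
            columns=[f"PC{i}" for i in scores.component_ids],
        )
        df.insert(0, "conformer", list(scores.conf_labels))
        df.to_csv(out / "scores.csv", index=False)
        artifacts["scores"] = out / "scores.csv"

        with open(out / "clusters.json", "w") as fh:
            json.dump(clusters.to_jsonable(), fh, sort_keys=True)
        artifacts["clusters"] = out / "clusters.json"

        write_pdb(rep_structures, out / "representatives.pdb")
        artifacts["representatives"] = out / "representatives.pdb"

        if hotspot_result is not None:
            rows = []
            for label, g in zip(hotspot_result.conf_labels, hotspot_result.grids):
                pos = g.positions
                for i in np.nonzero(g.hotspot)[0]:
                    rows.append(
                        {
                            "conformer": label,
                            "i": g.lattice[i, 0],
                            "j": g.lattice[i, 1],
                            "k": g.lattice[i, 2],
                            "x": pos[i, 0],
                            "y": pos[i, 1],
                            "z": pos[i, 2],
                            "favorability": g.scores[i],
                        }
                    )
            pd.DataFrame(
                rows,
                columns=["conformer", "i", "j", "k", "x", "y", "z", "favorability"],
            ).to_csv(out / "hotspots.csv", index=False)
            artifacts["hotspots"] = out / "hotspots.csv"

            cons = pd.DataFrame(
                hotspot_result.lattice, columns=["i", "j", "k"]
            )
            cons["count"] = hotspot_result.consensus
            cons[cons["count"] > 0].to_csv(out / "consensus.csv", index=False)
            artifacts["consensus"] = out / "consensus.csv"

        manifest = {
            "schema": "pocketdyn.manifest/1",
            "version": __version__,
            "parameters": cfg.to_jsonable(),
            "n_conformations": len(conformations),
            "n_clusters": clusters.n_clusters,
            "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
            "incomplete": False,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
        return manifest

    manifest = _write()
    return PipelineReport(
        model=model,
        scores=scores,
        clusters=clusters,
        representative_structures=rep_structures,
        hotspot_result=hotspot_result,
        manifest=manifest,
        out_dir=out,
    )
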