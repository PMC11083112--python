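"""End-to-end workflow: epitope -> DEEP-STD -> conformation/contacts/RDF -> validation.

A :class:`RunConfig` names the inputs and selections; :func:`run_pipeline`
executes the stages in dependency order, writes one JSON file per stage
into the output directory and records a :class:`RunManifest`.  Stages
whose configuration section is absent are skipped and noted.  Outputs are
deterministic for a fixed config and seed; wall-times live only in the
manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from glycostd import __version__
from glycostd.conformation import (
    LinkageSpec,
    dihedral_series,
    pucker_classify,
    ramachandran_states,
)
from glycostd.contacts import ContactSpec, contact_distances, dbscan_conformers, rdf
from glycostd.epitope import (
    compare_total_saturation,
    deep_std,
    relativize_and_bin,
    std_intensities,
)
from glycostd.errors import GlycostdError
from glycostd.relaxation import RelaxationParameters, r_noe_series, simulate_std
from glycostd.structures import Ensemble, read_pdb, read_std_table, read_xyz

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(GlycostdError):
    """A pipeline stage failed; the manifest records the failure point."""


@dataclass
class RunConfig:
    out_dir: str = "glycostd_out"
    seed: int = 0
    # inputs
    std_table_exp1: str | None = None   # e.g. D2O condition
    std_table_exp2: str | None = None   # e.g. H2O condition
    trajectory: str | None = None       # PDB (multi-model) or XYZ
    # selections / specs
    ligand_sel: str = "chain L"
    protein_sel: str = "chain P"
    linkages: list[dict] = field(default_factory=list)       # LinkageSpec kwargs
    pucker: dict | None = None          # {"h5": addr, "h2": addr, "threshold": 3.2}
    contacts: list[dict] = field(default_factory=list)       # ContactSpec kwargs
    rdf: dict | None = None             # rdf() kwargs minus ensemble
    cluster: dict | None = None         # dbscan_conformers() kwargs minus ensemble
    relaxation: dict = field(default_factory=dict)           # RelaxationParameters kwargs
    deep_std_threshold: float = 0.1
    n_frames_validation: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def checksum(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_checksum: str
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "config_checksum": self.config_checksum,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _load_trajectory(path: str) -> Ensemble:
    p = Path(path)
    if p.suffix.lower() == ".xyz":
        return read_xyz(p)
    return read_pdb(p)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all configured stages; raise :class:`PipelineError` on failure.

    Partial results are preserved: every completed stage's output file
    stays on disk and is listed in the manifest even when a later stage
    fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config_checksum=config.checksum())
    ensemble: Ensemble | None = None
    maps = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = fn()
            for w in caught:
                manifest.warnings.append(f"{name}: {w.message}")
            manifest.stages[name] = {
                "status": "ok",
                "outputs": outputs,
                "wall_time_s": round(time.perf_counter() - t0, 4),
            }
        except Exception as exc:
            manifest.stages[name] = {
                "status": "failed",
                "error": str(exc),
                "wall_time_s": round(time.perf_counter() - t0, 4),
            }
            manifest.to_json(out / "manifest.json")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- epitope ----------------------------------------------------------
    if config.std_table_exp1:
        def _epitope():
            files = []
            for key, path in (("exp1", config.std_table_exp1),
                              ("exp2", config.std_table_exp2)):
                if not path:
                    continue
                table = read_std_table(path, condition_label=key)
                emap = relativize_and_bin(std_intensities(table))
                maps[key] = emap
                fp = out / f"epitope_{key}.json"
                _write_json(fp, emap.to_dict())
                files.append(str(fp))
            return files
        stage("epitope", _epitope)
    else:
        manifest.stages["epitope"] = {"status": "skipped", "reason": "no STD tables configured"}

    # ---- DEEP-STD + total saturation --------------------------------------
    if "exp1" in maps and "exp2" in maps:
        def _deepstd():
            res = deep_std(maps["exp1"], maps["exp2"], config.deep_std_threshold)
            sat = compare_total_saturation(maps["exp1"], maps["exp2"])
            fp = out / "deepstd.json"
            _write_json(fp, {"deep_std": res.to_dict(), "saturation": sat.to_dict()})
            return [str(fp)]
        stage("deepstd", _deepstd)
    else:
        manifest.stages["deepstd"] = {"status": "skipped", "reason": "needs two conditions"}

    # ---- trajectory-based stages ------------------------------------------
    if config.trajectory:
        ensemble = _load_trajectory(config.trajectory)

    if ensemble is not None and (config.linkages or config.pucker):
        def _conformation():
            payload = {}
            for kwargs in config.linkages:
                spec = LinkageSpec(**kwargs)
                series = dihedral_series(ensemble, spec)
                cat = ramachandran_states(series)
                payload[spec.label] = {
                    "states": [
                        {
                            "phi_center": s.phi_center, "psi_center": s.psi_center,
                            "phi_mode": s.phi_mode, "psi_mode": s.psi_mode,
                            "population": s.population,
                        }
                        for s in cat.states
                    ],
                    "unassigned": float(np.mean(cat.assignment == -1)),
                }
            if config.pucker:
                ps = pucker_classify(ensemble, **config.pucker)
                payload["pucker"] = {
                    "fractions": ps.fractions,
                    "threshold": ps.threshold,
                    "mean_distance": float(np.mean(ps.distance_h5h2)),
                }
            fp = out / "conformation.json"
            _write_json(fp, payload)
            return [str(fp)]
        stage("conformation", _conformation)
    else:
        manifest.stages["conformation"] = {"status": "skipped", "reason": "not configured"}

    if ensemble is not None and config.contacts:
        def _contacts():
            specs = [ContactSpec(**kw) for kw in config.contacts]
            rep = contact_distances(ensemble, specs)
            fp = out / "contacts.json"
            _write_json(fp, {
                lab: {"mean": d["mean"], "sd": d["sd"]}
                for lab, d in rep.contacts.items()
            })
            return [str(fp)]
        stage("contacts", _contacts)
    else:
        manifest.stages["contacts"] = {"status": "skipped", "reason": "not configured"}

    if ensemble is not None and config.rdf:
        def _rdf():
            profile = rdf(ensemble, **config.rdf)
            fp = out / "rdf.json"
            _write_json(fp, {
                "bin_edges": profile.bin_edges.tolist(),
                "g": profile.g.tolist(),
                "rho_bulk": profile.rho_bulk,
                "n_ref": profile.n_ref,
                "n_frames": profile.n_frames,
            })
            return [str(fp)]
        stage("rdf", _rdf)
    else:
        manifest.stages["rdf"] = {"status": "skipped", "reason": "not configured"}

    if ensemble is not None and config.cluster is not None:
        def _cluster():
            res = dbscan_conformers(ensemble, **config.cluster)
            fp = out / "clusters.json"
            _write_json(fp, {
                "labels": res.labels.tolist(),
                "n_clusters": res.n_clusters,
                "representative_frames": {str(k): v for k, v in res.representative_frames.items()},
            })
            return [str(fp)]
        stage("cluster", _cluster)
    else:
        manifest.stages["cluster"] = {"status": "skipped", "reason": "not configured"}

    # ---- theoretical epitope + R-NOE --------------------------------------
    if ensemble is not None:
        def _validate():
            params = RelaxationParameters(**config.relaxation)
            calc = simulate_std(
                ensemble, config.ligand_sel, config.protein_sel, params,
                n_frames=config.n_frames_validation,
            )
            payload = {"std_calc": calc.std_calc}
            if "exp1" in maps:
                val = r_noe_series(maps["exp1"], calc)
                payload["r_noe"] = {
                    "value": val.r_noe,
                    "series_mean": val.series_mean,
                    "series_sd": val.series_sd,
                    "residuals": val.residuals,
                }
            fp = out / "validation.json"
            _write_json(fp, payload)
            return [str(fp)]
        stage("validation", _validate)
    else:
        manifest.stages["validation"] = {"status": "skipped", "reason": "no trajectory"}

    manifest.to_json(out / "manifest.json")
    return manifest
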