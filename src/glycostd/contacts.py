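"""Contact distances, RMSD/RMSF, conformer clustering and solvation RDF.

Contact distances follow the conventions used for charged-group
interactions in heparin-protein complexes: the sulfur atom stands for a
sulfate group, the carboxylate carbon for a carboxylic group, the
side-chain nitrogen (NZ) for lysine and the guanidinium carbon (CZ) for
arginine.  Averages default to the second half of the ensemble, the
production stage of a simulation.

The radial distribution function follows

    g(r) = V / (4 pi Npair) * p(r) / (r^2 dr)

where p(r) is the mean per-frame count of reference-solvent pairs in the
spherical shell [r, r + dr), Npair the number of possible pairs, and V
the cell volume, so that a uniform solvent gives g = 1.  No
periodic-boundary minimum-image correction is applied: analysis
ensembles are assumed to be re-imaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from glycostd.errors import SelectionError, ValidationError
from glycostd.structures import Ensemble, Frame, resolve_address, select

__all__ = [
    "ContactSpec", "ContactReport", "RdfProfile", "ClusterResult",
    "contact_distances", "rmsd_series", "rmsf_per_unit",
    "dbscan_conformers", "rdf", "kabsch_rotate",
]


@dataclass
class ContactSpec:
    """One ligand-atom / protein-atom distance to monitor."""

    label: str
    ligand_atom: str   # address, e.g. "L:3:S3" (S of a sulfate, C6 of a carboxylate)
    protein_atom: str  # address, e.g. "P:114:NZ" (Lys NZ, Arg CZ)


@dataclass
class ContactReport:
    contacts: dict[str, dict]  # label -> {"mean": A, "sd": A, "series": ndarray}

    def to_dict(self) -> dict:
        return {
            lab: {"mean": d["mean"], "sd": d["sd"], "series": list(map(float, d["series"]))}
            for lab, d in self.contacts.items()
        }


@dataclass
class RdfProfile:
    bin_edges: np.ndarray  # Angstrom
    g: np.ndarray          # dimensionless, one per bin
    rho_bulk: float        # solvent count / A^3
    n_ref: int
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ClusterResult:
    labels: np.ndarray               # frame -> cluster id, -1 = noise
    epsilon: float
    min_points: int
    representative_frames: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {-1})


def _default_frame_range(n: int) -> slice:
    # production stage: second half of the ensemble
    return slice(n // 2, n)


def contact_distances(
    ensemble: Ensemble,
    specs: list[ContactSpec],
    frame_range: slice | None = None,
    stride: int = 1,
) -> ContactReport:
    """Per-frame Euclidean contact distances with mean/sd over a frame range."""
    n = len(ensemble)
    if frame_range is None:
        frame_range = _default_frame_range(n)
    xyz = ensemble.coords()[frame_range][::stride]
    report: dict[str, dict] = {}
    for spec in specs:
        try:
            i = resolve_address(ensemble, spec.ligand_atom)
            j = resolve_address(ensemble, spec.protein_atom)
        except SelectionError as exc:
            raise SelectionError(f"contact {spec.label}: {exc}") from exc
        series = np.linalg.norm(xyz[:, i] - xyz[:, j], axis=1)
        report[spec.label] = {
            "mean": float(series.mean()),
            "sd": float(series.std(ddof=0)),
            "series": series,
        }
    return ContactReport(report)


def kabsch_rotate(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (both (n, 3)).

    Returns the transformed mobile coordinates.  Proper rotation only
    (reflections are excluded).
    """
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    H = mc.T @ tc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return mc @ R + target.mean(axis=0)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    ensemble: Ensemble,
    reference: Frame,
    sel: str = "not resname HOH",
    superpose: bool = True,
) -> np.ndarray:
    """RMSD of each frame's selection to a reference frame, in Angstrom."""
    idx = select(ensemble, sel)
    if not idx:
        raise ValidationError(f"selection {sel!r} is empty")
    ref_idx = select(reference.atoms, sel)
    if len(ref_idx) != len(idx):
        raise ValidationError(
            f"selection resolves to {len(idx)} atoms in the ensemble but "
            f"{len(ref_idx)} in the reference"
        )
    ref = reference.coords[ref_idx]
    out = np.empty(len(ensemble))
    xyz = ensemble.coords()[:, idx]
    for t in range(len(ensemble)):
        mob = xyz[t]
        if superpose:
            mob = kabsch_rotate(mob, ref)
        out[t] = _rmsd(mob, ref)
    return out


def rmsf_per_unit(
    ensemble: Ensemble,
    groups: list[str],
    superpose: bool = True,
    align_sel: str | None = None,
) -> dict[str, float]:
    """Mean per-atom positional fluctuation for each selection group.

    Frames are first globally superposed onto the first frame (over
    ``align_sel``, default all atoms) unless ``superpose`` is false;
    each atom's RMSF is the root-mean-square deviation from its
    time-average position, then averaged within the group.
    """
    if not groups:
        raise ValidationError("at least one group selection is required")
    xyz = ensemble.coords().copy()
    if superpose:
        aidx = select(ensemble, align_sel) if align_sel else list(range(ensemble.n_atoms))
        ref = xyz[0]
        for t in range(1, len(ensemble)):
            mc = xyz[t][aidx] - xyz[t][aidx].mean(axis=0)
            tc = ref[aidx] - ref[aidx].mean(axis=0)
            H = mc.T @ tc
            U, _, Vt = np.linalg.svd(H)
            D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
            R = U @ D @ Vt
            xyz[t] = (xyz[t] - xyz[t][aidx].mean(axis=0)) @ R + ref[aidx].mean(axis=0)
    mean_pos = xyz.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((xyz - mean_pos) ** 2, axis=2), axis=0))
    out: dict[str, float] = {}
    for g in groups:
        idx = select(ensemble, g)
        if not idx:
            raise ValidationError(f"group selection {g!r} is empty")
        out[g] = float(per_atom[idx].mean())
    return out


def dbscan_conformers(
    ensemble: Ensemble,
    sel: str = "not resname HOH",
    epsilon: float = 0.5,
    min_points: int = 25,
) -> ClusterResult:
    """DBSCAN clustering of frames under the pairwise best-fit RMSD metric.

    Core/border/noise semantics are standard; representative frames are
    cluster medoids (minimum summed RMSD to fellow members).
    """
    idx = select(ensemble, sel)
    if not idx:
        raise ValidationError(f"selection {sel!r} is empty")
    n = len(ensemble)
    xyz = ensemble.coords()[:, idx]
    centered = xyz - xyz.mean(axis=1, keepdims=True)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            moved = kabsch_rotate(centered[i], centered[j])
            dist[i, j] = dist[j, i] = _rmsd(moved, centered[j])
    labels = DBSCAN(eps=epsilon, min_samples=min_points, metric="precomputed").fit_predict(dist)
    reps: dict[int, int] = {}
    for cid in sorted(set(labels.tolist()) - {-1}):
        members = np.flatnonzero(labels == cid)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        reps[cid] = int(members[np.argmin(sums)])
    return ClusterResult(labels, epsilon, min_points, reps)


def rdf(
    ensemble: Ensemble,
    ref_sel: str,
    solvent_sel: str,
    r_max: float = 10.0,
    dr: float = 0.1,
    cell_volume: float | None = None,
) -> RdfProfile:
    """Radial distribution function of solvent around a reference atom set.

    Every reference atom contributes its own pair distances (no
    nearest-reference reduction), matching the pair-count normalization.
    ``cell_volume`` should be the simulation-cell volume in A^3; when not
    given it is estimated from the solvent's axis-aligned bounding box
    averaged over frames.
    """
    if r_max <= 0 or dr <= 0:
        raise ValidationError("r_max and dr must be positive")
    ref_idx = select(ensemble, ref_sel)
    sol_idx = select(ensemble, solvent_sel)
    if not ref_idx or not sol_idx:
        raise ValidationError("reference and solvent selections must be nonempty")
    n_bins = int(round(r_max / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    counts = np.zeros(n_bins)
    xyz = ensemble.coords()
    vol_est = 0.0
    for t in range(len(ensemble)):
        ref = xyz[t][ref_idx]
        sol = xyz[t][sol_idx]
        d = np.linalg.norm(ref[:, None, :] - sol[None, :, :], axis=2).ravel()
        h, _ = np.histogram(d, bins=edges)
        counts += h
        span = sol.max(axis=0) - sol.min(axis=0)
        vol_est += float(np.prod(span))
    n_frames = len(ensemble)
    counts /= n_frames
    V = cell_volume if cell_volume is not None else vol_est / n_frames
    n_pair = len(ref_idx) * len(sol_idx)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers ** 2 * dr
    g = V / n_pair * counts / shell
    rho_bulk = len(sol_idx) / V
    return RdfProfile(edges, g, rho_bulk, len(ref_idx), n_frames)
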