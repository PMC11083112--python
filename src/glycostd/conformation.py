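"""Glycosidic dihedral, Ramachandran-state and ring-pucker analysis.

Glycosidic torsions of 1->4 linked sugars are defined on protons:
phi = H1-C1-O4-C4 and psi = C1-O4-C4-H4.  State populations are read off
a periodic two-dimensional histogram of (phi, psi): occupied bins are
assigned to local density maxima by steepest ascent on the torus, each
basin is one conformational state, and basins below a minimum population
are left unassigned.

The L-iduronate ring pucker is classified per frame from the H5-H2
interproton distance, whose signature separates the 1C4 chair (~4.0 A)
from the 2S0 skew-boat (~2.4 A); the decision threshold defaults to the
midpoint, 3.2 A.  A two-state inversion of the H5-H2/H5-H4 NOE ratio
under the isolated-spin-pair approximation (NOE ~ r^-6, reference
distance conformation-independent) estimates the skew-boat fraction from
a single experimental ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from glycostd.errors import ValidationError
from glycostd.structures import Ensemble, Frame, resolve_address

__all__ = [
    "LinkageSpec", "DihedralSeries", "RamachandranState", "StateCatalog",
    "PuckerSeries", "dihedral", "dihedral_series", "ramachandran_states",
    "pucker_classify", "noe_two_state", "forward_noe_ratio",
]

CHAIR_1C4 = "chair_1C4"
SKEW_2S0 = "skew_2S0"


@dataclass
class LinkageSpec:
    """Atom addresses defining one glycosidic linkage's phi/psi torsions."""

    label: str
    atoms_phi: tuple[str, str, str, str]  # H1, C1, O4, C4
    atoms_psi: tuple[str, str, str, str]  # C1, O4, C4, H4


@dataclass
class DihedralSeries:
    linkage: LinkageSpec
    phi: np.ndarray  # degrees, per frame, in [-180, 180)
    psi: np.ndarray


@dataclass
class RamachandranState:
    phi_center: float  # circular mean of member frames, degrees
    psi_center: float
    phi_mode: float    # center of the peak histogram bin
    psi_mode: float
    population: float  # fraction of all frames


@dataclass
class StateCatalog:
    states: list[RamachandranState]
    assignment: np.ndarray  # frame -> state index, or -1 for unassigned
    bin_width: float
    min_pop: float


@dataclass
class PuckerSeries:
    distance_h5h2: np.ndarray  # Angstrom per frame
    labels: list[str]          # CHAIR_1C4 or SKEW_2S0 per frame
    fractions: dict[str, float]
    threshold: float


def dihedral(frame_or_coords, addresses=None) -> float:
    """Signed torsion angle (IUPAC convention) in degrees, in [-180, 180).

    Accepts either a :class:`Frame` plus four atom addresses, or a (4, 3)
    coordinate array directly.  The angle is positive for a clockwise
    rotation of the far bond when sighting along the central bond;
    180 degrees is reported as -180 per the half-open range convention.
    """
    if addresses is not None:
        frame: Frame = frame_or_coords
        idx = [resolve_address(frame.atoms, a) for a in addresses]
        if len(set(idx)) != 4:
            raise ValidationError("dihedral requires four distinct atoms")
        p = np.array([frame.atoms[i].position for i in idx])
    else:
        p = np.asarray(frame_or_coords, dtype=float)
        if p.shape != (4, 3):
            raise ValidationError("expected a (4, 3) coordinate array")
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * nb2 or np.linalg.norm(n2) < 1e-10 * nb2:
        raise ValidationError("collinear atoms: torsion undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / nb2))
    ang = np.degrees(np.arctan2(y, x))
    if ang >= 180.0 - 1e-9:
        ang -= 360.0
    return float(ang)


def dihedral_series(ensemble: Ensemble, linkage: LinkageSpec) -> DihedralSeries:
    """phi/psi torsions of one linkage over every frame of an ensemble."""
    iphi = [resolve_address(ensemble, a) for a in linkage.atoms_phi]
    ipsi = [resolve_address(ensemble, a) for a in linkage.atoms_psi]
    xyz = ensemble.coords()
    phi = np.array([dihedral(xyz[t, iphi]) for t in range(len(ensemble))])
    psi = np.array([dihedral(xyz[t, ipsi]) for t in range(len(ensemble))])
    return DihedralSeries(linkage, phi, psi)


# ---------------------------------------------------------------------------
# Ramachandran state detection on the torus
# ---------------------------------------------------------------------------

def _circmean_deg(values: np.ndarray) -> float:
    rad = np.radians(values)
    m = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    if m >= 180.0:
        m -= 360.0
    return float(m)


def _wrapped_neighbors(i: int, j: int, n: int):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            yield (i + di) % n, (j + dj) % n


def ramachandran_states(
    series: DihedralSeries,
    bin_width: float = 10.0,
    min_pop: float = 0.05,
) -> StateCatalog:
    """Detect populated (phi, psi) states by periodic density basins.

    The torus is binned at ``bin_width`` degrees; every occupied bin is
    assigned to a local maximum by steepest ascent over the 8-neighborhood
    (with periodic wrap).  Maxima not separated by at least two bins are
    merged into the denser one.  Basins holding less than ``min_pop`` of
    all frames are folded into the unassigned pool (state index -1).
    """
    n_frames = len(series.phi)
    if n_frames < 100:
        warnings.warn(
            f"only {n_frames} frames; state populations will be noisy", stacklevel=2
        )
    nbins = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nbins + 1)
    hist, _, _ = np.histogram2d(series.phi, series.psi, bins=[edges, edges])

    # steepest ascent: occupied bin -> its strictly densest neighbor
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    occupied = list(zip(*np.nonzero(hist)))
    for i, j in occupied:
        best, best_val = (i, j), hist[i, j]
        for ni, nj in _wrapped_neighbors(i, j, nbins):
            if hist[ni, nj] > best_val:
                best, best_val = (ni, nj), hist[ni, nj]
        parent[(i, j)] = best

    def root(cell):
        seen = set()
        while parent[cell] != cell:
            if cell in seen:  # defensive: plateau cycle
                break
            seen.add(cell)
            cell = parent[cell]
        return cell

    peaks = sorted({root(c) for c in occupied})

    # merge peaks not separated by >= 2 bins (toroidal Chebyshev distance)
    def _torus_cheb(a, b):
        d = []
        for x, y in zip(a, b):
            dd = abs(x - y) % nbins
            d.append(min(dd, nbins - dd))
        return max(d)

    merged: dict[tuple[int, int], tuple[int, int]] = {p: p for p in peaks}
    changed = True
    while changed:
        changed = False
        roots = sorted({merged[p] for p in peaks})
        for a in roots:
            for b in roots:
                if a >= b:
                    continue
                if _torus_cheb(a, b) < 2:
                    keep, drop = (a, b) if hist[a] >= hist[b] else (b, a)
                    for p in peaks:
                        if merged[p] == drop:
                            merged[p] = keep
                    changed = True

    # frame assignment via its bin's peak
    bin_phi = np.clip(((series.phi + 180.0) / bin_width).astype(int), 0, nbins - 1)
    bin_psi = np.clip(((series.psi + 180.0) / bin_width).astype(int), 0, nbins - 1)
    frame_peak = [merged[root((i, j))] for i, j in zip(bin_phi, bin_psi)]

    counts: dict[tuple[int, int], int] = {}
    for pk in frame_peak:
        counts[pk] = counts.get(pk, 0) + 1

    kept = [
        pk for pk, c in sorted(counts.items(), key=lambda kv: -kv[1])
        if c / n_frames >= min_pop
    ]
    index = {pk: k for k, pk in enumerate(kept)}
    assignment = np.array([index.get(pk, -1) for pk in frame_peak])

    centers = 0.5 * (edges[:-1] + edges[1:])
    states = []
    for pk in kept:
        members = assignment == index[pk]
        states.append(
            RamachandranState(
                phi_center=_circmean_deg(series.phi[members]),
                psi_center=_circmean_deg(series.psi[members]),
                phi_mode=float(centers[pk[0]]),
                psi_mode=float(centers[pk[1]]),
                population=float(members.sum()) / n_frames,
            )
        )
    return StateCatalog(states, assignment, bin_width, min_pop)


# ---------------------------------------------------------------------------
# Ring pucker
# ---------------------------------------------------------------------------

def pucker_classify(
    ensemble: Ensemble, h5: str, h2: str, threshold: float = 3.2
) -> PuckerSeries:
    """Classify each frame as chair (1C4) or skew-boat (2S0) by H5-H2 distance.

    A frame is labelled skew-boat when the distance is below ``threshold``
    (default: the midpoint of the 2.4 / 4.0 A conformer signatures).
    """
    i5 = resolve_address(ensemble, h5)
    i2 = resolve_address(ensemble, h2)
    xyz = ensemble.coords()
    d = np.linalg.norm(xyz[:, i5] - xyz[:, i2], axis=1)
    labels = [SKEW_2S0 if di < threshold else CHAIR_1C4 for di in d]
    n = len(labels)
    frac_skew = labels.count(SKEW_2S0) / n
    fractions = {SKEW_2S0: frac_skew, CHAIR_1C4: 1.0 - frac_skew}
    return PuckerSeries(d, labels, fractions, threshold)


# ---------------------------------------------------------------------------
# Two-state NOE inversion
# ---------------------------------------------------------------------------

def forward_noe_ratio(
    p_skew: float, r_short: float = 2.4, r_long: float = 4.0, r_ref: float = 2.45
) -> float:
    """NOE ratio predicted by a two-state mix under the r^-6 spin-pair model."""
    return (p_skew * r_short ** -6 + (1.0 - p_skew) * r_long ** -6) * r_ref ** 6


def noe_two_state(
    ratio_noe: float,
    r_short: float = 2.4,
    r_long: float = 4.0,
    r_ref: float = 2.45,
) -> float:
    """Invert an H5-H2/H5-H4 NOE ratio to the skew-boat population.

    Solves ratio = [p r_short^-6 + (1-p) r_long^-6] r_ref^6 for p under the
    isolated-spin-pair approximation with a conformation-independent
    reference distance.  Ratios outside the attainable range are clamped
    to [0, 1] with a warning.
    """
    if ratio_noe < 0:
        raise ValidationError("NOE ratio must be non-negative")
    a, b, c = r_short ** -6, r_long ** -6, r_ref ** -6
    p = (ratio_noe * c - b) / (a - b)
    if -1e-9 <= p < 0.0 or 1.0 < p <= 1.0 + 1e-9:  # round-off at the range edges
        p = min(1.0, max(0.0, p))
    if p < 0.0 or p > 1.0:
        warnings.warn(
            f"NOE ratio {ratio_noe:.4g} outside the two-state range; "
            f"population clamped", stacklevel=2,
        )
        p = min(1.0, max(0.0, p))
    return float(p)
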