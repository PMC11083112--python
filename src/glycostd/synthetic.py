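"""Synthetic fixtures: idealized rings, toy complexes, model STD tables.

Everything the analysis pipeline consumes can be generated here with
known ground truth: idealized pyranose conformers built at canonical
Cremer-Pople puckering phases, toy ligand-protein ensembles with
prescribed glycosidic-state weights, ring-pucker mixtures and contact
distances, uniform-density single-site water, and noisy STD intensity
tables produced by the relaxation model itself.

The ring builder solves a small weighted least-squares problem: ring
atoms are parameterized in cylindrical coordinates with their
out-of-plane displacements pinned to the Cremer-Pople pattern of the
requested conformer, while bond lengths (C-C 1.52 A, C-O 1.43 A) and
ring angles (~111 deg) are driven to target values.  Hydrogens are
placed tetrahedrally; the choice of which tetrahedral slot carries the
hydrogen at C2 and C5 encodes the iduronate stereochemistry and fixes
the H5-H2 distance signature (~4.0 A in the 1C4 chair, ~2.4 A in the
2S0 skew-boat).  Chairs use puckering amplitude Q = 0.57 A, the
skew-boat the canonical twist amplitude Q = 0.75 A at phase
(theta, phi) = (90, 330) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from glycostd.conformation import LinkageSpec
from glycostd.errors import ValidationError
from glycostd.relaxation import RelaxationParameters, simulate_std
from glycostd.structures import Atom, Ensemble, Frame, StdTable

__all__ = [
    "RingTemplate", "ToyComplexSpec", "build_ring",
    "generate_toy_complex", "generate_std_tables", "generate_uniform_solvent",
    "toy_linkage_spec",
]

RING_ORDER = ["O5", "C1", "C2", "C3", "C4", "C5"]
BOND_TARGETS = [1.43, 1.52, 1.52, 1.52, 1.52, 1.43]  # j -> j+1 around RING_ORDER
CC, CO, CH = 1.52, 1.43, 1.09
RING_ANGLE = np.deg2rad(111.0)

# Cremer-Pople (Q A, theta deg, phi deg) for the canonical conformers
_CP = {
    "chair_4C1": (0.57, 0.0, 0.0),
    "chair_1C4": (0.57, 180.0, 0.0),
    "skew_2S0": (0.75, 90.0, 330.0),
}

# Tetrahedral slot (+1/-1) carrying the hydrogen at each ring carbon;
# the C2/C5 entries encode the iduronate configuration that yields the
# H5-H2 conformer signature.
_H_SIGNS = {"C1": -1, "C2": 1, "C3": -1, "C4": 1, "C5": 1}


@dataclass
class RingTemplate:
    conformer: str
    atoms: dict[str, np.ndarray]  # name -> position (A)

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.atoms[a] - self.atoms[b]))


def _cp_z(Q: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    q2, q3 = Q * np.sin(th), Q * np.cos(th)
    j = np.arange(6)
    return (np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 4.0 * np.pi * j / 6.0)
            + np.sqrt(1.0 / 6.0) * q3 * (-1.0) ** j)


def _solve_ring(Q: float, theta: float, phi: float) -> np.ndarray:
    """Ring coordinates with CP out-of-plane pattern pinned, bonds/angles fit."""
    z = _cp_z(Q, theta, phi)

    def coords(x: np.ndarray) -> np.ndarray:
        rho = x[:6]
        alpha = np.concatenate([[0.0], x[6:]])
        return np.stack([rho * np.cos(alpha), rho * np.sin(alpha), z], axis=1)

    def residuals(x: np.ndarray) -> list[float]:
        p = coords(x)
        res = []
        for j in range(6):
            res.append(10.0 * (np.linalg.norm(p[(j + 1) % 6] - p[j]) - BOND_TARGETS[j]))
        for j in range(6):
            a = p[(j - 1) % 6] - p[j]
            b = p[(j + 1) % 6] - p[j]
            cosang = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            res.append(np.arccos(np.clip(cosang, -1, 1)) - RING_ANGLE)
        return res

    x0 = np.concatenate([np.full(6, 1.45), 2.0 * np.pi * np.arange(1, 6) / 6.0])
    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return coords(sol.x)


def _exocyclic(p: np.ndarray, j: int, sign: int, length: float) -> np.ndarray:
    """Substituent position at ring atom j on tetrahedral slot ``sign``."""
    a = p[(j - 1) % 6] - p[j]
    a = a / np.linalg.norm(a)
    b = p[(j + 1) % 6] - p[j]
    b = b / np.linalg.norm(b)
    u = -(a + b)
    u = u / np.linalg.norm(u)
    v = np.cross(a, b)
    v = v / np.linalg.norm(v)
    pc = np.cos(np.deg2rad(109.47)) / (u @ a)
    qc = np.sqrt(max(0.0, 1.0 - pc * pc))
    d = pc * u + sign * qc * v
    return p[j] + length * d / np.linalg.norm(d)


@lru_cache(maxsize=None)
def _build_ring_cached(conformer: str) -> tuple[tuple[str, tuple[float, float, float]], ...]:
    Q, theta, phi = _CP[conformer]
    p = _solve_ring(Q, theta, phi)
    atoms: dict[str, np.ndarray] = {name: p[j] for j, name in enumerate(RING_ORDER)}
    for j, name in enumerate(RING_ORDER):
        if not name.startswith("C"):
            continue
        sign = _H_SIGNS[name]
        atoms[f"H{name[1]}"] = _exocyclic(p, j, sign, CH)
        # remaining tetrahedral slot: O anchors at C1-C4, carboxylate C6 at C5
        if name == "C5":
            atoms["C6"] = _exocyclic(p, j, -sign, CC)
        else:
            atoms[f"O{name[1]}"] = _exocyclic(p, j, -sign, CO)
    return tuple((k, tuple(map(float, v))) for k, v in atoms.items())


def build_ring(conformer: str) -> RingTemplate:
    """Idealized six-membered pyranose ring at a canonical pucker.

    ``conformer`` is one of ``"chair_4C1"``, ``"chair_1C4"``,
    ``"skew_2S0"``.  Returns ring atoms O5/C1-C5, hydrogens H1-H5 and
    substituent anchors O1-O4/C6.
    """
    if conformer not in _CP:
        raise ValidationError(
            f"unknown conformer {conformer!r}; expected one of {sorted(_CP)}"
        )
    cached = _build_ring_cached(conformer)
    return RingTemplate(conformer, {k: np.array(v) for k, v in cached})


# ---------------------------------------------------------------------------
# Toy complex generator
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Prescribed statistical structure of a synthetic ligand-protein ensemble.

    ``dihedral_states`` are (phi, psi, weight, sigma) tuples in degrees for
    one glycosidic linkage; weights must sum to 1.  ``pucker_mix`` is the
    2S0 skew-boat fraction of the iduronate-like ring.  ``contact_targets``
    are (label, distance A, jitter sd A) triples realized as ligand/protein
    atom pairs.  ``water_density`` (count/A^3, e.g. 0.0334 for bulk water)
    fills a cubic cell of side ``water_cell`` centred on the ring with
    single-site waters, excluding positions within 2.5 A of solute.
    """

    n_frames: int = 1000
    seed: int = 0
    dihedral_states: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(-54.0, -32.0, 1.0, 10.0)]
    )
    pucker_mix: float = 0.64          # 2S0 fraction (free-state iduronate equilibrium)
    pucker_jitter: float = 0.02       # A, per-atom Gaussian jitter on ring atoms
    contact_targets: list[tuple[str, float, float]] = field(default_factory=list)
    water_density: float | None = None
    water_cell: float = 24.0          # A
    include_protein_protons: bool = True

    def __post_init__(self) -> None:
        w = sum(s[2] for s in self.dihedral_states)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"dihedral state weights must sum to 1, got {w}")
        if any(s[3] < 0 for s in self.dihedral_states):
            raise ValidationError("state sigmas must be non-negative")
        if not 0.0 <= self.pucker_mix <= 1.0:
            raise ValidationError("pucker_mix must be a fraction")
        for label, dist, jit in self.contact_targets:
            if dist <= 0 or jit < 0:
                raise ValidationError(
                    f"contact {label}: infeasible geometry (distance {dist}, jitter {jit})"
                )


def toy_linkage_spec(label: str = "B-A") -> LinkageSpec:
    """Linkage addresses matching :func:`generate_toy_complex` topology."""
    return LinkageSpec(
        label,
        atoms_phi=("L:1:H1", "L:1:C1", "L:1:O4", "L:1:C4"),
        atoms_psi=("L:1:C1", "L:1:O4", "L:1:C4", "L:1:H4"),
    )


def _place_by_torsion(p1, p2, p3, bond, angle_deg, torsion_deg):
    """NeRF placement: new atom bonded to p3 with given internal coordinates."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = p3 - p2
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n = n / np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(phi),
                  bond * np.sin(theta) * np.sin(phi)])
    return p3 + m @ d


def _wrap180(x: np.ndarray) -> np.ndarray:
    return (x + 180.0) % 360.0 - 180.0


# lab-frame anchors for the ligand sub-assemblies
_LINKAGE_OFFSET = np.array([0.0, 18.0, 0.0])
_CONTACT_OFFSET = np.array([0.0, -18.0, 0.0])
_CONTACT_SPACING = np.array([12.0, 0.0, 0.0])


def generate_toy_complex(spec: ToyComplexSpec) -> Ensemble:
    """Deterministic synthetic ensemble with prescribed statistics.

    Topology (constant across frames):

    * chain L, resid 1, residue GLY0: linkage atoms C1/O4/C4/H1/H4 whose
      phi/psi torsions are drawn from the requested wrapped-Gaussian
      state mixture;
    * chain L, resid 10, residue IDO: an iduronate-like ring flipping
      between the 1C4 chair and 2S0 skew-boat with probability
      ``pucker_mix`` for the skew form;
    * chain L/P, resid 20+i / 120+i: one atom pair per contact target at
      the prescribed mean distance with Gaussian jitter;
    * chain P, resid 200: three protein protons flanking the ring (these
      make the ring protons saturatable by the relaxation model);
    * chain W: single-site waters (O only), uniform in a cubic cell,
      excluded within 2.5 A of any solute atom, resampled every frame.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    # --- per-frame random draws -------------------------------------------
    weights = np.array([s[2] for s in spec.dihedral_states])
    state_idx = rng.choice(len(weights), size=n, p=weights)
    phis = np.empty(n)
    psis = np.empty(n)
    for k, (phi0, psi0, _w, sd) in enumerate(spec.dihedral_states):
        mask = state_idx == k
        phis[mask] = phi0 + sd * rng.standard_normal(mask.sum())
        psis[mask] = psi0 + sd * rng.standard_normal(mask.sum())
    phis, psis = _wrap180(phis), _wrap180(psis)
    skew = rng.random(n) < spec.pucker_mix

    ring_chair = build_ring("chair_1C4").atoms
    ring_skew = build_ring("skew_2S0").atoms
    ring_names = sorted(ring_chair)

    # --- static topology ---------------------------------------------------
    proto: list[tuple[str, str, str, int, str]] = []  # name, element, resname, resid, chain
    for nm in ("C1", "O4", "C4", "H1", "H4"):
        proto.append((nm, nm[0], "GLY0", 1, "L"))
    for nm in ring_names:
        proto.append((nm, nm[0], "IDO", 10, "L"))
    for i, (label, dist, jit) in enumerate(spec.contact_targets):
        proto.append(("S1", "S", "SUL", 20 + i, "L"))
        proto.append(("NZ", "N", "LYS", 120 + i, "P"))
    prot_h_offsets = []
    if spec.include_protein_protons:
        for k, off in enumerate(
            (np.array([2.6, 0.0, 0.0]), np.array([-2.8, 0.5, 0.3]),
             np.array([0.4, 2.9, -0.4]))
        ):
            proto.append((f"HP{k + 1}", "H", "PRT", 200, "P"))
            prot_h_offsets.append(off)
    n_water = 0
    if spec.water_density is not None:
        if spec.water_density < 0:
            raise ValidationError("water density must be non-negative")
        n_water = int(round(spec.water_density * spec.water_cell ** 3))
        for w in range(n_water):
            proto.append(("O", "O", "HOH", 1000 + w, "W"))

    # ring centroid anchors the water cell and the protein protons
    ring_center = np.mean([ring_chair[nm] for nm in RING_ORDER], axis=0)
    half = spec.water_cell / 2.0

    frames = []
    for t in range(n):
        coords: list[np.ndarray] = []
        # linkage: C1 at origin+offset, O4 along x, C4 in the xy-plane
        c1 = _LINKAGE_OFFSET + np.array([0.0, 0.0, 0.0])
        o4 = c1 + np.array([CO, 0.0, 0.0])
        c4 = _place_by_torsion(c1 + np.array([0.0, 1.0, 0.0]), c1, o4, CO, 116.0, 60.0)
        h1 = _place_by_torsion(c4, o4, c1, CH, 109.47, phis[t])
        h4 = _place_by_torsion(c1, o4, c4, CH, 109.47, psis[t])
        coords += [c1, o4, c4, h1, h4]
        ring = ring_skew if skew[t] else ring_chair
        for nm in ring_names:
            coords.append(ring[nm] + spec.pucker_jitter * rng.standard_normal(3))
        for i, (label, dist, jit) in enumerate(spec.contact_targets):
            base = _CONTACT_OFFSET + i * _CONTACT_SPACING
            d = dist + jit * rng.standard_normal()
            if d <= 0:
                raise ValidationError(f"contact {label}: non-positive sampled distance")
            coords.append(base)
            coords.append(base + np.array([d, 0.0, 0.0]))
        for off in prot_h_offsets:
            coords.append(ring_center + off)
        if n_water:
            solute = np.array(coords)
            placed = []
            while len(placed) < n_water:
                cand = ring_center - half + spec.water_cell * rng.random(
                    (max(64, n_water), 3)
                )
                dmin = np.min(
                    np.linalg.norm(cand[:, None, :] - solute[None, :, :], axis=2),
                    axis=1,
                )
                for ok in cand[dmin > 2.5]:
                    placed.append(ok)
                    if len(placed) == n_water:
                        break
            coords += placed
        atoms = [
            Atom(nm, el, resname, resid, chain, xyz)
            for (nm, el, resname, resid, chain), xyz in zip(proto, coords)
        ]
        frames.append(Frame(atoms, time_label=float(t)))
    return Ensemble(frames)


def generate_uniform_solvent(
    n_frames: int = 100,
    density: float = 0.0334,
    cell: float = 24.0,
    seed: int = 0,
) -> Ensemble:
    """Single reference atom at the centre of a cube of uniform waters.

    The bulk-water oxygen density is ~0.0334 / A^3.  No excluded volume:
    this is the analytic uniform limit in which g(r) = 1 everywhere.
    """
    rng = np.random.default_rng(seed)
    n_sol = int(round(density * cell ** 3))
    frames = []
    for t in range(n_frames):
        atoms = [Atom("REF", "C", "REF", 1, "L", np.full(3, cell / 2.0))]
        for w, pos in enumerate(rng.random((n_sol, 3)) * cell):
            atoms.append(Atom("O", "O", "HOH", 1000 + w, "W", pos))
        frames.append(Frame(atoms, time_label=float(t)))
    return Ensemble(frames)


# ---------------------------------------------------------------------------
# Model-generated STD tables
# ---------------------------------------------------------------------------

def generate_std_tables(
    ensemble: Ensemble,
    params: RelaxationParameters,
    noise_sd: float = 0.0,
    boost: dict[str, float] | None = None,
    seed: int = 0,
    ligand_sel: str = "chain L",
    protein_sel: str = "chain P",
    n_frames: int | None = None,
) -> tuple[StdTable, StdTable]:
    """Two synthetic solvent-condition STD tables from the relaxation model.

    Condition 1 is the back-calculated epitope verbatim; condition 2
    applies per-proton fractional boosts (mimicking extra saturation of
    protons near exchangeable residues, or attenuation by leakage) plus
    Gaussian noise.  Fractions f are converted to intensity pairs with
    I0 = 1 and Isat = 1 - f.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    calc = simulate_std(ensemble, ligand_sel, protein_sel, params, n_frames=n_frames)
    boost = boost or {}
    rows1: dict[str, tuple[float, float]] = {}
    rows2: dict[str, tuple[float, float]] = {}
    for proton, f in calc.std_calc.items():
        f2 = f * (1.0 + boost.get(proton, 0.0))
        if noise_sd:
            f2 += noise_sd * rng.standard_normal()
        rows1[proton] = (1.0, 1.0 - f)
        rows2[proton] = (1.0, 1.0 - f2)
    return StdTable("cond1", rows1), StdTable("cond2", rows2)
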