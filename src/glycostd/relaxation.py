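"""Complete-relaxation-matrix back-calculation of STD epitopes.

A proton network is built per frame from the ligand protons plus every
protein proton within a cutoff (default 10 A) of any ligand proton.
Homonuclear dipolar rates under isotropic tumbling with a single
correlation time tau_c populate the relaxation matrix:

    J(w)     = 2 tau_c / (5 (1 + w^2 tau_c^2))
    sigma_ij = k / r_ij^6 * (6 J(2 w0) - J(0))
    rho_i    = sum_j k / r_ij^6 * (J(0) + 3 J(w0) + 6 J(2 w0))  [+ leak]

with k = (mu0 / 4 pi)^2 gamma^4 hbar^2 / 10.  At 600 MHz and
tau_c = 34.956 ns the system tumbles slowly (w0 tau_c >> 1), so
cross-relaxation is negative (spin-diffusion limit).

Saturation transfer is modelled with the protein protons clamped at full
saturation from t = 0; the ligand block of the fractional-saturation
vector s evolves as ds/dt = -R_LL s - R_LP 1, giving

    s(t) = (I - exp(-R_LL t)) s_inf,   s_inf = -R_LL^{-1} R_LP 1,

which for an isolated ligand-protein pair reduces to the familiar
|sigma|/rho (1 - e^{-rho t}).  Predicted fractions are scaled by the
bound-ligand fraction [protein]/[ligand] (saturating-protein regime at
large ligand excess) and averaged over frames.  Agreement with an
experimental epitope is scored with the NOE R-factor

    R = sqrt( sum_k (STDexp_k - STDcalc_k)^2 / sum_k STDexp_k^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from glycostd.errors import ValidationError
from glycostd.structures import Ensemble, Frame, select

__all__ = [
    "RelaxationParameters", "SpinSystem", "RelaxationMatrix",
    "TheoreticalEpitope", "ValidationResult",
    "build_spin_system", "relaxation_matrix", "simulate_std",
    "r_noe", "r_noe_series", "two_spin_sigma_rho",
]

GAMMA_H = 2.6752218744e8   # proton gyromagnetic ratio, rad s^-1 T^-1
MU_0 = 1.25663706212e-06   # vacuum permeability, T m A^-1
HBAR = 1.054571817e-34     # reduced Planck constant, J s


@dataclass
class RelaxationParameters:
    """Spectrometer, tumbling and sample parameters for the back-calculation."""

    spectrometer_freq: float = 600.0  # MHz
    tau_c: float = 34.956             # ns, complex rotational correlation time
    ligand_conc: float = 2000.0       # uM
    protein_conc: float = 50.0        # uM
    cutoff: float = 10.0              # A, protein-proton inclusion radius
    t_sat: float = 0.5                # s, saturation time
    leak_rate: float = 0.0            # s^-1, optional external leakage added to rho

    def __post_init__(self) -> None:
        for name in ("spectrometer_freq", "tau_c", "ligand_conc",
                     "protein_conc", "cutoff", "t_sat"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.cutoff < 3.0:
            raise ValidationError("cutoff below 3 A would truncate direct contacts")

    @property
    def omega0(self) -> float:
        """Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.spectrometer_freq * 1e6

    @property
    def bound_fraction(self) -> float:
        return self.protein_conc / self.ligand_conc


@dataclass
class SpinSystem:
    """Proton network of one frame: all ligand protons + nearby protein protons."""

    ids: list[str]           # proton labels, chain:resid:name
    owner: np.ndarray        # "ligand" / "protein" per proton
    positions: np.ndarray    # (n, 3) Angstrom

    @property
    def ligand_index(self) -> np.ndarray:
        return np.flatnonzero(self.owner == "ligand")

    @property
    def protein_index(self) -> np.ndarray:
        return np.flatnonzero(self.owner == "protein")


@dataclass
class RelaxationMatrix:
    R: np.ndarray            # (n, n) s^-1; diagonal rho, off-diagonal sigma
    ids: list[str]


@dataclass
class TheoreticalEpitope:
    std_calc: dict[str, float]           # ligand proton -> fraction at t_sat
    per_frame: np.ndarray | None = None  # (n_frames, n_ligand_protons)
    ligand_protons: list[str] = field(default_factory=list)
    buildup: tuple[np.ndarray, np.ndarray] | None = None  # (times s, (nt, np) fractions)


@dataclass
class ValidationResult:
    r_noe: float
    residuals: dict[str, float]  # proton -> STDexp - STDcalc
    series: np.ndarray | None = None  # per-frame R-factors
    series_mean: float | None = None
    series_sd: float | None = None


def _proton_label(atom) -> str:
    return f"{atom.chain_id}:{atom.residue_id}:{atom.name}"


def build_spin_system(
    frame: Frame,
    ligand_sel: str,
    params: RelaxationParameters,
    protein_sel: str | None = None,
) -> SpinSystem:
    """Collect ligand protons and protein protons within the cutoff.

    Protein protons default to every hydrogen outside the ligand
    selection; only those within ``params.cutoff`` of at least one ligand
    proton enter the network.
    """
    lig_idx = [i for i in select(frame.atoms, ligand_sel)
               if frame.atoms[i].element == "H"]
    if not lig_idx:
        raise ValidationError(
            "no ligand hydrogens found; generate hydrogens upstream or fix the selection"
        )
    if protein_sel is not None:
        prot_pool = [i for i in select(frame.atoms, protein_sel)
                     if frame.atoms[i].element == "H" and i not in set(lig_idx)]
    else:
        lig_set = set(lig_idx)
        prot_pool = [i for i, a in enumerate(frame.atoms)
                     if a.element == "H" and i not in lig_set]
    lig_pos = np.array([frame.atoms[i].position for i in lig_idx])
    kept_prot = []
    for i in prot_pool:
        d = np.linalg.norm(lig_pos - frame.atoms[i].position, axis=1)
        if d.min() <= params.cutoff:
            kept_prot.append(i)
    order = lig_idx + kept_prot
    ids = [_proton_label(frame.atoms[i]) for i in order]
    owner = np.array(["ligand"] * len(lig_idx) + ["protein"] * len(kept_prot))
    pos = np.array([frame.atoms[i].position for i in order])
    return SpinSystem(ids, owner, pos)


def _spectral_density(omega: float, tau_c_s: float) -> float:
    return 2.0 * tau_c_s / (5.0 * (1.0 + (omega * tau_c_s) ** 2))


def two_spin_sigma_rho(r_angstrom: float, params: RelaxationParameters) -> tuple[float, float]:
    """Closed-form cross- and auto-relaxation rate of an isolated proton pair."""
    tau = params.tau_c * 1e-9
    w0 = params.omega0
    k = (MU_0 / (4.0 * np.pi)) ** 2 * GAMMA_H ** 4 * HBAR ** 2 / 10.0
    r6 = (r_angstrom * 1e-10) ** 6
    j0 = _spectral_density(0.0, tau)
    j1 = _spectral_density(w0, tau)
    j2 = _spectral_density(2.0 * w0, tau)
    sigma = k / r6 * (6.0 * j2 - j0)
    rho = k / r6 * (j0 + 3.0 * j1 + 6.0 * j2)
    return sigma, rho


def relaxation_matrix(spins: SpinSystem, params: RelaxationParameters) -> RelaxationMatrix:
    """Dipolar relaxation matrix over the spin system (s^-1)."""
    n = len(spins.ids)
    pos = spins.positions
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < 0.5):
        i, j = np.argwhere(off & (r < 0.5))[0]
        raise ValidationError(
            f"protons {spins.ids[i]} and {spins.ids[j]} nearly coincide "
            f"(r = {r[i, j]:.3f} A)"
        )
    tau = params.tau_c * 1e-9
    w0 = params.omega0
    k = (MU_0 / (4.0 * np.pi)) ** 2 * GAMMA_H ** 4 * HBAR ** 2 / 10.0
    j0 = _spectral_density(0.0, tau)
    j1 = _spectral_density(w0, tau)
    j2 = _spectral_density(2.0 * w0, tau)
    with np.errstate(divide="ignore"):
        inv_r6 = np.where(off, 1.0 / (r * 1e-10) ** 6, 0.0)
    sigma = k * inv_r6 * (6.0 * j2 - j0)
    rho = k * (j0 + 3.0 * j1 + 6.0 * j2) * inv_r6.sum(axis=1) + params.leak_rate
    R = sigma
    np.fill_diagonal(R, rho)
    return RelaxationMatrix(R, list(spins.ids))


def _propagate(Rmat: RelaxationMatrix, spins: SpinSystem,
               t: float) -> np.ndarray:
    """Ligand fractional saturation at time t with protein clamped at 1."""
    lig = spins.ligand_index
    prot = spins.protein_index
    R = Rmat.R
    R_ll = R[np.ix_(lig, lig)]
    s = np.zeros(len(lig))
    if prot.size:
        source = -R[np.ix_(lig, prot)] @ np.ones(prot.size)
    else:
        source = np.zeros(len(lig))
    # isolated protons (zero auto-relaxation) stay at zero saturation
    active = np.flatnonzero(np.abs(np.diag(R_ll)) > 0)
    if active.size:
        A = R_ll[np.ix_(active, active)]
        b = source[active]
        try:
            s_inf = np.linalg.solve(A, b)
            s[active] = s_inf - expm(-A * t) @ s_inf
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"saturation propagation failed; matrix condition "
                f"{np.linalg.cond(A):.3g}"
            ) from exc
    return s


def simulate_std(
    ensemble: Ensemble,
    ligand_sel: str,
    protein_sel: str | None,
    params: RelaxationParameters,
    n_frames: int | None = None,
    times: np.ndarray | None = None,
) -> TheoreticalEpitope:
    """Back-calculate the theoretical STD epitope from a coordinate ensemble.

    For each analysed frame a spin system and relaxation matrix are built
    and the ligand saturation propagated to ``params.t_sat``; the result
    is scaled by the bound-ligand fraction and averaged over frames.
    ``n_frames`` selects that many evenly spaced frames (default: all).
    ``times`` additionally records the build-up curve averaged over frames.
    """
    total = len(ensemble)
    if n_frames is None or n_frames >= total:
        frame_ids = list(range(total))
    else:
        frame_ids = list(np.linspace(0, total - 1, n_frames).round().astype(int))
    fbound = params.bound_fraction
    per_frame = []
    buildup_acc = None
    ligand_protons: list[str] | None = None
    for t_idx in frame_ids:
        frame = ensemble.frames[t_idx]
        spins = build_spin_system(frame, ligand_sel, params, protein_sel)
        Rmat = relaxation_matrix(spins, params)
        lig = spins.ligand_index
        labels = [spins.ids[i] for i in lig]
        if ligand_protons is None:
            ligand_protons = labels
        elif labels != ligand_protons:
            raise ValidationError("ligand proton set changed between frames")
        per_frame.append(fbound * _propagate(Rmat, spins, params.t_sat))
        if times is not None:
            curve = np.stack([fbound * _propagate(Rmat, spins, tt) for tt in times])
            buildup_acc = curve if buildup_acc is None else buildup_acc + curve
    per_frame_arr = np.stack(per_frame)
    mean_std = per_frame_arr.mean(axis=0)
    assert ligand_protons is not None
    buildup = None
    if times is not None and buildup_acc is not None:
        buildup = (np.asarray(times, dtype=float), buildup_acc / len(frame_ids))
    return TheoreticalEpitope(
        std_calc={p: float(v) for p, v in zip(ligand_protons, mean_std)},
        per_frame=per_frame_arr,
        ligand_protons=ligand_protons,
        buildup=buildup,
    )


def _common_vectors(exp_map, calc: TheoreticalEpitope,
                    normalize: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    exp_vals = exp_map.abs_std if hasattr(exp_map, "abs_std") else dict(exp_map)
    common = [p for p in exp_vals if p in calc.std_calc]
    if not common:
        raise ValidationError("no protons common to experimental and calculated epitopes")
    e = np.array([exp_vals[p] for p in common], dtype=float)
    c = np.array([calc.std_calc[p] for p in common], dtype=float)
    if normalize == "relative":
        if e.max() <= 0 or c.max() <= 0:
            raise ValidationError("cannot normalize epitopes with non-positive maxima")
        e = e / e.max()
        c = c / c.max()
    elif normalize != "none":
        raise ValidationError(f"unknown normalization {normalize!r}")
    return common, e, c


def r_noe(exp_map, calc: TheoreticalEpitope, normalize: str = "none") -> ValidationResult:
    """NOE R-factor between experimental and back-calculated STD epitopes.

    ``normalize="relative"`` rescales both epitopes to a common maximum of
    1 before comparison (both inputs are always treated identically).
    """
    common, e, c = _common_vectors(exp_map, calc, normalize)
    denom = float(np.sum(e ** 2))
    if denom == 0:
        raise ValidationError("all experimental STD values are zero; R-factor undefined")
    r = float(np.sqrt(np.sum((e - c) ** 2) / denom))
    residuals = {p: float(ev - cv) for p, ev, cv in zip(common, e, c)}
    return ValidationResult(r_noe=r, residuals=residuals)


def r_noe_series(exp_map, calc: TheoreticalEpitope,
                 normalize: str = "none") -> ValidationResult:
    """R-factor per analysed frame plus its mean and standard deviation."""
    if calc.per_frame is None:
        raise ValidationError("calculated epitope has no per-frame data")
    overall = r_noe(exp_map, calc, normalize)
    series = []
    for row in calc.per_frame:
        frame_calc = TheoreticalEpitope(
            std_calc={p: float(v) for p, v in zip(calc.ligand_protons, row)}
        )
        series.append(r_noe(exp_map, frame_calc, normalize).r_noe)
    arr = np.array(series)
    overall.series = arr
    overall.series_mean = float(arr.mean())
    overall.series_sd = float(arr.std(ddof=0))
    return overall
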