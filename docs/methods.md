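# Methods

`glycostd` analyses the recognition of heparin-like glycosaminoglycan
ligands by proteins, the canonical case being the antithrombin (AT)
activating pentasaccharide GlcNAc/NS6S-GlcA-GlcNS3S6S-IdoA2S-GlcNS6S
(units labelled E, D, C, B, A from the non-reducing end).  It combines
ligand-based NMR statistics (STD and differential DEEP-STD epitope
mapping) with geometric and solvation analysis of coordinate ensembles
and a complete-relaxation-matrix back-calculation of theoretical STD
epitopes.  This note records the models, their assumptions, and the
design choices taken where the problem left them open.

## STD epitopes and DEEP-STD factors

The fractional STD intensity of proton *i* is

    I_STD,i = (I0,i - Isat,i) / I0,i

from the off- (I0) and on-resonance (Isat) intensities.  Intensity units
are arbitrary but must be consistent within a table; only ratios enter
the analysis.  Relative epitopes divide by the most intense signal
(assigned 100 %).  The semi-quantitative bins are closed on their lower
edge: [80, 100] strong, [60, 80) medium, [40, 60) low, < 40 below.  The
conventional integer ranges (100-80 / 79-60 / 59-40) leave the edges
ambiguous; closing on the lower edge is the deterministic convention
used throughout.

The DEEP-STD factor compares one proton across two experimental
conditions (here D2O vs H2O):

    dSTD_i = STD1,i / STD2,i - (1/n) sum_j STD1,j / STD2,j

over the n protons observed in both conditions.  Mean-centering makes
the factors sum to zero exactly, which is property-tested.  A factor is
significant when |dSTD_i| > 0.1 (default threshold); both signs are
informative — a relative gain in H2O points to slow-exchanging polar
side chains (arginine), a relative loss to fast-exchanging ones
(lysine) or to solvation leakage.  Note that for n = 2 the two factors
are forced to +/-x, so either both or neither are significant; merged or
overlapping signals must be combined into one label by the caller, no
deconvolution is attempted.  Protons missing from one condition, or
with zero intensity in the denominator condition, are excluded and
reported.  Negative STD values propagate with a warning, never clipped.

Total saturation is the sum of absolute STD percentages over a
condition's protons.  A gain on going from D2O to H2O suggests a
high-affinity (long residence time) complex, which protects exchangeable
protein protons from the bulk; a loss or tie suggests medium/low
affinity.

## Glycosidic conformation

Torsions follow the proton-based convention for 1->4 linkages,
phi = H1-C1-O4-C4 and psi = C1-O4-C4-H4, signed by the IUPAC rule and
reported in [-180, 180) (180 maps to -180 so equality tests are
deterministic).  Conformational states are detected on a periodic
(phi, psi) histogram (default 10 degree bins): occupied bins drain to
their densest neighbour (8-neighbourhood with wrap-around), each
attractor is one basin, attractors closer than two bins merge into the
denser one, and basins holding under `min_pop` (default 5 %) of the
frames are folded into the unassigned pool.  Each state reports both
its mode (peak bin centre) and the circular mean of its member frames;
the mean is the better point estimate for symmetric peaks and is what
the recovery tests target (3 degrees at n = 10000, sigma = 10 degrees).
This basin method was chosen over a named clustering algorithm because
the underlying evidence is a density map; it needs no distance scale on
a periodic domain and degrades gracefully to "everything unassigned" on
flat densities.

The L-iduronate ring pucker is classified per frame from the H5-H2
distance, whose conformer signatures are ~4.0 A in the 1C4 chair and
~2.4 A in the 2S0 skew-boat.  The binary threshold defaults to the
midpoint, 3.2 A — the least-biased rule when only the two signatures
are known.  The two-state NOE inversion solves

    ratio = [p r_short^-6 + (1 - p) r_long^-6] * r_ref^6

for the skew population p, with r_ref the conformation-insensitive
H5-H4 distance (default 2.45 A).  This assumes the isolated-spin-pair
approximation (NOE proportional to r^-6, no spin diffusion) and a
strictly conformation-independent reference distance; both are
approximations, adequate for a semi-quantitative population estimate.
Out-of-range ratios clamp to [0, 1] with a warning.

## Contacts, fluctuations, clustering, solvation

Contact distances use the field's charged-group conventions: sulfate S,
carboxylate C, lysine NZ, arginine CZ.  Averages default to the second
half of the ensemble (the production stage of a simulation); a stride
parameter subsamples if desired.  RMSD uses optimal least-squares
(Kabsch) superposition when requested; RMSF superposes all frames onto
the first, measures each atom's RMS excursion about its time-average
position and averages within user-defined groups.  Conformer clustering
is DBSCAN (scikit-learn) on the pairwise best-fit-RMSD matrix with the
conventional epsilon = 0.5 A and min_points = 25; representative frames
are cluster medoids.

The radial distribution function of water oxygens around a reference
atom set is

    g(r) = V / (4 pi Npair) * p(r) / (r^2 dr)

with p(r) the mean per-frame pair count in the shell [r, r + dr), Npair
the number of reference-solvent pairs and V the cell volume, so uniform
solvent gives g = 1.  Every reference atom contributes independently
(no nearest-reference reduction).  Bin centres stand in for r.  V
should be passed explicitly for synthetic cells; otherwise it is
estimated from the solvent bounding box.  No minimum-image correction
is applied — ensembles are assumed re-imaged — which is the main
limitation for raw periodic trajectories.  The uniform-solvent test
evaluates the *bulk-region average* of g (r >= 3 A) because individual
0.1 A bins at bulk water density and 100 frames carry ~15 % counting
noise; the average over the bulk region has sub-percent noise.

## Relaxation-matrix STD back-calculation

Per frame, the spin system contains every ligand proton plus each
protein proton within the cutoff (default 10 A) of any ligand proton.
Homonuclear dipolar rates under isotropic tumbling with one correlation
time tau_c:

    J(w)     = 2 tau_c / (5 (1 + w^2 tau_c^2))
    sigma_ij = k r_ij^-6 (6 J(2 w0) - J(0))
    rho_i    = sum_j k r_ij^-6 (J(0) + 3 J(w0) + 6 J(2 w0))  [+ leak]
    k        = (mu0 / 4 pi)^2 gamma^4 hbar^2 / 10

Defaults: 600 MHz, tau_c = 34.956 ns, ligand 2000 uM, protein 50 uM,
t_sat = 0.5 s.  At these settings w0*tau_c >> 1 and sigma < 0 (spin
diffusion limit).  Physical constants are explicit CODATA literals so
unit tests can compare against an independently coded closed form at
1e-10 relative tolerance.

Saturation is modelled as instantaneous and complete on the protein
protons (clamped at fractional saturation 1 from t = 0); on-resonance
offset details are not modelled.  The ligand block then evolves as
ds/dt = -R_LL s - R_LP 1, solved by matrix exponential; an isolated
ligand-protein pair reduces to |sigma|/rho (1 - e^{-rho t}), which is
the analytic oracle used in tests.  The bound-state result is scaled by
the bound fraction [protein]/[ligand] (saturating-protein assumption at
large ligand excess; no explicit exchange kinetics, no koff).  The full
calculation runs per frame and averages the fractions, so the R-factor
can also be tracked frame by frame.  An optional scalar leak rate adds
to every rho_i to mimic external magnetization leakage (default 0).
Out of scope: full exchange-kinetics treatments (CORCEMA-ST),
methyl-rotation corrections, anisotropic tumbling.

Agreement with an experimental epitope uses the NOE R-factor

    R = sqrt( sum_k (STDexp_k - STDcalc_k)^2 / sum_k (STDexp_k)^2 )

over common protons (0 for perfect agreement, 1 for an all-zero
prediction).  The square root follows the standard NOE R-factor
convention.  Fractional and relative (max-normalized) epitopes are both
accepted; both inputs are always normalized identically.

## Synthetic data: what it emulates and what it does not

The generator exists so that every code path can be exercised against
known ground truth:

* **Rings** are built by pinning the six out-of-plane displacements to
  the Cremer-Pople pattern of the requested conformer (chairs
  Q = 0.57 A at theta = 0/180; the skew-boat at the canonical twist
  amplitude Q = 0.75 A, theta = 90, phi = 330) and least-squares
  fitting cylindrical coordinates to the target bond lengths (C-C
  1.52 A, C-O 1.43 A, weighted 10x) and ring angles (111 degrees).
  Hydrogens are placed on tetrahedral slots; the slot choice at C2/C5
  encodes the iduronate configuration and reproduces the 4.0 / 2.4 A
  H5-H2 signatures without any fitting to those distances.
* **Toy complexes** compose independent sub-assemblies: a 5-atom
  linkage whose phi/psi are drawn from a wrapped-Gaussian state
  mixture, a ring flipping between chair and skew with prescribed
  probability, ligand/protein atom pairs at prescribed jittered
  distances, three protein protons flanking the ring, and optional
  single-site (oxygen-only) uniform waters excluded within 2.5 A of
  solute.  All randomness flows through one `numpy` generator seeded
  from the spec, so equal seeds give byte-identical ensembles.
* **STD tables** are produced by running the relaxation model itself
  and converting fractions back to (I0 = 1, Isat = 1 - f) pairs; a
  second condition applies per-proton boosts (mimicking extra
  saturation near exchangeable residues) plus Gaussian noise, enabling
  closed-loop tests of the DEEP-STD statistics and the R-factor.

What the synthetic data does **not** emulate: force-field energetics
and correlated dynamics, realistic water structure (hydration shells,
hydrogen-bond networks), chemical-shift overlap, spectral noise
characteristics of real STD spectra, or full oligosaccharide topology.
Passing the recovery tests therefore demonstrates the *estimators* are
correct and well-calibrated at the stated sample sizes, not that any
particular physical system behaves this way.  Quantities that require
the original microsecond MD trajectories and the experimental spectra —
bound-state dihedral populations, experimental epitope maps and total
saturation percentages, crystal-structure contact distances, and the
published R-factors (~0.26/0.29) — are deliberately replaced here by
parameter-recovery and closed-loop suites that exercise the identical
code paths.

## Problem sizes and numerical choices

Test and validation problem sizes were chosen as the smallest that make
the statistical tolerances meaningful: 10000 frames for two-state
population recovery (+/-2 points), 5000 for the pucker mixture
(+/-2 points), 100 frames of bulk-density solvent for RDF normalization
(+/-5 % on the bulk average), ~1000-case property sweeps for exact
invariants.  Degenerate inputs are defined errors, not silent results:
empty selections, ambiguous single-atom addresses, all-nonpositive
epitopes, coincident protons (< 0.5 A), zero experimental denominators.
Ties in the basin search resolve toward the first-scanned bin;
DBSCAN labels are permutation-stable up to relabelling (tested).
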