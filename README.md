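# glycostd

Statistics and ensemble analysis for ligand-based NMR studies of
glycosaminoglycan–protein recognition — the motivating system being
heparin pentasaccharides bound to antithrombin (AT), whose
lysine/arginine-rich activation site (K11, R13, R46, R47, K114, K125,
R129) is probed by saturation-transfer-difference (STD) NMR in two
solvents.

The package provides, as a library plus a `glycostd` command line:

* **STD epitope maps** — absolute fractional intensities
  `I_STD = (I0 − Isat)/I0`, relative percentages (max = 100 %),
  semi-quantitative binning, and total-saturation comparison between
  D2O and H2O conditions as an affinity indicator.
* **DEEP-STD differential factors** —
  `ΔSTD_i = STD1_i/STD2_i − mean_j(STD1_j/STD2_j)` over the protons
  common to both conditions, with |ΔSTD| > 0.1 significance; the sign
  reports proximity to slow- vs fast-exchanging polar residues.
* **Conformational analysis of coordinate ensembles** — glycosidic
  torsions (φ = H1-C1-O4-C4, ψ = C1-O4-C4-H4), periodic Ramachandran
  density basins with state populations, iduronate ring-pucker
  classification from the H5–H2 distance (1C4 chair ≈ 4.0 Å, 2S0
  skew-boat ≈ 2.4 Å), and a two-state NOE-ratio population estimate.
* **Contacts and solvation** — charged-group contact distances
  (sulfate S, carboxylate C, Lys NZ, Arg CZ), RMSD/RMSF, DBSCAN
  conformer clustering under a best-fit RMSD metric, and water-oxygen
  radial distribution functions
  `g(r) = V/(4π·Npair) · p(r)/(r² dr)`.
* **Relaxation-matrix STD back-calculation** — per-frame proton
  networks, homonuclear dipolar cross/auto-relaxation rates at a single
  correlation time, matrix-exponential saturation transfer with the
  protein clamped saturated, and the NOE R-factor
  `R = √(Σ(STDexp−STDcalc)²/Σ STDexp²)` for validating ensembles
  against experimental epitopes.
* **Synthetic data** — idealized pyranose conformers, toy complexes
  with prescribed dihedral-state/pucker/contact statistics, uniform
  water boxes, and STD tables generated from the relaxation model, so
  every estimator is testable against known ground truth.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

Generate a toy complex whose linkage samples two conformational states
(78 %/22 %) and whose ring flips between chair and skew-boat (64 %
skew), derive STD tables from the relaxation model with one proton
boosted in the second condition, and run the analysis:

```python
from glycostd import *
from glycostd.synthetic import (ToyComplexSpec, generate_toy_complex,
                                generate_std_tables, toy_linkage_spec)
from glycostd.conformation import dihedral_series

spec = ToyComplexSpec(
    n_frames=500, seed=7,
    dihedral_states=[(44.0, 6.0, 0.78, 10.0), (-37.0, -28.0, 0.22, 10.0)],
    pucker_mix=0.64,
)
ens = generate_toy_complex(spec)
params = RelaxationParameters()          # 600 MHz, tau_c 34.956 ns, t_sat 0.5 s
t1, t2 = generate_std_tables(ens, params, boost={"L:10:H5": 0.4},
                             seed=7, n_frames=20)

m1 = relativize_and_bin(std_intensities(t1))
m2 = relativize_and_bin(std_intensities(t2))
print(deep_std(m1, m2).significant)      # ['L:10:H5']

cat = ramachandran_states(dihedral_series(ens, toy_linkage_spec()))
print([(round(s.phi_center), round(s.psi_center), round(s.population, 3))
       for s in cat.states])             # [(43, 6, 0.776), (-37, -28, 0.222)]

ps = pucker_classify(ens, "L:10:H5", "L:10:H2")
print(round(ps.fractions["skew_2S0"], 3))  # 0.632
```

The boosted ring proton is the only significant DEEP-STD factor
(ΔSTD = −0.245 in the condition-1/condition-2 convention: extra
saturation in condition 2 lowers its ratio), the two dihedral states
are recovered at 77.6 %/22.2 %, and the pucker mixture at 63.2 % —
all within sampling error of the generator's truth.  Comparing the
total saturations of the two tables (11.23 % vs 12.05 %) yields
`suggests_high_affinity`, the pattern expected when saturation grows on
moving to H2O.

The same workflow runs end to end from a JSON config:

```sh
glycostd run --config config.json --out-dir out/
```

producing per-stage JSON results and a run manifest with checksums,
wall-times and propagated warnings.

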