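# colloidkit

Structure-based descriptors for estimating colloidal protein–protein
interaction propensity:

* **Pseudo-protein shells** — trivalent spherical carbon cages (Goldberg
  polyhedra GP(h, k), default GP(3, 2): 380 atoms, ≈1.8 nm diameter) with
  one central atom, used as rigid scaffolds for protein-like surface
  charge patterns.
* **Charge topologies** — random per-atom charges drawn from a
  SASA-weighted, protein-like charge distribution, shifted to an exact
  target net charge; selection helpers produce descriptor-diverse sets
  (constant net charge/dipole) and dipole series.
* **Surface-patch descriptors** — the local sum of squared charges (lssc)
  and local sum of charges (lsc) within a cutoff radius, with summary
  scalars `mlssc = min(lssc)` and `mlsc = max(lsc)·min(lsc)`, plus a
  (d_cut, n) sensitivity scan.
* **Protein structure descriptors** — net charge, dipole moment
  (mass-center origin), Shrake–Rupley SASA, and the SAP family
  (per-residue SAP, SAPmax, SASA-normalized nSAP) from PDB/PQR input.
* **Mutation scans** — single charge-flip mutations (R→D, K→D, D→R, E→R),
  their net-charge and dipole changes, and class-level aggregation.
* **Solubility models** — ordinary least squares for
  `sol = c1·desc + c2·q + c3` with F-test significance, coefficient
  ratios `c2/c1`, Pearson correlations, and extraction of the bound
  minimum closest to contact from tabulated PMF curves.
* **Fixtures** — deterministic toy proteins, synthetic solubility tables
  and synthetic PMF curves, so everything runs offline.

Units: coordinates in Å, charges in e, dipole moments in eÅ
(1 eÅ ≈ 4.803 D), energies in kJ/mol.

## CLI

```bash
colloidkit build-shell --h 3 --k 2 --bond 1.42 --out shell.xyz
colloidkit gen-topologies --n 100 --q-target -2 --seed 7 --out tops/
colloidkit select tops/PP*.csv --mode varied --k-select 12 --out chosen.csv
colloidkit patch-desc tops/PP*.csv --dcut 5.0 --n 0 --out desc.csv
colloidkit fixtures toy-protein --seed 2 --n-residues 30 --out toy.pqr
colloidkit protein-desc toy.pqr --sap-radius 5 --probe 1.4 --out pdesc.csv
colloidkit mutation-scan toy.pqr --mol-class cytokine --out mut.csv
colloidkit fixtures solubility --seed 3 --out sol.csv
colloidkit fit-solubility sol.csv --descriptor p --out model.json
colloidkit fixtures pmf --out curve.dat && colloidkit pmf-min curve.dat
```

Every command writes a JSON sidecar (`<out>.json`) with the resolved
configuration and package version.

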