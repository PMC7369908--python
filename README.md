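# tyrlie

Binding free energy analysis for tyrosinase–ligand complexes with the
linear interaction energy (LIE) method, plus construction and geometric
validation of a Jahn–Teller-aware dummy-atom model for the active-site
Cu²⁺ ions.

Tyrosinase (TYR) is the binuclear type-3 copper enzyme that starts melanin
synthesis; its inhibitors — kojic acid and analogues, tropolone — are of
wide interest in medicine and cosmetics. This package is for computational
chemists who have (or simulate) MD-style ligand–surrounding interaction
energy time series and want desk-scale, reproducible binding-affinity
estimates, parameter calibration and interaction decomposition, without
rerunning any molecular dynamics.

## What it computes

**LIE estimator.** From the time-averaged ligand–surroundings interaction
energies of the bound (solvated protein complex) and free (ligand in
solvent) states,

```
ΔG_LIE = α (⟨V_vdw⟩_bound − ⟨V_vdw⟩_free) + β (⟨V_ele⟩_bound − ⟨V_ele⟩_free)
```

with α the non-polar scaling factor and β the polar one, chosen per ligand
chemistry (charged 0.50; no hydroxyl 0.43; one hydroxyl 0.37; two or more
0.33) in the literature scheme (α = 0.181), or fitted.

**Calibration.** (α, β) are refitted by no-intercept least squares of
experimental binding free energies ΔG_exp = RT ln K_i on the per-ligand
(ΔV_vdw, ΔV_ele) pairs, with Pearson r² quality for both parameterizations
and optional leave-one-out validation.

**Decomposition.** Per-residue and per-Cu²⁺ mean interaction energies of
the bound state, ranked to identify binding determinants (a presentation of
mean energies, not a rigorous free-energy partition).

**Cu²⁺ dummy site model.** Detects Cu sites in a PDB (His-N / water-O
coordination), places a +2 e core plus six charged dummies in a distorted
octahedron — axial arms elongated, as the Jahn–Teller effect demands for a
d⁹ ion — and validates coordination-distance statistics, axial/equatorial
elongation ratios and radial distribution functions on trajectories.

**Synthetic data.** Stationary AR(1) energy series and fluctuating
metal-site trajectories with prescribed means/spreads, so the entire
pipeline runs and is tested with no simulation engine; the nine-ligand
study tables (energy differences, K_i constants, coordination distances,
per-ion energies) ship as packaged fixtures.

## Worked example

Calibrate the LIE parameters on the packaged nine-ligand fixture (eight
ligands have measured constants; l-DOPA is excluded from the fit):

```
$ tyrlie calibrate --out report.json
alpha=0.197 beta=0.343 r2_model1=0.93 r2_model2=0.94 (8 ligands) -> report.json
```

The fitted α = 0.197 and β = 0.342 say that roughly 20% of the van der
Waals and 34% of the electrostatic interaction-energy change survive into
the binding free energy; r² ≈ 0.93–0.94 means both parameterizations rank
and scale the eight experimental affinities well. Per-ligand estimates:

```
$ tyrlie lie --out lie.csv
wrote 9 ligands to lie.csv (fitted alpha=0.197, beta=0.343)
$ head -4 lie.csv
ligand_id,dV_vdw,dV_ele,dG_lie1,dG_lie1_sem,dG_lie2,dG_lie2_sem,dG_exp
l-DOPA,-17.9500,-22.9300,-10.8159,0.3500,-11.3955,0.3649,
l-Tyr,-12.4400,-20.9100,-9.1519,0.2788,-9.6181,0.2904,-9.5497
TRO,-12.9000,-15.1600,-7.9441,0.3605,-7.7373,0.3347,-8.3177
```

`dG_lie1` is the literature parameterization, `dG_lie2` the fitted one,
`dG_exp` the RT ln K conversion of the measured constant (kcal/mol
throughout). Build the dummy model on the packaged synthetic two-copper
site:

```
$ tyrlie cudum --structure src/tyrlie/data/synthetic_cu_site.pdb --out-pdb site_dum.pdb
CU_1: 6 partners, charge sum +2.0 e, ax/eq distances 1.10/0.90 A
CU_101: 6 partners, charge sum +2.0 e, ax/eq distances 1.10/0.90 A
wrote dummy-augmented structure to site_dum.pdb
```

Each detected site gains seven HETATM records (core + 4 equatorial + 2
axial dummies) summing to exactly +2.0 e.

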