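# Methods

## The LIE estimator

The linear interaction energy method is an end-point free-energy estimate:
only the physical end states (ligand bound in the solvated protein; ligand
free in solvent) are sampled, and the binding free energy is modelled as a
linear response in the change of the ligand–surroundings interaction
energy averages,

ΔG_LIE = α·ΔV_vdw + β·ΔV_ele,  ΔV_x = ⟨V_x⟩_bound − ⟨V_x⟩_free.

Assumptions inherited from the linear-response derivation: the
electrostatic response of the surroundings is linear in the ligand's
charges (half-coupling argument behind β), and the non-polar term —
cavity formation, dispersion, hydrophobic effect — scales with the van der
Waals interaction energy (empirical α). The estimator is linear in each
ΔV, so uncertainties propagate in quadrature.

Two parameter schemes are implemented:

* **literature** — α = 0.181 with a chemistry-dependent β: 0.50 for
  charged ligands, 0.43 / 0.37 / 0.33 for neutral ligands with 0 / 1 / ≥2
  hydroxyl groups. A per-ligand override table ships with the fixture
  because two study ligands (the zwitterionic amino-acid substrates and the
  hydroxy-acid analogue KA4) resolve to the 0.33 class although no simple
  hydroxyl count reproduces that assignment; the overrides encode the
  observed classes rather than guessing a counting rule.
* **fitted** — (α, β) from no-intercept least squares of experimental
  affinities on the (ΔV_vdw, ΔV_ele) pairs, solved exactly via the 2×2
  normal equations. No intercept is used: the LIE functional form has
  none, and on the packaged fixture the no-intercept fit reproduces the
  published (0.197, 0.342) almost exactly while an intercept fit does not.
  If the normal-matrix condition number exceeds 1e12 the fit fails rather
  than regularize, since silent ridge-style shrinkage would misrepresent
  the method.

Model quality is the squared Pearson correlation between predicted and
experimental values (≥3 pairs, nonzero variance required). Note r² is
invariant under affine maps of either vector; it measures association, not
absolute agreement — leave-one-out RMSE is available as a sharper check.

Recomputing the fitted-parameter predictions from the *rounded* fixture
energy columns deviates from the published fitted-model column by roughly
0.07–0.18 kcal/mol systematically, consistent with the original fit having
been applied to unrounded energies; the package documents this and treats
the published fitted-model column as reference data, not a target.

## Experimental affinities

ΔG_exp = RT ln K with R = 1.987204×10⁻³ kcal/(mol·K) and K in molar on the
1 M standard state. Dissociation constants are treated identically to
inhibition constants. Default temperature is **298.15 K**: the fixture's
published experimental column is reproduced to ≤0.06 kcal/mol at 298.15 K
and noticeably worse at 300 K, so the package defaults to the value the
data supports; temperature is configurable everywhere it enters.

## Block averaging

MD interaction-energy series are strongly autocorrelated, so the standard
error of a time average is estimated by splitting the frames into
`n_blocks` contiguous, near-equal blocks and taking sd(block means)/√n_blocks.
The default is **5 blocks** over the analysis window — a common MD
convention; with ~2000 frames and a correlation time of tens of frames the
block means are effectively independent. `n_blocks = 1` returns sem 0 with
a warning (no spread is estimable from one block). Published ± values in
the fixture are carried as reference data; how they were originally
computed (blocks, replicas, or raw sd) is not recoverable, so they are not
reproduction targets. Windowing (`t_start`/`t_end`, inclusive) is the
caller's responsibility; defaults use all frames.

## Per-residue decomposition

Mean per-group electrostatic and van der Waals interaction energies over
the bound trajectory, ranked most-negative-first (strongest attraction)
with lexicographic tie-breaks. There is no rigorous decomposition of a
free energy into additive residue terms, so the report header marks the
output as presentation-only. "Importance" deliberately uses the signed
mean, not |mean|: a large positive (repulsive) term is not a binding
determinant.

## Cu²⁺ dummy-atom site model

A bare +2 point charge makes classical MD of copper sites unstable; the
dummy-cation construction distributes the charge over a core and six
massless dummies in an octahedron, stabilising coordination without
artificial metal–ligand bonds and softening the Cu–Cu repulsion of
binuclear sites. For a d⁹ ion the octahedron is Jahn–Teller distorted:
axial arms longer than equatorial.

Construction: Cu atoms are detected by element; coordination partners are
His side-chain nitrogens (ND1/NE2) and water oxygens within a 3.0 Å cutoff
(typical first-shell Cu–N/O distances are 1.9–2.4 Å). The axial direction
points at the partner with the largest metal distance — the elongated
contact — unless a partner is named explicitly (the config resolves the
ambiguous case where an axial water and an axial histidine compete). The
four equatorial arms lie in the orthogonal plane, rotated so their
fourfold direction set aligns with the remaining partners' azimuths via a
fourfold circular mean (θ = ¼·atan2(Σsin 4φᵢ, Σcos 4φᵢ)), which is smooth,
deterministic and exactly equivariant under rigid motions. Fewer than
three partners, or collinear partners, are errors.

The shipped charges (core 0.0 e, equatorial +0.32 e, axial +0.36 e) and
distances (0.90 / 1.10 Å) are **placeholders** satisfying the invariants —
charge sum exactly +2.0 e, axial ≥ equatorial; production force-field
values must come from a published dummy-cation parameterization, and no
geometric or charge property of the builder depends on the specific
numbers.

Validation on trajectories: per-partner distance mean/sd; the Jahn–Teller
score (mean axial distance / mean equatorial distance, >1 meaning
tetragonal elongation — 1.16 for Cu_B and 1.10 for Cu_A on the packaged
reference statistics); and a radial distribution function normalised by
spherical-shell volume and the mean density of the selected species inside
the analysis sphere (droplet normalisation, no periodic box, matching
spherical-boundary simulation setups).

## Synthetic data

Energy series are stationary Gaussian AR(1) processes,
v_t = μ + φ(v_{t−1} − μ) + ε_t with ε_t ~ N(0, σ²(1−φ²)) and v₀ drawn from
the stationary distribution. φ defaults to 0.9 — energies saved every few
dozen MD steps are strongly autocorrelated and AR(1) is the simplest
process with that structure. Defaults: 2000 frames at 2 ps spacing (a 4 ns
analysis window at desk scale), fluctuations σ_ele = 1.0 and
σ_vdw = 0.5 kcal/mol. Free-state means are not part of the reference data
(only differences enter the estimator), so generated bound/free pairs
place the free mean at a configurable solvation baseline
(ele −6.76, vdw −8.0 kcal/mol) and enforce the target ΔV exactly in the
population means.

Site trajectories draw each partner's metal distance i.i.d. N(target mean,
target sd) along its coordination direction with a small angular wobble
(0.03 rad), so recovered distance statistics match their targets by
construction.

What the generators do **not** emulate: force-field energetics, water
structure, cross-correlations between components or partners, slow
conformational drift, and non-Gaussian tails. Passing closure tests
therefore demonstrates the correctness of the averaging, differencing,
calibration and geometry code under the stated statistical model — not the
accuracy of any force field or sampling protocol on real systems.

All randomness uses numpy's PCG64 (`default_rng`); every generator takes
an explicit seed and is bit-reproducible; multi-series generators derive
sub-seeds via `SeedSequence`.

## Numerical conventions

* Energies kcal/mol, distances Å, times ps, temperatures K, charges e.
* Unit conversion of concentrations is exact power-of-ten scaling.
* Energy tables: UTF-8 delimited text (comma or tab auto-detected), `#`
  comments, columns `ligand_id,state,component,group,time_ps,energy_kcal`;
  NaN or non-numeric energies are parse errors with line numbers, and
  duplicate (identity, time) rows are rejected.
* Summary round-trips are stable at 6 decimal places; PDB coordinates at
  the format's 3 decimals.
* Ranking ties break lexicographically; equal-size block splits use
  `numpy.array_split` semantics when frames are not divisible.

## Problem sizes

The packaged analyses run on the nine-ligand fixture (eight with measured
constants), 2000-frame synthetic series/trajectories, and 500-seed
coverage simulations; everything completes in seconds on one CPU.

## Known limitations

* The β override table encodes observed class assignments for ambiguous
  ligands; it does not explain them.
* Per-residue terms are mean interaction energies, not free energies.
* The RDF assumes a non-periodic droplet; no periodic-boundary
  normalisation is provided.
* Dummy-model charges/distances are placeholders (above); the package
  builds and validates geometry but does not emit MD-engine parameter
  files.
* Trajectory analysis expects the frame-table dialect
  (`frame,atom_label,x,y,z`) or structures readable by biotite; no native
  MD trajectory formats (DCD/XTC) are parsed.
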