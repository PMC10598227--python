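# Methods

`noetools` models the restraint apparatus of solution-NMR structure
determination for a protein–ligand complex: NOE-derived distance
restraints with pseudoatom (wildcard) ambiguity, chemical-shift-derived
backbone dihedral restraints, hydrogen-bond restraints, a restrained
Cartesian refinement protocol, and the ensemble-level validation
statistics that accompany a deposited NMR ensemble. This note records the
model, its assumptions, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Restraint model

**NOE distance restraints.** Cross-peak intensities are assumed
pre-classified into four classes — strong, medium, weak, very weak —
mapped to fixed bounds of 1.8–2.8, 1.8–3.5, 1.8–5.0 and 1.8–6.0 Å. The
1.8 Å lower bound is the van der Waals contact floor shared by all
classes. Bounds from tables are taken verbatim as upper bounds;
pseudoatom multiplicity is handled at evaluation time (below), not by
bound corrections. A config hook (`methyl_bonus`, default 0 Å) exists for
protocols that inflate methyl bounds; the default applies none, because
published bound tables normally fold such corrections in.

**Pseudoatoms and effective distances.** A wildcard selector such as
`HD1*` expands to every matching proton; a restraint between two groups
is evaluated on one *effective* distance over the Cartesian product of
pairs. Two conventions are implemented:

- r⁻⁶ **averaging**: d_eff = (mean_p d_p⁻⁶)^(−1/6) — used by the
  refinement and by most structure-calculation engines;
- r⁻⁶ **summing**: d_eff = (Σ_p d_p⁻⁶)^(−1/6) — used by PDB validation
  reports.

For an N-pair group, d_eff(average) = N^(1/6) · d_eff(sum) exactly, so
the summing convention always yields shorter effective distances (it is
bounded above by the closest single pair). A consequence worth spelling
out: summing can only *lose* upper-bound violations and *gain*
lower-bound violations relative to averaging. Validation reports
therefore always compute both conventions side by side rather than
adjudicating between them.

**Dihedral restraints.** Backbone φ/ψ restraints carry a target angle and
a half-width of max(20°, 1.5·σ), where σ is the predictor's reported
uncertainty (TALOS-style tables). Angles live in (−180°, 180°] and all
differences are wrapped.

**Hydrogen bonds.** Each donor/acceptor triple (N, H, O) contributes two
restraints: H···O at 1.7–2.5 Å and N···O at 2.7–3.5 Å.

**Categories and accounting.** Distance restraints are categorised as
intra-residue (|i−j| = 0), sequential (1), medium-range (2–4), long-range
(>4), intermolecular (exactly one side on the ligand chain) or
hydrogen-bond. Accounting sums the five NOE categories into the NOE
total, sequential+medium+long into the inter-residue total, and NOE +
dihedral + hydrogen-bond into the grand total. The packaged per-category
manifest reproduces the published totals exactly (2738 / 2133 / 270 /
3124); the packaged intermolecular table carries 60 rows.

## Energy model and refinement

The refinement is a deliberately simple Cartesian surrogate for
torsion-angle simulated annealing: the acceptance surface (violations,
lowest-energy selection, enantiomer ordering) does not require a dynamics
engine, and a desk-scale, fully reproducible minimiser is easier to
reason about. Components (all harmonic unless noted):

| term | form | default constant |
|---|---|---|
| NOE / H-bond | flat-bottom soft-square on d_eff | k_noe = 50 /Å² |
| dihedral | harmonic in wrapped excess violation | k_dih = 200 /rad² |
| bond | k(d−d₀)² | 1000 /Å² |
| angle | k(θ−θ₀)² | 100 /rad² |
| improper torsion | k·wrap(φ−φ₀)² | 50 /rad² |
| steric repulsion | k(onset−d)² for d < onset | 25 /Å², onset = 0.80·(rᵢ+rⱼ) |

The soft-square NOE term is zero inside [lower, upper], quadratic in the
violation up to a switch distance (1 Å), then linear with matched value
and slope — energy and first derivative are continuous everywhere, which
the test suite checks numerically. All ligand covalent terms are scaled
by 0.2, the compromise that keeps a small-molecule topology intact
without letting it dominate; the scale is configurable.

The steric term is a pure repulsive soft core between atoms more than
four bonds apart and in different residues, with onsets from scaled
element radii (H 1.1, C 1.55, N 1.4, O 1.35 Å). It is the excluded-volume
"repel" term annealing protocols use — there is no attractive van der
Waals component and no electrostatics. It is load-bearing for the
enantiomer screen: without excluded volume a mirrored ligand can
interpenetrate the protein and satisfy every class-bounded shell.
Setting `k_repel = 0` disables it.

**Gradients and minimisation.** Every term has an exact analytic gradient
(including the chain rule through the r⁻⁶ effective distance and the
standard torsion derivatives); the refinement oracle is agreement with
central finite differences to 1e−5 relative on randomised
configurations. Minimisation is L-BFGS-B with the analytic gradient;
energies over accepted iterates are non-increasing and termination is on
the projected-gradient norm or an iteration cap. Terms are compiled once
per (structure, restraint set) into flat index arrays, so one
energy/gradient evaluation is a handful of vectorised numpy operations;
repulsion pairs further than 3 Å beyond their onset at the start of a
minimisation are pruned (a single minimisation does not move atoms that
far).

**Pools and selection.** A pool is `pool_size` independent runs, run *i*
perturbing the start with isotropic Gaussian noise (per-atom rms
`perturbation_rms`, per-coordinate σ = rms/√3) from a PCG64 generator
seeded `seed + i` — bitwise reproducible. Selection keeps the `keep_n`
members with the lowest NOE (or total) energy, stable-sorted with run
index breaking ties, mirroring the "N lowest NOE energies" convention of
deposited ensembles.

**Enantiomer screen.** The screen refines the same experimental restraint
set once per ligand hand, each hand using its own start pose and a
topology whose single chirality-encoding improper has the opposite sign
(the two arm-orienting torsions are trans and hence mirror-invariant).
The winner is the hand with the lower mean over the n lowest NOE
energies; every final structure's chirality sign is computed, and runs
whose final hand disagrees with their topology are flagged as inversions.
Absolute energies of the original torsion-angle-dynamics protocol are not
reproducible with this surrogate; only orderings and violation statistics
transfer.

## Synthetic complex generator

The generator produces the study conditions every downstream test
assumes; it is first-class, tested code.

- **Protein**: an ideal α-helix (default 30 residues, φ/ψ = −57°/−47°)
  built by exact internal-coordinate (NeRF) chaining with standard
  peptide geometry. Side chains are reduced to Cβ plus pseudo-methyl
  protons (HB1–3 for alanine, HB1–2 otherwise) and, for methyl-bearing
  residue types (V/L/I/T/M), a Cγ pseudo-methyl with HG1–3. The restraint
  machinery needs names and positions, not rotamer chemistry.
- **Ligand**: a rigid toy stereocenter (six heavy atoms) whose four
  tetrahedral substituents *all* carry restrainable protons: H1 on the
  center, a methyl (HF*), a two-carbon arm methyl (HG*), and an N-methyl
  amine (HN1, HI*). That choice is what makes NOE contacts triangulate
  the center in 3D and distinguish the hands. R and S are exact mirror
  images with identical atom tables.
- **Docking**: deterministic — the ligand's long axis is laid along the
  helix axis with the H1 face toward a four-residue pocket around the
  helix midpoint, then backed off until no heavy-atom pair is closer
  than 2.9 Å.
- **Topology**: every equilibrium value (bond, angle, improper) is
  *measured from the true structure*, so the truth has exactly zero
  covalent energy — the ground-truth contract is exact, not approximate.
  Under mirroring, bond/angle equilibria are unchanged and torsion
  equilibria negate.
- **Restraints**: every proton-group pair within a cutoff (default 5 Å,
  evaluated as the r⁻⁶-averaged effective distance on the truth) becomes
  an NOE restraint in the tightest class covering that distance. An
  optional noise draw |N(0, σ)| widens the class — noise can never create
  a false violation. Pairs whose r⁻⁶-sum effective distance falls below
  the 1.8 Å floor are skipped, so the truth is violation-free under
  *both* conventions. Helical i→i+4 hydrogen bonds and φ/ψ restraints
  (20° half-width) from true angles complete the set. An
  `intermolecular_cutoff` may exceed the intramolecular one, emulating
  long-mixing interface experiments; the screen fixture uses 4.5/6.0 Å.

What the generator does **not** emulate: spectral overlap, spin
diffusion, assignment errors or ambiguity beyond wildcard pseudoatoms,
real side-chain rotamers, loops or termini flexibility beyond what the
restraint pattern implies, and solvent. Passing tests therefore show that
the machinery is correct under clean, internally consistent restraints —
not that real spectra of comparable quality would yield comparable
precision.

## Problem sizes and protocols used by the shipped checks

- Parameter recovery: the default 30-residue fixture, starts perturbed at
  1.0 Å rms, 20 seeds, up to 2000 L-BFGS iterations; success means max
  r⁻⁶-average violation < 0.1 Å and backbone RMSD to truth < 0.5 Å
  (observed: 19–20 of 20 succeed; the refined structure is always closer
  to the truth than its start).
- Enantiomer screen: the 12-residue screen fixture, pools of 4 gently
  perturbed starts (0.5 Å rms) per hand, compared on the 3 lowest NOE
  energies, 10 seeds, plus the exact mirrored problem. The S-derived
  problem selects S and the mirrored one selects R in ≥ 9 of 10 seeds.
- Selection contract: a 100-member pool at 40 iterations (the contract is
  about ordering, not convergence), keep 20.

## Validation conventions

"Violations (mean ± sd)" is computed, by default, as the mean and
standard deviation over the per-model mean violations of the ensemble
(the per-cell alternative is a flag), since published tables rarely state
which convention they use. Region RMSD tables use mean pairwise RMSD —
each model pair independently superposed (Kabsch, proper rotation
enforced) — with backbone {N, CA, C, O} by default and {N, CA, C} as a
switch; heavy-atom RMSD covers all non-hydrogen atoms of the selected
residues. Contact sites use a 4.5 Å heavy-atom cutoff (a common van der
Waals contact convention; configurable). Restraints whose selectors
cannot be resolved on a deposited atom table are skipped with a log
message rather than failing the report, because deposited pseudoatom
dialects vary; the amide proton H/HN dialect difference is aliased
automatically.

Residue numbering is taken from the coordinate file (1-based,
chain-qualified); no renumbering between engineered-construct and native
numbering is performed (for the Bcl-2 chimera this means construct
residue 165 corresponds to native residue 206 — a documented offset, not
a transformation).

## Known limitations

- The Cartesian minimiser cannot cross high barriers; a fraction of
  heavily perturbed starts land in nearby local minima (visible as small
  residual covalent energy with near-zero NOE energy). The pool-and-select
  protocol is the mitigation, as in the original annealing setting.
- Absolute energies are not comparable to any dynamics engine's; only
  orderings, violations, and geometric statistics are meaningful.
- The toy ligand's amine may pyramidally invert during minimisation (its
  nitrogen is held by angles only); this is real chemistry and harmless
  to the screen, which reads the stereocenter, not the amine.
- No Ramachandran/MolProbity statistics and no buried-surface-area
  computation; contact-site overlap (Jaccard and unique-fraction) is the
  only interface-comparison statistic.
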