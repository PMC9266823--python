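# Methods

## Scope and model

The package analyzes peptide–receptor complexes through purely distance- and
charge-based descriptors. All structural criteria are defined on heavy atoms
so inputs never need hydrogens; coordinates are in Å, residue numbering is
1-based PDB numbering, energies are in kcal/mol, and times in ns.

### Intermolecular energetics

`E_inter` sums only receptor↔ligand atom pairs; intramolecular terms and
waters are excluded. The Coulomb term uses
`E = k Σ q_i q_j / (ε(r)·r)` with `k = 332.0636 kcal·Å·mol⁻¹·e⁻²`
(the unit conversion of `N_A e²/(4πϵ₀)`). Because the target use case is a
desolvated binding cleft scored without explicit water, the dielectric is a
screening function `ε(r)`:

- `linear` (default): `ε(r) = D·r`, `D = 4` — a common implicit-screening
  choice for protein interiors;
- `constant`: `ε(r) = D`;
- `sigmoidal`: the Mehler–Solmajer form `A + B/(1 + k e^{−λBr})` with
  `A = −8.5525`, `k = 7.7839`, `λ = 0.003627`, `B = D − A`, saturating at the
  bulk value `D` (default parameterization `D = 78.4` when selected).

The exact functional mix used for scoring (LJ only, Coulomb only, or their
sum) is configuration, not a fixed fact of the method: ranking of built
models defaults to LJ, per-residue comparison to Coulomb+LJ totals, and every
entry point accepts a `scheme`/`dielectric` choice.

The LJ 12-6 term uses per-atom well depths and `R_min/2` radii with
`ε_ij = √(ε_i ε_j)` and `R_min,ij = R_min/2_i + R_min/2_j`. Atom pairs closer
than 0.1 Å are treated as corrupt input and raise, naming the pair.

**Parameter table.** The packaged table
(`sstbind/data/params_amber_heavy.dat`) is an Amber-99-style heavy-atom
subset covering the 20 canonical residues, ACE/NME caps and water. Hydrogen
partial charges are collapsed onto their bonded heavy atom (e.g. backbone N
carries −0.4157 + 0.2719 = −0.1438 e), and a per-residue residual is absorbed
by CB (CA for Gly) so that each residue's charges sum exactly to its formal
charge. This keeps electrostatics of hydrogen-free models charge-correct at
the residue level; it is not a simulation-grade force field and is packaged
as data so it can be replaced wholesale.

**Per-residue decomposition** groups the same pair energies once by the
receptor atom's residue and once by the ligand atom's residue; both sides
therefore sum to the same global total (asserted to 1e-9 relative in the
tests), mirroring how per-residue interaction plots are drawn for both
binding partners.

### Binding-mode mechanism

The reaction coordinate is the salt-bridge distance `d_SB` between the
ligand lysine side-chain amino nitrogen (NZ) and the receptor aspartate
carboxylate carbon (CG by convention — the carboxylate carbon of Asp — both
atoms overridable in `DsbSpec`). Binding modes are identified from the d_SB
distribution with an explicit density-peak procedure (the field usually
reads these off d_SB-vs-time plots by eye; the procedure below is this
package's reproducible substitute):

1. Gaussian KDE of the d_SB samples, bandwidth 0.3 Å (an absolute bandwidth,
   chosen at the scale of the coordinate's thermal noise; a grid step of
   0.02 Å bounds center resolution).
2. Local maxima become candidate states. Window half-widths are capped at
   1.5 Å and shrunk to half the inter-peak gap minus the hysteresis so
   windows never overlap; peaks holding less than `min_peak_occupancy`
   (default 0.05) of the samples are dropped, and overlapping noise peaks
   are merged keeping the denser one.
3. Labels by center rank: `internal` when the smallest center ≤ 4 Å (a
   formed Lys–Asp bridge is ~3 Å), `external` when the largest ≥ 15 Å
   (detached at the extracellular lid, ~18.5 Å), the rest
   `intermediate_near`/`intermediate_far`. All boundaries are configurable.

Frame classification assigns each frame to the window containing its value;
a frame within the hysteresis margin (default 0.5 Å) of the current state's
boundary keeps that state, which suppresses label flicker at window edges.
Occupancies include an `unassigned` fraction and sum to one; dwell segments
tile the time axis. Transition events are state changes whose flanking
dwells both exceed `min_dwell`; moves to a smaller-center state are
associations, to a larger-center state dissociations.

### Geometry

- Interface residues: any heavy atom within 3.5 Å of the partner molecule
  (the standard contact criterion; whether such published cutoffs mean heavy
  or all atoms is often unstated — heavy-atom is chosen here and documented).
- H-bonds: N/O/S–N/O/S heavy-atom pairs ≤ 3.5 Å; without hydrogens any
  polar heavy atom is a plausible donor, so no angle term is applied.
  Same-residue pairs under 1.8 Å are covalent and excluded.
- Salt bridges: {Lys NZ, Arg NH1/NH2/NE, N-terminal N} vs {Asp OD1/OD2,
  Glu OE1/OE2, backbone O, OXT} across molecules, minimum N–O distance
  ≤ 4.0 Å (standard literature value, consistent with a formed bridge at a
  d_SB of ~3 Å).
- Water bridges: a water whose oxygen has at least one qualifying H-bond to
  the ligand selection *and* one to the receptor selection; deduplicated per
  water, reporting the shortest H-bond on each side.
- β-turns: `|Cα(i) − Cα(i+3)| ≤ 7 Å` outside helical context, the helix
  filter being `|Cα(j) − Cα(j+4)| ≤ 6.5 Å` over the surrounding window.
  This is a standard operational definition adopted because no stricter
  turn criterion is imposed by the analyses built on it.
- Kabsch superposition via SVD with a determinant correction guaranteeing a
  proper rotation.

### Seed-and-grow construction

`grow_peptide` is a transparent, greedy stand-in for homology-model-based
ligand growing (re-implementing a full modelling engine is out of scope and
not needed for restraint-satisfaction analyses). Residues are appended N-ward
from the seed, then C-ward, with ideal backbone internals (C–N 1.329 Å,
trans ω) placed by NeRF. Each appended residue searches the torsion pair
that actually determines its placement (ψ of the previous residue + its own
φ when growing C-ward; mirrored N-ward) over broad Ramachandran boxes
(α and β regions; Gly gains the mirrored-α box, Pro is restricted) on a 30°
grid with per-model uniform jitter of ± half a grid step. Candidates are
ranked by clash count first (heavy-atom pairs < 2.0 Å against the receptor
and non-adjacent ligand residues), then by Coulomb+LJ energy against the
receptor plus quadratic restraint penalties. Side chains are single
schematic conformers.

Restraints need a guidance mechanism because a greedy builder places one
residue at a time: a penalty on the final S–S or d_SB distance would act
only when the second partner appears, too late to steer the chain. Two terms
handle this:

- *distance-to-go guidance*: while the partner of a disulfide (or the
  restrained lysine) is not yet built, the current residue's Cα pays
  `w·max(0, d − reach)²` toward the placed partner/anchor, where `reach`
  is ~3.4–3.8 Å per remaining residue plus the side-chain length — the
  chain may wander within reach but not beyond it;
- *targeted side-chain axes*: a disulfide cysteine's SG is built pointing at
  the partner SG, and the restrained lysine's side chain at the receptor
  anchor, before the quadratic penalty `w·(d − target)²` selects among
  backbone candidates. `w` defaults to 50 kcal/mol/Å².

The growth is deterministic per `seed_rng` (one independent RNG stream per
model). Known limitation: with a seed far from the pocket the greedy
one-residue horizon cannot descend a full pocket depth, so a d_SB restraint
then *reduces* the achieved distance relative to unrestrained growth rather
than hitting the target exactly; grown from the lysine seed itself (the
restrained-growth use case), the target is met within ±1 Å.

`transplant_ligand` fits mapped receptor Cα pairs by Kabsch and applies the
rigid transform to the ligand, preserving ligand internal geometry exactly.
`relax` is steepest descent with backtracking line search on the
intermolecular Coulomb+LJ energy plus a quadratic soft-clash penalty below
2.0 Å, moving only the mobile selection; only energy-lowering steps are
accepted, so the reported trace is non-increasing by construction. It is a
local clash-relief tool, not a minimizer of a bonded force field: because
intramolecular terms are excluded, large step budgets can distort internal
geometry of the mobile selection.

### Sequence comparison

The global aligner is a Gotoh affine-gap dynamic program with the defaults
of the EMBOSS Needle tool: BLOSUM62 (loaded from Biopython's substitution
matrices), gap open 10, gap extend 0.5 (a gap of length L costs
`10 + 0.5·(L−1)`), and end gaps free. Free end gaps mean the optimum may
prefer a trailing/leading overhang over an interior gap — e.g. `FWKT` vs
`FWT` aligns as `FWKT`/`FWT-` (score 16), not `FW-T` (score 12). Ties in the
traceback prefer substitution columns, then a gap in the first sequence.
The DP is verified in the tests against exhaustive enumeration of all
alignments on short sequences and against Biopython's `PairwiseAligner`
configured identically.

Energy mapping onto alignment columns takes explicit per-side residue-number
offsets (`position = resid − offset`) because structure numbering routinely
drifts from sequence numbering; the module never guesses offsets, and a
profile residue that cannot be mapped raises listing the offenders. The
shared-key flag marks columns where both subtypes exceed a magnitude
threshold (default 1.0 kcal/mol — there is no community-standard cutoff for
"important residue", so it is explicit configuration).

## Synthetic fixtures: what they emulate and what they do not

The generators produce the study conditions at fixture scale, deterministic
per seed (byte-identical PDB re-runs):

- **Toy receptor** (~22 residues): a cylindrical pocket (radius 8 Å, axis z)
  of backbone-only glycines, an aspartate (resid 126) with its carboxylate
  carbon at the origin as the d_SB anchor, a tyrosine (301) hydroxyl
  mid-pocket, and two lid arginines (188, 191) whose guanidinium groups
  overhang the pocket mouth at z ≈ 17 Å.
- **SST-14 model**: a Cα hairpin with strands 1–7/10–14 and the apical turn
  exactly at FWKT (residues 7–10, `|Cα7 − Cα10| = 5.5 Å`), backbone C–N at
  1.33 Å, schematic single-conformer side chains. The cyclic form places the
  C3/C14 SG atoms facing each other at 2.05 Å: a correct disulfide *contact*
  for detection purposes, while the schematic CB–SG bond lengths are not
  chemically accurate.
- **Scenario trajectories**: rigid-body translation of the posed ligand
  along the pocket axis so each frame's d_SB equals its programmed segment
  mean plus Gaussian noise. The default scenario walks external
  (18.5 Å, 500 frames) → far intermediate (10 Å, 500) → near intermediate
  (5.5 Å, 400) → internal (3.0 Å, 600) at σ = 0.4 Å and 0.05 ns/frame
  (2000 frames ≙ 100 ns), the association pathway with its reported state
  distances. Sampled values are clipped at a 2 Å physical floor; requesting
  a segment *mean* below 2 Å is rejected as unphysical.
- **Intermediate fixture**: the ligand posed at d_SB = 5.5 Å with exactly
  three waters bridging K9's NZ to Asp126 OD1/OD2 and Tyr301 OH (each water
  oxygen 2.7–3.2 Å from both partners), plus two decoy waters H-bonded to
  one side only.
- **Energy fixtures**: ±1 e at 1.0 Å; an LJ dimer at its combined R_min; a
  Lys/Asp pair with NZ 3.0 Å from the carboxylate carbon.

What passing tests on these fixtures show: the *operations* are correct —
conservation, closed forms, parameter recovery, restraint satisfaction,
invariances. What they do not show: anything about real receptor
conformational ensembles. The fixtures have no membrane, no solvent beyond
the placed bridge waters, no realistic fold, and the trajectories are rigid
translations with programmed statistics, not dynamics. Recovering a 10 Å
intermediate here validates the estimator, not the biology.

## Numerical choices

- KDE grid step 0.02 Å; state half-width floor = bandwidth; ties in
  `min_dsb_frame` take the earliest frame; `rank_models` ties keep input
  order.
- `detect_states` warns below 100 frames and raises below 2.
- Superposition requires ≥ 3 non-degenerate points; RMSD is recomputed from
  the applied transform (not from the SVD singular values) so the reported
  value is exactly what the transform achieves.
- Relaxation accepts a step only if energy strictly decreases (30
  halvings of backtracking), stops on a gradient norm below 1e-4.
- PDB writing keeps 0.001 Å precision; reading keeps MODEL 1 only, altloc
  blank/'A', and rejects insertion codes loudly rather than renumbering.

## Known limitations

- The energy model is a scoring function, not a force field: no bonded
  terms, no polarization, no PME, no solvation free energy.
- The grower's one-residue greedy horizon cannot thread long arms into
  narrow pockets (documented above); it is a restraint-satisfaction builder,
  not a fold predictor.
- H-bond detection without hydrogens cannot distinguish donors from
  acceptors; with that information absent both roles are allowed.
- The β-turn rule is an operational Cα-distance definition, not a
  Ramachandran- or hydrogen-bond-based assignment.
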