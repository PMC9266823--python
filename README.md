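# sstbind

Analysis toolkit for peptide–GPCR binding modes, built around the system of
somatostatin-14 (SST, the cyclic neuropeptide `AGCKNFFWKTFTSC` with a C3–C14
disulfide) binding to somatostatin receptor subtype 4 (SSTR4), a class-A GPCR
with a buried acidic pocket residue (D126) and an extracellular loop "lid".

It is written for structural-bioinformatics users who want to quantify how a
peptide ligand enters a receptor pocket:

- **Energetics** — intermolecular interaction energy `E_inter` as Coulomb with
  a distance-dependent dielectric `ε(r)` plus Lennard-Jones 12-6, decomposed
  per residue on both the receptor and ligand sides, and used to rank
  candidate complexes (lowest `E_inter` = best).
- **Mechanism** — the salt-bridge distance
  `d_SB = |N(NZ, Lys9) − C(CG, Asp126)|` computed over a trajectory; binding
  modes (external ≈ 18.5 Å, intermediate ≈ 10 and 5–6 Å, internal ≈ 3 Å)
  detected as peaks of the d_SB kernel-density estimate, frames classified
  with hysteresis, association/dissociation events extracted.
- **Geometry** — interface residues at a 3.5 Å heavy-atom cutoff, hydrogen
  bonds, salt bridges, water bridges (waters H-bonded simultaneously to
  ligand and receptor), β-turns, disulfides, Kabsch superposition.
- **Construction** — growing a full peptide from a placed seed fragment by
  greedy torsion-grid search with disulfide and d_SB restraints, transplanting
  a ligand between receptors by Cα superposition, steepest-descent clash
  relaxation.
- **Subtype comparison** — Needleman–Wunsch global alignment (BLOSUM62,
  affine gaps 10/0.5, free end gaps) mapping per-residue energies of two
  receptor subtypes onto common alignment columns to find shared and
  subtype-specific key residues.
- **Synthetic data** — seeded generators for every fixture the pipeline
  needs: a toy pocket receptor, the cyclic SST-14 model, mechanism
  trajectories with programmed state means, the water-bridged intermediate,
  and known-answer energy systems.

The Coulomb energy is

```
E = k Σ_{i∈receptor, j∈ligand} q_i q_j / (ε(r_ij) · r_ij),   k = 332.0636 kcal·Å·mol⁻¹·e⁻²
```

with `ε(r) = D·r` (default `D = 4`), a constant model, or the
Mehler–Solmajer sigmoidal form; the LJ term uses
`ε_ij[(R_min,ij/r)¹² − 2(R_min,ij/r)⁶]` with Lorentz–Berthelot-style
combining. Charges come from a packaged Amber-99-style heavy-atom table in
which hydrogen charges are collapsed onto their bonded heavy atoms, so
per-residue sums equal formal charges and no structure needs protons.

## Worked example

```python
from sstbind import synthetic_data as sd
from sstbind.mechanism import dsb_timeseries, detect_states, classify_frames

traj, manifest = sd.make_scenario_trajectory()        # 2000 frames, 100 ns
series = dsb_timeseries(traj)
states = detect_states(series)
timeline = classify_frames(series, states)
for s in states.states:
    print(f"{s.label:18s} center {s.center:5.2f} A  occupancy {timeline.occupancies[s.label]:.3f}")
```

prints

```
internal           center  2.96 A  occupancy 0.300
intermediate_near  center  5.52 A  occupancy 0.200
intermediate_far   center 10.00 A  occupancy 0.250
external           center 18.50 A  occupancy 0.250
```

i.e. the four binding modes of the programmed association pathway are
recovered at their generated d_SB centers (3.0 / 5.5 / 10 / 18.5 Å) with the
programmed occupancies. The same pipeline is available from the shell:

```
sstbind simulate --generator scenario --seed 42 --out fixtures/
sstbind mechanism fixtures/scenario_trajectory.pdb fixtures/scenario_topology.pdb --out results/
```

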