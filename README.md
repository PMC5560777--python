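# pipgate

Quantitative analysis of PIP2-dependent gating in G protein–gated inwardly
rectifying potassium (GIRK/Kir3) channels, for people who work with MD
trajectories of channel–lipid systems and with the functional assays that
accompany them (whole-cell patch clamp with a voltage-sensitive phosphatase,
and proteoliposome K⁺ flux read out by ACMA fluorescence quench).

GIRK2 is a tetramer with four PIP2 binding pockets at the membrane–cytoplasm
interface. Conserved basic residues in the *tether helix* are numbered by
their position in that helix: K194 is the 0′ lysine (0′K), K199 the 5′
(5′K), K200 the 6′ (6′K, tyrosine in the 6′Y mutant), E203 the 9′ glutamate
(9′E). F192 (−2′F) from the four M2 helices forms the helix-bundle-crossing
(HBC) gate. The package measures, per trajectory frame:

* **Hydrogen bonds** between configured donor/acceptor pairs — tether-helix
  lysines, K64, K90 and R92 against the 1′/4′/5′ phosphate oxygens of PIP2,
  and the competing 6′K–9′E contact — using a geometric criterion
  (donor–acceptor ≤ 3.5 Å and D–H···A ≥ 150°; heavy-atom-only fallback at
  3.2 Å), with occupancy probabilities capped at a configurable maximum
  bond count (default 2).
* **The relative PIP2 association number**

  `S(t) = Σ_pockets [ N(0′K–5′PO4) + N(5′K–5′PO4) + N(6′–5′PO4) − N(6′–9′E) ]`

  a per-frame integer that is high while the 5′-phosphate is engaged in its
  canonical site and decays toward zero (or below) as the lipid disengages
  and the 6′K pairs with 9′E instead.
* **HBC gate diameter** — the mean of the two diagonal distances between
  the −2′F side-chain centres of mass, diagonals fixed at frame 0.
* **Pore hydration** — water-oxygen counts in 1 Å bins along the conduction
  axis (selectivity filter at z = 0, cytoplasm negative) inside an 8 Å
  cylinder, averaged in time windows, with dewetted bins flagged when a
  bin drops below 20% of the bulk reference.
* **Functional-assay metrics** — Ba²⁺-sensitive current, current density
  (pA/pF), percent change vs. the Ba²⁺ basal, single-exponential τ for
  Dr-Vsp depletion/recovery, fractional inhibition per Vsp activation time,
  and relative K⁺ flux / fractional activation from ACMA quench traces.

A seeded synthetic-data module generates toy tetramer trajectories (with
scripted bond schedules, gate diameter, and pore waters), whole-cell current
traces, and flux traces, each with exact ground truth for every metric — so
every analysis can be validated end to end without cluster-scale MD.

## Worked example

```python
import pipgate as pg
from pipgate.synthetic import TrajectoryScript, all_bonded_schedule, generate_channel_trajectory

script = TrajectoryScript(
    n_frames=100,
    bond_schedule=all_bonded_schedule(100),      # 0'K/5'K/6' bonded, all pockets
    gate_schedule=((0, 10.0), (99, 13.0)),       # gate opens 10 -> 13 Å
    seed=7,
)
model, traj, truth = generate_channel_trajectory(script)
roles = pg.ResidueRoleMap()                      # K194=0', K199=5', K200=6', E203=9'
pockets = pg.assign_pockets(traj, roles)
assoc = pg.association_score_series(traj, roles, pockets)
gate = pg.hbc_diameter(traj, roles)
print(assoc.score[:5], gate.diameter[0], gate.diameter[-1])
```

prints

```
[12 12 12 12 12] 10.000000000000002 13.000000000000002
```

i.e. three bonds in each of the four pockets with no 6′–9′E subtraction
(score 12), and the gate diameter following the scripted 10 → 13 Å opening
to within numerical precision.

The same analyses run from the shell:

```bash
pipgate simulate --out sim --n-frames 100 --seed 7
pipgate all --config run.yaml --out results_dir
pipgate rmsd structure_a.pdb structure_b.pdb
pipgate ephys --trace cell01.csv --events cell01.yaml
```

where `run.yaml` names either input files (`structure:`, `trajectory:`) or a
`simulate:` block, plus optional `roles:`, `criteria:`, `hydration:` and
`association:` overrides. Outputs are TSV tables (H-bond counts per pair and
pocket, occupancy summary, association score, gate diameter, hydration
long-form) plus a JSON manifest with the config hash and seed; identical
config and seed reproduce the tables byte for byte.

### Selection syntax

`select_atoms(model, query)` accepts the MDAnalysis selection language with
two conveniences: `chain A` is an alias for `chainID A`, and residue ranges
may be written `resid 88-92` as well as `resid 88:92`. Example:
`"chain A and resid 192 and name CA"`.

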