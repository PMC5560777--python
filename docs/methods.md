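# Methods

## The system and the quantities measured

GIRK2 (Kir3.2) is a four-fold symmetric K⁺ channel activated by the
membrane lipid PIP2. Each of the four lipid pockets is lined by residues
62–64 (N-terminal β-loop), 88–92 (slide helix) and 192–203 (HBC gate and
tether helix). The tether-helix basic residues are addressed by helix
position: 0′K (K194), 5′K (K199), 6′ (K200; tyrosine in the 6′Y mutant),
9′E (E203). The package quantifies how strongly the 5′-phosphate of PIP2 is
engaged by these residues over an MD trajectory, and whether that
engagement tracks opening of the helix-bundle-crossing gate formed by the
−2′F (F192) side chains, together with the functional readouts (Dr-Vsp
kinetics, Ba²⁺ normalizations, flux-assay activation) used to probe the
same interaction in cells and liposomes.

## Hydrogen-bond detection

A bond is declared between a donor heavy atom D (with covalent hydrogen H)
and an acceptor A when `d(D,A) ≤ 3.5 Å` and the D–H···A angle at H is
≥ 150°. Trajectories without explicit hydrogens use a heavy-atom-only rule,
`d(D,A) ≤ 3.2 Å`. These are widely used geometric defaults, configurable via
`HBondCriteria`; there is no energetic or electrostatic definition
(deliberately out of scope). "Bonds with the 5′-PO4" means the donor may
reach any acceptor oxygen of that phosphate group; a donor contacting two
oxygens through distinct hydrogens contributes two counts, and the cap
(below) applies only at the probability level. Backbone-amide donors are
included only for R92, whose side chain and amide both anchor the 1′-PO4.
Hydrogens are associated to donors by residue membership and a ≤ 1.25 Å
covalent distance at frame 0. Candidate pairs come from a k-d tree over the
acceptors; the test suite holds an independent all-pairs oracle to which
the detector must agree exactly.

Occupancy probability is `mean_t min(count, cap)/cap` with cap = 2 by
default, applied uniformly to all pairs (including 6′–9′E); cohort
summaries report mean ± SEM over (pocket × simulation) units.

## The relative PIP2 association number

Per frame, summed over the four pockets:
`N(0′K–5′PO4) + N(5′K–5′PO4) + N(6′–5′PO4) − N(6′–9′E)`.
The subtraction is the 6′-residue→9′E contact only; K64–9′E and other
contacts are reported separately, never subtracted. The per-frame score is
a raw (possibly negative) integer; presentation curves use a 10-ns running
mean with truncated windows at the edges, and the raw counts are always
persisted. The score is computed from the same per-pair time series the
H-bond module exports, so the two outputs cannot drift apart.

## Gate geometry and hydration

Gate diameter: the −2′F side-chain centre of mass (CB, CG, CD1, CD2, CE1,
CE2, CZ; atomic masses) is computed per subunit; the two diagonal pairings
are fixed at frame 0 as the two largest COM–COM distances and kept fixed so
the pairs cannot swap when the gate distorts; the diameter is the mean of
the two diagonals. It is a literal centre-of-mass cross distance — no van
der Waals radius is subtracted.

Pore axis: the origin is the mass-weighted centre of the selectivity-filter
backbone atoms (N, CA, C, O over all four chains); the unit axis points
from the origin toward the −2′F gate centre, and axial coordinates are
`z = −(r − origin)·axis`, so the filter sits at 0 Å and the pore interior
is negative, reaching roughly −25 Å at the bottom of M2. Water oxygens
(residue names TIP3/HOH/SOL/WAT, configurable) inside a cylinder of radius
8 Å are binned in 1 Å slabs over [−25, 0] Å and averaged within 10-ns
windows. Radius, bin width and window length are package defaults, chosen
as round values on the relevant length/time scales; only the axial extent
is dictated by the channel geometry.

Dewetting: a bin is flagged in a window when its mean count falls below
`0.2 ×` the bulk reference, defined as the median of the nonzero bins of
the first window. The 0.2 threshold is a package invention for marking
qualitatively dry segments (the phenomenon is usually indicated by eye on
density maps); an all-zero first window is an error because no bulk
reference exists, and a threshold of 0 flags nothing.

## Superposition and pocket RMSD

Rigid superposition is the Kabsch closed form (SVD of the covariance with a
determinant correction, so the rotation is always proper). Collinear or
< 3-point sets are rejected. The pocket Cα RMSD superposes on the pocket
selection itself (residues 62–64, 88–92, 192–203, Cα only, matched chains)
and reports the RMSD of that same selection. Whether the published figure
for the closed-vs-preopen comparison used one subunit or four, and what
superposition scope, is not stated anywhere we could find; pocket-selection
superposition over all matched chains is this package's documented choice,
and an explicit `chains=` argument restricts entries that also contain
non-channel chains.

## Assay metrics

Sign conventions: inward currents are negative. "Steady state" is the mean
of the last 20% of an epoch (configurable); epochs are delimited by the
annotated protocol events, with the basal epoch running from the trace
start to the first event and each drug/Ba/pulse epoch from its event to the
next.

* Ba²⁺-sensitive current: steady basal − steady current in Ba²⁺.
* Current density: current / capacitance (pA/pF), sign preserved.
* Percent change vs basal: `100·(drug − basal)/(basal − Ba)`; a drug that
  removes exactly the Ba²⁺-sensitive component gives −100%.
* Single-exponential fits use bounded least squares on
  `I(t) = I∞ + (I0 − I∞)·e^{−(t−t0)/τ}`, initialised with I∞ from the last
  10% of samples, I0 from the first sample, and τ from the 63%-of-span
  crossing; τ is bounded in [10⁻⁶, 10³] × segment length and a fit landing
  on a bound is flagged rather than silently returned.
* Fractional inhibition: `(pre − post)/(pre − Ba)` around a Vsp pulse,
  reported clipped to [−0.1, 1.1] with an out-of-range flag. Each cell is
  normalised to its own Ba²⁺-sensitive current, not a group mean.
* Relative flux: with fluorescence normalised to the pre-CCCP basal, the
  quench 900 s after lipid addition divided by the valinomycin-defined
  maximal quench. Point values use a 5-point running median, which makes
  the metric robust to single-sample noise near the addition artifacts.
  Because the basal normalisation cancels between numerator and
  denominator, the metric is exactly invariant under affine rescaling of
  the raw signal, as are fractional inhibition and fractional activation.
* Fractional activation: `(flux_X − flux_vehicle)/(flux_PIP2 −
  flux_vehicle)` — lipid-evoked flux after leak subtraction, normalised to
  the PI(4,5)P2 response.

The residual current that survives maximal Vsp depletion (~30% in the
underlying recordings) is reported by the metrics, not modelled.

## What the synthetic generators emulate — and what they do not

`generate_channel_trajectory` builds a C4-symmetric toy tetramer: filter
backbone at z = 0, −2′F rings whose centres of mass sit exactly on scripted
diagonals at z = −20 Å, pocket pseudo-residues for every role with explicit
donor hydrogens, four PIP pseudo-lipids with P1/P4/P5 phosphate groups, and
scripted pore waters. Bonded intervals place donor–acceptor pairs at 2.8 Å
with a collinear hydrogen; broken intervals at 6.0 Å; the 9′E acceptor
follows the 6′ donor so both the 6′–phosphate and 6′–9′E schedules can be
driven independently (a tyrosine 6′ has a single hydrogen aimed at the
phosphate, so its 6′–9′E count is structurally zero, matching the mutant's
behaviour). Waters are placed by rejection sampling inside the analysis
cylinder, either uniformly (optionally excluding scripted dry bands, with
the displaced waters redistributed) or with exact per-bin counts. All
randomness derives from the script seed, and identical scripts yield
byte-identical trajectory files.

This is *not* a physical simulation: no forces, no thermodynamics, no
membrane, no realistic stereochemistry. Passing tests demonstrate that the
analysis chain recovers known geometric/kinetic ground truth exactly or
within stated statistical bounds; they say nothing about force fields,
sampling, or the biology of real trajectories, which must be supplied by
the user as XTC/DCD/multi-model-PDB files.

The ephys generator produces piecewise steady epochs with exponential
Vsp transitions (defaults: Ba²⁺-sensitive current −500 pA, leak −20 pA,
τ_depletion 24.9 s, τ_recovery 35.8 s, fractional inhibition saturating at
0.70 for ≥300 ms activations, 10 Hz sampling, Gaussian noise). The flux
generator produces a basal plateau, a small CCCP inflection, a
lipid-dependent exponential quench whose amplitude is solved in closed form
so that the noiseless trace has exactly the configured true relative flux
under the 900-s normalisation, and a fast valinomycin collapse. Instant
solution-exchange steps stand in for wash-in/wash-out kinetics.

## Numerical and design choices

* Residue numbering follows the author (mouse GIRK2) numbering found in
  the files; the role map is config-overridable because deposited entries
  may renumber.
* Pocket assignment is locked at frame 0 (nearest 0′K NZ to each lipid
  centre) and never re-assigned on lipid diffusion; four fixed pockets are
  assumed throughout. Ambiguous nearest-pocket ties and lipid counts ≠ 4
  are errors, not warnings.
* Arrays are 0-based; residue numbers are 1-based author numbers;
  selection ranges are inclusive, matching PDB convention.
* Trajectory times are ns; formats without time metadata (multi-model PDB)
  get the frame index as time.
* GRO files carry no chain identifiers and store nm with 3 decimals
  (0.01 Å granularity). On re-read, repeated residue numbers are assigned
  chain letters by occurrence order, which restores the toy tetramer's
  A–D chains; cross-format coordinate agreement is asserted at the
  combined format precision, not tighter.
* Probability capping ("of two maximal bonds") is applied uniformly to all
  pairs including 6′–9′E, and is configurable, since different analyses
  may cap differently.
* The acceptance script uses 400-frame (1 ns/frame) trajectory scripts,
  50-replicate fit cohorts and 4-replicate flux cohorts — sizes chosen so
  every statistical bound in the test suite is comfortably resolved while
  the whole script stays in the seconds range on one CPU.

## Known limitations

* No periodic-boundary imaging beyond what the input coordinates provide;
  trajectories should be pre-imaged so each lipid stays near its pocket.
* No full pore-radius profiling (HOLE-style) and no wetting free energies;
  the hydration profile is a fixed-cylinder count.
* Exponential fitting assumes a single dominant relaxation; biphasic
  recoveries will be summarised by an effective τ with an elevated
  residual RMS.
* The flux metrics assume the standard event order (CCCP, then lipid or
  vehicle, then valinomycin) and at least 900 s of recording after lipid
  addition.
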