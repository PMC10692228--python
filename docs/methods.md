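# Methods

## The design problem

A thioether methacrylate ester installed on a cysteine of a peptide or
protein binder is a mild Michael acceptor. When the binder sits in its
non-covalent complex with the receptor, a suitably placed surface lysine
can add across the activated alkene (aza-Michael addition at NZ), fixing
the whole binder on the receptor; a surface cysteine can instead perform
thiol substitution, which displaces the binder as a free thiol and leaves
only the +112 Da methacrylate fragment behind. `covbinder` models the
*reacted* state: which ligand position, carrying which stereoisomer of the
reacted side chain, can form the covalent bond in correct geometry while
keeping the native binding mode.

## Candidate enumeration

Installable positions are the ligand residues with Cα–Cα distance
**strictly less than 14 Å** from the target nucleophile residue. The
companion template filter keeps candidate complexes whose ligand approaches
the intended nucleophile (< 14 Å for at least one ligand Cα) but stays away
from a competing reactive residue (no ligand Cα at ≤ 12 Å) — useful when a
second, more reactive cysteine would otherwise capture the electrophile.
Both cutoffs follow the strict-inequality convention throughout.

## Residue chemistry

Conjugate addition creates a stereocenter at the methacrylate α-carbon, so
the reacted methacrylate-cysteine exists as two diastereomeric side chains.
They are represented as two residue topologies, `MCR` and `MCS`, with an
identical atom inventory — CB, SG (thioether), CD (S-methylene), CE (the
stereocenter), CZ (methylene bonded to the nucleophile), the ester branch
(CX, OX1, OX2, ethyl CY1–CY2) — differing only in the sign of the branch
torsion CZ–CD–CE–CX (±120°). R/S labels follow CIP priorities evaluated on
the idealized geometry and are fixed by convention. The reacted nucleophile
is produced through a *residue patch*: `LYX` is lysine with one NZ proton
deleted, a connection declared at NZ, a virtual atom `VCM` marking the
ideal position of the incoming warhead methylene carbon, and a proton chi
sampling rotation about CE–NZ; `CYX` is the analogous cysteine variant at
SG. Virtual atoms never score and are never written to PDB output unless
explicitly requested; they exist purely as restraint anchors.

Because the quantum-chemically optimized geometry of the reacted side chain
is not published, the topologies use fixed idealized internal coordinates:
sp³ C–C 1.53 Å, C–S 1.81 Å, C–N 1.47 Å; sp² C=C 1.33 Å, C=O 1.21 Å, ester
C–O 1.34 Å; sp³ angles 109.5°, sp² angles 120°. All geometric claims in the
tests are made against these constants, not against any unpublished
structure. Topologies serialize to a line-oriented text format (`ATOM` /
`BOND` / `ICOOR` / `CHI` / `CONNECT` / `VIRTUAL_PARTNER` records) so new
electrophile chemotypes can be added without code changes.

Rotamer grids replace a full backbone-dependent rotamer library: heavy chi
angles are sampled on a 30° grid and refined by minimisation; proton-type
chis (rotations about the new covalent bond) at 10° resolution.

## Covalent restraints and scores

Each design carries exactly two harmonic distance restraints tying a real
atom to the virtual placeholder marking its ideal position in the partner
residue: warhead CZ ↔ nucleophile `VCM`, and nucleophile NZ (or SG) ↔
warhead `VNZ`. Each restraint contributes `((d − x₀)/σ)²` with x₀ = 0 and
σ = 0.3 Å; the **constraint score** is their sum, zero exactly at ideal
covalent geometry, and the selection filter is strict: a model with both
pairs at 0.3 Å deviation scores exactly 2.0 and fails.

The **interface score** is an explicit 12-6 proxy, not a physics-grade
force field: over all receptor–ligand heavy-atom pairs within 6 Å,
`ε((r_min/d)¹² − 2(r_min/d)⁶)` with ε = 0.1 per pair, r_min the sum of
per-element radii (C 1.7, N 1.55, O 1.52, S 1.8, P 1.8 Å), and the
repulsive branch capped at +10 per pair. Pairs connected through the
engineered covalent bond by three bonds or fewer are excluded, as in any
bonded force field — without this exclusion every correct covalent model
would pay the repulsion cap for its own bond. Lower is better; absolute
values are meaningful only for ranking models of the same complex, which is
why no comparison to published absolute interface energies is made
anywhere. The clash score reported per model is the repulsive part of the
same sum.

**Interface backbone RMSD** is computed over N, CA, C, O of the ligand
residues having any heavy atom within 8 Å of the receptor in the template,
after least-squares superposition on the receptor backbone; the near-native
filter is strict (< 1 Å).

## Sampling

For each candidate position and each stereoisomer the engine draws
`n_models` (default 100) random chi vectors from the rotamer grids and
minimises each by coordinate descent in two phases: first large sweeps
minimising the constraint score alone (snapping the covalent tether shut),
then smaller joint sweeps on the weighted total (constraint + interface,
weights 1:1) that refine packing without abandoning the tether. The
backbone is held fixed: the reference pipeline's refinement uses relatively
small moves around the native pose, and a rigid-backbone analog preserves
its selection logic at desk scale. Per-model random streams derive from
`seed + model_index`, so any subset of models is reproducible and two runs
with the same seed are bitwise identical. A model whose minimised
constraint score stays above 100 (each covalent pair > ~2 Å from its
anchor) is flagged unsatisfiable rather than raised.

Ranking is by interface score ascending with deterministic tie-breaks
(constraint score, then stereo tag, then model index); reports keep the top
10 with explicit pass/fail flags for both filters. Position ranking in the
end-to-end run puts positions with at least one passing model first,
ordered by their best passing interface score.

## The synthetic toy complex

`make_toy_complex` builds an ideal-geometry poly-alanine receptor helix
with the nucleophile (Lys or Cys) at a chosen position and grows the ligand
strand *outward from the reacted adduct geometry itself*, so the planted
position admits a chi vector with constraint score exactly zero by
construction (verified to ~1e-9 in the tests). The generator rejection-samples
(deterministically per seed) until the fixture has a *discriminating*
geometry:

* the planted tether path runs parallel to the receptor surface with its
  mid-chain atoms at van-der-Waals contact height (3.4–4.8 Å), so the
  correct design earns attractive interface contacts;
* every other ligand position's CB lies beyond the "stretch distance"
  (11.9 Å for lysine targets, 9.0 Å for cysteine; the joint maximum span of
  warhead plus nucleophile side chain is ≈ 12.1 / 9.2 Å on the idealized
  topologies), so tether-satisfying models at competing positions are
  pinned in near-fully-extended conformations away from those contacts;
* receptor and ligand backbones do not interpenetrate, and at least one
  competing position remains inside the enumeration cutoff so design
  recovery is a real comparison.

What the fixture does *not* emulate: real binding-site topography, solvent,
backbone flexibility, side-chain packing of a native interface, or any
sequence signal. Passing the design-recovery test therefore shows that the
engine's enumeration, restraint machinery, sampling and selection logic are
correct and deterministic — not that the proxy score predicts affinity or
labeling efficiency on real complexes.

## Mass arithmetic

Residue and atomic masses are standard IUPAC values embedded as constants;
monoisotopic and average tables are both provided because intact-protein MS
uses average masses while digest MS uses monoisotopic. The modification
grammar covers N-terminal acetyl (+C2H2O), C-terminal amide (−O +NH),
phosphoserine/-threonine (+HPO3), methacrylate-cysteine (+C6H8O2, average
112.13 Da, printed as +112), and the chloroacetamido-diaminobutyric residue
`X` (whole-residue formula C6H9ClN2O2; its reaction is substitution of
chloride, so its expected adduct is the peptide mass minus HCl, with no
methacrylate-only or released-thiol species). For methacrylate peptides the
three expected species are algebraically closed: full addition =
methacrylate-only + released thiol peptide, exactly, for every
grammar-valid peptide.

Labeling percentages are defined as deconvoluted peak-intensity shares —
the standard intact-MS convention. Labeling time courses are fit to
`f(t) = plateau · (1 − exp(−k_obs · t))` by least squares
(`scipy.optimize.curve_fit`), with the half-labeling time ln 2 / k_obs; a
flat series is flagged degenerate instead of fit.

In-silico digestion implements trypsin/P (cleavage after every K/R,
including before proline) with 0–2 missed cleavages by default and optional
length bounds. Site localization follows the depletion logic: for each
candidate site, the tracked peptides are those containing the site plus —
when the site is K/R, since labeling blocks its cleavage — those starting
immediately after it; the per-site depletion is the median treated/control
ratio over its peptides, and a site is called when its median falls below
0.5 while every other site's median stays above 0.75, otherwise the call is
"ambiguous". The 0.5/0.75 thresholds and median aggregation are this
package's quantitative rendering of qualitative depletion judgments; they
are documented defaults, not fitted values.

## Numerical conventions

Coordinates are Å in a right-handed frame; angles in degrees; dihedral sign
follows IUPAC (range (−180, 180]). Internal-coordinate placement and
re-measurement round-trip to 1e-6; RMSD comparisons are asserted at 1e-3 Å.
Altloc resolution keeps the highest-occupancy copy with ties broken toward
altloc 'A'; only the first MODEL of multi-model files is read; waters and
non-polymer heteroatoms are dropped; author residue numbering is preserved
exactly so published residue labels stay meaningful. PDB serialization is
round-trip safe at the format's 3-decimal precision and refuses coordinates
that overflow the fixed-width field.

## Problem sizes

The default validation scale is a 30-residue receptor, an 8-residue
ligand, and 100 models per stereoisomer per enumerated position (the
published sampling depth), which completes in well under a minute on one
core; property suites use 100–200 randomized instances per invariant.

## Known limitations

* The interface proxy has no electrostatics, solvation or hydrogen-bond
  terms; it reproduces the selection *logic* (constraint and RMSD filters,
  interface-score ranking), not published energies.
* Backbone is rigid during sampling; designs that require backbone
  accommodation will be scored pessimistically.
* The idealized internal coordinates are stated constants, not the
  unpublished quantum-chemical geometry of the reacted side chain;
  agreement at sub-Ångström level with that geometry is not claimed.
* Average-mass tables differ at the 0.01–0.05 Da level between IUPAC
  revisions; intact-mass comparisons should use tolerances above that.
* Experimental observables — labeling percentages, reaction rates, melting
  temperatures, crystallographic poses — are inputs to this toolkit, never
  predictions.
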