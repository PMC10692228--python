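# covbinder

Tools for turning native peptides and proteins into **lysine- or
cysteine-targeted covalent binders** carrying a thioether methacrylate
electrophile, and for the mass-spectrometric arithmetic used to verify the
resulting covalent adducts and localize the labeled site.

The package is aimed at structural chemical biologists who have a
receptor–ligand complex (e.g. a 14-3-3/phosphopeptide or toxin/anti-toxin
structure in PDB format) and want to know **where on the ligand to install
the electrophile** so that it reacts with a chosen surface lysine (via
aza-Michael addition at NZ) or cysteine (via thiol chemistry at SG), and
then to **confirm the covalent bond** from intact-protein and digest MS
data.

## What it computes

**Design side** (`structure`, `geometry`, `chemistry`, `design`, `app`):

* *Candidate enumeration* — ligand residues with Cα–Cα distance strictly
  below 14 Å of the target nucleophile.
* *Reacted-residue chemistry* — the methacrylate-cysteine side chain after
  conjugate addition creates a new stereocenter; both stereoisomers are
  modelled as residue topologies (`MCR`/`MCS`) with idealized internal
  coordinates, and the reacted lysine/cysteine as patched variants
  (`LYX`/`CYX`). Each covalent residue carries a *virtual atom* marking the
  ideal position of its partner atom.
* *Covalent sampling under harmonic restraints* — for every candidate
  position and both stereoisomers, side-chain χ angles of the warhead and
  of the nucleophile are sampled from rotamer grids and minimised under two
  harmonic distance restraints (real atom ↔ virtual placeholder, centred at
  0, σ = 0.3 Å). The **constraint score** is
  `Σ ((d − x₀)/σ)²`; a perfectly formed covalent bond scores 0.
* *Selection* — models are ranked by a documented 12-6 interface proxy
  score and filtered with the strict criteria **constraint score < 2** and
  **interface backbone RMSD < 1 Å** (N, CA, C, O of interface ligand
  residues after receptor superposition). The default sampling depth is
  200 models per position (100 per stereoisomer).

**MS side** (`mstools`):

* Peptide masses under the modification grammar `Ac-`, `-NH2`, `(pS)`,
  `(pT)`, `(mC)` (methacrylate-cysteine, +C6H8O2) and `X`
  (γ-chloroacetamido-diaminobutyric acid).
* Expected intact-MS adduct tables: full peptide addition, the
  methacrylate-only species (+112 Da) left by thiol substitution, and the
  complementary released thiol peptide — algebraically closed.
* Labeling quantification from deconvoluted species intensities,
  first-order labeling kinetics fits `f(t) = plateau·(1 − e^{−k t})`,
  trypsin/P in-silico digestion with missed cleavages, and depletion-based
  site localization (treated/control signal ratios of peptides containing
  or immediately following each candidate site).

A synthetic toy-complex generator (`fixtures`) builds receptor–peptide
complexes with a *planted* ideal covalent adduct and known ground truth, so
the entire engine is exercised end to end without any structure downloads.

## Worked example

```python
from covbinder.fixtures import ToyComplexSpec, make_toy_complex
from covbinder.app import RunConfig, run_design
from covbinder.mstools import expected_adducts

cx, truth = make_toy_complex(ToyComplexSpec(seed=0))
cfg = RunConfig(target_chain="A", target_residue=15, n_models=20,
                seed=7, output_dir="out")
result = run_design(cfg, complex_=cx)
print("candidates:", result.positions)
print("best position:", result.best_positions[0],
      "(planted:", truth.planted_position, ")")
print("passing models in top 10:",
      result.reports[result.best_positions[0]].n_passing)

table = expected_adducts("Ac-RSA-(pT)-(mC)-PSL-NH2", 27000.0, "average")
print({k: round(v, 1) for k, v in table.deltas.items()})
```

prints

```
candidates: [3, 4, 5, 6]
best position: 4 (planted: 4 )
passing models in top 10: 4
{'full_peptide_addition': 1067.1, 'warhead_only': 112.1,
 'released_thiol_peptide': 955.0}
```

The run enumerated four installable positions around the target lysine,
identified the planted position 4 as the top-ranked design with
constraint-satisfying (< 2), near-native (backbone RMSD < 1 Å) models, and
the adduct table shows the +112 Da methacrylate-only species expected when
the peptide is displaced by thiol substitution.

On a real complex, supply the deposited PDB file and chain selection
yourself:

```bash
covbinder enumerate complex.pdb --receptor-chains A --ligand-chain P \
    --target A:122
covbinder design --pdb complex.pdb --receptor-chains A --ligand-chain P \
    --target A:122 --seed 1 --out designs/
```

Other CLI verbs: `filter-structures`, `mass`, `digest`, `depletion`,
`fit-kinetics`, `make-fixture` (see `covbinder --help`).

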