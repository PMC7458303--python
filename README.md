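# pitha

Structure-based prediction of clinical immunogenicity for humanized and
full-human therapeutic antibodies.

## The problem

Therapeutic antibodies can elicit anti-drug antibodies (ADA) in patients,
degrading pharmacokinetics and efficacy. For humanized and full-human
antibodies the classical sequence "humanness" score does not separate
immunogenic from non-immunogenic molecules — the anti-drug response is
dominated by anti-idiotypic antibodies that bind the
complementarity-determining regions (CDRs) of the drug's variable fragment
(Fv). Three CDR features do discriminate:

* **CDR cavity volume** *V*<sub>cav</sub> (Å³) — the total volume of surface
  pockets whose lining atoms are at least 2/3 CDR-residue atoms.
  Non-immunogenic antibodies carry a markedly larger central cavity
  (mean 798 vs 361 Å³ across 29 crystal structures), which hinders
  anti-idiotypic binding.
* **CDR-H3 hydrophobic surface** *A*<sub>H3</sub> (Å²) — the summed
  solvent-accessible surface area (probe 1.4 Å) of the loop's hydrophobic
  atoms (C, S, and N except the non-protonated histidine side-chain
  nitrogen). Immunogenic antibodies have less hydrophobic CDR-H3 loops.
* **Glycine at the CDR-H2 β-turn** (heavy-chain Kabat 52–56) — a binary
  presence flag; of the 7 antibodies (out of 52) with no Gly at the turn,
  6 are immunogenic.

An RBF-kernel support-vector machine combines the features. Two variants
match the two deployment scenarios: `(V_cav, A_H3)` when a crystal structure
exists, and `(A_H3, Gly presence)` for homology-modeled structures, where
detected cavity volumes are unreliable. Features are min-max scaled to
[-1, 1]; (C, γ) are grid-searched (powers of two, exponent step 2)
maximizing leave-one-out accuracy, deterministically.

A companion sequence metric, the profile humanness score
S<sub>human</sub>(i) = min(M<sub>ir</sub> − B<sub>rr</sub>, 0) (PSSM
self-substitution score minus the BLOSUM62 diagonal; a residue is *rare*
when S<sub>human</sub> < −6), is implemented for CDR/framework sums and
rare-residue counts.

## Worked example

The package bundles the reference feature tables for 52 FDA-approved
antibodies: 29 with crystal structures (15 immunogenic / 14 not) and 23 with
modeled structures (13 / 10). Reproduce the headline experiments:

```sh
$ pitha reproduce loo-crystal-2feat
LOO accuracy, crystal table, (cavity, H3 area): 82.8%  (reference: 83%)

$ pitha reproduce test-modeled
Test accuracy on the modeled table: 65.2%  (reference: 65%)

$ pitha reproduce summary-stats
crystal cavity volume, immunogenic: mean 361 Å³ (reference: 361 Å³, n=15)
crystal cavity volume, non-immunogenic: mean 798 Å³ (reference: 798 Å³, n=14)
modeled H3 hydrophobic area, immunogenic: mean 356 Å² (reference: 356 Å², n=13)
modeled H3 hydrophobic area, non-immunogenic: mean 432 Å² (reference: 432 Å², n=10)

$ pitha reproduce gly-census
antibodies with no Gly at the CDR-H2 turn: 7 (reference: 7), of which immunogenic: 6 (reference: 6)
```

82.8% is 24 of 29 antibodies correctly classified under leave-one-out;
65.2% is 15 of 23 modeled-structure antibodies correctly predicted by the
model trained on the crystal table.

Feature extraction from a structure (PDB plus an ANARCI-style Kabat
numbering CSV with columns `chain,seq_index,kabat_number,insertion,residue`):

```sh
pitha features --pdb fv.pdb --numbering fv_kabat.csv \
    --heavy-chain H --light-chain L --out features.json
pitha predict --features features.csv --out predictions.json
```

`features` reports the cavity volume (from the builtin grid detector, or an
fpocket-style report via `--pocket-report`), the CDR-H3 hydrophobic area,
the Gly count/presence at the CDR-H2 turn, and provenance (detector path,
whether hydrogens were present). `predict` emits 1 (immunogenic) /
0 (non-immunogenic) per antibody, by default from the packaged
modeled-variant model trained on the crystal table.

From Python:

```python
from pitha import load_table, loo_accuracy, train_svm, predict

crystal = load_table("crystal")
print(loo_accuracy(crystal, "crystal"))   # 82.75862068965517
model = train_svm(crystal, "modeled")
results = predict(model, load_table("modeled").feature_vectors)
```

## Layout

* `pitha.antibody_model` — PDB/numbering parsing, Kabat CDR definitions
  (expanded heavy-chain H1 26–35, H2 49–65; H3 95–102; classical light),
  CDR-H2 β-turn glycine census, CDR-H3 length.
* `pitha.sasa` — Shrake–Rupley SASA with the radii set above, hydrophobic
  atom classification, per-region hydrophobic areas.
* `pitha.cavity` — builtin grid/flood-fill pocket detector, fpocket-style
  report parser, the 2/3 CDR rule, total CDR cavity volume.
* `pitha.humanness` — PSI-BLAST ASCII PSSM parsing, per-residue humanness,
  CDR/framework sums and rare counts.
* `pitha.classifier` — feature vectors, deterministic SMO-based RBF SVM,
  grid search, leave-one-out evaluation, prediction.
* `pitha.datasets` — the bundled reference tables with integrity checks and
  group statistics.
* `pitha.synthetic` — synthetic structures with known ground truth and the
  Monte-Carlo oracles used to validate the geometry code.

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
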