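# Methods

## Scope and model

`pitha` predicts the clinical immunogenicity (anti-drug antibody incidence ≥
2% of patients) of humanized and full-human therapeutic antibodies from
three features of the Fv region, combined by an RBF-kernel C-SVC:

1. total cavity volume at the CDR region (Å³),
2. hydrophobic solvent-accessible surface area of the CDR-H3 loop (Å²),
3. presence/absence of glycine at the CDR-H2 β-turn (binary).

The package consumes structures (PDB) and externally computed Kabat
numbering; it never assigns numbering itself, builds homology models, or
scrapes clinical labels. The bundled reference tables carry the feature
values and labels for the 52-antibody reference set (29 crystal, 23
modeled), so all classification experiments are reproducible without any
structural input.

## Region definitions

Heavy-chain CDRs use an expanded Kabat definition: H1 26–35 (the classical
definition starts at 31), H2 49–65 (classically 50), H3 95–102. Light-chain
loops are classical Kabat: L1 24–34, L2 50–56, L3 89–97. Insertion-coded
positions (35A, 52A, 100B, …) belong to the range of their base number.
The CDR-H2 β-turn is heavy 52–56, insertions included. Everything else is
framework. These ranges are frozen in `antibody_model._HEAVY_RANGES` /
`_LIGHT_RANGES`; whether H1 should stop at 35 or 35B is ambiguous in the
Kabat convention — insertions at 35 are included here.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic Fibonacci (golden-spiral) lattice,
default 960 points per atom; the exposed fraction of each probe-inflated
sphere (probe 1.4 Å) times 4π(r+1.4)² gives the atom's area. Radii: C 1.8,
N 1.65, O 1.4, S 1.85, polar H 1.0 Å. Non-polar hydrogens (bonded to C) are
excluded; hydrogens are assigned to the nearest heavy atom within 1.3 Å.
Hydrophobic atoms are C, S, and N, except a histidine side-chain nitrogen
with no attached hydrogen.

Hydrogen placement is out of scope. Crystal structures usually lack
hydrogens; the computation then runs heavy-atom-only, the result is flagged
`no_hydrogens`, and histidine is assumed NE2-protonated for the
hydrophobicity rule. This is a documented deviation from a pipeline that
adds hydrogens before the SASA step: heavy-atom-only areas are systematically
slightly different, which is acceptable for the classifier because the
bundled feature tables, not recomputed areas, feed the reference
experiments.

Region areas are computed over the whole Fv (the environment occludes the
loop), then summed over the region's residues. Numbering rows attach to
structure residues by their 1-based position within the chain.

Numerical behavior, measured on seeded 30-atom clusters against a
Monte-Carlo sphere-sampling oracle (10⁵ samples/atom): the isolated-sphere
closed form is exact to the lattice (≪0.5% at 960 points); per-atom areas
agree with the oracle within 2% plus the resolution of the two estimators
(3 oracle standard errors + one lattice cell) at 15 360 points; total areas
at 960 vs 3840 points differ by <0.5%. Areas are exactly
translation-invariant; under rotation they vary at the lattice-discretization
level (≲1–2% for the hydrophobic fraction), because the lattice orientation
is fixed — the standard behavior of point-lattice SASA codes.

## Cavity detection and the CDR rule

A pocket is attributed to the CDR region when its lining atoms are at least
two-thirds CDR-residue atoms — the threshold is inclusive and evaluated in
integer arithmetic (`3·n_CDR ≥ 2·n_total`), isolated in one predicate. The
volumes of all CDR pockets are summed; no pockets means volume 0.

Two detector paths share that rule:

* **External report.** `parse_pocket_report` reads an fpocket-style text
  (per-pocket `Volume :` line plus the pocket's atoms as PDB records).
  "Lining atoms" are whatever the external detector reported.
* **Builtin grid detector.** A 1.0 Å grid over the padded bounding box;
  cells inside any probe-inflated atom are solvent-excluded; the remaining
  open space is eroded by 2 cells (box boundary counts as open), components
  touching the boundary are bulk solvent, and bulk is geodesically re-dilated
  2 cells inside the open space. Open cells not reached are pocket cells;
  connected components of ≥30 cells are pockets, volume = cell count × 1 Å³,
  lining atoms = atoms within 4.5 Å of a pocket cell. All five constants are
  function parameters.

The builtin detector is an approximation built for self-contained operation,
not a replication of an alpha-sphere detector; its volumes agree with a
Monte-Carlo interior-volume oracle within 15% on a hollow-shell fixture
(inner radius 6 Å, narrow mouth) and it returns no pockets for convex
clusters. Exact reproduction of per-antibody cavity volumes from deposited
structures is not attempted — detector version and parameters dominate such
values, which is why the reference tables are bundled.

## Humanness score

S_human(i) = min(M_ir − B_rr, 0), with M_ir the PSSM self-substitution score
at position i and B_rr the BLOSUM62 diagonal of the query residue. A residue
is rare when S_human < −6, strictly (−6 itself is not rare); the threshold
lives in one predicate. Scores are summed over CDR and framework separately;
the two sums partition the whole-sequence sum. The module consumes a
PSI-BLAST ASCII PSSM supplied by the caller; because the scores depend on
the profile database used to build the PSSM, no absolute reference values
are asserted — only the formula, threshold, and bookkeeping are testable,
and are.

## Classifier protocol

* Feature variants: `crystal` = (cavity volume, H3 area); `modeled` =
  (H3 area, Gly presence); `crystal3` adds the Gly flag to `crystal`.
  Glycine enters as binary presence (tables keep the counts 0–4 for the
  descriptive statistics).
* Scaling: min-max to [-1, 1] with training-set extremes, frozen at
  training (the svm-scale default; a constant column maps to −1).
* Solver: C-SVC dual solved by SMO with second-order working-set selection,
  stopping tolerance 1e-3, libsvm's rho rule — re-implemented (numba JIT) so
  that the ~10⁵ fits of the grid protocol run in seconds. The test suite
  cross-checks predictions and decision values against an independent SVM
  implementation (scikit-learn's libsvm binding) over random problems and
  grid corners.
* Hyperparameters: exhaustive grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
  γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (the recommended coarse grid of libsvm's
  grid-search tool), selected **once per training set** by maximizing
  leave-one-out accuracy; ties break toward smaller C, then smaller γ. The
  protocol has no random state: results are permutation-invariant and
  identical across runs.
* Reported leave-one-out accuracy is the accuracy at the selected grid
  point (each held-out antibody predicted by an SVM retrained on the rest at
  fixed (C, γ)). Because the selection criterion and the reported metric
  coincide, the number carries the optimistic bias of grid-maximized
  cross-validation — the standard small-sample usage this package
  reproduces. An alternative nested protocol (re-selecting (C, γ) inside
  every fold with deterministic tie-breaks) was evaluated and rejected: on
  29-sample datasets its tie plateaus select degenerate near-constant
  models, collapsing accuracy toward the majority rate.

On the bundled tables the protocol yields: crystal table LOO 24/29 (two
features), 22/29 (three features), 23/29 (H3 + Gly); crystal-trained model
on the modeled table 15/23; modeled table LOO 19/23. The last is one
antibody above the reference value (18/23); reproducing it exactly would
require the fold shuffle of an unseeded 5-fold cross-validation, which is
not recoverable.

## Synthetic data and what it shows

`pitha.synthetic` generates the fixtures every geometric claim is tested on:
isolated atoms (closed-form SASA), seeded uniform-ball clusters, a hollow
shell with a narrow mouth (analytic interior volume), a 3-residue loop
sealed inside a tight shell (zero accessible area), and two-feature Gaussian
cluster datasets with controllable separation (10σ separation → 100%
leave-one-out; 0σ → near-chance). The oracles are implementationally
independent of the production code: random sphere/volume sampling vs a
deterministic lattice and a grid flood fill. All generators take explicit
seeds and are byte-reproducible.

These fixtures validate the geometry and the classifier machinery; they do
not emulate real antibody structures (no backbone geometry, no side chains,
no chain pairing), so passing tests demonstrate correctness of the
computations, not transferability of the features to arbitrary proteins.

## Degenerate inputs and tie-breaks

* Alternate locations: blank or 'A' kept; occupancy otherwise ignored.
* Waters and HETATM records are always dropped; unsupported elements
  (metals) raise rather than guessing a radius.
* A hydrogen with no heavy atom within 1.3 Å raises.
* Exactly 2/3 CDR lining atoms counts as a CDR pocket; exactly −6 humanness
  is not rare; decision value exactly 0 predicts non-immunogenic.
* Single-class or <6-antibody training sets are rejected.

## Known limitations

* The builtin pocket detector's volumes are grid- and parameter-dependent;
  only order-of-magnitude agreement with alpha-sphere detectors should be
  expected.
* Heavy-atom-only SASA shifts hydrophobic areas relative to
  hydrogen-complete inputs; compare like with like.
* The leave-one-out numbers inherit the optimistic bias discussed above;
  the honest generalization estimate in the reference set is the
  train-crystal/test-modeled experiment (15/23).
* With 52 antibodies total, all statistics are small-sample; the Student's
  t-tests on the group means (pooled by default, Welch available) should be
  read as descriptive.
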