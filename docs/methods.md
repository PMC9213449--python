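# Methods

## The problem and the model

`mtppi` predicts, per residue of a protein sequence, whether the residue
belongs to a protein–protein interaction (PPI) interface. Interface
annotations are scarce — they exist only for proteins whose bound complex
has been solved — while *structural* per-residue annotations (secondary
structure, solvent accessibility, buriedness) are available for every
solved structure. The package therefore frames interface prediction as a
multi-task sequence-labeling problem: one shared trunk, one output head
per task, and a composite cost

    L = α·L_IF + β·L_BU + γ·L_S3 + δ·L_S8 + ε·L_SA

with cross-entropy for the classification tasks (interface IF, buried
BU, 3- and 8-class secondary structure S3/S8) and squared error for
solvent accessibility (SA). Every task term is averaged **only over
unmasked residues**; a residue masked for a task contributes exactly
nothing to the loss or to any metric. Masking covers three situations:
padding, residues with incomplete side chains (masked for SA and BU),
and — the load-bearing case — proteins with no interface annotation at
all, whose entire IF vector is masked. Such proteins still train the
trunk through the related tasks, which is what lets the model learn from
a dataset *extended* with structure-only proteins ("data extension").

Interface positives are up-weighted in L_IF by the class-imbalance
weight, defined as the ratio of observed non-interface to interface
residues in the training + validation sets (≈ 6.4 at the default
synthetic conditions; roughly 1 interface residue per 6–7 others).

### Task weighting

Three weighting schemes are provided, all normalized to sum to 1:

* **A** — all active tasks equal.
* **B** — similar tasks grouped, each group sharing one task's weight,
  split equally inside the group. The two documented readings of the
  grouping differ: the prose pairing groups {S3, S8} and {BU, SA}; the
  equation pairing groups {BU, S3} and {S8, SA}. Both are implemented
  (`method_b_pairing="prose"|"equation"`, default prose); we do not
  guess which one the original experiments used.
* **C** — the interface weight equals the sum of all other weights
  (α = β+γ+δ+ε, others equal), i.e. IF carries 50% of the cost.

## Label generation from structures

* **Interface**: residue r of chain c is an interface residue iff some
  atom of r lies within `r_vdw(a) + r_vdw(b) + 0.5 Å` of an atom b of a
  residue in a *different* chain; the partner residue is labeled too.
  The embedded van der Waals radii are C 1.70, N 1.55, O 1.52, S 1.80,
  P 1.80, Se 1.90, H 1.20 Å (overridable); an unknown element is a hard
  error, never a silent default. Contacts are found with one KD-tree per
  chain and the exact per-pair threshold applied to candidates; a
  brute-force all-pairs oracle in the test suite guarantees equivalence.
  Single-chain structures have no defined interface (all labels
  missing, with a warning). All chains present in the file are treated
  as potential partners.
* **Secondary structure**: S8 from the DSSP structure column (blank →
  coil; the polyproline code of newer DSSP builds also maps to coil),
  coarsened to S3 by the fixed partition {C,S,T}→coil, {H,G,I}→helix,
  {E,B}→strand.
* **Accessibility / buried**: absolute ASA from DSSP; a residue is
  buried iff ASA / maxASA(residue type) < 0.07 (strict, with the
  Tien et al. theoretical maxASA table embedded). Exact floating-point
  equality at the 7% boundary counts as *not* buried.
* **Incomplete side chains** (masked for SA and BU) are detected as
  residues with fewer heavy atoms than the canonical count for their
  type; the detector is ours, since only the masking rule is specified
  upstream.
* A Shrake–Rupley routine (92 Fibonacci sphere points, probe 1.4 Å) is
  included so accessibility can be computed for toy fixtures without an
  external DSSP binary; DSSP files remain the primary source for real
  structures.

## Input features

76 features per residue, concatenated as PSSM(20) | HMM(30) | PHYS7(7) |
PSP19(19):

* PSSM log-odds from PSI-BLAST ascii profiles, used raw (a sigmoid
  squashing and per-column z-scoring are available as options, both off
  by default).
* 30 HHM values per residue from HHblits profiles: 20 match emissions +
  7 transitions + 3 local diversities, each integer score x transformed
  by 2^(−x/1000), `*` → 0 (hence all in [0, 1]).
* The 7 Meiler physicochemical descriptors and a 19-dimensional binary
  rigid-block indicator of side-chain composition; both are pure
  functions of residue identity. The rigid-block membership table is a
  documented, chemically motivated fragment decomposition (backbone
  unit, methyls/methylenes, branched CH, hydroxyl/thiol/thioether,
  carboxylate/amide/guanidinium/amine, aromatic rings, pyrrolidine,
  chain-length markers); glycine carries only the backbone block.
  Unknown residues ('X') get the mean Meiler row and a zero block row.

## Network and training

Trunk: input projection → transformer layers (multi-head self-attention
with padded keys masked) → same-padded 1-D convolutions → bidirectional
LSTM layers (the backward pass runs on per-row length-reversed input so
padding never leaks into real positions) → one linear head per task.
ReLU activations, dropout 0.25, glorot-uniform initialization. The
network is implemented directly in numpy with a small reverse-mode
autodiff engine (`mtppi.nn`); gradients are property-tested against
central finite differences.

Two presets: `paper` mirrors the published layer counts (2 transformer,
5 CNN, 4 biLSTM); its internal widths are pragmatic defaults, not
normative. `tiny` (1/2/1 layers, ≈27k parameters) is the desk-scale
configuration used by all synthetic experiments and tests.

Training follows the published protocol: Adam, batches of 4 proteins,
initial learning rate 2.5e−4, per-epoch validation monitored by the
interface AUC ROC, learning rate halved whenever the AUC falls strictly
below the previous epoch's value (ties are not decreases), stop at the
fourth decrease, and the retained model is the best-validation-AUC
checkpoint. "Previous" means the immediately preceding epoch; a
`best-so-far` monitor variant exists for sensitivity checks. Optional
data enhancement replaces a training protein, with probability 0.5, by a
random contiguous fragment of at least 30 residues, labels and masks
cropped consistently. The four-repeat protocol reports mean ± sample sd
over seeds `base_seed + repeat_index`.

Two numerical choices matter at desk scale:

* **SA target standardization.** SA labels are stored as the fraction of
  the residue's maximum accessibility (in [0, 1]). On that scale the MSE
  term is an order of magnitude smaller than the cross-entropy terms, so
  under equal task weights the accessibility gradient is numerically
  negligible and the trunk never learns exposure. The training loop
  therefore z-scores SA targets over the observed training residues
  (`standardize_sa=True`). Pearson correlation, the SA metric, is
  invariant to this affine transform.
* **Desk-scale schedule.** The experiment driver uses the tiny preset
  with learning rate 2e−3, batches of 16 and at most 20 epochs (early
  stopping active): small corpora need larger steps and more epochs than
  the full-scale configuration, whose values (2.5e−4, batch 4) remain
  the `TrainingConfig` defaults.

## Evaluation

Dataset-level metrics are micro-averaged over unmasked residues pooled
across proteins: AUC ROC (= the Mann–Whitney probability, tie-aware),
AUC PR (step-wise, threshold-grouped), and at the fixed 0.5 threshold
accuracy, precision, recall, specificity, MCC and F1; SA is scored by
Pearson correlation. Degenerate inputs (single-class labels, zero
variance) yield an explicit undefined signal, never a number. Two mean
AUCs from independent samples are compared with a one-sided z-test using
Hanley–McNeil standard errors. The per-protein error analysis is a
separate view: mean per-protein interface AUC over repeats (proteins
with no observed positive or negative flagged undefined and excluded)
against interface size, plus ordinary least-squares R² of each
related-task score against the interface AUC.

## Synthetic data: what it emulates, and what it does not

The generator produces corpora whose label tracks are mutually
consistent by construction: a 3-state Markov chain gives S3 segments, S8
is emitted conditional on S3, relative accessibility is a buried-core /
surface Beta mixture conditional on S3, buried is exactly the 7% rule
applied to the stored accessibility, and sequences are sampled with
hydrophobics enriched in the core. Interface positives are the top
fraction of a propensity field = standardized exposure + smoothed noise,
so they form contiguous patches that preferentially sit on exposed
residues; each protein's positive count is drawn around the 13.5%
target (the complement of a ≈6.4 class ratio), and exactly one third of
proteins carry interface annotations by default.

Profile-like features are a fixed linear mixing of the latent state
(secondary structure, per-residue exposure, and a deliberately weak
direct interface channel) plus unit Gaussian noise; the PHYS7/PSP19
blocks are the real sequence-determined tables. Two aspects of this
design carry the scientific content of the label-scarcity experiment
and were chosen as the package's study conditions: the *smoothed*
exposure that drives interface placement is not emitted as a feature —
a predictor must recover exposure from noisy per-residue channels and
aggregate it over sequence context, which is precisely the computation
the dense structural tasks supervise — and the direct interface channel
is weak enough (scale 0.15 against unit noise) that the full-label
single-task model is respectable while the multi-task model with data
extension sits a few points above it, mirroring the regime reported for
real data. What the generator does **not** emulate: real profile
statistics (the features are Gaussian mixtures, not PSI-BLAST output),
realistic 3-D geometry (toy complexes are jittered CA traces),
inter-protein homology and redundancy, or length distributions beyond a
uniform 30–60 range. Passing desk-scale experiments therefore
demonstrates that the machinery implements the intended mechanism, not
that the published real-data AUC values are reproduced.

Toy multi-chain coordinate files are emitted as CA-only PDB text with
controllable inter-chain separation and exact pinned contact distances;
their ground-truth interface labels come from an independent all-pairs
evaluation of the contact rule.

## Experiment designs

* **Task sweep**: every variant (IF, IFBU, …, IFBUS3S8SA; named by
  concatenated task codes) × {annotated dataset, extended dataset}, each
  cell mean ± sd over 4 repeats, one-sided significance against the
  single-task baseline.
* **Label scarcity**: at each kept fraction of annotated proteins, three
  strategies share the *identical* kept set (nested across fractions
  under a fixed seed): single-task on the kept proteins, multi-task on
  the kept proteins, multi-task on the full extended training set with
  interface labels visible only for the kept proteins. All strategies
  are evaluated on the byte-identical full validation set. The class
  weight is recomputed per masked configuration from currently observed
  interface residues (a fixed override is available).

## Known limitations

* The trunk widths of the `paper` preset are not the published model's
  (those are deferred to its reference and would be CPU-prohibitive);
  conclusions at full scale require real profiles and a GPU stack.
* The numpy training loop is single-threaded and desk-scale by design.
* The multi-task model trained on the annotated subset alone (without
  extension) can trail the single-task model at these corpus sizes —
  with equal task weights a quarter of the gradient serves the
  interface head, which small corpora cannot always afford. The
  extension effect, the package's central claim, is robust in the
  default conditions.
* PDB output of the toy-complex generator supports at most 62 chains
  (one-character chain ids); the contact rule itself has no such limit.
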