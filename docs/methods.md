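# Methods

## Problem and model

`dockmil` predicts protein–ligand binding affinity (pK units, −log Ki or
−log Kd) from *docking poses* rather than co-crystal structures.  Because
docking output is noisy — some poses sit close to the true binding mode,
others are several Ångström off — a single-pose predictor inherits that
noise.  The package therefore treats each protein–ligand entity as a
multi-instance *bag*: the K docking poses x₁…x_K of one ligand against its
receptor, with one real-valued label y for the whole bag and no per-pose
labels.  The assumption is the standard MIL premise that at least one
instance reflects the labeled binding mode.

The pipeline has three stages:

1. **Featurization.** Each pose-with-pocket becomes a point cloud of heavy
   atoms.  Protein atoms farther than `pocket_radius` (default 8 Å) from
   every ligand heavy atom are discarded; coordinates are centered on the
   ligand heavy-atom centroid.  Every atom carries a 19-dimensional feature
   vector: a 9-slot element one-hot (B, C, N, O, P, S, Se, halogen, metal),
   a hybridization code, heavy- and hetero-neighbor counts, five property
   bits (hydrophobic, aromatic, acceptor, donor, ring), the partial charge,
   and the Van der Waals radius.
2. **Instance embedding.** A graph-network backbone Gψ maps each instance
   to an embedding h_k ∈ R^D and, through a small scalar head, a per-pose
   affinity estimate (used for training stage 1 and for the Top/Avg
   baselines).  Two backbones are provided: a spatial graph network
   (`sgcnn`) over covalent (d ≤ 1.5 Å) and noncovalent (1.5 < d ≤ 4.5 Å)
   edges, and an E(n)-invariant network (`egnn`) over a 5 Å radius graph.
3. **Attention pooling.** The MIL head computes one logit per instance,
   logit_k = tanh(W h_kᵀ), softmax-normalizes them into weights a_k ≥ 0 with
   Σa_k = 1, pools z = Σ a_k h_k and maps z through three fully-connected
   layers to ŷ.  The map is invariant to instance order.  A multi-head
   variant splits the embedding into n_heads slices with per-head
   projections; n_heads = 1 reduces exactly to the single-head form.

Training is two-stage ("separate"): stage 1 trains the backbone on
individual instances, each labeled with its entity's y; stage 2 freezes the
backbone, extracts all embeddings, and trains the attention head on bags.
Both stages minimize MSE with RMSprop (lr 0.001 decayed by 0.9 at epochs
5, 10, 20, 30, 50, 70, 90; mini-batch 20; last-epoch checkpoint, no
validation-based selection).  An end-to-end single-stage option exists
behind the same interface with a batch size of one bag; it is smoke-tested
only.

## Baselines

`Top` predicts from the rank-1 pose (lowest docking score) via the stage-1
scalar head; `Avg` is the unweighted mean of the stage-1 predictions over
the bag.  When a crystal instance is present it participates in Avg and MIL
but never in Top (Top is defined by docking score).

## Design choices where the design was open

- **19-feature slot allocation.** The feature families are fixed; the exact
  slot split (9+1+1+1+5+1+1) follows the Pafnucy-lineage feature set with
  the Van der Waals radius in place of the molecule-membership code.
  Because that removes any explicit protein/ligand indicator, the instance's
  role mask is fed to the backbone as a 20th input channel: binding
  affinity is a property of the intermolecular structure, and without it
  the network cannot distinguish inter- from intramolecular contacts.
- **Perception rules.** Hybridization, aromaticity, rings, donors and
  acceptors are perceived from the parsed bond graph with documented
  heuristics (see `featurize.perceive_atoms`) rather than requiring a
  sanitizable molecule, so the same code path handles real files and
  synthetic point-atom structures.  RDKit perception on real molecules is
  the independent cross-check in tests.
- **Partial charges.** Read from Mol2 column 9 when present; otherwise
  computed by an in-repo PEOE (Gasteiger-type) iterative
  electronegativity-equalization with classic element/hybridization
  parameters (cross-checked against RDKit's Gasteiger charges on ethanol).
- **Covalent edges by distance.** Both edge types are thresholded on
  distance (1.5 / 4.5 Å, inclusive); the file bond table informs only the
  neighbor-count features.  Long covalent bonds (S–S ≈ 2.05 Å) therefore
  land in the noncovalent set; the synthetic generator does not produce
  them.
- **SGCNN internals.** The printed hyperparameters fix the stage structure
  (2 gated-graph steps per edge type) and the gather widths (16 covalent,
  12 noncovalent).  The reconstruction uses GRU node updates and messages
  linear in the neighbor state with two channels — one ungated and one
  gated by exp(−d/4.5) — so both hard within-cutoff neighbor counts and
  distance-weighted aggregates are representable.  Stage readouts are gated
  attention-sums; their concatenation is projected to the embedding
  dimension D.
- **EGNN internals.** Six layers, residual node updates, per-edge sigmoid
  attention, one scalar edge feature (the distance).  Coordinates are
  updated equivariantly inside the stack with a tanh-bounded per-edge
  shift (unbounded shifts destabilize deep stacks); only the invariant node
  channel is pooled (mean over nodes), so the embedding is E(n)-invariant.
- **Attention shape.** W is a single row per head producing one scalar
  logit per instance; softmax is applied directly to the tanh output.  The
  gated-attention alternative (a second projection after a matrix tanh) is
  deliberately not implemented.
- **Embedding standardization.** The head standardizes incoming embeddings
  to zero mean/unit variance per dimension (statistics fitted on the
  training store and stored with the head).  Without this, backbone output
  scales in the tens saturate tanh(W h) at initialization and the attention
  receives no gradient.
- **Label standardization.** Both stages standardize labels internally and
  de-standardize at prediction; the constants travel with the checkpoint.
- **Ragged bags.** Variable K is handled by segment softmax over
  concatenated bags; instances absent from a bag contribute no rows and
  hence carry exactly zero weight.
- **Loss.** MSE, matching the RMSE-centric evaluation.

## Synthetic data: what it emulates and what it does not

The generator (`dockmil.synthdata`) emulates the *structure* of a docking
campaign: entities with 1–10 pose instances, a controllable number of
"good" poses (RMSD to the true pose drawn from [0.3, 2.0] Å) among "bad"
ones ([4.0, 10.0] Å), docking scores only weakly informative of accuracy
(score = −7.0 + 0.2·RMSD + N(0, 1) kcal/mol, giving the imperfect
rank-vs-quality relation seen in real campaigns), and labels that are a
deterministic function of the **true** pose's geometry:

    y = 0.7 · (protein–ligand contacts within 4.5 Å) / n_ligand_atoms
        + 2.0 + N(0, label_noise_sd)

with constants chosen so labels span a realistic 4–11 pK range with
standard deviation ≈ 1.5.  Decoy poses carry no label information of their
own — the premise the MIL head must exploit.  Ligands are self-avoiding
random C/N/O chains (1.5 Å steps), which makes topological symmetry
vanishingly unlikely, so matched-order RMSD equals symmetry-corrected RMSD.
Pockets are random shells of protein atoms 3–6.5 Å from the ligand.
Entities belong to ligand template families; the group split keeps each
family wholly in train or test as a scaffold-split analog.

What the generator does **not** emulate: real chemistry (valence, torsions,
force fields), docking-engine score landscapes, receptor flexibility, or
the label noise structure of experimental assays.  Passing tests therefore
demonstrate that the MIL machinery extracts a pose-conditional signal that
is present by construction — not that the models reach any particular
accuracy on PDBbind-like data.

## Benchmark protocol and problem sizes

The package's synthetic benchmark (used by the test suite and
`scripts/acceptance.py`) runs, per seed: 350 entities (250 train / 100
test, random split), 10 poses per bag with 1–3 informative ones, label
noise 0.1 pK; SGCNN backbone at D = 32, hidden width 16 (the SGCNN's
linear message structure admits a sparse-aggregation fast path, making it
the cheaper backbone for repeated seeded runs; the EGNN's per-edge MLPs do
not); stage 1 for 15
epochs, stage 2 for 100 epochs with fully-connected widths (16, 8) — at
250 training bags a larger head memorizes the bags (train MSE below 0.01
in standardized units) and generalizes worse.  Ten seeds are used in the
test suite and five in the acceptance script.  These sizes are the
package's own desk-scale choice; the pipeline accepts arbitrary sizes.

The good-pose stratification analog trains and evaluates on
mixture-composition campaigns — 30% of entities with all poses good, 30%
with none, 40% with 1–4 good poses — because stratified groups are only
meaningful when the training data contains all compositions; a model
trained solely on 1–3-informative bags is out of distribution on all-good
bags and mispredicts them.

The noiseless-recovery experiment uses 700 entities (500/200), bags of one
true-pose instance plus 9 bad decoys (`include_crystal=True`,
`n_informative=0`, `label_noise_sd=0`), stage 1 for 40 epochs and stage 2
for 300.  "Exactly one instance carries the label signal" is read as the
bag containing the true pose itself: a decoy at 0.3–2 Å already blurs the
label (an oracle regressor on the best decoy's own geometry caps near
R² ≈ 0.92 under the default good-pose range), whereas the true pose
determines it exactly.

## Numerical choices

- Float64 throughout; the E(n)-invariance and permutation-invariance
  contracts are tested at 1e-4/1e-5 relative.
- Graph cutoffs are inclusive (d ≤ cutoff); coincident atoms produce no
  edge; both directions of each undirected edge are stored.
- Softmax uses the max-shift trick; segment softmax treats the shift as a
  constant (exact gradient).
- RMSprop uses α = 0.99, ε = 1e-8.
- Degenerate inputs: bags of K = 1 pool to the single embedding with
  weight exactly 1; zero-variance references report correlation metrics as
  missing rather than NaN; unknown elements outside the 9 one-hot classes
  keep their atom with an all-zero one-hot and a logged warning.

## Known limitations

- The backbones are NumPy implementations on an in-repo reverse-mode
  autodiff core; they are CPU-bound and sized for desk-scale experiments,
  not PDBbind-scale training.
- Pose RMSD is plain matched-order heavy-atom RMSD without
  graph-automorphism correction; on symmetric ligands it overestimates.
  The synthetic ligands avoid symmetry by construction.
- The PEOE parameter table covers H, B–I main-group elements common in
  drug-like molecules; others fall back to generic parameters with a
  logged warning.
- The rule-based donor/acceptor perception is intentionally coarse
  (N/O-based); it matches RDKit on simple fixtures but is not a SMARTS
  pharmacophore model.
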