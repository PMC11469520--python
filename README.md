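# qpharm — ligand-free pharmacophore elucidation

A pharmacophore is a 3D arrangement of typed interaction points — hydrogen
acceptor/donor, hydrophobic, aromatic, negative/positive ion — that a
binding ligand must satisfy; it is the standard geometric query of
structure-based virtual screening. Building one normally requires a
co-crystal structure of the protein with a ligand. `qpharm` is a toolkit
for building pharmacophores from the **protein structure alone**, for
computational chemists prototyping screening models when no bound ligand
exists.

The pipeline has three stages:

1. **Point prediction.** A trainable multilabel predictor scores every
   grid point of a binding-site box (0.5 Å spacing) with six class
   confidences, from a voxelized encoding of the local environment (cubic
   box of edge 9.5 Å at 0.5 Å resolution, typed Gaussian atom densities).
   Its final hidden layer provides a 32-dimensional embedding of the local
   environment. Predictions that clash with the protein or sit too far
   from a complementary functional group (e.g. an acceptor more than 4 Å
   from every protein donor group) are mined as adversarial negatives for
   retraining.
2. **Feature extraction.** Confidences are binarized, 26-connected
   components labelled, the top point per nearby complementary group kept,
   and nearby points merged by average-linkage agglomerative clustering
   with a 1.5 Å criterion; cluster centroids become the candidate features.
3. **Assembly by Q-learning.** Selecting a subset of candidates is a
   Markov decision process over heterogeneous protein–pharmacophore graphs
   G(V_f, V_p, E_ff, E_fp): each action adds a feature within δ_ff = 8 Å of
   the current graph, or terminates once the graph has ≥ 3 nodes. The
   reward of a graph is the F1 score its features earn when screened
   against a labelled active/decoy library. A scalar Q-function — invariant
   under rotation, translation and node reordering because geometry enters
   only through interatomic distances and nodes are sum-pooled — is trained
   on temporal-difference targets y_t = r_t + γ·max Q(G_{t+2}) with an
   ε-greedy policy whose exploration decays as
   ε_t = ε_T + (ε_o − ε_T)·e^(−t/α). An ensemble of 5 networks performs
   greedy rollouts from the highest-confidence seed features at inference.

Screening itself is built in: a molecule matches a pharmacophore if an
injective class-consistent assignment and a proper rigid transform place
every assigned molecule feature within the feature's tolerance radius
(1 Å default), with optional receptor-exclusion rejection of clashing
poses. Pharmacophores read and write Pharmit-compatible JSON.

All stages are exercisable end to end on synthetic pockets and libraries
with planted ground truth — no downloads.

## Worked example

```bash
python examples/04_q_learning_assembly.py
```

prints

```
trained 1 member for 300 episodes; mean reward of last 20 episodes: 0.79
planted optimal triple: (3, 5, 7)

greedy rollout from feature 3: terminal subset (3, 5, 7), reward 1.00
greedy rollout from feature 5: terminal subset (3, 5, 7), reward 1.00
greedy rollout from feature 7: terminal subset (3, 5, 7), reward 1.00
```

The synthetic task plants 8 candidate features of which exactly one
3-subset screens perfectly (F1 = 1.0, verified by exhaustive enumeration;
a random subset averages F1 ≈ 0.04). After 300 training episodes the
greedy policy, started from any feature of the optimum, adds exactly the
right partners and chooses to stop — it has learned both which features
belong together and when a pharmacophore is complete.

The other examples cover feature extraction (`01`, centroid errors
0.15–0.31 Å against planted sites), screening metrics (`02`, F1 = 1.0 and
enrichment factor 5.0 on a 20/80 planted library), and the enumeration
baseline (`03`).

The same pipeline is available as a CLI:

```bash
qpharm --seed 1 simulate task --out task/
qpharm --seed 1 train-q --features task/features.json --protein task/protein.pdb \
       --library task/library.jsonl --episodes 300 --ensemble-size 5 --out ens/
qpharm build-pharmacophore --ensemble ens/ --features task/features.json \
       --protein task/protein.pdb --library task/library.jsonl --out ranked/
qpharm screen --pharm ranked/rank1.json --library task/library.jsonl
```

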