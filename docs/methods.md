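# Methods

This note documents the models, conventions and numerical choices behind
`qpharm`, and what the synthetic study conditions do and do not show.

## Pharmacophore model and screening

A pharmacophore feature is a point X_f ∈ R³ with a class Z_f from
{HydrogenAcceptor, HydrogenDonor, Hydrophobic, Aromatic, NegativeIon,
PositiveIon} (stable codes 0–5) and a tolerance radius (default 1.0 Å —
a conventional search tolerance; files carry per-point radii that
override it). Features may carry a unit direction vector; directions are
stored and round-tripped through Pharmit-compatible JSON but ignored by
the matcher, which treats geometry as point constraints only. A
pharmacophore rejects two same-class features closer than 0.1 Å
(duplicate guard, keeps downstream graphs simple).

**Matching semantics.** A molecule conformer (a set of typed feature
points) matches iff there is an injective class-consistent assignment of
pharmacophore features to molecule features and a *proper* rigid
transform (no reflection — physical molecules) placing each assigned
molecule feature within the corresponding radius. The search prunes
assignments by pairwise distance compatibility
(|d_pharm(i,j) − d_mol(a,b)| ≤ r_i + r_j) and verifies survivors by
least-squares (Kabsch) superposition; the first satisfying assignment in
lexicographic order is returned. Feasibility is therefore *defined* by
the least-squares pose, a deliberate convention that makes the matcher
reproducible and testable against a closed-form oracle. All features
must be satisfied (hard filter); pharmacophores below 3 features are
refused, matching the minimum of the screening tools this emulates.
Multi-conformer molecules are records sharing an id, matched if any
record matches. Boundary conventions: matching uses ≤ radius; receptor
exclusion uses strict < r_excl (default 1.5 Å) with a 1e-9 slack
absorbing rotation round-off.

**Metrics.** precision, recall, F1 (zero-denominator cases defined as 0
so useless pharmacophores earn reward 0 rather than raising), enrichment
factor EF = precision / (active fraction) (EF = 1 for an unbiased random
classifier), and optionally F1 normalized by the best F1 achievable from
reference features.

## Functional-group annotation

Complementary protein groups are assigned purely from a residue/atom-name
table of standard amino-acid chemistry: backbone N → donor, backbone
O/OXT → acceptor; Ser/Thr/Tyr hydroxyls → donor+acceptor; Asn/Gln amide
O → acceptor, N → donor; Asp/Glu carboxylates → one merged anionic site
plus per-oxygen acceptors; Lys NZ and the Arg guanidinium → cationic (+
donors); His ring nitrogens → donor+acceptor with the ring an aromatic
site; Phe/Tyr/Trp rings → one aromatic site at the ring centroid (Trp's
fused system is a single site); aliphatic side-chain carbons → one
hydrophobic patch per residue at their centroid. The table is an
explicit, overridable stand-in for tool-specific SMARTS definitions;
unknown residues contribute only backbone groups. Feature-to-group
support cutoffs: acceptor→donor 4.0 Å, donor→acceptor 4.0 Å, ions 5.0 Å,
aromatic 6.0 Å, hydrophobic 5.0 Å; all config-overridable.

## Point predictor

**Input encoding.** A cubic box of edge 9.5 Å at 0.5 Å resolution,
centered on the query point, giving 20 grid points per edge (points at
0, 0.5, …, 9.5). Eight atom-type channels (aliphatic/aromatic C,
donor/other N, acceptor/other O, S, other heavy); hydrogens excluded.
Each atom adds a Gaussian density exp(−2d²/r²) of its van der Waals
radius r, truncated at 3r — at that radius the kernel is e⁻¹⁸, so the
discrete grid mass agrees with the closed-form truncated-kernel integral
to well under 0.1 %. Voxelization is translation-covariant by
construction.

**Reference model.** The trainable predictor is a compact fully-connected
network over the block-averaged voxel grid (4³ average pooling → 8×5³
inputs → 64 → 32 → 6 sigmoid outputs), trained with per-class binary
cross-entropy by Adam (hand-written, fully deterministic under a seed).
The 32-unit final hidden layer is the exposed per-point embedding. The
architecture is intentionally small so it trains on one CPU at
synthetic-fixture scale; it is configurable, and any object implementing
`predict_points(protein, points)` can stand in (the synthetic oracle
does). Multilabel outputs are independent confidences, not a simplex: a
hydroxyl environment can be donor and acceptor at once. A
zero-initialized model outputs 0.5 everywhere (σ(0)).

**Adversarial negatives.** Grid points where a class fires above 0.5 are
mined as all-negative training samples when they clash with the protein
(nearest heavy atom < 2.0 Å) or when the fired class has no complementary
group within its support cutoff. The firing threshold 0.5 is the
multilabel logistic midpoint; the 2.0 Å clash distance is a typical
lower bound for a non-bonded heavy-atom contact.

## Feature extraction

Per class: binarize at 0.5 (strict >; an untrained all-0.5 field yields
nothing), label 26-connected components (at 0.5 Å spacing even diagonal
contact is sub-bond-length), then for each complementary group within
the class cutoff of any component voxel emit the component's
top-confidence voxel among those within the cutoff of that group (ties
break to the lexicographically smallest voxel index; duplicates
collapse). Points are merged per class by average-linkage agglomerative
clustering, merging while the linkage distance is ≤ 1.5 Å; each cluster
becomes one feature at the unweighted centroid carrying the maximum
member confidence and the predictor embedding evaluated at the centroid.
Points are canonically sorted before clustering so the result is
invariant under input permutation. The box is user-supplied corners or a
reference-ligand bounding box padded by 4 Å.

## The assembly MDP and Q-learning

**States** are heterogeneous graphs G(V_f, V_p, E_ff, E_fp): selected
features, protein heavy atoms within δ_fp = 5 Å of any selected feature,
feature–feature edges within δ_ff = 8 Å and feature–protein edges within
δ_fp. **Actions** add one admissible feature (absent, within δ_ff of the
graph) or terminate once |V_f| ≥ 3 (a 4-feature minimum mode is
available for more selective models). **Reward** is the screening F1 of
the graph's feature set; graphs below the minimum earn 0. Episodes start
from a single-feature seed graph — uniformly sampled during training,
confidence-ranked at inference — and end on termination, a dead end, or
after adding every feature.

**Q-network.** The exposed contract is a scalar invariant under global
rotation, translation and node reordering (the value of a pharmacophore
cannot depend on the frame). The implementation separates a *fixed*
random-feature message-passing encoder — node attributes (class one-hot +
32-d embedding for features, atom-type one-hot for protein nodes) mixed
with a Gaussian radial basis of edge distances, one round of
message passing, sum/mean pooling plus class-histogram and count
summaries — from a trainable MLP head (64–64–1, ReLU). Invariance is
structural: only distances and permutation-symmetric pools enter.
Training fits the head; the encoder is shared by construction across
ensemble members, enabling descriptor caching per feature subset.

**TD targets.** Transitions from ε-greedy episodes (ε_t = ε_T +
(ε_o − ε_T)e^(−t/α); defaults ε_o = 0.9, ε_T = 0.1, α = episodes/4) fill
a replay buffer. Every few episodes the head is fitted to
y_t = r_t + γ·max over the next proposal set, evaluated with a target
copy re-synchronized every 100 gradient updates; after the episode
budget, a few fitted sweeps over the whole buffer polish the estimate.
One design choice deserves emphasis: the terminal option inside the max
is valued at its *exact* payoff R(G) rather than by the network, and
terminal transitions generate no extra regression pair. Valuing the
terminal option with the same network output that also carries the
continuation value would give one input two inconsistent targets and no
Bellman fixed point; with the exact-payoff convention the operator has a
well-defined fixed point that `value_iteration` computes exactly on
enumerable tasks, which is what the agreement test measures. Action
selection still scores termination with q(G_t), as the greedy argmax
over the proposal superset. The loss is squared TD error (the natural
bounded-below choice), γ defaults to 0.99, and training aborts if the
loss becomes non-finite. Dead ends (no candidates, termination not
allowed) end the episode with reward 0 and target y = r.

**Inference.** Each of the 5 ensemble members rolls out greedily from
the top-k (default 2) highest-confidence seeds, giving up to 10
pharmacophores; terminal graphs are deduplicated and ranked by screening
F1 when a library is available, else by terminal Q.

## Synthetic study conditions

The generators define the conditions under which the toolkit is
validated.

* **Pockets**: n_sites planted sites (default 4) pairwise ≥ 4 Å apart in
  a 12 Å box, each paired with a complementary group 2.5–3.2 Å away and
  oriented so no group kind falls within the support cutoff of a foreign
  site; the confidence oracle is a Gaussian bump (σ = 0.8 Å) per site
  over a smooth background of amplitude 0.05, and the embedding a smooth
  sinusoid of position. These values put component radii (~0.9 Å at the
  0.5 threshold) well inside the site separation.
* **Libraries**: actives are rigid-motion copies of the planted
  pharmacophore with isotropic jitter σ = 0.3 Å (resampled until the
  matcher verifies a match); decoys break the model by class shuffling,
  2–4 Å geometry perturbation, or full randomization, regenerated until
  the matcher verifies a non-match. Generation-time verification makes
  the matcher the single source of truth for separability; with radius
  1.0 Å the 20/80 default library separates exactly (F1 = 1, EF = 5).
* **Unique-optimum task**: 8 features (pairwise 2.2–6.8 Å, all mutually
  within δ_ff so the optimum is reachable from any of its own features),
  a designated triple, 12 actives / 28 decoys with jitter 0.25 Å.
  Each active carries the triple plus at most one extra candidate
  feature, with every extra's share of actives capped at 1/3: subsets
  overlapping the optimum then earn partial F1 (≤ 0.5 by the recall cap),
  grading the reward landscape the way real actives sharing additional
  interactions would, while exhaustive enumeration verifies at
  generation time that exactly one 3-subset reaches F1 = 1 and every
  other size-3..5 subset stays ≤ 0.5. The optimal triple also carries
  the highest predictor confidences (0.85–0.99 vs 0.55–0.80), mirroring
  sites the predictor strongly supports.

What passing under these conditions shows: the matcher, extractor and
learner are internally correct and the assembly policy can discover and
stop at a verified optimum under a graded reward. What it does not show:
performance on real proteins, where features are denser (a real binding
site yields on the order of a hundred candidates), rewards are far from
binary, actives are chemically diverse rather than geometric copies, and
the predictor must generalize across pockets rather than memorize one.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scales chosen
as sufficient for their statistical purpose: 200 random matcher
instances, 20 pockets × 4 sites, 100 random graphs/states for symmetry
and proposal checks, 300 training episodes with a single network for
policy recovery, 250 episodes at γ = 0.6 with 20 final fitted sweeps for
the value-iteration comparison (γ = 0.6 keeps Q* magnitudes near 1 so an
absolute 0.05 criterion is meaningful, and the fitted-sweep contraction
0.6^20 ≈ 4·10⁻⁵ removes iteration error, leaving pure regression error).
Ties in clustering and argmaxes break deterministically (canonical
sorts, first-maximum). All randomness flows through explicit
`numpy.random.Generator` seeds; there is no global random state.

## Known limitations

* The reference predictor is a pooled-voxel MLP, not a deep 3D CNN; it
  is sufficient for the separable synthetic fixtures but would need
  replacing for PDB-scale training.
* The Q-head is trained on a fixed random-feature graph descriptor;
  end-to-end trained message passing would scale better to hundreds of
  candidate features.
* Directional feature information is parsed and preserved but not used
  in matching.
* PDB reading takes the first model and first altloc only; mmCIF and
  protonation-state prediction are out of scope.
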