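# Methods

## The prediction problem

Protein function prediction is cast as multi-label classification: given a
protein's 3D structure and sequence, score each term of a Gene Ontology
namespace (biological process, molecular function or cellular component)
with the probability that the protein carries that annotation.  The model
operates on a residue graph G = (V, E): nodes are residues carrying feature
vectors, and edges connect residue pairs whose Cα atoms lie strictly closer
than 10 Å.  Chains are stratified by length — short (<100 residues), normal
(100–500) and long (>500) — because real annotation corpora are heavily
dominated by normal-length chains and graph networks tend to under-serve
the tails.

## Graph construction

`structures_io` reduces a PDB/mmCIF chain to its Cα trace (gemmi parser,
first model only; the highest-occupancy altloc wins, ties resolved toward
'A'; residues lacking a Cα are dropped and counted).  The contact map is
computed directly from coordinates with a strict `dist < threshold`
comparison, and flattened into a directed 2×M edge list containing both
orientations of every contact, ordered ascending by source then target.
Indices are 0-based throughout.  Hetero-residues, insertion codes and
chain breaks receive no special treatment beyond the Cα rule; unknown
residue names map to 'X'.

## Node features (adaAF)

Two encodings are fused: a 21-column one-hot residue encoding (20 standard
residues + 'X') and a per-residue embedding of width f2 from a pluggable
embedder.  The shipped embedder is a deterministic mock whose rows are
standard-normal functions of (residue letter, position, seed); a real
protein language model can be slotted in through the same
`embed(sequence) → N×f2` contract.  The adaptive augmentation-fusion block
then computes

1. `V = FC1(V_onehot) + FC2(V_emb)` — projection to a common width F;
2. `V' = V − γ·(V − μ)/σ + η` — "individualization": the batch-normalized
   component is *subtracted* from the input, isolating what is specific to
   each node relative to the batch; μ, σ are per-feature statistics over
   the node axis (σ floored at 1e-5), with running statistics at inference;
   γ and η are learnable scalars initialized to 1 and 0;
3. `W = 2·ReLU(FC3(V'))`, `V'' = V' ⊙ W` — non-negative attention
   reweighting able to double or silence features;
4. `out = Pool(δ1·V'' + δ2·BN(V))` — a δ-blend of the augmented path with a
   batch-normalized copy of the fused input, followed by adaptive average
   pooling along the feature axis.

δ1 defaults to 0.5 (δ2 = 1 − δ1); sensitivity in the source experiments was
flat in the 50:50–70:30 range.  Pool's output size defaults to F, making it
the identity; a smaller output size is exposed as an option since the
pooling axis and size are a genuinely open design point.  Whether γ, η are
learned is likewise unstated in the original description; they are learned
here.  For desk-scale synthetic experiments the defaults are f2 = 16 and
F = 16 (the real-embedder configuration would be f2 = 1280, F = 512 — the
block accepts any widths).

## The tower stack (DH-GNN)

Three GraphSAGE towers share the input graph but not parameters.  A
GraphSAGE layer transforms sampled neighbor features through a one-layer
MLP (linear + ReLU), mean-pools them, concatenates the aggregate with the
node's own state and applies `ReLU(W_sage · concat)`.  Neighbor sampling
defaults to the full neighborhood at desk scale (a fixed k is available for
large graphs); isolated nodes aggregate a zero vector.  Layer widths are
F → 256 → 256 → 256 in spirit; desk-scale defaults use 16 throughout.

During training the α tower adds elementwise U[0,1)·τ1 noise to its layer-1
and layer-2 outputs and the β tower subtracts U[0,1)·τ2, biasing them
toward long- and short-chain features respectively; τ1 = τ2 = 0.5 (scores
were reported stable for τ in 0.3–0.7).  Noise is training-only: inference
is deterministic, since stochastic predictions would be irreproducible.

Between layers 2 and 3 an interactive adapter block couples each extractor
to the Main tower.  Per node, the cosine similarity between the two towers'
states is computed (zero-norm rows get similarity 0).  The concatenated
pair passes through three parallel depthwise convolutions with kernel
sizes {1, 3, 5} *along the feature axis*; each path is projected to a
latent space of size max(8, d/4), scored, and the three scores are
softmax-normalized per node; the weighted sum of path feature maps,
projected back to width d, is the adaptive weight matrix.  The Main tower
receives it scaled by the similarity; the extractor receives it scaled by
1 − |similarity|, a re-scaling that damps exchange where the towers already
agree.  The published sketch of this block does not fix the convolution
axis, kernel count, latent width or normalization; this reconstruction
chooses the feature axis deliberately so that all node representations are
permutation-equivariant under node relabeling — a node-axis convolution
would make predictions depend on residue numbering, which has no physical
meaning for the readout.

Layer 3 consumes concatenations mixing abstraction levels: the Main tower
gets (h1 ‖ h2 ‖ exchange-from-α ‖ exchange-from-β), each extractor gets
(h1 ‖ h2-noisy ‖ exchange-from-Main); absent exchanges (adapters disabled
or single-tower configurations) are zero blocks of the same width, so the
architecture is unchanged across ablations.

## Readout (adaSAB) and prediction

Each tower's final node states receive a learned scalar attention score;
softmax over nodes yields attention weights.  A ζ-gate (ζ = 0.5 default)
squashes the raw score through a logistic and lets the α tower keep the
*pre-attention* representation for nodes with squashed score < ζ, the β
tower for the complement, and leaves Main ungated — the two extractor masks
partition the nodes at any ζ.  The gate is a hard mask on the value path
(the published formula relating ζ to the blend is not in the main text;
a soft interpolation would be the alternative).  The attended value plus
the query projection is layer-normalized per node; queries and values are
separate projections of the same tower's states.  A mean‖max readout over
nodes and a sigmoid linear head yield per-term probabilities per tower;
the final prediction averages the active towers (Main-only is available).
The readout and head are not specified in the original description and are
chosen as the standard symmetric option.

## Objective

Each active tower contributes a weighted binary cross-entropy

    WCE = −(1/Z) Σ_i Σ_j w_j (y_ij log ŷ_ij + (1 − y_ij) log(1 − ŷ_ij)),

with per-term weights w_j = max(1, min(10, Σ_i N_i⁺ / (l·N_j⁺))) computed
on the training split; terms never observed get the upper clamp 10 (the raw
formula divides by zero).  The printed normalizer Z = n² is the default, a
conventional Z = n·m switch exists; the choice rescales the loss but not
its argmin.  Probabilities are clipped to [1e-7, 1 − 1e-7].  The total loss
is the plain sum over active towers.  Training uses adaptive-moment
gradient descent (lr 1e-3), mini-batches of 8 graphs, early stopping on
validation AUPR (patience 10); optimizer, rate and batch size are not
claims about the original training, which reported none.

## Evaluation

CAFA protein-centric metrics over a threshold grid 0.01…0.99 (step 0.01):

* **Fmax** — at each threshold t, precision is averaged over proteins with
  ≥1 predicted term (score ≥ t) and recall over proteins with ≥1 true
  term; Fmax is the best F1 on the grid.
* **Smin** — remaining uncertainty ru(t) is the protein-averaged summed
  information content of false negatives, misinformation mi(t) likewise
  for false positives; Smin = min √(ru² + mi²).  IC(term) = −log2 of its
  training-split frequency.  Both the raw IC-scale value and a [0,1]
  normalization by the all-negative predictor's score are reported.
* **AUPR** — micro-averaged step-wise average precision over protein–term
  pairs (so a constant predictor scores the positive prevalence exactly);
  a term-centric macro variant exists for IC-band analyses.

Reports can be stratified by length class and IC band (<5, 5–10, >10).
A seeded stratified-downsampling helper balances length classes to the
smallest class, mirroring the 1:1:1 resampling of the source experiments.
Annotations are taken as given: no propagation to ontology ancestors is
performed (a no-op hook marks the spot), since the original preprocessing
does not describe it.

## Synthetic data

The generator emulates the input *formats* and the statistical handles the
method exercises, not protein physics.  Geometry is a seeded self-avoiding
random walk: consecutive Cα spacing 3.8 ± 0.05 Å, non-consecutive minimum
separation 3.0 Å, and a weak centroid pull (decaying on collision retries)
that compacts the chain enough to create long-range contacts at 10 Å.
Sequences draw a per-protein hydrophobic propensity from U(0.2, 0.6) so
composition varies between proteins.  Labels come from a logistic score on
two observable covariates — standardized hydrophobic fraction and
standardized log-length — with ±1 coefficient patterns per term and scale
equal to the signal strength; per-term frequencies follow a geometric
spectrum from 0.5 down to 2⁻⁶ (information content 1–6 bits) and are
realized exactly by taking the round(P·n) top-scoring proteins under
Gumbel-perturbed scores (signal 0 therefore degenerates to uniform random
assignment).  Frequency targets are attainable to ±20% only when P·n ≳ 2,
i.e. from roughly 120 proteins for the default spectrum.  What passing
tests on this data show: the pipeline can extract a composition/length
signal through the full graph stack.  What they do not show: performance
on real folds, real annotation sparsity (thousands of terms), or real
language-model embeddings.

## Numerical choices and engine

The network runs on a small reverse-mode automatic differentiation engine
over float64 NumPy arrays (dense linear algebra, elementwise
nonlinearities, axis reductions, concatenation, feature-axis padding and a
constant-sparse matmul for neighbor aggregation).  All stochastic elements
— initialization, splits, shuffling, noise, neighbor sampling — derive
from the run seed, so identical seeded runs are bit-reproducible.  Max
reductions break ties toward the first index; softmax subtracts the row
max; cosine similarity defines 0/0 = 0; BN/individualization statistics
switch from batch to running values at inference.  Desk-scale problem
sizes (widths 16, 24–120 proteins, ≤30 epochs) were chosen so the full
test suite and the acceptance pipeline run in minutes on one CPU core;
every width is configurable upward.

## Known limitations

* The adapter block and the ζ-gate are explicit reconstructions of
  algorithms only sketched in the source's main text; they satisfy the
  stated contracts (similarity modulation, path-weight normalization, mask
  complementarity) but are not claimed identical to the original code.
* The benchmark-scale results of the source (hundreds of thousands of
  real structures, GPU training, real ESM-1b embeddings) are out of scope;
  nothing here speaks to absolute accuracy on PDB-derived corpora.
* The mock embedder carries no evolutionary information; planted-signal
  learnability relies on the one-hot path.
* Batch statistics are per-graph (nodes of one protein), so very short
  chains see noisy normalization statistics.
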