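# Methods

## Problem and model

A phosphorylation site is a serine, threonine or tyrosine whose
phosphorylation may (or may not) have a downstream effect — regulation of
activity, localization, interactions, or disease association. `funcphos`
scores that functionality from two complementary views of the site and,
for enzymes, classifies the direction of the effect on catalytic
activity (induced vs inhibited).

**Structure branch.** Nodes of the site-centered subgraph are Cα atoms.
The node set is the center, every residue with Cα–Cα distance strictly
below the radius (default 8 Å), and the center's `k = 3` nearest
residues — the kNN rule guarantees a minimal neighbourhood even for
sites in extended, low-contact regions. Three edge rules (distance
< 8 Å, center-kNN, peptide bond between sequence-adjacent members) are
merged so each node pair carries at most one edge; the stored edge tag is
the highest-priority rule (distance > knn > peptide) that admitted it.
The edge set itself is what the GCN consumes, so the tags are
bookkeeping only.

**Node features (35 dims).** Amino-acid one-hot (20) + RSA (1) + pLDDT
(1) + sidechain vector (3) + 8-state secondary structure one-hot (8) +
degree (1) + eigenvector centrality (1). This 20+1+1+3+8+1+1 layout is
the unique integer decomposition consistent with one-hot amino acids, an
8-state secondary-structure alphabet, scalar RSA/pLDDT/degree/centrality
and a 3-vector sidechain direction summing to 35. Degree and centrality
are computed on the *whole-protein* contact graph (distance rule over
all residues) by default: a site-local subgraph has near-constant degree
by construction and would carry no information; a `centrality_scope`
switch restores the subgraph variant for ablations. The degree is
divided by 10 (a typical contact count at 8 Å) so it enters the encoder
on the same O(1) scale as the other features; pLDDT is scaled to [0, 1]
for the model but kept on its native 0–100 scale for statistics.

**Secondary structure and RSA.** The default secondary-structure backend
is the P-SEA Cα-geometry algorithm (via biotite), which assigns helix /
strand / coil from virtual angles and dihedrals of the Cα trace; these
three states occupy their slots of the 8-letter alphabet (H, E, C), and
chains shorter than four residues are all-coil. A full
hydrogen-bond-based assigner (DSSP) would populate all eight states; the
hook exists but requires an external binary. RSA is estimated by
Shrake–Rupley sampling over a coarse two-sphere residue model (a 2.4 Å
sphere at the Cα, a residue-specific 1.7–2.9 Å sphere at the sidechain
center, probe 1.4 Å, 120 Fibonacci points per sphere), normalized by the
Tien et al. (2013) theoretical maximum ASA and clipped to [0, 1]. This
is deliberately coarse — the pipeline's structures carry only Cα and a
sidechain pseudo-atom — but it preserves the buried-vs-exposed contrast
the feature is meant to encode.

**Eigenvector centrality.** Power iteration from the uniform vector on
`A + I` (the shift leaves eigenvectors unchanged and guarantees
convergence on bipartite components, where iterating on `A` alone
oscillates), tolerance 1e-8, ≤1000 iterations, per connected component,
L2-normalized, entries reported as absolute values. Edge-free components
get the uniform normalized vector by convention (a singleton residue
therefore scores 1).

**Sequence branch.** The embedder interface returns an L×D matrix plus
its column mean as a global vector. The production backend slot (`plm`)
expects a pretrained protein language model (D ≈ 2560); requesting it
without one installed raises immediately — there is no silent fallback.
The default `mock` backend is deterministic: row i is the unit-normalized
sum of a letter vector and 0.5× a position-bucket vector (bucket width
32), each drawn from generators seeded by (seed, letter) and (seed,
bucket). Identical residues in the same bucket embed identically; the
same letter across buckets stays strongly similar; different letters are
near-orthogonal. Sequences longer than the backend context window
(default 1022) are center-cropped around the site, which keeps the
site's local context intact and is deterministic.

**Query composition.** How the sequence side should enter the
cross-attention is genuinely open; the default query is two tokens —
projected global vector and projected site-residue embedding — which
keeps both a whole-protein and a site-local channel. A `window` mode
(global token + a fixed-width window of residue embeddings around the
site, indices clamped at chain ends) is available and is what the
distilled student consumes.

**Fusion and classifier.** Cross-attention uses the scaled dot product
`softmax(qkᵀ/√(C/d))v` with q from the sequence branch and k, v from the
GCN outputs; a single head is the validated setting. The √(C/d) scaling
is the standard choice; a `linear` option (dividing by C/d) exists for
comparison. Self-attention applies the same formula with q = k = v to
the fused tokens. The classifier flattens the tokens into a
256→256→512→1 MLP with ReLU, dropout after each hidden layer, and a
sigmoid output; ReLU and the absence of layer normalization are
documented defaults rather than reported settings. Probabilities are
clamped to [1e-7, 1 − 1e-7] inside the cross-entropy. Decision threshold
is strictly greater than 0.5; the measure-zero tie maps to the
negative/inhibited class.

**Ablations** are first-class: `no_gcn` (query straight to
self-attention), `no_esm` (mean-pooled graph vector alone), 
`no_cross_attention` (concatenate the query tokens with the pooled graph
token), `no_self_attention`.

## Curation rules

Functional labels: a site is positive iff it carries any
regulatory-function or disease-association annotation; unannotated sites
are negative. Regulatory types: only sites tagged with an enzymatic
activity direction are kept; "inhibited" overrides "induced" when both
tags are present, so conflicting records cannot produce contradictory
labels; the positive class of the classifier is *induced*. Protein
filters: isoform accessions (hyphen-suffixed) are dropped, then proteins
without a structure, then sites whose residue letter mismatches the
sequence at the stated 1-based position. Redundancy reduction is greedy
longest-first clustering at 0.8 identity, where identity is the best
ungapped k-mer-anchored alignment (k = 5) match count over the shorter
length — a deliberate simplification of cd-hit semantics that preserves
the threshold behaviour without the external binary. Negatives are
globally undersampled to 1:1 (configurable) into independent negative
sets; each balanced set splits 4:1 into train/test stratified by class,
and the training part is stratified into 5 CV folds. An optional
`group_by_protein` flag keeps every protein on one side of the
train/test split for leakage-aware evaluation (off by default, matching
the site-level procedure). Undersampling, splitting and fold assignment
are all reproducible from the curation seed.

## Training

AdamW (decoupled weight decay 0.01), binary cross entropy, per-fold
early stopping on validation AUROC with the best-epoch parameters
restored. The production recipe (batch 128, learning rate 1e-4, 50
epochs) reflects the validated large-corpus setting; the desk-scale
configuration used by the synthetic studies (below) is batch 32,
learning rate 2e-3, ≤50 epochs, patience 8, weight decay
0.03 — on a ~1800-sample benchmark
the production batch/step sizes would give too few, too-small updates to
converge. Transfer strategies: `scratch`, `multitask` (second classifier
head on the shared trunk; the joint loss is by construction the sum of
the two per-task BCEs), `transfer_embed_only` (copy everything except the
classifier, which is freshly initialized) and `transfer_all` (copy every
tensor). Distillation trains the sequence-only student MLP against the
teacher's output probabilities with soft-target cross entropy; the
student's final layer is zero-initialized so an untrained student
predicts exactly 0.5.

Metrics: accuracy, precision, recall, F1 and MCC from the confusion
counts at the 0.5 threshold (zero-denominator ratios, including MCC, are
defined as 0); AUROC and average precision from scikit-learn; both are
cross-checked against naive O(n²) oracles in the tests. Model-confidence
analyses: Spearman correlation between scores and site pLDDT
(average-rank ties; undefined on constant input), and per-stratum recall
over the pLDDT bins <30, 30–50, 50–70, 70–90, >90, half-open [lower,
upper) with the top bin closed. Group comparisons in the statistics
module use Welch's two-tailed unpaired t-test by default (a flag
restores the pooled-variance form); two zero-variance groups with equal
means report t = 0, p = 1.

## The synthetic benchmark

The generator emulates the statistical structure of real functional-site
corpora, not protein physics. Backbones alternate ideal α-helix segments
(2.3 Å radius, 1.5 Å rise, 100°/residue) with self-avoiding random-coil
walks at 3.8 Å Cα steps; sidechain pseudo-atoms sit 1 Å from the Cα in a
random direction (absent for glycine). Helix residues draw pLDDT from
U(70, 95), coil from U(30, 60), and sequence letters from
segment-specific pools (helix-formers vs coil/disorder-formers), so
confidence, secondary structure and local composition are mutually
informative, as they are in real predicted structures.

Structure is largely sequence-determined, as in real proteins, and the
generator makes that coupling explicit. Helix and coil segments draw
from disjoint letter pools, so a short window of sequence identifies
the local secondary structure; pLDDT is centered per segment at the
middle of its regime band (±3 between segments, per-residue jitter 2),
so confidence tracks whole elements the way real predicted-structure
confidence does. Each segment additionally draws an "anchored" flag
(probability 0.5, independent of helix/coil kind): anchored segments
steer into a compact core sphere (8 Å radius) and draw
hydrophobic/aromatic letters (W/F/M, rate 0.45), unanchored segments
live in a bounded peripheral shell (16–24 Å) — bounded on both sides so
the chain can always return to the core. Contact density, and with it
network centrality, is therefore high around the core and
sequence-correlated through the composition signature, while remaining
a genuinely 3D-computed feature with irreducible packing noise. About
10% of residues become S/T/Y candidate sites (minimum spacing 7); 35%
of sites get a ±3 motif (R at −3, P at +1).

Site labels follow a known logistic rule over coil membership, z-scored
whole-protein eigenvector centrality, and the motif indicator, with
weights (5.0, 1.0, 1.5) and bias −2.75. These defaults were set so that
a logistic regression on the true generative features — the benchmark's
Bayes-oracle surrogate — reaches AUROC ≥ 0.9 (measured 0.937), i.e. the
planted signal is recoverable while labels remain stochastic draws, with
the bulk of the signal on the sequence-visible coil term and a genuine
structural term (centrality) on top. Positives are coil- and
centrality-enriched by construction, mirroring the enrichment observed
on real corpora. The regulatory-type rule shares the centrality and
motif terms but flips the coil weight (−2.0, 1.0, 1.5, bias 2.2); about
72% of planted regulatory sites are induced, matching the imbalance of
real enzyme-activity annotations, and the feature overlap is what makes
transfer from the functional task useful. What passing on this
benchmark shows: the implementation can recover a planted
structure-borne signal end to end, the ablation ordering is as
designed, transfer semantics are exact. What it does not show:
performance on real proteins, where features correlate differently,
negatives are not missing-at-random, and language-model embeddings
carry far more than letter identity.

## Desk-scale study configuration

The standard studies (and `scripts/acceptance.py`) run on 200 generated
proteins (~2000 candidate sites, ~1800 after 1:1 undersampling), one
negative set, the mock embedder (D = 64), fusion width C = 64, dropout
0.15 and contact radius 6 Å for the model's graphs. The reduced width
matches the mock embedder dimension — the synthetic task does not need
the production capacity and the full cross-validation stays within
minutes on one CPU; dropout is halved because the narrower model
underfits at 0.3; the radius (a swept hyperparameter of the method) was
selected on validation AUROC — tighter subgraphs keep a site's own
neighbourhood from being averaged away by the attention readout. The
default `GraphConfig` radius stays at the published 8 Å.

The label-shuffle control permutes training and validation labels while
scoring against true test labels. It trains the full epoch budget and
keeps the final model rather than early-stopping: with shuffled labels
the validation AUROC is pure noise, and selecting a "best" epoch on
noise resurrects a transient, partially initialized model whose outputs
still correlate with input magnitude (empirically ~0.7 test AUROC a few
epochs in, decaying to chance at convergence). The structure ablation
(`no_gcn`) measures how much of the planted signal is reachable through
the two-token sequence query alone.

Distillation uses the mean probability of the five cross-validated fold
models as the teacher signal (averaging removes single-model wiggle
while keeping the signal the folds agree on) and a ±7-residue window
query (plus the global token) as the student input. On this benchmark
the student reaches teacher-level classification performance, but its
pointwise probability fidelity saturates near Pearson r ≈ 0.75: the
teacher's scores carry genuine structural information — the amino-acid
composition and topology of the site's 3D neighbourhood, which includes
sequence-distant residues — that no local-window sequence model can
reconstruct. This is the flip side of the large structure-ablation gap:
the more the graph branch contributes, the less reproducible the
teacher's probabilities are from local sequence context. Full-scale
protein-language-model embeddings soften this in the real system by
attending over the whole sequence.

## Numerical choices and limitations

- The neural core runs on a small reverse-mode autodiff engine over
  float64 numpy arrays, written for this package; gradients are verified
  against central finite differences in the tests. Exact run-to-run
  reproducibility on one machine is a design goal; bitwise equality
  across BLAS implementations is not guaranteed.
- Dropout masks are drawn from the training RNG; evaluation is
  deterministic.
- Checkpoints are single `.npz` archives holding the config JSON, all
  named parameter tensors and metadata, versioned.
- Multi-chain structure files use the first polymer chain (warning);
  non-standard residues map to X, get an all-zero amino-acid one-hot
  (warning) and are not site candidates. Experimental B-factors are
  accepted as a pLDDT stand-in, which changes the meaning of that
  feature and should be kept in mind off the AF2 convention.
- How the independent negative sets should be aggregated into one
  reported number is left to the caller: results are reported per
  negative set and per fold, plus their mean.
- The greedy identity clustering is not cd-hit: it has no short-word
  filter and its anchored identity is ungapped, so indel-heavy homologs
  may escape clustering at the same nominal threshold.
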