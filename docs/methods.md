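# Methods

This note documents the models and procedures implemented in `mirgo`, the
parameters that matter, the design decisions taken where the problem was
genuinely open, and what the synthetic fixture does and does not show.

## The global heterogeneous network

The vertex set mixes two molecule kinds, internally namespaced as
`mirna:<id>` and `protein:<id>` so gene symbols can never collide with miRNA
names. Three edge populations fill the block adjacency `[[M, MP], [MPᵀ, P]]`:

* **Co-expression (M).** Pearson correlation between mature-miRNA expression
  profiles, computed on pairwise-complete observations with a minimum overlap
  of 3 samples (`min_overlap`). Pairs with non-positive or undefined PCC
  (constant profile, too few shared samples) produce no edge; a zero weight
  is indistinguishable from no edge in a weighted walk, so zero-PCC pairs are
  dropped together with the negative ones. An optional floor (`pcc_min`,
  default 0 = no pruning) can sparsify the near-dense positive-PCC graph.
  Expression is supplied at precursor level; rows mapping to the same mature
  miRNA are averaged entry-wise (NaN-aware) first.
* **Protein interactions (P).** STRING-style combined scores in
  [0, `score_scale`], rescaled by `1/score_scale` (default 1000) so all three
  blocks share a [0, 1] weight scale. Duplicate rows keep the maximum score;
  self-pairs are dropped.
* **Targets (MP).** Validated miRNA–target pairs become weight-1.0 edges
  (the source databases assign no strength). Target proteins absent from the
  PPI namespace are kept as vertices and counted in the log.

Invariants enforced and tested: symmetry, weights in (0, 1], no self-loops,
edge-count conservation per block.

## Random-walk embedding

`walks_per_node` (γ, default 100) truncated walks of `walk_length` (t,
default 80) start from every vertex; the node visit order is reshuffled each
outer pass. The next node is drawn from the current node's neighbors with
probability proportional to edge weight — the networks are weighted, so the
walk should use the weights; `--unweighted` restores uniform choice.
Isolated vertices yield the degenerate length-1 walk, so **every** input
node receives a feature vector (this matters for the PPI ablation below).

The walk corpus trains a SkipGram model with hierarchical softmax. The
output vocabulary is arranged as a Huffman tree on corpus frequencies (ties
broken by lexicographic node id for determinism), giving expected path
length near the entropy bound and at most ⌈log₂|V|⌉+1 for balanced counts.
The probability of a context node is the product over its root path of
per-branch sigmoids σ(±Φ(vᵢ)·Ψ(bₗ)); by construction the probabilities of
all leaves sum to exactly 1, which the tests verify exhaustively up to 64
leaves. The per-pair loss gradient is σ(x)−(1−c) with x = Φ·Ψ and branch
code c; analytic gradients are checked against central finite differences.

Training is plain single-threaded SGD: Φ initialized Uniform(−0.5/d, 0.5/d)
from the seed, Ψ initialized at zero, learning rate decaying linearly from
0.025 to 1/100 of that over all scheduled updates. The gradients of all
context pairs of one center position are applied as a single vectorized
step (a mini-batch per center); this changes the update order relative to
pair-by-pair SGD but not the objective, and keeps the trainer deterministic
and fast in pure numpy. Bit-reproducibility under a fixed seed is a tested
guarantee; there is no parallel mode.

The embedding dimensionality `d` defaults to 512 and is *not* restricted to
powers of two — the hierarchical softmax places no such constraint on d.

## GO handling and training sets

The ontology is read from OBO 1.2 (via `obonet`); `is_a` and `part_of` are
the propagating relations (GO has no "has a" relation; `part_of` is the
closest real relation and the configurable default). Obsolete terms are
flagged and excluded from closures, alt_ids map to canonical ids, and a
cycle among propagating relations is a hard error.

Annotations come from GAF 2.x; rows with excluded evidence (default: IEA,
keeping only curated annotations) or a NOT qualifier are dropped.
Propagation closes each entity's term set under ancestors (the true-path
rule). The three namespace roots are excluded from propagated sets and from
all evaluation sets by default — including them would inflate precision for
free; `keep_roots` restores them.

Per-term training sets: positives are the entities annotated to the term
after propagation (propagating training labels is the default; a raw-label
mode exists). The negative pool contains entities with at least one
annotation that are annotated neither to the term nor to any of its
descendants — an entity annotated to a child is a positive under the
true-path rule and must never be a negative. Negatives are sampled uniformly
without replacement, |neg| = min(|pos|, pool). Terms with fewer than
`min_pos` (default 10) positives are skipped so that 10-fold CV keeps at
least one positive per fold. Sequence-level preprocessing of annotation
databases (length filters, identity clustering) is upstream of this package;
the annotation file is taken as already de-duplicated.

## Classification and calibration

One binary RBF-SVM per term, fit on embedding vectors. The hyper-parameter
grid is C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and kernel width ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}
(log₂ step 2), selected by stratified 10-fold cross-validated accuracy —
with balanced classes, accuracy equals balanced accuracy. Ties go to the
smaller C, then the smaller width, so regularization is preferred and the
selection is deterministic. Scores in [0, 1] come from a Platt-style
sigmoid fitted on out-of-fold decision values
(`CalibratedClassifierCV(SVC, method="sigmoid", ensemble=False)` with up to
5 stratified folds); calibration is per term. In the degenerate case of
fewer than two samples per class the score falls back to the logistic of
the raw decision value, which is 0.5 exactly on the boundary. Terms are
scored one-vs-rest and fully independently; no hierarchical consistency
correction is applied to scores, because the evaluation applies ancestor
closure itself.

## Evaluation

For each miRNA and threshold t, the predicted set is the ancestor closure of
all terms scoring ≥ t, roots excluded. Precision for a threshold averages
over the m(t) miRNAs with a nonempty predicted set; recall averages over all
N benchmark miRNAs, so a miRNA with no prediction contributes recall 0 but
does not dilute precision. F(t) is defined as 0 when Pre(t)+Rec(t)=0.
The threshold grid is 0.00–1.00 in steps of 0.01; F_max takes the smallest
threshold on ties. Coverage is the count of miRNAs with at least one correct
term at the F_max threshold. Evaluation defaults to the biological-process
namespace (`namespace="all"` evaluates everything). The paired comparison
draws `draw_size`=50 miRNAs without replacement, `reps`=30 times, computes
each method's F_max per draw, and applies a two-tailed paired t-test; two
identical methods return (t=0, p=1) rather than the 0/0 statistic.

Numerical conventions worth noting: thresholds are compared with ≥ (a score
exactly at the threshold is included, so t=1.0 keeps only perfect scores);
F_max ties break to the smaller threshold; sweep rows with m(t)=0 are
recorded but flagged unusable.

## The synthetic fixture

The generator plants one community structure across all data layers:

* **Expression:** a community latent-factor Gaussian model,
  x = √ρ_out·g + √(ρ_in−ρ_out)·f_c + √(1−ρ_in)·ε per sample, so the expected
  within-community PCC is ρ_in (default 0.7) and between-community ρ_out
  (default 0). Each mature miRNA has 1–2 precursors whose rows are the
  mature profile plus small noise.
* **PPI:** a stochastic block model (p_in=0.3, p_out=0.02) with STRING-like
  integer scores (within-block ≈ 900, between ≈ 400).
* **Targets:** each miRNA draws 4 targets, staying in its own community with
  fidelity q=0.9, and only from the best-studied 20% of each community's
  proteins (`target_hub_frac`). This mirrors the sparse, hub-concentrated
  coverage of curated target databases and is what makes the
  protein-interaction block genuinely load-bearing: without it, the non-hub
  majority of proteins are isolated vertices whose embeddings carry no
  signal.
* **Ontology and annotations:** a two-level DAG of 12 BP terms (one root,
  one mid-level term per community, leaf terms distributed round-robin);
  proteins carry their community's leaf terms with probability 0.9, a
  wrong-community leaf with probability ε=0.05, occasional IEA rows and NOT
  rows that the annotation filter must remove. The planted miRNA truth is
  the ancestor-closed term set of its community.

The canonical scenario is 60 miRNAs, 120 proteins, 3 communities, 20
samples, seed 1. Paired with desk-scale pipeline settings (20 walks of
length 40, window 5, 64 dimensions, reduced C/γ grids) the full pipeline
runs in well under a minute per condition on one CPU; the full-scale
defaults (100/80/16/512, full grids) remain on the CLI for real inputs.

What the fixture shows: end-to-end recovery of planted structure, the
direction of the PPI ablation, monotone degradation with annotation noise,
and bit-stable reproducibility. What it does not show: performance on real
data. Real co-expression is not block-structured Gaussian, real GO has tens
of thousands of terms with heavy-tailed annotation counts, real target data
has study bias far messier than a fixed hub fraction, and real benchmark
F_max values are far below the near-perfect recovery seen here. Passing the
fixture validates the machinery, not the biology.

## Known limitations

* The SkipGram trainer is pure numpy; at the full scale of real inputs
  (~20k nodes, γ=100, t=80, d=512) it is CPU-days, not minutes. The
  algorithmic complexity matches the standard implementations (O(corpus ·
  w · log|V| · d)), but no native/parallel path is provided because
  bit-reproducibility was prioritized.
* Only Pearson correlation is offered for co-expression, and only
  `is_a`/`part_of` for propagation.
* Negative sampling, biased second-order walks, and alternative learners are
  out of scope by design.
* Calibrated scores are per-term; cross-term score comparability relies on
  the shared balanced-training design rather than a global calibration.
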