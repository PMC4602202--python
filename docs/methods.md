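# Methods

This note records the model, the numerical conventions, the design
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Gene functional similarity

Each of the eight genomic sources defines a raw similarity
$r_{gh} \in [0,1]$ between genes:

| source | gene representation | raw measure |
|---|---|---|
| Exp | expression profile across tissues | absolute Pearson correlation |
| GO | information contents of annotated terms | cosine |
| KEGG / Pfam / miRNA | binary membership vector (pathways / domains / target sets) | cosine |
| TSFC | TF binding-site counts in the promoter | cosine |
| Seq / PPI | node in an undirected network | $1 - d_{gh}/D$ over shortest paths |

The information content of a term is $-\log(n_t/N)$ over annotated
genes.  The logarithm base only rescales all coordinates uniformly and
cancels in the cosine; natural log is used and the invariance is asserted
in the tests.  The same argument covers the IDF base in the phenotype
model.

Raw similarities are transformed with

$$S_{gh} = \exp\!\big((r_{gh} - 1)/\sigma\big),$$

where $\sigma$ is the standard deviation of all **off-diagonal** raw
values — the structurally-unit diagonal is excluded so it cannot shrink
$\sigma$.  The transform fixes $r=1 \mapsto S=1$, is strictly increasing
in $r$ (rank-preserving; asserted via Spearman), and compresses weak
similarities towards zero, which is its purpose: background similarity
should contribute little to the association sums.  If all off-diagonal
raw values are identical ($\sigma = 0$) the transform is undefined and
the build fails with an explicit degenerate-input error.

Conventions for edge cases: a constant expression profile has undefined
Pearson correlation and gets raw similarity 0; pairs in different network
components get raw similarity 0, with $D$ the largest finite distance;
genes absent from a source keep all-zero rows/columns in the transformed
matrix (coverage = absence of evidence), so they contribute nothing to
association scores.  Sequence-network edges are consumed pre-thresholded
(alignment e-value below 1e-4 applied upstream); the threshold appears
only in fixture generation.

## Phenotype similarity and seed genes

Disease records arrive as counts of standardized clinical terms.
TF is the within-record relative frequency, IDF the negative log of the
fraction of records containing the term; phenotype similarity is the
cosine of the TF-IDF vectors.  All-zero records give zero vectors (with a
warning) and similarity 0 to everything.

Seed genes for a query disease are the union of genes associated with the
query and with its $k=10$ most similar diseases (the query is always
excluded from its own top-$k$ list; its genes enter through the union).
Ties at the $k$-th position break lexicographically by disease id so the
output is deterministic.  $k$ is a config default, overridable.

## Feature vector

The canonical order is fixed: 11 variant scores (SIFT, PolyPhen2, LRT,
MutationTaster, MutationAccessor, MSRV, GERP, Phylop, SiPhy, CADD,
SInBaD) then 8 association scores (Exp, GO, KEGG, Seq, Pfam, PPI, TSFC,
miRNA).  SIFT and LRT are flipped ($1-x$, on the value as stored in the
score table) before min–max normalization; bounds come from the whole
reference score table, not the candidate set, so scores are comparable
across runs.  Association-score bounds are likewise computed once from
the full disease × gene score table with unfiltered seed sets;
fold-level seed filtering only shrinks raw scores and clipping handles
anything out of range.  Out-of-range raw values are clipped rather than
rejected — new data may exceed historical bounds.  Missing features are
exactly 0.  Association features depend on the variant only through its
host gene, so same-gene variants share the last 8 coordinates by
construction.

Whether a candidate gene may sit in its own seed set is protocol-
dependent: cross-validation removes it through the leakage filters, and
free prioritization exposes `exclude_candidate_genes_from_seeds`
(default on, matching the unbiased real-application protocol of choosing
seeds that host no candidate).

## Training and cross-validation

Positives are distinct (disease, causative variant) associations.
Negatives are drawn uniformly without replacement from the Cartesian
product of training diseases × training-half neutral variants, the same
number as positives.  The forest uses 500 trees, $\sqrt{19}$ features
per split, unlimited depth, and a fixed seed; the positive-class
probability is the prediction score.  These hyperparameters are package
defaults (the method itself does not prescribe them) and are all
overridable.

Cross-validation holds out diseases: the diseases carrying positive
variants are shuffled (seeded), stably sorted by positive-variant count,
and dealt round-robin into five folds — deterministic, and balancing
variants rather than disease counts.  Neutral variants split into two
halves, one for training and one as the neutral test sample.  Two leakage
rules are applied per fold before feature assembly: training variants in
any gene hosting a test variant are discarded, and seed genes associated
with a test disease or hosting a test variant are removed.  A post-hoc
assertion checks that training and test gene sets are disjoint.

Each positive test variant is prioritized against the configured negative
sample (`neutral`, `disease`, or `combined`).  Ranks use the average-rank
tie policy: $1 + \#\{\text{strictly above}\} + \tfrac12\#\{\text{ties}\}$.

## Evaluation metrics

Rank ratio = rank / list length, in $(0,1]$; the list length is
(#negatives + 1) when one positive is ranked against a negative set.
MRR averages within disease, then unweighted across diseases.  The
rank-ROC traces sensitivity (positives at or below a rank-ratio
threshold) against 1 − specificity over the distinct observed thresholds
plus endpoints {0, 1}; its trapezoidal area equals the exhaustive
Mann–Whitney statistic, which serves as the independent oracle in tests.
FPR at a score threshold is the per-disease fraction of neutral variants
scoring at or above it, averaged unweighted across diseases.  The top-$k$
enrichment test is the one-sided hypergeometric tail
$P(X \ge x)$ for $x$ functional candidates among the top $n$ of $N$,
computed through log-gamma survival functions (never raw factorials) and
cross-checked against exhaustive draw enumeration for small $N$.
Top-$k$ counts use an integer cutoff after average-rank assignment.

## Synthetic universe

The generator plants a disease → gene → variant causal chain whose
strength is one dial, `signal_strength` $\in [0,1]$:

* diseases fall into clusters sharing a signature term vocabulary
  (70% of term tokens from the signature), so cluster mates are mutually
  most similar under TF-IDF cosine;
* each cluster owns a disjoint gene pool; disease modules sample from the
  own pool with probability `signal_strength`, else genome-wide;
* pool genes co-behave in every source: expression loads on a cluster
  latent factor with weight $0.85 \cdot \text{signal}$; signature
  GO terms / pathways / domains / miRNA sets include pool genes with
  probability proportional to signal over a 3–5% background; binding
  counts get a Poisson lift on signature factors; networks have dense
  within-pool edges over a sparse background;
* causative variants sit in truth-associated genes and draw functional
  scores from a deleterious-mode Beta(6,2) with probability equal to the
  signal (Beta(2,2) null otherwise, on each score's native scale);
  neutral variants use benign-mode Beta(2,6).  At signal 0 the two
  classes are exchangeable, which is what the null-band acceptance check
  exercises;
* 20% of score cells are masked missing by default, exercising the
  zero-imputation path (real score databases have large coverage gaps);
* disease-control variants — the stand-in for an external database of
  variants causative for *other* diseases — draw from hidden per-cluster
  modules that are not among the query diseases.  Sampling them from the
  query diseases' own modules would let the seed-gene leakage filter ban
  essentially every module gene and erase the association signal, which
  is not the situation the control emulates;
* the `all_deleterious` switch gives neutral variants deleterious-mode
  scores too, isolating the gene-level features: with it on, only
  guilt-by-association separates disease-specific positives from the
  disease control (checked by an ablation test using the
  `feature_subset` config).

Default sizes are 300 genes, 40 diseases (8 clusters), 40 tissues, 400
causative + 800 neutral + 200 disease-control variants, signal 0.8 —
small enough that a full five-fold cross-validation runs in seconds,
large enough that per-disease metrics are stable.  Generation is fully
deterministic given the seed (serialized output is byte-identical across
repeats on one platform; across platforms, floating-point formatting of
the TSVs is the only caveat).

What passing the planted-signal benchmark shows: the whole pipeline —
similarity construction, TF-IDF seeds, feature assembly, leakage rules,
training, ranking, metrics — recovers a known signal and stays at chance
under the null.  What it does not show: performance on real data.  The
universe has no allele-frequency spectrum, no population structure, no
correlated missingness, no annotation noise, and its sources are
conditionally independent given the cluster structure, which is far
cleaner than real genomic evidence.

## Known limitations

* The exponential and shortest-path linear transforms follow the stated
  qualitative constraints (unit fixed point, monotonicity, weak-similarity
  suppression); equivalent forms satisfying the same constraints would
  differ only in calibration.
* Association scores are normalized per source; raw sums are not
  comparable across sources with different seed-set sizes.
* The `disease` negative protocol requires an external disease-control
  variant set; with none supplied the run refuses rather than silently
  reusing training positives.
* Variant effect annotation (host-gene assignment) and the functional
  scores themselves are consumed as inputs, never recomputed.
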