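# Methods

This note documents the statistical procedures, the choices made where the
design was genuinely open, the synthetic data the tests run on, and what
passing those tests does and does not establish.

## Domain-pair log-odds

For an interaction set I and a proteome with per-protein unique domain sets,
each interacting pair (P, Q) contributes every unique unordered combination
of P's and Q's domains once to the pair counts n(Dx, Dy); n_p is the total of
those counts. Marginal counts n(Dx) run over the *set* of proteins appearing
in at least one interaction — a protein in k interactions still contributes
each of its domains once. The score is

    LOD(Dx, Dy) = ln[ (n(Dx,Dy)/n_p) / ( (n(Dx)/n_c) · (n(Dy)/n_c) ) ]

with n_c the total of the marginal counts. Choices:

- **Natural log** throughout (the downstream semantic-similarity and
  literature scores are defined with ln; log base only rescales the feature
  monotonically and cannot change forest behaviour).
- **Set-level marginals**: "occurrences among interacting proteins" is read
  per protein, not per interaction membership. The alternative (weighting a
  protein by its degree) changes marginal frequencies for hubs; the set-level
  reading is the plain one and is what the worked 4-protein example in the
  test suite pins down.
- **Self-interactions are counted** here (a self-pair contributes the
  unordered combinations of a protein's domain set with itself). Exclusion
  rules apply only in the downstream network stages.
- **Unobserved pairs score exactly 0** on lookup and are absent from the
  table: absence of evidence is treated as no evidence, not negative
  evidence.

Both frequency tables normalise to 1 by construction; the test suite checks
this to 1e-12 and checks the whole table against a brute-force cross-product
counter on random toy instances.

## Features and orientation handling

The domain block of the feature vector (LOD sum / max / min-ceilinged-at-0,
scored and unscored combination counts, DOMINE hit count and max confidence)
is order-invariant; combinations are iterated in sorted order so the floating
sums are bit-identical between (a, b) and (b, a). "Minimum ceilinged at 0"
means min(0, min scored LOD): the feature is never positive, and 0 when all
scored combinations have positive LOD. A pair with no scored combinations has
an all-zero domain block (0 is the neutral LOD), not sentinel values.

Localization blocks are order-sensitive, so every pair appears twice in the
design (forward and block-swapped). At prediction time both orientations are
scored and combined by max — the union rule: thresholding the max equals the
union of the two orientations' thresholded calls at every cut-off
simultaneously. A mean combiner is available (`combine="mean"`) but is not
the default. Missing localization vectors are an error by default; an opt-in
mode zero-fills and appends a presence-indicator feature.

## Training protocol

Defaults follow the published protocol sizes: 1,330 positives, 101,300
uniform negatives, 1,300 degree-proportional "spiked" negatives, 400 fully
grown trees. The spike guards against the forest learning to recognise the
localization signature of frequently studied proteins rather than pairwise
compatibility. Sampled negatives are unordered pairs of distinct proteins,
rejected against the positives, a user-supplied exclusion list (the
generalisation of a pathway-database negative filter), and one another.
Forest backend is scikit-learn's RandomForestClassifier with
n_estimators=cfg.n_trees, no depth limit, min_samples_leaf=1; remaining
hyperparameters are the backend's classification defaults and are recorded in
the trained model's config. Confidence is the standard forest probability
(fraction of trees voting positive). Tests and the acceptance script use a
scaled protocol suited to a 200-protein synthetic proteome — 300 positives,
3,000 uniform plus 150 spiked negatives, the full 400 trees — chosen so the
class imbalance ratio (~10:1) is preserved at desk scale.

Prediction enumerates all n(n+1)/2 unordered pairs including self-pairs,
partitions them into fixed-size chunks, and scores chunks across threads;
the partition and merge order are deterministic, so output is independent of
thread count (asserted byte-for-byte in the tests).

## Randomization nulls

Two null models are used, deliberately distinct:

- **Degree-preserving rewiring** (pathway linkages, disease associations,
  functional-similarity and co-expression nulls): double edge swaps, 10×|E|
  attempted swaps per replicate, rejecting swaps that would create self-loops
  or multi-edges. Degree sequences are conserved exactly and are asserted per
  replicate in the tests. Edge swaps were chosen over stub-matching because
  they stay inside the simple-graph space without rejection loops.
- **Degree-proportional resampling** (disease literature null): new networks
  with the observed edge count whose endpoints are drawn with probability
  proportional to observed degree — similar degree distributions without
  conditioning on the exact sequence.

The linkage exceedance rule is strict: a pathway (or disease) pair is
retained only if its observed supporting-interaction count strictly exceeds
the count in at least `quantile · n_random` replicates; ties count against
retention, and with discrete counts this makes the rule conservative.
Empirical p-values are floored at 1/(n_random + 1).

## Pathway linkage network

Predicted self-interactions never support a linkage. A protein belonging to
both pathways of a pair contributes an interaction once if its partner lies
in the other pathway; pairs of a protein with itself are excluded. Edge
weights divide the observed count by the number of possible non-self
inter-pathway pairs, |A||B| − k − k(k−1)/2 with k = |A ∩ B|. Compound sharing
discounts compounds present in more than 15 pathways (ubiquitous currency
metabolites carry no linkage information); its null randomizes the *linkage*
graph itself, degree-preservingly.

MCL is implemented directly (dense numpy): expansion power 2, inflation 2.0,
prune threshold 1e-5, self-loops with weight equal to the node's maximum
incident weight for aperiodicity, iteration until the column-stochastic
matrix changes by less than 1e-6, clusters read off attractor rows with
overlaps merged to the lowest cluster index. No MCL library is available in
the dependency set; correctness is pinned by structural oracles
(disconnected components, a bridged two-clique instance that must split at
the bridge).

Cluster enrichment uses annotation counts: each pathway annotates every
ontology node that is an ancestor of (or equal to) one of its classes, one
annotation per (pathway, node) pair. For node t and a cluster, M_t = pathways
annotated at/below t, M_g = the cluster's total annotation count, M_gt = the
cluster's annotations at t, M_tot = all annotations; the p-value is the exact
hypergeometric upper tail computed with integer arithmetic, and Bonferroni
significance is 0.05 / (n_clusters · n_ontology_nodes). This corrects the
bias of a per-pathway Fisher test toward heavily annotated branches. The
implementation agrees with an exhaustive subset-enumeration oracle as exact
rationals for all parameter combinations with M_tot ≤ 12.

## Disease network and literature score

Disease pairs are candidate-linked through predicted interactions between
their causative gene sets (self-interactions never count; diseases without a
mapped MeSH-style term are dropped first) and retained under the same
exceedance rule. The literature score multiplies the PMID-set overlap
fraction |Px ∩ Py| / min(|Px|, |Py|) by −ln of the *worse* of the two
disease–term association p-values; it is symmetric, non-negative, and zero
when either the PMID sets are disjoint or either mapping is maximally
insignificant. The one-sided KS statistic is D = sup_x [F_ref(x) − F_obs(x)]
for the alternative "observed scores are stochastically larger"; the p-value
is the standard one-sided asymptotic bound exp(−2nmD²/(n+m)). The statistic
is verified against a brute-force pooled-grid supremum and scipy's one-sided
two-sample statistic.

## WGD retention model

    retained ~ log(DC) + DN + log(DC):DN,   logit link

with DC the degree centrality d(n)/(N−1) on the thresholded prediction
network and DN the fraction of a gene's neighbors retained in duplicate.
Genes are filtered at min_degree ∈ {1, 10}; the 10-neighbor fit exists
because a single-neighbor gene forces DN into {0, 1}. Fitting is maximum
likelihood (statsmodels Logit); uncertainty is a case-resampling bootstrap
with percentile intervals at 95/99/99.9% and stars by CI exclusion of zero —
resampled replicates with a single response class are redrawn (counted,
capped). CI exclusion rather than Wald tests matches the resampling-based
significance the model is defined with.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-condition module, not a test fixture:

- **Proteome**: 200 proteins, 40 domain families with mildly skewed
  popularity, 1–3 unique domains per protein, four compartment archetypes;
  localization vectors are archetype profiles plus Gaussian noise (sd 0.15),
  schema matching the default compartment/subprogram feature list.
- **Interactome**: the logit of interaction probability is a hidden
  domain-pair affinity sum plus a co-compartment bonus (1.5) plus an
  intercept calibrated by root-finding so the expected edge count is 600.
  Affinities are dense — each domain pair carries one with probability 0.25,
  magnitudes Gamma(2, 1) — so the generative probability varies continuously
  across pairs and rank-recovery of the signal is a meaningful target. A
  `misspecified` mode drives interactions from a latent per-protein
  compatibility invisible to domain features, emulating interactions the
  domain-based classifier cannot see.
- **Annotations**: ontology terms, pathway memberships and expression
  profiles follow the interaction graph under coherence knobs in [0, 1];
  knob 0 makes the corresponding downstream null true. The pathway-linkage
  control network places most background edges *within* pathways (as in real
  interactomes) plus a thin uniform cross-pathway layer (20 edges) and 14
  planted cross edges per planted pathway pair; intra-pathway edges never
  support a linkage but feed the degree-preserving null, which suppresses
  chance cross-pathway overdensities.
- **Retention flags**: for coverage tests, covariates (Zipf-distributed
  degrees, Beta(2,2) DN) and responses are drawn directly from the logistic
  model with gene-balance-signed coefficients (−2.0, −0.2, +5.0, +0.6); on
  graphs, flags are drawn by Gibbs sweeps of the same model, which captures
  the signs but is not an exact likelihood (and is only tested for signs).

What passing the suite shows: the statistics are computed correctly (oracle
equivalence), the nulls conserve what they claim to conserve, and the
pipeline recovers planted signal of realistic shape at realistic sizes. What
it does not show: performance on real proteomes — real domain frequency
spectra are heavier-tailed, real GO DAGs far deeper, real interaction data
biased toward well-studied proteins, and real localization predictors
imperfect in structured ways the archetype-plus-noise model does not emulate.

## Numerical and scale choices

- All randomness flows from numpy SeedSequence spawning; every output table
  is written in sorted order with `repr` floats, so equal seeds give
  byte-identical files.
- Problem sizes in tests and the acceptance script: 200-protein proteome for
  the end-to-end run; n_random = 200 at quantile 0.995 for the 20-seed
  linkage recovery checks and 1,000 at 0.999 for the single acceptance run;
  1,000 bootstrap replicates (of the 10,000 default) for the GLM recovery
  repetitions. These are the package's desk-scale defaults for synthetic
  validation; the full-size defaults remain in the public APIs.
- Degenerate inputs: graphs too constrained to rewire are returned unchanged
  with a warning; ontology terms with zero annotation probability are dropped
  from similarity with a warning rather than yielding infinities; zero
  sensitivity/specificity denominators return None rather than NaN.

## Known limitations

- The MCL attractor-reading heuristic assigns pruned-out nodes to their
  strongest column entry; exotic near-periodic weighted graphs may need the
  max_iter/tol knobs.
- The spiked-negative sampler can exhaust its rejection budget on very dense
  positive sets; the error suggests reducing the spike count.
- The one-sided KS p-value is asymptotic; at very small sample sizes it is
  conservative.
- Localization schemas are free-form: the package validates consistency
  within a proteome but cannot validate that a user's columns mean what a
  localization predictor's would.
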