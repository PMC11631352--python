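# Methods

`organaudit` is a toolkit for auditing and repairing the annotation of
organelle (mitochondrial 12S / chloroplast) rRNA amplicons in 16S microbiome
studies. Mitochondria and chloroplasts descend from free-living bacteria and
carry small-subunit rRNA genes that common V4 primer pairs co-amplify.
When a reference taxonomy contains organelle sequences similar to the ones
in a sample, those reads are labelled `Mitochondria`/`Chloroplast` and can
be filtered before analysis. When the sample carries *divergent* organelle
variants — dietary or symbiont mitochondria, heteroplasmic variants, NUMTs —
annotation often fails and the reads surface as `Unassigned` at domain
level. Because amplicon data are compositional, group-varying loads of such
cryptic reads bias relative abundances, alpha/beta diversity, and the tests
run on them. The remedy implemented here: extend the reference taxonomy
with diverse organelle rRNA sequences trimmed to the amplified region, so
cryptic reads classify as organelles and can be removed uniformly.

## Reference extension

`extend_reference` performs an in-silico PCR on each candidate organelle
sequence: the forward primer is located by exact IUPAC-degenerate matching
(`max_mismatch` substitutions allowed, default 0) on either strand, the
reverse-complemented reverse primer downstream of it, and the inter-primer
core is kept when its length lies in `[min_amplicon_len, max_amplicon_len]`
(defaults 100/500 nt; an optional 5'-anchored truncation to a fixed length
emulates pipelines that trim reads to 100 nt). The default primers are the
V4 pair 515f `GTGTGCCAGCMGCCGCGGTAA` / 806r `GGACTACHVGGGTWTCTAAT` as used
by the study protocols this toolkit targets; the forward primer is kept
verbatim even though it is two bases longer than the canonical 515f.
Extracted amplicons are filed under the dialect's canonical organelle
lineage — SILVA: `d__Bacteria; p__Proteobacteria; c__Alphaproteobacteria;
o__Rickettsiales; f__Mitochondria` and `...; o__Chloroplast`; Greengenes:
the same placement with `k__` and lowercase `mitochondria` — mirroring
where each release already files organelles, with the host's genus/species
appended when known. Exact (sequence, lineage) duplicates are skipped; id
collisions get a `.dupN` suffix so divergent taxonomic evidence is never
silently dropped. Organelle detection in any lineage is a case-insensitive
token match on `mitochondria`/`chloroplast`, making audits dialect-proof.

## Classifiers

Both classifiers are deliberate reimplementations of the two standard
annotation methods, built as scikit-learn-style estimators so they compose
with sklearn tooling.

**Consensus (`ConsensusTaxonomyClassifier`).** Queries are searched against
the reference with a shared-8-mer prefilter (top 50 candidates, ties broken
by id) followed by pairwise alignment. Search alignments are *query-global*
(the query aligns end to end, reference flanks are free), the semantics of
a vsearch-style global database search; identity is matches over alignment
columns excluding terminal gaps, with internal gap columns counted. Hits
with identity ≥ `perc_identity` (default 0.80), up to `maxaccepts`
(default 10), vote rank by rank: a rank is kept while a unique plurality
label reaches `min_consensus` (default 0.51); plurality ties fail the rank.
The reported score is the consensus fraction at the deepest kept rank; a
query with no accepted hits is `Unassigned`.

**Naive Bayes (`NaiveBayesTaxonomyClassifier`).** A multinomial naive
Bayes over overlapping k-mers (k = 7, as-written orientation), one class
per distinct full lineage, counts pooled within class, additive smoothing
`alpha = 0.001`, uniform priors. Instead of bootstrap resampling,
confidence is computed in closed form by aggregating posteriors up the
taxonomy: at each rank the label with maximal posterior mass is chosen and
its mass is the confidence; the lineage stops at the deepest rank with
confidence ≥ `confidence` (default 0.70). This is deterministic and
monotone: raising the threshold can only shorten lineages. Tests cross-check
the posteriors against sklearn's `MultinomialNB` on pooled per-class counts.

**Alignment scoring.** Match +1, mismatch −1, linear gap −2, computed with
Biopython's `PairwiseAligner` over a substitution matrix in which two IUPAC
codes match when their base sets intersect. The public
`semiglobal_align` defaults to an overlap alignment (terminal gaps free on
both sequences); it backs the positive filter, whose explicit coverage
threshold gives partial overlaps meaning. An independent dynamic-programming oracle
in the test suite checks the optimal scores.

**Positive filter.** The Deblur-style screen keeps a query iff some
sequence in a trusted rRNA set reaches identity ≥ 0.65 *and* coverage
≥ 0.50 (both inclusive). It shares the prefilter-and-align machinery but
applies no identity acceptance cutoff during search.

## Auditing

`composition_summary` partitions each sample's reads into Unassigned /
mitochondria / chloroplast / other using the lineage flags; zero-read
samples are flagged and excluded from proportions. "Unknown" means
`Unassigned` at domain level — partially resolved lineages are not unknown.
`reclassification_flow` accumulates read mass into (label under base) →
(label under extended) cells, with organelle labels overriding the rank
label. `filter_organelles` removes organelle rows without renormalizing,
so every pairwise log-ratio of retained features is bit-identical before
and after filtering — the formal reason compositional (CLR/Aitchison)
analyses are resistant to organelle contamination. `unknown_fold_change`
reports per-sample fold-reductions of the unknown fraction; an extended
fraction of 0 with positive base counts as ∞ (≥ any threshold) and samples
with base fraction 0 are excluded from the denominator. Read-proportion
folds are the default; unique-feature folds are available behind a flag
(`unique_feature_summary`).

## Diversity

Conventions follow the common amplicon diversity stack: Shannon in bits;
Simpson's evenness E = (1/Σp²)/S_obs (the inverse-Simpson-over-richness
variant, recorded here because the name is ambiguous in the literature);
Faith's PD includes the path to the tree root; rarefaction subsamples
without replacement to a fixed depth (default 1000 reads) and drops
shallower samples. Jaccard, Bray–Curtis and both UniFracs run through
scikit-bio/scipy; Aitchison is the Euclidean distance of CLR-transformed
unrarefied counts + pseudocount 1. Kruskal–Wallis (tie-corrected H,
chi-square p) tests alpha metrics; one-way PERMANOVA (seeded, p = (1 +
#{F_perm ≥ F_obs})/(1 + permutations), default 999 permutations — higher
precision available via flag) tests distance matrices. Effect size is the
test statistic itself (H or pseudo-F). `compare_conditions` pairs
base/extended results, reporting effect-size fold-changes (ext/base),
p-value shifts (ext − base) and α = 0.05 crossings; raw p-values are
primary, with a clearly-labelled Benjamini–Hochberg column alongside.

A subtlety worth recording: with few samples, sampled label permutations
occasionally reproduce the observed partition, so even perfectly separated
clusters give p slightly above the 1/(permutations+1) floor; the test
suite checks the exact enumerated null at n = 6 (exact p = 2/20) and the
floor at n = 24.

## The synthetic benchmark

The `simulate` module generates every fixture the tests need; all
generators are pure functions of (spec, seed).

* **Bacterial reference** — a 3-phyla × 4-genera × 3-species hierarchy of
  250-nt amplicons: independent random phylum roots, genus ancestors at
  half the between-phylum divergence (default 0.30) from their root,
  species at half the within-genus divergence (default 0.03) from their
  genus ancestor, plus a matching newick tree.
* **Organelle pool** — 12 variants radiating from a latent ancestral
  amplicon kept below 0.75 identity to every bacterial reference
  (rejection-sampled), each variant at divergence 0.20 from the ancestor —
  within the range reported for intra-individual 12S heteroplasmy — so any
  two variants are ~0.65 identical. The first quarter of the pool forms
  the base reference's organelle content; the rest are the cryptic
  variants. Pool records carry concrete primer flanks so reference
  extension exercises the in-silico PCR end to end.
* **Study** — two groups × 10 samples × 500 reads sharing one true
  bacterial community (per-sample Dirichlet-multinomial, concentration 50)
  but differing in organelle load (5% vs 30%), organelle reads drawn with
  4:1 preference for cryptic variants, and residual per-base substitution
  error 0.001 (feature tables emulate *denoised* ASV tables, hence the low
  rate). Identical reads collapse to features; ground truth records every
  feature's origin.
* **Controls** — a three-community toy example (three microbes at one read
  each plus light/dark mitochondrial variants at varying counts) whose
  apparent focal abundance is reported under no / partial / perfect
  filtering; organelle-free mock communities; per-character shuffled
  sequences (composition-preserving artifacts). The shuffled-sequence
  negative control is asserted for the consensus classifier only — a
  k-mer naive Bayes can recognize even shuffled organelle sequences by
  nucleotide composition, so it is exempt by design.

What the generator does *not* emulate: chimeras, indel errors, quality
scores, primer read-through, real 12S secondary-structure conservation, or
the long-tailed abundance distributions of environmental communities.
Passing benchmarks therefore demonstrate the mechanics of cryptic-read
recovery and its downstream statistics, not classifier accuracy on real
organelle diversity.

## Benchmark scales and numerical choices

The default benchmark sizes keep the whole suite desk-scale: the recovery
experiment classifies ~2200 unique features against 39- and 48-entry
references; the mock-community control uses 4 samples × 250 reads (mock
consortia are small by construction); the type-I-error simulation runs 500
PERMANOVA replicates (16 iid samples, 999 permutations); the
diversity-bias replication runs 200 replicate studies with error-free
reads so the fixed feature universe is classified once. Rarefaction in the
bias replication uses depth 50, below the worst-case post-filter sample
total. Ties are broken deterministically everywhere (lexicographic ids for
alignment ties, lexicographic labels for posterior ties); every stochastic
step takes an explicit seed and defaults to 0, never wall-clock.

## Known limitations

* The consensus classifier's prefilter is exact only while the reference
  fits the candidate budget (50 by default); oracle-equivalence is
  guaranteed and tested in that regime, which covers the synthetic
  benchmark but not release-scale references.
* Bootstrap (RDP-style) confidence, SortMeRNA's seed indexing, chimera
  detection and protein-space search are out of scope.
* Lineage placement of added organelles is fixed per dialect; hosts whose
  organelles are already filed elsewhere in a base release are not
  reconciled.
* PERMANOVA is the one-way formulation only.
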