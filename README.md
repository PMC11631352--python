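# organaudit

Organelle-aware taxonomy auditing for 16S rRNA amplicon studies.

Mitochondria and chloroplasts carry rRNA genes that standard V4 primers
(515f/806r) co-amplify alongside bacterial 16S. Reference taxonomies contain
only a thin sample of organelle diversity, so divergent ("cryptic")
mitochondrial reads — from diet, symbionts, heteroplasmy, or NUMTs — often
surface as `Unassigned` instead of `Mitochondria`. Because amplicon data are
compositional, sample-varying loads of such reads distort relative
abundances and alpha/beta-diversity comparisons, especially in cross-species
surveys. `organaudit` implements the remedy and the audit around it:

* **extend** a base reference taxonomy (SILVA or Greengenes lineage
  dialects) with organelle rRNA sequences trimmed in silico to the
  amplified region;
* **classify** amplicon sequence variants with two in-repo classifiers — an
  alignment top-hit **consensus** classifier (hits with identity ≥ 0.80
  vote rank-by-rank at ≥ 51% consensus) and a k-mer multinomial
  **naive-Bayes** classifier (k = 7, additive smoothing, posterior-mass
  confidence per rank) — plus a SortMeRNA-style **positive filter**
  (≥ 65% identity and ≥ 50% coverage to a trusted rRNA set);
* **audit** feature tables: per-sample Unassigned/organelle composition,
  base-vs-extended reclassification flows, organelle filtering, and
  fold-changes in unknown content;
* **quantify diversity effects**: rarefaction, four alpha metrics
  (observed features, Shannon, Simpson's evenness E, Faith's PD), five
  beta metrics (Jaccard, Bray–Curtis, Aitchison, unweighted/weighted
  UniFrac), Kruskal–Wallis and PERMANOVA, and base-vs-extended tables of
  effect-size folds and p-value shifts;
* **simulate** complete synthetic studies with controllable cryptic
  organelle content, for benchmarking the whole workflow end to end.

The package is aimed at microbiome bioinformaticians who suspect (or want
to rule out) cryptic organelle contamination in their own or published
amplicon datasets.

## Worked example

```python
from organaudit import (
    SimSpec, PrimerPair, ConsensusTaxonomyClassifier,
    generate_reference, generate_organelle_pool, simulate_study,
    extend_reference, composition_summary, unknown_fold_change,
)
from organaudit.simulate import study_query_records

spec = SimSpec()                       # 3x4x3 reference, 12-variant pool,
db, tree = generate_reference(spec)    # 2 groups x 10 samples x 500 reads
pool, base_ids = generate_organelle_pool(spec, db)

primers = PrimerPair()                 # V4 515f/806r defaults
base = extend_reference(db, [r for r in pool if r.id in base_ids],
                        "mitochondria", primers)
ext = extend_reference(db, pool, "mitochondria", primers)

queries, table, metadata, truth = simulate_study(spec, db, pool, base_ids)
recs = study_query_records(table, truth, queries)

a_base = {c.feature_id: c for c in
          ConsensusTaxonomyClassifier().fit(base).predict_classifications(recs)}
a_ext = {c.feature_id: c for c in
         ConsensusTaxonomyClassifier().fit(ext).predict_classifications(recs)}

fc = unknown_fold_change(composition_summary(table, a_base),
                         composition_summary(table, a_ext))
print(f"{fc.n_at_least_threshold}/{fc.n_evaluable} samples improved >= 10-fold")
```

Output:

```
20/20 samples improved >= 10-fold
```

Under the base reference every cryptic mitochondrial read in this benchmark
is `Unassigned`; under the extended reference all of them classify as
mitochondrial, non-organelle annotations are untouched, and the unknown
fraction of every sample drops more than ten-fold.

The same workflow is available from the shell:

```bash
organaudit simulate study --seed 1 --out-dir sim
organaudit extend-db --base-seqs sim/reference.fasta --base-tax sim/reference.tax.tsv \
    --dialect silva --organelle-seqs sim/organelle_pool.fasta \
    --organelle-kind mitochondria --out-prefix ext
organaudit classify --method consensus --ref-prefix ext \
    --queries sim/queries.fasta --out assignments.tsv
```

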