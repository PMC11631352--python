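import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from organaudit.align import semiglobal_align
from organaudit.io import SequenceRecord
from organaudit.refdb import PrimerPair, extend_reference, extract_amplicon
from organaudit.simulate import (SimSpec, fig1_apparent_abundance,
                                 generate_mock_fixture, generate_organelle_pool,
                                 generate_reference, organelle_ancestor,
                                 organelle_core, shuffle_sequences,
                                 simulate_fig1_communities, simulate_study)


class TestSimSpec:
    def test_divergence_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimSpec(within_genus_divergence=0.4, between_phylum_divergence=0.3)

    def test_invalid_load_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(organelle_load_by_group={"g": 1.5})


class TestGenerateReference:
    def test_entry_count(self, small_spec, small_reference):
        db, _ = small_reference
        assert len(db) == (small_spec.n_phyla * small_spec.genera_per_phylum
                           * small_spec.species_per_genus)

    def test_seed_reproducible(self, small_spec, small_reference):
        db, newick = small_reference
        db2, newick2 = generate_reference(small_spec)
        assert newick == newick2
        assert all(db.record(i).seq == db2.record(i).seq for i in db.ids())

    def test_tree_tips_match_reference_ids(self, small_reference):
        db, newick = small_reference
        tree = TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == set(db.ids())

    def test_within_genus_identity_exceeds_between_phylum(self, small_reference):
        db, _ = small_reference
        within = semiglobal_align(db.record("ref_p0g0s0").seq,
                                  db.record("ref_p0g0s1").seq,
                                  query_global=True).identity
        between = semiglobal_align(db.record("ref_p0g0s0").seq,
                                   db.record("ref_p1g0s0").seq,
                                   query_global=True).identity
        assert within > between


class TestOrganellePool:
    def test_base_subset_size(self, small_spec, small_pool):
        pool, base_subset = small_pool
        import math
        assert len(pool) == small_spec.organelle_pool_size
        assert len(base_subset) == math.ceil(
            small_spec.base_db_organelle_fraction * small_spec.organelle_pool_size)

    def test_variant_vs_ancestor_identity_tracks_divergence(
            self, small_spec, small_reference, small_pool):
        db, _ = small_reference
        pool, _ = small_pool
        anc = organelle_ancestor(small_spec, db)
        d = small_spec.organelle_divergence
        for rec in pool:
            ident = semiglobal_align(organelle_core(rec), anc,
                                     query_global=True).identity
            assert (1 - d) - 0.05 <= ident <= (1 - d) + 0.05

    def test_ancestor_far_from_bacteria(self, small_spec, small_reference):
        db, _ = small_reference
        anc = organelle_ancestor(small_spec, db)
        for fid in db.ids():
            assert semiglobal_align(anc, db.record(fid).seq).identity < 0.75

    def test_pool_records_carry_extractable_primer_flanks(self, small_pool):
        pool, _ = small_pool
        primers = PrimerPair()
        for rec in pool:
            amp = extract_amplicon(rec, primers)
            assert amp is not None and amp.seq == organelle_core(rec)

    def test_seed_reproducible(self, small_spec, small_reference, small_pool):
        db, _ = small_reference
        pool2, subset2 = generate_organelle_pool(small_spec, db)
        pool, subset = small_pool
        assert subset == subset2
        assert [r.seq for r in pool] == [r.seq for r in pool2]

    def test_cryptic_variants_absent_from_base_present_in_extended(
            self, small_reference, small_pool):
        db, _ = small_reference
        pool, base_subset = small_pool
        primers = PrimerPair()
        base = extend_reference(db, [r for r in pool if r.id in base_subset],
                                "mitochondria", primers)
        ext = extend_reference(db, pool, "mitochondria", primers)
        base_seqs = {base.record(i).seq for i in base.ids()}
        ext_seqs = {ext.record(i).seq for i in ext.ids()}
        cryptic = [r for r in pool if r.id not in base_subset]
        for rec in cryptic:
            assert organelle_core(rec) not in base_seqs
            assert organelle_core(rec) in ext_seqs


class TestFig1:
    def test_perfect_filter_restores_true_abundance(self):
        table, _ = simulate_fig1_communities()
        ab = fig1_apparent_abundance(table)
        assert np.allclose(ab["perfect_filter"], 1 / 3)

    def test_no_filter_dilution(self):
        table, _ = simulate_fig1_communities(organelle_counts=[6], n_microbes=3)
        ab = fig1_apparent_abundance(table)
        assert ab["no_filter"].iloc[0] == pytest.approx(1 / 9)

    def test_zero_organelles_all_scenarios_agree(self):
        table, _ = simulate_fig1_communities(organelle_counts=[0])
        ab = fig1_apparent_abundance(table)
        assert ab.nunique(axis=1).eq(1).all()

    def test_partial_filter_bias_differs_with_load(self):
        # identical true microbiomes, unequal organelle loads -> partial
        # filtering yields unequal apparent abundances (the bias illustrated)
        table, _ = simulate_fig1_communities(organelle_counts=[6, 3, 0])
        ab = fig1_apparent_abundance(table)
        assert ab["partial_filter"].nunique() > 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_fig1_communities(organelle_counts=[-1])


class TestStudy:
    @pytest.fixture()
    def study(self, small_spec, small_reference, small_pool):
        db, _ = small_reference
        pool, base_subset = small_pool
        return simulate_study(small_spec, db, pool, base_subset)

    def test_per_sample_totals(self, small_spec, study):
        _, table, _, _ = study
        assert (table.sum(axis=0) == small_spec.reads_per_sample).all()

    def test_group_loads_within_binomial_noise(self, small_spec,
                                               small_reference, small_pool):
        spec = SimSpec(**{**small_spec.__dict__, "n_samples_per_group": 20,
                          "reads_per_sample": 200})
        db, _ = small_reference
        pool, base_subset = small_pool
        _, _, _, truth = simulate_study(spec, db, pool, base_subset)
        for group, load in spec.organelle_load_by_group.items():
            realized = np.mean([l for s, l in truth.organelle_load.items()
                                if truth.sample_group[s] == group])
            n = spec.n_samples_per_group * spec.reads_per_sample
            sd = np.sqrt(load * (1 - load) / n)
            assert abs(realized - load) <= 3 * sd + 1e-12

    def test_seed_reproducible(self, small_spec, small_reference, small_pool,
                               study):
        db, _ = small_reference
        pool, base_subset = small_pool
        _, table2, _, _ = simulate_study(small_spec, db, pool, base_subset)
        pd.testing.assert_frame_equal(study[1], table2)

    def test_truth_covers_every_feature(self, study):
        _, table, _, truth = study
        assert set(table.index) <= set(truth.feature_origin)

    def test_metadata_groups_match_truth(self, study):
        _, _, metadata, truth = study
        assert dict(metadata["group"]) == truth.sample_group


class TestShuffle:
    def test_length_and_composition_preserved(self):
        rng = np.random.default_rng(0)
        recs = [SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 80)))
                for i in range(5)]
        out = shuffle_sequences(recs, seed=1)
        for before, after in zip(recs, out):
            assert after.id == before.id + ".shuf"
            assert len(after.seq) == len(before.seq)
            assert sorted(after.seq) == sorted(before.seq)

    def test_seed_reproducible(self):
        recs = [SequenceRecord("r", "ACGTACGTAAAACCCC")]
        assert shuffle_sequences(recs, 7)[0].seq == shuffle_sequences(recs, 7)[0].seq

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shuffle_sequences([], 0)


class TestMock:
    def test_no_organelle_truth_and_totals(self, small_spec, small_reference):
        db, _ = small_reference
        _, table, truth = generate_mock_fixture(small_spec, db)
        assert truth.organelle_features() == []
        assert (table.sum(axis=0) == small_spec.reads_per_sample).all()
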