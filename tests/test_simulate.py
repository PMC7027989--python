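import numpy as np
import pytest

from hornkit import dollo, kmer, simulate
from hornkit.io import parse_tree


class TestReadPool:
    def test_determinism(self):
        a, ta = simulate.sim_read_pool(3000, 0.4, 6.0, [(2000, 0.7, 3.0)],
                                       100, 0.002, 42)
        b, tb = simulate.sim_read_pool(3000, 0.4, 6.0, [(2000, 0.7, 3.0)],
                                       100, 0.002, 42)
        assert [(r.id, r.sequence, r.quality) for r in a] == \
               [(r.id, r.sequence, r.quality) for r in b]
        assert ta.source_of == tb.source_of

    def test_every_read_has_exactly_one_truth_entry(self):
        reads, truth = simulate.sim_read_pool(2000, 0.5, 4.0, [(1500, 0.6, 2.0)],
                                              100, 0.0, 7)
        assert {r.id for r in reads} == set(truth.source_of)

    def test_read_ids_do_not_encode_source(self):
        reads, truth = simulate.sim_read_pool(2000, 0.5, 4.0, [(1500, 0.6, 2.0)],
                                              100, 0.0, 7)
        assert all(r.id.startswith("read") for r in reads)
        sources = [truth.source_of[r.id] for r in reads]
        assert len(set(sources)) == 2      # shuffled together, both present

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            simulate.sim_read_pool(2000, 0.5, 0.0, [], 100, 0.0, 1)

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate.sim_read_pool(500, 0.5, 5.0, [], 100, 0.0, 1)

    def test_error_free_spectrum_depth_matches_lander_waterman(self):
        depth = 30.0
        read_len = 100
        reads, _ = simulate.sim_read_pool(50_000, 0.5, depth, [], read_len, 0.0, 2)
        sp = kmer.count_kmers(reads, 17)
        # expected k-mer depth = base depth * (L-k+1)/L
        expected = depth * (read_len - 17 + 1) / read_len
        mean_depth = sp.total_occurrences / sp.n_distinct
        assert abs(mean_depth - expected) / expected < 0.15

    def test_gc_blobs_separate(self, blob_pool, blob_profiles):
        _, truth = blob_pool
        host_gc = np.mean([p.gc for p in blob_profiles
                           if truth.source_of[p.read_id] == "host"])
        cont_gc = np.mean([p.gc for p in blob_profiles
                           if truth.source_of[p.read_id] != "host"])
        assert abs(host_gc - 0.50) < 0.02
        assert abs(cont_gc - 0.65) < 0.02


class TestDolloSim:
    def test_no_loss_limit_fills_gain_clade(self, balanced_quartet):
        m, truth = simulate.sim_dollo_matrix(balanced_quartet, 100, 0.0, 5)
        for fam in m.families:
            gain = balanced_quartet.node(truth.gain_of[fam])
            present = {s for s in m.species if m.df.loc[fam, s] >= 1}
            assert present == set(balanced_quartet.leaf_set(gain))

    def test_determinism(self, eight_leaf_tree):
        a, _ = simulate.sim_dollo_matrix(eight_leaf_tree, 300, 0.2, 3)
        b, _ = simulate.sim_dollo_matrix(eight_leaf_tree, 300, 0.2, 3)
        assert a.df.equals(b.df)

    def test_no_extinct_families(self, eight_leaf_tree):
        m, _ = simulate.sim_dollo_matrix(eight_leaf_tree, 500, 0.4, 4)
        assert (m.counts.sum(axis=1) >= 1).all()

    def test_zero_families_gives_empty_matrix(self, balanced_quartet):
        m, _ = simulate.sim_dollo_matrix(balanced_quartet, 0, 0.1, 1)
        assert m.shape == (0, 4)


class TestTandemSim:
    def test_determinism(self):
        a, _ = simulate.sim_tandem_annotation(seed=6)
        b, _ = simulate.sim_tandem_annotation(seed=6)
        assert a == b

    def test_background_families_are_singletons(self):
        genes, truth = simulate.sim_tandem_annotation(2, 30, 2, seed=7)
        array_fams = {a.family_id for a in truth.arrays}
        fam_counts: dict[str, int] = {}
        for g in genes:
            fam_counts[g.family_id] = fam_counts.get(g.family_id, 0) + 1
        for fam, n in fam_counts.items():
            if fam not in array_fams:
                assert n == 1

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate.sim_tandem_annotation(1, 4, 100, seed=1)


class TestCdsSim:
    def test_determinism(self):
        a, _ = simulate.sim_cds_set(10, 40, 0.5, seed=8)
        b, _ = simulate.sim_cds_set(10, 40, 0.5, seed=8)
        assert a == b

    def test_structure_start_stop_no_internal_stop(self):
        recs, _ = simulate.sim_cds_set(20, 50, 1.0, seed=9)
        from hornkit.scuo import STOP_CODONS
        for r in recs:
            assert len(r.sequence) % 3 == 0
            assert r.sequence[:3] == "ATG"
            codons = [r.sequence[i:i + 3] for i in range(0, len(r.sequence), 3)]
            assert codons[-1] in STOP_CODONS
            assert not any(c in STOP_CODONS for c in codons[:-1])

    def test_uniform_limit_scuo_small(self):
        from hornkit import scuo
        recs, _ = simulate.sim_cds_set(20, 2000, 1000.0, seed=10)
        vals = [u.scuo for u in scuo.usage_table(recs)]
        assert np.mean(vals) < 0.05

    def test_gc_target_nudges_composition(self):
        lo, tlo = simulate.sim_cds_set(30, 200, 5.0, gc_target=0.40, seed=11)
        hi, thi = simulate.sim_cds_set(30, 200, 5.0, gc_target=0.60, seed=11)
        assert thi.gc_achieved > tlo.gc_achieved
        assert tlo.gc_satisfied and thi.gc_satisfied

    def test_impossible_gc_target_flagged(self):
        _, t = simulate.sim_cds_set(10, 60, 5.0, gc_target=0.95, seed=12)
        assert not t.gc_satisfied


class TestAlignmentSim:
    def test_zero_rate_limit_identical_sequences(self, eight_leaf_tree):
        alns, _ = simulate.sim_alignment_series(eight_leaf_tree, 500, [1e-9],
                                                "JC_nt", 2)
        seqs = {r.sequence for r in alns[0]}
        assert len(seqs) == 1

    def test_determinism(self, eight_leaf_tree):
        a, _ = simulate.sim_alignment_series(eight_leaf_tree, 300, [1, 2], "JC_nt", 3)
        b, _ = simulate.sim_alignment_series(eight_leaf_tree, 300, [1, 2], "JC_nt", 3)
        assert [[r.sequence for r in aln] for aln in a] == \
               [[r.sequence for r in aln] for aln in b]

    def test_tree_without_lengths_rejected(self, balanced_quartet):
        with pytest.raises(ValueError, match="branch lengths"):
            simulate.sim_alignment_series(balanced_quartet, 100, [1], "JC_nt", 1)

    def test_amino_acid_model_uses_protein_alphabet(self, eight_leaf_tree):
        alns, _ = simulate.sim_alignment_series(eight_leaf_tree, 200, [1],
                                                "Poisson_aa", 4)
        assert set("".join(r.sequence for r in alns[0])) <= \
               set("ACDEFGHIKLMNPQRSTVWY")
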