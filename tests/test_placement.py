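import numpy as np
import pytest

from ecoplace.placement import (AlignedQuery, PlacementEngine, Recruiter,
                                assign_and_count, filter_pendant, merge_mates)
from ecoplace.refdata import parse_reference_package
from ecoplace.synth import reverse_translate, revcomp


def _query_from_leaf(pkg, leaf_label, columns=None, query_id="q"):
    """AlignedQuery whose residues copy a reference leaf exactly."""
    codes = pkg.alignment.encoded(leaf_label)
    cols = np.nonzero(codes >= 0)[0]
    if columns is not None:
        cols = cols[:columns]
    return AlignedQuery(query_id, pkg.gene, cols, codes[cols], score=100.0)


@pytest.fixture(scope="module")
def recruiter(rpob_package):
    return Recruiter([rpob_package])


class TestRecruitment:
    def _leaf_read(self, pkg, leaf, rng, start_aa=10, n_aa=50):
        aa = pkg.alignment.sequences[leaf].replace("-", "")
        return reverse_translate(aa[start_aa:start_aa + n_aa], rng)

    def test_exact_read_forward_frame_maps_to_leaf_columns(self, rpob_package,
                                                           recruiter, rng):
        leaf = sorted(rpob_package.alignment.sequences)[2]
        nt = self._leaf_read(rpob_package, leaf, rng)
        hit = recruiter.recruit_mate(nt)
        assert hit is not None
        assert hit["frame"] == 1
        codes = rpob_package.alignment.encoded(leaf)
        assert len(hit["columns"]) == 50
        np.testing.assert_array_equal(codes[hit["columns"]], hit["residues"])

    def test_reverse_complement_selects_reverse_frame(self, rpob_package,
                                                      recruiter, rng):
        leaf = sorted(rpob_package.alignment.sequences)[2]
        nt = self._leaf_read(rpob_package, leaf, rng)
        fwd = recruiter.recruit_mate(nt)
        rev = recruiter.recruit_mate(revcomp(nt))
        assert rev is not None and rev["frame"] == -1
        np.testing.assert_array_equal(fwd["columns"], rev["columns"])
        np.testing.assert_array_equal(fwd["residues"], rev["residues"])

    def test_random_reads_rarely_recruit(self, rpob_package, recruiter):
        """i.i.d.-random 150-mers pass the default score cutoff < 1% of the time."""
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        n_pass = sum(
            recruiter.recruit_mate("".join(rng.choice(bases, 150))) is not None
            for _ in range(1000))
        assert n_pass / 1000 < 0.01

    def test_non_nucleotide_read_rejected_not_crashed(self, recruiter):
        assert recruiter.recruit_mate("ACGTN" * 30) is None
        q, reason = recruiter.recruit_pair("x", "ACGTN" * 30, None)
        assert q is None


class TestMergeMates:
    def _q(self, cols, res, score, qid="r"):
        return AlignedQuery(qid, "rpoB", np.asarray(cols), np.asarray(res),
                            score=score)

    def test_disjoint_columns_union(self):
        q1 = self._q(range(10, 60), [1] * 50, 40.0)
        q2 = self._q(range(80, 130), [2] * 50, 40.0)
        m = merge_mates(q1, q2)
        assert len(m.columns) == 100
        assert set(m.columns) == set(range(10, 60)) | set(range(80, 130))

    def test_identical_mates_idempotent(self):
        q1 = self._q([5, 6, 7], [1, 2, 3], 30.0)
        m = merge_mates(q1, self._q([5, 6, 7], [1, 2, 3], 30.0))
        np.testing.assert_array_equal(m.columns, q1.columns)
        np.testing.assert_array_equal(m.residues, q1.residues)

    def test_conflict_resolved_by_higher_score(self):
        q1 = self._q([5, 6], [1, 2], 40.0)
        q2 = self._q([6, 7], [9, 4], 30.0)
        m = merge_mates(q1, q2)
        assert dict(zip(m.columns.tolist(), m.residues.tolist())) == \
            {5: 1, 6: 2, 7: 4}

    def test_conflict_tie_goes_to_mate1(self):
        q1 = self._q([6], [1], 30.0)
        q2 = self._q([6], [9], 30.0)
        assert merge_mates(q1, q2).residues.tolist() == [1]

    def test_empty_input_rejected(self):
        q1 = self._q([5], [1], 30.0)
        empty = self._q([], [], 30.0)
        with pytest.raises(ValueError):
            merge_mates(q1, empty)


class TestPlaceQuery:
    def test_identical_query_lands_on_terminal_edge(self, rpob_package,
                                                    rpob_engine):
        leaf_node = rpob_package.tree.leaves[3]
        label = rpob_package.tree.leaf_labels[leaf_node]
        q = _query_from_leaf(rpob_package, label, columns=100)
        p = rpob_engine.place(q)
        assert p.edge_id == leaf_node        # terminal edge id = leaf node id
        assert p.pendant_length < 1e-3
        assert p.clade == rpob_package.taxonomy.paths[label]

    def test_symmetric_tie_broken_to_lower_edge_id(self):
        newick = "(A:0.1,B:0.1);"
        fasta = ">A\nAAAAAAAAAAAA\n>B\nCCCCCCCCCCCC\n"
        tax = "A\tX;a\nB\tX;b\n"
        pkg = parse_reference_package(newick, fasta, tax)
        res = np.array([0] * 6 + [1] * 6)    # half A-like, half B-like
        q = AlignedQuery("q", pkg.gene, np.arange(12), res, score=1.0)
        p = PlacementEngine(pkg).place(q)
        assert p.edge_id == 0

    def test_empty_query_rejected(self, rpob_package, rpob_engine):
        q = AlignedQuery("q", "rpoB", np.array([], dtype=int),
                         np.array([], dtype=int), score=0.0)
        assert rpob_engine.place(q) is None

    def test_matches_bruteforce_oracle_on_random_instances(self):
        from ecoplace.harness import placement_oracle_check
        worst, mismatches = placement_oracle_check(seed=77, n_instances=15)
        assert mismatches == 0
        assert worst < 1e-6


class TestFilterPendant:
    def _p(self, pendant):
        from ecoplace.placement import Placement
        return Placement("q", "rpoB", 0, pendant, -10.0, ("X",))

    def test_boundary_exactly_two_is_kept(self):
        kept, removed = filter_pendant([self._p(2.0), self._p(2.0001)],
                                       threshold=2.0)
        assert [p.pendant_length for p in kept] == [2.0]
        assert [p.pendant_length for p in removed] == [2.0001]

    def test_threshold_monotonicity(self, rng):
        ps = [self._p(float(x)) for x in rng.uniform(0, 4, size=50)]
        kept_counts = [len(filter_pendant(ps, t)[0]) for t in (0.5, 1, 2, 3)]
        assert kept_counts == sorted(kept_counts)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_pendant([], threshold=0.0)


class TestAssignAndCount:
    def _placement(self, edge):
        from ecoplace.placement import Placement
        return Placement("q", "rpoB", edge, 0.1, -5.0, ())

    def test_hierarchy_roll_up(self):
        labeling = {0: ("SAR11", "Ia", "Ia.1"), 1: ("SAR11", "Ia")}
        ps = [self._placement(0)] * 3
        counts = assign_and_count(ps, labeling)
        assert counts["SAR11;Ia;Ia.1"] == 3
        assert counts["SAR11;Ia"] == 3
        assert counts["SAR11"] == 3

    def test_basal_placement_not_counted_in_subclade(self):
        labeling = {0: ("SAR11", "Ia", "Ia.1"), 1: ("SAR11", "Ia")}
        counts = assign_and_count([self._placement(1)], labeling)
        assert counts["SAR11;Ia"] == 1
        assert "SAR11;Ia;Ia.1" not in counts

    def test_empty_set_gives_empty_table(self):
        assert assign_and_count([], {0: ("X",)}).empty

    def test_unlabeled_edge_is_an_error(self):
        with pytest.raises(KeyError):
            assign_and_count([self._placement(5)], {0: ("X",)})

    def test_count_conservation_at_top_rank(self, rpob_package, rpob_engine,
                                            rng):
        # place a batch of leaf-derived queries and check totals
        placements = []
        for node in rpob_package.tree.leaves:
            label = rpob_package.tree.leaf_labels[node]
            q = _query_from_leaf(rpob_package, label, columns=40,
                                 query_id=label)
            placements.append(rpob_engine.place(q))
        counts = assign_and_count(placements, rpob_package.labeling)
        top = {p.split(";")[0] for p in counts.index}
        assert sum(counts[t] for t in top) == len(placements)
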