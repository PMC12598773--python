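import numpy as np
import pytest
from Bio.Seq import Seq

from ecoplace.substitution import encode_aa
from ecoplace.synth import (evolve_reference_set, generate_reads,
                            logistic_deep_fraction, make_station_truth,
                            revcomp, reverse_translate)


def _aa_distance(a: str, b: str) -> float:
    x, y = encode_aa(a), encode_aa(b)
    return float((x != y).mean())


class TestEvolveReferenceSet:
    def test_clade_structure_in_distances(self):
        pkg = evolve_reference_set(seed=1, n_clades=2, leaves_per_clade=2,
                                   depth_scale=0.3, n_columns=200)
        seqs = pkg.alignment.sequences
        clades = {}
        for label in seqs:
            clades.setdefault(label.rsplit("_", 1)[0], []).append(label)
        within, between = [], []
        names = [c for c in clades if c != "OG"]
        for c in names:
            a, b = clades[c]
            within.append(_aa_distance(seqs[a], seqs[b]))
        for la in clades[names[0]]:
            for lb in clades[names[1]]:
                between.append(_aa_distance(seqs[la], seqs[lb]))
        assert max(within) < min(between)

    def test_zero_depth_scale_gives_identical_sequences(self):
        pkg = evolve_reference_set(seed=2, n_clades=2, leaves_per_clade=2,
                                   depth_scale=0.0, n_columns=50)
        assert len(set(pkg.alignment.sequences.values())) == 1

    def test_same_seed_is_byte_identical(self):
        a = evolve_reference_set(seed=9, n_clades=3, leaves_per_clade=2,
                                 depth_scale=0.3, n_columns=60)
        b = evolve_reference_set(seed=9, n_clades=3, leaves_per_clade=2,
                                 depth_scale=0.3, n_columns=60)
        assert a.tree.newick() == b.tree.newick()
        assert a.alignment.to_fasta() == b.alignment.to_fasta()
        assert a.taxonomy.to_tsv() == b.taxonomy.to_tsv()

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            evolve_reference_set(seed=1, n_clades=1)
        with pytest.raises(ValueError):
            evolve_reference_set(seed=1, n_clades=2, leaves_per_clade=0)


class TestStationTruth:
    depths = np.arange(25.0, 525.0, 50.0)

    def test_logistic_limits_and_midpoint(self):
        assert logistic_deep_fraction(0.0, 300.0, 0.05) < 1e-6
        assert logistic_deep_fraction(300.0, 300.0, 0.05) == pytest.approx(0.5)
        # steepness -> infinity approaches a step function
        assert logistic_deep_fraction(301.0, 300.0, 1e3) == pytest.approx(1.0)
        assert logistic_deep_fraction(299.0, 300.0, 1e3) == pytest.approx(0.0)

    def test_deep_fraction_is_logistic_of_depth(self):
        truth = make_station_truth(3, self.depths, z_star=275.0, steepness=0.05)
        for z in (25.0, 275.0, 475.0):
            assert truth.deep_fraction(z) == pytest.approx(
                logistic_deep_fraction(z, 275.0, 0.05), abs=1e-12)

    def test_fractions_sum_to_one_per_depth(self):
        truth = make_station_truth(4, self.depths, z_star=200.0)
        sums = truth.clade_fractions.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_transition_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_station_truth(1, self.depths, z_star=5000.0)

    def test_needs_at_least_four_depths(self):
        with pytest.raises(ValueError, match="4 depths"):
            make_station_truth(1, [10.0, 100.0, 200.0], z_star=100.0)

    def test_lli_profile_peaks_at_configured_depth(self):
        truth = make_station_truth(5, self.depths, z_star=225.0)
        lli = truth.psbd_intensity["LLI"]
        assert truth.lli_peak_depth == 225.0
        assert lli.idxmax() == 225.0

    def test_prd_carriage_surface_only_by_default(self):
        truth = make_station_truth(6, self.depths, z_star=225.0)
        assert all(truth.prd_carriage[c] for c in truth.surface_clades)
        assert not any(truth.prd_carriage[c] for c in truth.deep_clades)


@pytest.fixture(scope="module")
def setup(rpob_package):
    depths = np.arange(25.0, 325.0, 50.0)
    truth = make_station_truth(7, depths, z_star=150.0,
                               surface_clades=("Ia.1", "Ia.3"),
                               deep_clades=("Ib.2", "IIa.B"),
                               background_clades=(), total_sigma=0.0)
    return truth, rpob_package


class TestGenerateReads:
    depths = np.arange(25.0, 325.0, 50.0)

    def test_reads_are_150bp_pairs_with_truth(self, setup):
        truth, pkg = setup
        reads, totals = generate_reads(truth, pkg, n_reads=50, seed=1)
        assert len(reads) > 0
        for r in reads:
            assert len(r.mate1) == 150 and len(r.mate2) == 150
            assert r.true_gene == "rpoB"
            assert r.true_clade in truth.clade_fractions.columns

    def test_zero_mutation_mate_translates_into_template(self, setup):
        truth, pkg = setup
        reads, _ = generate_reads(truth, pkg, n_reads=20, mutation_rate=0.0,
                                  seed=2)
        r = reads[0]
        leaf_aa = pkg.alignment.sequences[r.true_leaf].replace("-", "")
        frame_off = r.frame1 - 1
        aa = str(Seq(r.mate1[frame_off:frame_off + 147]).translate())
        assert aa in leaf_aa
        # mate2 is the reverse strand of the same template
        aa2 = str(Seq(revcomp(r.mate2)[(abs(r.frame2) - 1):][:147]).translate())
        assert aa2 in leaf_aa

    def test_no_reads_requested_gives_empty_set(self, setup):
        truth, pkg = setup
        reads, totals = generate_reads(truth, pkg, n_reads=0, seed=3)
        assert reads == []

    def test_invalid_mutation_rate_rejected(self, setup):
        truth, pkg = setup
        with pytest.raises(ValueError, match="mutation_rate"):
            generate_reads(truth, pkg, n_reads=10, mutation_rate=1.5)

    def test_determinism(self, setup):
        truth, pkg = setup
        a, _ = generate_reads(truth, pkg, n_reads=30, mutation_rate=0.01, seed=4)
        b, _ = generate_reads(truth, pkg, n_reads=30, mutation_rate=0.01, seed=4)
        assert [(r.read_id, r.mate1, r.mate2) for r in a] == \
               [(r.read_id, r.mate1, r.mate2) for r in b]

    def test_clade_sampling_matches_multinomial_bound(self, setup):
        """Per-clade read fractions stay within 3 binomial standard errors."""
        truth, pkg = setup
        n = 2000
        reads, _ = generate_reads(truth, pkg, n_reads=n, seed=5)
        z = truth.depths[0]
        sample = truth.sample_id(z)
        got = {}
        for r in reads:
            if r.sample_id == sample:
                got[r.true_clade] = got.get(r.true_clade, 0) + 1
        total = sum(got.values())
        for clade, p in truth.clade_fractions.loc[z].items():
            frac = got.get(clade, 0) / total
            bound = 3 * np.sqrt(p * (1 - p) / total) + 1e-9
            assert abs(frac - p) <= bound, clade


def test_reverse_translate_round_trips():
    rng = np.random.default_rng(0)
    aa = "MKVLAWYHDEQRSTCGFINP"
    nt = reverse_translate(aa, rng)
    assert str(Seq(nt).translate()) == aa
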