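import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import barcodegap as bg
from barcodegap.errors import (
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
)

SPECIES = {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "c1": "spC"}


def make_aln(rows, name="m"):
    return bg.MarkerAlignment(name, list(rows), dict(SPECIES), dict(rows))


class TestClassifySites:
    def test_identical_rows_all_monomorphic(self):
        sc = bg.classify_sites(make_aln({"a1": "ACGT", "a2": "ACGT", "b1": "ACGT"}))
        assert sc.n_snps == 0 and sc.n_indels == 0
        assert len(sc.monomorphic_sites) == 4

    def test_indel_precedence_with_gap_free_polymorphism(self):
        # col 2 has a gap (indel); col 3 varies among the gap-free rows (SNP)
        sc = bg.classify_sites(make_aln({"a1": "ACGT", "a2": "ACGA", "b1": "AC-T"}))
        assert sc.n_indels == 1 and sc.indel_sites == {2}
        assert sc.n_snps == 1 and sc.snp_sites == {3}

    def test_gapped_polymorphic_column_counted_in_both_tallies(self):
        # col 0: gap plus A/T among gap-free rows
        aln = make_aln({"a1": "AC", "a2": "TC", "b1": "-C"})
        both = bg.classify_sites(aln, count_gapped_polymorphic_as_snp=True)
        assert both.snp_sites == {0} and both.indel_sites == {0}
        only_indel = bg.classify_sites(aln, count_gapped_polymorphic_as_snp=False)
        assert only_indel.snp_sites == set() and only_indel.indel_sites == {0}

    def test_ambiguity_only_variation_is_monomorphic(self):
        sc = bg.classify_sites(make_aln({"a1": "AN", "a2": "AR", "b1": "AA"}))
        assert sc.n_snps == 0 and sc.n_indels == 0

    def test_single_sample_rejected(self):
        aln = bg.MarkerAlignment("m", ["a1"], {"a1": "spA"}, {"a1": "ACGT"})
        with pytest.raises(InsufficientDataError):
            bg.classify_sites(aln)


class TestPercentages:
    @pytest.mark.parametrize(
        "n_snps,length,expected",
        [(125, 452, 27.65), (94, 420, 22.38), (86, 391, 21.99), (76, 312, 24.36), (0, 100, 0.0)],
    )
    def test_pct_snp(self, n_snps, length, expected):
        assert bg.distances.pct_snp(n_snps, length) == expected

    @pytest.mark.parametrize(
        "n_snps,n_indels,length,expected",
        [(125, 78, 452, 44.91), (76, 18, 312, 30.13), (86, 0, 391, 21.99), (0, 0, 100, 0.0)],
    )
    def test_pct_variable(self, n_snps, n_indels, length, expected):
        assert bg.distances.pct_variable(n_snps, n_indels, length) == expected

    def test_half_up_at_tie(self):
        # 100*96/420 = 22.857142... -> 22.86 under half-up
        assert bg.percent(96, 420) == 22.86
        assert bg.round_half_up(0.125, 2) == 0.13


class TestPairDistances:
    def test_p_distance_examples(self):
        assert bg.p_distance_pair("ACGT", "ACGA") == (0.25, 4)
        assert bg.p_distance_pair("AC-T", "ACGT") == (0.0, 3)
        assert bg.p_distance_pair("A" * 452, "A" * 452) == (0.0, 452)

    def test_ambiguity_codes_excluded(self):
        assert bg.p_distance_pair("ANRT", "ACGT") == (0.0, 2)

    def test_k2p_identical(self):
        assert bg.k2p_distance_pair("ACGT", "ACGT") == (0.0, 0.0, 0.0)

    def test_k2p_single_transition(self):
        d, P, Q = bg.k2p_distance_pair("ACGT", "GCGT")
        assert (P, Q) == (0.25, 0.0)
        assert d == pytest.approx(-0.5 * math.log(0.5), abs=1e-12)

    def test_k2p_closed_form_p01_q005(self):
        # 20 sites: 2 transitions, 1 transversion -> P=0.1, Q=0.05
        a = "A" * 20
        b = "G" * 2 + "C" + "A" * 17
        d, P, Q = bg.k2p_distance_pair(a, b)
        assert (P, Q) == (0.1, 0.05)
        assert d == pytest.approx(0.170181, abs=5e-7)

    def test_k2p_saturation_raises_then_caps(self):
        a = "A" * 10
        b = "G" * 10  # P=1 -> 1-2P-Q < 0
        with pytest.raises(SaturationError):
            bg.k2p_distance_pair(a, b)
        d, _, _ = bg.k2p_distance_pair(a, b, d_max=5.0)
        assert d == 5.0

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            bg.p_distance_pair("--AA", "AA--")


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        m = bg.distance_matrix(make_aln({"a1": "ACGT", "a2": "ACGT"}), "k2p")
        assert np.allclose(m.values, 0.0)

    def test_matches_pair_function(self, tiny_alignment):
        for model, pairfun in [
            ("p_distance", lambda a, b: bg.p_distance_pair(a, b)[0]),
            ("k2p", lambda a, b: bg.k2p_distance_pair(a, b)[0]),
        ]:
            m = bg.distance_matrix(tiny_alignment, model)
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 0.0)
            rows = tiny_alignment.rows
            ids = tiny_alignment.sample_ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    assert m.values[i, j] == pytest.approx(
                        pairfun(rows[ids[i]], rows[ids[j]]), abs=1e-12
                    )

    def test_undefined_pair_identified(self):
        aln = make_aln({"a1": "AA--", "a2": "--AA", "b1": "AAAA"})
        with pytest.raises(UndefinedDistanceError, match="a1"):
            bg.distance_matrix(aln, "p_distance")

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_k2p_dominates_p_distance(self, seed):
        """K2P correction never falls below the uncorrected distance."""
        rng = np.random.default_rng(seed)
        rows = {
            sid: "".join(rng.choice(list("ACGT"), size=60))
            for sid in ("a1", "a2", "b1")
        }
        aln = make_aln(rows)
        try:
            k2p = bg.distance_matrix(aln, "k2p").values
        except SaturationError:
            return
        p = bg.distance_matrix(aln, "p_distance").values
        assert (k2p >= p - 1e-12).all()
        same = p == 0.0
        assert np.allclose(k2p[same], 0.0)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_gap_free_concat_p_distance_is_weighted_mean(self, seed):
        """p(concat) == comparable-site-weighted mean of per-marker p."""
        rng = np.random.default_rng(seed)
        lens = [13, 29]
        alns = []
        for k, L in enumerate(lens):
            rows = {
                sid: "".join(rng.choice(list("ACGT"), size=L))
                for sid in ("a1", "a2", "b1")
            }
            alns.append(make_aln(rows, name=f"m{k}"))
        cat = bg.concatenate_markers(alns)
        p_cat = bg.distance_matrix(cat, "p_distance").values
        per = [bg.distance_matrix(a, "p_distance").values for a in alns]
        weighted = (per[0] * lens[0] + per[1] * lens[1]) / sum(lens)
        assert np.allclose(p_cat, weighted, atol=1e-15)

    def test_k2p_estimator_consistency_on_simulated_pair(self):
        root = "".join(np.random.default_rng(0).choice(list("ACGT"), size=100_000))
        child = bg.evolve_k2p(root, 0.10, 2.0, seed=42)
        d, _, _ = bg.k2p_distance_pair(root, child)
        assert d == pytest.approx(0.10, abs=0.01)

    def test_k2p_error_shrinks_with_length(self):
        rng = np.random.default_rng(3)
        errs = []
        for L in (1_000, 100_000):
            root = "".join(rng.choice(list("ACGT"), size=L))
            reps = [
                abs(bg.k2p_distance_pair(root, bg.evolve_k2p(root, 0.1, 2.0, seed=s))[0] - 0.1)
                for s in range(5)
            ]
            errs.append(np.mean(reps))
        assert errs[1] < errs[0]


class TestPartitionBySpecies:
    def test_two_by_two_counts(self):
        aln = make_aln({"a1": "ACGT", "a2": "ACGA", "b1": "TCGA", "b2": "TCGT"})
        part = bg.partition_by_species(
            bg.distance_matrix(aln, "p_distance"), bg.SpeciesLabelMap(SPECIES)
        )
        assert len(part.pooled_intra) == 2
        assert len(part.pooled_inter) == 4
        assert len(part.inter["spA"]) == 4 and len(part.inter["spB"]) == 4
        n = 4
        assert len(part.pooled_intra) + len(part.pooled_inter) == n * (n - 1) // 2

    def test_single_species(self):
        species = bg.SpeciesLabelMap({"a1": "spA", "a2": "spA", "a3": "spA"})
        rows = {"a1": "ACGT", "a2": "ACGA", "a3": "ACGG"}
        aln = bg.MarkerAlignment("m", list(rows), dict(species.entries), rows)
        part = bg.partition_by_species(bg.distance_matrix(aln, "p_distance"), species)
        assert len(part.pooled_intra) == 3 and part.pooled_inter == []

    def test_singleton_species_has_empty_intra(self):
        aln = make_aln({"a1": "ACGT", "a2": "ACGA", "c1": "TTTT"})
        part = bg.partition_by_species(
            bg.distance_matrix(aln, "p_distance"), bg.SpeciesLabelMap(SPECIES)
        )
        assert part.intra["spC"] == []
        assert len(part.inter["spC"]) == 2


class TestVariabilityStats:
    def test_assembles_table_row(self):
        rows = {"a1": "ACGTA", "a2": "ACGAA", "b1": "AC-TA", "b2": "ACGTA"}
        aln = make_aln(rows)
        mat = bg.distance_matrix(aln, "k2p")
        part = bg.partition_by_species(mat, bg.SpeciesLabelMap(SPECIES))
        stats = bg.variability_stats(aln, mat, part)
        assert stats.length_bp == 5
        assert stats.n_snps == 1 and stats.n_indels == 1
        assert stats.pct_snp == 20.0 and stats.pct_variable == 40.0
        assert stats.mean_intra == pytest.approx(np.mean(part.pooled_intra))
        assert stats.mean_inter == pytest.approx(np.mean(part.pooled_inter))
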