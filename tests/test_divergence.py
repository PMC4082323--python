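import itertools
import math

import numpy as np
import pytest

from naspkit import divergence as dv
from naspkit.seqio import CodonAlignment, GeneticCode, RegionMap
from tests.conftest import aa_set, nt_set

# ---------------------------------------------------------------------------
# independent brute-force oracles

_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def oracle_site_counts(codon, r, code):
    """Enumerate all 9 single-nucleotide mutants with explicit ts/tv weights."""
    s = n = 0.0
    denom = 2 * r + 2  # per position: one transition (2R) + two transversions (1+1)
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(mutant):
                continue
            w = 2 * r if (codon[pos], base) in _TS else 1.0
            if code.amino_acid(mutant) == code.amino_acid(codon):
                s += w / denom
            else:
                n += w / denom
    return s, n


def oracle_pair_diffs(c1, c2, r, code):
    """Explicit enumeration of all pathway orderings between two codons."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    total_w = sd = nd = 0.0
    for order in itertools.permutations(positions):
        cur, w, syn, nsyn, ok = c1, 1.0, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            w *= 2 * r if (cur[pos], c2[pos]) in _TS else 1.0
            if code.amino_acid(nxt) == code.amino_acid(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            total_w += w
            sd += w * syn
            nd += w * nsyn
    if total_w == 0:
        return None  # fully blocked (not expected for sense codons)
    return sd / total_w, nd / total_w


# ---------------------------------------------------------------------------


class TestSiteCounts:
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_met_is_fully_nonsynonymous(self, r, std_code):
        assert dv.ng_site_counts("ATG", r, std_code) == (0.0, 3.0)

    def test_phe_equal_rates(self, std_code):
        s, n = dv.ng_site_counts("TTT", 0.5, std_code)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_phe_transition_weighting(self, std_code):
        # third position: synonymous change is the transition, weight 2R
        s, _ = dv.ng_site_counts("TTT", 2.0, std_code)
        assert s == pytest.approx(2 * 2 / (2 * 2 + 2))

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_matches_enumeration_oracle(self, r, std_code):
        for codon in std_code.sense_codons:
            expected = oracle_site_counts(codon, r, std_code)
            got = dv.ng_site_counts(codon, r, std_code)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_stop_paths_shrink_site_total(self, std_code):
        # Tyr TAT: two of three third-position changes reach stops
        s, n = dv.ng_site_counts("TAT", 0.5, std_code)
        assert s + n < 3.0

    def test_stop_codon_input_rejected(self, std_code):
        with pytest.raises(ValueError):
            dv.ng_site_counts("TAA", 0.5, std_code)

    def test_r_half_equals_unweighted_counts(self, std_code):
        for codon in std_code.sense_codons:
            s_half, n_half = dv.ng_site_counts(codon, 0.5, std_code)
            # unweighted: every mutant counts 1/3 of a site
            s_unw = n_unw = 0.0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1:]
                    if std_code.is_stop(mut):
                        continue
                    if std_code.amino_acid(mut) == std_code.amino_acid(codon):
                        s_unw += 1 / 3
                    else:
                        n_unw += 1 / 3
            assert s_half == pytest.approx(s_unw)
            assert n_half == pytest.approx(n_unw)


class TestPairwiseDifferences:
    @pytest.mark.parametrize(
        "c1, c2, expected",
        [
            ("TTT", "TTC", (1.0, 0.0)),
            ("TTT", "GTT", (0.0, 1.0)),
            ("TTT", "GTC", (1.0, 1.0)),  # both orderings: one syn + one nonsyn
            ("AAA", "AAA", (0.0, 0.0)),
        ],
    )
    def test_examples(self, c1, c2, expected, std_code):
        got = dv.ng_pairwise_differences(c1, c2, 0.5, std_code)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("r", [0.5, 2.0])
    def test_random_pairs_match_pathway_oracle(self, r, std_code):
        rng = np.random.default_rng(5)
        codons = list(std_code.sense_codons)
        for _ in range(300):
            c1, c2 = rng.choice(codons, size=2)
            expected = oracle_pair_diffs(c1, c2, r, std_code)
            got = dv.ng_pairwise_differences(c1, c2, r, std_code)
            assert expected is not None
            assert got == pytest.approx(expected, abs=1e-12)

    def test_difference_total_equals_changed_positions(self, std_code):
        sd, nd = dv.ng_pairwise_differences("TTT", "GAC", 1.0, std_code)
        assert sd + nd == pytest.approx(3.0)


def _pair_alignment(s1: str, s2: str) -> CodonAlignment:
    return CodonAlignment(nt_set(("a", s1), ("b", s2)))


class TestPDistance:
    def test_identical_rows_zero(self):
        est = dv.p_distance(aa_set(("a", "MKVL"), ("b", "MKVL")), "aa",
                            n_boot=200, seed=1)
        assert est.value == 0.0 and est.se == 0.0

    def test_half_different(self):
        est = dv.p_distance(aa_set(("a", "AAAA"), ("b", "AATT")), "aa",
                            n_boot=200, seed=1)
        assert est.value == pytest.approx(0.5)

    def test_group_mean_is_mean_of_pairs(self):
        trio = aa_set(("a", "AAAA"), ("b", "AATT"), ("c", "TTTT"))
        est = dv.p_distance(trio, "aa", n_boot=100, seed=1)
        # pairs: ab=0.5, ac=1.0, bc=0.5
        assert est.value == pytest.approx((0.5 + 1.0 + 0.5) / 3)
        assert est.scope == "group-mean"

    def test_bootstrap_se_matches_binomial(self):
        # one pair, 100 sites, 25 differences: SE ~ sqrt(p(1-p)/n)
        s1 = "A" * 100
        s2 = "T" * 25 + "A" * 75
        est = dv.p_distance(aa_set(("a", s1), ("b", s2)), "aa",
                            n_boot=1000, seed=7)
        expected = math.sqrt(0.25 * 0.75 / 100)
        assert est.se == pytest.approx(expected, rel=0.15)

    def test_bootstrap_converges_with_replicates(self):
        rng = np.random.default_rng(3)
        s1 = "".join(rng.choice(list("ACDE"), 200))
        s2 = "".join(rng.choice(list("ACDE"), 200))
        pair = aa_set(("a", s1), ("b", s2))
        se1 = dv.p_distance(pair, "aa", n_boot=1000, seed=11).se
        se4 = dv.p_distance(pair, "aa", n_boot=4000, seed=11).se
        assert se4 == pytest.approx(se1, rel=0.10)

    def test_nt_level_on_codon_alignment(self):
        aln = _pair_alignment("ATGAAA", "ATGAAG")
        est = dv.p_distance(aln, "nt", n_boot=100, seed=1)
        assert est.value == pytest.approx(1 / 6)


class TestPsPn:
    def test_identical_rows(self):
        ps, pn = dv.ps_pn(_pair_alignment("ATGAAA", "ATGAAA"), n_boot=100, seed=1)
        assert ps.value == 0.0 and pn.value == 0.0

    def test_single_synonymous_difference(self):
        base = "ATGGCT" * 50
        mutated = base[:-1] + "C"  # GCT -> GCC, synonymous Ala change
        ps, pn = dv.ps_pn(_pair_alignment(base, mutated), n_boot=100, seed=1)
        assert pn.value == 0.0
        assert ps.value > 0.0

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        codons = [c for c in GeneticCode.standard().sense_codons]
        s1 = "".join(rng.choice(codons, 60))
        s2 = "".join(rng.choice(codons, 60))
        a = dv.ps_pn(_pair_alignment(s1, s2), n_boot=200, seed=9)
        b = dv.ps_pn(_pair_alignment(s2, s1), n_boot=200, seed=9)
        assert a[0].value == pytest.approx(b[0].value)
        assert a[1].value == pytest.approx(b[1].value)


class TestZTest:
    def test_identical_sequences_degenerate(self):
        zt = dv.z_test_selection(_pair_alignment("ATGAAA" * 20, "ATGAAA" * 20),
                                 n_boot=200, seed=1)
        assert zt.z is None
        assert zt.p_value == 1.0
        assert "degenerate" in zt.flags

    def test_low_power_flag(self):
        base = "ATGGCT" * 20
        mutated = base[:-1] + "C"
        zt = dv.z_test_selection(_pair_alignment(base, mutated), n_boot=200, seed=1)
        assert "low_power" in zt.flags

    def test_alternatives_partition_probability(self):
        rng = np.random.default_rng(4)
        codons = list(GeneticCode.standard().sense_codons)
        s1 = "".join(rng.choice(codons, 80))
        s2 = "".join(rng.choice(codons, 80))
        aln = _pair_alignment(s1, s2)
        pur = dv.z_test_selection(aln, 0.5, "purifying", 300, 5)
        pos = dv.z_test_selection(aln, 0.5, "positive", 300, 5)
        assert pur.p_value + pos.p_value == pytest.approx(1.0, abs=1e-9)

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            dv.z_test_selection(_pair_alignment("ATGAAA", "ATGAAG"),
                                alternative="weird")


class TestSlidingWindow:
    def test_identical_rows_all_zero(self):
        aln = _pair_alignment("ATGAAA" * 20, "ATGAAA" * 20)
        profile = dv.sliding_window_pi(aln, window=50, step=10)
        assert all(x == 0.0 for x in profile.pi_total)

    def test_window_count_formula(self):
        aln = _pair_alignment("ATGAAA" * 20, "ATGAAA" * 20)  # length 120
        profile = dv.sliding_window_pi(aln, window=50, step=10)
        assert profile.starts == [1, 11, 21, 31, 41, 51, 61, 71]

    def test_single_difference_localised(self):
        s1 = list("ATGAAA" * 20)
        s2 = list(s1)
        s2[54] = "G"  # nucleotide position 55: AAA -> AGA (Lys->Arg)
        aln = _pair_alignment("".join(s1), "".join(s2))
        profile = dv.sliding_window_pi(aln, window=50, step=10)
        for start, pi in zip(profile.starts, profile.pi_total):
            if start <= 55 <= start + 49:
                assert pi == pytest.approx(1 / 50)
            else:
                assert pi == 0.0

    def test_window_larger_than_alignment_rejected(self):
        aln = _pair_alignment("ATGAAA", "ATGAAA")
        with pytest.raises(Exception):
            dv.sliding_window_pi(aln, window=50, step=10)


class TestRegionReport:
    def test_rows_and_bounds(self):
        rng = np.random.default_rng(8)
        codons = list(GeneticCode.standard().sense_codons)
        s1 = "".join(rng.choice(codons, 40))
        s2 = "".join(rng.choice(codons, 40))
        aln = _pair_alignment(s1, s2)
        regions = RegionMap({"HEAD": (1, 10), "TAIL": (31, 40)})
        rows = dv.region_report(aln, regions, n_boot=100, seed=1)
        labels = [r.label for r in rows]
        assert labels == ["HEAD", "TAIL", "REMAINDER", "ALL"]
        assert rows[-1].n_codons == 40

    def test_small_region_rejected(self):
        aln = _pair_alignment("ATGAAA" * 10, "ATGAAA" * 10)
        with pytest.raises(ValueError, match="minimum"):
            dv.region_report(aln, RegionMap({"TINY": (1, 2)}), n_boot=100, seed=1)

    def test_out_of_bounds_region_rejected(self):
        aln = _pair_alignment("ATGAAA" * 10, "ATGAAA" * 10)
        with pytest.raises(ValueError, match="exceeds"):
            dv.region_report(aln, RegionMap({"FAR": (8, 30)}), n_boot=100, seed=1)
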