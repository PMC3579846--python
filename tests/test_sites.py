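"""Site discovery, Hamming off-target scanning and SNP pre-screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfnscreen.sites import (
    TargetSpec,
    check_snps,
    count_offtargets,
    count_paired_offtargets,
    revcomp,
    scan_candidate_sites,
)

from conftest import AK2_LEFT, AK2_RIGHT, AK2_SPACER, brute_force_matches, random_seq


class TestScanCandidateSites:
    def test_window_count_on_unconstrained_sequence(self):
        cds = "ACGTACGTACGTACGTACGTACGTACGTAC"  # length 30, no N
        hits = scan_candidate_sites(cds, 9, 9, (5, 5))
        # L - window + 1 = 30 - 23 + 1 = 8 windows, ordered by start
        assert len(hits) == 8
        assert [h.cds_position for h in hits] == list(range(8))

    def test_first_half_only_restricts_start(self):
        cds = "ACGTACGTACGTACGTACGTACGTACGTAC"
        hits = scan_candidate_sites(cds, 9, 9, (5, 5), first_half_only=True)
        assert all(h.cds_position < 15 for h in hits)

    def test_one_window_per_spacer_length(self):
        rng = np.random.default_rng(0)
        cds = random_seq(rng, 60)
        for spacer in (5, 6, 7):
            hits = scan_candidate_sites(cds, 9, 9, (spacer, spacer))
            assert len(hits) == 60 - (18 + spacer) + 1

    def test_embedded_ak2_site_is_reported(self):
        rng = np.random.default_rng(42)
        site = AK2_LEFT + AK2_SPACER.upper() + AK2_RIGHT
        cds = random_seq(rng, 12) + site + random_seq(rng, 200 - 12 - len(site))
        hits = scan_candidate_sites(cds, 18, 12, (5, 5), gene_id="ak2")
        at_12 = [h for h in hits if h.cds_position == 12]
        assert len(at_12) == 1
        assert at_12[0].left_site == AK2_LEFT
        assert at_12[0].right_site == AK2_RIGHT

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            scan_candidate_sites("ACGTXACGT" * 5, 9, 9, (5, 5))
        with pytest.raises(ValueError):
            scan_candidate_sites("ACGT", 9, 9, (5, 5))


class TestCountOfftargets:
    def test_palindromic_query_matches_both_strands(self):
        hits = count_offtargets({"c1": "AAAAACGTAAAA"}, "ACGT", 0)
        assert [(h.start, h.strand, h.mismatches) for h in hits] == [
            (4, "+", 0), (4, "-", 0)]

    def test_single_substitution_needs_budget_one(self):
        genome = {"c1": "AGGT"}
        assert count_offtargets(genome, "ACGT", 0) == []
        hits = count_offtargets(genome, "ACGT", 1)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].mismatches == 1

    def test_n_in_genome_counts_as_mismatch(self):
        hits = count_offtargets({"c1": "ANGT"}, "ACGT", 0)
        assert all(h.strand == "-" or h.start != 0 for h in hits)
        hits1 = [h for h in count_offtargets({"c1": "ANGT"}, "ACGT", 1)
                 if h.strand == "+"]
        assert hits1 and hits1[0].mismatches == 1

    def test_k_not_below_query_length(self):
        with pytest.raises(ValueError):
            count_offtargets({"c1": "ACGTACGT"}, "ACG", 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        genome = {"c1": random_seq(rng, 10_000)}
        query = random_seq(rng, 18)
        for k in range(5):
            got = [(h.contig, h.start, h.strand, h.mismatches)
                   for h in count_offtargets(genome, query, k)]
            assert got == brute_force_matches(genome, query, k)

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(11)
        genome = {"c1": random_seq(rng, 5_000)}
        query = random_seq(rng, 12)
        prev: set = set()
        for k in range(6):
            cur = {(h.contig, h.start, h.strand)
                   for h in count_offtargets(genome, query, k)}
            assert prev <= cur
            prev = cur

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 3))
    def test_strand_symmetry(self, seed, k):
        """Scanning G with q equals scanning revcomp(G) with revcomp(q)
        after reflecting coordinates (strand is preserved: reverse-
        complementing both sequences maps plus-strand windows onto
        plus-strand windows)."""
        rng = np.random.default_rng(seed)
        genome_seq = random_seq(rng, 400)
        query = random_seq(rng, 10)
        fwd = count_offtargets({"c": genome_seq}, query, k)
        rev = count_offtargets({"c": revcomp(genome_seq)}, revcomp(query), k)
        n = len(genome_seq)
        reflected = sorted((n - h.end, h.strand, h.mismatches) for h in rev)
        assert sorted((h.start, h.strand, h.mismatches) for h in fwd) == reflected


class TestPairedOfftargets:
    def _background(self, seed, n=3000):
        return random_seq(np.random.default_rng(seed), n)

    def test_single_embedded_site_gives_one_heterodimeric_hit(self, ak2_spec):
        bg = self._background(1)
        site = AK2_LEFT + "ACGTA" + AK2_RIGHT
        genome = {"c1": bg[:700] + site + bg[700:]}
        hits = count_paired_offtargets(genome, ak2_spec, 0)
        assert len(hits) == 1
        assert hits[0].configuration == "LR"
        assert hits[0].start == 700
        assert hits[0].end == 700 + len(site)

    def test_homodimeric_left_left_configuration(self, ak2_spec):
        bg = self._background(2)
        ll_locus = AK2_LEFT + "ACGTAC" + revcomp(AK2_LEFT)
        genome = {"c1": bg[:500] + ll_locus + bg[500:]}
        hits = count_paired_offtargets(genome, ak2_spec, 0,
                                       spacer_range=(5, 6),
                                       allow_homodimer=True)
        assert [(h.start, h.configuration) for h in hits] == [(500, "LL")]
        # without the homodimer flag the locus is invisible
        assert count_paired_offtargets(genome, ak2_spec, 0,
                                       spacer_range=(5, 6)) == []

    def test_pairs_equal_cross_join_of_half_site_oracles(self, ak2_spec):
        rng = np.random.default_rng(3)
        genome = {"c1": random_seq(rng, 20_000)}
        k = 3
        lo, hi = 5, 7
        left = brute_force_matches(genome, ak2_spec.left_site, k)
        right = brute_force_matches(genome, ak2_spec.right_site, k)
        ll, lr = len(ak2_spec.left_site), len(ak2_spec.right_site)
        expected = set()
        l_plus = {s for c, s, st_, m in left if st_ == "+"}
        l_minus = {s for c, s, st_, m in left if st_ == "-"}
        r_plus = {s for c, s, st_, m in right if st_ == "+"}
        r_minus = {s for c, s, st_, m in right if st_ == "-"}
        for a in l_plus:
            for sp in range(lo, hi + 1):
                if a + ll + sp in r_plus:
                    expected.add((a, "LR", "+"))
                if a + ll + sp in l_minus:
                    expected.add((a, "LL", "+"))
        for a in r_minus:
            for sp in range(lo, hi + 1):
                if a + lr + sp in l_minus:
                    expected.add((a, "LR", "-"))
                if a + lr + sp in r_plus:
                    expected.add((a, "RR", "+"))
        hits = count_paired_offtargets(genome, ak2_spec, k,
                                       spacer_range=(lo, hi),
                                       allow_homodimer=True)
        got = {(h.start, h.configuration, h.strand) for h in hits}
        assert got == expected


class TestCheckSnps:
    def _amplicons(self, seed=9, n=8):
        rng = np.random.default_rng(seed)
        site = AK2_LEFT + AK2_SPACER.upper() + AK2_RIGHT
        ref = random_seq(rng, 40) + site + random_seq(rng, 40)
        return ref, [ref for _ in range(n)], 40

    def test_identical_individuals_pass(self, ak2_spec):
        _, seqs, _ = self._amplicons()
        result = check_snps(ak2_spec, seqs)
        assert result.passes and result.variant_positions == ()
        assert result.n_individuals == 8

    def test_variant_in_half_site_fails(self, ak2_spec):
        ref, seqs, off = self._amplicons()
        pos = off + 3  # inside the left half-site
        alt = "A" if ref[pos] != "A" else "C"
        seqs[-1] = ref[:pos] + alt + ref[pos + 1:]
        result = check_snps(ak2_spec, seqs)
        assert not result.passes
        assert 3 in result.variant_positions

    def test_spacer_variant_reported_but_passes(self, ak2_spec):
        ref, seqs, off = self._amplicons()
        pos = off + len(AK2_LEFT) + 2  # inside the spacer
        alt = "A" if ref[pos] != "A" else "C"
        seqs[0] = ref[:pos] + alt + ref[pos + 1:]
        result = check_snps(ak2_spec, seqs)
        assert result.passes
        assert len(AK2_LEFT) + 2 in result.variant_positions

    def test_length_mismatch_is_an_error(self, ak2_spec):
        _, seqs, _ = self._amplicons()
        seqs[1] = seqs[1][:-1]
        with pytest.raises(ValueError):
            check_snps(ak2_spec, seqs)


def test_target_spec_validation():
    with pytest.raises(ValueError):
        TargetSpec("g", "ACGTACGTX", (5, 7), "ACGTACGTA")
    with pytest.raises(ValueError):
        TargetSpec("g", "ACGT", (5, 7), "ACGTACGTA")  # too short
    with pytest.raises(ValueError):
        TargetSpec("g", "ACGTACGTA", (5, 25), "ACGTACGTA")  # spacer too wide
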