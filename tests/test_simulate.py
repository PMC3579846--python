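"""Synthetic-data generators: determinism, constraints, round-trips."""

import collections

import numpy as np
import pytest
from scipy.stats import binom

from zfnscreen.founders import call_pool_peaks, design_screen
from zfnscreen.lesions import classify_allele
from zfnscreen.simulate import (
    IndelSpectrum,
    make_locus,
    simulate_alleles,
    simulate_clone_set,
    simulate_founder_screen,
)


class TestMakeLocus:
    def test_same_seed_same_bytes(self, ak2_spec):
        a = make_locus(3, 5000, ak2_spec)
        b = make_locus(3, 5000, ak2_spec)
        assert a.to_fasta() == b.to_fasta()
        assert a.to_fasta() != make_locus(4, 5000, ak2_spec).to_fasta()

    def test_amplicon_length_and_site_centering(self, ak2_spec):
        for seed in range(100):
            locus = make_locus(seed, 3000, ak2_spec)
            amp_len = len(locus.amplicon_seq)
            assert 230 <= amp_len <= 350
            centre = locus.site_start_in_amplicon + locus.site_len / 2
            # site centre within the central 20% of the amplicon
            assert abs(centre / amp_len - 0.5) <= 0.1 + locus.site_len / amp_len
            assert (locus.amplicon_seq[locus.site_start_in_amplicon:]
                    .startswith(ak2_spec.left_site))

    def test_amplicon_is_a_contig_substring(self, ak2_spec):
        locus = make_locus(11, 4000, ak2_spec)
        assert locus.amplicon_seq in locus.contig_seq

    def test_short_contig_is_error(self, ak2_spec):
        with pytest.raises(ValueError):
            make_locus(0, 400, ak2_spec)


class TestIndelSpectrum:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            IndelSpectrum(p_insertion=0.5, p_deletion=0.5, p_complex=0.1)

    def test_deletion_tail_must_dominate(self):
        with pytest.raises(ValueError):
            IndelSpectrum(insertion_size_dist={4: 0.5, 30: 0.5},
                          deletion_size_dist={1: 1.0})


@pytest.fixture(scope="module")
def locus(ak2_spec):
    return make_locus(7, 3000, ak2_spec)


@pytest.fixture(scope="module")
def clone_setup(ak2_spec):
    loc = make_locus(9, 3000, ak2_spec)
    alleles = simulate_alleles(loc.amplicon_seq, loc.cut_pos,
                               IndelSpectrum(), 20, seed=5)
    return loc.amplicon_seq, alleles


class TestSimulateAlleles:
    def test_empty_request(self, locus):
        assert simulate_alleles(locus.amplicon_seq, locus.cut_pos,
                                IndelSpectrum(), 0, seed=1) == []

    def test_forced_duplication_round_trip(self, locus):
        spectrum = IndelSpectrum(
            p_insertion=1.0, p_deletion=0.0, p_complex=0.0,
            insertion_size_dist={4: 1.0},
            p_duplication_given_insertion=1.0)
        wt = locus.amplicon_seq
        for a in simulate_alleles(wt, locus.cut_pos, spectrum, 50, seed=2):
            assert a.net_delta == 4 and a.is_duplication
            call = classify_allele(wt, a.seq, locus.spacer_window)
            assert call.allele_class == "insertion"
            assert call.net_delta == 4
            assert call.is_duplication

    def test_class_frequencies_match_spectrum(self, locus):
        spectrum = IndelSpectrum()
        alleles = simulate_alleles(locus.amplicon_seq, locus.cut_pos,
                                   spectrum, 10_000, seed=3)
        freq = collections.Counter(a.allele_class for a in alleles)
        assert abs(freq["insertion"] / 10_000 - spectrum.p_insertion) < 0.02
        assert abs(freq["deletion"] / 10_000 - spectrum.p_deletion) < 0.02
        assert abs(freq["complex"] / 10_000 - spectrum.p_complex) < 0.02

    def test_truth_labels_are_self_consistent(self, locus):
        wt = locus.amplicon_seq
        for a in simulate_alleles(wt, locus.cut_pos, IndelSpectrum(),
                                  500, seed=4):
            assert a.net_delta == len(a.seq) - len(wt)
            assert a.net_delta == len(a.inserted_seq) - len(a.deleted_seq)


class TestSimulateCloneSet:
    def test_extreme_frequencies(self, clone_setup):
        wt, alleles = clone_setup
        records, truth = simulate_clone_set(wt, alleles, 0.0, 30, seed=6)
        assert all(seq == wt for _, seq in records)
        records, truth = simulate_clone_set(wt, alleles, 1.0, 30, seed=6)
        assert all(t["is_mutant"] for t in truth)

    def test_mutant_count_within_binomial_interval(self, clone_setup):
        wt, alleles = clone_setup
        p, n = 0.25, 96
        lo, hi = binom.ppf([0.005, 0.995], n, p)
        for seed in range(30):
            _, truth = simulate_clone_set(wt, alleles, p, n, seed=seed)
            k = sum(t["is_mutant"] for t in truth)
            assert lo <= k <= hi

    def test_determinism(self, clone_setup):
        wt, alleles = clone_setup
        a = simulate_clone_set(wt, alleles, 0.3, 50, seed=8)
        b = simulate_clone_set(wt, alleles, 0.3, 50, seed=8)
        assert a == b


class TestSimulateFounderScreen:
    def test_noise_free_single_het_fraction_is_exactly_one_eighth(self):
        plan = design_screen(60, 4)
        sim = simulate_founder_screen({-13: 0.08}, plan, peak_noise_cv=0.0,
                                      seed=12)
        for t, het in zip(sim.peak_tables, sim.het_per_well):
            if het.get(-13) == 1:
                total = sum(p.height for p in t.peaks)
                mutant = [p for p in t.peaks if p.size == sim.wt_size - 13]
                assert mutant[0].height / total == pytest.approx(0.125)
                break
        else:
            pytest.fail("no single-het pool simulated")

    def test_zero_transmission_gives_no_mutant_peaks(self):
        plan = design_screen(60, 4)
        sim = simulate_founder_screen({-13: 0.0}, plan, seed=1)
        for t in sim.peak_tables:
            assert len(t.peaks) == 1 and t.peaks[0].size == sim.wt_size

    def test_carrier_estimates_exact_without_noise(self):
        plan = design_screen(60, 4)
        sim = simulate_founder_screen({-13: 0.12, 4: 0.06}, plan,
                                      peak_noise_cv=0.0, seed=13)
        for t, het in zip(sim.peak_tables, sim.het_per_well):
            call = call_pool_peaks(t, sim.wt_size, plan.pool_size)
            got = {mp.net_delta: mp.est_carriers for mp in call.mutant_peaks}
            assert got == het

    def test_plus_a_artifact_doubles_peaks_and_merges_away(self):
        plan = design_screen(60, 4)
        kwargs = dict(plan=plan, peak_noise_cv=0.0, seed=14)
        clean = simulate_founder_screen({-13: 0.1, 4: 0.05}, **kwargs)
        noisy = simulate_founder_screen({-13: 0.1, 4: 0.05},
                                        plus_a_artifact=True, **kwargs)
        for t0, ta in zip(clean.peak_tables, noisy.peak_tables):
            assert len(ta.peaks) == 2 * len(t0.peaks)
            c0 = call_pool_peaks(t0, clean.wt_size, 4)
            ca = call_pool_peaks(ta, clean.wt_size, 4, merge_plus_a=True)
            assert ([(m.net_delta, m.est_carriers) for m in c0.mutant_peaks]
                    == [(m.net_delta, m.est_carriers) for m in ca.mutant_peaks])

    def test_determinism(self):
        plan = design_screen(60, 4)
        a = simulate_founder_screen({-13: 0.1}, plan, peak_noise_cv=0.2, seed=15)
        b = simulate_founder_screen({-13: 0.1}, plan, peak_noise_cv=0.2, seed=15)
        assert a == b
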