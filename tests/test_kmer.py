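"""k-mer counting, spectrum construction, peak detection, size estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomesizer import kmer, synth
from genomesizer.kmer import (KmerCountTable, KmerParams, KmerSpectrum,
                              NoCoveragePeakError, SpectrumPeaks,
                              count_kmers, estimate_genome_size, find_peaks,
                              spectrum_from_table)
from conftest import naive_kmer_counts

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestCountKmers:
    def test_canonical_collapse_of_reverse_complements(self):
        # ACG and CGT are reverse complements: one canonical key
        table = count_kmers(["ACGT"], KmerParams(k=3))
        assert table.as_dict() == {"ACG": 2}

    def test_read_shorter_than_k_yields_empty_table(self):
        table = count_kmers(["ACGT"], KmerParams(k=17))
        assert len(table) == 0

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            count_kmers([], KmerParams(k=3))

    def test_ambiguous_bases_skip_whole_windows(self):
        table = count_kmers(["ACGNACG"], KmerParams(k=3))
        # only the two flanking ACG windows survive; canonical(ACG)=ACG
        assert table.as_dict() == {"ACG": 2}

    def test_matches_naive_oracle_on_random_sequence(self):
        rng = np.random.default_rng(33)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        table = count_kmers([seq], KmerParams(k=17))
        assert table.as_dict() == naive_kmer_counts([seq], 17)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(dna, min_size=1, max_size=6), st.integers(3, 9))
    def test_matches_naive_oracle_property(self, reads, k):
        oracle = naive_kmer_counts(reads, k)
        table = count_kmers(reads, KmerParams(k=k))
        assert table.as_dict() == oracle
        assert table.n_instances == sum(oracle.values())

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.text(alphabet="ACGT", min_size=10, max_size=80),
                    min_size=1, max_size=5))
    def test_strand_invariance(self, reads):
        fwd = count_kmers(reads, KmerParams(k=7))
        rev = count_kmers([kmer.revcomp(r) for r in reads], KmerParams(k=7))
        assert fwd.as_dict() == rev.as_dict()

    def test_table_lookup_uses_canonical_form(self):
        table = count_kmers(["ACGT"], KmerParams(k=3))
        assert table["ACG"] == 2
        assert table["CGT"] == 2  # revcomp of ACG
        assert table.get("AAA") == 0


class TestSpectrum:
    def test_single_entry_table(self):
        table = KmerCountTable.from_dict({"ACG": 2}, k=3)
        spec = spectrum_from_table(table)
        assert spec.as_dict() == {2: 1}
        assert spec.n_instances == 2

    def test_counting_multiplicities(self):
        table = KmerCountTable.from_dict({"AAC": 1, "AAG": 1, "AAT": 3}, k=3)
        assert spectrum_from_table(table).as_dict() == {1: 2, 3: 1}

    def test_totals_conserved_from_simulated_reads(self, clean_readset):
        table = count_kmers(clean_readset.reads, KmerParams(k=17))
        spec = spectrum_from_table(table)
        assert spec.n_distinct == table.n_distinct
        assert spec.n_instances == table.n_instances

    def test_error_free_reads_single_dominant_mode(self, clean_readset,
                                                   small_genome):
        table = count_kmers(clean_readset.reads, KmerParams(k=17))
        spec = spectrum_from_table(table)
        # oracle mode of the raw per-k-mer counts
        oracle_mode = int(np.bincount(table.counts).argmax())
        peaks = find_peaks(spec)
        assert peaks.main_peak_depth == oracle_mode
        # expected k-mer coverage: 30 * (100-17+1)/100 = 25.2
        assert abs(peaks.main_peak_depth - 25.2) < 3

    def test_tsv_round_trip(self, tmp_path):
        spec = KmerSpectrum.from_dict({1: 10, 5: 3, 30: 7})
        p = tmp_path / "spec.tsv"
        spec.to_tsv(p)
        back = KmerSpectrum.from_tsv(p)
        assert back.as_dict() == spec.as_dict()


class TestFindPeaks:
    def test_hand_checkable_trough_and_mode(self):
        spec = KmerSpectrum.from_dict({1: 100, 2: 10, 3: 2, 4: 5, 5: 20, 6: 5})
        peaks = find_peaks(spec)
        assert peaks.error_boundary == 3
        assert peaks.main_peak_depth == 5

    def test_monotone_decreasing_spectrum_has_no_peak(self):
        spec = KmerSpectrum.from_dict({1: 100, 2: 50, 3: 25, 4: 12, 5: 6})
        with pytest.raises(NoCoveragePeakError):
            find_peaks(spec)

    def test_smoothing_never_alters_totals(self):
        spec = KmerSpectrum.from_dict({1: 50, 2: 3, 3: 8, 4: 30, 5: 9})
        before = (spec.n_distinct, spec.n_instances)
        find_peaks(spec, smoothing_window=3)
        assert (spec.n_distinct, spec.n_instances) == before

    def test_diploid_reads_show_heterozygous_shoulder(self):
        # 30x per haplotype: shared k-mers peak near 2x the haplotype
        # depth, haplotype-private k-mers near 1x -> shoulder at ~half
        g = synth.make_genome(100_000, het_rate=0.01, seed=5)
        rs = synth.simulate_reads(g, coverage=60, read_length=100,
                                  error_rate=0.0, seed=6)
        spec = spectrum_from_table(count_kmers(rs.reads, KmerParams(k=17)))
        peaks = find_peaks(spec)
        assert peaks.het_flag
        assert 0.35 * peaks.main_peak_depth <= peaks.het_shoulder_depth \
            <= 0.65 * peaks.main_peak_depth

    def test_haploid_reads_show_no_shoulder(self, clean_readset):
        spec = spectrum_from_table(count_kmers(clean_readset.reads,
                                               KmerParams(k=17)))
        assert not find_peaks(spec).het_flag


class TestEstimateGenomeSize:
    def test_single_depth_spectrum_equal_under_both_policies(self):
        spec = KmerSpectrum.from_dict({30: 1000})
        peaks = SpectrumPeaks(error_boundary=1, main_peak_depth=30)
        for policy in ("error_excluded", "all_instances"):
            assert estimate_genome_size(spec, peaks, policy).genome_size == 1000

    def test_error_exclusion_policy_difference(self):
        spec = KmerSpectrum.from_dict({1: 5000, 30: 1000})
        peaks = SpectrumPeaks(error_boundary=2, main_peak_depth=30)
        est = estimate_genome_size(spec, peaks)
        assert est.sizes["error_excluded"] == 1000
        assert est.sizes["all_instances"] == 1166  # (5000 + 30000) // 30

    def test_recovers_haploid_genome_within_5_percent(self, small_genome,
                                                      clean_readset):
        spec = spectrum_from_table(count_kmers(clean_readset.reads,
                                               KmerParams(k=17)))
        est = estimate_genome_size(spec, find_peaks(spec))
        assert abs(est.genome_size / small_genome.length - 1) < 0.05

    def test_error_reads_recovery_uses_error_excluded_total(self):
        g = synth.make_genome(80_000, het_rate=0.0, seed=41)
        rs = synth.simulate_reads(g, coverage=35, read_length=100,
                                  error_rate=0.01, seed=42)
        spec = spectrum_from_table(count_kmers(rs.reads, KmerParams(k=17)))
        est = estimate_genome_size(spec, find_peaks(spec))
        assert abs(est.genome_size / g.length - 1) < 0.05
        # error k-mers inflate the all-instances size
        assert est.sizes["all_instances"] > est.sizes["error_excluded"]

    def test_raising_error_rate_never_creates_peak_from_nothing(self):
        # at 8x coverage and 5% error, genomic k-mers drown in the error
        # tail; raising the error rate further must keep the no-peak state
        g = synth.make_genome(50_000, het_rate=0.0, seed=51)
        outcomes = []
        for err in (0.05, 0.08):
            rs = synth.simulate_reads(g, coverage=8, read_length=100,
                                      error_rate=err, seed=52)
            spec = spectrum_from_table(count_kmers(rs.reads, KmerParams(k=17)))
            try:
                find_peaks(spec)
                outcomes.append("peak")
            except NoCoveragePeakError:
                outcomes.append("no_peak")
        assert outcomes[0] == "no_peak"
        assert outcomes[1] == "no_peak"
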