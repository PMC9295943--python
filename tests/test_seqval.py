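"""Read classification, enrichment profiles, domains and count-table stats."""

import numpy as np
import pandas as pd
import pytest

import cenrich as cr
from cenrich.seqval import canonical_kmer

MONOMER = (
    "AATTCGATTCCATTAGATGATGACATTCCGTTTGACTCACAGAATTGAAC"
    "CACCGTATGATAAGGCCTTTCGAGGCCATTTGTGAAGCATATTTCAGAAC"
)  # 100 bp, arbitrary fixed sequence used as the satellite monomer in tests


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@pytest.fixture(scope="module")
def kset():
    return cr.KmerSet.from_monomer(MONOMER, k=18)


class TestKmerCounting:
    def test_read_with_two_set_kmers_is_positive(self, kset):
        filler = "G" * 30
        read = MONOMER[:18] + filler + MONOMER[30:48]
        n_pos, n_total, frac = cr.count_kmer_positive_reads([read], kset)
        assert (n_pos, n_total, frac) == (1, 1, 1.0)

    def test_single_matching_window_is_negative_at_min_hits_two(self, kset):
        # filler 'T' cannot extend the monomer prefix (MONOMER[18] is 'G'),
        # so exactly one window matches
        read = MONOMER[:18] + "T" * 60
        n_pos, _, _ = cr.count_kmer_positive_reads([read], kset)
        assert n_pos == 0

    def test_engineered_fraction(self, kset):
        positives = [MONOMER[i : i + 60] for i in range(4)]  # dense in set k-mers
        negatives = ["GC" * 30, "G" * 60, "CCCGGG" * 10, "GGGGCC" * 10,
                     "CGCGCG" * 10, "GCCGGC" * 10]
        _, n_total, frac = cr.count_kmer_positive_reads(positives + negatives, kset)
        assert n_total == 10 and frac == pytest.approx(0.4)

    def test_strand_invariance(self, kset):
        rng = np.random.default_rng(0)
        reads = [MONOMER[i : i + 40] for i in range(10)]
        reads += ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
        fwd = cr.count_kmer_positive_reads(reads, kset)
        rev = cr.count_kmer_positive_reads([_revcomp(r) for r in reads], kset)
        assert fwd[:2] == rev[:2]

    def test_short_read_counts_total_never_positive(self, kset):
        n_pos, n_total, _ = cr.count_kmer_positive_reads(["ACGT"], kset)
        assert (n_pos, n_total) == (0, 1)

    def test_n_windows_never_match(self, kset):
        read = MONOMER[:17] + "N" + MONOMER[18:40]
        # every window covering the N is dead; sufficient intact windows remain
        n_pos, _, _ = cr.count_kmer_positive_reads([read], kset)
        assert n_pos == 1  # windows beyond position 18 are intact
        dead = MONOMER[:18].replace(MONOMER[17], "N") + "G" * 30
        assert cr.count_kmer_positive_reads([dead], kset)[0] == 0

    def test_repeated_kmer_counts_twice_unless_distinct(self, kset):
        km = MONOMER[:18]
        read = km + "T" * 10 + km  # 'T' filler: neither extends nor precedes km
        assert cr.count_kmer_positive_reads([read], kset)[0] == 1
        assert cr.count_kmer_positive_reads([read], kset, distinct=True)[0] == 0

    def test_canonicalization(self):
        assert canonical_kmer("TTTT") == "AAAA"
        assert canonical_kmer("ACGT") == "ACGT"


class TestProfileAndDomains:
    def _counts(self, values, bin_width=2000):
        return cr.BinnedCounts(
            {("c", i * bin_width): v for i, v in enumerate(values)}, bin_width
        )

    def test_identical_tracks_give_zero_everywhere(self):
        a = self._counts([10, 20, 30])
        df = cr.binned_log2_profile(a, a)
        assert (df["log2_ratio"] == 0).all()

    def test_32x_bin_is_about_log2_32(self):
        sample = self._counts([3200, 1000, 1000])
        reference = self._counts([100, 1000, 1000])
        # Different totals: equalization rescales, so use large counts and
        # check the hot bin sits near log2(32 * R/S) after scaling.
        df = cr.binned_log2_profile(sample, reference, pseudocount=0.01)
        ts, tr = sample.total(), reference.total()
        expected = np.log2((3200 / ts) / (100 / tr))
        assert df["log2_ratio"].iloc[0] == pytest.approx(expected, abs=0.01)

    def test_bins_zero_in_both_give_zero(self):
        sample = self._counts([0, 10])
        reference = self._counts([0, 10])
        df = cr.binned_log2_profile(sample, reference)
        assert df["log2_ratio"].iloc[0] == 0.0

    def test_mismatched_bin_width_rejected(self):
        with pytest.raises(ValueError):
            cr.binned_log2_profile(self._counts([1], 2000), self._counts([1], 1000))

    def test_all_bins_above_threshold_one_domain(self):
        profile = pd.DataFrame(
            {"chrom": "c", "bin_start": [0, 2000, 4000], "fold": [6.0, 6.0, 6.0]}
        )
        [d] = cr.call_domains(profile, bin_width=2000)
        assert (d.start, d.end) == (0, 6000) and d.mean_fold == pytest.approx(6.0)

    def test_gap_handling(self):
        profile = pd.DataFrame(
            {"chrom": "c", "bin_start": [0, 2000, 4000, 6000], "fold": [6, 6, 1, 6]}
        )
        assert len(cr.call_domains(profile, 2000, max_gap_bins=0)) == 2
        merged = cr.call_domains(profile, 2000, max_gap_bins=1)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 8000)

    def test_threshold_is_strict(self):
        profile = pd.DataFrame({"chrom": "c", "bin_start": [0, 2000], "fold": [5.0, 4.9]})
        assert cr.call_domains(profile, 2000, min_fold=5) == []

    def test_mirror_invariance(self):
        folds = [1, 6, 6, 1, 6, 1]
        starts = [i * 2000 for i in range(6)]
        profile = pd.DataFrame({"chrom": "c", "bin_start": starts, "fold": folds})
        mirrored = pd.DataFrame(
            {"chrom": "c", "bin_start": starts, "fold": folds[::-1]}
        )
        total = starts[-1] + 2000
        fwd = [(d.start, d.end) for d in cr.call_domains(profile, 2000)]
        rev = sorted((total - e, total - s) for d in cr.call_domains(mirrored, 2000)
                     for s, e in [(d.start, d.end)])
        assert sorted(fwd) == rev

    def test_domain_region_coverage(self):
        domains = [cr.EnrichmentDomain("c", 1000, 2000, 7.0)]
        regions = cr.RegionSet(
            [cr.Region("c", 0, 4000, "HOR"), cr.Region("c", 1000, 2000, "cen_region"),
             cr.Region("c", 10000, 11000, "HSat2")]
        )
        df = cr.domain_region_coverage(domains, regions)
        by_label = df.set_index("label")
        assert by_label.loc["HOR", "proportion"] == pytest.approx(0.25)
        assert by_label.loc["cen_region", "proportion"] == 1.0
        assert by_label.loc["HSat2", "proportion"] == 0.0


class TestUncutSites:
    def test_identical_read_sets_give_100_percent(self, panel):
        reads = ["AAACCAGGTTT", "CCAGGCCAGG", "TTTT"]
        result = cr.uncut_site_fraction(reads, list(reads), [panel["ScrFI"]])
        assert result["ScrFI"] == pytest.approx(100.0)
        assert result["pooled"] == pytest.approx(100.0)

    def test_site_free_sample_gives_zero(self, panel):
        reference = ["AAACCAGGTTT"]
        sample = ["AAATTTAAATT"]
        result = cr.uncut_site_fraction(sample, reference, [panel["ScrFI"]])
        assert result["ScrFI"] == 0.0

    def test_derived_ratio(self, panel):
        # reference: 40 occurrences, sample: 6 -> 15%
        reference = ["AAACCAGGTTT"] * 40
        sample = ["AAACCAGGTTT"] * 6 + ["AAATTTAAATT"] * 34
        result = cr.uncut_site_fraction(sample, reference, [panel["ScrFI"]])
        assert result["ScrFI"] == pytest.approx(15.0)

    def test_overlapping_occurrences_all_counted(self, panel):
        # CCCGGG contains CCNGG candidates at 0 and 1: reads are observations,
        # so both count (no greedy resolution).
        result = cr.uncut_site_fraction(["CCCGGG"], ["CCCGGG"], [panel["ScrFI"]])
        assert result["ScrFI"] == pytest.approx(100.0)
        ref_only = cr.uncut_site_fraction(["CCAGGT"], ["CCCGGG"], [panel["ScrFI"]])
        assert ref_only["ScrFI"] == pytest.approx(50.0)  # 1 of 2 occurrences

    def test_zero_reference_reported_absent(self, panel):
        result = cr.uncut_site_fraction(["ACGT"], ["ACGT"], [panel["ScrFI"]])
        assert result["ScrFI"] is None and result["pooled"] is None


class TestLengthChangeAndCoverage:
    def test_length_change_cases(self):
        a = {"cen1": 120.0, "cen2": 150.0, "cen3": 80.0, "cen4": 10.0}
        b = {"cen1": 160.0, "cen2": 100.0, "cen3": 80.0, "cen4": 0.0}
        out = cr.length_change(a, b)
        assert out["cen1"] == pytest.approx(-25.0)
        assert out["cen2"] == pytest.approx(50.0)
        assert out["cen3"] == pytest.approx(0.0)
        assert out["cen4"] is None

    def test_coverage_table_derived(self):
        df = cr.coverage_threshold_table([0, 5, 15, 25], [0, 10])
        assert df["pct_bins"].tolist() == [100.0, 50.0]

    def test_coverage_table_non_increasing(self):
        rng = np.random.default_rng(4)
        cov = rng.poisson(10, size=500)
        df = cr.coverage_threshold_table(cov, list(range(0, 31, 5)))
        assert (df["pct_bins"].diff().dropna() <= 0).all()
        assert df["pct_bins"].iloc[0] == 100.0
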