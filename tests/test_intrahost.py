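import numpy as np
import pytest

from symbiocoal.intrahost import (
    call_within_host_variants,
    read_pair_four_gamete,
    within_host_folded_afs,
)
from symbiocoal.io_formats import PileupColumn
from symbiocoal.synthetic_data import PhaseObservation, ReadSimSpec, make_reads


def column(position, depth, alt_count, alt_base="T", ref="A", has_indel=False):
    calls = "." * (depth - alt_count) + alt_base * alt_count
    return PileupColumn(chrom="ref", position=position, ref_base=ref, depth=depth,
                        base_calls=calls, base_qualities="I" * depth,
                        has_indel=has_indel)


class TestBinomialCaller:
    def test_single_alternate_read_is_not_called(self):
        # P(X >= 1 | 100, 0.01) ~= 0.634
        cols = [column(i + 1, 100, 1 if i == 0 else 0) for i in range(20)]
        result = call_within_host_variants(cols, error_rate=0.01, alpha=0.05)
        assert result.variants == []

    def test_ten_alternate_reads_are_called(self):
        # P(X >= 10 | 100, 0.01) ~= 1.1e-7
        cols = [column(i + 1, 100, 10 if i == 0 else 0) for i in range(20)]
        result = call_within_host_variants(cols, error_rate=0.01, alpha=0.05)
        assert [v.position for v in result.variants] == [1]
        assert result.variants[0].alt_freq == pytest.approx(0.1)

    def test_high_coverage_columns_are_excluded(self):
        cols = [column(i + 1, 100, 0) for i in range(30)]
        cols.append(column(31, 300, 50))  # 3x the mean, huge alt count
        result = call_within_host_variants(cols, error_rate=0.01)
        assert result.variants == []
        assert result.n_coverage_filtered >= 1

    def test_sites_near_indels_are_excluded(self):
        cols = [column(i + 1, 100, 0) for i in range(30)]
        cols[14] = column(15, 100, 0, has_indel=True)
        cols[16] = column(17, 100, 30)  # 2 bp from the indel column
        result = call_within_host_variants(cols, error_rate=0.01, indel_window=5)
        assert result.variants == []
        assert result.n_indel_filtered >= 1

    def test_all_filtered_returns_status_not_error(self):
        # every column is itself indel-bearing, so all are excluded
        cols = [column(i + 1, 100, 0, has_indel=True) for i in range(3)]
        result = call_within_host_variants(cols, error_rate=0.01)
        assert result.status == "all columns filtered"
        assert np.isnan(result.pairwise_diversity)

    def test_phred_derived_error_rate(self):
        # quality 'I' = phred 40 = 1e-4; 3 alt reads at depth 100 clear alpha
        cols = [column(i + 1, 100, 3 if i == 0 else 0) for i in range(20)]
        result = call_within_host_variants(cols, error_rate=None, alpha=0.05)
        assert [v.position for v in result.variants] == [1]
        assert result.variants[0].error_prob_used == pytest.approx(1e-4)


class TestWithinHostAFS:
    def test_folding_of_high_frequency_variant(self):
        cols = [column(i + 1, 100, 0) for i in range(10)]
        cols[0] = column(1, 100, 90)
        result = call_within_host_variants(cols, error_rate=0.01)
        afs = within_host_folded_afs(result.variants, n_bins=10)
        assert afs.counts.sum() == 1
        assert int(np.argmax(afs.counts)) in (1, 2)  # the bins straddling 0.1

    def test_no_variants_yields_zero_histogram_with_status(self):
        afs = within_host_folded_afs([], n_bins=5)
        assert afs.counts.sum() == 0 and afs.status == "no variants"

    def test_balanced_mixture_mass_at_half(self):
        spec = ReadSimSpec(
            haplotypes=("A" * 2_000, "A" * 1_000 + "T" + "A" * 999),
            weights=(0.5, 0.5), depth=200, error_rate=0.0, read_length=100,
            insert_mean=300, insert_sd=25, seed=3,
        )
        rs = make_reads(spec)
        result = call_within_host_variants(rs.pileup, error_rate=1e-3)
        afs = within_host_folded_afs(result.variants, n_bins=10)
        assert afs.counts.sum() >= 1
        assert afs.counts[-2:].sum() == afs.counts.sum()  # everything near 0.5


def _phase_obs(counts):
    obs = []
    k = 0
    for config, n in counts.items():
        for _ in range(n):
            obs.append(PhaseObservation(
                f"r{k}", 10, "A" if config[0] == "A" else "C",
                20, "G" if config[1] == "B" else "T"))
            k += 1
    return obs


class TestReadPairFourGamete:
    def test_two_haplotype_mixture_is_never_flagged(self):
        tally = read_pair_four_gamete(_phase_obs({"AB": 120, "ab": 80}))
        assert tally.flagged() == []

    def test_balanced_four_gamete_pair_is_flagged(self):
        tally = read_pair_four_gamete(_phase_obs({"AB": 30, "Ab": 30, "aB": 30, "ab": 30}))
        (pair,) = tally.pairs
        assert pair.all_four_flag and pair.total == 120

    def test_rare_configurations_below_cutoff_are_not_flagged(self):
        tally = read_pair_four_gamete(_phase_obs({"AB": 94, "Ab": 2, "aB": 2, "ab": 2}))
        (pair,) = tally.pairs
        assert not pair.all_four_flag  # 0.02 <= 0.05

    def test_total_below_minimum_is_reported_not_flagged(self):
        tally = read_pair_four_gamete(_phase_obs({"AB": 25, "Ab": 25, "aB": 25, "ab": 24}))
        (pair,) = tally.pairs
        assert pair.total == 99
        assert not pair.all_four_flag
        assert pair.status == "below minimum observations"

    def test_proportion_exactly_at_cutoff_is_not_flagged(self):
        tally = read_pair_four_gamete(_phase_obs({"AB": 85, "Ab": 5, "aB": 5, "ab": 5}))
        (pair,) = tally.pairs
        assert not pair.all_four_flag  # 0.05 is not > 0.05

    def test_unknown_bases_are_discarded_and_counted(self):
        obs = _phase_obs({"AB": 60, "ab": 60})
        obs.append(PhaseObservation("weird", 10, "G", 20, "G"))
        tally = read_pair_four_gamete(obs)
        assert tally.n_discarded_observations == 1

    def test_three_haplotype_mixtures_are_never_flagged(self):
        """Without errors, reads from <= 3 haplotypes cannot show 4 gametes."""
        rng = np.random.default_rng(8)
        haps = ["AB", "Ab", "aB"]
        counts = {h: int(n) for h, n in zip(haps, rng.multinomial(600, [1/3]*3))}
        tally = read_pair_four_gamete(_phase_obs(counts))
        assert tally.flagged() == []


class TestReadBackedVersusConsensus:
    def test_read_backed_sees_at_least_consensus_failures(self):
        """Pooling reads across hosts samples more lineages than per-host
        consensus genomes, so the read-backed four-gamete failure proportion
        is at least the consensus-based one on the same loci."""
        from symbiocoal.io_formats import HaplotypeAlignment
        from symbiocoal.sumstats import four_gamete_profile

        L = 1_000
        base = ["A"] * L
        sites = (500, 560)

        def hap(a, b):
            s = base.copy()
            s[sites[0] - 1] = a
            s[sites[1] - 1] = b
            return "".join(s)

        # two hosts, each a 60:40 mixture; dominant haplotypes show only two
        # gametes, the full mixture all four
        host_mixtures = [
            ((hap("A", "C"), hap("T", "G")), (0.6, 0.4)),
            ((hap("T", "C"), hap("A", "G")), (0.6, 0.4)),
        ]
        all_obs = []
        for i, (haps, w) in enumerate(host_mixtures):
            rs = make_reads(ReadSimSpec(
                haplotypes=haps, weights=w, depth=150, error_rate=0.0,
                read_length=100, insert_mean=200, insert_sd=10, seed=40 + i))
            all_obs.extend(rs.phase_observations)
        site_alleles = {sites[0]: ("A", "T"), sites[1]: ("C", "G")}
        tally = read_pair_four_gamete(all_obs, site_alleles=site_alleles)
        eligible = [p for p in tally.pairs if p.status == "ok"]
        read_backed = sum(p.all_four_flag for p in eligible) / len(eligible)

        consensus = HaplotypeAlignment(
            sample_ids=["h1", "h2"],
            sequences=[m[0][0] for m in host_mixtures],
        )
        props, totals, _ = four_gamete_profile(consensus)
        consensus_prop = float(np.nansum(props[totals > 0])) if totals.sum() else 0.0
        assert read_backed >= consensus_prop
        assert read_backed == 1.0
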