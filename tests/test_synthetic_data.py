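import numpy as np
import pytest

from conftest import bootstrap_ci
from symbiocoal.coalescent_gc import SimParams
from symbiocoal.io_formats import write_fasta_alignment
from symbiocoal.sumstats import fst_between_hosts, host_group_frequencies
from symbiocoal.synthetic_data import (
    ReadSimSpec,
    _pileup_from_reads,
    fixture_F1,
    make_metapopulation_alignment,
    make_reads,
    make_vcf_fixture,
)
from symbiocoal.transmission_model import TransmissionParams


class TestFixtureF1:
    def test_structure(self):
        aln = fixture_F1()
        assert aln.n_samples == 4 and aln.genome_length == 100
        assert aln.variant_positions == [10, 50, 90]
        counts = []
        for pos in aln.variant_positions:
            col = aln.column(pos)
            counts.append(min(col.count("A"), col.count("T")))
        assert counts == [1, 2, 2]


class TestVcfFixture:
    def test_truth_table_round_trips_through_filter(self):
        from symbiocoal.io_formats import filter_consensus_sites

        records, truth = make_vcf_fixture(7, 5, seed=2)
        kept = {r.position for r in filter_consensus_sites(records, "genotyping")}
        for rec, ok in zip(records, truth):
            assert (rec.position in kept) == ok

    def test_mq0_only_violation_is_removed(self):
        from symbiocoal.io_formats import filter_consensus_sites

        records, truth = make_vcf_fixture(0, 4, seed=0)
        mq0_offenders = [r for r in records if r.mq0_reads == 6]
        assert mq0_offenders  # the cycle includes an MQ0-only violation
        assert filter_consensus_sites(records, "genotyping") == []


class TestMakeReads:
    def test_single_error_free_haplotype_has_no_alternate_calls(self):
        spec = ReadSimSpec(haplotypes=("ACGT" * 500,), weights=(1.0,), depth=30,
                           error_rate=0.0, read_length=100, insert_mean=250,
                           insert_sd=20, seed=1)
        rs = make_reads(spec)
        for col in rs.pileup:
            assert set(col.base_calls) <= {"."}

    def test_pileup_regenerates_identically_from_reads(self):
        spec = ReadSimSpec(haplotypes=("ACGT" * 500,), weights=(1.0,), depth=20,
                           error_rate=0.01, read_length=80, insert_mean=220,
                           insert_sd=15, seed=4)
        rs = make_reads(spec)
        regen = _pileup_from_reads(rs.reads, rs.reference, "ref", "%")
        assert len(regen) == len(rs.pileup)
        for a, b in zip(rs.pileup, regen):
            assert (a.position, a.depth, a.base_calls) == (b.position, b.depth, b.base_calls)

    def test_balanced_mixture_allele_frequencies(self):
        L = 4_000
        h1 = "A" * L
        h2 = "A" * 2_000 + "T" + "A" * (L - 2_001)
        spec = ReadSimSpec(haplotypes=(h1, h2), weights=(0.5, 0.5), depth=200,
                           error_rate=0.0, read_length=100, insert_mean=300,
                           insert_sd=25, seed=7)
        rs = make_reads(spec)
        (col,) = [c for c in rs.pileup if c.position == 2_001]
        alt = col.allele_counts().get("T", 0)
        lo, hi = (np.array([-1, 1]) * 2.58 * np.sqrt(col.depth * 0.25)) + col.depth / 2
        assert lo <= alt <= hi

    def test_depth_accounting(self):
        L, R, depth = 3_000, 100, 60
        spec = ReadSimSpec(haplotypes=("ACGT" * (L // 4),), weights=(1.0,),
                           depth=depth, error_rate=0.0, read_length=R,
                           insert_mean=300, insert_sd=20, seed=9)
        rs = make_reads(spec)
        total = sum(c.depth for c in rs.pileup)
        n_pairs = len(rs.reads) // 2
        assert total == n_pairs * 2 * R  # every read base lands in one column

    def test_read_length_guard(self):
        with pytest.raises(ValueError):
            ReadSimSpec(haplotypes=("ACGT",), weights=(1.0,), depth=10,
                        error_rate=0.0, read_length=10, insert_mean=20,
                        insert_sd=1, seed=0)


class TestMetapopulationAlignment:
    def test_seeded_call_is_byte_identical(self, tmp_path):
        params = SimParams(theta=1e-3, rho=1e-4, tract_length=500,
                           genome_length=5_000, sample_size=6, seed=0)
        a = make_metapopulation_alignment(params, hosts_sampled=3,
                                          symbionts_per_host=2, seed=5)
        b = make_metapopulation_alignment(params, hosts_sampled=3,
                                          symbionts_per_host=2, seed=5)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta_alignment(a, pa)
        write_fasta_alignment(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_mutation_off_gives_identical_sequences(self):
        params = TransmissionParams(n_hosts=10, n_symbionts=5, horizontal_rate=0.2,
                                    mutation_rate=0.0, bottleneck=2, seed=1)
        aln = make_metapopulation_alignment(params, hosts_sampled=4,
                                            symbionts_per_host=2, seed=2,
                                            genome_length=2_000)
        assert len(set(aln.sequences)) == 1

    def test_transmission_mode_drives_host_differentiation(self):
        """Strict vertical transmission differentiates hosts (Fst near 1 with
        intervals excluding 0); full horizontal transmission mixes them. The
        forward model carries no within-genome recombination, so a single
        replicate's Fst fluctuates with its one genealogy; the contrast is
        asserted on several seeded replicates."""
        def fst_for(h, b, seed):
            params = TransmissionParams(n_hosts=30, n_symbionts=8,
                                        horizontal_rate=h, mutation_rate=0.3,
                                        bottleneck=b, seed=seed)
            aln = make_metapopulation_alignment(params, hosts_sampled=4,
                                                symbionts_per_host=4, seed=seed,
                                                genome_length=20_000)
            hosts = sorted(set(aln.host_ids))
            f1, f2, n1, n2 = host_group_frequencies(aln, hosts[0], hosts[1])
            try:
                return fst_between_hosts(f1, f2, n1, n2, n_bootstrap=200, seed=seed)
            except ValueError:  # no informative sites this replicate
                return None

        vertical = [fst_for(0.0, 1, seed=20 + s) for s in range(6)]
        horizontal = [fst_for(1.0, 4, seed=20 + s) for s in range(6)]
        v_fst = [r.fst for r in vertical if r is not None]
        h_fst = [r.fst for r in horizontal if r is not None]
        assert np.mean(v_fst) > 0.6
        assert np.mean(h_fst) < 0.3
        assert np.mean(v_fst) > np.mean(h_fst) + 0.3
        strongly_differentiated = [r for r in vertical if r is not None and r.fst > 0.5]
        assert len(strongly_differentiated) >= 4
        assert all(r.ci_low > 0 for r in strongly_differentiated)
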