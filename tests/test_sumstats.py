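import math

import numpy as np
import pytest
from scipy import stats

from symbiocoal.coalescent_gc import SimParams, simulate_coalescent_gc
from symbiocoal.io_formats import HaplotypeAlignment
from symbiocoal.sumstats import (
    F4_BIN_EDGES,
    folded_afs,
    four_gamete_profile,
    fst_between_hosts,
    host_group_frequencies,
    nucleotide_diversity,
    summarize_alignment,
    tajimas_d,
    watterson_theta,
)


def aln_from(seqs, **kw):
    return HaplotypeAlignment(
        sample_ids=[f"s{i}" for i in range(len(seqs))], sequences=list(seqs), **kw
    )


class TestDiversityEstimators:
    def test_pi_single_pair(self):
        a = "A" * 100
        b = "A" * 96 + "CGTC"  # differs at 4 of 100 sites
        assert nucleotide_diversity(aln_from([a, b])) == pytest.approx(0.04)

    def test_pi_identical_sequences(self):
        assert nucleotide_diversity(aln_from(["ACGT" * 25] * 3)) == 0.0

    def test_f1_fixture_values(self, f1_alignment):
        assert nucleotide_diversity(f1_alignment) == pytest.approx(11 / 6 / 100)
        assert watterson_theta(f1_alignment) == pytest.approx(3 / ((11 / 6) * 100))
        assert tajimas_d(f1_alignment).d == pytest.approx(1.09, abs=0.01)

    def test_watterson_values(self):
        two = aln_from(["A" * 100, "C" * 3 + "A" * 97])
        assert watterson_theta(two) == pytest.approx(0.03)
        assert watterson_theta(aln_from(["A" * 50] * 2)) == 0.0
        # n = 4, S = 11, L = 1000: 11 / (a3 * 1000)
        base = ["A"] * 1000
        s2 = base.copy()
        for i in range(11):
            s2[i * 7] = "G"
        four = aln_from(["".join(base)] * 3 + ["".join(s2)])
        assert watterson_theta(four) == pytest.approx(11 / ((11 / 6) * 1000))

    def test_pi_equals_watterson_for_pairs(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            rep = simulate_coalescent_gc(
                SimParams(theta=2e-3, rho=0.0, tract_length=1, genome_length=2_000,
                          sample_size=2, seed=seed)
            )
            a = rep.alignment
            assert nucleotide_diversity(a) == pytest.approx(watterson_theta(a))

    def test_tajima_undefined_without_segregating_sites(self):
        r = tajimas_d(aln_from(["ACGT" * 10] * 4))
        assert not r.defined and math.isnan(r.d)

    def test_tajima_sign_matches_estimator_difference(self):
        for seed in range(8):
            rep = simulate_coalescent_gc(
                SimParams(theta=2e-3, rho=0.0, tract_length=1, genome_length=5_000,
                          sample_size=6, seed=100 + seed)
            )
            a = rep.alignment
            r = tajimas_d(a)
            if not r.defined:
                continue
            diff = nucleotide_diversity(a) - watterson_theta(a)
            assert r.d == 0 if diff == 0 else np.sign(r.d) == np.sign(diff)


class TestFoldedAFS:
    def test_f1_fixture_tally(self, f1_alignment):
        afs = folded_afs(f1_alignment)
        assert afs.counts.tolist() == [1, 2]

    def test_monomorphic_alignment_is_empty(self):
        assert folded_afs(aln_from(["ACGT" * 5] * 4)).n_sites == 0

    def test_total_matches_biallelic_site_count(self):
        rep = simulate_coalescent_gc(
            SimParams(theta=3e-3, rho=0.0, tract_length=1, genome_length=10_000,
                      sample_size=8, seed=5)
        )
        afs = folded_afs(rep.alignment)
        assert afs.n_sites == len(rep.alignment.variant_positions)

    def test_neutral_spectrum_shape(self):
        """Pooled neutral replicates follow the folded-SFS expectation
        proportional to 1/i + 1/(n-i) (halved at i = n/2). Uncertainty is
        assessed by bootstrapping whole replicates, since sites within a
        replicate share a genealogy and are not independent."""
        n, reps = 10, 200
        counts = np.zeros((reps, n // 2))
        for seed in range(reps):
            rep = simulate_coalescent_gc(
                SimParams(theta=1e-3, rho=0.0, tract_length=1, genome_length=20_000,
                          sample_size=n, seed=3_000 + seed)
            )
            counts[seed] = folded_afs(rep.alignment).counts
        expected = np.array(
            [1 / i + 1 / (n - i) if i != n - i else 1 / i for i in range(1, n // 2 + 1)]
        )
        expected /= expected.sum()
        pooled = counts.sum(axis=0)
        observed = pooled / pooled.sum()
        rng = np.random.default_rng(1)
        boots = np.empty((400, n // 2))
        for b in range(400):
            c = counts[rng.integers(reps, size=reps)].sum(axis=0)
            boots[b] = c / c.sum()
        z = (observed - expected) / boots.std(axis=0)
        assert np.abs(z).max() < 4.0


class TestFourGameteProfile:
    def test_all_four_combinations_in_first_bin(self):
        seqs = ["A" * 4 + "A" + "C" * 6 + "C" + "G" * 8,
                "A" * 4 + "A" + "C" * 6 + "G" + "G" * 8,
                "A" * 4 + "T" + "C" * 6 + "C" + "G" * 8,
                "A" * 4 + "T" + "C" * 6 + "G" + "G" * 8]
        props, totals, _ = four_gamete_profile(aln_from(seqs))
        assert totals[0] == 1 and props[0] == 1.0

    def test_singleton_pairs_are_not_counted(self, f1_alignment):
        # F1's site 10 is a singleton; only the (50, 90) pair is eligible
        _, totals, _ = four_gamete_profile(f1_alignment)
        assert totals.sum() == 1

    def test_empty_bins_are_nan_not_zero(self, f1_alignment):
        props, totals, _ = four_gamete_profile(f1_alignment)
        assert np.isnan(props[totals == 0]).all()

    def test_invariant_to_sample_order_and_allele_relabeling(self):
        rep = simulate_coalescent_gc(
            SimParams(theta=2e-3, rho=5e-4, tract_length=500, genome_length=10_000,
                      sample_size=6, seed=9)
        )
        a = rep.alignment
        props, totals, _ = four_gamete_profile(a)
        shuffled = aln_from([a.sequences[i] for i in (3, 0, 5, 1, 4, 2)])
        props2, totals2, _ = four_gamete_profile(shuffled)
        assert np.array_equal(totals, totals2)
        assert np.allclose(props, props2, equal_nan=True)
        comp = str.maketrans("ACGT", "TGCA")
        complemented = aln_from([s.translate(comp) for s in a.sequences])
        props3, totals3, _ = four_gamete_profile(complemented)
        assert np.array_equal(totals, totals3)
        assert np.allclose(props, props3, equal_nan=True)

    def test_bin_edges_are_left_open_right_closed(self):
        # distances 10 and 11 straddle the first bin edge
        base = ["A"] * 200
        seqs = []
        for k in range(4):
            s = base.copy()
            s[9] = "AATT"[k]
            s[19] = "ATAT"[k]
            s[30] = "TAAT"[k]
            seqs.append("".join(s))
        _, totals, _ = four_gamete_profile(aln_from(seqs))
        # pairs: (10,20) d=10 -> bin 1; (10,31) d=21, (20,31) d=11 -> bin 2
        assert totals[0] == 1 and totals[1] == 2


class TestHudsonFst:
    def test_fixed_differences_give_one(self):
        r = fst_between_hosts([1.0, 1.0], [0.0, 0.0], n_bootstrap=50, seed=0)
        assert r.fst == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        r = fst_between_hosts([0.3, 0.6], [0.3, 0.6], n_bootstrap=50, seed=0)
        assert r.fst == pytest.approx(0.0)

    def test_single_site_frequency_only_value(self):
        r = fst_between_hosts([0.2], [0.8], n_bootstrap=50, seed=0)
        assert r.fst == pytest.approx(0.36 / 0.68)

    def test_point_estimate_inside_bootstrap_interval(self):
        rng = np.random.default_rng(4)
        inside = 0
        for seed in range(30):
            p1 = rng.uniform(0, 1, size=40)
            p2 = np.clip(p1 + rng.normal(0, 0.2, size=40), 0, 1)
            r = fst_between_hosts(p1, p2, n_bootstrap=300, seed=seed)
            inside += r.ci_low <= r.fst <= r.ci_high
        assert inside >= 29

    def test_requires_usable_sites(self):
        with pytest.raises(ValueError):
            fst_between_hosts([0.0], [0.0], n_bootstrap=10, seed=0)

    def test_host_group_frequencies_from_alignment(self, f1_alignment):
        f1, f2, n1, n2 = host_group_frequencies(f1_alignment, "host0", "host1")
        assert n1 == n2 == 1
        assert len(f1) == 3


class TestSummaryVector:
    def test_feature_row_order_matches_contract(self, f1_alignment):
        sv = summarize_alignment(f1_alignment)
        row = sv.as_row()
        assert row[0] == pytest.approx(sv.pi)
        assert row[1] == pytest.approx(sv.watterson)
        assert len(row) == len(sv.TSV_COLUMNS) == 10
        assert row[8] == 4 and row[9] == 100
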