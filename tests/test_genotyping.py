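"""Pair counting, the Poisson genotype caller, calibration, the HWE
exact test (against a direct-enumeration oracle), and cohort filters."""

import itertools
from math import exp, lgamma, log

import numpy as np
import pytest

from alukit import (
    CallerModel,
    calibrate,
    call_genotype,
    cohort_filter,
    count_pairs,
    hwe_exact_test,
    kmers,
)
from alukit.genotyping import GenotypeCall, PairCounts, expected_ploidy
from alukit.pair_builder import REF_MINUS, REF_PLUS, KmerPair
from alukit.ref_index import GenomeLocation
from conftest import rand_seq


def make_pair(rng, eid="e1", chrom="chr1"):
    flank = rand_seq(rng, 25)
    return KmerPair(eid, REF_MINUS, GenomeLocation(chrom, 100, "+"),
                    flank + "TTTAACC", flank + "GGCCGGG")


class TestCountPairs:
    def test_counts_kmerA_occurrences(self, rng):
        p = make_pair(rng)
        reads = [rand_seq(rng, 30) + p.kmerA + rand_seq(rng, 30)] * 10
        (c,) = count_pairs(reads, [p])
        assert (c.nA, c.nB) == (10, 0)

    def test_reverse_complement_reads_count_identically(self, rng):
        p = make_pair(rng)
        reads = [rand_seq(rng, 30) + p.kmerA + rand_seq(rng, 30)] * 10
        (c,) = count_pairs([kmers.revcomp(r) for r in reads], [p])
        assert (c.nA, c.nB) == (10, 0)

    def test_reads_without_pair_kmers(self, rng):
        p = make_pair(rng)
        (c,) = count_pairs([rand_seq(rng, 100) for _ in range(5)], [p])
        assert (c.nA, c.nB) == (0, 0)

    def test_double_occurrence_counts_twice(self, rng):
        p = make_pair(rng)
        (c,) = count_pairs([p.kmerB + "TT" + p.kmerB], [p])
        assert (c.nA, c.nB) == (0, 2)


def posterior_oracle(nA, nB, hyps):
    """Flat-prior Poisson posterior computed from first principles."""
    def logpois(n, mu):
        return n * log(mu) - mu - lgamma(n + 1)
    lls = [logpois(nA, a) + logpois(nB, b) for a, b in hyps]
    mx = max(lls)
    ws = [exp(x - mx) for x in lls]
    return [w / sum(ws) for w in ws]


class TestCallGenotype:
    MODEL = CallerModel(lam=30, eps=0.3, min_posterior=0.99)

    @pytest.mark.parametrize(
        "counts,expected",
        [((30, 0), "AA"), ((0, 30), "BB"), ((14, 15), "AB"),
         ((0, 0), "NC"), ((15, 16), "AB")],
    )
    def test_diploid_examples(self, counts, expected):
        call = call_genotype(PairCounts("e", *counts), self.MODEL, ploidy=2)
        assert call.genotype == expected

    def test_posterior_matches_first_principles(self):
        hyps = [(30, 0.3), (15, 15), (0.3, 30)]
        for counts in [(30, 0), (14, 15), (5, 5), (0, 0), (22, 8)]:
            call = call_genotype(PairCounts("e", *counts), self.MODEL, ploidy=2)
            oracle = posterior_oracle(*counts, hyps)
            assert call.posterior == pytest.approx(max(oracle), rel=1e-9)

    def test_haploid_calls(self):
        assert call_genotype(PairCounts("e", 28, 0), self.MODEL, 1).genotype == "A"
        assert call_genotype(PairCounts("e", 0, 28), self.MODEL, 1).genotype == "B"

    def test_caller_symmetry_under_allele_swap(self):
        swap = {"AA": "BB", "BB": "AA", "AB": "AB", "NC": "NC"}
        for nA, nB in [(30, 0), (14, 15), (3, 27), (9, 9), (1, 2)]:
            fwd = call_genotype(PairCounts("e", nA, nB), self.MODEL, 2)
            rev = call_genotype(PairCounts("e", nB, nA), self.MODEL, 2)
            assert rev.genotype == swap[fwd.genotype]
            assert rev.posterior == pytest.approx(fwd.posterior, rel=1e-9)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            CallerModel(lam=0, eps=0.1)
        with pytest.raises(ValueError):
            CallerModel(lam=10, eps=20)
        with pytest.raises(ValueError):
            CallerModel(lam=10, eps=0.1, min_posterior=0.4)


class TestCalibrate:
    def test_median_total_count(self):
        counts = [PairCounts(f"e{i}", 30, 0) for i in range(60)] + \
                 [PairCounts(f"f{i}", 0, 30) for i in range(60)]
        model = calibrate(counts)
        assert model.lam == 30
        assert model.eps == pytest.approx(0.3)

    def test_uninformative_set_requires_fallback(self):
        counts = [PairCounts(f"e{i}", 0, 0) for i in range(200)]
        with pytest.raises(ValueError):
            calibrate(counts)
        model = calibrate(counts, fallback_lam=25)
        assert model.lam == 25

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate([])


def hwe_oracle(naa, nab, nbb):
    """Exact test by direct enumeration of heterozygote configurations."""
    n = naa + nab + nbb
    na = 2 * naa + nab
    configs = []
    for h in range(min(na, 2 * n - na) + 1):
        if (na - h) % 2:
            continue
        configs.append(h)
    def logp(h):
        return (h * log(2) + lgamma(n + 1) - lgamma(h + 1)
                - lgamma((na - h) // 2 + 1) - lgamma((2 * n - na - h) // 2 + 1))
    mx = max(logp(h) for h in configs)
    tot = sum(exp(logp(h) - mx) for h in configs)
    probs = {h: exp(logp(h) - mx) / tot for h in configs}
    po = probs[nab]
    return min(1.0, sum(p for p in probs.values() if p <= po * (1 + 1e-12)))


class TestHweExactTest:
    def test_balanced_table_is_consistent_with_hwe(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=0.2)

    def test_no_heterozygote_table_strongly_rejected(self):
        assert hwe_exact_test(50, 0, 50) < 1e-4

    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(1, 21):
            for naa in range(n + 1):
                for nab in range(n - naa + 1):
                    nbb = n - naa - nab
                    assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                        hwe_oracle(naa, nab, nbb), abs=1e-9
                    ), (naa, nab, nbb)

    def test_matches_enumeration_sampled_to_n50(self, rng):
        for _ in range(200):
            n = int(rng.integers(21, 51))
            naa = int(rng.integers(0, n + 1))
            nab = int(rng.integers(0, n - naa + 1))
            nbb = n - naa - nab
            assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
                hwe_oracle(naa, nab, nbb), abs=1e-9
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _call(eid, gt, ploidy=2):
    return GenotypeCall(eid, ploidy, gt, 1.0)


class TestCohortFilter:
    def cohort(self, gts, eid="e", chrom="chr1", cls=REF_MINUS):
        calls = {eid: {f"i{k}": _call(eid, g) for k, g in enumerate(gts)}}
        meta = {eid: (cls, chrom)}
        sexes = {f"i{k}": "F" for k in range(len(gts))}
        return calls, meta, sexes

    def test_hwe_consistent_element_kept(self):
        gts = ["AA"] * 25 + ["AB"] * 50 + ["BB"] * 25
        calls, meta, sexes = self.cohort(gts)
        validated, rej = cohort_filter(calls, meta, sexes)
        assert validated == ["e"] and rej == []

    def test_hwe_deviant_element_removed(self):
        gts = ["AA"] * 50 + ["BB"] * 50
        calls, meta, sexes = self.cohort(gts)
        validated, rej = cohort_filter(calls, meta, sexes)
        assert validated == [] and ("e", "hwe_deviation") in rej

    def test_monomorphic_ref_minus_removed_ref_plus_kept(self):
        gts = ["AA"] * 40
        calls, meta, sexes = self.cohort(gts, cls=REF_MINUS)
        assert cohort_filter(calls, meta, sexes)[0] == []
        calls, meta, sexes = self.cohort(gts, cls=REF_PLUS)
        assert cohort_filter(calls, meta, sexes)[0] == ["e"]

    def test_unexpected_ploidy_on_chry(self):
        # diploid calls on chrY in males are unexpected
        calls = {"e": {f"i{k}": _call("e", "AA", ploidy=2) for k in range(20)}}
        meta = {"e": (REF_PLUS, "chrY")}
        sexes = {f"i{k}": "M" for k in range(20)}
        validated, rej = cohort_filter(calls, meta, sexes)
        assert ("e", "unexpected_ploidy") in rej
        # haploid calls are what chrY in males should produce
        calls = {"e": {f"i{k}": GenotypeCall("e", 1, "A", 1.0) for k in range(20)}}
        validated, rej = cohort_filter(calls, meta, sexes)
        assert validated == ["e"]

    def test_nc_excluded_from_unexpected_fraction(self):
        calls = {"e": {f"i{k}": GenotypeCall("e", 2, "NC", 0.5) for k in range(20)}}
        meta = {"e": (REF_PLUS, "chrY")}
        sexes = {f"i{k}": "M" for k in range(20)}
        validated, _ = cohort_filter(calls, meta, sexes)
        assert validated == ["e"]

    def test_missing_metadata_rejected(self):
        calls, meta, sexes = self.cohort(["AA"] * 5)
        with pytest.raises(ValueError):
            cohort_filter(calls, {}, sexes)

    def test_expected_ploidy_rules(self):
        assert expected_ploidy("chr1", "M") == 2
        assert expected_ploidy("chrY", "M") == 1
        assert expected_ploidy("chrY", "F") == 0
        assert expected_ploidy("Y", "male") == 1
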