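"""REF+ discovery: TSD detection on constructed loci, homology bit
scores cross-checked against an independent Smith-Waterman
implementation, outgroup absence, and cascade monotonicity."""

import numpy as np
import pytest

from alukit import (
    build_kmer_set,
    build_signature_set,
    discover_ref_plus,
    find_tsd,
    kmers,
    scan_reference,
    score_homology,
)
from alukit.consensus import ALU_CONSENSUS
from alukit.ref_plus import bit_score, outgroup_absent, raw_sw_score
from conftest import rand_seq

SIG = "GGCCGGGCGC"
ALU = {"AluY": ALU_CONSENSUS}


def planted_locus(rng, tsd="ACTGA", d=300, left=500, right=500):
    """flank + TSD + Alu + polyA + TSD + flank, with signature->TSD2
    distance exactly d."""
    polya = "A" * (d - len(ALU_CONSENSUS))
    return rand_seq(rng, left) + tsd + ALU_CONSENSUS + polya + tsd + rand_seq(rng, right)


class TestScanReference:
    def test_planted_signatures_both_strands(self, sigs, rng):
        seq = (rand_seq(rng, 100) + SIG + rand_seq(rng, 200)
               + kmers.revcomp(SIG) + rand_seq(rng, 100)
               + "GGCCGGGCGT" + rand_seq(rng, 100))
        hits = scan_reference({"c": seq}, sigs)
        strands = sorted((h[0].pos, h[0].strand) for h in hits)
        assert (100, "+") in strands
        assert (310, "-") in strands
        assert (420, "+") in strands
        # minus-strand hits report the signature in element orientation
        for loc, sig in hits:
            assert sig in sigs.members

    def test_pure_n_chromosome_gives_no_hits(self, sigs):
        assert scan_reference({"c": "N" * 5000}, sigs) == []

    def test_hit_count_matches_bruteforce(self, sigs, rng):
        seq = rand_seq(rng, 100_000)
        hits = scan_reference({"c": seq}, sigs)
        brute = 0
        members = sigs.members
        for i in range(len(seq) - 9):
            w = seq[i : i + 10]
            brute += (w in members) + (kmers.revcomp(w) in members)
        assert len(hits) == brute


class TestFindTsd:
    def test_constructed_locus_d300(self, sigs, rng):
        genome = {"c": planted_locus(rng, tsd="ACTGA", d=300)}
        hits = scan_reference(genome, sigs)
        hit = next(h for h in hits if h[0].strand == "+" and h[0].pos == 505)
        cand = find_tsd(genome, hit)
        assert cand is not None
        assert cand.tsd.find("ACTGA") != -1 or "ACTGA" in cand.tsd
        s, e = cand.element_span
        assert s == hit[0].pos
        # downstream TSD copy sits at the end of the span
        assert genome["c"][e - 5 : e].endswith(cand.tsd[-5:])

    @pytest.mark.parametrize("d,found", [(269, False), (270, True),
                                         (350, True), (351, False)])
    def test_window_boundaries_inclusive(self, sigs, rng, d, found):
        # short synthetic element keeps d controllable below 288
        rng2 = np.random.default_rng(123)
        body = SIG + rand_seq(rng2, d - 10)
        tsd = "ACTGA"
        seq = rand_seq(rng2, 400) + tsd + body + tsd + rand_seq(rng2, 400)
        genome = {"c": seq}
        hit = (next(l for l, s in scan_reference(genome, build_signature_set())
                    if l.pos == 405), SIG)
        cand = find_tsd(genome, hit)
        assert (cand is not None) == found
        if found:
            assert cand.element_span == (405, 405 + d + 5)

    def test_polya_adjacent_tsd_still_reported(self, sigs, rng):
        # TSD of all A right against the polyA tail: extension is capped
        # and exact; the candidate must survive
        genome = {"c": planted_locus(rng, tsd="AAAAA", d=300)}
        hit = next(h for h in scan_reference(genome, sigs)
                   if h[0].strand == "+" and h[0].pos == 505)
        cand = find_tsd(genome, hit)
        assert cand is not None
        assert set(cand.tsd) >= {"A"} and len(cand.tsd) >= 5

    def test_minus_strand_locus(self, sigs, rng):
        fwd = planted_locus(rng, d=310)
        genome = {"c": kmers.revcomp(fwd)}
        sig_pos = len(fwd) - 10 - 505
        hit = next(h for h in scan_reference(genome, sigs)
                   if h[0].strand == "-" and h[0].pos == sig_pos)
        cand = find_tsd(genome, hit)
        assert cand is not None
        s, e = cand.element_span
        oriented = kmers.revcomp(genome["c"][s:e])
        assert oriented.startswith(SIG)

    def test_no_tsd_no_candidate(self, sigs, rng):
        # signature with no downstream repeat of the preceding 5-mer
        genome = {"c": rand_seq(rng, 500) + SIG + rand_seq(rng, 500)}
        hits = [h for h in scan_reference(genome, sigs) if h[0].strand == "+"
                and h[0].pos == 500]
        assert find_tsd(genome, hits[0]) is None


class TestScoreHomology:
    def test_consensus_scores_itself_at_full_bits(self):
        raw = raw_sw_score(ALU_CONSENSUS, ALU_CONSENSUS)
        assert raw == len(ALU_CONSENSUS)
        bits = bit_score(raw)
        expect = (1.28 * raw - np.log(0.46)) / np.log(2)
        assert bits == pytest.approx(expect)
        assert bits > 100

    def test_random_sequences_fall_below_threshold(self, rng):
        for _ in range(100):
            assert score_homology(rand_seq(rng, 300), ALU) < 100

    def test_diverged_copy_retained(self, rng):
        seq = list(ALU_CONSENSUS)
        idx = rng.choice(len(seq), size=int(0.2 * len(seq)), replace=False)
        for i in idx:
            seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
        assert score_homology("".join(seq), ALU) > 100

    def test_matches_independent_smith_waterman(self, rng):
        skbio_align = pytest.importorskip("skbio.alignment")
        queries = []
        for _ in range(5):  # substitution-diverged copies
            seq = list(ALU_CONSENSUS)
            idx = rng.choice(len(seq), size=30, replace=False)
            for i in idx:
                seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
            queries.append("".join(seq))
        # indel-bearing copies exercise the affine gap convention
        queries.append(ALU_CONSENSUS[:100] + ALU_CONSENSUS[110:])
        queries.append(ALU_CONSENSUS[:50] + "ACGTA" + ALU_CONSENSUS[50:])
        for query in queries:
            ours = raw_sw_score(query, ALU_CONSENSUS)
            ref = skbio_align.pair_align(
                query, ALU_CONSENSUS, mode="local",
                sub_score=(1.0, -2.0), gap_cost=(5.0, 2.0),
            ).score
            assert ours == ref

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            score_homology("ACGT" * 80, {})


class TestOutgroupAndCascade:
    def build(self, rng, n_alu=3, n_decoys=3):
        parts = []
        for i in range(n_alu):
            parts.append(planted_locus(rng, tsd="GATCC",
                                       d=int(295 + i * 10), left=400, right=0))
        for _ in range(n_decoys):
            # signature but provably no TSD: the preceding 5-mer is all A
            # and the downstream window contains no A at all
            downstream = "".join("CGT"[i] for i in
                                 np.random.default_rng(77).integers(0, 3, 400))
            parts.append(rand_seq(rng, 300) + "AAAAA" + SIG + downstream)
        return {"c": "".join(parts)}

    def test_cascade_is_monotone_and_exact_on_fixture(self, sigs, rng):
        genome = self.build(rng)
        cands, cascade = discover_ref_plus(genome, sigs, ALU)
        counts = list(cascade.values())
        assert counts == sorted(counts, reverse=True)
        assert cascade["with_tsd"] >= 3  # accidental seed repeats may add hits
        assert len(cands) == 3  # only true Alu spans clear the homology bar
        for c in cands:
            assert c.homology_bits > 100
            assert c.outgroup_absent is None

    def test_outgroup_equal_to_reference_fails_all(self, sigs, rng):
        genome = self.build(rng)
        og = build_kmer_set(genome, 32)
        cands, cascade = discover_ref_plus(genome, sigs, ALU, og)
        assert cascade["outgroup_absent"] == 0

    def test_outgroup_lacking_element_passes(self, sigs, rng):
        genome = {"c": planted_locus(rng, d=300)}
        og_genome = {"c": genome["c"][:500] + genome["c"][500 + 305:]}
        og = build_kmer_set(og_genome, 32)
        cands, cascade = discover_ref_plus(genome, sigs, ALU, og)
        assert cascade["outgroup_absent"] == 1
        assert cands[0].outgroup_absent is True
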