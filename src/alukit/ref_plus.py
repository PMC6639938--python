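"""Discovery of potentially polymorphic Alu elements present in the
reference genome (REF+ elements).

A REF+ candidate is a reference locus with (1) an intact Alu signature
motif, (2) a target site duplication (TSD) of at least 5 bp flanking
both ends, with the downstream copy 270-350 bp from the signature
start, (3) local-alignment homology above 100 bits against an Alu
consensus, and (4, optional) absence of the insertion junction from an
outgroup genome — a coarse proxy for the insertion being young. The
four stages form a monotone filtering cascade; per-stage counts are
returned so users can print their own cascade table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from . import kmers
from .ref_index import GenomeLocation, kmer_in_set
from .signatures import SignatureSet, scan_signatures

log = logging.getLogger(__name__)

TSD_SEED_LEN = 5
TSD_WINDOW = (270, 350)
MAX_TSD_LEN = 50
MIN_BITS = 100.0
JUNCTION_K = 32

# Smith-Waterman scoring and the ungapped Karlin-Altschul parameters for
# the +1/-2 scheme used to express raw scores in bits.
SW_MATCH, SW_MISMATCH, SW_OPEN, SW_EXTEND = 1, -2, -5, -2
KA_LAMBDA, KA_K = 1.28, 0.46


@dataclass
class RefPlusCandidate:
    """A reference Alu with TSD evidence.

    ``element_span`` is the 0-based half-open interval from the
    signature start to one past the last base of the downstream TSD
    copy, on the forward strand of the reference.
    """

    location: GenomeLocation          # signature start (forward-strand pos)
    strand: str
    tsd: str
    tsd2_end: int                     # 0-based last base of downstream TSD copy
    element_span: tuple[int, int]
    homology_bits: float = float("nan")
    outgroup_absent: bool | None = None


def scan_reference(
    reference: dict[str, str], sigs: SignatureSet
) -> list[tuple[GenomeLocation, str]]:
    """All signature occurrences in the reference, both strands.

    For a minus-strand hit the reported position is where the
    signature's reverse complement starts on the forward strand, and the
    reported 10-mer is the signature read 5'->3' on the minus strand.
    """
    out = []
    for chrom, seq in reference.items():
        for off, strand in scan_signatures(seq, sigs, both_strands=True):
            window = seq[off : off + sigs.k]
            sig = window if strand == "+" else kmers.revcomp(window)
            out.append((GenomeLocation(chrom, off, strand), sig))
    return out


def _find_tsd_oriented(seq: str, s: int, window: tuple[int, int], min_tsd: int):
    """TSD search on a sequence oriented so the element runs 5'->3'.

    ``s`` is the signature start. Returns (tsd_string, d, up_start,
    down_start, down_end) in oriented coordinates, or None. ``d`` is the
    distance from the signature start to the first base of the
    downstream copy of the 5-mer seed; the nearest copy wins. The seed
    is then extended outward to its maximal exact length.
    """
    lo, hi = window
    if s < TSD_SEED_LEN or s + hi + TSD_SEED_LEN > len(seq):
        return None
    seed = seq[s - TSD_SEED_LEN : s]
    if not kmers.is_acgt(seed):
        return None
    for d in range(lo, hi + 1):
        if seq[s + d : s + d + TSD_SEED_LEN] == seed:
            # extend leftward (into the true TSD when it is longer than
            # the seed); stop at sequence edges, mismatches, non-ACGT,
            # or a hard cap that keeps polyA-adjacent seeds from running
            # away through the homopolymer
            left = 0
            while (
                left < MAX_TSD_LEN - TSD_SEED_LEN
                and s - TSD_SEED_LEN - 1 - left >= 0
                and s + d - 1 - left >= s
                and seq[s - TSD_SEED_LEN - 1 - left] == seq[s + d - 1 - left]
                and seq[s - TSD_SEED_LEN - 1 - left] in "ACGT"
            ):
                left += 1
            # rightward extension: upstream copy runs into the element,
            # downstream copy into the 3' flank; usually stops at once
            right = 0
            while (
                left + TSD_SEED_LEN + right < MAX_TSD_LEN
                and s + right < s + d
                and s + d + TSD_SEED_LEN + right < len(seq)
                and seq[s + right] == seq[s + d + TSD_SEED_LEN + right]
                and seq[s + right] in "ACGT"
            ):
                right += 1
            up_start = s - TSD_SEED_LEN - left
            tsd = seq[up_start : s + right]
            if len(tsd) < min_tsd:
                return None
            return tsd, d, up_start, s + d - left, s + d + TSD_SEED_LEN + right
    return None


def find_tsd(
    reference: dict[str, str],
    hit: tuple[GenomeLocation, str],
    window: tuple[int, int] = TSD_WINDOW,
    min_tsd: int = TSD_SEED_LEN,
) -> RefPlusCandidate | None:
    """TSD test for one signature hit; None when no TSD is found."""
    loc, _sig = hit
    seq = reference[loc.chrom]
    n = len(seq)
    if loc.strand == "+":
        res = _find_tsd_oriented(seq, loc.pos, window, min_tsd)
        if res is None:
            return None
        tsd, d, _up, _down_start, down_end = res
        tsd2_end = down_end - 1
        span = (loc.pos, down_end)
    else:
        rc = kmers.revcomp(seq)
        s_rc = n - 10 - loc.pos  # signature start in minus-strand coordinates
        res = _find_tsd_oriented(rc, s_rc, window, min_tsd)
        if res is None:
            return None
        tsd, d, _up, _down_start, down_end = res
        # map oriented interval [s_rc, down_end) back to forward coords
        span = (n - down_end, n - s_rc)
        tsd2_end = n - down_end  # forward-strand coordinate of the span's 5' edge
    return RefPlusCandidate(
        location=loc, strand=loc.strand, tsd=tsd, tsd2_end=tsd2_end, element_span=span
    )


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = SW_MATCH
    a.mismatch_score = SW_MISMATCH
    a.open_gap_score = SW_OPEN + SW_EXTEND  # first gap base costs open+extend
    a.extend_gap_score = SW_EXTEND
    return a


def raw_sw_score(seq: str, consensus: str) -> float:
    """Smith-Waterman local alignment raw score (+1/-2, gap -5/-2)."""
    return float(_aligner().score(seq, consensus))


def bit_score(raw: float) -> float:
    """Karlin-Altschul normalised score: (lambda*S - ln K) / ln 2."""
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def score_homology(candidate_seq: str, alu_consensus: dict[str, str]) -> float:
    """Best bit score of a candidate span against the Alu library."""
    if not alu_consensus or not any(alu_consensus.values()):
        raise ValueError("empty Alu consensus library")
    clean = candidate_seq.replace("N", "")
    if not clean:
        return 0.0
    best = max(raw_sw_score(clean, rec) for rec in alu_consensus.values() if rec)
    return bit_score(best)


def junction_kmer(reference: dict[str, str], cand: RefPlusCandidate) -> str | None:
    """The 32-mer spanning the insertion junction (flank25 + first 7 of
    the element) on the element's strand; None near chromosome edges."""
    seq = reference[cand.location.chrom]
    if cand.strand == "+":
        s = cand.location.pos
        frag = seq[s - 25 : s + 7]
    else:
        e = cand.element_span[1]
        frag = kmers.revcomp(seq[e - 7 : e + 25])
    return frag if len(frag) == JUNCTION_K and kmers.is_acgt(frag) else None


def outgroup_absent(
    reference: dict[str, str],
    cand: RefPlusCandidate,
    outgroup_kmers: np.ndarray | None,
) -> bool | None:
    """True when the junction 32-mer is absent from the outgroup genome.

    A coarse presence test: with no outgroup supplied the stage is
    skipped (None = unknown, candidate retained).
    """
    if outgroup_kmers is None:
        return None
    jk = junction_kmer(reference, cand)
    if jk is None:
        return False
    return not kmer_in_set(jk, outgroup_kmers)


def discover_ref_plus(
    reference: dict[str, str],
    sigs: SignatureSet,
    alu_consensus: dict[str, str],
    outgroup_kmers: np.ndarray | None = None,
    window: tuple[int, int] = TSD_WINDOW,
    min_bits: float = MIN_BITS,
    min_tsd: int = TSD_SEED_LEN,
) -> tuple[list[RefPlusCandidate], dict[str, int]]:
    """Run the four-stage REF+ cascade; returns (candidates, stage counts)."""
    hits = scan_reference(reference, sigs)
    cascade = {"signature_hits": len(hits)}
    with_tsd = [c for c in (find_tsd(reference, h, window, min_tsd) for h in hits) if c]
    cascade["with_tsd"] = len(with_tsd)
    homologous = []
    for c in with_tsd:
        s, e = c.element_span
        span_seq = reference[c.location.chrom][s:e]
        if c.strand == "-":
            span_seq = kmers.revcomp(span_seq)
        c.homology_bits = score_homology(span_seq, alu_consensus)
        if c.homology_bits > min_bits:
            homologous.append(c)
    cascade["homologous"] = len(homologous)
    kept = []
    if outgroup_kmers is None:
        log.warning("no outgroup genome supplied; outgroup-absence stage skipped")
        for c in homologous:
            c.outgroup_absent = None
        kept = homologous
    else:
        for c in homologous:
            c.outgroup_absent = outgroup_absent(reference, c, outgroup_kmers)
            if c.outgroup_absent:
                kept.append(c)
    cascade["outgroup_absent"] = len(kept)
    return kept, cascade
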