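"""Discovery of Alu insertions present in raw reads but absent from the
reference (REF– elements).

Reads are scanned, alignment-free, for Alu signature motifs; each hit
with at least 25 bases of upstream flank contributes a 35-mer
(flank25 + signature10). A 35-mer supported by enough reads becomes a
candidate when its 25 bp flank localises uniquely in the reference and
the 10 bases following the flank in the reference differ from the
signature observed in the reads — i.e. the individual carries an Alu
junction the reference does not have.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import kmers
from .io import iter_reads
from .ref_index import GenomeLocation, LocateIndex
from .signatures import SignatureSet, _member_code_arrays, _member_hits

log = logging.getLogger(__name__)

FLANK_LEN = 25
MIN_SUPPORT = 3
MAX_SUPPORT = 100

_BATCH_READS = 20_000


@dataclass(frozen=True)
class RefMinusCandidate:
    """A putative Alu insertion absent from the reference.

    ``location`` is where the 25 bp flank sits on the forward strand of
    the reference; ``breakpoint`` is the 0-based insertion point (the
    base just 3' of the flank on the element's strand).
    """

    flank25: str
    signature10: str
    location: GenomeLocation
    ref_next10: str
    support: int
    breakpoint: int


def _scan_batch(
    seqs: list[str], fwd_table: np.ndarray, k: int, counts: Counter
) -> None:
    # Concatenate reads with an N spacer so one vectorised pass covers
    # the whole batch; the spacer invalidates windows crossing reads.
    joined = "N".join(seqs)
    starts = np.zeros(len(seqs), dtype=np.int64)
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    starts[1:] = np.cumsum(lens + 1)[:-1]
    vals, valid = kmers.kmer_codes(kmers.encode(joined), k)
    for g in _member_hits(vals, valid, fwd_table):
        ri = int(np.searchsorted(starts, g, side="right")) - 1
        off = int(g) - int(starts[ri])
        if off >= FLANK_LEN:
            frag = joined[g - FLANK_LEN : g + k]
            if "N" not in frag:
                counts[frag] += 1


def scan_reads(reads, sigs: SignatureSet) -> Counter:
    """Count (flank25 + signature10) 35-mers over a read stream.

    Every read is scanned in both orientations; a signature hit with at
    least 25 preceding bases on the hit's strand emits the 35-mer in the
    element's orientation. Reads shorter than 35 bases cannot emit and
    are skipped.
    """
    k = sigs.k
    fwd_table, _ = _member_code_arrays(sigs)
    counts: Counter = Counter()
    batch: list[str] = []
    for seq in iter_reads(reads):
        if len(seq) < FLANK_LEN + k:
            continue
        batch.append(seq)
        batch.append(kmers.revcomp(seq))
        if len(batch) >= _BATCH_READS:
            _scan_batch(batch, fwd_table, k, counts)
            batch = []
    if batch:
        _scan_batch(batch, fwd_table, k, counts)
    return counts


def call_candidates(
    counted: Counter,
    index: LocateIndex,
    reference: dict[str, str],
    min_support: int = MIN_SUPPORT,
    max_support: int = MAX_SUPPORT,
) -> list[RefMinusCandidate]:
    """Turn supported 35-mers into REF– candidates.

    Keeps 35-mers with min_support <= count <= max_support whose flank
    has a unique reference location and whose reference continuation
    differs from the observed signature. Candidates sharing one
    breakpoint/flank (signature one-mismatch variants in mutated or
    erroneous reads) are merged, summing support and keeping the
    best-supported signature.
    """
    sig_k = len(next(iter(counted))) - FLANK_LEN if counted else 10
    merged: dict[tuple, RefMinusCandidate] = {}
    for kmer35, support in counted.items():
        if not (min_support <= support <= max_support):
            continue
        flank = kmer35[:FLANK_LEN]
        sig = kmer35[FLANK_LEN:]
        if not kmers.is_acgt(flank):
            continue
        loc = index.unique_location(flank)
        if loc is None:
            continue
        chrom_seq = reference[loc.chrom]
        if loc.strand == "+":
            nxt_start = loc.pos + FLANK_LEN
            ref_next = chrom_seq[nxt_start : nxt_start + sig_k]
            breakpoint = loc.pos + FLANK_LEN
        else:
            seg = chrom_seq[max(0, loc.pos - sig_k) : loc.pos]
            ref_next = kmers.revcomp(seg) if seg else ""
            breakpoint = loc.pos
        if len(ref_next) < sig_k:
            log.warning("flank at %s:%d runs off the chromosome end; dropped",
                        loc.chrom, loc.pos)
            continue
        if ref_next == sig:
            continue  # the junction already exists in the reference
        key = (loc.chrom, breakpoint, loc.strand, flank)
        prev = merged.get(key)
        if prev is None:
            merged[key] = RefMinusCandidate(flank, sig, loc, ref_next, support, breakpoint)
        else:
            best_sig = prev.signature10 if prev.support >= support else sig
            merged[key] = RefMinusCandidate(
                flank, best_sig, loc, prev.ref_next10, prev.support + support, breakpoint
            )
    return sorted(merged.values(), key=lambda c: (c.location.chrom, c.breakpoint))


def discover_ref_minus(
    reads,
    sigs: SignatureSet,
    index: LocateIndex,
    reference: dict[str, str],
    min_support: int = MIN_SUPPORT,
    max_support: int = MAX_SUPPORT,
) -> list[RefMinusCandidate]:
    """Full REF– discovery: scan the read stream, then call candidates."""
    return call_candidates(scan_reads(reads, sigs), index, reference,
                           min_support, max_support)
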