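"""Alu signature sequences and signature scanning.

An intact Alu element starts with a well conserved 10 bp motif
(consensus GGCCGGGCGC). The signature set is this consensus plus every
sequence one substitution away: 3*L + 1 members, 31 for L = 10. A
sequence window "carries a signature" when it is a member of this set,
which is exactly a Hamming-distance <= 1 match to the consensus but
implemented as an O(1) hash lookup per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kmers

log = logging.getLogger(__name__)

ALU_SIGNATURE_CONSENSUS = "GGCCGGGCGC"

_BASES = "ACGT"


@dataclass(frozen=True)
class SignatureSet:
    """Consensus motif plus all one-mismatch variants."""

    consensus: str
    members: frozenset[str] = field(repr=False)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.members

    @property
    def k(self) -> int:
        return len(self.consensus)


def build_signature_set(consensus: str = ALU_SIGNATURE_CONSENSUS) -> SignatureSet:
    """Consensus plus every sequence at Hamming distance exactly 1.

    For an L-base ACGT consensus this yields 3L + 1 distinct sequences.
    """
    if not kmers.is_acgt(consensus):
        raise ValueError(f"consensus must be non-empty uppercase ACGT, got {consensus!r}")
    members = {consensus}
    for i, orig in enumerate(consensus):
        for b in _BASES:
            if b != orig:
                members.add(consensus[:i] + b + consensus[i + 1 :])
    return SignatureSet(consensus=consensus, members=frozenset(members))


def _member_code_arrays(sigs: SignatureSet) -> tuple[np.ndarray, np.ndarray]:
    fwd = np.array(sorted(kmers.code_of(m) for m in sigs.members), dtype=np.uint64)
    rev = np.array(
        sorted(kmers.code_of(kmers.revcomp(m)) for m in sigs.members), dtype=np.uint64
    )
    return fwd, rev


def _member_hits(vals: np.ndarray, valid: np.ndarray, table: np.ndarray) -> np.ndarray:
    if len(vals) == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.searchsorted(table, vals)
    idx[idx == len(table)] = 0
    hit = (table[idx] == vals) & valid
    return np.flatnonzero(hit)


def scan_signatures(
    seq: str, sigs: SignatureSet, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All signature occurrences in a sequence.

    Returns ``(offset, strand)`` tuples, 0-based, sorted by offset. A
    ``-`` hit at offset i means the reverse complement of a signature
    member starts at i on the given sequence (the signature itself reads
    5'->3' on the minus strand). Windows containing non-ACGT characters
    never match.
    """
    k = sigs.k
    if len(seq) < k:
        return []
    codes = kmers.encode(seq)
    vals, valid = kmers.kmer_codes(codes, k)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.debug("skipped %d windows containing non-ACGT characters", n_invalid)
    fwd_table, rev_table = _member_code_arrays(sigs)
    hits = [(int(i), "+") for i in _member_hits(vals, valid, fwd_table)]
    if both_strands:
        hits += [(int(i), "-") for i in _member_hits(vals, valid, rev_table)]
    hits.sort()
    return hits
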