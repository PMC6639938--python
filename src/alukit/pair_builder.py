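"""Allele-specific bipartite 32-mer pairs.

Each polymorphic-insertion breakpoint yields two 32-mers sharing the
same 25 bp genomic flank (5' of the insertion point, on the element's
strand) and differing in the last 7 bases: allele A carries the 7-mer
continuing the reference sequence, allele B the non-reference
alternative. For a REF– element allele B starts the Alu (first 7 of the
signature); for a REF+ element allele A starts the Alu (the element is
in the reference) and allele B continues past the downstream TSD copy,
i.e. the sequence an individual lacking the element would have.

Pair-level filters remove pairs that cannot genotype cleanly:
duplicate k-mers shared between pairs, breakpoints too close together,
GC-extreme k-mers, and pairs whose allele-A 32-mer is not unique in the
reference or whose allele-B 32-mer occurs in it at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import kmers
from .ref_index import GenomeLocation
from .ref_minus import RefMinusCandidate
from .ref_plus import RefPlusCandidate

log = logging.getLogger(__name__)

K_TOTAL = 32
FLANK_LEN = 25
BRANCH_LEN = K_TOTAL - FLANK_LEN  # 7

REF_MINUS = "REF_MINUS"
REF_PLUS = "REF_PLUS"

MIN_DISTANCE = 32
GC_MAX = 0.80


@dataclass(frozen=True)
class KmerPair:
    element_id: str
    element_class: str
    location: GenomeLocation       # breakpoint, 0-based, element strand
    kmerA: str                     # reference allele
    kmerB: str                     # alternative allele

    def validate(self) -> None:
        if self.element_class not in (REF_MINUS, REF_PLUS):
            raise ValueError(f"{self.element_id}: bad class {self.element_class!r}")
        if len(self.kmerA) != K_TOTAL or len(self.kmerB) != K_TOTAL:
            raise ValueError(f"{self.element_id}: k-mers must be {K_TOTAL} bases")
        if not (kmers.is_acgt(self.kmerA) and kmers.is_acgt(self.kmerB)):
            raise ValueError(f"{self.element_id}: non-ACGT k-mer")
        if self.kmerA[:FLANK_LEN] != self.kmerB[:FLANK_LEN]:
            raise ValueError(f"{self.element_id}: pair does not share the 25 bp flank")
        if self.kmerA == self.kmerB:
            raise ValueError(f"{self.element_id}: degenerate pair (kmerA == kmerB)")


@dataclass
class PairDatabase:
    reference: str
    pairs: list[KmerPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[KmerPair]:
        return sorted(self.pairs, key=lambda p: (p.location.chrom, p.location.pos,
                                                 p.element_class))


def build_pair(
    candidate: RefMinusCandidate | RefPlusCandidate, reference: dict[str, str]
) -> KmerPair | None:
    """Construct the 32-mer pair for one candidate; None when degenerate
    or when a branch runs off the chromosome."""
    if isinstance(candidate, RefMinusCandidate):
        flank = candidate.flank25
        kmer_a = flank + candidate.ref_next10[:BRANCH_LEN]
        kmer_b = flank + candidate.signature10[:BRANCH_LEN]
        loc = GenomeLocation(candidate.location.chrom, candidate.breakpoint,
                             candidate.location.strand)
        eid = f"RM_{loc.chrom}_{loc.pos + 1}"
        cls = REF_MINUS
    elif isinstance(candidate, RefPlusCandidate):
        seq = reference[candidate.location.chrom]
        s, e = candidate.element_span
        if candidate.strand == "+":
            ok = s >= FLANK_LEN and e + BRANCH_LEN <= len(seq)
        else:
            ok = s >= BRANCH_LEN and e + FLANK_LEN <= len(seq)
        if not ok:
            log.info("candidate at %s:%d dropped: flank/branch runs off chromosome",
                     candidate.location.chrom, s)
            return None
        if candidate.strand == "+":
            flank = seq[s - FLANK_LEN : s]
            branch_a = seq[s : s + BRANCH_LEN]
            branch_b = seq[e : e + BRANCH_LEN]
            bp = s
        else:
            flank = kmers.revcomp(seq[e : e + FLANK_LEN])
            branch_a = kmers.revcomp(seq[e - BRANCH_LEN : e])
            branch_b = kmers.revcomp(seq[s - BRANCH_LEN : s])
            bp = e
        kmer_a, kmer_b = flank + branch_a, flank + branch_b
        loc = GenomeLocation(candidate.location.chrom, bp, candidate.strand)
        eid = f"RP_{loc.chrom}_{loc.pos + 1}"
        cls = REF_PLUS
    else:
        raise TypeError(f"unsupported candidate type {type(candidate)!r}")

    pair = KmerPair(eid, cls, loc, kmer_a, kmer_b)
    try:
        pair.validate()
    except ValueError as e:
        log.info("candidate dropped at pair building: %s", e)
        return None
    return pair


def filter_pairs(
    pairs: list[KmerPair],
    reference: dict[str, str],
    min_distance: int = MIN_DISTANCE,
    gc_max: float = GC_MAX,
) -> tuple[list[KmerPair], list[tuple[str, str]]]:
    """Apply the pair-level filters; returns (kept, rejection log).

    All four criteria are evaluated on the full input set and the union
    of failures removed, so the result is independent of any processing
    order. Reference-occurrence checks are canonical (both strands):
    allele A must occur exactly once, allele B never.
    """
    rejected: dict[str, list[str]] = {}

    def reject(pair: KmerPair, reason: str) -> None:
        rejected.setdefault(pair.element_id, []).append(reason)

    # (a) duplicate k-mers shared between pairs (canonical form)
    owners: dict[str, list[KmerPair]] = {}
    for p in pairs:
        for m in (p.kmerA, p.kmerB):
            owners.setdefault(kmers.canonical(m), []).append(p)
    for canon, ps in owners.items():
        if len({p.element_id for p in ps}) >= 2:
            for p in ps:
                reject(p, "duplicate_kmer")

    # (b) closely located breakpoints on one chromosome
    by_chrom: dict[str, list[KmerPair]] = {}
    for p in pairs:
        by_chrom.setdefault(p.location.chrom, []).append(p)
    for ps in by_chrom.values():
        ps.sort(key=lambda p: p.location.pos)
        for a, b in zip(ps, ps[1:]):
            if b.location.pos - a.location.pos < min_distance:
                reject(a, "closely_located")
                reject(b, "closely_located")

    # (c) GC-extreme k-mers
    for p in pairs:
        if kmers.gc_fraction(p.kmerA) > gc_max or kmers.gc_fraction(p.kmerB) > gc_max:
            reject(p, "gc_rich")

    # (d) reference occurrence: kmerA exactly once, kmerB never
    queries = sorted({m for p in pairs for m in (p.kmerA, p.kmerB)})
    counts = kmers.count_kmers_in_genome(reference, queries) if queries else {}
    for p in pairs:
        if counts.get(p.kmerA, 0) != 1:
            reject(p, "kmerA_not_unique_in_reference")
        if counts.get(p.kmerB, 0) != 0:
            reject(p, "kmerB_present_in_reference")

    kept = [p for p in pairs if p.element_id not in rejected]
    rejection_log = [(eid, reason) for eid, rs in sorted(rejected.items())
                     for reason in rs]
    return kept, rejection_log


def merge_databases(*databases: PairDatabase) -> PairDatabase:
    """Union of pair databases, deduplicated by (chrom, pos, class) and
    deterministically sorted. Reference tags must agree."""
    refs = {db.reference for db in databases if len(db.pairs) > 0 or db.reference}
    refs.discard("")
    if len(refs) > 1:
        raise ValueError(f"conflicting reference declarations: {sorted(refs)}")
    ref = refs.pop() if refs else ""
    seen: dict[tuple, KmerPair] = {}
    for db in databases:
        for p in db.pairs:
            seen.setdefault((p.location.chrom, p.location.pos, p.element_class), p)
    merged = PairDatabase(reference=ref, pairs=list(seen.values()))
    merged.pairs = merged.sorted_pairs()
    return merged
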