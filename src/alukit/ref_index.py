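"""Exact-location 25-mer index of a reference genome.

Maps any 25-mer to its genomic occurrences (forward-strand coordinates,
with the strand recording which orientation matched) and answers
uniqueness queries. K-mers are stored in canonical form so both strands
share one entry; per-k-mer occurrence lists are capped (default 4)
because the discovery pipeline only ever needs to distinguish "absent /
unique / repeated" — total occurrence counts are kept exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np

from . import kmers
from .io import open_text

INDEX_K = 25
DEFAULT_CAP = 4

_FORMAT_VERSION = "1"


@dataclass(frozen=True, order=True)
class GenomeLocation:
    """0-based forward-strand position of a k-mer's first base."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class LocateIndex:
    """Sorted-array index of all canonical 25-mers of a genome."""

    def __init__(
        self,
        k: int,
        cap: int,
        chrom_names: list[str],
        codes: np.ndarray,
        counts: np.ndarray,
        starts: np.ndarray,
        occ_chrom: np.ndarray,
        occ_pos: np.ndarray,
        occ_fwd_canon: np.ndarray,
    ):
        self.k = k
        self.cap = cap
        self.chrom_names = chrom_names
        self._codes = codes            # sorted unique canonical codes
        self._counts = counts          # exact total occurrence count per code
        self._starts = starts          # offsets into the (capped) occ arrays
        self._occ_chrom = occ_chrom
        self._occ_pos = occ_pos
        self._occ_fwd_canon = occ_fwd_canon  # genome window equals canonical form

    def __len__(self) -> int:
        return len(self._codes)

    def _find(self, kmer: str) -> tuple[int | None, bool]:
        if len(kmer) != self.k or not kmers.is_acgt(kmer):
            raise ValueError(f"query must be an ACGT {self.k}-mer, got {kmer!r}")
        code = kmers.code_of(kmer)
        rc = kmers.code_of(kmers.revcomp(kmer))
        canon = min(code, rc)
        query_is_canon = code <= rc
        i = int(np.searchsorted(self._codes, np.uint64(canon)))
        if i >= len(self._codes) or int(self._codes[i]) != canon:
            return None, query_is_canon
        return i, query_is_canon

    def count(self, kmer: str) -> int:
        """Exact number of genomic occurrences (both strands)."""
        i, _ = self._find(kmer)
        return 0 if i is None else int(self._counts[i])

    def locate(self, kmer: str) -> list[GenomeLocation]:
        """Occurrences of a 25-mer; capped at ``cap`` entries per k-mer."""
        i, query_is_canon = self._find(kmer)
        if i is None:
            return []
        lo = int(self._starts[i])
        hi = int(self._starts[i + 1]) if i + 1 < len(self._starts) else len(self._occ_pos)
        out = []
        for j in range(lo, hi):
            win_is_canon = bool(self._occ_fwd_canon[j])
            strand = "+" if (query_is_canon == win_is_canon) else "-"
            out.append(
                GenomeLocation(
                    self.chrom_names[int(self._occ_chrom[j])],
                    int(self._occ_pos[j]),
                    strand,
                )
            )
        return out

    def unique_location(self, kmer: str) -> GenomeLocation | None:
        """The single occurrence iff exactly one exists, counting strands."""
        i, _ = self._find(kmer)
        if i is None or int(self._counts[i]) != 1:
            return None
        return self.locate(kmer)[0]

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """TSV dump: k-mer (canonical), total count, capped occurrence list."""
        with open(path, "w") as fh:
            fh.write(f"#locate-index\tv{_FORMAT_VERSION}\n")
            fh.write(f"#k={self.k}\t#cap={self.cap}\n")
            fh.write("#chroms=" + ",".join(self.chrom_names) + "\n")
            n = len(self._occ_pos)
            for i, code in enumerate(self._codes):
                lo = int(self._starts[i])
                hi = int(self._starts[i + 1]) if i + 1 < len(self._starts) else n
                occs = ";".join(
                    f"{int(self._occ_chrom[j])}:{int(self._occ_pos[j])}:"
                    f"{'C' if self._occ_fwd_canon[j] else 'R'}"
                    for j in range(lo, hi)
                )
                fh.write(f"{kmers.decode(int(code), self.k)}\t{int(self._counts[i])}\t{occs}\n")

    @classmethod
    def load(cls, path: str) -> "LocateIndex":
        with open_text(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#locate-index\tv" + _FORMAT_VERSION):
                raise ValueError(f"not a v{_FORMAT_VERSION} locate-index file: {path}")
            meta = fh.readline().rstrip("\n").split("\t")
            k = int(meta[0].split("=")[1])
            cap = int(meta[1].split("=")[1])
            chroms = fh.readline().rstrip("\n").split("=", 1)[1].split(",")
            codes, counts, starts = [], [], []
            oc, op, of = [], [], []
            for line in fh:
                kmer, cnt, occs = line.rstrip("\n").split("\t")
                codes.append(kmers.code_of(kmer))
                counts.append(int(cnt))
                starts.append(len(op))
                if occs:
                    for tok in occs.split(";"):
                        c, p, o = tok.split(":")
                        oc.append(int(c))
                        op.append(int(p))
                        of.append(o == "C")
        return cls(
            k,
            cap,
            chroms,
            np.array(codes, dtype=np.uint64),
            np.array(counts, dtype=np.int64),
            np.array(starts, dtype=np.int64),
            np.array(oc, dtype=np.int32),
            np.array(op, dtype=np.int64),
            np.array(of, dtype=bool),
        )


def build_index(
    reference: dict[str, str], k: int = INDEX_K, cap: int = DEFAULT_CAP
) -> LocateIndex:
    """Index every ACGT-only k-mer window of every sequence.

    Windows containing N (or any non-ACGT character) are skipped. Both
    strands are covered through canonical-form storage.
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    chrom_names = list(reference)
    all_codes, all_pos, all_chrom, all_fwd = [], [], [], []
    for ci, name in enumerate(chrom_names):
        seq = reference[name]
        vals, valid = kmers.kmer_codes(kmers.encode(seq), k)
        if len(vals) == 0:
            continue
        canon, fwd_is_canon = kmers.canonical_codes(vals, k)
        pos = np.flatnonzero(valid)
        all_codes.append(canon[pos])
        all_pos.append(pos)
        all_chrom.append(np.full(len(pos), ci, dtype=np.int32))
        all_fwd.append(fwd_is_canon[pos])
    if not all_codes:
        return LocateIndex(
            k, cap, chrom_names,
            np.empty(0, np.uint64), np.empty(0, np.int64), np.empty(0, np.int64),
            np.empty(0, np.int32), np.empty(0, np.int64), np.empty(0, bool),
        )
    codes = np.concatenate(all_codes)
    pos = np.concatenate(all_pos)
    chrom = np.concatenate(all_chrom)
    fwd = np.concatenate(all_fwd)

    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    uniq, start_idx, counts = np.unique(sc, return_index=True, return_counts=True)
    # keep at most `cap` occurrences per k-mer (exact counts kept separately)
    ranks = np.arange(len(sc)) - np.repeat(start_idx, counts)
    keep = ranks < cap
    kept_counts = np.minimum(counts, cap)
    starts = np.concatenate(([0], np.cumsum(kept_counts)[:-1]))
    sel = order[keep]
    return LocateIndex(
        k, cap, chrom_names,
        uniq, counts.astype(np.int64), starts.astype(np.int64),
        chrom[sel], pos[sel].astype(np.int64), fwd[sel],
    )


def build_kmer_set(sequences: dict[str, str], k: int) -> np.ndarray:
    """Sorted array of all canonical k-mer codes of a genome.

    Used for the coarse outgroup-absence test (k = 32 junction k-mers).
    """
    parts = []
    for seq in sequences.values():
        vals, valid = kmers.kmer_codes(kmers.encode(seq), k)
        if len(vals):
            canon, _ = kmers.canonical_codes(vals, k)
            parts.append(canon[valid])
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def kmer_in_set(kmer: str, table: np.ndarray) -> bool:
    code = np.uint64(kmers.code_of(kmers.canonical(kmer)))
    i = int(np.searchsorted(table, code))
    return i < len(table) and table[i] == code
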