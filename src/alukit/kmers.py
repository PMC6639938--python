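"""Core k-mer primitives: reverse complement, canonical form, GC content,
and vectorised 2-bit k-mer encoding used by the scanners and indexes.

All k-mers handled here are <= 32 bases so a k-mer packs into a single
uint64 (2 bits per base, A=0 C=1 G=2 T=3, first base in the highest
occupied bits). Windows containing any non-ACGT character are invalid by
definition and are masked out, never matched.
"""

from __future__ import annotations

import numpy as np

MAX_K = 32

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; 4 marks anything that is not A/C/G/T
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_BASES = "ACGT"

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string. N maps to N."""
    if not seq:
        raise ValueError("cannot reverse-complement an empty sequence")
    out = seq.translate(_COMPLEMENT)[::-1]
    if any(c not in "ACGTN" for c in out):
        raise ValueError(f"non-ACGTN character in sequence {seq[:40]!r}")
    return out


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    if any(c not in "ACGT" for c in kmer):
        raise ValueError(f"canonical form requires an ACGT k-mer, got {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases over the sequence length."""
    if not seq:
        raise ValueError("GC fraction of an empty sequence is undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_acgt(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq)


# ---------------------------------------------------------------------------
# vectorised encoding


def encode(seq: str) -> np.ndarray:
    """Per-base 2-bit codes (uint8); non-ACGT bases become the sentinel 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes over a base-code array.

    Returns ``(vals, valid)`` where ``vals[i]`` is the packed code of the
    window starting at ``i`` and ``valid[i]`` is False when the window
    contains any non-ACGT base. Length is ``len(codes) - k + 1``.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = len(codes) - k + 1
    if n <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals |= codes[j : j + n].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    # invalid windows may carry garbage from the sentinel; zero them out
    vals[~valid] = 0
    return vals, valid


def code_of(kmer: str) -> int:
    """Packed integer code of a single ACGT k-mer."""
    if not is_acgt(kmer) or len(kmer) > MAX_K:
        raise ValueError(f"not an ACGT k-mer of length <= {MAX_K}: {kmer!r}")
    v = 0
    for c in kmer:
        v = (v << 2) | int(_CODE[ord(c)])
    return v


def decode(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_codes(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes, vectorised.

    Complementing flips every 2-bit group (A<->T, C<->G under the 0..3
    encoding); reversal is a 2-bit-group bit reversal of the 64-bit word
    followed by a right shift to drop the unused high bits.
    """
    x = (~vals).astype(np.uint64)
    x = ((x & _M2) << np.uint64(2)) | ((x >> np.uint64(2)) & _M2)
    x = ((x & _M4) << np.uint64(4)) | ((x >> np.uint64(4)) & _M4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes and a flag telling whether the forward form won."""
    rc = revcomp_codes(vals, k)
    fwd_is_canon = vals <= rc
    return np.minimum(vals, rc), fwd_is_canon


def count_kmers_in_genome(
    sequences: dict[str, str], kmers: list[str]
) -> dict[str, int]:
    """Occurrence counts of query k-mers in a genome, both strands.

    A query matches wherever it or its reverse complement occurs on the
    forward strand of any sequence (i.e. canonical counting). All queries
    must share one length. Brute-force single pass over the genome;
    intended for desk-scale genomes.
    """
    if not kmers:
        return {}
    ks = {len(m) for m in kmers}
    if len(ks) != 1:
        raise ValueError("all query k-mers must have the same length")
    k = ks.pop()
    canon = {}
    for m in kmers:
        canon.setdefault(code_of(canonical(m)), []).append(m)
    query = np.array(sorted(canon), dtype=np.uint64)
    counts = np.zeros(len(query), dtype=np.int64)
    for seq in sequences.values():
        vals, valid = kmer_codes(encode(seq), k)
        if len(vals) == 0:
            continue
        cvals, _ = canonical_codes(vals, k)
        cvals = cvals[valid]
        idx = np.searchsorted(query, cvals)
        idx[idx == len(query)] = 0
        hit = query[idx] == cvals
        np.add.at(counts, idx[hit], 1)
    out: dict[str, int] = {}
    for q, c in zip(query, counts):
        for m in canon[int(q)]:
            out[m] = int(c)
    return out
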