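"""Standard-format readers and writers.

FASTA/FASTQ go through Biopython (gzip handled transparently), BAM/SAM
through pysam as a plain read container (alignments are ignored: the
method is alignment-free). Candidate / pair / call databases are
versioned TSV: greppable, diffable, header lines carry the tool version
and the reference tag.

Coordinates are 0-based half-open everywhere in memory and 1-based
inclusive in every user-facing file; `to_user_pos` / `from_user_pos`
are the (inverse) converters.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

TOOL_TAG = "alukit/0.1.0"


def to_user_pos(pos0: int) -> int:
    """0-based internal position -> 1-based user-facing position."""
    return pos0 + 1


def from_user_pos(pos1: int) -> int:
    """1-based user-facing position -> 0-based internal position."""
    return pos1 - 1


def open_text(path: str, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sequence formats


def read_fasta(path: str) -> dict[str, str]:
    """Whole FASTA into {name: uppercase sequence}; duplicate names error."""
    out: dict[str, str] = {}
    with open_text(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            if name in out:
                raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
            out[name] = seq.upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq_reads(path: str) -> Iterator[str]:
    """Uppercased read sequences from a FASTQ(.gz) file, streaming."""
    with open_text(path) as fh:
        i = 0
        try:
            for _title, seq, qual in FastqGeneralIterator(fh):
                i += 1
                if len(seq) != len(qual):
                    raise ValueError("sequence/quality length mismatch")
                yield seq.upper()
        except ValueError as e:
            raise ValueError(f"malformed FASTQ record {i + 1} in {path}: {e}") from e


def iter_bam_reads(path: str) -> Iterator[str]:
    """Read sequences from BAM/SAM/CRAM; secondary/supplementary skipped."""
    import pysam

    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary:
                    continue
                seq = rec.query_sequence
                if seq:
                    yield seq.upper()
    finally:
        pysam.set_verbosity(save)


def iter_reads(source) -> Iterator[str]:
    """Read sequences from FASTQ(.gz)/BAM/SAM paths, a list of paths, or
    any iterable of sequence strings.

    A bare ACGTN string is taken as a read; anything else string-shaped
    is taken as a path."""
    if isinstance(source, str):
        if set(source.upper()) <= set("ACGTN"):
            yield source.upper()
        elif source.lower().endswith((".bam", ".sam", ".cram")):
            yield from iter_bam_reads(source)
        else:
            yield from iter_fastq_reads(source)
        return
    for item in source:
        yield from iter_reads(item)


def write_fastq_pair(
    read_pairs: Iterable[tuple[str, str, str]], prefix: str, gz: bool = False
) -> tuple[str, str]:
    """Write (name, seq1, seq2) tuples to <prefix>_1.fq / <prefix>_2.fq."""
    ext = ".fq.gz" if gz else ".fq"
    p1, p2 = prefix + "_1" + ext, prefix + "_2" + ext
    with open_text(p1, "wt") as f1, open_text(p2, "wt") as f2:
        for name, s1, s2 in read_pairs:
            q1, q2 = "I" * len(s1), "I" * len(s2)
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
    return p1, p2


# ---------------------------------------------------------------------------
# TSV databases


def _write_tsv(path: str, ref_name: str, columns: list[str], rows: Iterable[list]) -> None:
    with open_text(path, "wt") as fh:
        fh.write(f"#tool={TOOL_TAG}\n")
        fh.write(f"#ref={ref_name}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_tsv(path: str) -> tuple[str, list[str], list[list[str]]]:
    ref_name = ""
    with open_text(path) as fh:
        header: list[str] = []
        rows: list[list[str]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#ref="):
                    ref_name = line.split("=", 1)[1]
                continue
            if not header:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    return ref_name, header, rows


CANDIDATE_COLUMNS = ["chrom", "pos", "strand", "flank25", "signature10", "ref_next10", "support"]


def write_candidates(candidates, path: str, ref_name: str) -> None:
    """REF– candidate TSV; `pos` is the 1-based insertion breakpoint."""
    rows = [
        [c.location.chrom, to_user_pos(c.breakpoint), c.location.strand,
         c.flank25, c.signature10, c.ref_next10, c.support]
        for c in sorted(candidates, key=lambda c: (c.location.chrom, c.breakpoint))
    ]
    _write_tsv(path, ref_name, CANDIDATE_COLUMNS, rows)


def read_candidates(path: str):
    from .ref_index import GenomeLocation
    from .ref_minus import RefMinusCandidate

    ref_name, header, rows = _read_tsv(path)
    if header != CANDIDATE_COLUMNS:
        raise ValueError(f"unexpected candidate columns in {path}: {header}")
    out = []
    for chrom, pos, strand, flank, sig, nxt, support in rows:
        bp = from_user_pos(int(pos))
        loc_pos = bp - 25 if strand == "+" else bp
        out.append(
            RefMinusCandidate(
                flank25=flank, signature10=sig,
                location=GenomeLocation(chrom, loc_pos, strand),
                ref_next10=nxt, support=int(support), breakpoint=bp,
            )
        )
    return ref_name, out


REFPLUS_COLUMNS = ["chrom", "start", "end", "strand", "tsd", "tsd_len",
                   "homology_bits", "outgroup_absent"]


def write_refplus(candidates, path: str, ref_name: str) -> None:
    """REF+ TSV; start/end are the 1-based inclusive element span."""
    rows = []
    for c in sorted(candidates, key=lambda c: (c.location.chrom, c.element_span[0])):
        s, e = c.element_span
        og = {True: "yes", False: "no", None: "unknown"}[c.outgroup_absent]
        rows.append([c.location.chrom, to_user_pos(s), to_user_pos(e - 1),
                     c.strand, c.tsd, len(c.tsd), f"{c.homology_bits:.1f}", og])
    _write_tsv(path, ref_name, REFPLUS_COLUMNS, rows)


PAIR_COLUMNS = ["element_id", "class", "chrom", "pos", "strand", "kmerA", "kmerB"]


def write_pairs(database, path: str) -> None:
    """Pair database TSV (genotyping input). Refuses invalid pairs."""
    rows = []
    for p in database.sorted_pairs():
        p.validate()
        rows.append([p.element_id, p.element_class, p.location.chrom,
                     to_user_pos(p.location.pos), p.location.strand, p.kmerA, p.kmerB])
    with open_text(path, "wt") as fh:
        fh.write(f"#tool={TOOL_TAG}\n")
        fh.write(f"#ref={database.reference}\n")
        fh.write("#k=32\n")
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_pairs(path: str):
    from .pair_builder import KmerPair, PairDatabase
    from .ref_index import GenomeLocation

    ref_name, header, rows = _read_tsv(path)
    if header != PAIR_COLUMNS:
        raise ValueError(f"unexpected pair columns in {path}: {header}")
    pairs = []
    for eid, cls, chrom, pos, strand, ka, kb in rows:
        p = KmerPair(
            element_id=eid, element_class=cls,
            location=GenomeLocation(chrom, from_user_pos(int(pos)), strand),
            kmerA=ka, kmerB=kb,
        )
        p.validate()
        pairs.append(p)
    return PairDatabase(reference=ref_name, pairs=pairs)


CALL_COLUMNS = ["element_id", "nA", "nB", "genotype", "posterior"]


def write_calls(calls, path: str, ref_name: str) -> None:
    rows = [
        [c.element_id, c.nA, c.nB, c.genotype, f"{c.posterior:.6f}"]
        for c in calls
    ]
    _write_tsv(path, ref_name, CALL_COLUMNS, rows)


def read_calls(path: str):
    from .genotyping import GenotypeCall

    ref_name, header, rows = _read_tsv(path)
    if header != CALL_COLUMNS:
        raise ValueError(f"unexpected call columns in {path}: {header}")
    out = []
    for eid, na, nb, gt, post in rows:
        ploidy = 1 if gt in ("A", "B") else 2
        out.append(GenotypeCall(element_id=eid, ploidy=ploidy, genotype=gt,
                                posterior=float(post), nA=int(na), nB=int(nb)))
    return ref_name, out


TRUTH_COLUMNS = ["chrom", "pos", "zygosity", "haplotype", "tsd", "polya_len", "alu_len"]


def write_truth(truth, path: str, ref_name: str) -> None:
    rows = [
        [t.chrom, to_user_pos(t.pos), t.zygosity, t.haplotype or ".",
         t.tsd, t.polyA_len, len(t.alu_seq)]
        for t in truth
    ]
    _write_tsv(path, ref_name, TRUTH_COLUMNS, rows)
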