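"""Planted-insertion simulation and sensitivity evaluation.

The simulator turns a haploid reference into a diploid genome carrying
planted Alu insertions with the canonical insertion anatomy — the 15
bases 5' of the breakpoint duplicated as a target site duplication
(TSD), the (optionally mutated) element body, and a 5-80 bp polyA tail
— then generates wgsim-style paired short reads (uniform fragment
sampling, Gaussian insert size, i.i.d. substitution errors). Discovery
output is scored against the planted truth with the false negatives
decomposed into FN1 (flank not uniquely localisable in the reference)
and FN2 (insertion window overlapping unsequenced N runs).

Placement, zygosity and polyA draws come from an RNG stream separate
from the element-mutation stream, so at a fixed seed the planted
positions — and hence the FN2 set — are identical across mutation
rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import kmers
from .consensus import ALU_CONSENSUS
from .ref_index import LocateIndex
from .ref_minus import RefMinusCandidate

log = logging.getLogger(__name__)

TSD_LEN = 15
POLYA_RANGE = (5, 80)
MIN_SEPARATION = 200
MATCH_TOLERANCE = 5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedInsertion:
    chrom: str
    pos: int                   # 0-based insertion point on the reference
    zygosity: str              # het / hom / absent
    haplotype: str | None      # "1" / "2" for het, "both" for hom, None otherwise
    alu_seq: str
    tsd: str
    polyA_len: int
    fn_class: str = "unclassified"   # annotated by evaluate_discovery

    @property
    def payload(self) -> str:
        return self.alu_seq + "A" * self.polyA_len + self.tsd


@dataclass(frozen=True)
class ReadSimParams:
    base_error_rate: float = 0.005
    read_len: int = 151
    outer_distance: int = 500
    insert_sd: float = 50.0
    n_read_pairs: int = 0
    seed: int = 1

    def __post_init__(self):
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if min(self.read_len, self.outer_distance, self.insert_sd) <= 0:
            raise ValueError("read_len, outer_distance and insert_sd must be positive")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        codes = kmers.encode(seq)[hit]
        shift = rng.integers(1, 4, size=len(hit))
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode()


def plant_insertions(
    genome: dict[str, str],
    n: int,
    mutation_rate: float = 0.0,
    seed: int = 1,
    alu_seq: str = ALU_CONSENSUS,
    hom_fraction: float = 0.0,
    absent_fraction: float = 0.0,
    min_separation: int = MIN_SEPARATION,
    polya_range: tuple[int, int] = POLYA_RANGE,
) -> tuple[dict[str, str], list[PlantedInsertion]]:
    """Build a diploid genome with n planted insertions and its truth set.

    Each insertion duplicates the 15 bases 5' of a uniformly drawn
    breakpoint as the TSD and inserts element + polyA + TSD-copy there.
    Element bodies receive i.i.d. substitutions at ``mutation_rate``
    (the signature motif included — mutated signatures are part of the
    simulated detectability). By default all insertions are
    heterozygous (one haplotype each); ``hom_fraction`` of them go on
    both haplotypes and ``absent_fraction`` are recorded in the truth
    but not planted (designed-absent loci for genotyping tests).
    Breakpoints keep ``min_separation`` bases apart so planted loci do
    not interfere with each other.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3]")
    ss = np.random.SeedSequence(seed)
    place_rng, mut_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    usable = lengths - TSD_LEN - 1
    if (usable <= 0).all():
        raise ValueError("no chromosome long enough to plant into")
    total_acgt = sum(s.count(c) for s in genome.values() for c in "ACGT")
    if n > total_acgt:
        raise ValueError(f"cannot plant {n} insertions into {total_acgt} usable bases")

    weights = np.clip(usable, 0, None).astype(float)
    weights /= weights.sum()
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    records: list[tuple[str, int]] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("could not place insertions with the required separation")
        ci = int(place_rng.choice(len(chroms), p=weights))
        pos = int(place_rng.integers(TSD_LEN, usable[ci] + TSD_LEN))
        if any(abs(pos - q) < min_separation for q in taken[chroms[ci]]):
            continue
        taken[chroms[ci]].append(pos)
        records.append((chroms[ci], pos))

    n_hom = int(round(hom_fraction * n))
    n_abs = int(round(absent_fraction * n))
    zygosities = ["hom"] * n_hom + ["absent"] * n_abs + ["het"] * (n - n_hom - n_abs)
    place_rng.shuffle(zygosities)

    truth: list[PlantedInsertion] = []
    for (chrom, pos), zyg in zip(records, zygosities):
        polya = int(place_rng.integers(polya_range[0], polya_range[1] + 1))
        hap = None
        if zyg == "het":
            hap = str(1 + int(place_rng.integers(0, 2)))
        elif zyg == "hom":
            hap = "both"
        body = _mutate(alu_seq, mutation_rate, mut_rng)
        tsd = genome[chrom][pos - TSD_LEN : pos]
        truth.append(PlantedInsertion(chrom, pos, zyg, hap, body, tsd, polya))
    truth.sort(key=lambda t: (t.chrom, t.pos))

    diploid: dict[str, str] = {}
    for hap_no in ("1", "2"):
        for chrom in chroms:
            seq = genome[chrom]
            inserts = [
                t for t in truth
                if t.chrom == chrom and t.haplotype in (hap_no, "both")
            ]
            for t in sorted(inserts, key=lambda t: -t.pos):
                seq = seq[: t.pos] + t.payload + seq[t.pos :]
            diploid[f"{chrom}_h{hap_no}"] = seq
    return diploid, truth


def simulate_reads(genome: dict[str, str], params: ReadSimParams):
    """wgsim-style paired reads; yields (name, seq1, seq2) tuples.

    Fragments are sampled uniformly across all sequences (weighted by
    length), lengths ~ Normal(outer_distance, insert_sd) clipped to at
    least 2*read_len; read 2 is the reverse complement of the fragment's
    3' end. Substitution errors hit ACGT bases i.i.d. at
    ``base_error_rate``; N bases pass through unchanged.
    """
    rng = np.random.default_rng(params.seed)
    names = [c for c in genome if len(genome[c]) >= params.outer_distance]
    skipped = set(genome) - set(names)
    for c in skipped:
        log.warning("sequence %s shorter than the outer distance; skipped", c)
    if not names:
        raise ValueError("no sequence is long enough for the requested fragments")
    lengths = np.array([len(genome[c]) for c in names], dtype=np.float64)
    probs = lengths / lengths.sum()
    counts = rng.multinomial(params.n_read_pairs, probs)
    rl = params.read_len
    pair_no = 0
    for ci, n_frag in enumerate(counts):
        if n_frag == 0:
            continue
        seq = genome[names[ci]]
        L = len(seq)
        sizes = rng.normal(params.outer_distance, params.insert_sd, size=n_frag)
        sizes = np.clip(np.rint(sizes), 2 * rl, L).astype(np.int64)
        starts = (rng.random(n_frag) * (L - sizes + 1)).astype(np.int64)
        r1 = np.empty((n_frag, rl), dtype=np.uint8)
        r2 = np.empty((n_frag, rl), dtype=np.uint8)
        for i in range(n_frag):
            s, size = int(starts[i]), int(sizes[i])
            frag = seq[s : s + size]
            r1[i] = np.frombuffer(frag[:rl].encode(), dtype=np.uint8)
            r2[i] = np.frombuffer(kmers.revcomp(frag[-rl:]).encode(), dtype=np.uint8)
        for arr in (r1, r2):
            if params.base_error_rate > 0:
                codes = kmers.encode(arr.tobytes().decode())
                err = (rng.random(arr.size) < params.base_error_rate) & (codes < 4)
                flat = arr.reshape(-1)
                hit = np.flatnonzero(err)
                if len(hit):
                    shift = rng.integers(1, 4, size=len(hit))
                    flat[hit] = _BASES[(codes[hit] + shift) % 4]
        for i in range(n_frag):
            pair_no += 1
            yield (
                f"sim_{names[ci]}_{pair_no}",
                r1[i].tobytes().decode(),
                r2[i].tobytes().decode(),
            )


def pairs_from_truth(
    truth: list[PlantedInsertion],
    reference: dict[str, str],
    ref_name: str = "simulated",
):
    """Breakpoint 32-mer pairs for designed loci, straight from truth.

    Builds the REF–-style pair (allele A = reference continuation,
    allele B = first bases of the planted element body) for every truth
    record, including designed-absent loci — the pair database a
    genotyping experiment with known truth needs. Loci whose flank or
    branches are unavailable or degenerate are skipped.
    """
    from .pair_builder import REF_MINUS, KmerPair, PairDatabase
    from .ref_index import GenomeLocation

    pairs = []
    for t in truth:
        flank = reference[t.chrom][max(0, t.pos - 25) : t.pos]
        cont_a = reference[t.chrom][t.pos : t.pos + 7]
        cont_b = t.alu_seq[:7]
        if len(flank) < 25 or len(cont_a) < 7:
            continue
        p = KmerPair(
            f"SIM_{t.chrom}_{t.pos + 1}", REF_MINUS,
            GenomeLocation(t.chrom, t.pos, "+"),
            flank + cont_a, flank + cont_b,
        )
        try:
            p.validate()
        except ValueError:
            continue
        pairs.append(p)
    return PairDatabase(reference=ref_name, pairs=pairs)


def pairs_for_coverage(total_len: int, coverage: float, read_len: int = 151) -> int:
    """Read pairs needed for a given depth over a haploid genome length."""
    return int(np.ceil(coverage * total_len / (2 * read_len)))


@dataclass
class DiscoveryReport:
    n_planted: int
    detected: int
    fn1: int
    fn2: int
    missed_other: int
    false_discoveries: int
    sensitivity: float
    fn1_rate: float
    fn2_rate: float
    per_insertion: list[PlantedInsertion] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_planted": self.n_planted,
            "detected": self.detected,
            "FN1": self.fn1,
            "FN2": self.fn2,
            "missed_other": self.missed_other,
            "false_discoveries": self.false_discoveries,
            "sensitivity": self.sensitivity,
            "FN1_rate": self.fn1_rate,
            "FN2_rate": self.fn2_rate,
        }


def evaluate_discovery(
    truth: list[PlantedInsertion],
    discovered: list[RefMinusCandidate],
    index: LocateIndex,
    reference: dict[str, str],
    tolerance: int = MATCH_TOLERANCE,
) -> DiscoveryReport:
    """Match discoveries to planted insertions and decompose the misses.

    A planted insertion is detected when any discovery lies within
    ``tolerance`` bases of its breakpoint on the same chromosome.
    Unmatched insertions are FN2 when the insertion window (25 bp flank
    + 10 bp signature footprint) overlaps an N run, FN1 when the 25-mer
    5' of the breakpoint does not localise uniquely in the reference,
    and "missed-other" otherwise. Discoveries matching no planted
    insertion count as false discoveries.
    """
    planted = [t for t in truth if t.zygosity != "absent"]
    by_chrom: dict[str, list[int]] = {}
    for d in discovered:
        by_chrom.setdefault(d.location.chrom, []).append(d.breakpoint)
    for v in by_chrom.values():
        v.sort()

    annotated: list[PlantedInsertion] = []
    n_det = n_fn1 = n_fn2 = n_other = 0
    matched_dis: set[tuple[str, int]] = set()
    for t in planted:
        bps = by_chrom.get(t.chrom, [])
        i = int(np.searchsorted(bps, t.pos))
        near = [bp for bp in bps[max(0, i - 2) : i + 2] if abs(bp - t.pos) <= tolerance]
        if near:
            n_det += 1
            cls = "detectable"
            matched_dis.update((t.chrom, bp) for bp in near)
        else:
            window = reference[t.chrom][max(0, t.pos - 25) : t.pos + 10]
            flank = reference[t.chrom][max(0, t.pos - 25) : t.pos]
            if "N" in window or len(flank) < 25:
                cls = "FN2_Nregion"
                n_fn2 += 1
            elif index.count(flank) != 1:
                cls = "FN1_nonunique"
                n_fn1 += 1
            else:
                cls = "missed_other"
                n_other += 1
        annotated.append(PlantedInsertion(
            t.chrom, t.pos, t.zygosity, t.haplotype, t.alu_seq, t.tsd,
            t.polyA_len, fn_class=cls,
        ))
    false_dis = sum(
        1 for d in discovered if (d.location.chrom, d.breakpoint) not in matched_dis
    )
    n = len(planted)
    return DiscoveryReport(
        n_planted=n, detected=n_det, fn1=n_fn1, fn2=n_fn2, missed_other=n_other,
        false_discoveries=false_dis,
        sensitivity=n_det / n if n else 0.0,
        fn1_rate=n_fn1 / n if n else 0.0,
        fn2_rate=n_fn2 / n if n else 0.0,
        per_insertion=annotated,
    )
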