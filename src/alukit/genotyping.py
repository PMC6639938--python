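"""Alignment-free genotyping of known insertions from raw reads.

The frequency of each pair's two 32-mers is counted over the read
stream (canonical matching, so both strands collapse). Genotypes are
called with a flat-prior Bayes classifier: under each genotype
hypothesis the two allele counts are independent Poisson draws whose
intensities come from the expected per-allele k-mer coverage ``lam``
and a small leak rate ``eps`` for an absent allele:

    ploidy 2:   AA (lam, eps)   AB (lam/2, lam/2)   BB (eps, lam)
    ploidy 1:   A  (lam, eps)                       B  (eps, lam)

The maximum-posterior genotype is called iff its posterior clears
``min_posterior``; otherwise NC (no call). ``lam`` is calibrated per
individual as the median total pair count over informative pairs.

Cohort-level reliability filters then drop elements that genotype
badly across many individuals: unexpected-ploidy calls, deviation from
Hardy-Weinberg equilibrium, and monomorphic REF– elements (a REF–
element seen in reads but never carrying a B allele in the cohort is an
artifact by construction; monomorphic REF+ elements are legitimate and
kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from . import kmers
from .io import iter_reads
from .pair_builder import K_TOTAL, REF_MINUS, KmerPair

log = logging.getLogger(__name__)

MIN_POSTERIOR = 0.99
MAX_UNEXPECTED = 0.02
HWE_ALPHA = 1e-4
MIN_CALIBRATION_PAIRS = 100

_BATCH_READS = 20_000


@dataclass(frozen=True)
class PairCounts:
    element_id: str
    nA: int
    nB: int


@dataclass(frozen=True)
class GenotypeCall:
    element_id: str
    ploidy: int
    genotype: str          # AA/AB/BB (ploidy 2), A/B (ploidy 1), or NC
    posterior: float
    nA: int = 0
    nB: int = 0


@dataclass(frozen=True)
class CallerModel:
    lam: float                       # expected per-allele k-mer coverage
    eps: float                       # leak intensity of an absent allele
    min_posterior: float = MIN_POSTERIOR

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0 < self.eps < self.lam:
            raise ValueError("eps must be in (0, lam)")
        if not 0.5 < self.min_posterior < 1:
            raise ValueError("min_posterior must be in (0.5, 1)")


def count_pairs(reads, pairs: list[KmerPair]) -> list[PairCounts]:
    """Exact 32-mer occurrence counts over a read stream, canonical.

    A read containing a pair k-mer twice contributes 2. Both
    orientations of every query are matched against the forward read
    stream, which is equivalent to canonical counting.
    """
    lookup: dict[int, tuple[int, int]] = {}
    for i, p in enumerate(pairs):
        for allele, m in enumerate((p.kmerA, p.kmerB)):
            lookup[kmers.code_of(m)] = (i, allele)
            lookup[kmers.code_of(kmers.revcomp(m))] = (i, allele)
    query = np.array(sorted(lookup), dtype=np.uint64)
    targets = np.array([lookup[int(q)] for q in query], dtype=np.int64)
    counts = np.zeros((len(pairs), 2), dtype=np.int64)

    def flush(batch: list[str]) -> None:
        joined = "N".join(batch)
        vals, valid = kmers.kmer_codes(kmers.encode(joined), K_TOTAL)
        if len(vals) == 0:
            return
        vals = vals[valid]
        idx = np.searchsorted(query, vals)
        idx[idx == len(query)] = 0
        hit = query[idx] == vals
        t = targets[idx[hit]]
        np.add.at(counts, (t[:, 0], t[:, 1]), 1)

    batch: list[str] = []
    for seq in iter_reads(reads):
        batch.append(seq)
        if len(batch) >= _BATCH_READS:
            flush(batch)
            batch = []
    if batch:
        flush(batch)
    return [PairCounts(p.element_id, int(counts[i, 0]), int(counts[i, 1]))
            for i, p in enumerate(pairs)]


def _log_poisson(n: int, mu: float) -> float:
    return n * np.log(mu) - mu - gammaln(n + 1)


def _hypotheses(model: CallerModel, ploidy: int) -> list[tuple[str, float, float]]:
    lam, eps = model.lam, model.eps
    if ploidy == 2:
        return [("AA", lam, eps), ("AB", lam / 2, lam / 2), ("BB", eps, lam)]
    if ploidy == 1:
        return [("A", lam, eps), ("B", eps, lam)]
    raise ValueError(f"ploidy must be 1 or 2, got {ploidy}")


def call_genotype(counts: PairCounts, model: CallerModel, ploidy: int = 2) -> GenotypeCall:
    """Flat-prior Bayes call among the genotype hypotheses."""
    if ploidy == 0:
        return GenotypeCall(counts.element_id, 0, "NC", 0.0, counts.nA, counts.nB)
    hyps = _hypotheses(model, ploidy)
    logls = np.array([
        _log_poisson(counts.nA, ma) + _log_poisson(counts.nB, mb)
        for _, ma, mb in hyps
    ])
    post = np.exp(logls - logsumexp(logls))
    best = int(np.argmax(post))
    name = hyps[best][0] if post[best] >= model.min_posterior else "NC"
    return GenotypeCall(counts.element_id, ploidy, name, float(post[best]),
                        counts.nA, counts.nB)


def calibrate(
    all_counts: list[PairCounts],
    fallback_lam: float | None = None,
    min_posterior: float = MIN_POSTERIOR,
) -> CallerModel:
    """Per-individual model calibration.

    lam = median of (nA + nB) over informative pairs (total > 0);
    eps = max(0.01 * lam, 0.1). With fewer than 100 informative pairs a
    user-supplied expected k-mer coverage is required instead.
    """
    if not all_counts:
        raise ValueError("cannot calibrate from an empty count set")
    totals = [c.nA + c.nB for c in all_counts if c.nA + c.nB > 0]
    if len(totals) >= MIN_CALIBRATION_PAIRS:
        lam = float(np.median(totals))
    elif fallback_lam is not None:
        log.warning("only %d informative pairs; using supplied coverage %.1f",
                    len(totals), fallback_lam)
        lam = float(fallback_lam)
    else:
        raise ValueError(
            f"only {len(totals)} informative pairs (<{MIN_CALIBRATION_PAIRS}) and "
            "no fallback coverage supplied"
        )
    if lam <= 0:
        raise ValueError("calibrated lam is not positive; supply a coverage estimate")
    return CallerModel(lam=lam, eps=max(0.01 * lam, 0.1), min_posterior=min_posterior)


def genotype_individual(
    reads,
    pairs: list[KmerPair],
    ploidy_of=None,
    fallback_lam: float | None = None,
    min_posterior: float = MIN_POSTERIOR,
) -> list[GenotypeCall]:
    """Count, calibrate, and call every pair for one individual.

    ``ploidy_of(chrom)`` gives the expected ploidy per chromosome
    (default: diploid everywhere).
    """
    counts = count_pairs(reads, pairs)
    model = calibrate(counts, fallback_lam=fallback_lam, min_posterior=min_posterior)
    if ploidy_of is None:
        ploidy_of = lambda chrom: 2
    return [
        call_genotype(c, model, ploidy_of(p.location.chrom))
        for c, p in zip(counts, pairs)
    ]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote configuration no more probable than the observed one
    (the standard minor-configuration summation), using the exact
    hypergeometric-type distribution of the heterozygote count.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare, common = min(n_a, n_b), max(n_a, n_b)
    # log P(het = h | allele counts) up to a shared constant; h shares
    # the rare-allele count's parity
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = (common - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    probs = np.exp(logp - logsumexp(logp))
    p_obs = probs[hets == n_ab]
    if len(p_obs) == 0:  # observed table inconsistent with allele parity
        raise ValueError("inconsistent genotype table")
    p = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# cohort-level reliability filtering


def expected_ploidy(chrom: str, sex: str) -> int:
    """Expected ploidy per chromosome: autosomes diploid; chrY haploid
    in males and absent in females. (chrX is treated as an autosome
    here; the reliability rule targets chrY specifically.)"""
    if chrom.lstrip("chr").upper() == "Y":
        return 1 if sex.upper().startswith("M") else 0
    return 2


def cohort_filter(
    calls: dict[str, dict[str, GenotypeCall]],
    element_meta: dict[str, tuple[str, str]],
    sex_map: dict[str, str],
    max_unexpected: float = MAX_UNEXPECTED,
    hwe_alpha: float = HWE_ALPHA,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Cohort reliability filters; returns (validated ids, rejections).

    ``calls`` maps element_id -> {individual -> GenotypeCall};
    ``element_meta`` maps element_id -> (element_class, chrom).
    Removes elements with (a) a fraction of unexpected-ploidy calls
    above ``max_unexpected`` (NC excluded from the denominator), (b)
    HWE exact-test p below ``hwe_alpha`` (autosomal diploid calls), and
    (c) REF– elements with no B allele anywhere in the cohort.
    """
    unknown = set(calls) - set(element_meta)
    if unknown:
        raise ValueError(f"elements missing from metadata: {sorted(unknown)[:5]}")
    missing_sex = {ind for percall in calls.values() for ind in percall} - set(sex_map)
    if missing_sex:
        raise ValueError(f"individuals missing from sex map: {sorted(missing_sex)[:5]}")

    validated, rejections = [], []
    for eid, per_ind in calls.items():
        cls, chrom = element_meta[eid]
        reasons = []
        n_called = n_unexpected = 0
        tallies = {"AA": 0, "AB": 0, "BB": 0}
        n_b_alleles = 0
        for ind, call in per_ind.items():
            if call.genotype == "NC":
                continue
            n_called += 1
            exp = expected_ploidy(chrom, sex_map[ind])
            if call.ploidy != exp:
                n_unexpected += 1
            if call.genotype in tallies and call.ploidy == 2 and exp == 2:
                tallies[call.genotype] += 1
            n_b_alleles += call.genotype.count("B")
        if n_called and n_unexpected / n_called > max_unexpected:
            reasons.append("unexpected_ploidy")
        if sum(tallies.values()) > 0:
            p = hwe_exact_test(tallies["AA"], tallies["AB"], tallies["BB"])
            if p < hwe_alpha:
                reasons.append("hwe_deviation")
        if cls == REF_MINUS and n_b_alleles == 0:
            reasons.append("monomorphic_ref_minus")
        if reasons:
            rejections.extend((eid, r) for r in reasons)
        else:
            validated.append(eid)
    return validated, rejections
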