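"""Deterministic toy genomes with documented planted structures.

These generators back the test suite and the quickstart demo: random
ACGT genomes, a genome carrying an exact duplicated block (defeats
unique flank localisation -> FN1), a genome with N runs (unsequenced
regions -> FN2), and a full end-to-end demo directory. Everything is a
pure function of the seed.
"""

from __future__ import annotations

import os

import numpy as np

from . import io, simulator
from .signatures import build_signature_set

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FIXTURE_KINDS = ("toy_genome", "duplication", "n_region", "full_demo")


def random_genome(
    seed: int, length: int = 100_000, n_chroms: int = 1, prefix: str = "chr"
) -> dict[str, str]:
    """Uniform-random ACGT genome, deterministic under the seed."""
    rng = np.random.default_rng(seed)
    per = length // n_chroms
    return {
        f"{prefix}{i + 1}": _BASES[rng.integers(0, 4, size=per)].tobytes().decode()
        for i in range(n_chroms)
    }


def duplication_genome(
    seed: int, length: int = 100_000, block_len: int = 10_000
) -> dict[str, str]:
    """Random genome whose central region repeats an exact block.

    The duplicated block makes every 25-mer inside it non-unique, so
    insertions planted there become FN1 in the simulator evaluation.
    """
    if length < 3 * block_len:
        raise ValueError("length must be at least 3x the block length")
    g = random_genome(seed, length)
    name, seq = next(iter(g.items()))
    block = seq[:block_len]
    mid = length // 2
    seq = seq[:mid] + block + seq[mid + block_len :]
    return {name: seq}


def n_region_genome(
    seed: int, length: int = 100_000, n_runs: int = 4, run_len: int = 2_000
) -> dict[str, str]:
    """Random genome with evenly spaced N runs (unsequenced regions)."""
    g = random_genome(seed, length)
    name, seq = next(iter(g.items()))
    arr = list(seq)
    gap = length // (n_runs + 1)
    for i in range(1, n_runs + 1):
        start = i * gap
        arr[start : start + run_len] = "N" * run_len
    return {name: "".join(arr)}


def make_fixture(kind: str, seed: int, out_dir: str, **kw) -> dict[str, str]:
    """Write a fixture directory; returns the paths written."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    if kind == "toy_genome":
        genome = random_genome(seed, **kw)
    elif kind == "duplication":
        genome = duplication_genome(seed, **kw)
    elif kind == "n_region":
        genome = n_region_genome(seed, **kw)
    else:  # full_demo: genome + planted diploid + reads + truth
        genome = random_genome(seed, length=kw.pop("length", 200_000))
        ref_path = os.path.join(out_dir, "ref.fa")
        io.write_fasta(genome, ref_path)
        paths["ref"] = ref_path
        diploid, truth = simulator.plant_insertions(
            genome, n=kw.pop("n", 20), mutation_rate=kw.pop("mutation_rate", 0.0),
            seed=seed,
        )
        total = sum(len(s) for s in genome.values())
        params = simulator.ReadSimParams(
            n_read_pairs=simulator.pairs_for_coverage(total, kw.pop("coverage", 40.0)),
            seed=seed,
        )
        p1, p2 = io.write_fastq_pair(
            simulator.simulate_reads(diploid, params),
            os.path.join(out_dir, "reads"),
        )
        truth_path = os.path.join(out_dir, "truth.tsv")
        io.write_truth(truth, truth_path, ref_name="full_demo")
        sig_path = os.path.join(out_dir, "signatures.txt")
        with open(sig_path, "w") as fh:
            for m in sorted(build_signature_set().members):
                fh.write(m + "\n")
        paths.update({"reads_1": p1, "reads_2": p2, "truth": truth_path,
                      "signatures": sig_path})
        return paths
    ref_path = os.path.join(out_dir, "ref.fa")
    io.write_fasta(genome, ref_path)
    paths["ref"] = ref_path
    return paths
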