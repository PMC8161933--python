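"""Shared fixtures: hand-built separable repeats and the seeded benchmark run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from emmul.io_alignments import (
    CandidateLocation,
    MultireadRecord,
    ReadAlignment,
    ReferenceGenome,
)
from emmul.evaluate import evaluate_run
from emmul.pipeline import RunConfig, resolve
from emmul.simulate import SimulatedRead, SimulationConfig, simulate_dataset

# substitution that is never bisulfite-ambiguous: A<->C, G<->T
_SAFE_SUB = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class SeparableFixture:
    """10 kb genome, one 2-copy repeat diverged every 15 bp (>=6 diffs per
    100 bp window), error-free fully methylated reads, unique reads covering
    both copies. Every multiread is separable by the score margin alone."""

    genome: ReferenceGenome
    unique: list[ReadAlignment]
    multireads: list[MultireadRecord]
    truth: dict[str, tuple[str, int, str]]
    copy_a: int = 2000
    copy_b: int = 6000
    unit: int = 300
    read_len: int = 100


def make_separable_fixture(seed: int = 42) -> SeparableFixture:
    rng = np.random.default_rng(seed)
    L, K, unit = 10_000, 100, 300
    copy_a, copy_b = 2000, 6000
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=L))
    seq[copy_b : copy_b + unit] = seq[copy_a : copy_a + unit]
    diff_offsets = list(range(7, unit, 15))  # 20 diffs, >=6 in any 100 bp window
    for off in diff_offsets:
        seq[copy_b + off] = _SAFE_SUB[seq[copy_b + off]]
    genome = ReferenceGenome({"chr": "".join(seq)})
    ref = genome.sequences["chr"]

    def read_at(rid: str, start: int, candidates: list[int]) -> tuple:
        bases = ref[start : start + K]
        quals = np.full(K, 40, dtype=int)
        return rid, start, bases, quals, candidates

    unique: list[ReadAlignment] = []
    for i, s in enumerate(list(range(1900, 2301, 25)) + list(range(5900, 6301, 25))):
        unique.append(
            ReadAlignment(
                read_id=f"u{i:03d}", contig="chr", start=s, strand="OT",
                is_reverse=False, bases=ref[s : s + K],
                quals=np.full(K, 40, dtype=int), cigar=[("M", K)],
            )
        )
    multireads: list[MultireadRecord] = []
    truth: dict[str, tuple[str, int, str]] = {}
    for i, s in enumerate(range(copy_a, copy_a + unit - K + 1, 10)):
        rid = f"m{i:03d}"
        decoy = copy_b + (s - copy_a)
        cands = [
            CandidateLocation("chr", s, "OT", False, [("M", K)]),
            CandidateLocation("chr", decoy, "OT", False, [("M", K)]),
        ]
        multireads.append(
            MultireadRecord(
                read_id=rid, bases=ref[s : s + K],
                quals=np.full(K, 40, dtype=int), candidates=cands,
            )
        )
        truth[rid] = ("chr", s, "OT")
    return SeparableFixture(genome=genome, unique=unique, multireads=multireads, truth=truth)


@pytest.fixture(scope="session")
def separable():
    return make_separable_fixture()


@pytest.fixture(scope="session")
def benchmark_run():
    """Default-condition 100 kb benchmark (20X, 100 bp, 1% error, repeat
    families with 2-15 copies), resolved and evaluated once per session."""
    ds = simulate_dataset(SimulationConfig(seed=1))
    classified = ds.to_classified()
    result = resolve(ds.reference, classified.unique, classified.multireads, RunConfig(seed=1))
    truth = {m.read_id: ds.truth()[m.read_id] for m in classified.multireads}
    evaluation = evaluate_run(result.assignments, classified.multireads, truth, baseline_seed=7)
    return {
        "dataset": ds,
        "classified": classified,
        "result": result,
        "truth": truth,
        "evaluation": evaluation,
    }
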