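"""Benchmark statistics for multiread resolution against truth labels.

recall r  = assigned multireads / all multireads
accuracy p = correctly placed / assigned
F1        = 2pr / (p + r)

PerRight(i) splits the correctly placed multireads with exactly i candidate
positions between the method under test and a random-selection baseline:
PerRight_our(i) = n_our / (n_our + n_random), and symmetrically for random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_alignments import MultireadRecord
from .smoothness import Assignment

Truth = Mapping[str, tuple[str, int, str]]


def _is_correct(a: Assignment, truth: Truth, tolerance_bp: int = 0) -> bool:
    t = truth.get(a.read_id)
    if t is None:
        raise KeyError(f"assignment for unknown read id {a.read_id}")
    contig, start, strand = t
    return (
        a.contig == contig
        and a.strand == strand
        and abs(a.start - start) <= tolerance_bp
    )


def recall_accuracy(
    assignments: Sequence[Assignment],
    truth: Truth,
    n_multireads: int | None = None,
    tolerance_bp: int = 0,
) -> tuple[float, float]:
    """(accuracy p, recall r). p is reported as 0 when nothing was assigned."""
    if n_multireads is None:
        n_multireads = len(truth)
    assigned = [a for a in assignments if a.stage != "unresolved"]
    r = len(assigned) / n_multireads if n_multireads else 0.0
    if not assigned:
        return 0.0, r
    correct = sum(_is_correct(a, truth, tolerance_bp) for a in assigned)
    return correct / len(assigned), r


def f1(p: float, r: float) -> float:
    """Harmonic mean of accuracy and recall; 0 when both are 0."""
    if not 0.0 <= p <= 1.0 or not 0.0 <= r <= 1.0:
        raise ValueError("p and r must be probabilities")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def random_baseline(
    multireads: Iterable[MultireadRecord], seed: int | np.random.Generator = 0
) -> list[Assignment]:
    """Assign each multiread to a uniformly random candidate (the comparator
    the per-stratum PerRight statistic is defined against)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for m in multireads:
        j = int(rng.integers(0, m.q))
        c = m.candidates[j]
        out.append(
            Assignment(
                read_id=m.read_id,
                contig=c.contig,
                start=c.start,
                strand=c.strand,
                candidate_index=j,
                stage="random",
            )
        )
    return out


def random_baseline_score_ties(
    multireads: Iterable[MultireadRecord],
    scores_by_read: Mapping[str, Sequence[float]],
    seed: int | np.random.Generator = 0,
    tie_tol: float = 1e-9,
) -> list[Assignment]:
    """Random selection restricted to candidates tying the best score.

    ``scores_by_read`` maps read id to the per-candidate S_j values (in
    candidate order). Candidates within ``tie_tol`` of the maximum are the tie
    set; one of them is drawn uniformly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for m in multireads:
        s = np.asarray(scores_by_read[m.read_id], dtype=float)
        if s.size != m.q:
            raise ValueError(f"{m.read_id}: {s.size} scores for {m.q} candidates")
        tied = np.flatnonzero(s >= s.max() - tie_tol)
        j = int(tied[rng.integers(0, tied.size)])
        c = m.candidates[j]
        out.append(
            Assignment(
                read_id=m.read_id,
                contig=c.contig,
                start=c.start,
                strand=c.strand,
                candidate_index=j,
                stage="random",
            )
        )
    return out


def per_right(
    assignments_our: Sequence[Assignment],
    assignments_random: Sequence[Assignment],
    truth: Truth,
    q_by_read: Mapping[str, int],
    tolerance_bp: int = 0,
) -> pd.DataFrame:
    """Per-stratum PerRight table indexed by candidate count i.

    Columns: n (stratum size), n_our, n_random (correct counts) and the two
    PerRight shares. Strata where neither method placed a read correctly are
    omitted.
    """
    ours = {a.read_id for a in assignments_our if a.stage != "unresolved"}
    rand = {a.read_id for a in assignments_random}
    if set(q_by_read) - rand:
        raise ValueError("random baseline does not cover all multireads")
    correct_our: dict[int, int] = {}
    correct_rand: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for rid, q in q_by_read.items():
        sizes[q] = sizes.get(q, 0) + 1
    for a in assignments_our:
        if a.stage == "unresolved":
            continue
        q = q_by_read[a.read_id]
        if _is_correct(a, truth, tolerance_bp):
            correct_our[q] = correct_our.get(q, 0) + 1
    for a in assignments_random:
        q = q_by_read[a.read_id]
        if _is_correct(a, truth, tolerance_bp):
            correct_rand[q] = correct_rand.get(q, 0) + 1
    rows = []
    for q in sorted(sizes):
        n_our = correct_our.get(q, 0)
        n_rand = correct_rand.get(q, 0)
        if n_our + n_rand == 0:
            continue
        rows.append(
            {
                "i": q,
                "n": sizes[q],
                "n_our": n_our,
                "n_random": n_rand,
                "perright_our": n_our / (n_our + n_rand),
                "perright_random": n_rand / (n_our + n_rand),
            }
        )
    return pd.DataFrame(rows).set_index("i") if rows else pd.DataFrame(
        columns=["n", "n_our", "n_random", "perright_our", "perright_random"]
    )


@dataclass
class EvaluationResult:
    p: float
    r: float
    f1: float
    n_multireads: int
    n_assigned: int
    n_correct: int
    stage_counts: dict[str, int]
    per_right: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.p,
            "recall": self.r,
            "f1": self.f1,
            "n_multireads": self.n_multireads,
            "n_assigned": self.n_assigned,
            "n_correct": self.n_correct,
            "stage_counts": self.stage_counts,
            "per_right": self.per_right.reset_index().to_dict(orient="records"),
        }


def evaluate_run(
    assignments: Sequence[Assignment],
    multireads: Sequence[MultireadRecord],
    truth: Truth,
    baseline_seed: int = 0,
    tolerance_bp: int = 0,
) -> EvaluationResult:
    """Full benchmark: recall/accuracy/F1 plus PerRight against random selection."""
    n_multi = len(multireads)
    p, r = recall_accuracy(assignments, truth, n_multireads=n_multi, tolerance_bp=tolerance_bp)
    assigned = [a for a in assignments if a.stage != "unresolved"]
    n_correct = sum(_is_correct(a, truth, tolerance_bp) for a in assigned)
    stage_counts: dict[str, int] = {}
    for a in assignments:
        stage_counts[a.stage] = stage_counts.get(a.stage, 0) + 1
    baseline = random_baseline(multireads, seed=baseline_seed)
    q_by_read = {m.read_id: m.q for m in multireads}
    pr = per_right(assignments, baseline, truth, q_by_read, tolerance_bp)
    return EvaluationResult(
        p=p,
        r=r,
        f1=f1(p, r),
        n_multireads=n_multi,
        n_assigned=len(assigned),
        n_correct=n_correct,
        stage_counts=stage_counts,
        per_right=pr,
    )
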