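"""Coverage-smoothness resolution for multireads without a usable score margin.

The working assumption is that once every read is placed, per-locus coverage
should be locally uniform; a candidate placement is therefore charged the
population variance of coverage inside a window centred on it, and the
candidate with minimal loss wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_alignments import MultireadRecord, UniqueReadIndex

DEFAULT_WIN_LEN = 200


@dataclass
class Assignment:
    """The resolved location of one multiread."""

    read_id: str
    contig: str
    start: int
    strand: str
    candidate_index: int
    stage: str  # 'score' | 'smoothness' | 'random' | 'unresolved'
    s_max: float | None = None
    s_nextmax: float | None = None
    margin: float | None = None
    losses: list[float] | None = None


class CoverageState:
    """Mutable per-contig integer coverage, seeded from unique reads."""

    def __init__(self, contig_lengths: dict[str, int]):
        self.arrays = {c: np.zeros(n, dtype=np.int32) for c, n in contig_lengths.items()}

    @classmethod
    def from_unique_index(cls, index: UniqueReadIndex) -> "CoverageState":
        state = cls(index.contig_lengths)
        for contig, cov in index.coverage.items():
            state.arrays[contig] += cov
        return state

    def add_span(self, contig: str, start: int, end: int) -> None:
        self.arrays[contig][start:end] += 1


def window_loss(a: Sequence[float]) -> float:
    """Population variance of a coverage window (the smoothness loss)."""
    arr = np.asarray(a, dtype=float)
    if arr.size == 0:
        raise ValueError("empty coverage window")
    x_bar = arr.mean()
    return float(np.mean((arr - x_bar) ** 2))


def _window_bounds(center: int, win_len: int, contig_len: int) -> tuple[int, int]:
    w0 = max(0, center - win_len // 2)
    w1 = min(contig_len, w0 + win_len)
    w0 = max(0, w1 - win_len)
    return w0, w1


def candidate_loss(
    coverage: CoverageState,
    contig: str,
    span: tuple[int, int],
    win_len: int = DEFAULT_WIN_LEN,
) -> float:
    """Loss of hypothetically placing one read over ``span``; pure query.

    The window is centred on the candidate span and truncated at contig edges
    (the mean is recomputed over the truncated length).
    """
    cov = coverage.arrays[contig]
    start, end = span
    center = (start + end) // 2
    w0, w1 = _window_bounds(center, win_len, len(cov))
    a = cov[w0:w1].astype(float)
    lo, hi = max(start, w0), min(end, w1)
    if lo < hi:
        a = a.copy()
        a[lo - w0 : hi - w0] += 1.0
    return window_loss(a)


def resolve_by_smoothness(
    deferred: Iterable[MultireadRecord],
    coverage: CoverageState,
    win_len: int = DEFAULT_WIN_LEN,
    rng: np.random.Generator | None = None,
) -> list[Assignment]:
    """Assign every deferred multiread to its minimum-loss candidate.

    Multireads are processed least-ambiguous first (ascending Q, then read id);
    each winner is committed to the coverage state before the next read is
    considered, which is what makes the uniformity assumption actionable.
    Pairwise elimination over all candidate pairs is equivalent to the global
    argmin of the per-candidate loss, which is what is computed. Ties go to
    the lowest (contig, start); candidate deduplication makes that unique.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    assignments: list[Assignment] = []
    for m in sorted(deferred, key=lambda m: (m.q, m.read_id)):
        losses = [
            candidate_loss(coverage, c.contig, c.ref_span(), win_len) for c in m.candidates
        ]
        best = min(losses)
        tied = [j for j, l in enumerate(losses) if l == best]
        j_star = min(tied, key=lambda j: (m.candidates[j].contig, m.candidates[j].start))
        cand = m.candidates[j_star]
        coverage.add_span(cand.contig, *cand.ref_span())
        assignments.append(
            Assignment(
                read_id=m.read_id,
                contig=cand.contig,
                start=cand.start,
                strand=cand.strand,
                candidate_index=j_star,
                stage="smoothness",
                losses=[float(l) for l in losses],
            )
        )
    return assignments
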