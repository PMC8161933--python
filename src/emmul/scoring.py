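"""Base-level rescoring of multiread candidate locations.

Each candidate location j of a multiread M receives

    S_j = sum_k (S_MkGs + S_MkUt) / 2

where S_MkGs weighs the bisulfite-aware substitution score of read base M_k
against reference base G_s by the probability of actually observing M_k given
G_s (SNP rate plus context-specific methylation priors), and S_MkUt is the
analogous score of M_k against the stack of unique-read bases aligned to the
same locus, averaged over the stack, with the sequencing-error probabilities
of both bases setting the weight. Loci with no unique coverage substitute
S_MkGs for S_MkUt. The best candidate is accepted only when it beats the
runner-up by more than a margin sigma; otherwise the read is deferred to the
coverage-smoothness stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_alignments import (
    A, C, G, T, N,
    MultireadRecord,
    ReferenceGenome,
    UniqueReadIndex,
    encode_bases,
    normalize_strand,
    phred_to_eps,
)
from .smoothness import Assignment

_BASE_CODE = {"A": A, "C": C, "G": G, "T": T, "N": N}

#: bisulfite scoring matrix for the original-top strand; rows = reference
#: base, columns = read base, order A,C,G,T,N. Matches scale with reduced
#: credit for the ambiguous read-T (it may come from T or a converted C).
OT_SCORE = np.array(
    [
        [6, -18, -18, -18, -25],
        [-18, 6, -18, 3, -25],
        [-18, -18, 6, -18, -25],
        [-18, -18, -18, 3, -25],
        [-25, -25, -25, -25, 25],
    ],
    dtype=float,
)

DEFAULT_GAP_SCORE = -25.0
S_MAXCELL = 6.0

_COMP_PERM = np.array([T, G, C, A, N])


@dataclass(frozen=True)
class ScoringMatrix:
    """Strand-aware 5x5 substitution score table plus per-reference-base totals."""

    table: np.ndarray
    gap_score: float = DEFAULT_GAP_SCORE

    @property
    def row_total(self) -> np.ndarray:
        """S[Gs]: total score over the four standard read bases, per reference base."""
        return self.table[:, :4].sum(axis=1)

    def score(self, gs: str, mk: str) -> float:
        return float(self.table[_BASE_CODE[gs], _BASE_CODE[mk]])

    def total(self, gs: str) -> float:
        return float(self.row_total[_BASE_CODE[gs]])

    @classmethod
    def for_strand(cls, strand: str, gap_score: float = DEFAULT_GAP_SCORE) -> "ScoringMatrix":
        """OT matrix as tabulated above; the OB matrix is its base-complement mirror.

        On OB the tolerated bisulfite mismatch is reference G / read A (the
        converted base appears as A in genome-forward orientation).
        """
        if normalize_strand(strand) == "OT":
            return cls(OT_SCORE.copy(), gap_score)
        tbl = OT_SCORE[np.ix_(_COMP_PERM, _COMP_PERM)].copy()
        return cls(tbl, gap_score)


# ---------------------------------------------------------------------------
# observation model


@dataclass
class ObservationModel:
    """P(Mk | Gs): probability of observing read base Mk given reference Gs.

    Built from a per-site SNP probability (split uniformly over the three
    substitutions) and per-context methylation priors: an unmethylated C reads
    as T on the OT strand, an unmethylated bottom-strand C reads as A at the
    corresponding G on the OB strand. Contexts: 1 = CpG, 2 = CH, 0 = neither
    (non-C/G reference base). Entries involving N are fixed at 1/4.
    """

    snp_rate: float
    m_cpg: float
    m_ch: float

    def __post_init__(self) -> None:
        for name in ("snp_rate", "m_cpg", "m_ch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        self.tables = {
            "OT": self._build("OT"),
            "OB": self._build("OB"),
        }

    def _build(self, strand: str) -> np.ndarray:
        """(context, gs, mk) probability table, shape (3, 5, 5)."""
        snp = self.snp_rate
        base = np.full((4, 4), snp / 3.0)
        np.fill_diagonal(base, 1.0 - snp)
        tables = np.zeros((3, 5, 5))
        special = C if strand == "OT" else G
        observed = T if strand == "OT" else A  # what an unmethylated C reads as
        for ctx, m in ((0, None), (1, self.m_cpg), (2, self.m_ch)):
            tab = base.copy()
            if m is not None:
                row = np.full(4, snp / 3.0)
                row[special] = (1.0 - snp) * m
                row[observed] = snp / 3.0 + (1.0 - snp) * (1.0 - m)
                tab[special] = row
            tab /= tab.sum(axis=1, keepdims=True)
            full = np.full((5, 5), 0.25)
            full[:4, :4] = tab
            tables[ctx] = full
        return tables

    def prob(self, mk: str, gs: str, strand: str = "OT", context: int = 0) -> float:
        return float(
            self.tables[normalize_strand(strand)][context, _BASE_CODE[gs], _BASE_CODE[mk]]
        )


def build_observation_model(
    snp_rate: float, m_cpg: float, m_ch: float
) -> ObservationModel:
    return ObservationModel(snp_rate=snp_rate, m_cpg=m_cpg, m_ch=m_ch)


# ---------------------------------------------------------------------------
# per-base scores


def score_base_vs_reference(
    mk: str,
    gs: str,
    model: ObservationModel,
    matrix: ScoringMatrix,
    strand: str = "OT",
    context: int = 0,
) -> float:
    """Weighted reference score of one read base against one reference base:

    P(Mk,Gs) * Score(Mk,Gs) + (1 - P(Mk,Gs)) * (S[Gs] - Score(Mk,Gs))
    """
    p = model.prob(mk, gs, strand, context)
    sc = matrix.score(gs, mk)
    return p * sc + (1.0 - p) * (matrix.total(gs) - sc)


def agreement_probability(
    mk: str, ult: str, eps_k: float, eps_lt: float, mode: str = "corrected"
) -> float:
    """P(Mk -> Ult): probability weight for a read-base/unique-base pair.

    In ``corrected`` mode equal bases get the probability that no sequencing
    error occurred in either base, 1 - (eps_lt + eps_k - eps_lt*eps_k), and
    unequal bases its complement. ``literal`` mode swaps the two branches.
    """
    either_err = eps_lt + eps_k - eps_lt * eps_k
    same = mk == ult
    if mode == "corrected":
        return 1.0 - either_err if same else either_err
    if mode == "literal":
        return either_err if same else 1.0 - either_err
    raise ValueError(f"unknown agreement mode: {mode!r}")


def score_base_vs_unique_stack(
    mk: str,
    stack: Sequence[tuple[str, float]],
    eps_k: float,
    matrix: ScoringMatrix,
    mode: str = "corrected",
) -> float:
    """Mean over the unique-read stack of the per-read weighted score.

    ``stack`` holds (unique-read base, eps) pairs aligned to the same
    reference locus as the multiread base ``mk``.
    """
    if not stack:
        raise ValueError("empty unique-read stack; apply the substitution rule instead")
    total = 0.0
    for ult, eps_lt in stack:
        p = agreement_probability(mk, ult, eps_k, eps_lt, mode)
        sc = matrix.score(ult, mk)
        total += p * sc + (1.0 - p) * (matrix.total(ult) - sc)
    return total / len(stack)


# ---------------------------------------------------------------------------
# candidate-level scoring


@dataclass
class PositionScore:
    read_id: str
    candidate_index: int
    contig: str
    start: int
    strand: str
    s_ref: float
    s_unique: float
    s_j: float
    n_overlap: int


def default_sigma(read_length: int, fraction: float = 0.02) -> float:
    """Margin threshold scaling with read length: fraction * K * S_maxcell."""
    return fraction * read_length * S_MAXCELL


class PositionScorer:
    """Vectorised scorer for all candidates of classified multireads."""

    def __init__(
        self,
        genome: ReferenceGenome,
        unique_index: UniqueReadIndex,
        model: ObservationModel,
        gap_score: float = DEFAULT_GAP_SCORE,
        agreement_mode: str = "corrected",
    ):
        self.genome = genome
        self.index = unique_index
        self.model = model
        self.agreement_mode = agreement_mode
        self.matrices = {
            s: ScoringMatrix.for_strand(s, gap_score) for s in ("OT", "OB")
        }
        # combined Eq-4 lookup: [strand][context, gs, mk]
        self._s4 = {}
        for strand, matrix in self.matrices.items():
            p = model.tables[strand]  # (3,5,5)
            sc = matrix.table[None, :, :]
            tot = matrix.row_total[None, :, None]
            self._s4[strand] = p * sc + (1.0 - p) * (tot - sc)

    def score(self, multiread: MultireadRecord, j: int) -> PositionScore:
        cand = multiread.candidates[j]
        strand = normalize_strand(cand.strand)
        matrix = self.matrices[strand]
        bases, quals = multiread.oriented(cand)
        mk_all = encode_bases(bases)
        eps_all = phred_to_eps(quals)

        start, end = cand.ref_span()
        contig_len = self.genome.lengths[cand.contig]
        if start < 0 or end > contig_len:
            raise ValueError(
                f"{multiread.read_id}: candidate window [{start},{end}) exceeds "
                f"contig {cand.contig} ({contig_len} bp)"
            )
        ridx, gpos, n_gap = _walk_cigar(cand.cigar, start)
        enc = self.genome.encoded(cand.contig)
        ctx = self.genome.context_codes(cand.contig)
        mk = mk_all[ridx]
        eps_k = eps_all[ridx]
        s_ref_pb = self._s4[strand][ctx[gpos], enc[gpos], mk]

        sums = np.zeros(gpos.size)
        counts = np.zeros(gpos.size, dtype=np.int32)
        overlaps = self.index.overlapping(cand.contig, start, end)
        tbl = matrix.table
        tot = matrix.row_total
        for u in overlaps:
            upos, ub, ue = u.base_map()
            idx = np.searchsorted(gpos, upos)
            idx_c = np.minimum(idx, gpos.size - 1)
            valid = gpos[idx_c] == upos
            if not valid.any():
                continue
            slots = idx_c[valid]
            ub_v, ue_v = ub[valid], ue[valid]
            mk_v, me_v = mk[slots], eps_k[slots]
            either_err = ue_v + me_v - ue_v * me_v
            agree = ub_v == mk_v
            if self.agreement_mode == "corrected":
                p = np.where(agree, 1.0 - either_err, either_err)
            else:
                p = np.where(agree, either_err, 1.0 - either_err)
            sc = tbl[ub_v, mk_v]
            term = p * sc + (1.0 - p) * (tot[ub_v] - sc)
            np.add.at(sums, slots, term)
            np.add.at(counts, slots, 1)

        covered = counts > 0
        s_uni_pb = np.where(covered, sums / np.maximum(counts, 1), s_ref_pb)
        gap_total = n_gap * matrix.gap_score
        s_ref = float(s_ref_pb.sum() + gap_total)
        s_unique = float(s_uni_pb.sum() + gap_total)
        return PositionScore(
            read_id=multiread.read_id,
            candidate_index=j,
            contig=cand.contig,
            start=cand.start,
            strand=cand.strand,
            s_ref=s_ref,
            s_unique=s_unique,
            s_j=0.5 * (s_ref + s_unique),
            n_overlap=len(overlaps),
        )

    def score_all(self, multiread: MultireadRecord) -> list[PositionScore]:
        return [self.score(multiread, j) for j in range(multiread.q)]


def _walk_cigar(cigar, start: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Read indices and reference positions of M-aligned bases, plus gap count.

    Soft-clipped bases are excluded from scoring; each inserted or deleted
    base counts once toward the gap penalty.
    """
    ridx, gpos = [], []
    q, r, n_gap = 0, start, 0
    for op, n in cigar:
        if op == "M":
            ridx.append(np.arange(q, q + n))
            gpos.append(np.arange(r, r + n))
            q += n
            r += n
        elif op == "I":
            q += n
            n_gap += n
        elif op == "D":
            r += n
            n_gap += n
        elif op == "S":
            q += n
    if ridx:
        return np.concatenate(ridx), np.concatenate(gpos), n_gap
    return np.empty(0, dtype=int), np.empty(0, dtype=int), n_gap


def select_by_margin(scores: Sequence[PositionScore], sigma: float) -> Assignment | None:
    """Accept the argmax candidate iff S_max - S_nextmax > sigma, else defer.

    A single-candidate list is always accepted; ties always defer.
    """
    if not scores:
        raise ValueError("empty score list")
    ranked = sorted(scores, key=lambda s: s.s_j, reverse=True)
    best = ranked[0]
    if len(ranked) == 1:
        return Assignment(
            read_id=best.read_id,
            contig=best.contig,
            start=best.start,
            strand=best.strand,
            candidate_index=best.candidate_index,
            stage="score",
            s_max=best.s_j,
            s_nextmax=None,
            margin=None,
        )
    margin = best.s_j - ranked[1].s_j
    if margin > sigma:
        return Assignment(
            read_id=best.read_id,
            contig=best.contig,
            start=best.start,
            strand=best.strand,
            candidate_index=best.candidate_index,
            stage="score",
            s_max=best.s_j,
            s_nextmax=ranked[1].s_j,
            margin=margin,
        )
    return None
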