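"""End-to-end orchestration: classify -> score -> margin select -> smoothness -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_alignments import (
    MultireadRecord,
    ReadAlignment,
    ReferenceGenome,
    build_unique_index,
    classify_reads,
    load_reference,
    write_resolved,
)
from .scoring import (
    DEFAULT_GAP_SCORE,
    PositionScorer,
    build_observation_model,
    default_sigma,
    select_by_margin,
)
from .smoothness import (
    DEFAULT_WIN_LEN,
    Assignment,
    CoverageState,
    resolve_by_smoothness,
)

logger = logging.getLogger("emmul")


@dataclass
class RunConfig:
    """Tunable parameters of one resolution run."""

    snp_rate: float = 0.001
    m_cpg: float = 0.7
    m_ch: float = 0.005
    sigma: float | None = None  # None -> default_sigma(read length)
    agreement_mode: str = "corrected"
    gap_score: float = DEFAULT_GAP_SCORE
    win_len: int = DEFAULT_WIN_LEN
    seed: int = 0
    default_phred: int = 30

    def __post_init__(self) -> None:
        for name in ("snp_rate", "m_cpg", "m_ch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.agreement_mode not in ("corrected", "literal"):
            raise ValueError(f"agreement_mode must be corrected|literal, got {self.agreement_mode!r}")
        if self.win_len < 1:
            raise ValueError("win_len must be >= 1")


@dataclass
class ResolveResult:
    assignments: list[Assignment]
    n_multireads: int
    n_stage1: int
    n_stage2: int
    n_unresolved: int

    def by_read(self) -> dict[str, Assignment]:
        return {a.read_id: a for a in self.assignments}


def resolve(
    genome: ReferenceGenome,
    unique_reads: Sequence[ReadAlignment],
    multireads: Sequence[MultireadRecord],
    config: RunConfig | None = None,
) -> ResolveResult:
    """Resolve every multiread: sigma-margin scoring first, smoothness second.

    Stage 1 scores each candidate against the reference and overlapping unique
    reads and accepts the top candidate when its lead over the runner-up
    exceeds sigma. Deferred reads go to stage 2, which places each at the
    candidate minimising the local coverage-variance loss, updating coverage
    (unique reads + stage-1 placements) incrementally.
    """
    if config is None:
        config = RunConfig()
    logger.info(
        "resolve: %d unique reads, %d multireads; snp_rate=%g m_cpg=%g m_ch=%g "
        "sigma=%s agreement=%s win_len=%d seed=%d",
        len(unique_reads), len(multireads), config.snp_rate, config.m_cpg,
        config.m_ch, config.sigma, config.agreement_mode, config.win_len, config.seed,
    )
    index = build_unique_index(unique_reads, genome)
    model = build_observation_model(config.snp_rate, config.m_cpg, config.m_ch)
    scorer = PositionScorer(
        genome, index, model, gap_score=config.gap_score, agreement_mode=config.agreement_mode
    )

    stage1: list[Assignment] = []
    deferred: list[MultireadRecord] = []
    empty: list[Assignment] = []
    for m in multireads:
        scores = scorer.score_all(m)
        sigma = config.sigma if config.sigma is not None else default_sigma(len(m.bases))
        chosen = select_by_margin(scores, sigma)
        if chosen is not None:
            stage1.append(chosen)
        else:
            deferred.append(m)

    coverage = CoverageState.from_unique_index(index)
    by_id = {m.read_id: m for m in multireads}
    for a in stage1:
        cand = by_id[a.read_id].candidates[a.candidate_index]
        coverage.add_span(cand.contig, *cand.ref_span())

    rng = np.random.default_rng(config.seed)
    stage2 = resolve_by_smoothness(deferred, coverage, win_len=config.win_len, rng=rng)

    order = {m.read_id: i for i, m in enumerate(multireads)}
    assignments = sorted(stage1 + stage2 + empty, key=lambda a: order[a.read_id])
    n_unres = sum(a.stage == "unresolved" for a in assignments)
    logger.info(
        "resolved: stage1=%d stage2=%d unresolved=%d", len(stage1), len(stage2), n_unres
    )
    return ResolveResult(
        assignments=assignments,
        n_multireads=len(multireads),
        n_stage1=len(stage1),
        n_stage2=len(stage2),
        n_unresolved=n_unres,
    )


def resolve_files(
    ref_path,
    aln_path,
    out_path,
    report_path,
    config: RunConfig | None = None,
) -> ResolveResult:
    """File-level front end: FASTA + SAM/BAM in, resolved SAM/BAM + TSV report out."""
    if config is None:
        config = RunConfig()
    genome = load_reference(ref_path)
    classified = classify_reads(aln_path, reference=genome, default_phred=config.default_phred)
    logger.info(
        "classified: %d unique, %d multireads, %d unmapped",
        len(classified.unique), len(classified.multireads), classified.n_unmapped,
    )
    result = resolve(genome, classified.unique, classified.multireads, config)
    write_resolved(result.assignments, classified.multireads, genome, out_path, report_path)
    return result
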