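"""Synthetic bisulfite-sequencing datasets with engineered repeats and truth labels.

The generator builds a random genome carrying repeat families (one unit copied
several times, each copy independently diverged), injects donor SNPs, draws a
per-cytosine methylome on both strands, samples single-end reads to a target
depth, applies bisulfite conversion and sequencing errors, and emits a
candidate SAM in which each read is reported at its true location plus every
repeat-homologous location whose bisulfite-space Hamming distance falls within
a band of the best candidate — reads with two or more candidates are the
synthetic multireads. Everything is reproducible from a single seed and no
external aligner is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_alignments import A, C, G, T, ReferenceGenome, revcomp

_IDX2BASE = np.frombuffer("ACGTN".encode(), dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _IDX2BASE[codes].tobytes().decode()


@dataclass(frozen=True)
class RepeatFamily:
    unit_length: int
    copies: int
    divergence: float


@dataclass(frozen=True)
class RepeatCopy:
    family: int
    copy: int
    start: int
    end: int


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults mirror a typical whole-genome bisulfite run: 100 bp single-end
    reads at 20X, SNP rate 0.001, CpG methylation 70%, CH methylation 0.5%,
    sequencing error 1%, complete bisulfite conversion.
    """

    genome_length: int = 100_000
    repeat_families: tuple[RepeatFamily, ...] = (
        RepeatFamily(500, 2, 0.02),
        RepeatFamily(500, 5, 0.02),
        RepeatFamily(500, 10, 0.02),
        RepeatFamily(500, 15, 0.02),
    )
    read_length: int = 100
    depth: float = 20.0
    snp_rate: float = 0.001
    m_cpg: float = 0.7
    m_ch: float = 0.005
    error_rate: float = 0.01
    conversion: float = 1.0
    candidate_band: int = 8
    contig: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "m_cpg", "m_ch", "error_rate", "conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length <= 0 or self.read_length <= 0 or self.depth <= 0:
            raise ValueError("genome length, read length and depth must be positive")
        total = sum(f.unit_length * f.copies for f in self.repeat_families)
        if total > self.genome_length // 2:
            raise ValueError("repeat content exceeds half the genome; packing infeasible")

    @property
    def phred(self) -> int:
        if self.error_rate <= 0:
            return 40
        return max(2, round(-10.0 * math.log10(self.error_rate)))


# ---------------------------------------------------------------------------
# genome / methylome


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceGenome, list[RepeatCopy]]:
    """Random ACGT background with disjoint, evenly spaced repeat copies."""
    L = config.genome_length
    seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    copies: list[RepeatCopy] = []
    n_copies = sum(f.copies for f in config.repeat_families)
    total_repeat = sum(f.unit_length * f.copies for f in config.repeat_families)
    gap = (L - total_repeat) // (n_copies + 1)
    pos = gap
    for fi, fam in enumerate(config.repeat_families):
        unit = rng.integers(0, 4, size=fam.unit_length, dtype=np.uint8)
        for ci in range(fam.copies):
            copy = unit.copy()
            mut = rng.random(fam.unit_length) < fam.divergence
            if mut.any():
                shift = rng.integers(1, 4, size=int(mut.sum()))
                copy[mut] = (copy[mut] + shift) % 4
            seq[pos : pos + fam.unit_length] = copy
            copies.append(RepeatCopy(fi, ci, pos, pos + fam.unit_length))
            pos += fam.unit_length + gap
    return ReferenceGenome({config.contig: _decode(seq)}), copies


def inject_snps(
    genome: ReferenceGenome, snp_rate: float, rng: np.random.Generator
) -> tuple[ReferenceGenome, dict[str, np.ndarray]]:
    """Donor haplotype: each reference site mutated with probability snp_rate."""
    donor: dict[str, str] = {}
    snp_positions: dict[str, np.ndarray] = {}
    for contig, seq in genome.sequences.items():
        enc = genome.encoded(contig).copy()
        mut = rng.random(enc.size) < snp_rate
        mut &= enc < 4
        idx = np.flatnonzero(mut)
        if idx.size:
            enc[idx] = (enc[idx] + rng.integers(1, 4, size=idx.size)) % 4
        donor[contig] = _decode(enc)
        snp_positions[contig] = idx
    return ReferenceGenome(donor), snp_positions


@dataclass
class Methylome:
    """Per-cytosine methylation state on both strands of one genome.

    ``top[i]`` is meaningful where the sequence has C at i (top-strand
    cytosine), ``bottom[i]`` where it has G (bottom-strand cytosine). The two
    strands are drawn independently; strand symmetry is not imposed.
    """

    top: dict[str, np.ndarray]
    bottom: dict[str, np.ndarray]


def simulate_methylome(
    genome: ReferenceGenome, m_cpg: float, m_ch: float, rng: np.random.Generator
) -> Methylome:
    top: dict[str, np.ndarray] = {}
    bottom: dict[str, np.ndarray] = {}
    for contig in genome.sequences:
        enc = genome.encoded(contig)
        ctx = genome.context_codes(contig)  # 1 = CpG, 2 = CH at C/G sites
        prob = np.where(ctx == 1, m_cpg, np.where(ctx == 2, m_ch, 0.0))
        top[contig] = (rng.random(enc.size) < prob) & (enc == C)
        bottom[contig] = (rng.random(enc.size) < prob) & (enc == G)
    return Methylome(top=top, bottom=bottom)


# ---------------------------------------------------------------------------
# reads


@dataclass
class SimulatedRead:
    read_id: str
    contig: str
    true_start: int
    strand: str  # 'OT' | 'OB'
    bases_fwd: str  # genome-forward orientation, post conversion + errors
    phred: int
    candidates: list[int]  # candidate starts, sorted
    distances: list[int]  # bisulfite Hamming distance per candidate
    error_offsets: list[int]  # forward-space offsets of injected errors
    meth_states: list[tuple[int, bool]]  # (forward offset, methylated) per read cytosine

    @property
    def q(self) -> int:
        return len(self.candidates)

    @property
    def bases_sequenced(self) -> str:
        return revcomp(self.bases_fwd) if self.strand == "OB" else self.bases_fwd

    @property
    def primary(self) -> int:
        order = sorted(zip(self.distances, self.candidates))
        return order[0][1]


def _bisulfite_mismatches(
    read: np.ndarray, ref: np.ndarray, strand: str
) -> np.ndarray:
    """Mismatch mask under the asymmetric bisulfite wildcard."""
    match = read == ref
    if strand == "OT":
        match |= (ref == C) & (read == T)
    else:
        match |= (ref == G) & (read == A)
    return ~match


def simulate_reads(
    donor: ReferenceGenome,
    methylome: Methylome,
    reference: ReferenceGenome,
    repeats: list[RepeatCopy],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Sample reads to the target depth and attach candidate locations.

    Reads come uniformly from both strands of the donor haplotype; candidate
    search compares the finished read against the *reference* (what an aligner
    would see) at the true location and at homologous offsets inside every
    other copy of the containing repeat family.
    """
    contig = config.contig
    L = donor.lengths[contig]
    K = config.read_length
    if K > L:
        raise ValueError("read length exceeds genome length")
    n_reads = int(round(config.depth * L / K))
    if n_reads == 0:
        raise ValueError("zero reads requested; increase depth")
    denc = donor.encoded(contig)
    renc = reference.encoded(contig)
    meth_top = methylome.top[contig]
    meth_bot = methylome.bottom[contig]

    copy_id = np.full(L, -1, dtype=np.int32)
    for i, rc in enumerate(repeats):
        copy_id[rc.start : rc.end] = i

    width = len(str(max(n_reads - 1, 1)))
    starts = rng.integers(0, L - K + 1, size=n_reads)
    is_ob = rng.random(n_reads) < 0.5
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        s = int(starts[i])
        strand = "OB" if is_ob[i] else "OT"
        window = denc[s : s + K].copy()
        # bisulfite conversion of unmethylated cytosines on the sampled strand
        if strand == "OT":
            cyt = np.flatnonzero(window == C)
            meth = meth_top[s + cyt]
            convert = ~meth
        else:
            cyt = np.flatnonzero(window == G)
            meth = meth_bot[s + cyt]
            convert = ~meth
        if config.conversion < 1.0:
            convert &= rng.random(cyt.size) < config.conversion
        window[cyt[convert]] = T if strand == "OT" else A
        # sequencing errors
        err_mask = rng.random(K) < config.error_rate
        err_idx = np.flatnonzero(err_mask)
        if err_idx.size:
            window[err_idx] = (window[err_idx] + rng.integers(1, 4, size=err_idx.size)) % 4

        # candidate search over repeat homologs
        cands = [s]
        dists = [int(_bisulfite_mismatches(window, renc[s : s + K], strand).sum())]
        cid = copy_id[s]
        if cid >= 0 and s + K <= repeats[cid].end:
            home = repeats[cid]
            for rc in repeats:
                if rc.family != home.family or rc is home:
                    continue
                p = rc.start + (s - home.start)
                d = int(_bisulfite_mismatches(window, renc[p : p + K], strand).sum())
                cands.append(p)
                dists.append(d)
            d_min = min(dists)
            keep = [
                (p, d)
                for p, d in zip(cands, dists)
                if d <= d_min + config.candidate_band or p == s
            ]
            keep.sort()
            cands = [p for p, _ in keep]
            dists = [d for _, d in keep]
        reads.append(
            SimulatedRead(
                read_id=f"r{i:0{width}d}",
                contig=contig,
                true_start=s,
                strand=strand,
                bases_fwd=_decode(window),
                phred=config.phred,
                candidates=cands,
                distances=dists,
                error_offsets=[int(e) for e in err_idx],
                meth_states=[(int(o), bool(m)) for o, m in zip(cyt, meth)],
            )
        )
    return reads


# ---------------------------------------------------------------------------
# dataset orchestration and text output


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: ReferenceGenome
    donor: ReferenceGenome
    snp_positions: dict[str, np.ndarray]
    methylome: Methylome
    repeats: list[RepeatCopy]
    reads: list[SimulatedRead]

    @property
    def multireads(self) -> list[SimulatedRead]:
        return [r for r in self.reads if r.q >= 2]

    def truth(self) -> dict[str, tuple[str, int, str]]:
        return {r.read_id: (r.contig, r.true_start, r.strand) for r in self.reads}

    def to_classified(self):
        """In-memory classification equivalent to writing and re-parsing the SAM."""
        from .io_alignments import (
            CandidateLocation,
            ClassifyResult,
            MultireadRecord,
            ReadAlignment,
        )

        unique, multi = [], []
        for r in self.reads:
            K = len(r.bases_fwd)
            quals = np.full(K, r.phred, dtype=int)
            is_rev = r.strand == "OB"
            cigar = [("M", K)]
            if r.q == 1:
                unique.append(
                    ReadAlignment(
                        read_id=r.read_id,
                        contig=r.contig,
                        start=r.true_start,
                        strand=r.strand,
                        is_reverse=is_rev,
                        bases=r.bases_fwd,
                        quals=quals,
                        cigar=cigar,
                    )
                )
            else:
                cands = [
                    CandidateLocation(r.contig, s, r.strand, is_rev, list(cigar))
                    for s in r.candidates
                ]
                multi.append(
                    MultireadRecord(
                        read_id=r.read_id,
                        bases=r.bases_sequenced,
                        quals=quals[::-1] if is_rev else quals,
                        candidates=cands,
                    )
                )
        return ClassifyResult(unique=unique, multireads=multi, n_unmapped=0)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "bed": outdir / "repeats.bed",
            "fastq": outdir / "reads.fastq",
            "sam": outdir / "candidates.sam",
            "truth": outdir / "truth.tsv",
            "methylome": outdir / "methylome.tsv",
        }
        write_fasta(self.reference, paths["fasta"])
        write_repeats_bed(self.repeats, self.config.contig, paths["bed"])
        write_fastq(self.reads, paths["fastq"])
        write_candidates_sam(self.reads, self.reference, paths["sam"])
        write_truth_tsv(self.reads, paths["truth"])
        write_methylome_tsv(self.methylome, self.donor, paths["methylome"])
        return paths


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator pipeline from one seed."""
    rng = np.random.default_rng(config.seed)
    reference, repeats = simulate_genome(config, rng)
    donor, snp_positions = inject_snps(reference, config.snp_rate, rng)
    methylome = simulate_methylome(donor, config.m_cpg, config.m_ch, rng)
    reads = simulate_reads(donor, methylome, reference, repeats, config, rng)
    return SimulatedDataset(
        config=config,
        reference=reference,
        donor=donor,
        snp_positions=snp_positions,
        methylome=methylome,
        repeats=repeats,
        reads=reads,
    )


def write_fasta(genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_repeats_bed(repeats: list[RepeatCopy], contig: str, path) -> None:
    with open(path, "w") as fh:
        for rc in repeats:
            fh.write(f"{contig}\t{rc.start}\t{rc.end}\tfam{rc.family}_copy{rc.copy}\n")


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases_sequenced}\n+\n{chr(r.phred + 33) * len(r.bases_fwd)}\n")


def write_truth_tsv(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tstrand\tn_candidates\terror_offsets\tmeth_states\n")
        for r in reads:
            errs = ",".join(str(e) for e in r.error_offsets)
            meth = ",".join(f"{o}:{int(m)}" for o, m in r.meth_states)
            fh.write(
                f"{r.read_id}\t{r.contig}\t{r.true_start}\t{r.strand}\t{r.q}\t{errs}\t{meth}\n"
            )


def write_methylome_tsv(methylome: Methylome, genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tstrand\tcontext\tmethylated\n")
        for contig in genome.sequences:
            ctx = genome.context_codes(contig)
            enc = genome.encoded(contig)
            for strand, arr, base in (("+", methylome.top[contig], C), ("-", methylome.bottom[contig], G)):
                for pos in np.flatnonzero(enc == base):
                    label = "CpG" if ctx[pos] == 1 else "CH"
                    fh.write(f"{contig}\t{pos}\t{strand}\t{label}\t{int(arr[pos])}\n")


def write_candidates_sam(reads: list[SimulatedRead], genome: ReferenceGenome, path) -> None:
    """Plain-text SAM: one primary (best-distance) record per read plus
    secondary records for the remaining candidates. SEQ/QUAL are stored on the
    primary only, as aligners do."""
    import pysam

    from .io_alignments import sam_header

    header = sam_header(genome)
    contigs = list(genome.sequences)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            primary = r.primary
            for start in r.candidates:
                rec = pysam.AlignedSegment(header)
                rec.query_name = r.read_id
                rec.reference_id = contigs.index(r.contig)
                rec.reference_start = start
                rec.cigarstring = f"{len(r.bases_fwd)}M"
                flag = 16 if r.strand == "OB" else 0
                if start != primary:
                    flag |= 256
                else:
                    rec.query_sequence = r.bases_fwd
                    rec.query_qualities = [r.phred] * len(r.bases_fwd)
                rec.flag = flag
                rec.mapping_quality = 40 if r.q == 1 else 1
                rec.set_tag("XG", "CT" if r.strand == "OT" else "GA")
                out.write(rec)
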