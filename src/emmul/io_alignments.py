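"""Reference/alignment I/O: FASTA loading, read classification, interval indexing.

Coordinates are 0-based half-open everywhere inside the package; 1-based
conversion happens only at the SAM/BAM boundary (handled by pysam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

BASES = "ACGTN"
A, C, G, T, N = range(5)

# byte -> base code; everything that is not ACGT (either case) becomes N
_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: minimum per-base error probability; Phred caps at 40 in practice and a
#: literal 0 would make the agreement model degenerate
EPS_FLOOR = 1e-4


def encode_bases(seq: str) -> np.ndarray:
    """Map a base string onto uint8 codes A=0, C=1, G=2, T=3, N=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def phred_to_eps(quals: np.ndarray) -> np.ndarray:
    """Per-base error probability eps = 10^(-Q/10), floored at EPS_FLOOR."""
    return np.maximum(10.0 ** (-np.asarray(quals, dtype=float) / 10.0), EPS_FLOOR)


def normalize_strand(value: str) -> str:
    """Collapse bisulfite strand labels onto the two genome-forward classes.

    OT/CTOB libraries read the C->T converted top strand; OB/CTOT read the
    G->A converted bottom strand (Bismark's XG:Z:CT / XG:Z:GA convention).
    """
    v = value.upper()
    if v in ("OT", "CTOB", "CT", "+"):
        return "OT"
    if v in ("OB", "CTOT", "GA", "-"):
        return "OB"
    raise ValueError(f"unknown bisulfite strand label: {value!r}")


# ---------------------------------------------------------------------------
# reference genome


@dataclass
class ReferenceGenome:
    """Uppercase reference sequences over {A,C,G,T,N}, keyed by contig."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self._encoded: dict[str, np.ndarray] = {}
        self._context: dict[str, np.ndarray] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def encoded(self, contig: str) -> np.ndarray:
        arr = self._encoded.get(contig)
        if arr is None:
            arr = encode_bases(self.sequences[contig])
            self._encoded[contig] = arr
        return arr

    def context_codes(self, contig: str) -> np.ndarray:
        """Methylation context per locus: 0 = not a C/G, 1 = CpG, 2 = CH.

        A top-strand C at i is CpG iff seq[i+1] == G; a bottom-strand C
        (top-strand G at i) is CpG iff seq[i-1] == C (CpG is palindromic).
        """
        ctx = self._context.get(contig)
        if ctx is None:
            enc = self.encoded(contig)
            ctx = np.zeros(enc.shape, dtype=np.uint8)
            is_c = enc == C
            is_g = enc == G
            nxt_g = np.zeros_like(is_c)
            nxt_g[:-1] = enc[1:] == G
            prv_c = np.zeros_like(is_g)
            prv_c[1:] = enc[:-1] == C
            ctx[is_c] = np.where(nxt_g[is_c], 1, 2)
            ctx[is_g] = np.where(prv_c[is_g], 1, 2)
            self._context[contig] = ctx
        return ctx


def load_reference(path) -> ReferenceGenome:
    """Load a FASTA reference; uppercases and maps IUPAC ambiguity codes to N."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate contig name in FASTA: {record.id}")
        enc = encode_bases(str(record.seq))
        sequences[record.id] = "".join(BASES[i] for i in enc)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# alignments

_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MD")

_CIGAR_OP_CODES = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def _cigar_from_pysam(cigartuples) -> list[tuple[str, int]]:
    out = []
    for code, length in cigartuples:
        op = _CIGAR_OP_CODES.get(code)
        if op is None:
            raise ValueError(f"unsupported CIGAR op code {code}")
        out.append((op, length))
    return out


@dataclass
class CandidateLocation:
    contig: str
    start: int
    strand: str  # 'OT' or 'OB'
    is_reverse: bool
    cigar: list[tuple[str, int]]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.start, self.strand)

    def ref_span(self) -> tuple[int, int]:
        end = self.start + sum(n for op, n in self.cigar if op in _REF_OPS)
        return self.start, end


@dataclass
class ReadAlignment:
    """One aligned read in genome-forward orientation (bases as stored in SAM)."""

    read_id: str
    contig: str
    start: int
    strand: str
    is_reverse: bool
    bases: str
    quals: np.ndarray
    cigar: list[tuple[str, int]]
    is_unique: bool = True

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.bases):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {qlen} != read length {len(self.bases)}"
            )
        if len(self.quals) != len(self.bases):
            raise ValueError(f"{self.read_id}: quality/base length mismatch")
        if self.start < 0:
            raise ValueError(f"{self.read_id}: negative alignment start")
        self._base_map: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def ref_span(self) -> tuple[int, int]:
        end = self.start + sum(n for op, n in self.cigar if op in _REF_OPS)
        return self.start, end

    def aligned_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(read indices, reference positions) of M-aligned bases, both sorted."""
        ridx: list[np.ndarray] = []
        gpos: list[np.ndarray] = []
        q = 0
        r = self.start
        for op, n in self.cigar:
            if op == "M":
                ridx.append(np.arange(q, q + n))
                gpos.append(np.arange(r, r + n))
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op == "D":
                r += n
        if not ridx:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        return np.concatenate(ridx), np.concatenate(gpos)

    def base_map(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ref positions, base codes, eps) of M-aligned bases; cached."""
        if self._base_map is None:
            ridx, gpos = self.aligned_pairs()
            codes = encode_bases(self.bases)[ridx]
            eps = phred_to_eps(self.quals)[ridx]
            self._base_map = (gpos, codes, eps)
        return self._base_map


@dataclass
class MultireadRecord:
    """An ambiguously mapped read with its Q >= 2 candidate locations.

    ``bases``/``quals`` are stored in sequenced orientation; use
    :meth:`oriented` to obtain the genome-forward view for a candidate.
    """

    read_id: str
    bases: str
    quals: np.ndarray
    candidates: list[CandidateLocation]

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError(f"{self.read_id}: a multiread needs >=2 candidates")
        keys = [c.key for c in self.candidates]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.read_id}: duplicate candidate locations")

    @property
    def q(self) -> int:
        return len(self.candidates)

    def oriented(self, candidate: CandidateLocation) -> tuple[str, np.ndarray]:
        """Read bases/quals in genome-forward orientation at this candidate."""
        if candidate.is_reverse:
            return revcomp(self.bases), self.quals[::-1]
        return self.bases, self.quals


@dataclass
class ClassifyResult:
    unique: list[ReadAlignment]
    multireads: list[MultireadRecord]
    n_unmapped: int

    @property
    def n_reads(self) -> int:
        return len(self.unique) + len(self.multireads) + self.n_unmapped


def _strand_of(rec: pysam.AlignedSegment) -> str:
    if rec.has_tag("XG"):
        return normalize_strand(rec.get_tag("XG"))
    if rec.has_tag("YS"):
        return normalize_strand(rec.get_tag("YS"))
    return "OB" if rec.is_reverse else "OT"


def classify_reads(
    path,
    reference: ReferenceGenome | None = None,
    default_phred: int = 30,
) -> ClassifyResult:
    """Group SAM/BAM records by read id into unique reads and multireads.

    Candidates sharing a (contig, start, strand) triple are deduplicated; a
    read left with a single candidate is unique. Unmapped reads are counted
    and dropped. Reads without stored qualities get a uniform ``default_phred``.
    """
    groups: dict[str, dict] = {}
    unmapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                unmapped.add(rec.query_name)
                continue
            if rec.is_supplementary:
                continue
            strand = _strand_of(rec)
            cand = CandidateLocation(
                contig=rec.reference_name,
                start=rec.reference_start,
                strand=strand,
                is_reverse=rec.is_reverse,
                cigar=_cigar_from_pysam(rec.cigartuples),
            )
            if reference is not None:
                clen = reference.lengths.get(cand.contig)
                if clen is None:
                    raise ValueError(f"contig {cand.contig} absent from reference")
                if cand.ref_span()[1] > clen:
                    raise ValueError(
                        f"{rec.query_name}: alignment exceeds contig {cand.contig} bounds"
                    )
            g = groups.setdefault(rec.query_name, {"cands": [], "seq": None})
            g["cands"].append(cand)
            if rec.query_sequence and g["seq"] is None:
                seq = rec.query_sequence.upper()
                quals = rec.query_qualities
                if quals is None:
                    quals = np.full(len(seq), default_phred, dtype=int)
                else:
                    quals = np.asarray(quals, dtype=int)
                # store in sequenced orientation
                if rec.is_reverse:
                    seq, quals = revcomp(seq), quals[::-1]
                g["seq"] = (seq, quals)

    unmapped -= set(groups)  # a read id both mapped and unmapped counts as mapped
    unique: list[ReadAlignment] = []
    multireads: list[MultireadRecord] = []
    for read_id in sorted(groups):
        g = groups[read_id]
        if g["seq"] is None:
            raise ValueError(f"{read_id}: no alignment record carries the read sequence")
        seq, quals = g["seq"]
        dedup: dict[tuple, CandidateLocation] = {}
        for cand in g["cands"]:
            dedup.setdefault(cand.key, cand)
        cands = sorted(dedup.values(), key=lambda c: c.key)
        if len(cands) == 1:
            cand = cands[0]
            fwd_seq, fwd_quals = (revcomp(seq), quals[::-1]) if cand.is_reverse else (seq, quals)
            unique.append(
                ReadAlignment(
                    read_id=read_id,
                    contig=cand.contig,
                    start=cand.start,
                    strand=cand.strand,
                    is_reverse=cand.is_reverse,
                    bases=fwd_seq,
                    quals=fwd_quals,
                    cigar=cand.cigar,
                )
            )
        else:
            multireads.append(
                MultireadRecord(read_id=read_id, bases=seq, quals=quals, candidates=cands)
            )
    return ClassifyResult(unique=unique, multireads=multireads, n_unmapped=len(unmapped))


# ---------------------------------------------------------------------------
# unique-read index


class UniqueReadIndex:
    """Interval-indexed store of unique reads with per-contig coverage."""

    def __init__(self, contig_lengths: dict[str, int]):
        self.contig_lengths = dict(contig_lengths)
        self.trees: dict[str, IntervalTree] = {c: IntervalTree() for c in contig_lengths}
        self.coverage: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.int32) for c, n in contig_lengths.items()
        }
        self.n_reads = 0

    def add(self, read: ReadAlignment) -> None:
        start, end = read.ref_span()
        clen = self.contig_lengths.get(read.contig)
        if clen is None:
            raise ValueError(f"contig {read.contig} not in index")
        if end > clen or start < 0:
            raise ValueError(f"{read.read_id}: span [{start},{end}) outside contig")
        self.trees[read.contig][start:end] = read
        cov = self.coverage[read.contig]
        pos = read.start
        for op, n in read.cigar:
            if op == "M":
                cov[pos : pos + n] += 1
                pos += n
            elif op == "D":
                pos += n
        self.n_reads += 1

    def overlapping(self, contig: str, start: int, end: int) -> list[ReadAlignment]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def coverage_at(self, contig: str, pos: int) -> int:
        return int(self.coverage[contig][pos])


def build_unique_index(
    unique_reads: Iterable[ReadAlignment], reference: ReferenceGenome
) -> UniqueReadIndex:
    index = UniqueReadIndex(reference.lengths)
    for read in unique_reads:
        index.add(read)
    return index


# ---------------------------------------------------------------------------
# output


def sam_header(reference: ReferenceGenome, extra_pg: bool = True) -> pysam.AlignmentHeader:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference.lengths.items()],
    }
    if extra_pg:
        header["PG"] = [{"ID": "emmul", "PN": "emmul", "VN": "0.1.0"}]
    return pysam.AlignmentHeader.from_dict(header)


def write_resolved(
    assignments: Sequence,
    multireads: Sequence[MultireadRecord],
    reference: ReferenceGenome,
    out_path,
    report_path,
) -> None:
    """Write one primary record per resolved multiread plus the TSV report.

    ``assignments`` entries must expose read_id, contig, start, strand, stage,
    candidate_index, s_max, s_nextmax, margin (see :class:`emmul.smoothness.Assignment`).
    """
    by_id = {m.read_id: m for m in multireads}
    header = sam_header(reference)
    mode = "wb" if str(out_path).endswith(".bam") else "wh"
    rows = []
    assigned_ids = set()
    with pysam.AlignmentFile(str(out_path), mode, header=header) as out:
        for a in assignments:
            m = by_id.get(a.read_id)
            if m is None:
                raise ValueError(f"assignment for unknown read {a.read_id}")
            cand = m.candidates[a.candidate_index]
            if (cand.contig, cand.start, cand.strand) != (a.contig, a.start, a.strand):
                raise ValueError(f"{a.read_id}: assignment does not match a candidate")
            seq, quals = m.oriented(cand)
            rec = pysam.AlignedSegment(header)
            rec.query_name = m.read_id
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in quals)
            )
            rec.reference_id = list(reference.sequences).index(cand.contig)
            rec.reference_start = cand.start
            rec.cigarstring = "".join(f"{n}{op}" for op, n in cand.cigar)
            rec.flag = 16 if cand.is_reverse else 0
            rec.mapping_quality = 40
            rec.set_tag("XG", "CT" if cand.strand == "OT" else "GA")
            rec.set_tag("ZS", a.stage)
            out.write(rec)
            assigned_ids.add(a.read_id)
            rows.append(
                (a.read_id, a.contig, a.start, a.strand, _fmt(a.s_max), _fmt(a.s_nextmax),
                 _fmt(a.margin), a.stage)
            )
    for m in multireads:
        if m.read_id not in assigned_ids:
            rows.append((m.read_id, "", "", "", "", "", "", "unresolved"))
    with open(report_path, "w") as fh:
        fh.write("read_id\tcontig\tstart\tstrand\ts_max\ts_nextmax\tmargin\tstage\n")
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}"
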