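# Methods

## Model

A bisulfite multiread *M* (length *K*, *Q* ≥ 2 candidate positions, all taken
from the aligner's primary plus secondary records for one read id) is assigned
in two stages.

### Stage 1 — weighted base-level score with a margin rule

Each candidate *j* gets

S_j = Σ_k (S_{M_k G_s} + S_{M_k U_t}) / 2,

the equal-weight combination of a reference term and a unique-read term,
summed over the M-aligned bases of the candidate's CIGAR (soft-clipped bases
are excluded; each inserted or deleted base adds the gap score, −25 by
default, to both halves).

**Substitution matrix.** The strand-aware 5×5 matrix over {A,C,G,T,N}
(rows = reference, columns = read) for the original-top (OT) strand is

|   | A | C | G | T | N |
|---|---|---|---|---|---|
| A | 6 | −18 | −18 | −18 | −25 |
| C | −18 | 6 | −18 | **3** | −25 |
| G | −18 | −18 | 6 | −18 | −25 |
| T | −18 | −18 | −18 | **3** | −25 |
| N | −25 | −25 | −25 | −25 | 25 |

Reference C / read T scores +3 because a converted unmethylated cytosine reads
as T; the T/T match also scores 3 rather than 6 because a read T is ambiguous
evidence (it may be a genomic T or a converted C). The original-bottom (OB)
strand matrix is the base-complement mirror, so reference G / read A is the
tolerated pair. Candidates labelled CTOT/CTOB by the upstream aligner are
mapped onto these two genome-forward classes (Bismark's XG:Z:CT / XG:Z:GA).
S[G_s] is the matrix row total over the four standard read bases.

**Observation model.** P(M_k | G_s) combines a per-site SNP probability
(default 0.001, split uniformly over the three substitutions — no per-mutation
rates are assumed) with context-specific methylation priors: for a reference C
on OT (or G on OB) in CpG context, P(C|C) = (1−snp)·m_CpG and
P(T|C) = snp/3 + (1−snp)·(1−m_CpG); CH contexts use m_CH. Defaults
m_CpG = 0.7, m_CH = 0.005. Context is recomputed from the reference per
candidate locus (C followed by G → CpG; the bottom-strand mirror uses the
preceding base). Rows are renormalised to sum to 1; any pairing involving N
gets probability 1/4. The reference term is then

S_{M_k G_s} = P·Score + (1−P)·(S[G_s] − Score).

**Unique-read term.** For each of the *n* unique reads overlapping the
candidate span (≥1 bp reference-span intersection) that has a base aligned to
the same reference locus as M_k (resolved through both CIGARs; deletions
contribute nothing), the analogous weighted score is computed with weight
P(M_k → U_lt): the probability that neither base carries a sequencing error,
1 − (ε_lt + ε_k − ε_lt·ε_k) when the bases agree and its complement when they
differ, with ε = 10^(−Q/10) from Phred scores, floored at 10⁻⁴ (records
without stored qualities get a uniform configurable Phred, default 30). The
per-read results are averaged over the stack. Where no unique base covers a
locus, S_{M_k U_t} := S_{M_k G_s}. An alternative
(`agreement_mode="literal"`) swaps the two branches, assigning near-zero
weight to agreeing error-free bases; the default (`"corrected"`) is the
orientation consistent with the weight's meaning as a no-error probability.

**Margin rule.** The argmax candidate is accepted iff
S_max − S_nextmax > σ; ties and sub-threshold margins defer the read. σ
defaults to 0.02·K·6 (2% of the maximal attainable score of a K-bp read), so
the threshold scales with read length; it is configurable (`--sigma`).

### Stage 2 — coverage smoothness

Deferred reads are placed under the assumption that total coverage should be
locally uniform. For each candidate, the loss is the population variance of
coverage within a window (default WinLen = 200 bp, configurable) centred on
the candidate span, with the hypothetical placement added; windows truncate at
contig edges and the mean is recomputed over the truncated length. The
coverage state starts from unique reads plus stage-1 assignments and is
updated after every placement. Reads are processed least-ambiguous first
(ascending Q, then read id), which makes the procedure deterministic;
pairwise elimination over candidate pairs reduces to the global argmin of the
per-candidate loss, which is what is computed. Ties go to the lowest
(contig, start). Stage 2 always assigns, so "unresolved" occurs only for
degenerate inputs.

The method is a single-pass score-then-smooth procedure; no
expectation–maximisation iteration or re-estimation of the methylation priors
takes place.

## Synthetic data generator

The simulator emulates a WGBS experiment over a small genome so the resolver
can be benchmarked with exact truth labels and no external aligner:

- **Genome**: uniform random ACGT background (default 100 kb) with repeat
  families — one random unit copied at disjoint, evenly spaced positions, each
  copy independently substituted at the divergence rate (default four families
  of 500 bp at 2% divergence with 2, 5, 10 and 15 copies). A BED records every
  copy.
- **Donor haplotype**: SNPs injected at rate 0.001 (uniform substitutions).
- **Methylome**: every cytosine on both strands drawn independently —
  P(methylated) = 0.7 in CpG context, 0.005 in CH context. Strand symmetry is
  deliberately not imposed.
- **Reads**: single-end 100 bp, sampled uniformly from both strands to 20X
  (N = depth·L/K). Unmethylated cytosines on the sampled strand convert with
  efficiency 1.0 by default; sequencing errors are uniform at rate 0.01 with a
  constant Phred quality matching that rate (so ε in the scoring model equals
  the simulated error probability).
- **Candidates**: each read is reported at its true location plus every
  homologous offset in the other copies of its repeat family whose
  bisulfite-space Hamming distance (read T matches reference C on OT, read A
  matches reference G on OB) is within a band (default 8) of the best
  candidate; the true location is always reported. The band emulates an
  aligner configured to report all plausible ambiguous hits, which is what
  populates the higher ambiguity strata. Reads with one candidate are the
  unique reads; the SAM stores SEQ/QUAL on the primary (minimum-distance)
  record only, as aligners do.

Default parameter values are the study conditions of the benchmark; the
defaults above (window length, σ scaling, candidate band, repeat family
layout) were fixed once as realistic and are not tuned per dataset.

**What the simulation does not model**: indels and structural variants (reads
are gapless, though the scorer handles I/D CIGARs), paired-end libraries,
quality-score variation along the read, incomplete conversion by default,
chimeric reads, and real repeat-family structure (nested or truncated
elements). Consequently, passing benchmarks here demonstrates the method's
discriminative and uniformising behaviour under controlled ambiguity, not
performance on a real genome.

## Evaluation

recall r = assigned/total multireads; accuracy p = correct/assigned (exact
coordinate-and-strand match by default; a ±bp tolerance flag exists because
real-data validation schemes that shorten unique reads make exact-start
matching ill-defined); F1 = 2pr/(p+r), defined as 0 at p+r=0. PerRight(i)
splits the correctly placed multireads with exactly i candidates between the
method and a random-selection baseline. The baseline randomises over all
candidates (pure random); a second mode restricted to candidates tying the
best score is provided, but pure random is the reported comparator. Accuracy is
reported over both stages combined, with per-stage counts available in the
result.

## Numerical choices and edge cases

- Coordinates 0-based half-open internally; 1-based only at the SAM boundary.
- ε floor 10⁻⁴ prevents degenerate zero error probabilities at high Phred.
- Duplicate candidate triples (contig, start, strand) are deduplicated at
  classification; a read reduced to one candidate is reclassified unique.
- Scores are computed in double precision with a vectorised per-candidate
  gather; identical inputs give bit-identical scores.
- Stage-2 ties (equal losses) resolve to the lowest coordinate, making runs
  reproducible byte-for-byte given a seed.
- Benchmark problem sizes (100 kb genome for the headline run, 30 kb with
  2/4/8-copy families for the five-seed depth and error-rate sweeps) were
  chosen so the full suite runs comfortably on a laptop while keeping every
  ambiguity stratum populated with hundreds of reads.

## Known limitations

- Accuracy on near-identical repeat copies is bounded by the information
  available in a 100 bp window: when two copies agree everywhere within the
  window, only coverage smoothness can separate them, and its expected
  per-read accuracy approaches 1/Q as coverage flattens.
- Mixing strands in the unique-read term adds noise at C/G sites with
  intermediate methylation (an OT unique read legitimately shows T where an
  OB multiread shows C); the tolerant matrix entries soften but do not remove
  this.
- The observation model treats SNPs and methylation as independent of
  position; no local re-estimation is performed.
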