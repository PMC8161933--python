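# emmul

Resolve ambiguously mapped bisulfite-sequencing reads (**multireads**) to a
single best genomic location.

## The problem

Bisulfite treatment converts unmethylated cytosine to uracil (read as T),
which erases much of the sequence complexity of a genome: a read T may match
either a reference T or a converted reference C. As a result a sizeable
fraction of BS-seq reads aligns equally well to several positions — typically
inside repeat families — and is discarded by standard pipelines, wasting
depth and leaving the methylation state of repetitive regions unresolvable.
`emmul` rescues these reads for anyone running WGBS pipelines who wants
methylation calls in repeats: it takes the aligner's output (a SAM/BAM in
which a multiread carries all of its candidate positions) and assigns each
multiread to one location.

## The method

For a multiread *M* of length *K* with candidate positions *j = 1..Q*, every
candidate is scored base by base:

- **Reference term.** For read base *M_k* over reference base *G_s*,

  *S_{M_k G_s} = P(M_k, G_s)·Score(M_k, G_s) + (1 − P(M_k, G_s))·(S[G_s] − Score(M_k, G_s))*

  where *Score* is a bisulfite-aware 5×5 substitution matrix (reference C /
  read T is rewarded on the original-top strand, reference G / read A on the
  original-bottom strand), *S[G_s]* is the row total of the matrix for
  reference base *G_s*, and *P(M_k, G_s)* is the probability of observing
  *M_k* given *G_s* built from the SNP rate and the context-specific
  methylation priors (CpG vs CH).

- **Unique-read term.** For every uniquely mapped read *U_l* overlapping the
  candidate, the same weighted score is computed against the unique-read base
  at the locus, with the weight *P(M_k → U_lt)* equal to the probability that
  neither base carries a sequencing error (from the Phred qualities), and the
  result is averaged over the *n* overlapping unique reads. Loci with no
  unique coverage fall back to the reference term.

- **Decision.** *S_j = Σ_k (S_{M_k G_s} + S_{M_k U_t})/2*. The best candidate
  is accepted when *S_max − S_nextmax > σ*; otherwise the read is deferred to
  a **coverage-smoothness** stage, which places each deferred read at the
  candidate minimising the local coverage variance
  *loss = (1/WinLen)·Σ_i (a[i] − x̄)²* in a window centred on the candidate,
  updating coverage incrementally.

The package also ships a synthetic bisulfite-read simulator (random genome
with engineered repeat families, donor SNPs, per-cytosine methylome on both
strands, bisulfite conversion, sequencing errors, candidate SAM and full truth
labels) and the benchmark statistics: recall, accuracy, F1 and the
per-ambiguity-stratum *PerRight* shares against a random-selection baseline.

## Worked example

```bash
emmul simulate --outdir sim --seed 2
emmul resolve --ref sim/genome.fa --bam sim/candidates.sam \
      --out sim/resolved.sam --report sim/report.tsv --seed 2
emmul evaluate --assignments sim/report.tsv --truth sim/truth.tsv \
      --sam sim/candidates.sam --seed 2 --out sim/metrics.json
```

With the default simulation (100 kb genome, repeat families of 2/5/10/15
copies at 2% divergence, 100 bp reads at 20X, 1% error), this prints on
standard error:

```
reads=20000 multireads=2543 outdir=sim
multireads=2543 stage1=2029 stage2=514 unresolved=0
accuracy=0.6724 recall=1.0000 f1=0.8041
```

i.e. 12.7% of reads are ambiguous; ~80% of those are separated by the score
margin alone and the rest by coverage smoothness; every multiread receives a
location (recall 1.0) and about two thirds land exactly on their true
coordinate — versus ~13% for random selection over candidates (the expected
1/Q rate). `sim/metrics.json` additionally reports the PerRight share per
ambiguity stratum, which grows with the number of candidate positions (the
harder the random guess, the larger the advantage of scoring).

The same run is available without the CLI through `emmul.simulate_dataset`,
`emmul.resolve` and `emmul.evaluate_run`.

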