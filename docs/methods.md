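# Methods

## Scope and model

`codonuse` analyses codon-usage bias in a small corpus of coding
sequences. The statistical object is the codon count table of each gene
(64 non-negative integers summing to length/3) plus the pooled corpus
table; every index is a deterministic function of these counts, so the
whole analysis is reproducible from the FASTA input alone.

## QC rules

A record passes as a CDS when it is in frame (length a positive multiple
of 3), starts with ATG, ends with TAA/TAG/TGA, and contains only A/C/G/T
(U is normalized to T on input; ambiguity codes are rejected outright,
because every downstream formula assumes unambiguous codons). Exact
nucleotide-string duplicates are dropped, first occurrence kept; duplicate
identity is by sequence, not by id. mRNA records with UTRs are handled by
`--cds-only`, which extracts the longest forward-strand ATG..STOP ORF over
frames 0/1/2 and computes indices on it, while GC% and length stay
full-record descriptives (the defensible default for record-level tables;
whether published GC values used record or CDS is generally ambiguous).

## Indices: definitions and numerical choices

**Reference weights / CAI.** w(codon) = count/max-count within each
synonymous family of the reference table; families unused in the
reference have undefined w and their codons are skipped in CAI. Zero-count
codons inside a used family get the pseudo-weight 0.5/max-count — the
standard fix for log(0); it deliberately scales with reference depth
(deeper reference ⇒ stronger evidence a missing codon is truly avoided),
which is why only observed weights are scale-invariant. CAI is the
geometric mean of w over the gene's codon occurrences, computed as
exp(Σ count·ln w / N) to avoid underflow; Met, Trp and STOP occurrences
are excluded by default (single-codon families carry no bias information;
STOP is untranslated) and the exclusion set is configurable. The default
reference is the pooled input corpus — self-contained and reproducible —
with a `--reference` FASTA override. Published CAI values computed against
an unstated external reference are therefore not expected to reproduce
exactly; the contract is CAI ∈ (0,1] with 1 iff every included codon is
family-maximal.

**RSCU.** The default *fraction* convention is the within-family fraction
(family sums 1; threshold 0.5 in two-fold families); the *classical*
convention multiplies by the degeneracy n_i (family sums n_i; neutral
value 1). The two differ codon-wise by exactly n_i.

**RCBS.** Codon proportions f_xyz = count/total and positional base
proportions f_n(m) are both taken from the same gene, making the ratio
dimensionless and scale-free. Codons with count 0 get value 0 (no
occurrence, no bias evidence). The denominator cannot vanish for a counted
codon since its own bases contribute to each position.

**MRCBS.** RCBS divided by the maximum RCBS in the codon's family; ties
all map to 1. Gene-level RCBS and MRCBS scores are geometric means over
codon occurrences, in log space. A plain unrooted product over hundreds
of codons would vanish numerically and could not lie in the (0,1] range
MRCBS scores are interpreted on, so the 1/N root is applied exactly as in
CAI.

**Expression classification.** Mean MRCBS per amino acid is taken over
used codons (count > 0) across all sequences. Structurally-zero rows of
unused codons are excluded: counting them would cap every two-fold family
at 0.5 and make the 0.62 threshold unreachable by construction. The
threshold itself defaults to 0.62 and the comparison is strict (>).

## Downstream statistics

**Sequential ANOVA.** `anova_fixed` computes fit-order (Type I) sums of
squares by explicit least-squares projections, with each factor's DF the
column-rank it adds. This matters because codon identity determines the
amino acid: entered after amino acid, codon adds only 64−21 = 43 DF.
The conventional three-source table (sequences 18, amino acids 20,
codons 63 DF for a 19×64 design) is therefore produced by
`anova_three_source`, which merges two two-way fits — value ~ sequence +
codon supplies the Sequences and Codons rows and the residual, value ~
sequence + amino_acid supplies the Amino acids row, F-tested against that
same residual. F-ratios are reported as NaN on zero-noise data.

**z-screen.** Each codon's value is standardized against the across-codon
mean and sample sd (n−1), with a two-sided normal p-value and a flag at
p < alpha (default 0.05). This is the only construction that can flag
individual codons when each contributes a single summary value; flags are
invariant under affine transformations of the input.

**Normality summary.** Rather than an arbitrary formal test, the package
reports mean, sample sd and the empirical coverage of mean ± 1·sd and
± 2·sd (≈68% / ≈95% for normal data). A constant input is degenerate:
sd 0, coverage 1.

**PCA.** Correlation-matrix PCA (columns standardized) of the per-(sequence,
codon) rows of RSCU, MRCBS and RCBS, restricted to used codons — zero
rows for unused codons are identical across the three indices and would
manufacture correlation. Eigenvalues are returned descending and sum to
the number of columns; proportions are eigenvalue/k (the only
self-consistent definition — component percentages quoted from other
conventions need not agree); each component's largest-magnitude loading
is made positive.

## Synthetic generator

`SyntheticSpec` defaults define the emulated study conditions: 19
sequences of 801–3999 nt with GC% in (33, 45), ATG start, i.i.d. body
(amino acid ~ composition vector, codon ~ per-family preferences, STOP
codons excluded from the body), one terminal STOP drawn from a
configurable STOP-preference vector (default uniform, so the STOP family
is exercised). Amino-acid composition defaults to uniform over the 20
amino acids. When no codon preferences are supplied, a corpus-level
preference vector is Dirichlet-sampled (concentration 20) around an
AT-leaning mean with codon weight 0.35^#GC, which puts the expected
corpus GC near 39% — mid-band, emulating AT-rich plant transcripts. GC
control is by per-sequence rejection sampling (cap 1000 attempts, then an
error naming the conflict), never by distorting preferences, so the
recorded ground truth stays exact. Every draw is ledgered; generation is
deterministic given (seed, index) via numpy SeedSequence spawning, and a
corpus is byte-identical across runs for a fixed seed.

What the generator does *not* emulate: UTRs (ORF-only output; the ORF
extraction path is tested by wrapping a synthetic ORF in fixed dummy
UTRs), phylogenetic correlation between sequences, indels, and
within-gene positional heterogeneity of codon usage. Passing tests on
synthetic corpora therefore certify the index algebra and the pipeline
plumbing, not biological claims about any real gene set.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale inputs chosen as the package's
own verification conditions: 19-sequence corpora for pipeline checks;
50 genes of 300–1200 nt for oracle-equivalence (log-space scores vs
60-digit product-then-root, tolerance 1e-10); 45 genes of 3000–3999 nt
(≥50,000 pooled codons) for preference recovery (MAE < 0.02, the
multinomial rate); a 10,000-codon positionally-independent gene for RCBS
convergence. For that last check the per-codon tolerance is aggregate:
each codon's count is ~156 ± 12 at n = 10,000, so the *maximum*
|RCBS − 1| over 64 codons sits near 0.2–0.3 even under perfect
independence; the implemented check is mean |RCBS − 1| < 0.1 plus the
gene score within 0.1 of 1, the law-of-large-numbers reading that the
statistic actually supports.

## Limitations

- CAI depends on the reference set; cross-study comparisons require the
  same reference.
- The z-screen treats per-codon summary values as approximately normal;
  it is a screen, not a calibrated test, and no multiple-testing
  correction is applied.
- `anova_three_source` mirrors the conventional merged presentation; the
  two merged fits do not form a single orthogonal decomposition (the
  amino-acid SS overlaps the codon SS), which is why `anova_fixed` with
  rank-aware DF is also exposed.
- Degenerate inputs are handled by degradation, not failure: single-
  sequence corpora skip ANOVA/z-screen, constant index columns skip PCA,
  both logged.
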