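# Methods

This note documents the models, parameters and design choices behind
`rootspec`, what the synthetic generators do and do not emulate, and the
package's known limitations.

## Specificity index and screening

The index operates on replicate-aggregated, tissue-level TPM:

    tau = sum_i (1 - x̂_i) / (N - 1),   x̂_i = log10(x_i + 1) / log10(xmax + 1).

Properties relied on throughout: 0 ≤ x̂_i ≤ 1 whenever xmax > 0, hence
τ ∈ [0, 1]; τ is invariant under tissue permutation; lowering a non-maximal
tissue value never decreases τ. Because the normalization is logarithmic, τ
is *not* invariant to rescaling all tissue values — TPM must be used on its
natural scale. The classic linear-scale index (x̂_i = x_i/xmax) is provided
as `classic_tau` for comparison only.

Degenerate inputs: an all-zero gene has log10(xmax+1) = 0 and τ is returned
as NaN (the gene can never be called specific). The same applies when xmax
is so small that log10(xmax+1) underflows to zero in double precision. Ties
for the maximum set xsec = xmax, which fails every screening rule, and the
reported maximal tissue is the lexicographically first of the tied tissues —
a gene maximally expressed in two tissues is not tissue-specific.

Screening thresholds (τ > 0.85; rule 1: 2 < xmax ≤ 20 with xmax/xsec ≥ 4;
rule 2: xmax > 20 with xmax/xsec ≥ 10; rule 3: xsec = 0 with xmax ≥ 1) are
compared exactly as printed, in double precision, with no epsilon slack.
Ratios use raw aggregated TPM — the logarithm appears only inside x̂.
Profiles with 0 < xmax ≤ 2 and xsec ≠ 0 satisfy no rule and fail screening;
this gap is deliberate, not an oversight. All constants live in
`ScreeningThresholds` and are configurable.

Replicates are aggregated by the mean by default (median available). The
mean keeps τ deterministic and matches common practice; for tissues with
2–3 replicates the median would discard most of the information.

## Orthogroup intersection

`conserved_specific` requires, for each focal-species specific gene, at
least one specific orthogroup co-member in *every* required species ("any
witness" semantics). Genes absent from every orthogroup are dropped with a
logged count: without homology evidence, conservation is undecidable. The
operation is antitone in each specific set (shrinking any input set can
only shrink the result), which the tests verify against exhaustive
enumeration over all (gene, orthogroup, species) triples.

## Promoter definition

A promoter is the requested number of base pairs immediately 5' of the
translation start — the first base of the first CDS of the representative
transcript (the one with the largest summed CDS length; annotations rarely
flag a canonical transcript, and the longest CDS is a stable deterministic
choice). Genes without any CDS fall back to the transcript 5' end with a
warning. GFF3 1-based inclusive coordinates are converted to 0-based
half-open internally. Promoters are truncated, never padded, at contig
boundaries; Ns are preserved and never matched by the scanner. Overlap with
upstream genes is not trimmed. Default lengths follow the species
convention used in the analyses this package supports: 3 000 bp for rice
and maize, 2 500 bp for Arabidopsis.

## Motif discovery

The enumerative stage counts *genes* containing a k-mer (either strand, a
k-mer and its reverse complement collapsed to the lexicographically smaller
representative), not occurrences — this matches the gene-level frequency
statistic and is robust to tandem repeats. Significance is the one-sided
hypergeometric tail: drawing the foreground genes from the pooled
foreground+background gene universe, with genes containing the k-mer as
successes (equivalent to a one-sided Fisher exact test on the 2×2 table).
Benjamini–Hochberg correction is applied within each k, not pooled across
k, because the candidate universes differ by orders of magnitude between
k = 6 and k = 9. Ranking is by ascending p, then descending foreground
fraction, then lexicographic k-mer — fully deterministic.

"Sequence continuity truncation" of reported motifs is implemented as
exhaustive substring extraction: ambiguous IUPAC positions break a
consensus into unambiguous A/C/G/T runs, and every contiguous substring of
length 6–9 becomes a candidate core (this reproduces nested core families
such as AGCTAGC / AGCTAGCT / AGCTAGCTA). Cores are deduplicated and
canonicalized identically to the enumerator. The cross-tool consensus keeps
cores reported by ≥ 2 distinct tools (background runs of one tool count
once); per tool, a core is classed `**` when recovered under both the
embryo and endosperm backgrounds, `*` under exactly one, `NA` under
neither, and the core's overall class is the strongest per-tool class. A
separate flag records recovery by background-free tools.

MEME-minimal parsing renders each PWM column as its highest-probability
base when that probability is ≥ 0.6, otherwise as the IUPAC ambiguity code
of all bases with probability ≥ 0.25; PWM rows must sum to 1 within 1e-3.

## Scanning and the frequency statistic

Scanning is exact overlapping string matching. Both strands are searched by
default (the reverse strand by matching the reverse complement of the motif
against the stored sequence); palindromic motifs are reported once, on the
plus strand, so a site is never double-counted. A `forward`-only mode
preserves the alternative reading for single-strand analyses.

Frequency of occurrence is presence/absence: 100 × (genes with ≥ 1 site) /
(genes in set). Genes in a set that lack a promoter record stay in the
denominator (logged) — silently shrinking the denominator would inflate the
statistic. The optional two-set comparison uses a one-sided Fisher exact
test per motif with BH correction across motifs; the method itself
prescribes no test, so this is offered as a reasonable default rather than
a canonical choice.

Positional profiles place each site at the offset of its 3'-most base
counted backwards from the ATG (a site abutting the ATG sits at −1, in the
bin [−bin, 0)), which makes profiles comparable across promoters of unequal
(truncated) length.

## Synthetic generators

All generators consume one explicit integer seed and emit truth tables
sufficient to compute exact sensitivity and specificity downstream.

*Expression*: 13 tissues (root, shoot, leaf, tillering bud, stigma, ovary,
pollen, husk, pericarp, SAM, IM, embryo, endosperm), 2 replicates per
tissue by default. Background genes draw a baseline TPM from a log-normal
(ln-mean log 5, ln-sd 1.0 — median ≈ 5 TPM with a realistic heavy tail),
multiplied by per-tissue log-normal wobble (ln-sd 0.4) and per-replicate
log-normal noise (ln-sd 0.2). Planted rule-2 genes draw their target-tissue
mean from U(30, 100) and constant off-target leak from U(0, 0.3): the ratio
bound (≥ 100 in expectation) and τ > 0.9 then hold analytically even in the
worst corner of the leak law, leaving margin for replicate noise on the
target tissue. Planted rule-3 genes have exactly zero leak (τ = 1 by
construction); zeros survive the multiplicative noise exactly. Leaks are
held constant across replicates — they model residual background, not
signal. What this generator does **not** emulate: count noise at low TPM,
correlated tissues (e.g. embryo/endosperm co-expression), batch effects,
or compositional coupling between genes; passing recovery tests therefore
demonstrates the screening logic, not robustness to those artefacts.

*Promoters*: i.i.d. base composition (uniform by default) or an optional
first-order Markov chain; default 1 kb sequences, 200 foreground + 200
background. Planted cores are inserted by overwriting at a drawn position
(uniform or 3'-biased via a Beta(3,1) position law) on a random strand,
never overlapping a previous insertion, so sequence lengths are exact.
Foreground/background insertion probabilities default to 0.6 / 0.05. Real
promoters are not i.i.d. — CpG/ATA composition bias, repeats and TATA
elements all violate this — so enrichment results on synthetic data
validate the statistics, not genomic base-rate behaviour.

*Orthogroups*: a chosen fraction of orthogroups receive one tissue-specific
gene per species; the remainder receive filler genes, with leftover
specific genes spread at most one species per orthogroup so that no
non-conserved orthogroup can accidentally satisfy the conservation
predicate. Truth counts are therefore exact.

## Problem sizes

The bundled verification runs use: 10 000 random profiles for the
screening-rule oracle; a 2 100-gene, 13-tissue matrix (100 planted root
genes) for recovery; 50–100 orthogroups for conservation; 200 random
1–10 kb sequences for scanner equivalence; 200 + 200 promoters of 1 kb for
discovery and 300 + 300 for the frequency statistic. These sizes give exact
or overwhelming statistical resolution for every assertion while keeping a
full run on one CPU around a minute.

## Known limitations

- τ on very small TPM values is sensitive to the +1 pseudocount; values
  ≪ 1 compress toward x̂ ≈ 0 and can make τ large while the screening rules
  (by design) reject such genes via the xmax gap.
- The built-in enumerative discovery finds exact, unambiguous cores only;
  degenerate motifs are recovered only through their unambiguous substrings
  or via external tool reports.
- Orthogroup granularity is taken as given; no within-orthogroup tree
  resolution is attempted.
- The promoter definition is annotation-driven (CDS start); TSS-seq/CAGE
  evidence is out of scope.
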