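# Methods

## Scope and coordinate conventions

`pairsplice` detects alternative splicing (AS) without a reference genome
by gapped pairwise alignment of a gene's de novo assembled isoforms. The
pipeline starts from assembled transcripts (the assembler's cluster/isoform
naming is the gene grouping, here `<gene>_i<k>`; `<gene>_as<k>` marks
labelled antisense transcripts) and ends at event tables, ORF/domain
impacts, enrichment statistics, and expression summaries. All coordinates
are 0-based half-open on both genomic and transcript axes, everywhere in
the package. Only the sense strand is considered: the method presumes a
strand-specific library, which is what makes AS distinguishable from
natural antisense transcription in the first place.

## Pairwise alignment model

The aligner is a deliberate, dependency-free re-statement of what a
cDNA-vs-cDNA BLAT comparison provides, with the published thresholds as
contracts: seeds are exact shared k-mers (tile size 18, zero seed
mismatches; `N` never matches), seeds on one diagonal are merged and
extended into maximal exact blocks, and blocks are chained by dynamic
programming maximizing (matched bases − 4 per gap opened). Ties go to the
chain whose first block starts leftmost on the query — a declared
tie-break, not a claim of BLAT equivalence. Between consecutive blocks,
equal advances on both sequences are treated as substitution columns;
the remainder is an indel carried by one transcript. Identity is computed
over aligned columns only (gaps excluded); chains under 96% identity or
with any gap above 10,000 nt are discarded. Terminal overhangs have only
one flanking block and never become AS candidates.

The chaining DP is checked against an exhaustive best-chain search on
instances with up to 12 blocks, and identity against an independent
recount of matches along the reported blocks.

## Event calling and classification

An internal indel whose two flanking blocks are each ≥ 18 nt is a
candidate alternative region; candidates shorter than 12 nt are dropped
(indistinguishable from alignment noise — the minimum is configurable).
Classification uses only the region's terminal 2-mers, in a declared rule
order (IR > AltD > AltA > ES): a canonical pair (GT-AG, GC-AG, AT-AC) is
intron retention; otherwise a donor-like 5' 2-mer (GT/GC/AT) is an
alternative donor; otherwise an acceptor-like 3' 2-mer (AG/AC) is an
alternative acceptor; a region with no splice signal at either end is an
exon skip (its real splice signals sit in the flanking introns, which a
cDNA never contains). The full decision table is isolated in one function;
a strict mode withholds the last bucket as `unclassified` instead.

Deduplication happens at two levels. Candidates from different pairs of
one gene merge when they share carrier transcript, type, and boundaries
within ±3 nt (`supporting_pairs` accumulates). Additionally — because a
skipped exon is present in, and therefore reported on, every isoform that
retains it — events of one gene with identical type and identical region
sequence on different carriers collapse to one event on the
lexicographically first carrier. Without this second merge, multi-event
genes would systematically inflate exon-skipping counts. Event
coordinates are reported on the carrier (longer) transcript.

## ORF, frame, and domain impact

Each transcript's single longest ATG-to-stop ORF over the three sense
frames is used (ties to the 5'-most start; minimum 30 encoded amino
acids). An event is 5' UTR, CDS, 3' UTR, or spanning relative to that ORF;
a CDS-overlapping region preserves the reading frame iff its length is a
multiple of three. The CDS overlap maps to amino acids by flooring the
start and ceiling the end codon index; a domain is "affected" by any
overlap of at least one amino acid (no minimum-overlap threshold).
Domains downstream of a frame shift are *not* counted as affected — only
directly overlapped intervals are, a conservative documented choice.
Domain annotations are read from the standard hmmscan per-domain tabular
layout using envelope coordinates (converted from 1-based inclusive).

## Enrichment statistics

Domain over-occurrence in AS genes uses a two-sided Fisher exact test by
the minimum-likelihood convention, computed by exact enumeration of the
hypergeometric support (log-space pmf, no asymptotic approximation), on
gene-level presence/absence counts over genes that carry at least one
domain. A domain is flagged when p < 0.01 **and** its AS-gene proportion
exceeds its constitutive proportion: the direction filter is applied after
the two-sided test so p-values stay comparable with mainstream tools. GO
enrichment is the upper-tail hypergeometric probability P(X ≥ k) per term
against the whole background, Benjamini–Hochberg corrected (step-up,
`p_adj(i) = min_{j≥i} m·p(j)/j`, capped at 1), flagged at p_adj < 0.05.
Annotations are taken as given — no GO-graph ancestor propagation.

## Expression summary

RPKM is the exact formula `1e9·C/(N·L)` with no pseudocount; group
distributions are summarized on the log2(RPKM + 1) scale (the +1 offset is
a declared choice). RPKM is computed per transcript; gene-level use should
aggregate counts upstream. Read mapping itself is out of scope — counts
arrive as a TSV contract.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
so every stage is testable without external data:

* **Gene models** — 4–8 exons of 80–300 nt, introns 80–400 nt, GC content
  0.45, sense strand only. Each intron's terminal dinucleotides are drawn
  from the canonical pairs at 92/7/1% (GT-AG/GC-AG/AT-AC).
* **Events** — 30% of genes carry ≥ 1 planted event (constitutive genes
  get a single isoform); 32% of AS genes carry two events, placed on
  non-adjacent features so regions never overlap. Multi-event genes are
  drawn with ≥ 6 exons, which is the minimum capacity for two non-adjacent
  events — without this the configured multi-event fraction would be
  under-realized. Event types follow the configured mix, whose default is
  the exact ratio (1776, 1435, 1169, 1028)/5408 ≈ 33/27/22/19%.
* **Region lengths** — shifted geometric (minimum 12 nt) with mean 91 nt.
  Only the mean and a log-scale histogram of the underlying distribution
  are known; the geometric family is a declared choice for a
  heavy-right-tailed length law.
* **Recoverability by construction** — the region's first base differs
  from the base following its insertion point and its last base from the
  base preceding it, removing indel-placement ambiguity, so planted
  coordinates are exact. Region terminal 2-mers are constrained to
  classify as the planted type. Two deviation classes can be planted
  deliberately (`p_multi_skip`: adjacent double exon skips recorded as two
  truth events; `p_altpos_canonical`: alt-donor/acceptor regions whose
  ends form a canonical pair and are therefore read as intron retention);
  both default to 0 since their real-world rates are undocumented.
* **ORFs and domains** — exonic sequence is rewritten so the constitutive
  transcript carries a long planted ORF (event-critical bases are never
  touched); domain intervals (15–60 aa, 40-entry vocabulary) are planted
  inside each isoform's realized longest ORF and written in hmmscan
  per-domain layout.
* **Expression** — independent negative-binomial counts per transcript
  with per-kilobase mean 50 and dispersion 2; AS-gene isoforms at 2× the
  base mean and antisense transcripts (5% of genes) at 0.25×, matching the
  direction (not a published magnitude) of the observed abundance
  differences. Dispersion above 1e6 switches to the Poisson limit.
* **GO terms** — 1–5 random terms per gene from a 30-term vocabulary, with
  one term planted at elevated probability in AS genes so enrichment
  output is non-trivial.

What the generator does **not** emulate: assembly artifacts (chimeras,
fragmented or redundant isoforms), sequencing error, unequal isoform
support, paralog cross-clustering, non-canonical splice sites, overlapping
events, and genes whose isoform count exceeds one per event. Passing the
recovery tests therefore demonstrates correctness of the detection logic
on clean input, not robustness to assembler noise.

## Validation (concordance) logic

Detected events are compared against the generator's truth, which plays
the role a cDNA-to-genome alignment plays when a genome exists: each truth
event carries its projection onto every isoform containing the region. A
detected event "overlaps completely" when its carrier interval matches a
projection within ±3 nt (the same tolerance as dedup, for internal
consistency) and types agree. A detected exon skip spanning ≥ 2 adjacent
truth skips is `merged_multi_skip`; a detected intron retention matching
an alt-position truth region with canonical ends is `altpos_as_ir`;
everything else detected is spurious, and unrecovered truth is missed.
The four detected buckets always partition the detected set (asserted on
every run).

## Problem sizes and numerical choices

The test suite exercises recovery at 60–500 genes and the acceptance
script at 200 (sensitivity/overlap) and 2,000 genes (type mix, lengths,
gene-level fractions) — sizes at which the multinomial noise on a
percentage is ≈ 1–3 points, chosen so stochastic summaries are stable
while whole runs complete in seconds. Fisher p-values are validated
against exact integer enumeration for all 2×2 tables with total ≤ 40;
hypergeometric tails against exact rational sums; BH against the direct
step-up formula and an independent statistics library. Floating-point
pmf comparisons in the Fisher sum use a 1e-7 relative guard, the
convention of mainstream implementations. Degenerate inputs: empty event
sets summarize to zeros (not an error); a zero-margin 2×2 table is an
undefined test (error); single-isoform clusters are constitutive by
definition and never aligned.

## Known limitations

* Exon skipping is inferred purely from the absence of splice signals at
  the region ends; a genuine skipped exon that happens to start or end
  with a splice-like dinucleotide will be misclassified (alt-donor/
  acceptor or intron retention) — the transcript-only analogue of the
  deviation classes quantified in the concordance report.
* Gene clustering is taken from the assembler's naming; mis-clustered
  paralogs would produce low-identity chains that are silently discarded.
* PSI-style quantification of isoform ratios is out of scope; events are
  presence-only, with `supporting_pairs` as the only evidence weight.
* The enrichment module treats annotations as flat sets; GO hierarchy
  effects are not modelled.
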