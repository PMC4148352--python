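# pairsplice

Genome-free detection and characterization of alternative splicing (AS)
from de novo assembled transcripts.

## The problem

For most non-model organisms there is no reference genome, so AS cannot be
found by the usual cDNA-to-genome alignment. When a strand-specific
RNA-Seq library is assembled de novo, however, the assembler already
groups transcripts into genes, and the isoforms of one gene can be
compared **directly against each other**: a gapped pairwise alignment of
two isoforms shows the alternative region as an indel flanked by two
matching blocks. `pairsplice` implements this *cDNA pair-gapped alignment*
strategy as a tested, reproducible pipeline for transcriptome studies of
species such as the medicinal plant *Digitalis purpurea*.

## Method

1. **Pairwise gapped alignment** (`pair_align`) — every unordered isoform
   pair of a gene cluster is aligned with a seed–chain–extend algorithm:
   exact shared 18-mers, maximal exact blocks, highest-scoring collinear
   chain. Chains below 96% identity or with a gap over 10,000 nt are
   discarded.
2. **Event calling** (`as_caller`) — an indel flanked by matched blocks is
   a candidate alternative region. Its terminal dinucleotides classify it
   against the canonical splice pairs GT-AG / GC-AG / AT-AC:
   both ends canonical → intron retention (IR); 5' end a donor signal →
   alternative donor (AltD); 3' end an acceptor signal → alternative
   acceptor (AltA); neither → exon skipping (ES, whose splice signals live
   in the flanking introns and are invisible in cDNA). Candidates found in
   several pairs are deduplicated (±3 nt).
3. **ORF and protein-domain impact** (`orf_domain`) — the longest
   ATG-to-stop ORF of the carrier transcript locates each event
   (5' UTR / CDS / 3' UTR); an AS region of length `L` preserves the
   reading frame iff `L mod 3 == 0`. CDS footprints are mapped to amino
   acids (`aa = floor((nt − orf_start)/3)`) and intersected with
   hmmscan-style domain annotations.
4. **Enrichment statistics** (`enrichment`) — exact two-sided Fisher tests
   for protein domains over-represented in AS genes (flagged at p < 0.01
   with an AS-direction filter) and upper-tail hypergeometric GO
   enrichment with Benjamini–Hochberg FDR correction (p_adj < 0.05).
5. **Expression summary** (`expression`) — RPKM
   (`1e9·C/(N·L)`) per transcript and log2 distribution comparisons of AS
   genes, all genes, and labelled antisense transcripts.
6. **Synthetic data + validation** (`synthetic_data`, `concordance`) — a
   generator plants multi-exon gene models with canonical splice sites,
   AS events of the four types in configurable proportions, ORFs, domain
   intervals, and negative-binomial counts; detected events are scored
   against this ground truth, including the two documented deviation
   classes (adjacent exon skips merged into one event; alternative-position
   regions with canonical ends misread as intron retention).

## Worked example

```python
from pairsplice import (
    GeneratorConfig, generate_dataset, clusters_from_records,
    AlignParams, CallerOptions,
)
from pairsplice.pipeline import detect_events
from pairsplice.as_caller import summarize_types
from pairsplice.concordance import compare_event_sets

cfg = GeneratorConfig(n_genes=500, seed=42)
models, records, truth = generate_dataset(cfg)
clusters = clusters_from_records(records)
_, events, _ = detect_events(clusters, AlignParams(), CallerOptions())

s = summarize_types(events)
print(f"{s.total_events} AS events in {s.single_event_genes + s.multi_event_genes} genes")
for t, c in s.counts.items():
    print(f"  {t:18s} {c:4d}  ({s.percentages[t]}%)")
print(f"mean region length: {s.mean_region_length:.1f} nt")
rep = compare_event_sets(events, truth)
print(f"recovered {rep.complete_overlap}/{rep.n_truth} planted events "
      f"(missed {rep.missed}, spurious {rep.spurious})")
```

prints

```
203 AS events in 157 genes
  intron_retention     72  (35%)
  exon_skipping        51  (25%)
  alt_donor            49  (24%)
  alt_acceptor         31  (15%)
mean region length: 95.4 nt
recovered 203/203 planted events (missed 0, spurious 0)
```

Every planted event is recovered at exact coordinates with the correct
type on noise-free data; the per-type percentages fluctuate around the
configured mix (default 33/27/22/19% for IR/ES/AltD/AltA) with multinomial
noise at this sample size, and the mean alternative-region length around
the configured 91 nt.

The same pipeline is available from the shell:

```bash
pairsplice simulate --n-genes 200 --seed 42 --outdir data/
pairsplice run --synthetic --n-genes 200 --seed 42 --outdir out/
pairsplice call --fasta data/transcripts.fasta --out events.tsv
pairsplice validate --events events.tsv --truth data/truth_events.tsv --out concordance.tsv
```

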