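"""Calling and classifying alternative-splicing events from pair alignments.

An indel flanked by two matched blocks in a transcript-pair alignment is a
candidate alternative region.  The region's terminal dinucleotides decide
its type against the canonical splice pairs (GT-AG, GC-AG, AT-AC):

1. both ends form a canonical pair            -> intron retention
2. else 5' end is a donor signal (GT/GC/AT)   -> alternative donor site
3. else 3' end is an acceptor signal (AG/AC)  -> alternative acceptor site
4. else                                       -> exon skipping
   (skipped exons carry no splice signal of their own in cDNA)

Strict mode withholds rule-4 regions as ``unclassified`` instead.  The
rule order is isolated in :func:`classify` so it is easy to revise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .errors import ValidationError
from .io import TranscriptCluster
from .pair_align import AlignmentChain, AlignParams, Indel

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
DONOR_SIGNALS = {"GT", "GC", "AT"}
ACCEPTOR_SIGNALS = {"AG", "AC"}

IR = "intron_retention"
ES = "exon_skipping"
ALT_DONOR = "alt_donor"
ALT_ACCEPTOR = "alt_acceptor"
UNCLASSIFIED = "unclassified"
AS_TYPES = (IR, ES, ALT_DONOR, ALT_ACCEPTOR)


@dataclass(frozen=True)
class CallerOptions:
    """Tunables of the event caller.

    min_event_len: indels shorter than this are ignored (alignment noise).
    dedup_tol: boundary tolerance (nt) when merging the same region found
        in several transcript pairs.
    strict: route non-canonical rule-4 regions to ``unclassified`` and
        exclude them from the event set.
    collapse_duplicates: additionally merge events of one gene whose region
        sequences are identical but sit on different carrier isoforms (a
        skipped exon is present in, and thus reported on, every isoform
        that retains it); the event is kept on the lexicographically first
        carrier so gene-level event counts are not inflated.
    """

    min_event_len: int = 12
    dedup_tol: int = 3
    strict: bool = False
    collapse_duplicates: bool = True


@dataclass(frozen=True)
class CandidateRegion:
    """A flanked indel lifted to transcript coordinates, pre-classification."""

    long_tx: str
    short_tx: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ASEvent:
    """A classified, deduplicated alternative-splicing event.

    Coordinates are 0-based half-open on ``long_tx``, the transcript that
    carries the alternative region.
    """

    gene_id: str
    long_tx: str
    short_tx: str
    start: int
    end: int
    as_type: str
    donor2: str
    acceptor2: str
    supporting_pairs: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


def classify(region_seq: str, strict: bool = False) -> str:
    """Type of an alternative region from its terminal 2-mers alone."""
    if len(region_seq) < 4:
        raise ValidationError(
            f"region of length {len(region_seq)} too short to classify (need >= 4 nt)"
        )
    donor2 = region_seq[:2].upper()
    acceptor2 = region_seq[-2:].upper()
    if (donor2, acceptor2) in CANONICAL_PAIRS:
        return IR
    if donor2 in DONOR_SIGNALS:
        return ALT_DONOR
    if acceptor2 in ACCEPTOR_SIGNALS:
        return ALT_ACCEPTOR
    return UNCLASSIFIED if strict else ES


def extract_candidates(
    chain: AlignmentChain,
    params: AlignParams | None = None,
    options: CallerOptions | None = None,
) -> list[CandidateRegion]:
    """Candidate alternative regions from a chain's internal indels.

    Only indels flanked on both sides by blocks of at least
    ``params.min_block`` nt, with length within
    [options.min_event_len, params.max_gap], survive.
    """
    params = params or AlignParams()
    options = options or CallerOptions()
    out = []
    for indel in chain.indels:
        if indel.left_flank_len < params.min_block or indel.right_flank_len < params.min_block:
            continue
        if not (options.min_event_len <= indel.length <= params.max_gap):
            continue
        long_tx = chain.query_id if indel.carrier == "query" else chain.target_id
        short_tx = chain.target_id if indel.carrier == "query" else chain.query_id
        out.append(
            CandidateRegion(
                long_tx=long_tx,
                short_tx=short_tx,
                start=indel.pos_carrier,
                end=indel.pos_carrier + indel.length,
            )
        )
    return out


def call_events(
    chains_by_gene: dict[str, list[AlignmentChain]],
    sequences: dict[str, str],
    params: AlignParams | None = None,
    options: CallerOptions | None = None,
) -> list[ASEvent]:
    """Classify and deduplicate candidates into gene-level AS events.

    Candidates from different pairs of the same gene merge when they sit on
    the same carrier transcript with the same type and boundaries within
    ``options.dedup_tol``; ``supporting_pairs`` counts the merged pairs.
    """
    params = params or AlignParams()
    options = options or CallerOptions()
    events: list[ASEvent] = []
    for gene_id in sorted(chains_by_gene):
        merged: list[ASEvent] = []
        candidates: list[CandidateRegion] = []
        for chain in chains_by_gene[gene_id]:
            candidates.extend(extract_candidates(chain, params, options))
        candidates.sort(key=lambda c: (c.long_tx, c.start, c.end, c.short_tx))
        for cand in candidates:
            if cand.long_tx not in sequences:
                raise ValidationError(f"no sequence for transcript {cand.long_tx}")
            region = sequences[cand.long_tx][cand.start : cand.end]
            as_type = classify(region, strict=options.strict)
            if as_type == UNCLASSIFIED:
                continue
            hit = None
            for ev in merged:
                if (
                    ev.long_tx == cand.long_tx
                    and ev.as_type == as_type
                    and abs(ev.start - cand.start) <= options.dedup_tol
                    and abs(ev.end - cand.end) <= options.dedup_tol
                ):
                    hit = ev
                    break
            if hit is None:
                merged.append(
                    ASEvent(
                        gene_id=gene_id,
                        long_tx=cand.long_tx,
                        short_tx=cand.short_tx,
                        start=cand.start,
                        end=cand.end,
                        as_type=as_type,
                        donor2=region[:2],
                        acceptor2=region[-2:],
                    )
                )
            else:
                hit.supporting_pairs += 1
        if options.collapse_duplicates:
            by_seq: dict[tuple[str, str], ASEvent] = {}
            collapsed: list[ASEvent] = []
            for ev in merged:
                key = (ev.as_type, sequences[ev.long_tx][ev.start : ev.end])
                prior = by_seq.get(key)
                if prior is None:
                    by_seq[key] = ev
                    collapsed.append(ev)
                else:
                    prior.supporting_pairs += ev.supporting_pairs
            merged = collapsed
        events.extend(merged)
    return events


def _pct(count: int, total: int) -> int:
    return int(100.0 * count / total + 0.5) if total else 0


@dataclass
class TypeSummary:
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, int] = field(default_factory=dict)
    total_events: int = 0
    mean_region_length: float = 0.0
    single_event_genes: int = 0
    multi_event_genes: int = 0


def type_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Rounded percentage per type from raw per-type tallies."""
    total = sum(counts.values())
    return {k: _pct(v, total) for k, v in counts.items()}


def summarize_types(events: list[ASEvent]) -> TypeSummary:
    """Per-type counts/percentages, length mean, single- vs multi-event genes."""
    counts = {t: 0 for t in AS_TYPES}
    per_gene: dict[str, int] = defaultdict(int)
    lengths = []
    for ev in events:
        counts[ev.as_type] = counts.get(ev.as_type, 0) + 1
        per_gene[ev.gene_id] += 1
        lengths.append(ev.length)
    total = len(events)
    return TypeSummary(
        counts=counts,
        percentages=type_percentages(counts),
        total_events=total,
        mean_region_length=(sum(lengths) / total) if total else 0.0,
        single_event_genes=sum(1 for n in per_gene.values() if n == 1),
        multi_event_genes=sum(1 for n in per_gene.values() if n > 1),
    )


def events_to_rows(events: list[ASEvent]) -> list[dict]:
    return [
        {
            "gene_id": ev.gene_id,
            "long_tx": ev.long_tx,
            "short_tx": ev.short_tx,
            "start": ev.start,
            "end": ev.end,
            "length": ev.length,
            "as_type": ev.as_type,
            "donor2": ev.donor2,
            "acceptor2": ev.acceptor2,
            "supporting_pairs": ev.supporting_pairs,
        }
        for ev in events
    ]


def write_events_tsv(events: list[ASEvent], path) -> None:
    import pandas as pd

    pd.DataFrame(
        events_to_rows(events),
        columns=[
            "gene_id",
            "long_tx",
            "short_tx",
            "start",
            "end",
            "length",
            "as_type",
            "donor2",
            "acceptor2",
            "supporting_pairs",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_events_bed(events: list[ASEvent], path) -> None:
    """BED6 on carrier-transcript coordinates; score = supporting pairs."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                f"{ev.long_tx}\t{ev.start}\t{ev.end}\t{ev.as_type}\t{ev.supporting_pairs}\t+\n"
            )
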