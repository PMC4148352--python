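"""ORF location, reading-frame effect, and protein-domain impact of events.

Each transcript's longest sense-strand ORF (ATG to stop, three frames) is
translated; an event's transcript interval is intersected with the ORF and
mapped to amino-acid coordinates, then against domain annotation intervals
from an hmmscan-style per-domain table.  An alternative region whose length
is a multiple of three preserves the downstream reading frame; any other
CDS-overlapping region shifts it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .as_caller import ASEvent
from .errors import ParseError, ValidationError

STOP_CODONS = {"TAA", "TAG", "TGA"}

UTR5 = "utr5"
CDS = "cds"
UTR3 = "utr3"
SPANNING = "spanning"
NONCODING = "noncoding_tx"

FRAME_PRESERVED = "preserved"
FRAME_SHIFTED = "shifted"
FRAME_NA = "not_applicable"


@dataclass(frozen=True)
class ORFAnnotation:
    """Longest open reading frame of a transcript.

    ``orf_start``/``orf_end`` are 0-based half-open nt coordinates on the
    transcript and include the stop codon; ``protein`` excludes the stop.
    """

    transcript_id: str
    orf_start: int
    orf_end: int
    protein: str


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain annotation interval, 0-based half-open in aa."""

    protein_id: str
    domain_name: str
    domain_acc: str
    aa_start: int
    aa_end: int
    score: float = 0.0
    evalue: float = 0.0


@dataclass
class EventImpact:
    event: ASEvent
    region_class: str
    frame: str
    protein_interval: tuple[int, int] | None
    affected_domains: list[str] = field(default_factory=list)


def find_longest_orf(
    seq: str, transcript_id: str = "", min_codons: int = 30
) -> ORFAnnotation | None:
    """Longest ATG..stop ORF over the three sense frames.

    Ties break toward the 5'-most start.  Returns None when no ORF encodes
    at least ``min_codons`` amino acids.  Reverse-strand frames are never
    searched: the library is strand-specific.
    """
    seq = seq.upper()
    best: tuple[int, int] | None = None  # (start, end) incl. stop
    best_aa = -1
    for frame in range(3):
        open_start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    aa = (pos - open_start) // 3
                    if aa > best_aa or (aa == best_aa and open_start < best[0]):
                        best = (open_start, pos + 3)
                        best_aa = aa
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
    if best is None or best_aa < min_codons:
        return None
    start, end = best
    protein = str(Seq(seq[start:end]).translate())
    assert protein.endswith("*")
    return ORFAnnotation(
        transcript_id=transcript_id, orf_start=start, orf_end=end, protein=protein[:-1]
    )


def region_class(start: int, end: int, orf: ORFAnnotation | None) -> str:
    if orf is None:
        return NONCODING
    if end <= orf.orf_start:
        return UTR5
    if start >= orf.orf_end:
        return UTR3
    if start >= orf.orf_start and end <= orf.orf_end:
        return CDS
    return SPANNING


def frame_status(event: ASEvent, orf: ORFAnnotation | None) -> str:
    """Frame effect of an event: preserved/shifted when it overlaps the CDS."""
    if orf is None:
        return FRAME_NA
    overlap = min(event.end, orf.orf_end) - max(event.start, orf.orf_start)
    if overlap <= 0:
        return FRAME_NA
    return FRAME_PRESERVED if event.length % 3 == 0 else FRAME_SHIFTED


def nt_to_aa_interval(start: int, end: int, orf: ORFAnnotation) -> tuple[int, int] | None:
    """Map a transcript nt interval to the aa interval it touches.

    The overlap with the ORF is floored at the start codon index and
    ceiled at the end; None when the interval misses the ORF.
    """
    ov_s = max(start, orf.orf_start)
    ov_e = min(end, orf.orf_end)
    if ov_e <= ov_s:
        return None
    aa_s = (ov_s - orf.orf_start) // 3
    aa_e = math.ceil((ov_e - orf.orf_start) / 3)
    return aa_s, min(aa_e, len(orf.protein) + 1)


def event_domain_impact(
    event: ASEvent,
    orf: ORFAnnotation | None,
    domain_hits: list[DomainHit],
) -> EventImpact:
    """Intersect an event's protein footprint with domain intervals.

    ``domain_hits`` must already be restricted to the event's transcript
    protein.  Any >= 1 aa overlap marks a domain affected.
    """
    cls = region_class(event.start, event.end, orf)
    frame = frame_status(event, orf)
    interval = None
    affected: list[str] = []
    if orf is not None:
        for hit in domain_hits:
            if hit.aa_end > len(orf.protein) or hit.aa_start < 0:
                raise ValidationError(
                    f"domain hit {hit.domain_acc} [{hit.aa_start},{hit.aa_end}) "
                    f"outside protein of length {len(orf.protein)} ({hit.protein_id})"
                )
        interval = nt_to_aa_interval(event.start, event.end, orf)
    if interval is not None:
        for hit in domain_hits:
            if hit.aa_start < interval[1] and interval[0] < hit.aa_end:
                affected.append(hit.domain_acc)
    return EventImpact(
        event=event,
        region_class=cls,
        frame=frame,
        protein_interval=interval,
        affected_domains=affected,
    )


def read_domain_table(path) -> list[DomainHit]:
    """Parse an hmmscan per-domain tabular file (``--domtblout`` layout).

    Envelope coordinates (columns 20-21, 1-based inclusive) become 0-based
    half-open.  Comment lines starting with '#' are skipped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ParseError(f"line {lineno}: expected >= 22 columns, got {len(fields)}")
            try:
                env_from = int(fields[19])
                env_to = int(fields[20])
                score = float(fields[13])
                evalue = float(fields[12])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric coordinate or score ({exc})")
            hits.append(
                DomainHit(
                    protein_id=fields[3],
                    domain_name=fields[0],
                    domain_acc=fields[1],
                    aa_start=env_from - 1,
                    aa_end=env_to,
                    score=score,
                    evalue=evalue,
                )
            )
    return hits


def impacts_to_rows(impacts: list[EventImpact]) -> list[dict]:
    rows = []
    for imp in impacts:
        ev = imp.event
        rows.append(
            {
                "gene_id": ev.gene_id,
                "long_tx": ev.long_tx,
                "start": ev.start,
                "end": ev.end,
                "as_type": ev.as_type,
                "region_class": imp.region_class,
                "frame": imp.frame,
                "aa_start": imp.protein_interval[0] if imp.protein_interval else "",
                "aa_end": imp.protein_interval[1] if imp.protein_interval else "",
                "affected_domains": ";".join(imp.affected_domains),
            }
        )
    return rows
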