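"""Concordance between pair-gapped detection and genome-anchored truth.

Detected events are compared with the generator's truth events (which
carry transcript-coordinate projections onto every isoform containing the
region).  A detected event overlaps a truth event completely when its
carrier interval matches a projection within a small tolerance and the
types agree.  Two documented deviation classes are tallied separately:

* ``merged_multi_skip`` — adjacent skipped exons reported as one
  spanning exon-skipping event;
* ``altpos_as_ir`` — an alternative-position region whose terminal
  2-mers happen to form a canonical splice pair, reported as intron
  retention.

Remaining detected events are spurious; truth events never recovered are
missed.  The four detected buckets always partition the detected set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .as_caller import ASEvent, CANONICAL_PAIRS, ES, IR
from .errors import ValidationError
from .synthetic_data import TruthEvent


@dataclass
class ConcordanceReport:
    n_truth: int = 0
    n_detected: int = 0
    complete_overlap: int = 0
    merged_multi_skip: int = 0
    altpos_as_ir: int = 0
    spurious: int = 0
    missed: int = 0
    assignments: list[tuple[str, str]] = field(default_factory=list)  # (detected key, bucket)

    @property
    def complete_overlap_fraction(self) -> float:
        return self.complete_overlap / self.n_detected if self.n_detected else 0.0

    def check_partition(self) -> None:
        total = self.complete_overlap + self.merged_multi_skip + self.altpos_as_ir + self.spurious
        assert total == self.n_detected, "concordance buckets do not partition detected events"


def _within(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def compare_event_sets(
    detected: list[ASEvent],
    truth: list[TruthEvent],
    tol: int = 3,
    transcripts: set[str] | None = None,
) -> ConcordanceReport:
    """Bucket every detected event against truth; tally missed truth.

    ``transcripts``, when given, is the universe of known transcript ids;
    a detected event on an unknown transcript raises a validation error.
    """
    if transcripts is not None:
        for ev in detected:
            if ev.long_tx not in transcripts:
                raise ValidationError(f"detected event on unknown transcript {ev.long_tx}")

    by_gene: dict[str, list[TruthEvent]] = {}
    for t in truth:
        by_gene.setdefault(t.gene_id, []).append(t)

    report = ConcordanceReport(n_truth=len(truth), n_detected=len(detected))
    recovered: set[int] = set()  # ids of truth objects matched in any bucket

    for ev in detected:
        key = f"{ev.long_tx}:{ev.start}-{ev.end}:{ev.as_type}"
        cands = by_gene.get(ev.gene_id, [])
        # exact bucket: matching projection and agreeing type
        hit = next(
            (
                t
                for t in cands
                if t.as_type == ev.as_type
                and ev.long_tx in t.projections
                and _within((ev.start, ev.end), t.projections[ev.long_tx], tol)
            ),
            None,
        )
        if hit is not None:
            recovered.add(id(hit))
            report.complete_overlap += 1
            report.assignments.append((key, "complete_overlap"))
            continue
        # merged multi-skip: one detected ES spanning >=2 adjacent truth ES
        if ev.as_type == ES:
            parts = sorted(
                (
                    t
                    for t in cands
                    if t.as_type == ES
                    and ev.long_tx in t.projections
                    and t.projections[ev.long_tx][0] >= ev.start - tol
                    and t.projections[ev.long_tx][1] <= ev.end + tol
                ),
                key=lambda t: t.projections[ev.long_tx],
            )
            if len(parts) >= 2:
                ivs = [t.projections[ev.long_tx] for t in parts]
                contiguous = all(ivs[i][1] == ivs[i + 1][0] for i in range(len(ivs) - 1))
                spans = _within((ivs[0][0], ivs[-1][1]), (ev.start, ev.end), tol)
                if contiguous and spans:
                    recovered.update(id(t) for t in parts)
                    report.merged_multi_skip += 1
                    report.assignments.append((key, "merged_multi_skip"))
                    continue
        # alternative position misread as intron retention
        if ev.as_type == IR:
            hit = next(
                (
                    t
                    for t in cands
                    if t.as_type in ("alt_donor", "alt_acceptor")
                    and (t.donor2, t.acceptor2) in CANONICAL_PAIRS
                    and ev.long_tx in t.projections
                    and _within((ev.start, ev.end), t.projections[ev.long_tx], tol)
                ),
                None,
            )
            if hit is not None:
                recovered.add(id(hit))
                report.altpos_as_ir += 1
                report.assignments.append((key, "altpos_as_ir"))
                continue
        report.spurious += 1
        report.assignments.append((key, "spurious"))

    report.missed = sum(1 for t in truth if id(t) not in recovered)
    report.check_partition()
    return report


def report_to_rows(report: ConcordanceReport) -> list[dict]:
    return [
        {"metric": "n_truth", "value": report.n_truth},
        {"metric": "n_detected", "value": report.n_detected},
        {"metric": "complete_overlap", "value": report.complete_overlap},
        {"metric": "complete_overlap_fraction", "value": round(report.complete_overlap_fraction, 4)},
        {"metric": "merged_multi_skip", "value": report.merged_multi_skip},
        {"metric": "altpos_as_ir", "value": report.altpos_as_ir},
        {"metric": "spurious", "value": report.spurious},
        {"metric": "missed", "value": report.missed},
    ]
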