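"""Reading transcript FASTA and grouping isoforms into gene clusters.

De novo assemblers emit transcripts whose identifiers encode cluster
membership (gene) and isoform index.  This package's convention is
``<gene_id>_i<k>`` for sense isoforms and ``<gene_id>_as<k>`` for
antisense transcripts distinguished by a strand-specific library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

VALID_ALPHABET = set("ACGTN")


@dataclass
class TranscriptCluster:
    """A gene's set of assembled isoform sequences.

    ``isoforms`` maps transcript id to its uppercase nucleotide sequence;
    ``antisense`` holds transcripts labelled as natural antisense, which
    never enter pairwise AS detection.
    """

    gene_id: str
    isoforms: dict[str, str] = field(default_factory=dict)
    antisense: dict[str, str] = field(default_factory=dict)

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)


def check_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValidationError(f"{name} is empty")
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValidationError(f"{name} has characters outside ACGTN: {sorted(bad)}")
    return seq


def split_transcript_id(tx_id: str) -> tuple[str, str]:
    """Split ``gene0001_i2`` into ``("gene0001", "i2")``."""
    gene, _, suffix = tx_id.rpartition("_")
    if not gene or not suffix:
        raise ValidationError(f"transcript id {tx_id!r} lacks a _i<k>/_as<k> suffix")
    return gene, suffix


def clusters_from_records(records: Iterable[SeqRecord]) -> list[TranscriptCluster]:
    """Group FASTA records into per-gene clusters by id convention."""
    by_gene: dict[str, TranscriptCluster] = {}
    for rec in records:
        gene, suffix = split_transcript_id(rec.id)
        cluster = by_gene.setdefault(gene, TranscriptCluster(gene_id=gene))
        seq = check_sequence(str(rec.seq), rec.id)
        if suffix.startswith("as"):
            cluster.antisense[rec.id] = seq
        else:
            cluster.isoforms[rec.id] = seq
    return [by_gene[g] for g in sorted(by_gene)]


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def read_clusters(path) -> list[TranscriptCluster]:
    return clusters_from_records(read_fasta(path))


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def make_record(tx_id: str, seq: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(seq), id=tx_id, description=description)
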