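"""Synthetic multi-exon gene models with planted alternative-splicing events.

The generator emulates the statistical structure the analysis assumes:
multi-exon genes on the sense strand with canonical splice dinucleotides,
isoform sets carrying planted events of the four AS types in configurable
proportions, alternative-region lengths from a shifted geometric law with
a configurable mean, a configurable fraction of multi-event genes, ORFs
embedded in transcripts with planted protein-domain intervals, and
negative-binomial read counts.  Every downstream stage of the pipeline is
testable against the emitted ground truth without any external data.

All coordinates are 0-based half-open, on genomic and transcript axes
alike.  Genes are sense-strand only (strand-specific library); labelled
antisense transcripts can be planted for the expression summary.

Planted events are recoverable at exact coordinates by construction: the
generator separates each alternative region from its flanks (the region's
first base differs from the base that follows the region's insertion
point, and its last base from the base preceding it), removing the
left/right shift ambiguity inherent to indel placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .as_caller import ALT_ACCEPTOR, ALT_DONOR, ES, IR
from .errors import GenerationError, ValidationError
from .io import make_record
from .orf_domain import STOP_CODONS, DomainHit, find_longest_orf, nt_to_aa_interval

SPLICE_PAIRS = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
DONOR_FIRST = {"G", "A"}  # first chars of donor signals
BASES = ("A", "C", "G", "T")
ALL_DINUCS = tuple(a + b for a in BASES for b in BASES)
SAFE_DONOR2 = tuple(d for d in ALL_DINUCS if d not in {"GT", "GC", "AT"})
SAFE_ACCEPTOR2 = tuple(d for d in ALL_DINUCS if d not in {"AG", "AC"})
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)
CANONICAL_FOR_DONOR = {"GT": "AG", "GC": "AG", "AT": "AC"}
DONOR_FOR_ACCEPTOR = {"AG": "GT", "AC": "AT"}

#: GO vocabulary used by :func:`simulate_go_terms`; the first term is
#: planted with elevated probability in AS genes so enrichment output is
#: non-trivial on synthetic runs.
GO_VOCAB = tuple(f"GO:{i:07d}" for i in range(1, 31))
DOMAIN_VOCAB = tuple((f"DOM{i:03d}", f"PF{i:05d}") for i in range(1, 41))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset; defaults encode the study conditions.

    Type mix defaults to (IR, ES, AltD, AltA) = (0.33, 0.27, 0.22, 0.19),
    splice-pair mix to 92/7/1% GT-AG/GC-AG/AT-AC, mean alternative-region
    length to 91 nt, and the multi-event fraction of AS genes to 0.32.
    """

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (80, 400)
    splice_mix: tuple[float, float, float] = (0.92, 0.07, 0.01)
    as_type_mix: tuple[float, float, float, float] = (
        1776 / 5408,
        1435 / 5408,
        1169 / 5408,
        1028 / 5408,
    )
    p_as_gene: float = 0.30
    p_multi_event: float = 0.32
    as_region_len_mean: float = 91.0
    as_region_len_min: int = 12
    gc_content: float = 0.45
    seed: int = 0
    nb_mean: float = 50.0
    nb_dispersion: float = 2.0
    as_expr_factor: float = 2.0
    antisense_fraction: float = 0.05
    antisense_expr_factor: float = 0.25
    p_multi_skip: float = 0.0
    p_altpos_canonical: float = 0.0

    def validate(self) -> None:
        for name in ("splice_mix", "as_type_mix"):
            mix = getattr(self, name)
            if any(not (0.0 <= x <= 1.0) for x in mix):
                raise ValidationError(f"{name} proportions must lie in [0, 1]")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {sum(mix)})")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValidationError(f"{name} range ({lo}, {hi}) is empty or non-positive")
        if self.exons_per_gene[0] < 3:
            raise ValidationError("genes need at least 3 exons to host events")
        if self.exon_len[0] < 20:
            raise ValidationError("minimum exon length must be >= 20 (event flanks)")
        if self.as_region_len_mean <= self.as_region_len_min:
            raise ValidationError("as_region_len_mean must exceed as_region_len_min")
        if self.as_region_len_min < 4:
            raise ValidationError("as_region_len_min must be >= 4 (terminal 2-mers)")
        for name in (
            "p_as_gene",
            "p_multi_event",
            "gc_content",
            "antisense_fraction",
            "p_multi_skip",
            "p_altpos_canonical",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class TruthEvent:
    """A planted event with its genomic origin and transcript projections."""

    gene_id: str
    event_id: str
    as_type: str
    carrier_tx: str
    other_tx: str
    start: int  # on carrier_tx
    end: int
    genomic_start: int
    genomic_end: int
    donor2: str
    acceptor2: str
    ambiguous: bool = False
    group_id: str = ""  # shared by the two halves of a planted double skip
    projections: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruthModel:
    """A synthetic gene: genomic sequence, exon structure, isoform chains."""

    gene_id: str
    genomic_seq: str
    strand: str
    exons: list[tuple[int, int]]
    intron_dinucs: list[tuple[str, str]]
    isoforms: list[tuple[str, list[tuple[int, int]]]]
    planted_events: list[TruthEvent] = field(default_factory=list)
    antisense: list[tuple[str, str]] = field(default_factory=list)  # (tx_id, seq)

    def isoform_seq(self, tx_id: str) -> str:
        for tid, chain in self.isoforms:
            if tid == tx_id:
                return "".join(self.genomic_seq[s:e] for s, e in chain)
        for tid, seq in self.antisense:
            if tid == tx_id:
                return seq
        raise ValidationError(f"{tx_id} is not an isoform of {self.gene_id}")

    @property
    def is_as(self) -> bool:
        return bool(self.planted_events)


def _region_length(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    # shifted geometric: min + (G-1), G ~ Geom(p); mean = min + 1/p - 1
    p = 1.0 / (cfg.as_region_len_mean - cfg.as_region_len_min + 1.0)
    return int(cfg.as_region_len_min + rng.geometric(p) - 1)


def _base_not(rng: np.random.Generator, *excluded: str) -> str:
    choices = [b for b in BASES if b not in excluded]
    return choices[int(rng.integers(len(choices)))]


def _choice(rng: np.random.Generator, seq, p=None) -> object:
    idx = rng.choice(len(seq), p=p)
    return seq[int(idx)]


def _project(interval: tuple[int, int], chain: list[tuple[int, int]]):
    """Transcript coordinates of a genomic interval contained in one segment."""
    offset = 0
    s, e = interval
    for seg_s, seg_e in chain:
        if seg_s <= s and e <= seg_e:
            return (offset + s - seg_s, offset + e - seg_s)
        offset += seg_e - seg_s
    return None


def _place_events(rng, n_exons: int, specs: list[tuple[str, bool]]):
    """Assign each event spec a feature index with disjoint touched exons.

    Returns list of (as_type, double_skip, feature_index) or None on failure.
    Intron events on intron i touch exons {i, i+1}; a skip of exon j touches
    {j-1, j, j+1} (and {j-1..j+2} for a double skip).
    """
    for _ in range(40):
        used: set[int] = set()
        placed = []
        ok = True
        for as_type, double in specs:
            if as_type == ES:
                hi = n_exons - 3 if double else n_exons - 2
                cands = list(range(1, hi + 1))
            else:
                cands = list(range(0, n_exons - 1))
            rng.shuffle(cands)
            found = None
            for c in cands:
                if as_type == ES:
                    touch = set(range(c - 1, c + 3 if double else c + 2))
                else:
                    touch = {c, c + 1}
                if touch & used:
                    continue
                found = c
                used |= touch
                break
            if found is None:
                ok = False
                break
            placed.append((as_type, double, found))
        if ok:
            return placed
    return None


def _plant_orf(seq: list[str], tx_map: list[int], protected: set[int], rng) -> None:
    """Rewrite exonic bases so the constitutive transcript carries a long ORF.

    Protected positions (event-critical bases) are never modified; a stop
    codon that cannot be removed without touching one is simply left in
    place (the realized ORF is whatever the ORF finder later reports).
    """
    t_len = len(tx_map)
    if t_len < 200:
        return
    start = int(rng.integers(3, 16))
    n_codons = int(0.7 * (t_len - start - 3) / 3)
    if n_codons < 40:
        return

    def write_codon(pos: int, candidates: tuple[str, ...]) -> bool:
        order = rng.permutation(len(candidates))
        g = [tx_map[pos], tx_map[pos + 1], tx_map[pos + 2]]
        for i in order:
            codon = candidates[int(i)]
            if all(g[j] not in protected or seq[g[j]] == codon[j] for j in range(3)):
                for j in range(3):
                    seq[g[j]] = codon[j]
                return True
        return False

    if not write_codon(start, ("ATG",)):
        return
    for c in range(1, n_codons):
        pos = start + 3 * c
        current = seq[tx_map[pos]] + seq[tx_map[pos + 1]] + seq[tx_map[pos + 2]]
        if current in STOP_CODONS:
            write_codon(pos, NON_STOP_CODONS)
    write_codon(start + 3 * n_codons, ("TAA", "TAG", "TGA"))


def _generate_gene(gene_id: str, cfg: GeneratorConfig, rng) -> tuple[GroundTruthModel, list[TruthEvent]]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    specs: list[tuple[str, bool]] = []
    if rng.random() < cfg.p_as_gene:
        n_events = 2 if rng.random() < cfg.p_multi_event else 1
        for _ in range(n_events):
            as_type = _choice(rng, (IR, ES, ALT_DONOR, ALT_ACCEPTOR), p=cfg.as_type_mix)
            double = as_type == ES and rng.random() < cfg.p_multi_skip
            specs.append((as_type, double))
        # a gene hosting two (or double-skip) events needs room for
        # non-adjacent features; multi-AS genes are drawn with >= 6 exons
        # so the configured multi-event fraction is realized in expectation
        need = 6 if (n_events > 1 or any(d for _, d in specs)) else cfg.exons_per_gene[0]
        if n_exons < need <= cfg.exons_per_gene[1]:
            n_exons = int(rng.integers(need, cfg.exons_per_gene[1] + 1))
    placements = _place_events(rng, n_exons, specs)
    if placements is None and len(specs) > 1:
        placements = _place_events(rng, n_exons, specs[:1])
    if placements is None and specs:
        raise GenerationError(
            f"{gene_id}: cannot place {len(specs)} event(s) in a {n_exons}-exon gene"
        )
    placements = placements or []

    exon_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, n_exons).tolist()
    intron_lens = rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1, n_exons - 1).tolist()
    event_lens: list[int | tuple[int, int]] = []
    for as_type, double, idx in placements:
        if as_type == IR:
            L = _region_length(rng, cfg)
            intron_lens[idx] = L
            event_lens.append(L)
        elif as_type in (ALT_DONOR, ALT_ACCEPTOR):
            L = _region_length(rng, cfg)
            intron_lens[idx] = max(intron_lens[idx], L + 8)
            event_lens.append(L)
        elif double:
            L1, L2 = _region_length(rng, cfg), _region_length(rng, cfg)
            exon_lens[idx], exon_lens[idx + 1] = L1, L2
            event_lens.append((L1, L2))
        else:
            L = _region_length(rng, cfg)
            exon_lens[idx] = L
            event_lens.append(L)

    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_exons):
        exons.append((pos, pos + exon_lens[i]))
        pos += exon_lens[i]
        if i < n_exons - 1:
            introns.append((pos, pos + intron_lens[i]))
            pos += intron_lens[i]
    g_len = pos

    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = [BASES[i] for i in rng.choice(4, size=g_len, p=probs)]

    intron_dinucs: list[tuple[str, str]] = []
    for s, e in introns:
        donor, acceptor = _choice(rng, SPLICE_PAIRS, p=cfg.splice_mix)
        seq[s], seq[s + 1] = donor[0], donor[1]
        seq[e - 2], seq[e - 1] = acceptor[0], acceptor[1]
        intron_dinucs.append((donor, acceptor))

    protected: set[int] = set()

    def set_bases(start_pos: int, bases: str) -> None:
        for off, b in enumerate(bases):
            seq[start_pos + off] = b
            protected.add(start_pos + off)

    truth_raw = []  # (as_type, region_g or pair, flank info, ambiguous, feature idx)
    for (as_type, double, idx), L in zip(placements, event_lens):
        ambiguous = False
        if as_type == IR:
            r_s, r_e = introns[idx]
            x_last = exons[idx][1] - 1
            y_first = exons[idx + 1][0]
        elif as_type == ALT_DONOR:
            r_s = introns[idx][0]
            r_e = r_s + L
            donor = intron_dinucs[idx][0]
            if rng.random() < cfg.p_altpos_canonical:
                set_bases(r_e - 2, CANONICAL_FOR_DONOR[donor])
                ambiguous = True
            else:
                set_bases(r_e - 2, _choice(rng, SAFE_ACCEPTOR2))
            x_last = exons[idx][1] - 1
            y_first = exons[idx + 1][0]
        elif as_type == ALT_ACCEPTOR:
            r_e = introns[idx][1]
            r_s = r_e - L
            acceptor = intron_dinucs[idx][1]
            if rng.random() < cfg.p_altpos_canonical:
                set_bases(r_s, DONOR_FOR_ACCEPTOR[acceptor])
                ambiguous = True
            else:
                set_bases(r_s, _choice(rng, SAFE_DONOR2))
            x_last = exons[idx][1] - 1
            y_first = exons[idx + 1][0]
        else:  # exon skipping (single or adjacent double)
            last_exon = idx + 1 if double else idx
            r_s, r_e = exons[idx][0], exons[last_exon][1]
            set_bases(exons[idx][0], _choice(rng, SAFE_DONOR2))
            set_bases(exons[last_exon][1] - 2, _choice(rng, SAFE_ACCEPTOR2))
            x_last = exons[idx - 1][1] - 1
            y_first = exons[last_exon + 1][0]
        # kill indel-placement ambiguity: region must not shift left or right
        region_first = seq[r_s]
        region_last = seq[r_e - 1]
        set_bases(x_last, _base_not(rng, region_last))
        set_bases(y_first, _base_not(rng, region_first))
        truth_raw.append((as_type, double, idx, (r_s, r_e), ambiguous))

    tx_map = [p for s, e in exons for p in range(s, e)]
    _plant_orf(seq, tx_map, protected, rng)
    genomic = "".join(seq)

    const_chain = list(exons)
    isoforms: list[tuple[str, list[tuple[int, int]]]] = [(f"{gene_id}_i1", const_chain)]
    events: list[TruthEvent] = []
    for k, (as_type, double, idx, (r_s, r_e), ambiguous) in enumerate(truth_raw):
        alt_tx = f"{gene_id}_i{k + 2}"
        chain = list(exons)
        if as_type == IR:
            chain[idx : idx + 2] = [(exons[idx][0], exons[idx + 1][1])]
        elif as_type == ALT_DONOR:
            chain[idx] = (exons[idx][0], exons[idx][1] + (r_e - r_s))
        elif as_type == ALT_ACCEPTOR:
            chain[idx + 1] = (exons[idx + 1][0] - (r_e - r_s), exons[idx + 1][1])
        else:
            del chain[idx : idx + 2 if double else idx + 1]
        isoforms.append((alt_tx, chain))

        regions = [(r_s, exons[idx][1]), (exons[idx + 1][0], r_e)] if double else [(r_s, r_e)]
        group = f"{gene_id}_g{k + 1}" if double else ""
        for part, (gs, ge) in enumerate(regions):
            if as_type == ES:
                carrier_tx, other_tx = f"{gene_id}_i1", alt_tx
            else:
                carrier_tx, other_tx = alt_tx, f"{gene_id}_i1"
            events.append(
                TruthEvent(
                    gene_id=gene_id,
                    event_id=f"{gene_id}_e{k + 1}" + (f".{part + 1}" if double else ""),
                    as_type=as_type,
                    carrier_tx=carrier_tx,
                    other_tx=other_tx,
                    start=-1,
                    end=-1,
                    genomic_start=gs,
                    genomic_end=ge,
                    donor2=genomic[gs : gs + 2],
                    acceptor2=genomic[ge - 2 : ge],
                    ambiguous=ambiguous,
                    group_id=group,
                )
            )

    for ev in events:
        for tx_id, chain in isoforms:
            proj = _project((ev.genomic_start, ev.genomic_end), chain)
            if proj is not None:
                ev.projections[tx_id] = proj
        if ev.carrier_tx not in ev.projections:
            raise GenerationError(f"{gene_id}: event {ev.event_id} lost its carrier projection")
        ev.start, ev.end = ev.projections[ev.carrier_tx]

    model = GroundTruthModel(
        gene_id=gene_id,
        genomic_seq=genomic,
        strand="+",
        exons=exons,
        intron_dinucs=intron_dinucs,
        isoforms=isoforms,
        planted_events=events,
    )
    if rng.random() < cfg.antisense_fraction:
        from Bio.Seq import Seq as _Seq

        model.antisense.append(
            (f"{gene_id}_as1", str(_Seq(model.isoform_seq(f"{gene_id}_i1")).reverse_complement()))
        )
    return model, events


def generate_dataset(config: GeneratorConfig):
    """Generate gene models, transcript FASTA records, and the truth table.

    Deterministic given ``config.seed``.  Returns
    (models, fasta records, truth events).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    models: list[GroundTruthModel] = []
    records = []
    truths: list[TruthEvent] = []
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:05d}"
        model, events = _generate_gene(gene_id, config, rng)
        models.append(model)
        truths.extend(events)
        for tx_id, _chain in model.isoforms:
            records.append(make_record(tx_id, model.isoform_seq(tx_id)))
        for tx_id, seq in model.antisense:
            records.append(make_record(tx_id, seq, description="antisense"))
    return models, records, truths


def simulate_expression(models: list[GroundTruthModel], config: GeneratorConfig) -> pd.DataFrame:
    """Independent negative-binomial read counts per transcript.

    The NB mean scales with transcript length (nb_mean is per kilobase);
    AS-gene isoforms get ``as_expr_factor`` times the base mean and
    antisense transcripts ``antisense_expr_factor`` times.  Deterministic
    given the config seed; dispersion above 1e6 falls back to the Poisson
    limit.
    """
    if config.nb_mean <= 0 or config.nb_dispersion <= 0:
        raise ValidationError("nb_mean and nb_dispersion must be positive")
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for model in models:
        for tx_id, _chain in model.isoforms:
            length = len(model.isoform_seq(tx_id))
            group = "as" if model.is_as else "sense"
            factor = config.as_expr_factor if model.is_as else 1.0
            rows.append((tx_id, model.gene_id, group, length, factor))
        for tx_id, seq in model.antisense:
            rows.append((tx_id, model.gene_id, "antisense", len(seq), config.antisense_expr_factor))
    df = pd.DataFrame(rows, columns=["feature_id", "gene_id", "group", "length", "_factor"])
    mu = config.nb_mean * (df["length"] / 1000.0) * df["_factor"]
    r = config.nb_dispersion
    if len(df) == 0:
        counts = np.array([], dtype=int)
    elif r > 1e6:
        counts = rng.poisson(mu.to_numpy())
    else:
        p = r / (r + mu.to_numpy())
        counts = rng.negative_binomial(r, p)
    df["mapped_reads"] = counts.astype(int)
    return df.drop(columns="_factor")


def simulate_domains(models: list[GroundTruthModel], config: GeneratorConfig):
    """Plant protein-domain intervals inside each isoform's realized ORF.

    Returns (domain hits, {transcript: ORFAnnotation}).  Domains are drawn
    from a 40-entry vocabulary with lengths 15-60 aa at uniform positions.
    """
    rng = np.random.default_rng([config.seed, 2])
    hits: list[DomainHit] = []
    orfs = {}
    for model in models:
        for tx_id, _chain in model.isoforms:
            orf = find_longest_orf(model.isoform_seq(tx_id), tx_id)
            if orf is None:
                continue
            orfs[tx_id] = orf
            plen = len(orf.protein)
            if plen < 20:
                continue
            for _ in range(int(rng.integers(1, 4))):
                name, acc = _choice(rng, DOMAIN_VOCAB)
                dlen = int(rng.integers(15, min(60, plen) + 1))
                start = int(rng.integers(0, plen - dlen + 1))
                hits.append(
                    DomainHit(
                        protein_id=tx_id,
                        domain_name=name,
                        domain_acc=acc,
                        aa_start=start,
                        aa_end=start + dlen,
                        score=float(np.round(rng.uniform(20, 200), 1)),
                        evalue=float(f"{rng.uniform(1e-30, 1e-5):.2e}"),
                    )
                )
    return hits, orfs


def simulate_go_terms(models: list[GroundTruthModel], config: GeneratorConfig) -> dict[str, set[str]]:
    """Random GO-term annotation per gene, with the first vocabulary term
    enriched in AS genes (P = 0.4 vs 0.1) so enrichment output is exercised."""
    rng = np.random.default_rng([config.seed, 3])
    annot: dict[str, set[str]] = {}
    for model in models:
        n_terms = int(rng.integers(1, 6))
        terms = {str(t) for t in rng.choice(GO_VOCAB, size=n_terms, replace=False)}
        p_sig = 0.4 if model.is_as else 0.1
        if rng.random() < p_sig:
            terms.add(GO_VOCAB[0])
        annot[model.gene_id] = terms
    return annot


# ---------------------------------------------------------------------------
# plain-text writers


def truth_to_frame(truths: list[TruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "event_id": t.event_id,
                "as_type": t.as_type,
                "carrier_tx": t.carrier_tx,
                "other_tx": t.other_tx,
                "start": t.start,
                "end": t.end,
                "length": t.length,
                "donor2": t.donor2,
                "acceptor2": t.acceptor2,
                "ambiguous": t.ambiguous,
                "group_id": t.group_id,
                "projections": ";".join(
                    f"{tx}:{s}-{e}" for tx, (s, e) in sorted(t.projections.items())
                ),
            }
            for t in truths
        ]
    )


def write_truth_tsv(truths: list[TruthEvent], path) -> None:
    truth_to_frame(truths).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        projections = {}
        if row.projections:
            for part in str(row.projections).split(";"):
                tx, span = part.rsplit(":", 1)
                s, e = span.split("-")
                projections[tx] = (int(s), int(e))
        out.append(
            TruthEvent(
                gene_id=row.gene_id,
                event_id=row.event_id,
                as_type=row.as_type,
                carrier_tx=row.carrier_tx,
                other_tx=row.other_tx,
                start=int(row.start),
                end=int(row.end),
                genomic_start=-1,
                genomic_end=-1,
                donor2=row.donor2,
                acceptor2=row.acceptor2,
                ambiguous=bool(row.ambiguous),
                group_id=str(row.group_id),
                projections=projections,
            )
        )
    return out


def write_gff3(models: list[GroundTruthModel], path) -> None:
    """Gene models as GFF3 (gene/mRNA/exon); seqid is the gene's own contig."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            end = len(m.genomic_seq)
            fh.write(
                f"{m.gene_id}\tpairsplice_sim\tgene\t1\t{end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            for tx_id, chain in m.isoforms:
                fh.write(
                    f"{m.gene_id}\tpairsplice_sim\tmRNA\t{chain[0][0] + 1}\t{chain[-1][1]}\t.\t"
                    f"{m.strand}\t.\tID={tx_id};Parent={m.gene_id}\n"
                )
                for i, (s, e) in enumerate(chain, start=1):
                    fh.write(
                        f"{m.gene_id}\tpairsplice_sim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                    )


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_domain_table(hits: list[DomainHit], orfs: dict, path) -> None:
    """Write hits in the hmmscan per-domain tabular layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("# synthetic per-domain hits (hmmscan --domtblout layout)\n")
        fh.write("# target_name acc tlen query_name acc qlen E-value score bias # of "
                 "c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to "
                 "env_from env_to acc description\n")
        for h in hits:
            qlen = len(orfs[h.protein_id].protein) if h.protein_id in orfs else 0
            tlen = h.aa_end - h.aa_start
            fh.write(
                f"{h.domain_name} {h.domain_acc} {tlen} {h.protein_id} - {qlen} "
                f"{h.evalue:.2e} {h.score:.1f} 0.0 1 1 {h.evalue:.2e} {h.evalue:.2e} "
                f"{h.score:.1f} 0.0 1 {tlen} {h.aa_start + 1} {h.aa_end} "
                f"{h.aa_start + 1} {h.aa_end} 0.90 planted synthetic domain\n"
            )


def gene_domain_presence(hits: list[DomainHit]) -> dict[str, set[str]]:
    """Gene-level presence sets: gene id -> set of domain accessions."""
    from .io import split_transcript_id

    presence: dict[str, set[str]] = {}
    for h in hits:
        gene, _ = split_transcript_id(h.protein_id)
        presence.setdefault(gene, set()).add(h.domain_acc)
    return presence
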