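"""Event classification, candidate extraction, dedup, and type summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pairsplice import as_caller
from pairsplice.as_caller import (
    ALT_ACCEPTOR,
    ALT_DONOR,
    ES,
    IR,
    UNCLASSIFIED,
    ASEvent,
    CallerOptions,
    CandidateRegion,
    call_events,
    classify,
    extract_candidates,
    summarize_types,
    type_percentages,
)
from pairsplice.concordance import compare_event_sets
from pairsplice.errors import ValidationError
from pairsplice.pair_align import AlignmentChain, AlignParams, Indel

DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


def expected_class(donor2: str, acceptor2: str) -> str:
    """Hand-written truth table for the terminal-2-mer classification rule."""
    if (donor2, acceptor2) in {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}:
        return IR
    if donor2 in {"GT", "GC", "AT"}:
        return ALT_DONOR
    if acceptor2 in {"AG", "AC"}:
        return ALT_ACCEPTOR
    return ES


def test_classify_all_256_terminal_pairs():
    for donor2 in DINUCS:
        for acceptor2 in DINUCS:
            region = donor2 + "TTTT" + acceptor2
            assert classify(region) == expected_class(donor2, acceptor2)


def test_classify_strict_mode_withholds_rule4():
    assert classify("CCTTTTTTCC", strict=True) == UNCLASSIFIED
    assert classify("GTTTTTTTAG", strict=True) == IR


def test_classify_examples():
    assert classify("GTAAGT" + "T" * 20 + "TTGCAG") == IR
    assert classify("GT" + "A" * 10 + "CC") == ALT_DONOR
    assert classify("CA" + "A" * 10 + "AG") == ALT_ACCEPTOR
    assert classify("CCTT" + "A" * 10 + "TTCC") == ES


def test_classify_too_short_raises():
    with pytest.raises(ValidationError):
        classify("GTA")


@settings(max_examples=64, deadline=None, derandomize=True)
@given(
    donor2=st.sampled_from(DINUCS),
    acceptor2=st.sampled_from(DINUCS),
    middle=st.text(alphabet="ACGT", min_size=0, max_size=40),
)
def test_classify_depends_only_on_terminal_2mers(donor2, acceptor2, middle):
    region = donor2 + middle + acceptor2
    assert classify(region) == expected_class(donor2, acceptor2)


def _chain(blocks, indels, qid="g_i2", tid="g_i1"):
    return AlignmentChain(
        query_id=qid, target_id=tid, blocks=blocks, indels=indels, identity=100.0
    )


def test_extract_candidate_from_flanked_indel():
    chain = _chain(
        [(0, 120, 0, 120), (210, 330, 120, 240)],
        [Indel("query", 120, 90, 120, 120, 120)],
    )
    cands = extract_candidates(chain)
    assert cands == [CandidateRegion(long_tx="g_i2", short_tx="g_i1", start=120, end=210)]
    assert cands[0].length == 90


def test_extract_candidate_respects_max_gap_and_min_len():
    big = _chain([(0, 50, 0, 50), (10100, 10150, 50, 100)], [Indel("query", 50, 10050, 50, 50, 50)])
    assert extract_candidates(big, AlignParams(max_gap=10_000)) == []
    tiny = _chain([(0, 50, 0, 50), (55, 105, 50, 100)], [Indel("query", 50, 5, 50, 50, 50)])
    assert extract_candidates(tiny) == []  # below min_event_len=12


def test_extract_candidate_requires_both_flanks():
    short_flank = _chain(
        [(0, 10, 0, 10), (100, 200, 10, 110)], [Indel("query", 10, 90, 10, 10, 100)]
    )
    assert extract_candidates(short_flank) == []
    # a chain with no internal indel (terminal overhang only) yields nothing
    assert extract_candidates(_chain([(0, 100, 0, 100)], [])) == []


def _ir_gene(rng, gene="g"):
    """Three isoforms: i2 retains a 90-nt canonical intron absent in i1/i3."""
    from conftest import random_dna

    x = random_dna(rng, 120)
    y = random_dna(rng, 120)
    intron = "GT" + random_dna(rng, 86) + "AG"
    while intron[-1] == x[-1] or intron[0] == y[0]:
        x = random_dna(rng, 120)
        y = random_dna(rng, 120)
    seqs = {f"{gene}_i1": x + y, f"{gene}_i2": x + intron + y, f"{gene}_i3": x + y}
    return seqs, intron


def test_call_events_merges_same_region_across_pairs():
    from pairsplice.pair_align import all_pairs
    from pairsplice.io import TranscriptCluster

    rng = np.random.default_rng(4)
    seqs, intron = _ir_gene(rng)
    cluster = TranscriptCluster("g", isoforms=seqs)
    chains = all_pairs(cluster)
    events = call_events({"g": chains}, seqs)
    assert len(events) == 1
    ev = events[0]
    assert ev.as_type == IR
    assert ev.long_tx == "g_i2"
    assert (ev.start, ev.end) == (120, 210)
    assert ev.supporting_pairs == 2  # pairs (i1,i2) and (i2,i3)
    assert (ev.donor2, ev.acceptor2) == ("GT", "AG")


def test_call_events_counts_distinct_regions_separately():
    # two distinct flanked indels on the same carrier -> 2 events, 1 AS gene
    chain = _chain(
        [(0, 100, 0, 100), (150, 250, 100, 200), (300, 400, 200, 300)],
        [
            Indel("query", 100, 50, 100, 100, 100),
            Indel("query", 250, 50, 200, 100, 100),
        ],
    )
    seqs = {
        "g_i2": "A" * 100 + "GT" + "C" * 46 + "AG" + "A" * 100 + "GT" + "G" * 46 + "AG" + "A" * 100,
        "g_i1": "A" * 300,
    }
    events = call_events({"g": [chain]}, seqs)
    assert len(events) == 2
    assert len({ev.gene_id for ev in events}) == 1


def test_call_events_dedup_tolerance_and_support_sum():
    # both shifted boundaries see GT..AG so the type agrees across candidates
    carrier = "A" * 100 + "GTGT" + "C" * 84 + "AGAG" + "A" * 98
    seqs = {"g_i2": carrier, "g_i1": "A" * 200}
    mk = lambda s: _chain(
        [(0, s, 0, s), (s + 90, 290, s, 200)], [Indel("query", s, 90, s, s, 200 - s)]
    )
    # starts 100 and 102 are within the +-3 dedup tolerance
    events = call_events({"g": [mk(100), mk(102)]}, seqs)
    assert len(events) == 1
    assert events[0].supporting_pairs == 2


def test_summarize_reproduces_reported_percentages():
    counts = {IR: 1776, ES: 1435, ALT_DONOR: 1169, ALT_ACCEPTOR: 1028}
    assert type_percentages(counts) == {IR: 33, ES: 27, ALT_DONOR: 22, ALT_ACCEPTOR: 19}
    assert 100 - 1 <= sum(type_percentages(counts).values()) <= 100 + 1


def test_summarize_single_event_and_lengths():
    ev = lambda g, s, e, t: ASEvent(g, f"{g}_i2", f"{g}_i1", s, e, t, "GT", "AG")
    single = summarize_types([ev("g1", 0, 90, IR)])
    assert single.percentages == {IR: 100, ES: 0, ALT_DONOR: 0, ALT_ACCEPTOR: 0}
    two = summarize_types([ev("g1", 0, 90, IR), ev("g1", 200, 292, ES)])
    assert two.mean_region_length == pytest.approx(91.0)
    assert (two.single_event_genes, two.multi_event_genes) == (0, 1)
    empty = summarize_types([])
    assert empty.total_events == 0 and empty.mean_region_length == 0.0


def test_summary_counts_partition_total(small_detection):
    _clusters, _chains, events, _seqs, _truths = small_detection
    s = summarize_types(events)
    assert sum(s.counts.values()) == s.total_events == len(events)


def test_synthetic_recovery_on_shared_dataset(small_detection):
    """Noise-free planted events are all recovered at exact coordinates."""
    _clusters, _chains, events, _seqs, truths = small_detection
    report = compare_event_sets(events, truths)
    assert report.missed == 0
    assert report.spurious == 0
    assert report.complete_overlap == report.n_detected
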