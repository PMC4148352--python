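"""Generator contracts: determinism, planted-event structure, statistics."""

import dataclasses
import io as std_io

import numpy as np
import pytest
from scipy.stats import binomtest

from pairsplice.as_caller import ALT_ACCEPTOR, ALT_DONOR, ES, IR
from pairsplice.errors import GenerationError, ValidationError
from pairsplice.io import clusters_from_records, read_fasta, write_fasta
from pairsplice.synthetic_data import (
    SPLICE_PAIRS,
    GeneratorConfig,
    generate_dataset,
    simulate_expression,
    truth_to_frame,
    write_truth_tsv,
)


def fasta_bytes(records) -> bytes:
    buf = std_io.StringIO()
    from Bio import SeqIO

    SeqIO.write(records, buf, "fasta")
    return buf.getvalue().encode()


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = GeneratorConfig(n_genes=20, seed=9)
    out = []
    for run in (1, 2):
        _models, records, truths = generate_dataset(cfg)
        t_path = tmp_path / f"truth{run}.tsv"
        write_truth_tsv(truths, t_path)
        out.append((fasta_bytes(records), t_path.read_bytes()))
    assert out[0] == out[1]


def test_forced_intron_retention_regions_are_canonical():
    cfg = GeneratorConfig(n_genes=50, seed=4, as_type_mix=(1.0, 0, 0, 0), p_as_gene=1.0)
    models, _records, truths = generate_dataset(cfg)
    assert len(truths) > 0
    for t in truths:
        assert t.as_type == IR
        assert (t.donor2, t.acceptor2) in set(SPLICE_PAIRS)
    # the retained sequence on the carrier starts/ends with the recorded pair
    by_gene = {m.gene_id: m for m in models}
    for t in truths:
        region = by_gene[t.gene_id].isoform_seq(t.carrier_tx)[t.start : t.end]
        assert region[:2] == t.donor2 and region[-2:] == t.acceptor2


def test_truth_type_proportions_near_configured_mix():
    cfg = GeneratorConfig(n_genes=500, seed=6)
    _models, _records, truths = generate_dataset(cfg)
    counts = {t: 0 for t in (IR, ES, ALT_DONOR, ALT_ACCEPTOR)}
    for t in truths:
        counts[t.as_type] += 1
    total = sum(counts.values())
    for as_type, target in zip((IR, ES, ALT_DONOR, ALT_ACCEPTOR), (33, 27, 22, 19)):
        assert abs(100 * counts[as_type] / total - target) <= 5


def test_event_rates_consistent_with_config():
    """p_as_gene and p_multi_event are realized in expectation (alpha=0.001)."""
    cfg = GeneratorConfig(n_genes=500, seed=8)
    models, _records, truths = generate_dataset(cfg)
    per_gene = {}
    for t in truths:
        per_gene[t.gene_id] = per_gene.get(t.gene_id, 0) + 1
    n_as = len(per_gene)
    assert binomtest(n_as, len(models), cfg.p_as_gene).pvalue > 0.001
    n_multi = sum(1 for v in per_gene.values() if v > 1)
    assert binomtest(n_multi, n_as, cfg.p_multi_event).pvalue > 0.001


def test_pairwise_string_diff_recovers_planted_region(small_dataset):
    """Brute-force longest-common-prefix/suffix diff equals the truth region."""
    _cfg, models, _records, truths = small_dataset
    by_gene = {m.gene_id: m for m in models}
    singles = {}
    for t in truths:
        singles.setdefault(t.gene_id, []).append(t)
    checked = 0
    for gene_id, events in singles.items():
        if len(events) != 1 or events[0].group_id:
            continue  # multi-event pairs differ in more than one region
        t = events[0]
        model = by_gene[gene_id]
        long_seq = model.isoform_seq(t.carrier_tx)
        short_seq = model.isoform_seq(t.other_tx)
        assert len(long_seq) - len(short_seq) == t.length
        lcp = 0
        while lcp < len(short_seq) and long_seq[lcp] == short_seq[lcp]:
            lcp += 1
        lcs = 0
        while (
            lcs < len(short_seq) - lcp
            and long_seq[len(long_seq) - 1 - lcs] == short_seq[len(short_seq) - 1 - lcs]
        ):
            lcs += 1
        assert (lcp, len(long_seq) - lcs) == (t.start, t.end)
        checked += 1
    assert checked > 5


def test_region_lengths_have_configured_mean():
    cfg = GeneratorConfig(n_genes=800, seed=10, p_as_gene=1.0)
    _models, _records, truths = generate_dataset(cfg)
    lens = np.array([t.length for t in truths])
    se = lens.std(ddof=1) / np.sqrt(lens.size)
    assert abs(lens.mean() - cfg.as_region_len_mean) < 4 * se + 1


def test_fasta_roundtrip_through_own_reader(small_dataset, tmp_path):
    _cfg, _models, records, _truths = small_dataset
    path = tmp_path / "tx.fasta"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [(r.id, str(r.seq)) for r in back] == [(r.id, str(r.seq)) for r in records]
    clusters = clusters_from_records(back)
    assert sum(c.n_isoforms + len(c.antisense) for c in clusters) == len(records)


def test_model_structural_invariants(small_dataset):
    _cfg, models, _records, _truths = small_dataset
    for m in models:
        # exons ascending, non-overlapping
        assert all(s < e for s, e in m.exons)
        assert all(a[1] <= b[0] for a, b in zip(m.exons, m.exons[1:]))
        # recorded intron dinucleotides match the genomic sequence
        for i, (donor, acceptor) in enumerate(m.intron_dinucs):
            intron_start = m.exons[i][1]
            intron_end = m.exons[i + 1][0]
            assert m.genomic_seq[intron_start : intron_start + 2] == donor
            assert m.genomic_seq[intron_end - 2 : intron_end] == acceptor
        # isoform sequence equals concatenation of its intervals
        for tx_id, chain in m.isoforms:
            assert m.isoform_seq(tx_id) == "".join(m.genomic_seq[s:e] for s, e in chain)


def test_config_validation_errors():
    with pytest.raises(ValidationError):
        GeneratorConfig(as_type_mix=(0.5, 0.5, 0.5, 0.5)).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(splice_mix=(0.9, 0.2, -0.1)).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(exon_len=(100, 50)).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(as_region_len_mean=5.0).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(nb_mean=-1).validate()


def test_generation_error_names_gene():
    cfg = GeneratorConfig(
        n_genes=5,
        seed=0,
        exons_per_gene=(3, 3),
        as_type_mix=(0, 1.0, 0, 0),
        p_as_gene=1.0,
        p_multi_skip=1.0,
    )
    with pytest.raises(GenerationError, match="gene"):
        generate_dataset(cfg)


def test_config_yaml_roundtrip(tmp_path):
    cfg = GeneratorConfig(n_genes=7, seed=5, p_multi_skip=0.2)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert GeneratorConfig.from_yaml(path) == cfg
    path.write_text("bogus_key: 1\n")
    with pytest.raises(ValidationError):
        GeneratorConfig.from_yaml(path)


def test_expression_poisson_limit():
    cfg = GeneratorConfig(n_genes=400, seed=12, nb_mean=100.0, nb_dispersion=1e9)
    models, _records, _truths = generate_dataset(cfg)
    counts = simulate_expression(models, cfg)
    base = counts[counts["group"] == "sense"]
    # Poisson limit: mean count ~ nb_mean * length/1e3; normalize out length
    norm = base["mapped_reads"] / (base["length"] / 1000.0)
    se = norm.std(ddof=1) / np.sqrt(len(norm))
    assert abs(norm.mean() - 100.0) < 3 * se


def test_expression_empty_and_deterministic():
    cfg = GeneratorConfig(n_genes=0)
    assert len(simulate_expression([], cfg)) == 0
    cfg2 = GeneratorConfig(n_genes=30, seed=2)
    models, _r, _t = generate_dataset(cfg2)
    a = simulate_expression(models, cfg2)
    b = simulate_expression(models, cfg2)
    assert a.equals(b)
    with pytest.raises(ValidationError):
        simulate_expression(models, dataclasses.replace(cfg2, nb_dispersion=0.0))


def test_truth_table_shape(small_dataset):
    _cfg, _models, _records, truths = small_dataset
    df = truth_to_frame(truths)
    assert {"gene_id", "as_type", "carrier_tx", "start", "end", "length", "donor2", "acceptor2"} <= set(df.columns)
    assert (df["length"] == df["end"] - df["start"]).all()
    assert (df["length"] >= 12).all()
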