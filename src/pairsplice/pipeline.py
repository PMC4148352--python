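"""End-to-end orchestration: inputs -> alignment -> events -> impacts -> stats.

The pipeline runs either on a user FASTA of assembled transcripts (ids
encoding gene clusters) or in synthetic mode on a generated dataset, in
which case the generator's ground truth also powers a concordance report.
All outputs are plain text and fully determined by the configuration and
seed; a JSON manifest records every parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import as_caller, concordance, enrichment, expression, io, orf_domain, pair_align
from .errors import ValidationError
from .synthetic_data import (
    GeneratorConfig,
    gene_domain_presence,
    generate_dataset,
    simulate_domains,
    simulate_expression,
    simulate_go_terms,
    truth_to_frame,
    write_counts_tsv,
    write_domain_table,
    write_gff3,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full-run configuration; exactly one of fasta/generator must be set."""

    fasta: str | None = None
    generator: GeneratorConfig | None = None
    align_params: pair_align.AlignParams = field(default_factory=pair_align.AlignParams)
    caller_options: as_caller.CallerOptions = field(default_factory=as_caller.CallerOptions)
    orf_min_codons: int = 30
    domain_table: str | None = None
    go_table: str | None = None
    counts_table: str | None = None
    outdir: str = "pairsplice_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.fasta is None) == (self.generator is None):
            raise ValidationError("exactly one of fasta / generator must be provided")


def detect_events(
    clusters: list[io.TranscriptCluster],
    params: pair_align.AlignParams,
    options: as_caller.CallerOptions,
):
    """Align all isoform pairs per cluster and call events.

    Returns (chains_by_gene, events, sequences).  Single-isoform clusters
    are skipped (constitutive by definition).
    """
    sequences: dict[str, str] = {}
    chains_by_gene: dict[str, list[pair_align.AlignmentChain]] = {}
    for cluster in clusters:
        sequences.update(cluster.isoforms)
        if cluster.n_isoforms < 2:
            continue
        chains = pair_align.all_pairs(cluster, params)
        if chains:
            chains_by_gene[cluster.gene_id] = chains
    events = as_caller.call_events(chains_by_gene, sequences, params, options)
    return chains_by_gene, events, sequences


def compute_impacts(
    events: list[as_caller.ASEvent],
    sequences: dict[str, str],
    hits_by_protein: dict[str, list[orf_domain.DomainHit]],
    min_codons: int = 30,
) -> list[orf_domain.EventImpact]:
    """ORF/frame/domain impact per event, on the carrier transcript."""
    orf_cache: dict[str, orf_domain.ORFAnnotation | None] = {}
    impacts = []
    for ev in events:
        if ev.long_tx not in orf_cache:
            orf_cache[ev.long_tx] = orf_domain.find_longest_orf(
                sequences[ev.long_tx], ev.long_tx, min_codons=min_codons
            )
        orf = orf_cache[ev.long_tx]
        impacts.append(
            orf_domain.event_domain_impact(ev, orf, hits_by_protein.get(ev.long_tx, []))
        )
    return impacts


def frame_partition(impacts: list[orf_domain.EventImpact]) -> dict[str, int]:
    counts = {"preserved": 0, "shifted": 0, "not_applicable": 0}
    for imp in impacts:
        counts[imp.frame] += 1
    counts["cds_total"] = counts["preserved"] + counts["shifted"]
    return counts


def read_go_table(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    annot: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        annot.setdefault(gene, set()).add(term)
    return annot


def write_go_table(annot: dict[str, set[str]], path) -> None:
    rows = [(g, t) for g in sorted(annot) for t in sorted(annot[g])]
    pd.DataFrame(rows, columns=["gene_id", "go_term"]).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle; returns a result dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": []}

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return outdir / name

    truths = None
    models = None
    if config.generator is not None:
        logger.info("stage: simulate")
        gen = dataclasses.replace(config.generator, seed=config.seed)
        models, records, truths = generate_dataset(gen)
        io.write_fasta(records, emit("transcripts.fasta"))
        write_gff3(models, emit("models.gff3"))
        write_truth_tsv(truths, emit("truth_events.tsv"))
        counts = simulate_expression(models, gen)
        write_counts_tsv(counts, emit("counts.tsv"))
        hits, orfs = simulate_domains(models, gen)
        write_domain_table(hits, orfs, emit("domains.domtbl"))
        annot = simulate_go_terms(models, gen)
        write_go_table(annot, emit("go_annotation.tsv"))
        clusters = io.clusters_from_records(records)
        manifest["generator"] = dataclasses.asdict(gen)
    else:
        logger.info("stage: read input fasta %s", config.fasta)
        clusters = io.read_clusters(config.fasta)
        hits = (
            orf_domain.read_domain_table(config.domain_table) if config.domain_table else []
        )
        annot = read_go_table(config.go_table) if config.go_table else {}
        counts = (
            pd.read_csv(config.counts_table, sep="\t") if config.counts_table else None
        )
    manifest["align_params"] = dataclasses.asdict(config.align_params)
    manifest["caller_options"] = dataclasses.asdict(config.caller_options)
    manifest["orf_min_codons"] = config.orf_min_codons

    logger.info("stage: align + call (%d clusters)", len(clusters))
    _chains, events, sequences = detect_events(
        clusters, config.align_params, config.caller_options
    )
    as_caller.write_events_tsv(events, emit("events.tsv"))
    as_caller.write_events_bed(events, emit("events.bed"))

    summary = as_caller.summarize_types(events)
    pd.DataFrame(
        [
            {
                "as_type": t,
                "count": summary.counts.get(t, 0),
                "percent": summary.percentages.get(t, 0),
            }
            for t in as_caller.AS_TYPES
        ]
    ).to_csv(emit("type_summary.tsv"), sep="\t", index=False)
    with open(emit("type_summary.txt"), "w") as fh:
        fh.write(f"total events\t{summary.total_events}\n")
        for t in as_caller.AS_TYPES:
            fh.write(f"{t}\t{summary.counts.get(t, 0)}\t{summary.percentages.get(t, 0)}%\n")
        fh.write(f"mean region length\t{summary.mean_region_length:.1f}\n")
        fh.write(f"single-event genes\t{summary.single_event_genes}\n")
        fh.write(f"multi-event genes\t{summary.multi_event_genes}\n")

    logger.info("stage: impact")
    hits_by_protein: dict[str, list[orf_domain.DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    impacts = compute_impacts(events, sequences, hits_by_protein, config.orf_min_codons)
    pd.DataFrame(orf_domain.impacts_to_rows(impacts)).to_csv(
        emit("impacts.tsv"), sep="\t", index=False
    )
    frames = frame_partition(impacts)

    logger.info("stage: enrichment")
    as_genes = {ev.gene_id for ev in events}
    all_genes = {c.gene_id for c in clusters}
    presence = gene_domain_presence(hits)
    genes_with_domains = set(presence)
    as_dom = as_genes & genes_with_domains
    const_dom = genes_with_domains - as_genes
    domain_counts: dict[str, tuple[int, int]] = {}
    for gene, accs in presence.items():
        for acc in accs:
            k_as, k_c = domain_counts.get(acc, (0, 0))
            if gene in as_genes:
                domain_counts[acc] = (k_as + 1, k_c)
            else:
                domain_counts[acc] = (k_as, k_c + 1)
    dom_results = []
    if as_dom and const_dom:
        dom_results = enrichment.domain_as_enrichment(
            domain_counts, len(as_dom), len(const_dom)
        )
        pd.DataFrame(enrichment.results_to_rows(dom_results)).to_csv(
            emit("domain_enrichment.tsv"), sep="\t", index=False
        )
    go_results = []
    if annot and as_genes:
        go_results = enrichment.go_enrichment_bh(as_genes & all_genes, annot, all_genes)
        pd.DataFrame(enrichment.results_to_rows(go_results)).to_csv(
            emit("go_enrichment.tsv"), sep="\t", index=False
        )

    expr_summary = None
    if counts is not None and len(counts):
        logger.info("stage: expression")
        table = expression.rpkm_table(counts)
        sense = [f for f in table["feature_id"] if not f.rsplit("_", 1)[-1].startswith("as")]
        groups = {
            "as_genes": {f for f in sense if f.rsplit("_", 1)[0] in as_genes},
            "all_genes": set(sense),
            "antisense": {
                f for f in table["feature_id"] if f.rsplit("_", 1)[-1].startswith("as")
            },
        }
        expr_summary, dist = expression.group_distribution_summary(table, groups)
        expr_summary.to_csv(emit("expression_summary.tsv"), sep="\t", index=False)
        dist.to_csv(emit("expression_distribution.tsv"), sep="\t", index=False)

    report = None
    if truths is not None:
        logger.info("stage: concordance")
        report = concordance.compare_event_sets(events, truths, tol=config.caller_options.dedup_tol)
        pd.DataFrame(concordance.report_to_rows(report)).to_csv(
            emit("concordance.tsv"), sep="\t", index=False
        )

    manifest["n_clusters"] = len(clusters)
    manifest["n_events"] = len(events)
    manifest["frame_partition"] = frames
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "clusters": clusters,
        "events": events,
        "summary": summary,
        "impacts": impacts,
        "frame_partition": frames,
        "domain_enrichment": dom_results,
        "go_enrichment": go_results,
        "expression_summary": expr_summary,
        "concordance": report,
        "truth": truths,
        "models": models,
    }
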