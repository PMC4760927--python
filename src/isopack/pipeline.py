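"""End-to-end assembly: reads -> splicing graphs -> packed paths -> transcripts."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .assembly import (
    Transcript,
    items_to_transcripts,
    single_node_transcript,
    write_fasta,
    write_path_report,
)
from .balance import BalanceParams, prepare
from .build import BuildConfig, build_graphs
from .graph import SplicingGraph, break_cycles
from .packing import run as run_packing

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of a full assembly run (defaults as published)."""

    k: int = 25
    alpha: float = 10.0
    beta: float = 1.4
    gamma: float = 1.5
    min_kmer_count: int = 2
    min_junction_reads: int = 2
    tip_length_factor: float = 2.0
    strand_mode: str = "stranded"
    min_transcript_length: int = 200
    seed: int = 0

    def build_config(self) -> BuildConfig:
        return BuildConfig(
            k=self.k,
            min_kmer_count=self.min_kmer_count,
            min_junction_reads=self.min_junction_reads,
            tip_length_factor=self.tip_length_factor,
            strand_mode=self.strand_mode,
        )

    def balance_params(self) -> BalanceParams:
        return BalanceParams(alpha=self.alpha, beta=self.beta, gamma=self.gamma)


def assemble_component(
    graph: SplicingGraph,
    config: RunConfig,
    gene_id: str,
    mean_read_length: float | None = None,
) -> list[Transcript]:
    """Balance and pack one per-gene splicing graph into transcripts."""
    if graph.n_edges() == 0:
        nodes = graph.nodes
        if len(nodes) != 1:
            log.warning("component %s has %d disconnected nodes", gene_id, len(nodes))
        out: list[Transcript] = []
        for i, n in enumerate(nodes):
            out.extend(
                single_node_transcript(
                    graph, n, f"{gene_id}" if len(nodes) == 1 else f"{gene_id}_{i}",
                    min_length=config.min_transcript_length,
                    mean_read_length=mean_read_length,
                    k=config.k,
                )
            )
        return out
    g = break_cycles(graph)
    balanced = prepare(g, config.balance_params())
    _, items = run_packing(balanced)
    return items_to_transcripts(
        balanced,
        items,
        k=config.k,
        gene_id=gene_id,
        min_length=config.min_transcript_length,
        mean_read_length=mean_read_length,
    )


def assemble_reads(
    reads: Sequence[str], config: RunConfig | None = None
) -> list[Transcript]:
    """Assemble raw read sequences into transcripts across all genes."""
    config = config or RunConfig()
    components = build_graphs(reads, config.build_config())
    mean_rl = sum(len(r) for r in reads) / len(reads)
    transcripts: list[Transcript] = []
    for i, comp in enumerate(components):
        transcripts.extend(
            assemble_component(
                comp, config, gene_id=f"comp{i + 1}", mean_read_length=mean_rl
            )
        )
    return transcripts


def assemble_to_dir(
    reads: Sequence[str],
    out_dir: str | Path,
    config: RunConfig | None = None,
    inputs: Sequence[str] = (),
) -> list[Transcript]:
    """Assemble and write transcripts.fa, paths.tsv and a run manifest."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts = assemble_reads(reads, config)
    fa = out / "transcripts.fa"
    tsv = out / "paths.tsv"
    manifest = out / "manifest.json"
    try:
        if transcripts:
            with open(fa, "w") as fh:
                write_fasta(transcripts, fh)
        with open(tsv, "w") as fh:
            write_path_report(transcripts, fh)
        with open(manifest, "w") as fh:
            json.dump(
                {
                    "version": __version__,
                    "config": asdict(config),
                    "inputs": list(inputs),
                    "n_reads": len(reads),
                    "n_transcripts": len(transcripts),
                    "n_genes": len({t.gene_id for t in transcripts}),
                },
                fh,
                indent=2,
            )
            fh.write("\n")
    except Exception:
        for p in (fa, tsv, manifest):  # no partial outputs
            p.unlink(missing_ok=True)
        raise
    return transcripts


def simulate_and_score(
    sim_config,
    run_config: RunConfig | None = None,
    specs=None,
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.95,
    max_indel: float = 0.005,
):
    """Simulate genes and reads, assemble, and score against the truth.

    Returns the evaluation report (with simulation provenance attached)
    plus the gene models and assembled transcripts for inspection.
    """
    from .evaluate import evaluate
    from .sim import make_genes, simulate_reads

    run_config = run_config or RunConfig()
    genes = make_genes(sim_config, specs=specs, k=run_config.k)
    reads, _truth = simulate_reads(genes, sim_config)
    transcripts = assemble_reads([seq for _, seq in reads], run_config)
    assembled = {t.transcript_id: t.sequence for t in transcripts}
    reference = {
        g.isoform_id(i): g.isoform_seq(i)
        for g in genes
        for i in range(len(g.isoforms))
    }
    if not assembled:
        raise RuntimeError("assembly produced no transcripts to evaluate")
    report = evaluate(
        assembled,
        reference,
        identity_threshold=identity_threshold,
        coverage_threshold=coverage_threshold,
        max_indel=max_indel,
    )
    report.provenance.update(
        {
            "seed": sim_config.seed,
            "n_genes": sim_config.n_genes,
            "sim_config": asdict(sim_config),
            "run_config": asdict(run_config),
        }
    )
    return report, genes, transcripts
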