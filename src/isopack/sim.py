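"""Synthetic ground truth: toy genes with splicing isoforms and simulated reads.

Each gene is a handful of random exon sequences plus an isoform set
realizing one alternative-splicing event (skipped exon, retained
intron, mutually exclusive exons) or a single isoform.  Expression is a
per-isoform read depth, by default drawn log-uniformly across a wide
dynamic range to mimic the spread of real transcript abundances.
Fragments start uniformly along the isoform (no positional bias), so
expected per-base coverage is analytic; substitution errors are i.i.d.
Cross-gene k-mer collisions are rejected at generation time, so each
gene must come out of the graph builder as its own component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from .build import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

EVENT_TYPES = ("single", "skipped_exon", "retained_intron", "mutually_exclusive")


@dataclass(frozen=True)
class GeneSpec:
    """Requested structure for one gene; None fields are randomized."""

    event_type: str = "skipped_exon"
    exon_lengths: tuple[int, ...] | None = None
    depths: tuple[float, ...] | None = None  # one per isoform


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    exons: tuple[str, ...]
    isoforms: tuple[tuple[int, ...], ...]
    event_type: str
    expression: tuple[float, ...]  # reads-per-base depth per isoform

    def isoform_seq(self, i: int) -> str:
        return "".join(self.exons[e] for e in self.isoforms[i])

    def isoform_id(self, i: int) -> str:
        return f"{self.gene_id}.iso{i + 1}"


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 10
    event_type: str = "skipped_exon"
    exon_length_range: tuple[int, int] = (150, 350)
    read_length: int = 100
    depth_range: tuple[float, float] = (5.0, 200.0)
    error_rate: float = 0.0
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    stranded: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.exon_length_range[0] <= 0 or self.depth_range[0] <= 0:
            raise ValueError("ranges must be positive")


def _isoform_structure(event_type: str, n_exons: int) -> tuple[tuple[int, ...], ...]:
    if event_type == "single":
        return (tuple(range(n_exons)),)
    if event_type in ("skipped_exon", "retained_intron"):
        if n_exons < 3:
            raise ValueError(f"{event_type} needs at least 3 exons")
        full = tuple(range(n_exons))
        mid = n_exons // 2
        return (full, full[:mid] + full[mid + 1:])
    if event_type == "mutually_exclusive":
        if n_exons < 4:
            raise ValueError("mutually_exclusive needs at least 4 exons")
        full = list(range(n_exons))
        a, b = n_exons // 2 - 1, n_exons // 2
        iso1 = tuple(e for e in full if e != b)
        iso2 = tuple(e for e in full if e != a)
        return (iso1, iso2)
    raise ValueError(f"unknown event type {event_type!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_gene(
    rng: np.random.Generator,
    spec: GeneSpec,
    config: SimConfig,
    gene_id: str = "g1",
) -> GeneModel:
    """One gene realizing the requested event with random exon sequences."""
    n_exons = (
        len(spec.exon_lengths)
        if spec.exon_lengths is not None
        else {"single": 3, "skipped_exon": 3, "retained_intron": 3,
              "mutually_exclusive": 4}[spec.event_type]
    )
    isoforms = _isoform_structure(spec.event_type, n_exons)
    lengths = spec.exon_lengths or tuple(
        int(rng.integers(*config.exon_length_range)) for _ in range(n_exons)
    )
    exons = tuple(_random_seq(rng, L) for L in lengths)
    if spec.depths is not None:
        if len(spec.depths) != len(isoforms):
            raise ValueError("one depth per isoform required")
        depths = tuple(float(d) for d in spec.depths)
    else:
        lo, hi = config.depth_range
        depths = tuple(
            float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
            for _ in isoforms
        )
    return GeneModel(
        gene_id=gene_id,
        exons=exons,
        isoforms=isoforms,
        event_type=spec.event_type,
        expression=depths,
    )


def _gene_kmers(gene: GeneModel, k: int) -> set[str]:
    kms: set[str] = set()
    for i in range(len(gene.isoforms)):
        seq = gene.isoform_seq(i)
        for j in range(len(seq) - k + 1):
            kms.add(seq[j : j + k])
            kms.add(revcomp(seq[j : j + k]))
    return kms


def make_genes(
    config: SimConfig,
    specs: Sequence[GeneSpec] | None = None,
    k: int = 25,
    max_tries: int = 50,
) -> list[GeneModel]:
    """A gene set with no shared k-mers across genes (rejection sampling)."""
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs = [GeneSpec(event_type=config.event_type)] * config.n_genes
    seen: set[str] = set()
    genes: list[GeneModel] = []
    for idx, spec in enumerate(specs):
        for _ in range(max_tries):
            gene = make_gene(rng, spec, config, gene_id=f"g{idx + 1}")
            kms = _gene_kmers(gene, k)
            if not (kms & seen):
                seen |= kms
                genes.append(gene)
                break
        else:
            raise RuntimeError(f"could not draw gene {idx + 1} without k-mer overlap")
    return genes


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    genes: Sequence[GeneModel], config: SimConfig
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Draw reads with known provenance.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)``
    pairs (two entries per fragment in paired mode, ids suffixed /1 and
    /2) and truth rows are ``(read_id, gene_id, isoform_id)``.  Fragment
    count per isoform = round(depth * isoform_length / bases_per_fragment).
    """
    rng = np.random.default_rng(config.seed + 1)
    rl = config.read_length
    reads: list[tuple[str, str]] = []
    truth: list[tuple[str, str, str]] = []
    for gene in genes:
        for i in range(len(gene.isoforms)):
            iso = gene.isoform_seq(i)
            iso_id = gene.isoform_id(i)
            L = len(iso)
            if rl > L:
                raise ValueError(
                    f"read length {rl} exceeds isoform {iso_id} length {L}"
                )
            yield_per_frag = 2 * rl if config.paired else rl
            n_frags = round(gene.expression[i] * L / yield_per_frag)
            for f in range(n_frags):
                if config.paired:
                    flen = int(
                        np.clip(
                            rng.normal(config.fragment_mean, config.fragment_sd),
                            rl,
                            L,
                        )
                    )
                else:
                    flen = rl
                start = int(rng.integers(0, L - flen + 1))
                frag = iso[start : start + flen]
                flip = (not config.stranded) and rng.random() < 0.5
                rid = f"{iso_id}:{f}"
                if config.paired:
                    template = revcomp(frag) if flip else frag
                    left, right = template[:rl], revcomp(template[-rl:])
                    reads.append((rid + "/1", _mutate(rng, left, config.error_rate)))
                    reads.append((rid + "/2", _mutate(rng, right, config.error_rate)))
                    truth.append((rid + "/1", gene.gene_id, iso_id))
                    truth.append((rid + "/2", gene.gene_id, iso_id))
                else:
                    seq = revcomp(frag) if flip else frag
                    reads.append((rid, _mutate(rng, seq, config.error_rate)))
                    truth.append((rid, gene.gene_id, iso_id))
    if not reads:
        raise ValueError("simulation produced zero reads")
    return reads, truth


def write_reference_fasta(genes: Sequence[GeneModel], fh: TextIO) -> None:
    for gene in genes:
        for i in range(len(gene.isoforms)):
            fh.write(f">{gene.isoform_id(i)}\n")
            seq = gene.isoform_seq(i)
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")


def write_truth_table(genes: Sequence[GeneModel], fh: TextIO) -> None:
    fh.write("gene_id\tisoform_id\tevent_type\tlength\tdepth\n")
    for gene in genes:
        for i in range(len(gene.isoforms)):
            fh.write(
                f"{gene.gene_id}\t{gene.isoform_id(i)}\t{gene.event_type}\t"
                f"{len(gene.isoform_seq(i))}\t{gene.expression[i]:g}\n"
            )


def write_reads_fastq(reads: Sequence[tuple[str, str]], fh: TextIO) -> None:
    """FASTQ with constant quality 'I' (simulated reads carry no error model
    beyond the substitution rate)."""
    for rid, seq in reads:
        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
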