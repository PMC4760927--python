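"""k-mer front end: counting, collapsing, junction weighting, trimming."""

import numpy as np
import pytest

from isopack import BuildConfig, build_graphs, count_kmers, max_incompatible_set, topological_order
from isopack.build import (
    collapse_linear_paths,
    revcomp,
    trim_and_split,
    weight_junctions,
    _recollapse,
)
from isopack.sim import GeneSpec, SimConfig, make_genes, simulate_reads


def tile_reads(seq: str, read_len: int, step: int = 1) -> list[str]:
    return [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]


@pytest.fixture(scope="module")
def skipped_exon_gene():
    cfg = SimConfig(n_genes=1, seed=5)
    [gene] = make_genes(cfg, specs=[GeneSpec("skipped_exon", depths=(50.0, 10.0))])
    return gene


class TestCountKmers:
    def test_direct_window_count(self):
        kg = count_kmers(["ACGTACGTACGTACGTA"], BuildConfig(k=16))
        assert kg.kmer_count == {"ACGTACGTACGTACGT": 1, "CGTACGTACGTACGTA": 1}

    def test_duplicate_reads_double_counts(self):
        r = "ACGTACGTACGTACGTACGT"
        once = count_kmers([r], BuildConfig(k=16)).kmer_count
        twice = count_kmers([r, r], BuildConfig(k=16)).kmer_count
        assert twice == {km: 2 * c for km, c in once.items()}

    def test_tiling_reads_recover_all_windows(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        k = 25
        kg = count_kmers(tile_reads(seq, 100), BuildConfig(k=k))
        assert len(kg.kmer_count) == len({seq[i:i+k] for i in range(500 - k + 1)})

    def test_non_acgt_kmers_dropped(self):
        kg = count_kmers(["ACGTN" + "A" * 20], BuildConfig(k=20))
        assert all("N" not in km for km in kg.kmer_count)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            count_kmers([], BuildConfig())

    def test_k_longer_than_every_read_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["ACGT" * 5], BuildConfig(k=25))


class TestCollapse:
    def test_single_chain_collapses_to_one_node(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        cfg = BuildConfig(k=25, min_kmer_count=0)
        kg = count_kmers(tile_reads(seq, 75), cfg)
        g = collapse_linear_paths(kg, cfg)
        assert g.n_nodes() == 1
        assert g.n_edges() == 0
        assert g.node_seq(0) == seq

    def test_skipped_exon_locus_forms_bubble(self, skipped_exon_gene):
        gene = skipped_exon_gene
        cfg = BuildConfig(k=25, min_kmer_count=0)
        reads = tile_reads(gene.isoform_seq(0), 100) + tile_reads(gene.isoform_seq(1), 100)
        kg = count_kmers(reads, cfg)
        g = collapse_linear_paths(kg, cfg)
        assert g.n_nodes() >= 3
        assert g.n_edges() == 4
        order = topological_order(g)
        assert len(max_incompatible_set(g, order)) == 2

    def test_recollapse_is_idempotent(self, skipped_exon_gene):
        gene = skipped_exon_gene
        cfg = BuildConfig(k=25, min_kmer_count=0)
        reads = tile_reads(gene.isoform_seq(0), 100)
        g = collapse_linear_paths(count_kmers(reads, cfg), cfg)
        g2 = _recollapse(g, cfg.k)
        assert g2.n_nodes() == g.n_nodes()
        assert g2.edges == g.edges


class TestWeightJunctions:
    def test_spanning_reads_counted_exactly(self, skipped_exon_gene):
        gene = skipped_exon_gene
        cfg = BuildConfig(k=25, min_kmer_count=0, min_junction_reads=0)
        reads = tile_reads(gene.isoform_seq(0), 100) + tile_reads(gene.isoform_seq(1), 100)
        kg = count_kmers(reads, cfg)
        g = weight_junctions(collapse_linear_paths(kg, cfg), reads, cfg)
        # brute-force oracle: count reads containing each junction window
        from isopack.build import junction_window

        for u, v in g.edges:
            win = junction_window(g, u, v, cfg.k)
            expected = sum(r.count(win) for r in reads)
            assert g.edge_weight(u, v) == expected
            assert expected > 0

    def test_two_coverage_levels_separate_on_junctions(self, skipped_exon_gene):
        gene = skipped_exon_gene
        cfg = BuildConfig(k=25)
        sim = SimConfig(n_genes=1, seed=8)
        reads = [s for _, s in simulate_reads([gene], sim)[0]]
        comps = build_graphs(reads, cfg)
        assert len(comps) == 1
        g = comps[0]
        weights = sorted(g.edge_weight(u, v) for u, v in g.edges)
        # inclusion junctions ~50x, skip junction ~10x: clear separation
        assert weights[0] < weights[-1] / 2

    def test_read_away_from_junctions_contributes_nothing(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        cfg = BuildConfig(k=25, min_kmer_count=0, min_junction_reads=0)
        kg = count_kmers(tile_reads(seq, 60), cfg)
        g = collapse_linear_paths(kg, cfg)
        g2 = weight_junctions(g, ["T" * 60], cfg)
        assert g2.n_edges() == 0  # single node, no junctions at all


class TestTrimAndSplit:
    def test_weak_spur_removed_leaving_linear_gene(self):
        from isopack import SplicingGraph

        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        g = SplicingGraph()
        g.add_node(0, seq=seq[:212], cov=50)
        g.add_node(1, seq=seq[188:], cov=50)   # shares the k-1 overlap with 0
        g.add_node(2, seq="G" * 30, cov=1)     # short, weak spur
        g.add_edge(0, 1, 50)
        g.add_edge(0, 2, 1)
        cfg = BuildConfig(k=25, min_junction_reads=3)
        comps = trim_and_split(g, cfg)
        assert len(comps) == 1
        [comp] = comps
        # spur and its weak junction gone; the linear remainder re-collapsed
        assert comp.n_nodes() == 1
        assert comp.node_seq(0) == seq

    def test_unrelated_loci_split_into_components(self):
        sim = SimConfig(n_genes=2, event_type="single", seed=9)
        genes = make_genes(sim)
        reads = [s for _, s in simulate_reads(genes, sim)[0]]
        comps = build_graphs(reads, BuildConfig())
        assert len(comps) == 2

    def test_clean_single_isoform_graph_is_fixed_point(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        cfg = BuildConfig(k=25, min_kmer_count=0, min_junction_reads=0)
        g = collapse_linear_paths(count_kmers(tile_reads(seq, 75), cfg), cfg)
        comps = trim_and_split(g, cfg)
        assert len(comps) == 1
        assert comps[0].node_seq(0) == seq


class TestEndToEnd:
    def test_single_isoform_gene_reconstructed_exactly(self):
        sim = SimConfig(n_genes=1, event_type="single", seed=12)
        genes = make_genes(sim)
        truth = genes[0].isoform_seq(0)
        reads = tile_reads(truth, 100) * 2  # every k-mer passes the noise floor
        comps = build_graphs(reads, BuildConfig())
        assert len(comps) == 1
        assert comps[0].n_nodes() == 1
        assert comps[0].node_seq(0) == truth

    def test_sampled_reads_recover_almost_all_of_the_transcript(self):
        sim = SimConfig(n_genes=1, event_type="single", seed=12)
        genes = make_genes(sim)
        truth = genes[0].isoform_seq(0)
        reads = [s for _, s in simulate_reads(genes, sim)[0]]
        [comp] = build_graphs(reads, BuildConfig())
        assert comp.n_nodes() == 1
        seq = comp.node_seq(0)
        # terminal bases can drop below the k-mer noise floor
        assert seq in truth
        assert len(seq) >= 0.99 * len(truth)

    def test_two_isoform_gene_cut_cardinality_two(self):
        sim = SimConfig(n_genes=1, seed=21)
        genes = make_genes(sim, specs=[GeneSpec("skipped_exon", depths=(50.0, 10.0))])
        reads = [s for _, s in simulate_reads(genes, sim)[0]]
        [g] = build_graphs(reads, BuildConfig())
        cut = max_incompatible_set(g, topological_order(g))
        assert len(cut) == 2

    def test_no_zero_weight_edges_emitted(self):
        sim = SimConfig(n_genes=3, seed=30)
        genes = make_genes(sim)
        reads = [s for _, s in simulate_reads(genes, sim)[0]]
        for g in build_graphs(reads, BuildConfig()):
            for u, v in g.edges:
                assert g.edge_weight(u, v) > 0

    def test_kmer_mass_conserved_in_counting(self):
        reads = ["ACGTACGTACGTACGTACGTACGTACGT", "TTTTTTTTTTTTTTTTTTTTTTTTTT"]
        cfg = BuildConfig(k=25, min_kmer_count=0)
        kg = count_kmers(reads, cfg)
        total_windows = sum(len(r) - cfg.k + 1 for r in reads)
        assert sum(kg.kmer_count.values()) == total_windows

    def test_unstranded_reads_yield_single_component(self):
        sim = SimConfig(n_genes=1, event_type="single", stranded=False, seed=15)
        genes = make_genes(sim)
        truth = genes[0].isoform_seq(0)
        # mixed-orientation reads, deterministic tiling of both strands
        reads = tile_reads(truth, 100) + tile_reads(revcomp(truth), 100)
        comps = build_graphs(reads, BuildConfig(strand_mode="unstranded"))
        assert len(comps) == 1
        seq = comps[0].node_seq(0)
        assert seq == truth or seq == revcomp(truth)
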