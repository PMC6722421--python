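"""Gene-family clustering on seed genomes.

First step of the SCG extraction strategy: a small random subset of genomes
("seeds") is fully clustered into gene families via all-vs-all protein
similarity search, score normalization for sequence length, per-gene
best-bidirectional-hit score cutoffs, and Markov clustering (MCL) of the
resulting weighted graph.

The built-in pairwise scorer is Smith-Waterman on amino acids (BLOSUM62,
affine gaps 11/1) with Karlin-Altschul scaling to bit scores. An optional
k-mer prefilter skips pairs sharing no exact k-mer; it is a performance
guardrail, safe for the divergences at which family membership is decided.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Gene, Genome

logger = logging.getLogger(__name__)

# gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041
_LN2 = math.log(2.0)


def bit_score(raw: float) -> float:
    """Karlin-Altschul bit score of a raw BLOSUM62 local-alignment score."""
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / _LN2


def make_protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


@dataclass
class GeneFamily:
    """A cluster of homologous genes over the seed genomes.

    ``seed_sc_presence`` counts the seed genomes containing exactly one
    member of the family (single-copy presence among seeds).
    """

    family_id: str
    members: list[tuple[str, str]]  # (gene_id, genome_id)
    seed_sc_presence: int

    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.members]


def select_seed_genomes(genomes: list[Genome], n_seed: int, rng_seed: int) -> list[str]:
    """Uniform random sample (without replacement) of genome ids, reproducible."""
    if not genomes:
        raise ValueError("no genomes to select seeds from")
    if n_seed <= 0:
        raise ValueError(f"n_seed must be positive, got {n_seed}")
    ids = sorted(g.genome_id for g in genomes)
    rng = np.random.default_rng(rng_seed)
    n = min(n_seed, len(ids))
    chosen = rng.choice(len(ids), size=n, replace=False)
    return sorted(ids[i] for i in chosen)


def _kmer_candidate_pairs(genes: list[Gene], k: int) -> set[tuple[int, int]]:
    """Index i<j pairs of genes sharing at least one exact amino-acid k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genes):
        for kmer in {g.aa_seq[p : p + k] for p in range(len(g.aa_seq) - k + 1)}:
            index[kmer].append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) < 2:
            continue
        for a in range(len(hits)):
            for b in range(a + 1, len(hits)):
                pairs.add((hits[a], hits[b]))
    return pairs


def score_gene_pairs(seed_genes: list[Gene], bit_floor: float = 25.0,
                     kmer_prefilter: bool = True, k: int = 5) -> nx.Graph:
    """All-vs-all protein similarity graph over the seed genes.

    Edges carry ``raw_score`` (bits) for every pair whose Smith-Waterman
    bit score exceeds ``bit_floor``. The scorer is symmetric, so each
    unordered pair is scored once (symmetrization by maximum is implicit).
    """
    if len(seed_genes) < 2:
        raise ValueError("need at least two genes")
    graph = nx.Graph()
    for g in seed_genes:
        graph.add_node(g.gene_id, genome_id=g.genome_id, length=len(g.aa_seq))
    aligner = make_protein_aligner("local")
    if kmer_prefilter:
        pairs = _kmer_candidate_pairs(seed_genes, k)
    else:
        n = len(seed_genes)
        pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
    for i, j in pairs:
        a, b = seed_genes[i], seed_genes[j]
        raw = aligner.score(a.aa_seq, b.aa_seq)
        bits = bit_score(raw)
        if bits > bit_floor:
            graph.add_edge(a.gene_id, b.gene_id, raw_score=bits)
    return graph


def _fit_loglog(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares y ~ a*x + b; degenerate x collapses to the mean."""
    if len(x) == 0:
        return 0.0, 0.0
    if np.var(x) < 1e-12:
        return 0.0, float(np.mean(y))
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def normalize_and_filter_scores(graph: nx.Graph, min_fit_points: int = 5) -> nx.Graph:
    """Length-normalize scores per genome pair and apply per-gene BBH cutoffs.

    For each ordered genome pair the best hit of every gene is collected and
    log10(raw) is regressed on log10(len_a * len_b); the normalized score of
    an edge is raw / 10^fitted (max over the two directed fits). Each gene's
    cutoff is the smallest normalized score among its reciprocal best hits
    in other genomes; edges below a gene's cutoff are dropped.
    """
    if graph.number_of_edges() == 0:
        return graph.copy()
    genome_of = nx.get_node_attributes(graph, "genome_id")
    length_of = nx.get_node_attributes(graph, "length")

    # best hit of each gene in each other genome (by raw score)
    best_hit: dict[tuple[str, str], tuple[str, float]] = {}
    for u, v, d in graph.edges(data=True):
        s = d["raw_score"]
        for src, dst in ((u, v), (v, u)):
            key = (src, genome_of[dst])
            if key not in best_hit or s > best_hit[key][1] or (
                    s == best_hit[key][1] and dst < best_hit[key][0]):
                best_hit[key] = (dst, s)

    # per ordered genome pair, regression points from best-hit edges
    points: dict[tuple[str, str], list[tuple[float, float]]] = defaultdict(list)
    for (src, dst_genome), (dst, s) in best_hit.items():
        x = math.log10(length_of[src] * length_of[dst])
        points[(genome_of[src], dst_genome)].append((x, math.log10(s)))

    all_pts = [p for pts in points.values() for p in pts]
    gx = np.array([p[0] for p in all_pts])
    gy = np.array([p[1] for p in all_pts])
    global_fit = _fit_loglog(gx, gy)
    fits: dict[tuple[str, str], tuple[float, float]] = {}
    for pair, pts in points.items():
        if len(pts) >= min_fit_points:
            fits[pair] = _fit_loglog(np.array([p[0] for p in pts]),
                                     np.array([p[1] for p in pts]))
        else:
            fits[pair] = global_fit

    out = nx.Graph()
    out.add_nodes_from(graph.nodes(data=True))
    for u, v, d in graph.edges(data=True):
        raw = d["raw_score"]
        x = math.log10(length_of[u] * length_of[v])
        norms = []
        for pair in ((genome_of[u], genome_of[v]), (genome_of[v], genome_of[u])):
            a, b = fits.get(pair, global_fit)
            norms.append(raw / 10 ** (a * x + b))
        out.add_edge(u, v, raw_score=raw, norm_score=max(norms))

    # reciprocal-best-hit cutoffs on normalized scores
    nbest: dict[tuple[str, str], tuple[str, float]] = {}
    for u, v, d in out.edges(data=True):
        s = d["norm_score"]
        for src, dst in ((u, v), (v, u)):
            if genome_of[src] == genome_of[dst]:
                continue
            key = (src, genome_of[dst])
            if key not in nbest or s > nbest[key][1] or (
                    s == nbest[key][1] and dst < nbest[key][0]):
                nbest[key] = (dst, s)
    cutoff: dict[str, float] = {}
    for (src, dst_genome), (dst, s) in nbest.items():
        back = nbest.get((dst, genome_of[src]))
        if back is not None and back[0] == src:  # reciprocal
            cutoff[src] = min(cutoff.get(src, math.inf), s)
    drop = [(u, v) for u, v, d in out.edges(data=True)
            if d["norm_score"] < cutoff.get(u, 0.0)
            or d["norm_score"] < cutoff.get(v, 0.0)]
    out.remove_edges_from(drop)
    return out


def write_graph_abc(graph: nx.Graph, path) -> None:
    """Dump the similarity graph as an edge list (node node weight)."""
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            w = d.get("norm_score", d.get("raw_score", 1.0))
            fh.write(f"{u}\t{v}\t{w:.6f}\n")


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5,
                prune: float = 1e-5, tol: float = 1e-6,
                max_iter: int = 100) -> list[GeneFamily]:
    """Markov clustering of the weighted similarity graph into gene families.

    Self-loops are added (weight = max incident edge weight, 1 for isolates),
    the column-stochastic matrix is iterated through expansion (squaring) and
    inflation (elementwise power + renormalization) with pruning, and
    families are the connected components of the attractor graph.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    max_w = np.zeros(n)
    for u, v, d in graph.edges(data=True):
        w = d.get("norm_score", d.get("raw_score", 1.0))
        i, j = idx[u], idx[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        max_w[i] = max(max_w[i], w)
        max_w[j] = max(max_w[j], w)
    loops = np.where(max_w > 0, max_w, 1.0)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loops)
    m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def _colnorm(mat: sp.csc_matrix) -> sp.csc_matrix:
        sums = np.asarray(mat.sum(axis=0)).ravel()
        sums[sums == 0] = 1.0
        return mat @ sp.diags(1.0 / sums)

    m = _colnorm(m)
    for _ in range(max_iter):
        expanded = (m @ m).tocsc()
        expanded.data **= inflation
        expanded.data[expanded.data < prune] = 0.0
        expanded.eliminate_zeros()
        expanded = _colnorm(expanded)
        change = abs(expanded - m).max() if (expanded - m).nnz else 0.0
        m = expanded
        if change < tol:
            break

    attractor = (m + m.T).tocsr()
    n_comp, labels = sp.csgraph.connected_components(attractor, directed=False)
    comps: dict[int, list[str]] = defaultdict(list)
    for node, lab in zip(nodes, labels):
        comps[lab].append(node)
    genome_of = nx.get_node_attributes(graph, "genome_id")
    groups = sorted(comps.values(), key=lambda ms: (-len(ms), min(ms)))
    families = []
    for i, members in enumerate(groups):
        members = sorted(members)
        per_genome: dict[str, int] = defaultdict(int)
        for g in members:
            per_genome[genome_of[g]] += 1
        sc = sum(1 for c in per_genome.values() if c == 1)
        families.append(GeneFamily(
            family_id=f"F{i + 1:05d}",
            members=[(g, genome_of[g]) for g in members],
            seed_sc_presence=sc))
    return families
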