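"""De novo species clustering at a CNI cutoff, diagnostics and classification.

Species are the connected components of the graph joining genome pairs whose
CNI is at or above the cutoff (nonhierarchical single-linkage clustering).
Each cluster gets exclusivity (every within-cluster CNI exceeds every
CNI from a member to an outsider) and transitivity (every within-cluster
CNI is at or above the cutoff) diagnostics; a cutoff scan re-clusters over a
grid and counts non-exclusive clusters. New genomes are classified against
one representative per species, which transitivity makes sufficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._align import align_protein_set
from .genome_io import Genome
from .scg_profiler import Profile, resolve_best_profile, score_genome_genes
from .supermatrix import CNIMatrix, back_translate_alignment

logger = logging.getLogger(__name__)


@dataclass
class SpeciesCluster:
    """A de novo species: members plus exclusivity/transitivity diagnostics."""

    cluster_id: str
    members: list[str]
    min_within_cni: Optional[float] = None   # undefined for singletons
    max_between_cni: Optional[float] = None  # undefined for single-cluster data
    nearest_cluster_id: Optional[str] = None
    exclusive: bool = True
    transitive: bool = True
    representative: Optional[str] = None


def cluster_single_linkage(cni: CNIMatrix, cni_cutoff: float) -> list[SpeciesCluster]:
    """Connected components of the CNI >= cutoff graph, deterministically labeled.

    Pairs with undefined CNI (no shared compared sites) contribute no edge.
    Cluster ids are assigned by decreasing size, then smallest member id.
    """
    vals = cni.values
    adj = np.nan_to_num(vals, nan=-1.0) >= cni_cutoff
    np.fill_diagonal(adj, False)
    n_comp, labels = sp.csgraph.connected_components(
        sp.csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for g, lab in zip(cni.genome_ids, labels):
        groups.setdefault(lab, []).append(g)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    return [SpeciesCluster(cluster_id=f"C{i + 1:03d}", members=sorted(ms))
            for i, ms in enumerate(ordered)]


def evaluate_exclusivity(clusters: list[SpeciesCluster], cni: CNIMatrix,
                         cni_cutoff: float) -> list[SpeciesCluster]:
    """Fill min-within / max-between CNI, nearest cluster and the flags."""
    idx = {g: i for i, g in enumerate(cni.genome_ids)}
    member_of = {g: c.cluster_id for c in clusters for g in c.members}
    vals = cni.values
    for c in clusters:
        mi = [idx[g] for g in c.members]
        if len(mi) >= 2:
            sub = vals[np.ix_(mi, mi)]
            within = sub[np.triu_indices(len(mi), k=1)]
            within = within[~np.isnan(within)]
            c.min_within_cni = float(within.min()) if within.size else None
        else:
            c.min_within_cni = None
        out = [i for g, i in idx.items() if member_of[g] != c.cluster_id]
        if out:
            between = vals[np.ix_(mi, out)]
            if np.all(np.isnan(between)):
                c.max_between_cni = None
                c.nearest_cluster_id = None
            else:
                flat = np.nanargmax(between)
                r, col = np.unravel_index(flat, between.shape)
                c.max_between_cni = float(between[r, col])
                c.nearest_cluster_id = member_of[cni.genome_ids[out[col]]]
        else:
            c.max_between_cni = None
            c.nearest_cluster_id = None
        if c.min_within_cni is None:
            c.exclusive = True
            c.transitive = True
        else:
            c.exclusive = (c.max_between_cni is None
                           or c.min_within_cni > c.max_between_cni)
            c.transitive = c.min_within_cni >= cni_cutoff
    return clusters


def scan_cutoffs(cni: CNIMatrix,
                 cutoff_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Re-cluster over a cutoff grid, counting non-exclusive clusters."""
    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(0.80, 0.9901, 0.005), 4)
    rows = []
    for cutoff in cutoff_grid:
        clusters = evaluate_exclusivity(
            cluster_single_linkage(cni, float(cutoff)), cni, float(cutoff))
        rows.append((float(cutoff), len(clusters),
                     sum(1 for c in clusters if not c.exclusive)))
    return pd.DataFrame(rows, columns=["cutoff", "n_clusters", "n_nonexclusive"])


def select_representatives(clusters: list[SpeciesCluster],
                           copy_matrix: pd.DataFrame) -> list[SpeciesCluster]:
    """Per cluster, the member with most SCGs present (ties: smallest id)."""
    present = (copy_matrix >= 1).sum(axis=1)
    for c in clusters:
        c.representative = min(c.members, key=lambda g: (-int(present.get(g, 0)), g))
    return clusters


# --- classification of new genomes -----------------------------------------

@dataclass
class ReferenceDB:
    """Everything needed to classify a new genome against named species."""

    profiles: list[Profile]               # cutoffs trained
    scg_ids: list[str]
    representatives: dict[str, str]       # cluster_id -> representative genome
    rep_genes: dict[str, dict[str, tuple[str, str]]]  # genome -> scg -> (aa, nt)
    cluster_names: dict[str, str] = field(default_factory=dict)
    completeness_min: float = 0.90


@dataclass(frozen=True)
class Assignment:
    status: str            # assigned | ambiguous | novel | unclassifiable
    clusters: tuple[str, ...]
    cnis: tuple[float, ...]
    nearest_cluster: Optional[str]
    nearest_cni: Optional[float]
    completeness: float
    names: tuple[str, ...] = ()


def _pairwise_scg_cni(query_genes: dict[str, tuple[str, str]],
                      rep_genes: dict[str, tuple[str, str]],
                      aligner: str = "star") -> Optional[float]:
    ident = comp = 0
    for scg in sorted(set(query_genes) & set(rep_genes)):
        (qa, qn), (ra, rn) = query_genes[scg], rep_genes[scg]
        aln = align_protein_set([qa, ra], method=aligner)
        ntq, ntr = back_translate_alignment(aln, [qn, rn])
        for a, b in zip(ntq, ntr):
            if a in "ACGT" and b in "ACGT":
                comp += 1
                if a == b:
                    ident += 1
    return ident / comp if comp else None


def classify_genome(query: Genome, ref: ReferenceDB, cni_cutoff: float = 0.94,
                    aligner: str = "star") -> Assignment:
    """Classify a genome against one representative per species.

    The query's SCGs are extracted with the trained profiles; pairwise CNI to
    each representative is computed over shared SCGs. CNI at or above the
    cutoff to exactly one representative assigns the species; to several,
    the call is flagged ambiguous (a transitivity violation); to none, the
    genome is a novel candidate species.
    """
    hits = resolve_best_profile(score_genome_genes(ref.profiles, query))
    cutoffs = {p.profile_id: p.cutoff for p in ref.profiles
               if p.cutoff is not None}
    gene_lookup = {g.gene_id: g for g in query.genes}
    best: dict[str, tuple[float, str]] = {}
    # small slack guards boundary hits against text-serialization rounding
    # of the profile scores (cutoffs often sit exactly on a training score)
    slack = 1e-3
    for h in hits:
        if h.profile_id not in cutoffs or h.score < cutoffs[h.profile_id] - slack:
            continue
        cur = best.get(h.profile_id)
        if cur is None or h.score > cur[0] or (h.score == cur[0]
                                               and h.gene_id < cur[1]):
            best[h.profile_id] = (h.score, h.gene_id)
    query_genes = {scg: (gene_lookup[gid].aa_seq, gene_lookup[gid].nt_seq)
                   for scg, (_, gid) in best.items() if scg in set(ref.scg_ids)}
    completeness = len(query_genes) / len(ref.scg_ids) if ref.scg_ids else 0.0
    if completeness <= ref.completeness_min:
        return Assignment(status="unclassifiable", clusters=(), cnis=(),
                          nearest_cluster=None, nearest_cni=None,
                          completeness=completeness)
    cni_by_cluster: dict[str, float] = {}
    for cluster_id, rep in sorted(ref.representatives.items()):
        cni = _pairwise_scg_cni(query_genes, ref.rep_genes.get(rep, {}), aligner)
        if cni is not None:
            cni_by_cluster[cluster_id] = cni
    if not cni_by_cluster:
        return Assignment(status="novel", clusters=(), cnis=(),
                          nearest_cluster=None, nearest_cni=None,
                          completeness=completeness)
    nearest = max(sorted(cni_by_cluster), key=lambda c: cni_by_cluster[c])
    above = sorted((c for c, v in cni_by_cluster.items() if v >= cni_cutoff),
                   key=lambda c: -cni_by_cluster[c])
    names = tuple(ref.cluster_names.get(c, "") for c in above)
    if len(above) == 1:
        status = "assigned"
    elif len(above) > 1:
        status = "ambiguous (transitivity violation)"
        logger.warning("genome %s within species range of multiple clusters: %s",
                       query.genome_id, above)
    else:
        status = "novel"
    return Assignment(status=status, clusters=tuple(above),
                      cnis=tuple(cni_by_cluster[c] for c in above),
                      nearest_cluster=nearest,
                      nearest_cni=cni_by_cluster[nearest],
                      completeness=completeness, names=names)


# --- tabular output ---------------------------------------------------------

def clusters_frame(clusters: list[SpeciesCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g, c.cluster_id) for c in clusters for g in c.members],
        columns=["genome_id", "cluster_id"])


def cluster_summary_frame(clusters: list[SpeciesCluster]) -> pd.DataFrame:
    def _fmt(v):
        return float("nan") if v is None else v
    return pd.DataFrame(
        [(c.cluster_id, len(c.members), _fmt(c.min_within_cni),
          _fmt(c.max_between_cni), c.nearest_cluster_id or "",
          c.exclusive, c.transitive, c.representative or "")
         for c in clusters],
        columns=["cluster_id", "n_genomes", "min_within_cni",
                 "max_between_cni", "nearest_cluster_id", "exclusive",
                 "transitive", "representative"])
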