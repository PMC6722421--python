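"""Core-gene supermatrix construction and core nucleotide identity (CNI).

Per-SCG protein alignments are imposed on the underlying codon sequences
("reverse alignment"), concatenated into one supermatrix (one row per
genome, SCGs in sorted-id order), and pairwise CNI is the fraction of
identical sites among columns where both genomes have an unambiguous
nucleotide (pairwise deletion of gaps/N; uncorrected p-distance converted
to a similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import align_protein_set
from .genome_io import Genome, translate_cds
from .scg_profiler import Hit

logger = logging.getLogger(__name__)

_ACGT = frozenset(b"ACGT")


class SupermatrixError(ValueError):
    pass


@dataclass
class Supermatrix:
    """Concatenated per-SCG nucleotide alignments, one row per genome."""

    genome_ids: list[str]
    rows: dict[str, str]                      # genome_id -> aligned row
    block_map: dict[str, tuple[int, int]]     # scg_id -> [start, end)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def block(self, genome_id: str, scg_id: str) -> str:
        s, e = self.block_map[scg_id]
        return self.rows[genome_id][s:e]


@dataclass
class CNIMatrix:
    """Symmetric pairwise core nucleotide identities over genomes.

    ``values[i, j]`` is NaN where two genomes share no compared site.
    """

    genome_ids: list[str]
    values: np.ndarray          # (n, n) float, fractions or NaN
    compared_sites: np.ndarray  # (n, n) int

    def get(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])


def back_translate_alignment(aa_alignment: list[str], cds_seqs: list[str],
                             names: list[str] | None = None) -> list[str]:
    """Expand a protein alignment to codons using each row's source CDS.

    Each residue column expands to its codon, each gap to ``---``. The
    ungapped protein row must equal the CDS translation (trailing stop
    dropped); a mismatch raises an error naming the offending row/position.
    """
    if names is None:
        names = [f"row{i}" for i in range(len(aa_alignment))]
    out = []
    for row, cds, name in zip(aa_alignment, cds_seqs, names):
        ungapped = row.replace("-", "")
        translated = translate_cds(cds)
        if translated != ungapped:
            pos = next((i for i, (a, b) in enumerate(zip(translated, ungapped))
                        if a != b), min(len(translated), len(ungapped)))
            raise SupermatrixError(
                f"translation mismatch for {name} at residue {pos}: "
                f"alignment row does not match CDS translation")
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(ungapped))]
        it = iter(codons)
        out.append("".join("---" if c == "-" else next(it) for c in row))
    return out


def choose_scg_copies(resolved_hits: list[Hit], cutoffs: dict[str, float],
                      scg_ids: list[str]) -> dict[str, dict[str, str]]:
    """Per SCG and genome, the gene id of the best-scoring passing copy."""
    scg_set = set(scg_ids)
    best: dict[str, dict[str, tuple[float, str]]] = {s: {} for s in scg_ids}
    for h in resolved_hits:
        if h.profile_id not in scg_set or h.score < cutoffs[h.profile_id]:
            continue
        cur = best[h.profile_id].get(h.genome_id)
        if cur is None or h.score > cur[0] or (h.score == cur[0]
                                               and h.gene_id < cur[1]):
            best[h.profile_id][h.genome_id] = (h.score, h.gene_id)
    return {s: {g: gid for g, (_, gid) in per.items()}
            for s, per in best.items()}


def build_scg_alignments(genomes: list[Genome], copies: dict[str, dict[str, str]],
                         genome_ids: list[str],
                         aligner: str = "star") -> dict[str, dict[str, str]]:
    """Aligned nucleotide rows per SCG for the given genomes.

    Protein sequences of the chosen copies are multiply aligned and
    back-translated; the result maps scg_id -> genome_id -> aligned row.
    """
    gene_lookup = {g.gene_id: g for genome in genomes for g in genome.genes}
    keep = set(genome_ids)
    result: dict[str, dict[str, str]] = {}
    for scg_id in sorted(copies):
        members = [(g, gid) for g, gid in sorted(copies[scg_id].items())
                   if g in keep]
        if not members:
            continue
        aa = [gene_lookup[gid].aa_seq for _, gid in members]
        nt = [gene_lookup[gid].nt_seq for _, gid in members]
        aln = align_protein_set(aa, method=aligner)
        nt_aln = back_translate_alignment(aln, nt, names=[gid for _, gid in members])
        result[scg_id] = {g: row for (g, _), row in zip(members, nt_aln)}
    return result


def build_supermatrix(scg_alignments: dict[str, dict[str, str]],
                      genome_ids: list[str]) -> Supermatrix:
    """Concatenate per-SCG nucleotide alignments (sorted SCG-id order).

    A genome lacking an SCG gets an all-gap block of that SCG's width; a
    genome present in no SCG at all is an error.
    """
    genome_ids = sorted(genome_ids)
    present = {g for rows in scg_alignments.values() for g in rows}
    orphans = [g for g in genome_ids if g not in present]
    if orphans:
        raise SupermatrixError(f"genomes absent from every SCG: {orphans}")
    parts: dict[str, list[str]] = {g: [] for g in genome_ids}
    block_map: dict[str, tuple[int, int]] = {}
    offset = 0
    for scg_id in sorted(scg_alignments):
        rows = scg_alignments[scg_id]
        width = len(next(iter(rows.values())))
        if any(len(r) != width for r in rows.values()):
            raise SupermatrixError(f"ragged alignment for SCG {scg_id}")
        gaps = "-" * width
        for g in genome_ids:
            parts[g].append(rows.get(g, gaps))
        block_map[scg_id] = (offset, offset + width)
        offset += width
    return Supermatrix(genome_ids=genome_ids,
                       rows={g: "".join(p) for g, p in parts.items()},
                       block_map=block_map)


def _to_array(sm: Supermatrix) -> np.ndarray:
    return np.frombuffer(
        "".join(sm.rows[g] for g in sm.genome_ids).encode("ascii"),
        dtype=np.uint8).reshape(len(sm.genome_ids), sm.width)


def pairwise_cni(sm: Supermatrix) -> CNIMatrix:
    """Pairwise CNI with pairwise deletion of gap/N columns."""
    n = len(sm.genome_ids)
    if n < 2:
        raise SupermatrixError("need at least two genomes for pairwise CNI")
    arr = _to_array(sm)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    values = np.full((n, n), np.nan)
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        compared[i, i] = int(valid[i].sum())
        if compared[i, i] > 0:
            values[i, i] = 1.0
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            compared[i, j] = compared[j, i] = c
            if c == 0:
                logger.warning("no compared sites between %s and %s",
                               sm.genome_ids[i], sm.genome_ids[j])
                continue
            ident = int((arr[i][both] == arr[j][both]).sum())
            values[i, j] = values[j, i] = ident / c
    return CNIMatrix(genome_ids=list(sm.genome_ids), values=values,
                     compared_sites=compared)


def trim_columns(sm: Supermatrix, trim_gap_max: float) -> Supermatrix:
    """Drop columns whose gap fraction exceeds ``trim_gap_max`` (strict >)."""
    arr = _to_array(sm)
    gap_frac = (arr == ord("-")).mean(axis=0)
    keep = gap_frac <= trim_gap_max
    if not keep.any():
        raise SupermatrixError("all columns trimmed")
    new_rows = {g: arr[i][keep].tobytes().decode("ascii")
                for i, g in enumerate(sm.genome_ids)}
    block_map: dict[str, tuple[int, int]] = {}
    offset = 0
    for scg_id in sorted(sm.block_map, key=lambda s: sm.block_map[s][0]):
        s, e = sm.block_map[scg_id]
        w = int(keep[s:e].sum())
        block_map[scg_id] = (offset, offset + w)
        offset += w
    return Supermatrix(genome_ids=list(sm.genome_ids), rows=new_rows,
                       block_map=block_map)


def select_top_scgs(copy_matrix: pd.DataFrame, top_scg_count: int) -> list[str]:
    """SCGs with the largest single-copy presence counts (ties by id)."""
    counts = (copy_matrix == 1).sum(axis=0)
    ranked = sorted(counts.index, key=lambda s: (-counts[s], s))
    if len(ranked) < top_scg_count:
        logger.warning("only %d SCGs available, requested %d",
                       len(ranked), top_scg_count)
    return ranked[:top_scg_count]


# --- writers ----------------------------------------------------------------

def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sm.genome_ids:
            fh.write(f">{g}\n{sm.rows[g]}\n")


def read_supermatrix_fasta(path: str | Path,
                           block_map: dict[str, tuple[int, int]] | None = None
                           ) -> Supermatrix:
    from Bio import SeqIO
    rows = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    ids = sorted(rows)
    if block_map is None:
        block_map = {"ALL": (0, len(rows[ids[0]]))}
    return Supermatrix(genome_ids=ids, rows=rows, block_map=block_map)


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP (names of arbitrary length, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.genome_ids)} {sm.width}\n")
        for g in sm.genome_ids:
            fh.write(f"{g}  {sm.rows[g]}\n")


def cni_long_frame(cni: CNIMatrix) -> pd.DataFrame:
    recs = []
    ids = cni.genome_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            recs.append((ids[i], ids[j], cni.values[i, j],
                         int(cni.compared_sites[i, j])))
    return pd.DataFrame(recs, columns=["genome_a", "genome_b", "cni",
                                       "compared_sites"])


def cni_square_frame(cni: CNIMatrix) -> pd.DataFrame:
    return pd.DataFrame(cni.values, index=cni.genome_ids,
                        columns=cni.genome_ids)
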