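"""Candidate SCG selection, profile construction, search and cutoff training.

Steps 2-4 of the SCG extraction strategy: gene families that are single-copy
in more than k seed genomes become candidate SCGs; each candidate's seed
sequences are aligned and turned into a position-specific score profile; all
genomes are scanned with every profile; a per-profile bit-score cutoff is
trained by F-measure maximization over "best hit per genome = true" labels;
and the definitive SCGs are the candidates with exactly one passing copy in
at least p% of all genomes.

The profile is a simplified position-specific scorer (log-odds match scores
per column, per-column affine gap penalties), not a full profile HMM; the
method only requires a per-gene score that admits a trained cutoff. Reported
scores are local-alignment bits minus an empirically calibrated,
length-scaled null anchor, so the 0-bit reporting floor excludes nearly all
random sequences.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._align import (ALPHABET, AA_INDEX, N_SYMBOLS, STOP_IDX, X_IDX,
                     align_protein_set, encode_aa, profile_local_score)
from .genome_io import Genome
from .seed_families import GeneFamily

logger = logging.getLogger(__name__)

# Robinson & Robinson amino-acid background frequencies, ALPHABET order
BACKGROUND = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.091,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

X_SCORE = -0.5   # unknown residue
STOP_SCORE = -4.0  # internal stop; floor so pseudogene-like inputs still align


@dataclass
class Profile:
    """Position-specific score model for one candidate SCG.

    ``null_score`` anchors the empirical null distribution: the location of
    the best local-alignment score of background-random sequences of length
    ``null_len`` against this profile (mean + 3 sd over a seeded sample).
    Reported hit scores are raw bits minus this anchor, log-scaled for
    query length, so a 0-bit reporting floor excludes nearly all random
    sequences.
    """

    profile_id: str
    match_scores: np.ndarray        # (length, N_SYMBOLS), bits
    gap_open: np.ndarray            # (length,), <= 0 bits
    gap_extend: np.ndarray          # (length,), <= 0 bits
    consensus: str
    cutoff: Optional[float] = None  # trained bit-score threshold
    null_score: Optional[float] = None
    null_len: int = 150

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    def null_at(self, seq_len: int) -> float:
        """Null anchor for a query of the given length (log length scaling)."""
        if self.null_score is None:
            return math.log2(max(seq_len, 1) * self.length)
        return self.null_score + math.log2(max(seq_len, 1) / self.null_len)


@dataclass(frozen=True)
class Hit:
    gene_id: str
    genome_id: str
    profile_id: str
    score: float
    is_best_in_genome: bool


@dataclass(frozen=True)
class CutoffTrainingResult:
    profile_id: str
    cutoff: float
    precision: float
    recall: float
    f_measure: float


def select_candidate_families(families: list[GeneFamily],
                              k_candidate: int) -> list[GeneFamily]:
    """Keep families single-copy in more than ``k_candidate`` seed genomes."""
    kept = [f for f in families if f.seed_sc_presence > k_candidate]
    if not kept:
        logger.warning("no candidate SCGs at k=%d over %d families",
                       k_candidate, len(families))
    return kept


def build_profile(alignment: list[str], profile_id: str = "P",
                  background: np.ndarray | None = None,
                  pseudocount: float = 1.0,
                  max_col_gap: float = 0.5,
                  gap_open_floor: float = -8.0,
                  gap_extend_floor: float = -4.0,
                  gap_cap: float = -0.25) -> Profile:
    """Build a position-specific score profile from a protein alignment.

    Match columns are those with gap fraction < ``max_col_gap``. Emission
    probabilities use a background pseudocount of total mass ``pseudocount``;
    match scores are log2(emission / background). Gap penalties derive from
    observed per-column gap opening/extension frequencies, clipped to
    [floor, gap_cap] so they stay strictly negative.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(r) != width for r in alignment):
        raise ValueError("ragged alignment")
    nrows = len(alignment)
    cols = [[r[c] for r in alignment] for c in range(width)]
    match_cols = [c for c, col in enumerate(cols)
                  if col.count("-") / nrows < max_col_gap]
    if not match_cols:
        raise ValueError(f"profile {profile_id}: no match columns")

    if background is None:
        background = BACKGROUND
    L = len(match_cols)
    scores = np.zeros((L, N_SYMBOLS))
    gap_open = np.zeros(L)
    gap_extend = np.zeros(L)
    consensus = []
    prev_col: Optional[int] = None
    for out_j, c in enumerate(match_cols):
        col = cols[c]
        counts = np.zeros(len(ALPHABET))
        nres = 0
        for ch in col:
            if ch == "-":
                continue
            nres += 1
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        emission = (counts + pseudocount * background) / (nres + pseudocount)
        scores[out_j, : len(ALPHABET)] = np.log2(emission / background)
        scores[out_j, X_IDX] = X_SCORE
        scores[out_j, STOP_IDX] = STOP_SCORE
        consensus.append(ALPHABET[int(np.argmax(counts))] if nres else "X")
        opens = exts = 0
        for r in range(nrows):
            if col[r] != "-":
                continue
            prev_gap = prev_col is not None and cols[prev_col][r] == "-"
            if prev_gap:
                exts += 1
            else:
                opens += 1
        gap_open[out_j] = np.clip(math.log2((opens + 0.5) / (nrows + 1)),
                                  gap_open_floor, gap_cap)
        gap_extend[out_j] = np.clip(math.log2((exts + 0.5) / (nrows + 1)),
                                    gap_extend_floor, gap_cap)
        prev_col = c
    return Profile(profile_id=profile_id, match_scores=scores,
                   gap_open=gap_open, gap_extend=gap_extend,
                   consensus="".join(consensus))


def calibrate_profile_null(profile: Profile, n_samples: int = 30) -> Profile:
    """Fix the profile's empirical null anchor from seeded random sequences.

    Background-distributed random sequences of length ``null_len`` are
    scored against the profile; the anchor is mean + 3 sd of those maxima.
    The RNG seed derives from the profile id, so calibration is
    reproducible and independent of call order.
    """
    import zlib

    from ._align import profile_local_score as _score

    rng = np.random.default_rng(
        zlib.crc32(profile.profile_id.encode()) & 0x7FFFFFFF)
    aa_idx = np.arange(len(ALPHABET))
    maxima = np.empty(n_samples)
    for i in range(n_samples):
        seq = rng.choice(aa_idx, size=profile.null_len, p=BACKGROUND)
        maxima[i] = _score(seq.astype(np.int64), profile.match_scores,
                           profile.gap_open, profile.gap_extend)
    profile.null_score = float(maxima.mean() + 3.0 * maxima.std())
    return profile


def build_family_profiles(families: list[GeneFamily], genomes: list[Genome],
                          aligner: str = "star") -> list[Profile]:
    """Align each candidate family's seed proteins and build its profile."""
    gene_lookup = {g.gene_id: g for genome in genomes for g in genome.genes}
    profiles = []
    for fam in families:
        seqs = [gene_lookup[gid].aa_seq for gid in fam.gene_ids()]
        aln = align_protein_set(seqs, method=aligner)
        profiles.append(calibrate_profile_null(
            build_profile(aln, profile_id=fam.family_id)))
    return profiles


def _profile_kmer_index(profiles: list[Profile], k: int) -> dict[str, set[int]]:
    index: dict[str, set[int]] = defaultdict(set)
    for i, p in enumerate(profiles):
        for pos in range(len(p.consensus) - k + 1):
            index[p.consensus[pos : pos + k]].add(i)
    return index


def score_genome_genes(profiles: list[Profile], genome: Genome,
                       score_floor: float = 0.0, prefilter: bool = True,
                       k: int = 5) -> list[Hit]:
    """Scan one genome's genes with every profile; report hits above the floor.

    The reported score is the local-alignment bit score minus the profile's
    length-scaled empirical null anchor. ``is_best_in_genome`` marks, per
    profile, the highest-scoring gene of this genome (ties broken by gene id).
    """
    if not genome.genes:
        return []
    kindex = _profile_kmer_index(profiles, k) if prefilter else None
    raw_hits: list[tuple[str, int, float]] = []
    for gene in genome.genes:
        seq = encode_aa(gene.aa_seq)
        if kindex is not None:
            cand: set[int] = set()
            for pos in range(len(gene.aa_seq) - k + 1):
                cand |= kindex.get(gene.aa_seq[pos : pos + k], set())
            candidates = sorted(cand)
        else:
            candidates = range(len(profiles))
        for pi in candidates:
            p = profiles[pi]
            raw = profile_local_score(seq, p.match_scores, p.gap_open,
                                      p.gap_extend)
            score = raw - p.null_at(len(gene.aa_seq))
            if score > score_floor:
                raw_hits.append((gene.gene_id, pi, score))

    best: dict[int, tuple[float, str]] = {}
    for gid, pi, s in raw_hits:
        cur = best.get(pi)
        if cur is None or s > cur[0] or (s == cur[0] and gid < cur[1]):
            best[pi] = (s, gid)
    return [Hit(gene_id=gid, genome_id=genome.genome_id,
                profile_id=profiles[pi].profile_id, score=s,
                is_best_in_genome=(best[pi][1] == gid))
            for gid, pi, s in raw_hits]


def resolve_best_profile(hits: list[Hit]) -> list[Hit]:
    """Keep only each gene's highest-scoring profile (ties: smallest id)."""
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if (cur is None or h.score > cur.score
                or (h.score == cur.score and h.profile_id < cur.profile_id)):
            best[h.gene_id] = h
    return sorted(best.values(), key=lambda h: (h.genome_id, h.gene_id))


def train_score_cutoff(profile_id: str, hits: list[Hit]) -> CutoffTrainingResult:
    """Train a profile's score cutoff by F-measure maximization.

    Per genome with any hit, the best-scoring gene is labeled true, all
    others false. Candidate thresholds are the distinct hit scores; a
    threshold keeps hits with score >= t. Among F-ties the lowest (most
    inclusive) threshold wins.
    """
    if not hits:
        raise ValueError(f"no hits for profile {profile_id}")
    by_genome: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        by_genome[h.genome_id].append(h)
    labels: list[tuple[float, bool]] = []
    for genome_hits in by_genome.values():
        top = min(genome_hits, key=lambda h: (-h.score, h.gene_id))
        for h in genome_hits:
            labels.append((h.score, h is top))
    n_true = len(by_genome)
    best: Optional[tuple[float, float, float, float]] = None  # (f, -t, p, r)
    for t in sorted({s for s, _ in labels}):
        above = [(s, tr) for s, tr in labels if s >= t]
        true_above = sum(1 for _, tr in above if tr)
        precision = true_above / len(above) if above else 0.0
        recall = true_above / n_true
        f = (2 * precision * recall / (precision + recall)
             if precision + recall > 0 else 0.0)
        key = (f, -t)
        if best is None or key > (best[0], best[1]):
            best = (f, -t, precision, recall)
    f, neg_t, precision, recall = best
    return CutoffTrainingResult(profile_id=profile_id, cutoff=-neg_t,
                                precision=precision, recall=recall,
                                f_measure=f)


def train_all_cutoffs(resolved_hits: list[Hit]) -> dict[str, CutoffTrainingResult]:
    by_profile: dict[str, list[Hit]] = defaultdict(list)
    for h in resolved_hits:
        by_profile[h.profile_id].append(h)
    return {pid: train_score_cutoff(pid, hs) for pid, hs in sorted(by_profile.items())}


def build_copy_matrix(resolved_hits: list[Hit], genome_ids: list[str],
                      cutoffs: dict[str, float]) -> pd.DataFrame:
    """Genomes x candidate SCGs copy-count matrix after applying cutoffs.

    A gene counts toward (genome, candidate) when its retained best-profile
    hit has score >= the candidate's trained cutoff.
    """
    candidates = sorted(cutoffs)
    mat = pd.DataFrame(0, index=sorted(genome_ids), columns=candidates, dtype=int)
    for h in resolved_hits:
        if h.profile_id in cutoffs and h.score >= cutoffs[h.profile_id]:
            mat.loc[h.genome_id, h.profile_id] += 1
    return mat


def select_definitive_scgs(matrix: pd.DataFrame, p_final: float) -> list[str]:
    """Candidates single-copy in at least p_final percent of all genomes."""
    if matrix.empty:
        raise ValueError("empty copy matrix")
    frac_sc = (matrix == 1).mean(axis=0)
    return sorted(frac_sc.index[frac_sc >= p_final / 100.0])


# --- plain-text profile serialization -------------------------------------

def write_profiles(profiles: list[Profile], path: str | Path) -> None:
    """Serialize profiles to a documented per-column score table."""
    with open(path, "w") as fh:
        fh.write("# coretax profile set v1\n")
        fh.write("# columns: pos gap_open gap_extend " +
                 " ".join(ALPHABET) + " X *\n")
        for p in profiles:
            cutoff = "NA" if p.cutoff is None else f"{p.cutoff:.6f}"
            null = "NA" if p.null_score is None else f"{p.null_score:.6f}"
            fh.write(f">{p.profile_id} length={p.length} cutoff={cutoff} "
                     f"null={null} null_len={p.null_len} "
                     f"consensus={p.consensus}\n")
            for j in range(p.length):
                row = [str(j + 1), f"{p.gap_open[j]:.6f}", f"{p.gap_extend[j]:.6f}"]
                row += [f"{s:.6f}" for s in p.match_scores[j]]
                fh.write("\t".join(row) + "\n")


def read_profiles(path: str | Path) -> list[Profile]:
    profiles: list[Profile] = []
    header = None
    rows: list[list[float]] = []

    def _flush():
        if header is None:
            return
        pid, cutoff, consensus, null_score, null_len = header
        arr = np.array(rows)
        profiles.append(Profile(
            profile_id=pid, match_scores=arr[:, 2:],
            gap_open=arr[:, 0], gap_extend=arr[:, 1],
            consensus=consensus, cutoff=cutoff,
            null_score=null_score, null_len=null_len))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                rows = []
                parts = line[1:].split()
                pid = parts[0]
                kv = dict(p.split("=", 1) for p in parts[1:])
                cutoff = None if kv["cutoff"] == "NA" else float(kv["cutoff"])
                null = kv.get("null", "NA")
                null_score = None if null == "NA" else float(null)
                header = (pid, cutoff, kv.get("consensus", ""),
                          null_score, int(kv.get("null_len", 150)))
            else:
                vals = line.split("\t")
                rows.append([float(v) for v in vals[1:]])
        _flush()
    return profiles


def hits_to_frame(hits: list[Hit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.genome_id, h.profile_id, h.score, h.is_best_in_genome)
         for h in hits],
        columns=["gene_id", "genome_id", "profile_id", "score",
                 "is_best_in_genome"])


def hits_from_frame(df: pd.DataFrame) -> list[Hit]:
    return [Hit(gene_id=r.gene_id, genome_id=r.genome_id,
                profile_id=r.profile_id, score=float(r.score),
                is_best_in_genome=bool(r.is_best_in_genome))
            for r in df.itertuples(index=False)]
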