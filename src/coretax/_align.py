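"""Low-level alignment kernels.

- a numba-compiled local (free-flanks) dynamic program scoring an amino-acid
  sequence against a position-specific score profile with per-column affine
  gap penalties;
- a star multiple aligner (global affine-gap pairwise alignments merged
  around the longest sequence) used as the built-in protein MSA;
- an adapter that shells out to mafft when configured.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from numba import njit

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

# profile alphabet: 20 amino acids + X (unknown) + * (stop)
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_SYMBOLS = len(ALPHABET) + 2  # + X, *
X_IDX = len(ALPHABET)
STOP_IDX = len(ALPHABET) + 1


def encode_aa(seq: str) -> np.ndarray:
    """Map an amino-acid string to profile alphabet indices (unknown -> X)."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c == "*":
            out[i] = STOP_IDX
        else:
            out[i] = AA_INDEX.get(c, X_IDX)
    return out


@njit(cache=False)
def profile_local_score(seq: np.ndarray, emit: np.ndarray,
                        gap_open: np.ndarray, gap_extend: np.ndarray) -> float:
    """Best local alignment score (bits) of seq against a profile.

    emit: (L, N_SYMBOLS) per-column match scores; gap_open/gap_extend: (L,)
    penalties (<= 0) applied both to skipped profile columns and to inserted
    sequence residues. Free flanks on both sides (Smith-Waterman style).
    """
    n = seq.shape[0]
    L = emit.shape[0]
    NEG = -1e30
    m_prev = np.full(L + 1, NEG)
    ix_prev = np.full(L + 1, NEG)
    iy_prev = np.full(L + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        m_cur = np.full(L + 1, NEG)
        ix_cur = np.full(L + 1, NEG)
        iy_cur = np.full(L + 1, NEG)
        s = seq[i - 1]
        for j in range(1, L + 1):
            diag = 0.0
            if m_prev[j - 1] > diag:
                diag = m_prev[j - 1]
            if ix_prev[j - 1] > diag:
                diag = ix_prev[j - 1]
            if iy_prev[j - 1] > diag:
                diag = iy_prev[j - 1]
            m_cur[j] = diag + emit[j - 1, s]
            # insertion: extra sequence residue between profile columns
            a = m_prev[j] + gap_open[j - 1]
            b = ix_prev[j] + gap_extend[j - 1]
            ix_cur[j] = a if a > b else b
            # deletion: profile column j skipped
            a = m_cur[j - 1] + gap_open[j - 1]
            b = iy_cur[j - 1] + gap_extend[j - 1]
            iy_cur[j] = a if a > b else b
            if m_cur[j] > best:
                best = m_cur[j]
        m_prev, ix_prev, iy_prev = m_cur, ix_cur, iy_cur
    return best


_global_aligner: Align.PairwiseAligner | None = None


def _get_global_aligner() -> Align.PairwiseAligner:
    global _global_aligner
    if _global_aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _global_aligner = a
    return _global_aligner


def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    aln = _get_global_aligner().align(a, b)[0]
    # rebuild gapped rows from the alignment coordinates
    ra, rb = [], []
    ca = cb = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        while ca < sa:
            ra.append(a[ca]); rb.append("-"); ca += 1
        while cb < sb:
            ra.append("-"); rb.append(b[cb]); cb += 1
        ra.append(a[ca:ea]); rb.append(b[cb:eb])
        ca, cb = ea, eb
    while ca < len(a):
        ra.append(a[ca]); rb.append("-"); ca += 1
    while cb < len(b):
        ra.append("-"); rb.append(b[cb]); cb += 1
    return "".join(ra), "".join(rb)


def star_align(seqs: list[str]) -> list[str]:
    """Star multiple alignment around the longest sequence.

    Each sequence is globally aligned to the center; gaps are merged under
    the once-a-gap-always-a-gap rule. Residue order of every input sequence
    is preserved.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return [seqs[0]]
    center_i = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_i]
    # msa rows in input order; center row tracked separately
    msa_center = center
    rows: list[str | None] = [None] * len(seqs)
    rows[center_i] = center
    for i, s in enumerate(seqs):
        if i == center_i:
            continue
        ac, asq = _pairwise_global(center, s)
        # merge (ac, asq) into current msa using center coordinates
        merged_center, merged_rows, new_row = _merge_into_msa(
            msa_center, [r for r in rows if r is not None], ac, asq)
        msa_center = merged_center
        it = iter(merged_rows)
        for j in range(len(seqs)):
            if rows[j] is not None:
                rows[j] = next(it)
        rows[i] = new_row
    return [r if r is not None else "" for r in rows]


def _merge_into_msa(msa_center: str, msa_rows: list[str],
                    pair_center: str, pair_other: str):
    """Merge a pairwise alignment (center vs other) into an MSA keyed on center."""
    out_rows = [[] for _ in msa_rows]
    out_center: list[str] = []
    out_other: list[str] = []
    i = j = 0  # positions in msa_center / pair_center
    nm, np_ = len(msa_center), len(pair_center)
    while i < nm or j < np_:
        if i < nm and msa_center[i] == "-":
            # gap column already in msa (center gapped there): other gets a gap
            out_center.append("-")
            for k, r in enumerate(msa_rows):
                out_rows[k].append(r[i])
            out_other.append("-")
            i += 1
        elif j < np_ and pair_center[j] == "-":
            # pairwise alignment inserted a gap in center: msa rows get gaps
            out_center.append("-")
            for k in range(len(msa_rows)):
                out_rows[k].append("-")
            out_other.append(pair_other[j])
            j += 1
        else:
            # both consume one center residue
            out_center.append(msa_center[i])
            for k, r in enumerate(msa_rows):
                out_rows[k].append(r[i])
            out_other.append(pair_other[j])
            i += 1
            j += 1
    return ("".join(out_center),
            ["".join(r) for r in out_rows],
            "".join(out_other))


def mafft_align(seqs: list[str]) -> list[str]:
    """External MSA adapter calling mafft; requires mafft on PATH."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return [seqs[0]]
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        with open(fin, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        res = subprocess.run(["mafft", "--quiet", "--auto", str(fin)],
                             capture_output=True, text=True, check=True)
        recs = {r.id: str(r.seq).upper()
                for r in SeqIO.parse(_as_handle(res.stdout), "fasta")}
    return [recs[f"s{i}"] for i in range(len(seqs))]


def _as_handle(text: str):
    import io
    return io.StringIO(text)


def align_protein_set(aa_seqs: list[str], method: str = "star") -> list[str]:
    """Multiple alignment of protein sequences (built-in star or mafft adapter)."""
    if method == "star":
        return star_align(aa_seqs)
    if method == "mafft":
        return mafft_align(aa_seqs)
    raise ValueError(f"unknown aligner {method!r}")
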