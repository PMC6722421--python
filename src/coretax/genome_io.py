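"""Reading and writing of per-genome CDS sets and tabular metadata.

One genome = one nucleotide multi-FASTA of predicted coding sequences.
A dataset is described by a manifest TSV with columns
``genome_id``, ``cds_path``, ``strain_name``, ``declared_species``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_STOPS = set(_TABLE11.stop_codons)


class GenomeIOError(ValueError):
    """Raised for malformed genome inputs (empty files, duplicate headers...)."""


@dataclass(frozen=True)
class Gene:
    """A single coding sequence with its translation.

    ``aa_seq`` is derived from ``nt_seq`` with the bacterial genetic code
    (translation table 11); a single trailing stop codon is dropped.
    """

    gene_id: str
    genome_id: str
    nt_seq: str
    aa_seq: str


@dataclass
class Genome:
    """A genome: its identifier, CDS set and source metadata."""

    genome_id: str
    genes: list[Gene]
    strain_name: Optional[str] = None
    declared_species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise GenomeIOError("genome_id must be nonempty")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise GenomeIOError(f"duplicate gene ids in genome {self.genome_id}")


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and collapse ambiguity codes to N."""
    up = seq.upper()
    return "".join(c if c in _VALID_NT else "N" for c in up)


def translate_cds(nt_seq: str) -> str:
    """Translate a CDS with the bacterial code (table 11).

    A single trailing stop codon is dropped; internal stops become ``*``;
    codons containing N become ``X``. Trailing 1-2 leftover nucleotides are
    ignored with a warning.
    """
    if len(nt_seq) < 3:
        raise GenomeIOError(f"CDS shorter than one codon: {nt_seq!r}")
    leftover = len(nt_seq) % 3
    if leftover:
        logger.warning("CDS length %d not a multiple of 3; ignoring %d trailing nt",
                       len(nt_seq), leftover)
        nt_seq = nt_seq[: len(nt_seq) - leftover]
    aas = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3]
        if "N" in codon:
            aas.append("X")
        elif codon in _STOPS:
            aas.append("*")
        else:
            aas.append(_TABLE11.forward_table[codon])
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def read_genome_cds(path: str | Path, genome_id: str,
                    strain_name: Optional[str] = None,
                    declared_species: Optional[str] = None) -> Genome:
    """Read one genome's CDS multi-FASTA into a :class:`Genome`.

    Gene ids are the first whitespace token of each header, namespaced with
    ``genome_id|`` when not already so, which guarantees dataset-wide
    uniqueness. Sequences are uppercased and ambiguity codes become N.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"empty genome: no FASTA records in {path}")
    genes: list[Gene] = []
    seen: set[str] = set()
    prefix = f"{genome_id}|"
    for rec in records:
        raw_id = rec.id
        if raw_id in seen:
            raise GenomeIOError(f"duplicate header {raw_id!r} in {path}")
        seen.add(raw_id)
        gene_id = raw_id if raw_id.startswith(prefix) else prefix + raw_id
        nt = normalize_nt(str(rec.seq))
        genes.append(Gene(gene_id=gene_id, genome_id=genome_id,
                          nt_seq=nt, aa_seq=translate_cds(nt)))
    return Genome(genome_id=genome_id, genes=genes,
                  strain_name=strain_name, declared_species=declared_species)


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    """Write a genome's CDS set back to nucleotide FASTA."""
    records = [SeqRecord(Seq(g.nt_seq), id=g.gene_id, description="")
               for g in genome.genes]
    SeqIO.write(records, str(path), "fasta")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a genome manifest TSV (genome_id, cds_path, strain_name, declared_species)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"genome_id", "cds_path"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeIOError(f"manifest missing columns: {sorted(missing)}")
    for col in ("strain_name", "declared_species"):
        if col not in df.columns:
            df[col] = ""
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise GenomeIOError(f"duplicate genome ids in manifest: {dups}")
    return df


def load_genomes(manifest: pd.DataFrame, base_dir: str | Path = ".") -> list[Genome]:
    """Load every genome listed in a manifest; relative paths resolve against base_dir."""
    base = Path(base_dir)
    genomes = []
    for row in manifest.itertuples(index=False):
        p = Path(row.cds_path)
        if not p.is_absolute():
            p = base / p
        genomes.append(read_genome_cds(
            p, row.genome_id,
            strain_name=row.strain_name or None,
            declared_species=row.declared_species or None))
    return genomes


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as UTF-8 TSV with a header row and '.' decimals."""
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
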