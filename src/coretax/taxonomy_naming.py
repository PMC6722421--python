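"""Reconciliation of de novo clusters with published species names.

Type genomes are located by matching normalized assembly strain names
against normalized type-strain synonyms from a user-supplied table. A
cluster holding type genomes of exactly one species takes that name; type
genomes of several species in one cluster signal heterotypic synonyms and
the oldest name wins (a merger); type genomes of different subspecies of one
species landing in different clusters elevate the non-nominate subspecies to
species rank (a split). Finally, genomes' declared species labels are
compared to their cluster's assigned name to produce a reclassification
report.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .species_clustering import SpeciesCluster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TypeGenomeRecord:
    genome_id: str
    species_name: str
    subspecies_name: Optional[str]
    strain_synonyms: tuple[str, ...]
    publication_year: int
    validly_published: bool

    def __post_init__(self) -> None:
        if not self.species_name:
            raise ValueError("species_name must be nonempty")
        if self.publication_year <= 1700:
            raise ValueError(f"implausible publication year {self.publication_year}")


@dataclass
class ClusterName:
    cluster_id: str
    name: str
    status: str  # typed | merger | split_elevated | unnamed
    merged_names: list[str] = field(default_factory=list)
    notes: str = ""


_PUNCT = re.compile(r"[\s\-_.,;:/()'\"]+")


def normalize_strain_name(raw: Optional[str]) -> Optional[str]:
    """Canonical form of a strain designation, or None when unusable.

    Uppercases, strips whitespace/hyphens/punctuation and a leading bare
    "STRAIN" token; a result consisting only of digits carries no
    collection information and is returned as None (unusable).
    """
    if raw is None:
        return None
    s = _PUNCT.sub("", raw.upper())
    if s.startswith("STRAIN"):
        s = s[len("STRAIN"):]
    if not s or s.isdigit():
        return None
    return s


def read_type_strain_table(path: str | Path) -> pd.DataFrame:
    """Read type_strains.tsv: species_name, subspecies_name, year, valid, synonym."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species_name", "year", "synonym"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"type strain table missing columns: {sorted(missing)}")
    if "subspecies_name" not in df.columns:
        df["subspecies_name"] = ""
    if "valid" not in df.columns:
        df["valid"] = "true"
    return df


def match_type_genomes(manifest: pd.DataFrame, type_table: pd.DataFrame
                       ) -> tuple[list[TypeGenomeRecord], pd.DataFrame]:
    """Identify type genomes by normalized strain-name lookup.

    Returns the matched records plus a conflict report: a genome whose
    strain name matches the type strains of two different species is
    reported, never silently assigned.
    """
    # group synonym rows per (species, subspecies)
    keys = {}
    for row in type_table.itertuples(index=False):
        key = (row.species_name, row.subspecies_name or None)
        if key not in keys:
            keys[key] = {"year": int(row.year),
                         "valid": str(row.valid).lower() in ("true", "1", "yes"),
                         "synonyms": []}
        keys[key]["synonyms"].append(row.synonym)

    norm_index: dict[str, list[tuple[str, Optional[str]]]] = {}
    for (sp, subsp), info in keys.items():
        for syn in info["synonyms"]:
            norm = normalize_strain_name(syn)
            if norm is None:
                logger.info("type strain synonym %r of %s is unusable", syn, sp)
                continue
            norm_index.setdefault(norm, []).append((sp, subsp))

    records: list[TypeGenomeRecord] = []
    conflicts = []
    for row in manifest.itertuples(index=False):
        norm = normalize_strain_name(getattr(row, "strain_name", "") or None)
        if norm is None or norm not in norm_index:
            continue
        matches = sorted(set(norm_index[norm]), key=lambda t: (t[0], t[1] or ""))
        species = sorted({sp for sp, _ in matches})
        if len(species) > 1:
            conflicts.append((row.genome_id, norm, "; ".join(species)))
            continue
        sp, subsp = matches[0]
        info = keys[(sp, subsp)]
        records.append(TypeGenomeRecord(
            genome_id=row.genome_id, species_name=sp, subspecies_name=subsp,
            strain_synonyms=tuple(info["synonyms"]),
            publication_year=info["year"],
            validly_published=info["valid"]))
    conflict_df = pd.DataFrame(
        conflicts, columns=["genome_id", "normalized_strain", "species"])
    return records, conflict_df


def _nominate_subspecies(species_name: str, subspecies_name: str) -> bool:
    """The nominate subspecies repeats the species epithet (e.g. subsp. casei)."""
    return species_name.split()[-1] == subspecies_name.split()[-1]


def _elevated_binomial(species_name: str, subspecies_name: str) -> str:
    genus = species_name.split()[0]
    return f"{genus} {subspecies_name.split()[-1]}"


def name_clusters(clusters: list[SpeciesCluster],
                  type_records: list[TypeGenomeRecord]) -> list[ClusterName]:
    """Assign published names to clusters; detect mergers and splits."""
    by_genome: dict[str, list[TypeGenomeRecord]] = {}
    for r in type_records:
        by_genome.setdefault(r.genome_id, []).append(r)
    cluster_of: dict[str, str] = {g: c.cluster_id
                                  for c in clusters for g in c.members}

    names: list[ClusterName] = []
    cluster_records: dict[str, list[TypeGenomeRecord]] = {}
    for c in clusters:
        recs = [r for g in c.members for r in by_genome.get(g, [])]
        cluster_records[c.cluster_id] = recs
        species = sorted({r.species_name for r in recs})
        if not species:
            names.append(ClusterName(cluster_id=c.cluster_id, name="",
                                     status="unnamed"))
        elif len(species) == 1:
            names.append(ClusterName(cluster_id=c.cluster_id, name=species[0],
                                     status="typed"))
        else:
            year_of = {sp: min(r.publication_year for r in recs
                               if r.species_name == sp) for sp in species}
            oldest_year = min(year_of.values())
            oldest = sorted(sp for sp in species if year_of[sp] == oldest_year)
            notes = ""
            if len(oldest) > 1:
                notes = ("publication-year tie between "
                         + " and ".join(oldest)
                         + "; alphabetically first chosen")
                logger.warning("cluster %s: %s", c.cluster_id, notes)
            names.append(ClusterName(cluster_id=c.cluster_id, name=oldest[0],
                                     status="merger", merged_names=species,
                                     notes=notes))

    # split detection: subspecies of one species in different clusters
    subsp_clusters: dict[str, dict[str, set[str]]] = {}
    for r in type_records:
        if r.genome_id not in cluster_of or not r.subspecies_name:
            continue
        subsp_clusters.setdefault(r.species_name, {}).setdefault(
            r.subspecies_name, set()).add(cluster_of[r.genome_id])
    name_by_cluster = {n.cluster_id: n for n in names}
    for species, per_subsp in sorted(subsp_clusters.items()):
        all_clusters = set().union(*per_subsp.values())
        if len(all_clusters) < 2:
            continue
        nominate_clusters = set().union(
            *(cs for subsp, cs in per_subsp.items()
              if _nominate_subspecies(species, subsp)), set())
        for subsp, cs in sorted(per_subsp.items()):
            if _nominate_subspecies(species, subsp):
                continue
            for cid in sorted(cs - nominate_clusters):
                entry = name_by_cluster[cid]
                elevated = _elevated_binomial(species, subsp)
                entry.status = "split_elevated"
                entry.name = elevated
                entry.notes = (entry.notes + "; " if entry.notes else "") + (
                    f"{species} subsp. {subsp.split()[-1]} elevated to "
                    f"{elevated} (nominate subspecies in another cluster)")
    return names


def report_reclassifications(manifest: pd.DataFrame,
                             clusters: list[SpeciesCluster],
                             names: list[ClusterName]) -> pd.DataFrame:
    """Compare declared species labels against assigned cluster names."""
    cluster_of = {g: c.cluster_id for c in clusters for g in c.members}
    name_of = {n.cluster_id: n for n in names}
    rows = []
    for row in manifest.itertuples(index=False):
        gid = row.genome_id
        if gid not in cluster_of:
            continue
        cid = cluster_of[gid]
        entry = name_of[cid]
        declared = (getattr(row, "declared_species", "") or "").strip()
        if entry.status == "unnamed":
            category = "assigned-to-unnamed"
        elif not declared:
            category = "unclassified->assigned"
        elif declared == entry.name:
            category = "unchanged"
        else:
            category = "relabeled"
        rows.append((gid, declared, cid, entry.name, entry.status, category))
    return pd.DataFrame(rows, columns=["genome_id", "declared_species",
                                       "cluster_id", "assigned_name",
                                       "name_status", "category"])


def cluster_names_frame(names: list[ClusterName]) -> pd.DataFrame:
    return pd.DataFrame(
        [(n.cluster_id, n.name, n.status, ",".join(n.merged_names), n.notes)
         for n in names],
        columns=["cluster_id", "name", "status", "merged_names", "notes"])
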