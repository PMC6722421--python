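"""Synthetic pangenome generator with known species structure.

Emulates the statistical structure of a multi-species bacterial genome
collection: a sharp high-CNI mode within species and a broad low-CNI mode
between species separated by an empty gap, occasional gene loss and
duplication, and low-level cross-species contamination. Evolution is
substitution-only (no indels), which keeps reverse alignment exact and the
expected CNI analytically computable; gap behavior downstream is exercised
through gene loss instead.

The emitted files are exactly the pipeline's input formats (per-genome CDS
FASTA, manifest TSV, type-strain table) plus a ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationParams:
    """Study conditions for the generator.

    ``within_div`` is the maximum expected *pairwise* core divergence within
    a species; ``between_div`` the expected pairwise divergence between
    species ancestors. Defaults put the two CNI modes at >=0.97 and ~0.85,
    straddling an empty (0.90, 0.94) gap.
    """

    n_species: int = 5
    genomes_per_species: int = 4
    n_core_families: int = 150
    n_accessory_families: int = 50
    gene_len_codons: tuple[int, int] = (60, 150)
    within_div: float = 0.03
    between_div: float = 0.15
    loss_prob: float = 0.02
    dup_prob: float = 0.01
    contam_prob: float = 0.01
    accessory_presence: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.between_div > self.within_div:
            raise SimulationError("between_div must exceed within_div")
        for name in ("loss_prob", "dup_prob", "contam_prob",
                     "accessory_presence"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SimulationError(f"{name} must be in [0, 1), got {v}")
        if self.gene_len_codons[0] < 10:
            raise SimulationError("genes must be at least 10 codons")
        if self.n_species < 1 or self.genomes_per_species < 1:
            raise SimulationError("need at least one species and one genome")


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset."""

    genome_species: dict[str, str]
    family_class: dict[str, str]                  # core | accessory
    planted_completeness: dict[str, float]
    planted_redundancy: dict[str, float]
    type_genomes: dict[str, str]                  # species -> genome_id
    species_names: dict[str, str]                 # species key -> binomial


def mutate_sequence(nt_seq: str, per_site_prob: float,
                    rng: np.random.Generator) -> str:
    """Substitute each site independently with the given probability.

    A mutated site becomes a uniformly chosen *different* base; length and
    reading frame are preserved (no indels).
    """
    if not 0 <= per_site_prob <= 1:
        raise SimulationError(
            f"per-site probability must be in [0, 1], got {per_site_prob}")
    arr = np.frombuffer(nt_seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < per_site_prob
    if hit.any():
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def branch_prob_for_pairwise(divergence: float) -> float:
    """Per-branch substitution probability realizing a target pairwise divergence.

    Two sequences mutated independently from an ancestor with per-site
    probability p differ at a site with probability 2p(1-p) + (2/3)p^2;
    this inverts that relation.
    """
    if not 0 <= divergence < 0.75:
        raise SimulationError(f"pairwise divergence {divergence} out of range")
    # (4/3) p^2 - 2 p + D = 0
    return (2 - math.sqrt(4 - (16.0 / 3.0) * divergence)) / (8.0 / 3.0)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> SimTruth:
    """Generate a dataset with known species structure under ``params``.

    Writes ``cds/<genome>.fasta`` per genome, ``manifest.tsv``,
    ``type_strains.tsv`` (one type genome per species) and ``truth.tsv``;
    returns the ground truth. Byte-identical for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    outdir = Path(outdir)
    (outdir / "cds").mkdir(parents=True, exist_ok=True)

    n_fam = params.n_core_families + params.n_accessory_families
    fam_ids = [f"FAM{i + 1:04d}" for i in range(n_fam)]
    family_class = {f: ("core" if i < params.n_core_families else "accessory")
                    for i, f in enumerate(fam_ids)}
    lens = rng.integers(params.gene_len_codons[0], params.gene_len_codons[1] + 1,
                        size=n_fam)
    ancestors = {f: _random_cds(int(lens[i]), rng) for i, f in enumerate(fam_ids)}

    p_between = branch_prob_for_pairwise(params.between_div)
    species_keys = [f"sp{si + 1:02d}" for si in range(params.n_species)]
    species_names = {k: f"Synthetica {_epithet(si)}"
                     for si, k in enumerate(species_keys)}
    species_seqs = {
        k: {f: mutate_sequence(seq, p_between, rng)
            for f, seq in ancestors.items()}
        for k in species_keys
    }

    genome_species: dict[str, str] = {}
    planted_completeness: dict[str, float] = {}
    planted_redundancy: dict[str, float] = {}
    type_genomes: dict[str, str] = {}
    manifest_rows = []
    p_within_max = params.within_div / 2.0

    for si, sk in enumerate(species_keys):
        for gi in range(params.genomes_per_species):
            gid = f"{sk.upper()}G{gi + 1:02d}"
            genome_species[gid] = species_names[sk]
            p_g = float(rng.uniform(0.0, p_within_max)) if p_within_max > 0 else 0.0
            copies: dict[str, list[str]] = {}
            for f in fam_ids:
                core = family_class[f] == "core"
                present = True
                if not core:
                    present = rng.random() < params.accessory_presence
                elif params.loss_prob > 0 and rng.random() < params.loss_prob:
                    present = False
                if not present:
                    continue
                seq = mutate_sequence(species_seqs[sk][f], p_g, rng)
                copies[f] = [seq]
                if params.dup_prob > 0 and rng.random() < params.dup_prob:
                    copies[f].append(mutate_sequence(seq, 0.005, rng))
            if params.contam_prob > 0 and params.n_species > 1:
                donors = [k for k in species_keys if k != sk]
                for f in fam_ids:
                    if family_class[f] != "core" or f not in copies:
                        continue
                    if rng.random() < params.contam_prob:
                        donor = donors[int(rng.integers(len(donors)))]
                        copies[f].append(species_seqs[donor][f])
            core_ids = [f for f in fam_ids if family_class[f] == "core"]
            planted_completeness[gid] = (
                sum(1 for f in core_ids if f in copies) / len(core_ids))
            planted_redundancy[gid] = (
                sum(1 for f in core_ids if len(copies.get(f, [])) >= 2)
                / len(core_ids))

            fasta = outdir / "cds" / f"{gid}.fasta"
            with open(fasta, "w") as fh:
                for f in fam_ids:
                    for ci, seq in enumerate(copies.get(f, [])):
                        fh.write(f">{f}.{ci + 1}\n{seq}\n")
            strain = (f"DSM {1000 + si}" if gi == 0
                      else f"STR{si + 1:02d}-{gi + 1:02d}")
            if gi == 0:
                type_genomes[species_names[sk]] = gid
            manifest_rows.append((gid, f"cds/{gid}.fasta", strain,
                                  species_names[sk]))

    manifest = pd.DataFrame(manifest_rows, columns=[
        "genome_id", "cds_path", "strain_name", "declared_species"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    type_rows = []
    for si, sk in enumerate(species_keys):
        name = species_names[sk]
        year = 1900 + si
        for syn in (f"DSM {1000 + si}", f"DSM-{1000 + si}", f"LMG {2000 + si}"):
            type_rows.append((name, "", year, "true", syn))
    pd.DataFrame(type_rows, columns=[
        "species_name", "subspecies_name", "year", "valid", "synonym"
    ]).to_csv(outdir / "type_strains.tsv", sep="\t", index=False)

    truth = pd.DataFrame(
        [(g, genome_species[g], planted_completeness[g], planted_redundancy[g])
         for g in sorted(genome_species)],
        columns=["genome_id", "species", "planted_completeness",
                 "planted_redundancy"])
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    return SimTruth(genome_species=genome_species, family_class=family_class,
                    planted_completeness=planted_completeness,
                    planted_redundancy=planted_redundancy,
                    type_genomes=type_genomes, species_names=species_names)


_EPITHETS = ["primus", "secundus", "tertius", "quartus", "quintus", "sextus",
             "septimus", "octavus", "nonus", "decimus"]


def _epithet(i: int) -> str:
    if i < len(_EPITHETS):
        return _EPITHETS[i]
    return f"{_EPITHETS[i % len(_EPITHETS)]}{i // len(_EPITHETS) + 1}"
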