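"""End-to-end pipeline orchestration with resumable, checksummed stages.

Stages run in order: seed gene-family clustering, profile construction,
genome-wide search + cutoff training + copy matrix, genome QC, supermatrix +
CNI, species clustering + diagnostics, phylogeny supermatrix export, and
naming. Each stage writes its outputs into the run directory; a rerun with
an unchanged configuration and inputs verifies the recorded checksums and
loads the stage outputs from disk instead of recomputing them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from . import genome_io, genome_qc, scg_profiler, seed_families
from . import species_clustering, supermatrix, taxonomy_naming

logger = logging.getLogger(__name__)

STAGES = ["seed-families", "profiles", "search", "qc", "cni", "cluster",
          "phylogeny", "name"]


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of a pipeline run."""

    config: dict
    rng_seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)  # {name, outputs{path: sha}, skipped}

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "rng_seed": self.rng_seed,
                       "version": self.version, "stages": self.stages},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], rng_seed=d["rng_seed"],
                   version=d.get("version", "?"), stages=d.get("stages", []))


# --------------------------------------------------------------------------
# per-stage compute / save / load

def _stage_seed_families(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    genomes = state["genomes"]
    seed_ids = seed_families.select_seed_genomes(genomes, cfg.n_seed, cfg.rng_seed)
    seed_genes = [g for genome in genomes if genome.genome_id in seed_ids
                  for g in genome.genes]
    graph = seed_families.score_gene_pairs(
        seed_genes, bit_floor=cfg.bit_floor,
        kmer_prefilter=cfg.kmer_prefilter, k=cfg.prefilter_k)
    graph = seed_families.normalize_and_filter_scores(graph)
    families = seed_families.mcl_cluster(graph, inflation=cfg.mcl_inflation)
    state["seed_ids"] = seed_ids
    state["families"] = families


def _save_seed_families(state: dict, outdir: Path) -> list[Path]:
    p1 = outdir / "seed_genomes.txt"
    p1.write_text("".join(f"{g}\n" for g in state["seed_ids"]))
    rows = [(f.family_id, gid, genome, f.seed_sc_presence)
            for f in state["families"] for gid, genome in f.members]
    df = pd.DataFrame(rows, columns=["family_id", "gene_id", "genome_id",
                                     "seed_sc_presence"])
    p2 = outdir / "seed_families.tsv"
    genome_io.write_table(df, p2)
    return [p1, p2]


def _load_seed_families(state: dict, outdir: Path) -> None:
    state["seed_ids"] = (outdir / "seed_genomes.txt").read_text().split()
    df = pd.read_csv(outdir / "seed_families.tsv", sep="\t", dtype={
        "family_id": str, "gene_id": str, "genome_id": str})
    families = []
    for fid, grp in df.groupby("family_id", sort=True):
        families.append(seed_families.GeneFamily(
            family_id=fid,
            members=[(r.gene_id, r.genome_id) for r in grp.itertuples()],
            seed_sc_presence=int(grp["seed_sc_presence"].iloc[0])))
    state["families"] = families


def _stage_profiles(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    candidates = scg_profiler.select_candidate_families(
        state["families"], cfg.k_candidate)
    if not candidates:
        raise PipelineError(
            f"no candidate SCGs (k_candidate={cfg.k_candidate}); "
            "lower k_candidate or add seed genomes")
    state["profiles"] = scg_profiler.build_family_profiles(
        candidates, state["genomes"], aligner=cfg.aligner)


def _save_profiles(state: dict, outdir: Path) -> list[Path]:
    p = outdir / "profiles.txt"
    scg_profiler.write_profiles(state["profiles"], p)
    return [p]


def _load_profiles(state: dict, outdir: Path) -> None:
    state["profiles"] = scg_profiler.read_profiles(outdir / "profiles.txt")


def _stage_search(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    profiles = state["profiles"]
    all_hits: list[scg_profiler.Hit] = []
    for genome in state["genomes"]:
        all_hits.extend(scg_profiler.score_genome_genes(
            profiles, genome, score_floor=cfg.score_floor,
            prefilter=cfg.kmer_prefilter, k=cfg.prefilter_k))
    resolved = scg_profiler.resolve_best_profile(all_hits)
    results = scg_profiler.train_all_cutoffs(resolved)
    cutoffs = {pid: r.cutoff for pid, r in results.items()}
    for p in profiles:
        p.cutoff = cutoffs.get(p.profile_id)
    genome_ids = [g.genome_id for g in state["genomes"]]
    copy_matrix = scg_profiler.build_copy_matrix(resolved, genome_ids, cutoffs)
    scg_ids = scg_profiler.select_definitive_scgs(copy_matrix, cfg.p_final)
    if not scg_ids:
        raise PipelineError(f"no definitive SCGs at p={cfg.p_final}%")
    state.update(hits=resolved, cutoff_results=results,
                 copy_matrix=copy_matrix, scg_ids=scg_ids)


def _save_search(state: dict, outdir: Path) -> list[Path]:
    paths = []
    p = outdir / "hits.tsv"
    genome_io.write_table(scg_profiler.hits_to_frame(state["hits"]), p)
    paths.append(p)
    rows = [(r.profile_id, r.cutoff, r.precision, r.recall, r.f_measure)
            for r in state["cutoff_results"].values()]
    p = outdir / "cutoffs.tsv"
    genome_io.write_table(pd.DataFrame(rows, columns=[
        "profile_id", "cutoff", "precision", "recall", "f_measure"]), p)
    paths.append(p)
    p = outdir / "profiles_trained.txt"
    scg_profiler.write_profiles(state["profiles"], p)
    paths.append(p)
    p = outdir / "copy_matrix.tsv"
    state["copy_matrix"].rename_axis("genome_id").reset_index().to_csv(
        p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "scgs.txt"
    p.write_text("".join(f"{s}\n" for s in state["scg_ids"]))
    paths.append(p)
    return paths


def _load_search(state: dict, outdir: Path) -> None:
    state["hits"] = scg_profiler.hits_from_frame(
        pd.read_csv(outdir / "hits.tsv", sep="\t", dtype={
            "gene_id": str, "genome_id": str, "profile_id": str}))
    df = pd.read_csv(outdir / "cutoffs.tsv", sep="\t")
    state["cutoff_results"] = {
        r.profile_id: scg_profiler.CutoffTrainingResult(
            profile_id=r.profile_id, cutoff=float(r.cutoff),
            precision=float(r.precision), recall=float(r.recall),
            f_measure=float(r.f_measure))
        for r in df.itertuples(index=False)}
    state["profiles"] = scg_profiler.read_profiles(outdir / "profiles_trained.txt")
    cm = pd.read_csv(outdir / "copy_matrix.tsv", sep="\t", index_col="genome_id")
    cm.index = cm.index.astype(str)
    state["copy_matrix"] = cm
    state["scg_ids"] = (outdir / "scgs.txt").read_text().split()


def _stage_qc(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    final_matrix = state["copy_matrix"][state["scg_ids"]]
    records = genome_qc.assess_all_genomes(
        final_matrix, cfg.completeness_min, cfg.redundancy_max)
    passing = genome_qc.filter_genomes(records)
    if len(passing) < 2:
        raise PipelineError("fewer than two genomes passed quality control")
    state.update(quality=records, passing=passing)


def _save_qc(state: dict, outdir: Path) -> list[Path]:
    p = outdir / "quality.tsv"
    genome_io.write_table(genome_qc.quality_frame(state["quality"]), p)
    return [p]


def _load_qc(state: dict, outdir: Path) -> None:
    df = pd.read_csv(outdir / "quality.tsv", sep="\t",
                     dtype={"genome_id": str, "reason": str},
                     keep_default_na=False)
    records = [genome_qc.QualityRecord(
        genome_id=r.genome_id, completeness=float(r.completeness),
        redundancy=float(r.redundancy),
        passed=str(r.passed).lower() == "true", reason=r.reason)
        for r in df.itertuples(index=False)]
    state["quality"] = records
    state["passing"] = [r.genome_id for r in records if r.passed]


def _stage_cni(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    cutoffs = {pid: r.cutoff for pid, r in state["cutoff_results"].items()}
    copies = supermatrix.choose_scg_copies(state["hits"], cutoffs,
                                           state["scg_ids"])
    alignments = supermatrix.build_scg_alignments(
        state["genomes"], copies, state["passing"], aligner=cfg.aligner)
    sm = supermatrix.build_supermatrix(alignments, state["passing"])
    cni = supermatrix.pairwise_cni(sm)
    state.update(scg_copies=copies, supermatrix=sm, cni=cni)


def _save_cni(state: dict, outdir: Path) -> list[Path]:
    sm = state["supermatrix"]
    paths = []
    p = outdir / "supermatrix.fasta"
    supermatrix.write_supermatrix_fasta(sm, p)
    paths.append(p)
    p = outdir / "supermatrix.phylip"
    supermatrix.write_supermatrix_phylip(sm, p)
    paths.append(p)
    p = outdir / "blocks.tsv"
    genome_io.write_table(pd.DataFrame(
        [(s, a, b) for s, (a, b) in sorted(sm.block_map.items())],
        columns=["scg_id", "start", "end"]), p)
    paths.append(p)
    p = outdir / "cni_long.tsv"
    genome_io.write_table(supermatrix.cni_long_frame(state["cni"]), p)
    paths.append(p)
    p = outdir / "cni_matrix.tsv"
    supermatrix.cni_square_frame(state["cni"]).rename_axis(
        "genome_id").reset_index().to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths


def _load_cni(state: dict, outdir: Path) -> None:
    blocks = pd.read_csv(outdir / "blocks.tsv", sep="\t", dtype={"scg_id": str})
    block_map = {r.scg_id: (int(r.start), int(r.end))
                 for r in blocks.itertuples(index=False)}
    sm = supermatrix.read_supermatrix_fasta(outdir / "supermatrix.fasta",
                                            block_map)
    sq = pd.read_csv(outdir / "cni_matrix.tsv", sep="\t",
                     index_col="genome_id")
    ids = list(sq.index.astype(str))
    long = pd.read_csv(outdir / "cni_long.tsv", sep="\t",
                       dtype={"genome_a": str, "genome_b": str})
    n = len(ids)
    compared = np.zeros((n, n), dtype=int)
    idx = {g: i for i, g in enumerate(ids)}
    for r in long.itertuples(index=False):
        i, j = idx[r.genome_a], idx[r.genome_b]
        compared[i, j] = compared[j, i] = int(r.compared_sites)
    values = sq.to_numpy(dtype=float)
    for i in range(n):
        compared[i, i] = 1 if not np.isnan(values[i, i]) else 0
    state["supermatrix"] = sm
    state["cni"] = supermatrix.CNIMatrix(genome_ids=ids, values=values,
                                         compared_sites=compared)
    cutoffs = {pid: r.cutoff for pid, r in state["cutoff_results"].items()}
    state["scg_copies"] = supermatrix.choose_scg_copies(
        state["hits"], cutoffs, state["scg_ids"])


def _stage_cluster(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    cni = state["cni"]
    clusters = species_clustering.cluster_single_linkage(cni, cfg.cni_cutoff)
    clusters = species_clustering.evaluate_exclusivity(clusters, cni,
                                                       cfg.cni_cutoff)
    final_matrix = state["copy_matrix"][state["scg_ids"]]
    clusters = species_clustering.select_representatives(clusters, final_matrix)
    scan = species_clustering.scan_cutoffs(cni)
    state.update(clusters=clusters, cutoff_scan=scan)


def _save_cluster(state: dict, outdir: Path) -> list[Path]:
    paths = []
    p = outdir / "clusters.tsv"
    genome_io.write_table(
        species_clustering.clusters_frame(state["clusters"]), p)
    paths.append(p)
    p = outdir / "cluster_summary.tsv"
    genome_io.write_table(
        species_clustering.cluster_summary_frame(state["clusters"]), p)
    paths.append(p)
    p = outdir / "cutoff_scan.tsv"
    genome_io.write_table(state["cutoff_scan"], p)
    paths.append(p)
    # representative SCG genes, for classification of new genomes
    gene_lookup = {g.gene_id: g for genome in state["genomes"]
                   for g in genome.genes}
    rows = []
    for c in state["clusters"]:
        rep = c.representative
        for scg, per_genome in sorted(state["scg_copies"].items()):
            gid = per_genome.get(rep)
            if gid is not None:
                gene = gene_lookup[gid]
                rows.append((c.cluster_id, rep, scg, gid, gene.nt_seq))
    p = outdir / "ref_genes.tsv"
    genome_io.write_table(pd.DataFrame(rows, columns=[
        "cluster_id", "genome_id", "scg_id", "gene_id", "nt_seq"]), p)
    paths.append(p)
    return paths


def _load_cluster(state: dict, outdir: Path) -> None:
    summary = pd.read_csv(outdir / "cluster_summary.tsv", sep="\t",
                          dtype={"cluster_id": str, "nearest_cluster_id": str,
                                 "representative": str},
                          keep_default_na=False)
    membership = pd.read_csv(outdir / "clusters.tsv", sep="\t",
                             dtype={"genome_id": str, "cluster_id": str})
    members = {cid: sorted(grp["genome_id"])
               for cid, grp in membership.groupby("cluster_id")}
    clusters = []
    for r in summary.itertuples(index=False):
        def _opt(v):
            try:
                f = float(v)
            except (TypeError, ValueError):
                return None
            return None if np.isnan(f) else f
        clusters.append(species_clustering.SpeciesCluster(
            cluster_id=r.cluster_id, members=members[r.cluster_id],
            min_within_cni=_opt(r.min_within_cni),
            max_between_cni=_opt(r.max_between_cni),
            nearest_cluster_id=r.nearest_cluster_id or None,
            exclusive=str(r.exclusive).lower() == "true",
            transitive=str(r.transitive).lower() == "true",
            representative=r.representative or None))
    state["clusters"] = clusters
    state["cutoff_scan"] = pd.read_csv(outdir / "cutoff_scan.tsv", sep="\t")


def _stage_phylogeny(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    reps = sorted(c.representative for c in state["clusters"])
    final_matrix = state["copy_matrix"].loc[reps, state["scg_ids"]]
    top = supermatrix.select_top_scgs(final_matrix, cfg.top_scg_count)
    alignments = supermatrix.build_scg_alignments(
        state["genomes"],
        {s: state["scg_copies"][s] for s in top},
        reps, aligner=cfg.aligner)
    sm = supermatrix.build_supermatrix(alignments, reps)
    state["phylo_supermatrix"] = supermatrix.trim_columns(sm, cfg.trim_gap_max)


def _save_phylogeny(state: dict, outdir: Path) -> list[Path]:
    p1 = outdir / "phylo_supermatrix.fasta"
    supermatrix.write_supermatrix_fasta(state["phylo_supermatrix"], p1)
    p2 = outdir / "phylo_supermatrix.phylip"
    supermatrix.write_supermatrix_phylip(state["phylo_supermatrix"], p2)
    return [p1, p2]


def _load_phylogeny(state: dict, outdir: Path) -> None:
    state["phylo_supermatrix"] = supermatrix.read_supermatrix_fasta(
        outdir / "phylo_supermatrix.fasta")


def _stage_name(state: dict, cfg: PipelineConfig, outdir: Path) -> None:
    if state.get("type_table") is None:
        logger.info("no type strain table supplied; clusters stay unnamed")
        state["type_records"], state["type_conflicts"] = [], pd.DataFrame(
            columns=["genome_id", "normalized_strain", "species"])
    else:
        state["type_records"], state["type_conflicts"] = (
            taxonomy_naming.match_type_genomes(state["manifest"],
                                               state["type_table"]))
    state["cluster_names"] = taxonomy_naming.name_clusters(
        state["clusters"], state["type_records"])
    state["reclassifications"] = taxonomy_naming.report_reclassifications(
        state["manifest"], state["clusters"], state["cluster_names"])


def _save_name(state: dict, outdir: Path) -> list[Path]:
    paths = []
    p = outdir / "cluster_names.tsv"
    genome_io.write_table(
        taxonomy_naming.cluster_names_frame(state["cluster_names"]), p)
    paths.append(p)
    p = outdir / "reclassifications.tsv"
    genome_io.write_table(state["reclassifications"], p)
    paths.append(p)
    p = outdir / "type_conflicts.tsv"
    genome_io.write_table(state["type_conflicts"], p)
    paths.append(p)
    return paths


def _load_name(state: dict, outdir: Path) -> None:
    df = pd.read_csv(outdir / "cluster_names.tsv", sep="\t",
                     dtype=str, keep_default_na=False)
    state["cluster_names"] = [
        taxonomy_naming.ClusterName(
            cluster_id=r.cluster_id, name=r.name, status=r.status,
            merged_names=[m for m in r.merged_names.split(",") if m],
            notes=r.notes)
        for r in df.itertuples(index=False)]
    state["reclassifications"] = pd.read_csv(
        outdir / "reclassifications.tsv", sep="\t", dtype=str,
        keep_default_na=False)


_STAGE_FUNCS: dict[str, tuple[Callable, Callable, Callable]] = {
    "seed-families": (_stage_seed_families, _save_seed_families,
                      _load_seed_families),
    "profiles": (_stage_profiles, _save_profiles, _load_profiles),
    "search": (_stage_search, _save_search, _load_search),
    "qc": (_stage_qc, _save_qc, _load_qc),
    "cni": (_stage_cni, _save_cni, _load_cni),
    "cluster": (_stage_cluster, _save_cluster, _load_cluster),
    "phylogeny": (_stage_phylogeny, _save_phylogeny, _load_phylogeny),
    "name": (_stage_name, _save_name, _load_name),
}


def run_pipeline(config: PipelineConfig, manifest_path: str | Path,
                 outdir: str | Path,
                 type_strains_path: str | Path | None = None,
                 stop_after: Optional[str] = None,
                 resume: bool = True) -> RunManifest:
    """Run the pipeline end to end; returns the run manifest.

    With ``resume`` (default), stages whose recorded output checksums match
    the files on disk are loaded instead of recomputed; any config change
    invalidates the cache. ``stop_after`` limits execution to a stage prefix.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise PipelineError(f"genome manifest not found: {manifest_path}")
    if stop_after is not None and stop_after not in STAGES:
        raise PipelineError(f"unknown stage {stop_after!r}; stages: {STAGES}")

    manifest = genome_io.read_manifest(manifest_path)
    state: dict = {
        "manifest": manifest,
        "genomes": genome_io.load_genomes(manifest, manifest_path.parent),
        "type_table": (taxonomy_naming.read_type_strain_table(type_strains_path)
                       if type_strains_path else None),
    }

    prev: Optional[RunManifest] = None
    manifest_json = outdir / "run_manifest.json"
    if resume and manifest_json.exists():
        prev = RunManifest.from_json(manifest_json)
        if prev.config != config.to_dict():
            logger.info("configuration changed; ignoring previous run")
            prev = None

    run = RunManifest(config=config.to_dict(), rng_seed=config.rng_seed)
    prev_stages = {s["name"]: s for s in prev.stages} if prev else {}
    for stage in STAGES:
        compute, save, load = _STAGE_FUNCS[stage]
        cached = prev_stages.get(stage)
        can_skip = (cached is not None
                    and all(Path(p).exists() and _sha256(Path(p)) == sha
                            for p, sha in cached["outputs"].items()))
        t0 = time.monotonic()
        if can_skip:
            load(state, outdir)
            run.stages.append({**cached, "skipped": True})
            logger.info("stage %-13s skipped (resumed from disk)", stage)
        else:
            compute(state, config, outdir)
            outputs = save(state, outdir)
            run.stages.append({
                "name": stage,
                "outputs": {str(p): _sha256(p) for p in outputs},
                "skipped": False,
            })
            logger.info("stage %-13s done in %.1fs", stage,
                        time.monotonic() - t0)
        run.to_json(manifest_json)
        if stage == stop_after:
            break
    return run


def load_reference_db(outdir: str | Path) -> species_clustering.ReferenceDB:
    """Load a finished run directory as a classification reference."""
    outdir = Path(outdir)
    profiles = scg_profiler.read_profiles(outdir / "profiles_trained.txt")
    scg_ids = (outdir / "scgs.txt").read_text().split()
    summary = pd.read_csv(outdir / "cluster_summary.tsv", sep="\t",
                          dtype={"cluster_id": str, "representative": str})
    representatives = {r.cluster_id: r.representative
                       for r in summary.itertuples(index=False)}
    ref = pd.read_csv(outdir / "ref_genes.tsv", sep="\t", dtype=str)
    rep_genes: dict[str, dict[str, tuple[str, str]]] = {}
    for r in ref.itertuples(index=False):
        aa = genome_io.translate_cds(r.nt_seq)
        rep_genes.setdefault(r.genome_id, {})[r.scg_id] = (aa, r.nt_seq)
    names_path = outdir / "cluster_names.tsv"
    cluster_names: dict[str, str] = {}
    if names_path.exists():
        nm = pd.read_csv(names_path, sep="\t", dtype=str, keep_default_na=False)
        cluster_names = {r.cluster_id: r.name for r in nm.itertuples(index=False)}
    cfg = RunManifest.from_json(outdir / "run_manifest.json").config
    return species_clustering.ReferenceDB(
        profiles=profiles, scg_ids=scg_ids, representatives=representatives,
        rep_genes=rep_genes, cluster_names=cluster_names,
        completeness_min=float(cfg.get("completeness_min", 0.90)))
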