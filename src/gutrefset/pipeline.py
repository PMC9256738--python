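"""End-to-end reference-set construction.

Stage order is fixed: quality scoring -> filtration -> per-individual
dereplication -> all-vs-all distances -> average-linkage clustering at
the species bound -> representative selection.  Every intermediate is
persisted under the output directory and the run configuration is
serialised into the manifest, so a build is reproducible from its
output alone.  The only randomness is the fixed k-mer hash seed; the
build itself is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from gutrefset import cluster as _cluster
from gutrefset import debias, genome_io, minhash, novelty, quality

log = logging.getLogger("gutrefset")


@dataclass
class RunConfig:
    metadata_path: str = "full_metadata.csv"
    fasta_root: str | None = None
    out_dir: str = "gutrefset_out"
    kmer_size: int = minhash.DEFAULT_K
    sketch_size: int = minhash.DEFAULT_SKETCH_SIZE
    hash_seed: int = minhash.DEFAULT_HASH_SEED
    completeness_min: float = quality.COMPLETENESS_MIN
    contamination_max: float = quality.CONTAMINATION_MAX
    heterogeneity_max: float = quality.HETEROGENEITY_MAX
    allow_missing_heterogeneity: bool = False
    species_bound: float = _cluster.SPECIES_BOUND
    t_species: float = novelty.T_SPECIES
    t_genus: float = novelty.T_GENUS
    t_family: float = novelty.T_FAMILY
    ura_window_unique: int = 100
    ura_min_reads: int = 50
    ura_alpha: float = 0.05
    read_length: int = 100

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BuildResult:
    clusters: list
    representatives: dict[str, str]  # assembly_id -> representative FASTA path
    counts: dict[str, int]
    manifest_path: str
    quality_table: pd.DataFrame
    decisions: list
    store: minhash.DistanceStore


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _full_path(cfg: RunConfig, p: str) -> str:
    if cfg.fasta_root is not None and not os.path.isabs(p):
        return os.path.join(cfg.fasta_root, p)
    return p


def run_build(config: RunConfig) -> BuildResult:
    """Execute the published stage order and persist every intermediate."""
    os.makedirs(config.out_dir, exist_ok=True)

    # --- load metadata and genomes -------------------------------------
    table = genome_io.load_metadata(config.metadata_path)
    records = [r for r in table.records if not r.excluded]
    excluded = [r for r in table.records if r.excluded]
    log.info("metadata: %d rows, %d excluded by DoNotTake", len(table), len(excluded))

    loaded = []
    for rec in records:
        path = _full_path(config, rec.fasta_path)
        if not os.path.exists(path):
            raise StageError("load", f"missing FASTA for {rec.assembly_id}: {path}")
        loaded.append(rec.with_contigs(genome_io.read_fasta(path)))
    if not loaded:
        raise StageError("load", "no usable assemblies in metadata")

    # --- quality -------------------------------------------------------
    metrics: dict[str, quality.QualityMetrics] = {}
    qrows = []
    passing = []
    for rec in loaded:
        stats = genome_io.assembly_stats(rec.contigs)
        m = quality.QualityMetrics(
            rec.completeness, rec.contamination, rec.heterogeneity, stats["n50"]
        )
        metrics[rec.assembly_id] = m
        ok, reasons = quality.passes_filters(
            m,
            completeness_min=config.completeness_min,
            contamination_max=config.contamination_max,
            heterogeneity_max=config.heterogeneity_max,
            allow_missing_heterogeneity=config.allow_missing_heterogeneity,
        )
        qrows.append(
            {
                "assembly_id": rec.assembly_id,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "heterogeneity": m.heterogeneity,
                "length": stats["length"],
                "n_contigs": stats["n_contigs"],
                "n50": stats["n50"],
                "quality_score": quality.quality_score(m),
                "pass": ok,
                "reasons": ";".join(reasons),
            }
        )
        if ok:
            passing.append(rec)
    qtable = pd.DataFrame(qrows)
    qtable.to_csv(os.path.join(config.out_dir, "quality.tsv"), sep="\t", index=False)
    if not passing:
        raise StageError("quality", "no assemblies passed filters")
    log.info("quality: %d/%d assemblies passed", len(passing), len(loaded))

    # --- sketches ------------------------------------------------------
    sketches = {
        rec.assembly_id: minhash.sketch_genome(
            rec, k=config.kmer_size, s=config.sketch_size, hash_seed=config.hash_seed
        )
        for rec in passing
    }

    # --- per-individual dereplication ---------------------------------
    retained, decisions = debias.dedup_pool(
        passing, sketches, metrics, threshold=config.species_bound
    )
    pd.DataFrame(
        [
            {
                "assembly_id": d.assembly_id,
                "kept": d.kept,
                "blocked_by": d.blocked_by or "",
                "distance_to_blocker": (
                    "" if d.distance_to_blocker is None else f"{d.distance_to_blocker:.6f}"
                ),
                "quality_score": d.score,
            }
            for d in decisions
        ]
    ).to_csv(os.path.join(config.out_dir, "dedup_decisions.tsv"), sep="\t", index=False)
    if not retained:
        raise StageError("filter", "dereplication removed every assembly")
    log.info("debias: %d/%d assemblies retained", len(retained), len(passing))

    # --- distances -----------------------------------------------------
    if len(retained) == 1:
        store = minhash.DistanceStore.create([retained[0].assembly_id])
        clusters = [
            _cluster.SpeciesCluster(
                0,
                (retained[0].assembly_id,),
                retained[0].assembly_id,
                quality.quality_score(metrics[retained[0].assembly_id]),
            )
        ]
    else:
        store = minhash.pairwise_distances(
            [sketches[r.assembly_id] for r in retained],
            path=os.path.join(config.out_dir, "distances.mmap"),
        )
        clusters, _ = _cluster.average_linkage_cluster(
            store, metrics, bound=config.species_bound
        )
    log.info("cluster: %d species clusters", len(clusters))

    # --- representatives ----------------------------------------------
    rep_dir = os.path.join(config.out_dir, "representatives")
    os.makedirs(rep_dir, exist_ok=True)
    by_id = {r.assembly_id: r for r in retained}
    rep_paths: dict[str, str] = {}
    manifest_rows = []
    for cl in clusters:
        rec = by_id[cl.representative_id]
        dest = os.path.join(rep_dir, f"{cl.representative_id}.fa")
        genome_io.write_fasta(dest, rec.contigs)
        rep_paths[cl.representative_id] = dest
        manifest_rows.append(
            {
                "cluster_id": cl.cluster_id,
                "representative": cl.representative_id,
                "representative_score": cl.representative_score,
                "size": len(cl),
                "members": ",".join(cl.member_ids),
                "fasta": os.path.relpath(dest, config.out_dir),
            }
        )
    manifest_df = pd.DataFrame(manifest_rows)
    manifest_df.to_csv(os.path.join(config.out_dir, "clusters.tsv"), sep="\t", index=False)

    counts = {
        "metadata_rows": len(table),
        "excluded_do_not_take": len(excluded),
        "loaded": len(loaded),
        "quality_pass": len(passing),
        "dedup_kept": len(retained),
        "clusters": len(clusters),
    }
    manifest = {
        "config": config.to_json(),
        "counts": counts,
        "representatives": sorted(rep_paths),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return BuildResult(clusters, rep_paths, counts, manifest_path, qtable, decisions, store)


def run_novelty(
    config: RunConfig, external_dir: str, rep_paths: dict[str, str] | None = None
) -> pd.DataFrame:
    """Classify representatives against an external reference directory."""
    if rep_paths is None:
        rep_dir = os.path.join(config.out_dir, "representatives")
        rep_paths = {
            os.path.splitext(f)[0]: os.path.join(rep_dir, f)
            for f in sorted(os.listdir(rep_dir))
            if f.endswith((".fa", ".fasta", ".fna"))
        }
    ext_files = sorted(
        f for f in os.listdir(external_dir) if f.endswith((".fa", ".fasta", ".fna"))
    )
    if not ext_files:
        raise StageError("novelty", f"no FASTA files in external dir {external_dir}")
    if not rep_paths:
        raise StageError("novelty", "no representative genomes to classify")

    def _sk(gid, path):
        return minhash.sketch_sequence(
            [c.sequence for c in genome_io.read_fasta(path)],
            k=config.kmer_size,
            s=config.sketch_size,
            genome_id=gid,
            hash_seed=config.hash_seed,
        )

    reps = [_sk(gid, p) for gid, p in sorted(rep_paths.items())]
    ext = [_sk(os.path.splitext(f)[0], os.path.join(external_dir, f)) for f in ext_files]
    calls = novelty.classify_novelty(
        reps, ext, t_species=config.t_species, t_genus=config.t_genus, t_family=config.t_family
    )
    df = pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "nearest_external_id": c.nearest_external_id,
                "nearest_distance": c.nearest_distance,
                "tier": c.tier,
            }
            for c in calls
        ]
    )
    df.to_csv(os.path.join(config.out_dir, "novelty.tsv"), sep="\t", index=False)
    return df
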