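"""End-to-end orchestration: reads -> graph -> clusters -> fingerprint -> trees.

`run_pipeline` chains the stages on an in-memory :class:`ReadSet`; every stage
is equally usable on its own (see the stage modules), and the CLI wraps this
module.  `simulate_study` wires the synthetic repeatome generator to the
pipeline inputs for simulation studies, including hybrid genomes.

The observed/expected ("obs") master matrix is built from clusters that pass
all filters (species-specific, contamination, NA); the raw-edges master
additionally keeps NA-flagged clusters, since edge counts are always defined
— mirroring how the method retains more clusters for its edges analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .archive import ClusterRecord, filter_records, parse_archive, write_archive
from .cluster import (
    ClusterPartition,
    SimilarityGraph,
    build_graph,
    cluster_read_counts,
    edge_count_array,
    louvain,
    matrices_from_counts,
)
from .fingerprint import (
    gower_distance,
    pcoa_distance,
    subset_by_annotation,
    sum_master,
    to_dissimilarity,
)
from .matrices import MasterMatrix
from .multivariate import (
    OrdinationResult,
    PhyloTree,
    SplitSystem,
    bootstrap_support,
    neighbornet,
    nj_tree,
    pcoa,
)
from .simulate import (
    HybridSpec,
    default_study,
    evolve_families,
    make_hybrid,
    sample_reads,
)
from .species import ReadSet, SpeciesProfile

__all__ = ["PipelineResult", "run_pipeline", "records_from_graph", "simulate_study"]

logger = logging.getLogger(__name__)


def records_from_graph(
    graph: SimilarityGraph,
    partition: ClusterPartition,
    read_annotations: dict[str, str] | None = None,
    min_cluster_size: int = 2,
) -> list[ClusterRecord]:
    """Build one :class:`ClusterRecord` per cluster of the partition.

    Clusters below ``min_cluster_size`` reads (by default the singletons,
    i.e. unclustered non-repetitive reads) get no record, matching how
    comparative-clustering archives only report proper clusters.  A cluster
    containing reads of a single species gets no between-species matrix
    (species_specific).  Annotation proportions are the fraction of the
    cluster's reads carrying each label.
    """
    labels = graph.species_labels
    counts_all = edge_count_array(graph, partition)
    records = []
    for cid in range(1, partition.n_clusters + 1):
        nodes = partition.clusters[cid - 1]
        if len(nodes) < min_cluster_size:
            continue
        counts = cluster_read_counts(graph, partition, cid)
        n_species = sum(1 for v in counts.values() if v > 0)
        edges, obs_exp = matrices_from_counts(counts_all[cid], labels)
        if n_species <= 1:
            obs_exp = None
        annotations: dict[str, float] = {}
        if read_annotations:
            size = len(nodes)
            tally: dict[str, int] = {}
            for node in nodes:
                label = read_annotations.get(graph.read_ids[node])
                if label:
                    tally[label] = tally.get(label, 0) + 1
            annotations = {lab: c / size for lab, c in tally.items()}
        records.append(
            ClusterRecord(
                cluster_id=cid,
                edges=edges,
                obs_exp=obs_exp,
                read_counts=counts,
                annotations=annotations,
            )
        )
    return records


@dataclass
class PipelineResult:
    graph: SimilarityGraph
    partition: ClusterPartition
    records: list[ClusterRecord]
    kept: list[ClusterRecord]
    filter_report: dict[str, int]
    master_obs: MasterMatrix | None
    master_edges: MasterMatrix | None
    pcoa_obs: OrdinationResult | None
    tree: PhyloTree | None
    network: SplitSystem | None
    subsets: dict[str, dict]
    manifest: dict = field(default_factory=dict)

    @property
    def repetitive_fraction(self) -> float:
        """Fraction of reads placed in non-singleton clusters."""
        sizes = self.partition.sizes()
        total = sizes.sum()
        return float(sizes[sizes > 1].sum() / total) if total else 0.0


def _analyze_master(master: MasterMatrix):
    """PCoA on the square-rooted distance role of a master matrix."""
    return pcoa(pcoa_distance(master))


def run_pipeline(
    reads: ReadSet,
    seed: int = 0,
    min_identity: float = 0.90,
    min_overlap_frac: float = 0.55,
    kmer: int = 13,
    resolution: float = 1.0,
    rdna_min_hit: float = 0.01,
    bootstrap: int = 0,
    subset_labels: tuple[str, ...] = (),
    read_annotations: dict[str, str] | None = None,
    archive_dir=None,
    min_cluster_size: int = 2,
) -> PipelineResult:
    """Run the full fingerprint pipeline on a prepared read pool.

    When ``archive_dir`` is given, cluster records are round-tripped through
    the on-disk archive dialect (written, then re-parsed) so that the
    downstream analysis consumes exactly what the archive holds.
    """
    graph = build_graph(reads, min_identity, min_overlap_frac, kmer)
    partition = louvain(graph, seed=seed, resolution=resolution)
    records = records_from_graph(graph, partition, read_annotations,
                                 min_cluster_size=min_cluster_size)
    if archive_dir is not None:
        write_archive(records, archive_dir)
        records = parse_archive(archive_dir)

    kept, report = filter_records(records)
    kept_edges, _ = filter_records(records, drop_na=False)
    logger.info(
        "clusters: %d total; removed %s; retained %d (obs) / %d (edges); "
        "repetitive read fraction %.1f%%",
        len(records), report, len(kept), len(kept_edges),
        100.0 * _repetitive_fraction(partition),
    )

    master_obs = master_edges = None
    pcoa_obs = tree = network = None
    if kept:
        master_obs = sum_master([to_dissimilarity(r.obs_exp) for r in kept], "obs")
        pcoa_obs = _analyze_master(master_obs)
        gower = gower_distance(master_obs)
        if len(master_obs.species) >= 3:
            if bootstrap > 0 and len(kept) >= 2:
                tree = bootstrap_support(
                    [to_dissimilarity(r.obs_exp) for r in kept],
                    replicates=bootstrap,
                    seed=seed,
                )
            else:
                tree = nj_tree(gower)
        if len(master_obs.species) >= 4:
            network = neighbornet(gower)
    if kept_edges:
        master_edges = sum_master(
            [to_dissimilarity(r.edges) for r in kept_edges], "edges"
        )

    subsets: dict[str, dict] = {}
    for label in subset_labels:
        sub = subset_by_annotation(kept, label, min_hit=rdna_min_hit)
        if not sub:
            logger.info("subset %r: no annotated clusters; ordination skipped", label)
            subsets[label] = {"n_clusters": 0}
            continue
        sub_master = sum_master(
            [to_dissimilarity(r.obs_exp) for r in sub], "obs"
        )
        sub_master.subset_label = label
        entry = {
            "n_clusters": len(sub),
            "cluster_ids": [r.cluster_id for r in sub],
            "master": sub_master,
            "pcoa": _analyze_master(sub_master),
        }
        if len(sub_master.species) >= 4:
            entry["network"] = neighbornet(gower_distance(sub_master))
        subsets[label] = entry

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "min_identity": min_identity,
            "min_overlap_frac": min_overlap_frac,
            "kmer": kmer,
            "resolution": resolution,
            "rdna_min_hit": rdna_min_hit,
            "bootstrap": bootstrap,
            "subset_labels": list(subset_labels),
        },
        "n_reads": len(reads),
        "reads_per_species": reads.counts_per_species(),
        "n_clusters": partition.n_clusters,
        "repetitive_fraction": _repetitive_fraction(partition),
        "filter_report": report,
        "n_kept_obs": len(kept),
        "n_kept_edges": len(kept_edges),
    }
    return PipelineResult(
        graph, partition, records, kept, report,
        master_obs, master_edges, pcoa_obs, tree, network, subsets, manifest,
    )


def _repetitive_fraction(partition: ClusterPartition) -> float:
    sizes = partition.sizes()
    total = sizes.sum()
    return float(sizes[sizes > 1].sum() / total) if total else 0.0


def simulate_study(
    seed: int,
    reads_per_species: int = 2000,
    hybrid: HybridSpec | None = None,
    hybrid_prefix: str = "HHHH",
    error_rate: float = 0.0,
    background_fraction: float = 0.6,
    read_length: int = 100,
) -> tuple[ReadSet, pd.DataFrame, dict[str, str], str]:
    """Simulate the default six-species study (optionally plus a hybrid).

    Returns the read pool, the truth table, the read -> annotation-label map
    (for rDNA-like families) and the true tree in Newick.  All randomness —
    family consensus sequences, evolution, hybrid resampling, read sampling —
    derives from ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sub = rng.integers(0, 2**31 - 1, size=4)
    tree, families, profiles = default_study(reads_per_species, seed=int(sub[0]))
    pools = evolve_families(tree, families, seed=int(sub[1]))
    gsizes = {p.label: p.genome_size for p in profiles}
    if hybrid is not None:
        pool, gsize = make_hybrid(pools, hybrid, seed=int(sub[2]), genome_sizes=gsizes)
        pools[hybrid.child] = pool
        profiles = profiles + [
            SpeciesProfile(hybrid.child, hybrid_prefix, gsize or 1.0,
                           budget=reads_per_species)
        ]
    readset, truth = sample_reads(
        pools,
        profiles,
        read_length=read_length,
        error_rate=error_rate,
        background_fraction=background_fraction,
        seed=int(sub[3]),
    )
    fam_label = {f.family_id: f.annotation_label for f in families if f.annotation_label}
    annotations = {
        rid: fam_label[fam]
        for rid, fam in zip(truth.read_id, truth.family)
        if fam in fam_label
    }
    return readset, truth, annotations, tree
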