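"""End-to-end workflows stitching the pipeline stages together.

Two recovery workflows run the full chain on generator output and join
the results against ground truth; they back the package's
parameter-recovery checks and serve as usage examples:

* :func:`run_transcriptome_recovery` — reads -> clustering -> expression;
* :func:`run_proteomics_recovery` — proteins -> digest -> simulated
  detections -> protein groups -> top-3 quantification.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass

import pandas as pd

from .clustering import ClusterAssignment, greedy_cluster
from .digest import IonIndex, enumerate_ions
from .expression import summarize_expression
from .inference import (ProteinGroup, aggregate_intensities, assign_peptides,
                        build_groups, normalize_and_rank, read_observations)
from .synthetic import GroundTruth, SimulationConfig, simulate_detections, \
    simulate_transcriptome


@dataclass
class TranscriptomeRecovery:
    """Clustered, quantified synthetic pools joined with ground truth."""

    truth: GroundTruth
    assignment: ClusterAssignment
    expression: pd.DataFrame   # per-cluster table from summarize_expression
    gene_table: pd.DataFrame   # per-gene truth vs. estimate

    @property
    def n_clusters(self) -> int:
        return self.assignment.n_clusters


def merge_pools(reads) -> "OrderedDict[str, str]":
    merged: "OrderedDict[str, str]" = OrderedDict()
    for pool in reads.values():
        merged.update(pool)
    return merged


def run_transcriptome_recovery(config: SimulationConfig, k: int = 15,
                               min_shared_fraction: float = 0.5,
                               ) -> TranscriptomeRecovery:
    """Simulate pools, cluster, quantify, and align clusters to genes.

    Each cluster is attributed to the gene contributing most of its reads
    (with the attribution purity recorded); each gene is then matched to
    the cluster holding most of its reads, giving a per-gene table of true
    versus estimated sex ratio and bias label.
    """
    reads, truth = simulate_transcriptome(config)
    merged = merge_pools(reads)
    assignment = greedy_cluster(merged, k=k,
                                min_shared_fraction=min_shared_fraction)
    expression = summarize_expression(assignment, truth.sample_of_read)

    cluster_of_gene: dict[str, str] = {}
    purity: dict[str, float] = {}
    gene_read_counts: dict[str, Counter] = {}
    for cluster, members in assignment.members.items():
        origins = Counter(truth.read_origin[r] for r in members)
        top_gene, top_n = origins.most_common(1)[0]
        purity[cluster] = top_n / len(members)
        gene_read_counts.setdefault(top_gene, Counter())[cluster] = top_n
    for gene, clusters in gene_read_counts.items():
        cluster_of_gene[gene] = clusters.most_common(1)[0][0]

    by_cluster = expression.set_index("cluster_id")
    true_ratio = truth.true_log10_ratio()
    rows = []
    for gene in truth.genes.index:
        cluster = cluster_of_gene.get(gene)
        est_ratio = est_bias = None
        cluster_purity = None
        if cluster is not None:
            est_ratio = by_cluster.loc[cluster, "log10_sex_ratio"]
            est_bias = by_cluster.loc[cluster, "bias"]
            cluster_purity = purity[cluster]
        rows.append((gene, cluster, truth.genes.loc[gene, "bias"],
                     true_ratio[gene], est_bias, est_ratio, cluster_purity))
    gene_table = pd.DataFrame(rows, columns=[
        "gene_id", "cluster_id", "true_bias", "true_log10_ratio",
        "est_bias", "est_log10_ratio", "cluster_purity"])
    return TranscriptomeRecovery(truth=truth, assignment=assignment,
                                 expression=expression, gene_table=gene_table)


def bias_confusion(gene_table: pd.DataFrame) -> dict[str, float]:
    """Sensitivity and specificity of sex-bias calls against ground truth.

    A biased gene counts as correctly detected only when its estimated
    label matches the true tissue; any biased call on an unbiased gene is
    a false positive.
    """
    biased = gene_table[gene_table["true_bias"] != "unbiased"]
    unbiased = gene_table[gene_table["true_bias"] == "unbiased"]
    tp = (biased["est_bias"] == biased["true_bias"]).sum()
    tn = (unbiased["est_bias"] == "unbiased").sum()
    return {
        "sensitivity": tp / len(biased) if len(biased) else float("nan"),
        "specificity": tn / len(unbiased) if len(unbiased) else float("nan"),
    }


@dataclass
class ProteomicsRecovery:
    """Simulated detections pushed through grouping and quantification."""

    truth: GroundTruth
    index: IonIndex
    detections: pd.DataFrame
    groups: list[ProteinGroup]
    recovered_fraction: float
    unassigned: list[str]


def run_proteomics_recovery(config: SimulationConfig,
                            detection_seed: int | None = None,
                            ) -> ProteomicsRecovery:
    """Digest the ground-truth proteins and recover them as protein groups.

    Uses one database entry per gene (its true translation) with the gene
    as its own cluster, so with non-homologous random proteins each gene
    should come back as a distinct single-member group.
    ``recovered_fraction`` is the fraction of genes recovered as exactly
    one single-member group.
    """
    _, truth = simulate_transcriptome(config)
    db = {gene: truth.genes.loc[gene, "protein"] for gene in truth.genes.index}
    index = enumerate_ions(db)
    detections, _ = simulate_detections(db, config, seed=detection_seed)
    observations = read_observations(detections)
    assignment, unassigned = assign_peptides(observations, index)
    groups = build_groups(assignment, {gene: gene for gene in db})
    intensities = aggregate_intensities(observations)
    try:
        groups = normalize_and_rank(groups, intensities)
    except ValueError:
        pass  # no quantifiable group; groups stay unquantified
    singletons = {next(iter(g.member_cluster_ids))
                  for g in groups if len(g.member_cluster_ids) == 1}
    recovered = len(singletons & set(db)) / len(db) if db else float("nan")
    return ProteomicsRecovery(truth=truth, index=index, detections=detections,
                              groups=groups, recovered_fraction=recovered,
                              unassigned=unassigned)
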