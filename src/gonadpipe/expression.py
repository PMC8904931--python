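"""Per-cluster TPM, pseudocounted log10 sex ratio, bias calls and ranking.

Abundance of a gene-level cluster is its read count normalized to the
total reads of the sample, reported as transcripts per million (TPM); no
length normalization is applied because one long read represents one
transcript molecule.  The sex ratio of a cluster is

    log10((mean testis TPM + p) / (mean ovary TPM + p)),   p = 1.0 TPM,

where tissue means are taken over biological replicates before the
pseudocount is applied.  A cluster is called sex-biased when the
pseudocounted ratio exceeds a 10-fold difference, i.e. |ratio| > 1.
Clusters are ranked from most ovary-biased (rank 1) to most testis-biased.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .clustering import ClusterAssignment, SampleLabel

PSEUDOCOUNT_TPM = 1.0


def sex_ratio(mean_testis_tpm: float, mean_ovary_tpm: float,
              pseudocount: float = PSEUDOCOUNT_TPM) -> float:
    """log10 of the pseudocounted testis:ovary TPM ratio.

    The pseudocount keeps the ratio finite when either tissue has zero
    abundance.  Inputs must be non-negative.
    """
    if mean_testis_tpm < 0 or mean_ovary_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log10((mean_testis_tpm + pseudocount) /
                      (mean_ovary_tpm + pseudocount))


def classify_bias(log10_sex_ratio: float, fold_threshold: float = 10.0) -> str:
    """Label a cluster testis-biased, ovary-biased, or unbiased.

    The threshold is a strict >``fold_threshold``-fold difference applied
    to the pseudocounted ratio: exactly 10-fold is unbiased.
    """
    cut = math.log10(fold_threshold)
    if log10_sex_ratio > cut:
        return "testis"
    if log10_sex_ratio < -cut:
        return "ovary"
    return "unbiased"


def report_round(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching tabular report conventions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def compute_tpm(assignment: ClusterAssignment,
                sample_of_read: Mapping[str, SampleLabel],
                samples: Iterable[SampleLabel] | None = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read counts and TPM per cluster per sample.

    Returns ``(counts, tpm)`` as cluster x sample DataFrames whose columns
    are :class:`SampleLabel` objects.  ``tpm = 1e6 * count / total_reads``
    within each sample.  A sample listed in ``samples`` (or present in
    ``sample_of_read``) with zero reads in the assignment is an error.
    """
    for read in assignment.read_to_cluster:
        if read not in sample_of_read:
            raise ValueError(f"read {read!r} has no sample label")
    if samples is None:
        samples = sorted({sample_of_read[r] for r in assignment.read_to_cluster})
    else:
        samples = sorted(samples)
    clusters = list(assignment.representatives)
    pairs = pd.DataFrame({
        "cluster": list(assignment.read_to_cluster.values()),
        "sample": [sample_of_read[r] for r in assignment.read_to_cluster]})
    counts = (pd.crosstab(pairs["cluster"], pairs["sample"])
              .reindex(index=clusters, columns=samples, fill_value=0)
              .astype(int))
    counts.index.name = "cluster_id"
    totals = counts.sum(axis=0)
    for sample, total in totals.items():
        if total == 0:
            raise ValueError(f"sample {sample.tag} has zero reads")
    tpm = counts / totals * 1e6
    return counts, tpm


def rank_by_sex_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """1-based rank from most ovary-biased to most testis-biased.

    Ascending sort on ``log10_sex_ratio`` with ties broken by cluster id
    (lexicographic), so ranking is total and deterministic.
    """
    ordered = table.sort_values(
        ["log10_sex_ratio", "cluster_id"], kind="mergesort")
    ordered = ordered.reset_index(drop=True)
    ordered["rank"] = ordered.index + 1
    return ordered


def summarize_expression(assignment: ClusterAssignment,
                         sample_of_read: Mapping[str, SampleLabel],
                         pseudocount: float = PSEUDOCOUNT_TPM,
                         fold_threshold: float = 10.0,
                         rank_singletons: bool = False) -> pd.DataFrame:
    """Full per-cluster expression table for one species.

    Columns: per-sample counts and TPM (``count_<tag>``/``tpm_<tag>``),
    replicate-mean testis and ovary TPM, ``log10_sex_ratio``, ``bias`` and
    ``rank``.  Singleton clusters (one read in total) are reported but get
    no rank unless ``rank_singletons`` is set, mirroring summary statistics
    that exclude singletons.
    """
    species = {s.species for s in sample_of_read.values()}
    if len(species) > 1:
        raise ValueError(
            f"summarize_expression handles one species at a time, got {sorted(species)}")
    counts, tpm = compute_tpm(assignment, sample_of_read)
    testis = [s for s in counts.columns if s.tissue == "testis"]
    ovary = [s for s in counts.columns if s.tissue == "ovary"]
    if not testis or not ovary:
        raise ValueError("need at least one testis and one ovary sample")

    table = pd.DataFrame({"cluster_id": counts.index})
    for sample in counts.columns:
        table[f"count_{sample.tag}"] = counts[sample].to_numpy()
        table[f"tpm_{sample.tag}"] = tpm[sample].to_numpy()
    table["n_reads"] = counts.sum(axis=1).to_numpy()
    table["mean_testis_tpm"] = tpm[testis].mean(axis=1).to_numpy()
    table["mean_ovary_tpm"] = tpm[ovary].mean(axis=1).to_numpy()
    table["log10_sex_ratio"] = [
        sex_ratio(t, o, pseudocount)
        for t, o in zip(table["mean_testis_tpm"], table["mean_ovary_tpm"])]
    table["bias"] = [classify_bias(r, fold_threshold)
                     for r in table["log10_sex_ratio"]]

    rankable = table if rank_singletons else table[table["n_reads"] > 1]
    ranked = rank_by_sex_ratio(rankable[["cluster_id", "log10_sex_ratio"]])
    rank_of = dict(zip(ranked["cluster_id"], ranked["rank"]))
    table["rank"] = [rank_of.get(c, pd.NA) for c in table["cluster_id"]]
    return table
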