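"""Expression normalization, mRNA-mass gene sets and the core transcriptome.

Per-gene read counts become RPKM (reads per kilobase per million mapped
reads) and TPM (transcripts per million); replicates are summarized as
mean and standard deviation of RPKM.  Ranking genes by mean RPKM and
taking the smallest prefix whose summed expression reaches a fraction p
of the total gives the "p mRNA-mass set" — in these bacteria the 0.5
set is a few dozen genes, under 4% of the genome.  The core
transcriptome is the subset of core-genome families whose genes appear
in the 0.9 mass set of every organism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pangenome import GeneFamilyMatrix

__all__ = [
    "ExpressionTable",
    "rpkm",
    "tpm",
    "aggregate_replicates",
    "mass_fraction_set",
    "core_transcriptome",
    "read_counts_tsv",
]


def rpkm(counts, lengths) -> np.ndarray:
    """RPKM: counts / (kb of gene x millions of mapped reads)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if np.any(lengths <= 0):
        raise ValueError("non-positive gene length")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total counts")
    return counts / ((lengths / 1e3) * (total / 1e6))


def tpm(counts, lengths) -> np.ndarray:
    """TPM: length-normalized rates rescaled to sum to one million."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("non-positive gene length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("zero total rate")
    return rate / total * 1e6


def aggregate_replicates(rpkm_replicates: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample standard deviation of per-gene RPKM over replicates.

    With a single replicate the standard deviation is undefined and
    reported as 0 with a warning.
    """
    if not rpkm_replicates:
        raise ValueError("no replicates")
    arr = np.vstack(rpkm_replicates)
    if arr.shape[0] == 1:
        warnings.warn("single replicate: standard deviation reported as 0", stacklevel=2)
        return arr[0].copy(), np.zeros(arr.shape[1])
    return arr.mean(axis=0), arr.std(axis=0, ddof=1)


@dataclass
class ExpressionTable:
    """Counts, RPKM/TPM and replicate summaries for one organism.

    ``replicates`` holds per-biological-replicate count vectors aligned
    with ``gene_ids``; technical replicates should be averaged into a
    biological replicate before construction (see
    :func:`merge_technical_replicates`).
    """

    organism_label: str
    gene_ids: list[str]
    gene_lengths: np.ndarray
    replicates: list[np.ndarray]
    rpkm_replicates: list[np.ndarray] = field(init=False)
    tpm_replicates: list[np.ndarray] = field(init=False)
    mean_rpkm: np.ndarray = field(init=False)
    sd_rpkm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        n = len(self.gene_ids)
        if len(self.gene_lengths) != n:
            raise ValueError("gene_lengths does not match gene_ids")
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        for r in self.replicates:
            if len(r) != n:
                raise ValueError("replicate count vector does not match gene_ids")
            if np.any(r < 0):
                raise ValueError("negative counts")
        self.rpkm_replicates = [rpkm(r, self.gene_lengths) for r in self.replicates]
        self.tpm_replicates = [tpm(r, self.gene_lengths) for r in self.replicates]
        self.mean_rpkm, self.sd_rpkm = aggregate_replicates(self.rpkm_replicates)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "length_bp": self.gene_lengths.astype(int),
                "mean_rpkm": self.mean_rpkm,
                "sd_rpkm": self.sd_rpkm,
                "mean_tpm": np.vstack(self.tpm_replicates).mean(axis=0),
            }
        )
        return df


def merge_technical_replicates(counts: list[np.ndarray]) -> np.ndarray:
    """Average technical replicates into one biological replicate."""
    if not counts:
        raise ValueError("no technical replicates")
    return np.vstack([np.asarray(c, dtype=float) for c in counts]).mean(axis=0)


def mass_fraction_set(
    mean_rpkm: dict[str, float] | pd.Series, p: float
) -> list[str]:
    """Smallest descending-rank gene prefix carrying a fraction p of mRNA mass.

    Genes are ranked by decreasing mean RPKM (ties by gene id); the
    returned list is the shortest prefix whose summed RPKM reaches
    p x total, in rank order.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    series = pd.Series(mean_rpkm, dtype=float)
    total = series.sum()
    if total <= 0:
        raise ValueError("all-zero expression")
    order = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    target = p * total
    out: list[str] = []
    acc = 0.0
    for gene_id, value in order:
        out.append(gene_id)
        acc += value
        if acc >= target:
            break
    return out


def percentile_threshold_set(values: dict[str, float] | pd.Series, q: float) -> list[str]:
    """Genes at or above the q-th percentile of the expression values.

    An alternative, value-percentile reading of "top expressed genes":
    the set of genes whose expression is at least the q-th percentile of
    the per-gene distribution.  It is NOT the cumulative-mass set used
    by the default analyses (the two differ sharply for heavy-tailed
    expression) and is provided only for comparison.
    """
    series = pd.Series(values, dtype=float)
    cut = np.percentile(series.to_numpy(), q)
    keep = series[series >= cut]
    return sorted(keep.index, key=lambda g: (-keep[g], g))


def core_transcriptome(
    core_cluster_ids: set[str] | list[str],
    mass_sets_90: dict[str, set[str] | list[str]],
    matrix: GeneFamilyMatrix,
) -> set[str]:
    """Core families expressed in the 0.9 mRNA-mass set of every organism.

    ``mass_sets_90`` maps each organism label to its 0.9 mass gene-id
    set; a family counts as expressed in an organism when any of its
    member genes there is in that set.
    """
    missing = set(matrix.genome_labels) - set(mass_sets_90)
    if missing:
        raise ValueError(f"organisms missing expression data: {sorted(missing)}")
    sets = {org: set(genes) for org, genes in mass_sets_90.items()}
    members_by_cluster: dict[str, dict[str, set[str]]] = {}
    for c in matrix.clusters:
        per_org: dict[str, set[str]] = {}
        for genome, gene_id in c["members"]:
            per_org.setdefault(genome, set()).add(gene_id)
        members_by_cluster[c["cluster_id"]] = per_org
    out: set[str] = set()
    for cid in core_cluster_ids:
        per_org = members_by_cluster.get(cid, {})
        if all(
            per_org.get(org, set()) & sets[org] for org in matrix.genome_labels
        ):
            out.add(cid)
    return out


def read_counts_tsv(path) -> pd.Series:
    """Read a two-column (gene_id, count) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene_id, count)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if s.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return s
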