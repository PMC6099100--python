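"""Gene-family clustering across genomes, core/pan counts and rarefaction.

Families are built by greedy centroid clustering: genes are visited in
order of decreasing length (ties by gene id), each joining the first
existing cluster whose representative aligns at or above the identity
cutoff (default 70%), otherwise founding a new cluster.  Identity is
computed from a global protein alignment (BLOSUM62, affine gap open 11 /
extend 1) as identical columns over the full alignment length including
gaps.  A shared k-mer prefilter skips hopeless alignments; it is
permissive enough that pairs near the cutoff always reach the aligner.

Greedy centroids, unlike transitive single linkage, cannot chain two
distinct families together through an intermediate gene; the clustering
is deterministic and independent of the order genomes are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import AnnotatedGenome, coding_genes, gene_sequence, translate_cds

__all__ = [
    "GeneFamilyMatrix",
    "protein_identity",
    "nucleotide_identity",
    "cluster_proteins",
    "cluster_families",
    "core_pan_counts",
    "rarefaction",
]


@lru_cache(maxsize=None)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


@lru_cache(maxsize=None)
def _nucleotide_aligner() -> Align.PairwiseAligner:
    # megablast-flavoured scores
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = "global"
    return aligner


def _alignment_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    alignment = aligner.align(a, b)[0]
    c = alignment.counts()
    columns = c.identities + c.mismatches + c.gaps
    return c.identities / columns


def protein_identity(a: str, b: str) -> float:
    """Global-alignment identity of two protein sequences in [0, 1].

    Identical aligned positions divided by the alignment length
    including gap columns.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    return _alignment_identity(_protein_aligner(), a, b)


def nucleotide_identity(a: str, b: str) -> float:
    """Global-alignment identity of two nucleotide sequences in [0, 1]."""
    if not a or not b:
        raise ValueError("empty sequence")
    return _alignment_identity(_nucleotide_aligner(), a, b)


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


@dataclass
class GeneFamilyMatrix:
    """Ortholog clusters x genomes presence/absence."""

    clusters: list[dict]  # {cluster_id, representative, members: [(genome, gene_id)]}
    presence: pd.DataFrame  # bool, index cluster_id, columns genome labels
    identity_cutoff: float

    @property
    def genome_labels(self) -> list[str]:
        return list(self.presence.columns)

    def core_cluster_ids(self) -> list[str]:
        mask = self.presence.all(axis=1)
        return list(self.presence.index[mask])

    def gene_to_cluster(self) -> dict[tuple[str, str], str]:
        out = {}
        for c in self.clusters:
            for member in c["members"]:
                out[tuple(member)] = c["cluster_id"]
        return out

    def cluster_label(self, cluster_id: str, reference_genome: str | None) -> str:
        """Cluster name: the reference genome's member gene id if present."""
        if reference_genome is not None:
            for c in self.clusters:
                if c["cluster_id"] == cluster_id:
                    for genome, gene_id in c["members"]:
                        if genome == reference_genome:
                            return gene_id
        return cluster_id


def cluster_proteins(
    records: list[tuple[str, str, str]],
    genome_labels: list[str],
    cutoff: float = 0.70,
    identity_fn=protein_identity,
    prefilter_k: int = 5,
    prefilter_min_shared: float = 0.2,
) -> GeneFamilyMatrix:
    """Greedy centroid clustering of (genome, gene_id, sequence) records.

    Visit order is decreasing sequence length, ties by gene_id then
    genome label, so the result does not depend on genome input order.
    ``prefilter_min_shared`` is the minimum fraction of the smaller
    sequence's k-mers that must be shared with a cluster representative
    before the full alignment is attempted; set to 0 to disable.
    """
    if not genome_labels:
        raise ValueError("no genomes")
    ordered = sorted(records, key=lambda r: (-len(r[2]), r[1], r[0]))
    reps: list[tuple[str, frozenset[str]]] = []  # (sequence, kmer set) per cluster
    clusters: list[dict] = []
    for genome, gene_id, seq in ordered:
        kmers = _kmer_set(seq, prefilter_k)
        placed = False
        for idx, (rep_seq, rep_kmers) in enumerate(reps):
            if prefilter_min_shared > 0:
                shared = len(kmers & rep_kmers) / min(len(kmers), len(rep_kmers))
                if shared < prefilter_min_shared:
                    continue
            if identity_fn(seq, rep_seq) >= cutoff:
                clusters[idx]["members"].append((genome, gene_id))
                placed = True
                break
        if not placed:
            cid = f"fam{len(clusters):05d}"
            clusters.append(
                {
                    "cluster_id": cid,
                    "representative": (genome, gene_id),
                    "members": [(genome, gene_id)],
                }
            )
            reps.append((seq, kmers))
    presence = pd.DataFrame(
        False,
        index=[c["cluster_id"] for c in clusters],
        columns=list(genome_labels),
    )
    for c in clusters:
        for genome, _gene in c["members"]:
            presence.loc[c["cluster_id"], genome] = True
    return GeneFamilyMatrix(
        clusters=clusters, presence=presence, identity_cutoff=cutoff
    )


def cluster_families(
    genomes: list[AnnotatedGenome],
    cutoff: float = 0.70,
    mode: str = "protein",
    **kwargs,
) -> GeneFamilyMatrix:
    """Cluster the coding genes of several genomes into families.

    ``mode="protein"`` translates each CDS (bacterial code) and clusters
    on protein identity; ``mode="nucleotide"`` clusters the CDS
    nucleotide sequences directly.
    """
    if not genomes:
        raise ValueError("no genomes")
    records: list[tuple[str, str, str]] = []
    for genome in genomes:
        for gene in coding_genes(genome):
            nt = gene_sequence(genome, gene)
            seq = translate_cds(nt) if mode == "protein" else nt
            records.append((genome.organism_label, gene.gene_id, seq))
    identity_fn = protein_identity if mode == "protein" else nucleotide_identity
    return cluster_proteins(
        records,
        [g.organism_label for g in genomes],
        cutoff=cutoff,
        identity_fn=identity_fn,
        **kwargs,
    )


def core_pan_counts(matrix: GeneFamilyMatrix) -> dict[str, int]:
    """Core (all-genome) cluster count, pan size, and total gene count."""
    return {
        "core": int(matrix.presence.all(axis=1).sum()),
        "pan": int(len(matrix.presence)),
        "total_genes": int(sum(len(c["members"]) for c in matrix.clusters)),
    }


def rarefaction(
    matrix: GeneFamilyMatrix, orderings: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean pan-genome growth over random genome orderings.

    For k = 1..G, averages over ``orderings`` random permutations the
    cumulative pan size after k genomes and the number of families first
    seen with the k-th genome.  Exhaustive over all permutations when
    G! <= orderings.
    """
    presence = matrix.presence.to_numpy()
    G = presence.shape[1]
    if G < 1:
        raise ValueError("no genomes")
    rng = np.random.default_rng(seed)
    from math import factorial

    if factorial(G) <= orderings:
        from itertools import permutations

        perms = [np.array(p) for p in permutations(range(G))]
    else:
        perms = [rng.permutation(G) for _ in range(orderings)]
    pan_sum = np.zeros(G)
    new_sum = np.zeros(G)
    for perm in perms:
        seen = np.zeros(presence.shape[0], dtype=bool)
        for k, g in enumerate(perm):
            newly = presence[:, g] & ~seen
            seen |= presence[:, g]
            new_sum[k] += newly.sum()
            pan_sum[k] += seen.sum()
    n = len(perms)
    return pd.DataFrame(
        {
            "k": np.arange(1, G + 1),
            "mean_pan": pan_sum / n,
            "mean_new": new_sum / n,
        }
    )
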