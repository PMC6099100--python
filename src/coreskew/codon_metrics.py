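"""Per-gene GC content and Codon Adaptation Index (CAI).

CAI follows the classical relative-adaptiveness definition: within each
synonymous-codon family of a reference gene set, every codon gets
w = (its count) / (count of the family's most-used codon); a gene's CAI
is the geometric mean of w over its codons, leaving out single-codon
families (ATG, TGG) and stops, which carry no choice.  The reference
set defaults to all coding sequences of the genome.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

__all__ = ["CodonUsage", "gene_gc", "build_codon_usage", "cai", "codon_metrics_table"]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid for the 61 sense codons (bacterial code)
_CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
_STOP_CODONS = frozenset(_TABLE11.stop_codons)

#: amino acid -> synonymous codon family
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)

#: codons excluded from CAI: stops plus single-codon families (M, W)
_UNINFORMATIVE = _STOP_CODONS | {
    c for aa, fam in _FAMILIES.items() if len(fam) == 1 for c in fam
}


def gene_gc(nt: str) -> float:
    """GC fraction of a sequence; N bases are ignored entirely."""
    counts = Counter(nt.upper())
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def _codons(nt: str) -> list[str]:
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    return [nt[i : i + 3] for i in range(0, len(nt), 3)]


@dataclass
class CodonUsage:
    """Pooled codon counts and relative adaptiveness of a reference set."""

    counts: dict[str, int]
    relative_adaptiveness: dict[str, float]


def build_codon_usage(genes_nt: list[str]) -> CodonUsage:
    """Pool codon counts over a reference gene set and derive w values.

    Within each synonymous family, w = count / max family count; a codon
    never observed gets the pseudo-count value 0.5 / max family count so
    its log is finite.  Families observed zero times overall get w = 1
    for every member (no information, no penalty).
    """
    if not genes_nt:
        raise ValueError("empty reference set")
    counts: Counter[str] = Counter()
    for nt in genes_nt:
        counts.update(c for c in _codons(nt) if c in _CODON_TO_AA)
    w: dict[str, float] = {}
    for fam in _FAMILIES.values():
        fam_max = max(counts[c] for c in fam)
        for c in fam:
            if fam_max == 0:
                w[c] = 1.0
            elif counts[c] == 0:
                w[c] = 0.5 / fam_max
            else:
                w[c] = counts[c] / fam_max
    return CodonUsage(counts=dict(counts), relative_adaptiveness=w)


def cai(gene_nt: str, usage: CodonUsage) -> float:
    """Codon Adaptation Index of one gene against a reference usage.

    Geometric mean of relative adaptiveness over the gene's codons,
    excluding ATG, TGG and stop codons.
    """
    log_sum = 0.0
    n = 0
    for c in _codons(gene_nt):
        if c in _UNINFORMATIVE or c not in _CODON_TO_AA:
            continue
        log_sum += math.log(usage.relative_adaptiveness[c])
        n += 1
    if n == 0:
        raise ValueError("no informative codons (only ATG/TGG/stops)")
    return math.exp(log_sum / n)


def codon_metrics_table(
    gene_ids: list[str], genes_nt: list[str], usage: CodonUsage | None = None
) -> pd.DataFrame:
    """Per-gene length, GC fraction and CAI as a DataFrame.

    ``usage`` defaults to the usage built from the genes themselves
    (whole-genome reference).
    """
    if usage is None:
        usage = build_codon_usage(genes_nt)
    rows = [
        {
            "gene_id": gid,
            "length_bp": len(nt),
            "gc_fraction": gene_gc(nt),
            "cai": cai(nt, usage),
        }
        for gid, nt in zip(gene_ids, genes_nt)
    ]
    return pd.DataFrame(rows)
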