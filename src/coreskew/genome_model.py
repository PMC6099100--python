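"""Genome sequences and gene annotations.

Reads a single-contig nucleotide FASTA plus a GFF3 (or a minimal TSV
feature table) into an :class:`AnnotatedGenome`, the container every
downstream stage consumes.  Internally all coordinates are 0-based
half-open; GFF3 input/output uses the standard 1-based inclusive
convention.  The chromosome is assumed circular, but features wrapping
the sequence end are rejected (assemblies are conventionally linearized
at the origin).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "read_fasta",
    "read_features",
    "read_feature_table",
    "write_gff3",
    "coding_genes",
    "gene_sequence",
    "translate_cds",
    "reverse_complement",
]

_VALID_CHARS = frozenset("ACGTN")

#: GFF3 feature types mapped onto the four internal classes.
_FEATURE_CLASS = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}

#: Product descriptions matching these (case-insensitive) are excluded from
#: the coding-gene set even when annotated as CDS: ribonucleases are
#: untranslated-RNA machinery the expression analyses leave out.
_RNASE_PATTERN = re.compile(r"rnase|ribonuclease", re.IGNORECASE)

_PSEUDO_PATTERN = re.compile(r"pseudo", re.IGNORECASE)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the chromosome.

    Coordinates are 0-based half-open; ``strand`` is +1 (forward) or -1
    (reverse); ``feature_class`` is one of CDS / rRNA / tRNA / other_RNA.
    """

    gene_id: str
    start: int
    end: int
    strand: int
    feature_class: str = "CDS"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in (+1, -1):
            raise ValueError(f"{self.gene_id}: strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class AnnotatedGenome:
    """One organism's chromosome plus its gene features."""

    organism_label: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.end > self.length_bp:
                raise ValueError(
                    f"feature {f.gene_id} [{f.start}, {f.end}) exceeds genome "
                    f"length {self.length_bp}"
                )
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)


def read_fasta(path, organism_label: str | None = None) -> AnnotatedGenome:
    """Read a single-record nucleotide FASTA into an AnnotatedGenome.

    The sequence is uppercased; characters outside A/C/G/T/N are
    rejected.  Multi-record files are refused — the chromosome must be a
    single closed contig.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    if len(records) > 1:
        raise ValueError(
            f"{path}: multi-record FASTA ({len(records)} records); "
            "the chromosome must be a single contig"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"{path}: illegal sequence characters {sorted(bad)}")
    if not seq:
        raise ValueError(f"{path}: empty sequence")
    return AnnotatedGenome(organism_label=organism_label or rec.id, sequence=seq)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_features(path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach GFF3 features to a genome read with :func:`read_fasta`.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Feature types CDS/rRNA/tRNA map to
    the matching class; everything else becomes other_RNA.  Region/
    chromosome-level lines are skipped.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype in ("region", "chromosome", "gene"):
                continue
            if strand == "+":
                strand_i = +1
            elif strand == "-":
                strand_i = -1
            else:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            start_i = int(start) - 1
            end_i = int(end)
            if start_i < 0 or end_i > genome.length_bp or end_i <= start_i:
                raise ValueError(
                    f"{path}:{lineno}: coordinates [{start}, {end}] out of "
                    f"range for genome of {genome.length_bp} bp"
                )
            adict = _parse_gff_attributes(attrs)
            gene_id = adict.get("ID") or adict.get("locus_tag")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: feature lacks ID attribute")
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    start=start_i,
                    end=end_i,
                    strand=strand_i,
                    feature_class=_FEATURE_CLASS.get(ftype, "other_RNA"),
                    product=adict.get("product", ""),
                )
            )
    out = replace_features(genome, features)
    out.validate()
    return out


def read_feature_table(path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Attach features from a minimal TSV table.

    Columns: gene_id, start (1-based), end (inclusive), strand (+/-),
    type, product.  An alternate annotation source for genomes whose
    features were extracted from a GenBank flat file.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns")
            gene_id, start, end, strand, ftype = cols[:5]
            product = cols[5] if len(cols) > 5 else ""
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    start=int(start) - 1,
                    end=int(end),
                    strand=+1 if strand == "+" else -1,
                    feature_class=_FEATURE_CLASS.get(ftype, "other_RNA"),
                    product=product,
                )
            )
    out = replace_features(genome, features)
    out.validate()
    return out


def replace_features(
    genome: AnnotatedGenome, features: list[GeneFeature]
) -> AnnotatedGenome:
    return AnnotatedGenome(
        organism_label=genome.organism_label,
        sequence=genome.sequence,
        features=list(features),
    )


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Write the genome's features as GFF3 (1-based inclusive)."""
    class_to_type = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "other_RNA": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {genome.organism_label} 1 {genome.length_bp}\n"
        )
        for f in genome.features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        genome.organism_label,
                        "coreskew",
                        class_to_type[f.feature_class],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        "+" if f.strand == +1 else "-",
                        "0" if f.feature_class == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def coding_genes(
    genome: AnnotatedGenome, drop_pseudo: bool = False
) -> list[GeneFeature]:
    """Protein-coding genes, ordered by start coordinate.

    Keeps only CDS features and drops ribonucleases (matched on product
    text) — untranslated-RNA machinery is excluded from expression and
    codon analyses.  ``drop_pseudo`` additionally removes features whose
    product mentions "pseudo".
    """
    out = [
        f
        for f in genome.features
        if f.feature_class == "CDS" and not _RNASE_PATTERN.search(f.product)
    ]
    if drop_pseudo:
        out = [f for f in out if not _PSEUDO_PATTERN.search(f.product)]
    return sorted(out, key=lambda f: (f.start, f.gene_id))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def gene_sequence(genome: AnnotatedGenome, gene: GeneFeature) -> str:
    """Gene nucleotide sequence, 5'->3' on the coding strand."""
    if gene.end > genome.length_bp:
        raise ValueError(
            f"{gene.gene_id}: [{gene.start}, {gene.end}) outside genome of "
            f"{genome.length_bp} bp"
        )
    nt = genome.sequence[gene.start : gene.end]
    return nt if gene.strand == +1 else reverse_complement(nt)


def translate_cds(nt: str, internal_stop: str = "error") -> str:
    """Translate a CDS under the bacterial genetic code (table 11).

    A trailing stop codon is removed.  An internal stop raises by
    default; ``internal_stop="mask"`` replaces it with X instead.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        if internal_stop == "mask":
            aa = aa.replace("*", "X")
        else:
            raise ValueError(f"internal stop codon at aa position {aa.index('*')}")
    return aa
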