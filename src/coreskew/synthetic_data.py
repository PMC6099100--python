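"""Synthetic multi-genome datasets with planted ground truth.

Emulates the structure of a small clade of low-GC lactic-acid-bacterium
chromosomes: ~2 Mb circular genomes linearized at the replication
origin, a planted terminus, leading-strand coding bias (~77% of genes on
the forward strand of the right replichore), shared gene families with
tunable protein divergence around a clustering cutoff, and heavy-tailed
expression in which a few dozen genes carry half of the mRNA mass.
Every emitted dataset ships its ground truth (origin/terminus, gene
classes, family memberships, true expression rates) so each pipeline
stage can be tested against what was planted, with no downloads.

The generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_model import AnnotatedGenome, GeneFeature, write_gff3
from .codon_metrics import _FAMILIES  # aa -> synonymous codons (table 11)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_pan_genome",
    "generate_genome_sequence",
    "simulate_expression_counts",
    "generate_dataset",
    "write_dataset",
]

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_STOP = "TAA"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic clade; defaults mirror the study system.

    ``family_identity`` is the target pairwise protein identity within a
    gene family (fraction); ``skew_amplitude`` the per-strand excess of
    G over C and T over A in intergenic background on the leading
    strand; ``coding_keto_bias`` the preference for G/T-bearing codons
    during back-translation, which makes coding regions carry the same
    strand asymmetry.  ``core_offset_log10`` shifts core-family
    expression upward in log10 units.  ``terminal_region_bp`` plants an
    unbiased skew/strand plateau of that width around the terminus
    (0 = sharp terminus).
    """

    n_genomes: int = 6
    genome_length: int = 2_000_000
    n_core_families: int = 400
    n_accessory_families: int = 6300
    accessory_presence: float = 0.21
    terminus_fraction: float = 0.55
    forward_bias: float = 0.77
    gc_content: float = 0.36
    skew_amplitude: float = 0.15
    coding_keto_bias: float = 0.35
    family_identity: float = 0.90
    protein_length_range: tuple[int, int] = (100, 500)
    terminal_region_bp: int = 0
    # expression model: lognormal body with a Pareto tail grafted above
    # the body's 95th percentile
    expr_log10_mu: float = 1.0
    expr_log10_sigma: float = 0.45
    expr_tail_alpha: float = 0.95
    expr_tail_quantile: float = 0.90
    core_offset_log10: float = 0.8
    organism_sigma_log10: float = 0.10
    n_replicates: int = 3
    read_depth: float = 5e6
    overdispersion: float = 0.1
    n_trna: int = 4
    n_rrna: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accessory_presence", "terminus_fraction", "forward_bias",
                     "gc_content"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.2 <= self.family_identity <= 1.0:
            raise ValueError("family_identity must be in [0.2, 1]")
        if self.genome_length <= 0 or self.n_genomes < 1:
            raise ValueError("positive genome_length and n_genomes required")


@dataclass
class GroundTruth:
    """Everything planted: to be validated against the emitted files."""

    origin_bp: int
    terminus_bp: int
    terminal_region: tuple[int, int] | None
    core_family_ids: list[str]
    accessory_family_ids: list[str]
    # per organism: gene_id -> {family, replichore_strand_class, is_core}
    genes: dict[str, dict[str, dict]]
    # per organism: gene_id -> true transcript rate
    true_rates: dict[str, dict[str, float]]

    def expected_mass_set(self, organism: str, p: float) -> list[str]:
        """Mass set implied by the true rates (RPKM is proportional to rate)."""
        rates = self.true_rates[organism]
        order = sorted(rates.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(rates.values())
        out, acc = [], 0.0
        for gid, r in order:
            out.append(gid)
            acc += r
            if acc >= p * total:
                break
        return out


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: list[AnnotatedGenome]
    counts: dict[str, list[dict[str, float]]]  # organism -> replicate -> gene counts
    truth: GroundTruth
    proteins: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate(self) -> None:
        """Self-check: ground truth must agree with the emitted objects."""
        from .genome_model import gene_sequence, translate_cds, coding_genes

        for genome in self.genomes:
            genome.validate()
            truth_genes = self.truth.genes[genome.organism_label]
            cds = coding_genes(genome)
            assert {g.gene_id for g in cds} == set(truth_genes), "gene set mismatch"
            for g in cds:
                aa = translate_cds(gene_sequence(genome, g))
                assert aa == self.proteins[genome.organism_label][g.gene_id], (
                    f"{g.gene_id}: sequence does not encode the planted protein"
                )
            for rep in self.counts[genome.organism_label]:
                assert set(rep) == set(truth_genes), "counts gene set mismatch"


def _codon_sampler(cfg: SimulationConfig):
    """Per-amino-acid codon choice probabilities.

    Codon weight is the product over its bases of a composition factor
    (targeting overall GC content) and a keto factor (favouring G/T so
    coding strands carry replication-strand asymmetry).
    """
    gc, ks = cfg.gc_content, cfg.coding_keto_bias
    base_w = {
        "G": gc * (1 + ks),
        "C": gc * (1 - ks),
        "T": (1 - gc) * (1 + ks),
        "A": (1 - gc) * (1 - ks),
    }
    table: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in _FAMILIES.items():
        w = np.array([np.prod([base_w[b] for b in c]) for c in codons])
        table[aa] = (codons, w / w.sum())
    return table


def _back_translate(protein: str, table, rng: np.random.Generator) -> str:
    parts = []
    for aa in protein:
        codons, probs = table[aa]
        parts.append(codons[rng.choice(len(codons), p=probs)])
    parts.append(_STOP)
    return "".join(parts)


def _mutate_protein(
    protein: str, per_site: float, rng: np.random.Generator
) -> str:
    if per_site <= 0:
        return protein
    chars = list(protein)
    hits = np.nonzero(rng.random(len(chars)) < per_site)[0]
    for i in hits:
        choices = _AAS.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def generate_pan_genome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, dict], dict[str, list[str]]]:
    """Draw gene families and per-genome protein sequences.

    Returns ``families`` (family_id -> {is_core, length, ancestor}) and
    ``membership`` (family_id -> list of organism labels carrying it).
    Within-family divergence: each member is mutated independently from
    the ancestor with per-site probability 1 - sqrt(target identity), so
    the expected pairwise identity between members hits the target.
    """
    if not 0.2 <= cfg.family_identity <= 1.0:
        raise ValueError("family identity target must be in [0.2, 1]")
    organisms = [f"syn{i + 1}" for i in range(cfg.n_genomes)]
    lo, hi = cfg.protein_length_range
    families: dict[str, dict] = {}
    membership: dict[str, list[str]] = {}
    n_total = cfg.n_core_families + cfg.n_accessory_families
    for i in range(n_total):
        fid = f"fam{i:05d}"
        is_core = i < cfg.n_core_families
        length = int(rng.integers(lo, hi + 1))
        ancestor = "M" + "".join(
            _AAS[j] for j in rng.integers(len(_AAS), size=length - 1)
        )
        families[fid] = {"is_core": is_core, "length": length, "ancestor": ancestor}
        if is_core:
            membership[fid] = list(organisms)
        else:
            # accessory families occupy a nonempty PROPER subset of the
            # genomes, so the planted core count is exact by construction
            present = [o for o in organisms if rng.random() < cfg.accessory_presence]
            if not present:
                present = [organisms[int(rng.integers(cfg.n_genomes))]]
            if len(present) == cfg.n_genomes > 1:
                drop = int(rng.integers(cfg.n_genomes))
                present = [o for j, o in enumerate(organisms) if j != drop]
            membership[fid] = present
    return families, membership


def _member_proteins(
    cfg: SimulationConfig,
    families: dict[str, dict],
    membership: dict[str, list[str]],
    rng: np.random.Generator,
) -> dict[str, dict[str, str]]:
    """organism -> family_id -> that organism's protein variant."""
    per_site = 1.0 - float(np.sqrt(cfg.family_identity))
    out: dict[str, dict[str, str]] = {}
    for fid, fam in families.items():
        for org in membership[fid]:
            variant = _mutate_protein(fam["ancestor"], per_site, rng)
            out.setdefault(org, {})[fid] = variant
    return out


def generate_genome_sequence(
    cfg: SimulationConfig,
    organism: str,
    proteins: dict[str, str],
    families: dict[str, dict],
    rng: np.random.Generator,
) -> tuple[AnnotatedGenome, dict[str, dict], dict[str, str]]:
    """Assemble one chromosome with planted skew, bias and terminus.

    The origin sits at coordinate 0 (assemblies are conventionally
    rotated to ori) and the terminus at ``terminus_fraction`` x length,
    so the right replichore [0, terminus) is the longer arc.  Genes on
    the right replichore go to the forward strand with probability
    ``forward_bias`` (the leading strand there); on the left replichore
    the leading strand is the reverse strand.  Intergenic background
    carries a per-strand G-over-C and T-over-A excess of
    ``skew_amplitude`` that flips sign at the terminus; inside an
    optional terminal-region plateau both the compositional skew and the
    strand bias are switched off.
    """
    L = cfg.genome_length
    ter = int(cfg.terminus_fraction * L)
    region = None
    if cfg.terminal_region_bp > 0:
        half = cfg.terminal_region_bp // 2
        region = (ter - half, ter + half)
    table = _codon_sampler(cfg)

    fam_ids = sorted(proteins)
    gene_nt = {fid: _back_translate(proteins[fid], table, rng) for fid in fam_ids}
    order = list(rng.permutation(fam_ids))
    n_right = int(round(len(order) * ter / L))
    arcs = [(0, ter, order[:n_right], +1), (ter, L, order[n_right:], -1)]

    seq = np.empty(L, dtype="U1")
    features: list[GeneFeature] = []
    truth_genes: dict[str, dict] = {}
    proteins_by_gene: dict[str, str] = {}

    def fill_background(a: int, b: int, leading: int) -> None:
        if b <= a:
            return
        gc, s = cfg.gc_content, cfg.skew_amplitude * leading
        segs = [(a, b, s)]
        if region is not None:
            segs = []
            for x0, x1 in ((a, min(b, region[0])), (max(a, region[1]), b)):
                if x1 > x0:
                    segs.append((x0, x1, s))
            x0, x1 = max(a, region[0]), min(b, region[1])
            if x1 > x0:
                segs.append((x0, x1, 0.0))
        for x0, x1, sk in segs:
            p = np.array(
                [
                    gc / 2 * (1 + sk),
                    gc / 2 * (1 - sk),
                    (1 - gc) / 2 * (1 + sk),
                    (1 - gc) / 2 * (1 - sk),
                ]
            )
            p /= p.sum()
            seq[x0:x1] = np.array(list("GCTA"))[rng.choice(4, size=x1 - x0, p=p)]

    rna_features: list[tuple[str, int, str]] = []
    for i in range(cfg.n_trna):
        rna_features.append((f"{organism}_trna{i}", 76, "tRNA"))
    for i in range(cfg.n_rrna):
        rna_features.append((f"{organism}_rrna{i}", 1500, "rRNA"))

    gene_counter = 0
    for arc_start, arc_end, arc_fams, leading in arcs:
        # each item: (kind "CDS"|"RNA", name, nt length, rna type or None)
        items = [("CDS", fid, len(gene_nt[fid]), None) for fid in arc_fams]
        if leading == +1 and rna_features:
            items = [
                ("RNA", name, length, ftype) for name, length, ftype in rna_features
            ] + items
        total_bp = sum(it[2] for it in items)
        free = (arc_end - arc_start) - total_bp
        if free < len(items) + 1:
            raise ValueError(
                f"{organism}: genes ({total_bp} bp) do not fit in replichore "
                f"of {arc_end - arc_start} bp"
            )
        gap = free // (len(items) + 1)
        pos = arc_start + gap
        prev_end = arc_start
        for kind, name, nt_len, ftype in items:
            start, end = pos, pos + nt_len
            fill_background(prev_end, start, leading)
            mid = (start + end) / 2
            in_region = region is not None and region[0] <= mid < region[1]
            if kind == "RNA":
                fill_background(start, end, leading)  # RNA content is background
                features.append(
                    GeneFeature(name, start, end, +1, ftype, f"synthetic {ftype}")
                )
            else:
                fid = name
                if in_region:
                    strand = +1 if rng.random() < 0.5 else -1
                else:
                    on_leading = rng.random() < cfg.forward_bias
                    strand = leading if on_leading else -leading
                nt = gene_nt[fid]
                if strand == -1:
                    comp = str.maketrans("ACGT", "TGCA")
                    nt = nt.translate(comp)[::-1]
                seq[start:end] = list(nt)
                gene_id = f"{organism}_g{gene_counter:05d}"
                gene_counter += 1
                side = "right" if mid < ter else "left"
                features.append(
                    GeneFeature(
                        gene_id,
                        start,
                        end,
                        strand,
                        "CDS",
                        ("core" if families[fid]["is_core"] else "accessory")
                        + f" family {fid} protein",
                    )
                )
                truth_genes[gene_id] = {
                    "family": fid,
                    "is_core": families[fid]["is_core"],
                    "class": f"{side}_{'fwd' if strand == +1 else 'rev'}",
                }
                proteins_by_gene[gene_id] = proteins[fid]
            prev_end = end
            pos = end + gap
        fill_background(prev_end, arc_end, leading)

    genome = AnnotatedGenome(
        organism_label=organism,
        sequence="".join(seq),
        features=sorted(features, key=lambda f: f.start),
    )
    genome.validate()
    return genome, truth_genes, proteins_by_gene


def _true_rates(
    cfg: SimulationConfig,
    family_rate: dict[str, float],
    truth_genes: dict[str, dict],
    rng: np.random.Generator,
) -> dict[str, float]:
    rates = {}
    for gene_id, info in truth_genes.items():
        noise = 10 ** (rng.normal(0.0, cfg.organism_sigma_log10))
        rates[gene_id] = family_rate[info["family"]] * noise
    return rates


def _family_rates(
    cfg: SimulationConfig, families: dict[str, dict], rng: np.random.Generator
) -> dict[str, float]:
    """Family-level transcript rates: lognormal body, Pareto(alpha) tail.

    Draws a lognormal body; values above the body's analytic
    ``expr_tail_quantile`` are replaced by q x U^(-1/alpha), grafting a
    heavy Pareto tail that concentrates half of the mRNA mass in a few
    dozen families.  Core families are shifted up by
    ``core_offset_log10`` afterwards.
    """
    from scipy.stats import norm

    out: dict[str, float] = {}
    q = 10 ** (
        cfg.expr_log10_mu
        + norm.ppf(cfg.expr_tail_quantile) * cfg.expr_log10_sigma
    )
    for fid, fam in families.items():
        body = 10 ** rng.normal(cfg.expr_log10_mu, cfg.expr_log10_sigma)
        if body > q:
            rate = q * rng.random() ** (-1.0 / cfg.expr_tail_alpha)
        else:
            rate = body
        if fam["is_core"]:
            rate *= 10**cfg.core_offset_log10
        out[fid] = rate
    return out


def simulate_expression_counts(
    cfg: SimulationConfig,
    true_rates: dict[str, float],
    gene_lengths: dict[str, int],
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Replicate count tables for one organism.

    Expected counts are proportional to rate x length (reads per
    transcript scale with its length) at total depth ``read_depth``;
    replicate noise is gamma-Poisson with variance m + phi m^2.
    """
    gene_ids = sorted(true_rates)
    rate = np.array([true_rates[g] for g in gene_ids])
    length = np.array([gene_lengths[g] for g in gene_ids], dtype=float)
    weight = rate * length
    mean = cfg.read_depth * weight / weight.sum()
    replicates = []
    for _ in range(cfg.n_replicates):
        if cfg.overdispersion > 0:
            lam = rng.gamma(1.0 / cfg.overdispersion, mean * cfg.overdispersion)
        else:
            lam = mean
        counts = rng.poisson(lam).astype(float)
        replicates.append(dict(zip(gene_ids, counts)))
    return replicates


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full clade: genomes, counts, ground truth; self-checked."""
    rng = np.random.default_rng(cfg.seed)
    families, membership = generate_pan_genome(cfg, rng)
    proteins = _member_proteins(cfg, families, membership, rng)
    family_rate = _family_rates(cfg, families, rng)

    genomes: list[AnnotatedGenome] = []
    truth_genes: dict[str, dict[str, dict]] = {}
    true_rates: dict[str, dict[str, float]] = {}
    counts: dict[str, list[dict[str, float]]] = {}
    proteins_by_org: dict[str, dict[str, str]] = {}
    organisms = [f"syn{i + 1}" for i in range(cfg.n_genomes)]
    ter = int(cfg.terminus_fraction * cfg.genome_length)
    region = None
    if cfg.terminal_region_bp > 0:
        half = cfg.terminal_region_bp // 2
        region = (ter - half, ter + half)
    for org in organisms:
        genome, tg, pg = generate_genome_sequence(
            cfg, org, proteins.get(org, {}), families, rng
        )
        genomes.append(genome)
        truth_genes[org] = tg
        proteins_by_org[org] = pg
        rates = _true_rates(cfg, family_rate, tg, rng)
        true_rates[org] = rates
        lengths = {
            f.gene_id: f.length
            for f in genome.features
            if f.feature_class == "CDS"
        }
        counts[org] = simulate_expression_counts(cfg, rates, lengths, rng)

    truth = GroundTruth(
        origin_bp=0,
        terminus_bp=ter,
        terminal_region=region,
        core_family_ids=[f for f, fam in families.items() if fam["is_core"]],
        accessory_family_ids=[f for f, fam in families.items() if not fam["is_core"]],
        genes=truth_genes,
        true_rates=true_rates,
    )
    dataset = SyntheticDataset(
        config=cfg,
        genomes=genomes,
        counts=counts,
        truth=truth,
        proteins=proteins_by_org,
    )
    dataset.validate()
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit FASTA, GFF3, per-replicate counts TSVs and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in dataset.genomes:
        org = genome.organism_label
        with open(outdir / f"{org}.fna", "w") as fh:
            fh.write(f">{org}\n")
            for i in range(0, genome.length_bp, 80):
                fh.write(genome.sequence[i : i + 80] + "\n")
        write_gff3(genome, outdir / f"{org}.gff3")
        for r, rep in enumerate(dataset.counts[org], 1):
            with open(outdir / f"{org}.counts.rep{r}.tsv", "w") as fh:
                for gid in sorted(rep):
                    fh.write(f"{gid}\t{rep[gid]:g}\n")
    truth = asdict(dataset.truth)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
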