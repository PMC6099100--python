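"""End-to-end orchestration over a multi-organism run configuration.

Runs genome loading, skew/terminus calling, codon metrics, gene-family
clustering, expression normalization, mRNA-mass sets, the core
transcriptome, and the comparative statistics, writing every table to
the output directory together with a JSON manifest (seed, input hashes)
so a run is reproducible as a single artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_model import (
    AnnotatedGenome,
    coding_genes,
    gene_sequence,
    read_fasta,
    read_features,
)
from .skew_terminus import call_terminus, strand_bias_table, terminus_locus_listing
from .codon_metrics import codon_metrics_table
from .pangenome import cluster_families, core_pan_counts, rarefaction
from .transcriptome import (
    ExpressionTable,
    core_transcriptome,
    mass_fraction_set,
    read_counts_tsv,
)
from .stats_compare import (
    core_correlations,
    core_vs_noncore_table,
    log10_rpkm,
    normalized_location,
)

logger = logging.getLogger("coreskew")

__all__ = ["OrganismInput", "RunConfig", "run_pipeline", "summary_report"]


@dataclass
class OrganismInput:
    label: str
    fasta: str
    gff: str
    counts: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    organisms: list[OrganismInput]
    outdir: str = "coreskew_out"
    identity_cutoff: float = 0.70
    mass_thresholds: tuple[float, float] = (0.5, 0.9)
    mass_metric: str = "rpkm"  # or "tpm": molar-fraction-correct alternative
    reference_label: str | None = None
    seed: int = 0
    skew_stride: int = 1000
    epsilon: float = 0.02
    origin_override: int | None = None
    no_expression: bool = False
    drop_pseudo: bool = False  # drop CDS whose product mentions "pseudo"
    rarefaction_orderings: int = 100

    def __post_init__(self) -> None:
        if not self.organisms:
            raise ValueError("at least one organism required")
        for t in self.mass_thresholds:
            if not 0 < t <= 1:
                raise ValueError("mass thresholds must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        organisms = [OrganismInput(**o) for o in raw.pop("organisms")]
        if "mass_thresholds" in raw:
            raw["mass_thresholds"] = tuple(raw["mass_thresholds"])
        return cls(organisms=organisms, **raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, organism: str | None = None):
    where = f"stage {name}" + (f" (organism {organism})" if organism else "")

    class _Ctx:
        def __enter__(self):
            logger.info("running %s", where)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"{where} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir), "organisms": [o.label for o in config.organisms]}

    genomes: list[AnnotatedGenome] = []
    for org in config.organisms:
        with _stage("genome_model", org.label):
            genome = read_fasta(org.fasta, organism_label=org.label)
            genome = read_features(org.gff, genome)
            if config.drop_pseudo:
                from .genome_model import _PSEUDO_PATTERN, replace_features

                genome = replace_features(
                    genome,
                    [
                        f
                        for f in genome.features
                        if not _PSEUDO_PATTERN.search(f.product)
                    ],
                )
            genomes.append(genome)

    calls = {}
    for genome in genomes:
        with _stage("skew_terminus", genome.organism_label):
            call = call_terminus(
                genome,
                stride=config.skew_stride,
                epsilon=config.epsilon,
                origin_override=config.origin_override,
            )
            calls[genome.organism_label] = call
            curves = call.curves
            grid = curves["combined"].positions
            df = pd.DataFrame({"position": grid.astype(int)})
            for kind in ("GC", "TA", "coding_density"):
                if kind in curves:
                    c = curves[kind]
                    df[kind.lower()] = np.interp(grid, c.positions, c.values)
            df["combined"] = curves["combined"].values
            df.to_csv(outdir / f"{genome.organism_label}.skew.tsv", sep="\t", index=False)
            with open(outdir / f"{genome.organism_label}.terminus.json", "w") as fh:
                json.dump(
                    {
                        "terminus_bp": call.terminus_bp,
                        "origin_bp": call.origin_bp,
                        "region": call.region,
                        "is_region": call.is_region,
                        "epsilon": call.epsilon_used,
                    },
                    fh,
                    indent=1,
                )
            listing = terminus_locus_listing(genome, call)
            pd.DataFrame(listing).to_csv(
                outdir / f"{genome.organism_label}.terminus_locus.tsv",
                sep="\t",
                index=False,
            )

    with _stage("strand_bias"):
        bias = strand_bias_table([(g, calls[g.organism_label]) for g in genomes])
        bias.to_csv(outdir / "strand_bias.tsv", sep="\t", index=False)
        bundle["strand_bias"] = bias

    metrics = {}
    for genome in genomes:
        with _stage("codon_metrics", genome.organism_label):
            genes = coding_genes(genome)
            nts = [gene_sequence(genome, g) for g in genes]
            df = codon_metrics_table([g.gene_id for g in genes], nts)
            df.to_csv(outdir / f"{genome.organism_label}.codon_metrics.tsv", sep="\t", index=False)
            metrics[genome.organism_label] = df

    with _stage("pangenome"):
        matrix = cluster_families(genomes, cutoff=config.identity_cutoff)
        counts = core_pan_counts(matrix)
        bundle["core_pan"] = counts
        matrix.presence.astype(int).to_csv(outdir / "gene_presence_absence.csv")
        members = [
            {
                "cluster_id": c["cluster_id"],
                "label": matrix.cluster_label(c["cluster_id"], config.reference_label),
                "genome": genome,
                "gene_id": gene_id,
            }
            for c in matrix.clusters
            for genome, gene_id in c["members"]
        ]
        pd.DataFrame(members).to_csv(outdir / "cluster_members.tsv", sep="\t", index=False)
        if len(genomes) >= 2:
            rar = rarefaction(
                matrix, orderings=config.rarefaction_orderings, seed=config.seed
            )
            rar.to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)
        bundle["family_matrix"] = matrix

    core_ids = set(matrix.core_cluster_ids())
    gene_to_cluster = matrix.gene_to_cluster()
    core_gene_ids = {
        g.organism_label: {
            f.gene_id
            for f in coding_genes(g)
            if gene_to_cluster.get((g.organism_label, f.gene_id)) in core_ids
        }
        for g in genomes
    }
    bundle["core_cluster_ids"] = core_ids

    if config.no_expression:
        _write_manifest(config, bundle, outdir)
        summary_report(bundle, genomes, outdir)
        return bundle

    expression: dict[str, ExpressionTable] = {}
    mass_sets: dict[str, dict[float, list[str]]] = {}
    lo_p, hi_p = min(config.mass_thresholds), max(config.mass_thresholds)
    for genome, org in zip(genomes, config.organisms):
        with _stage("transcriptome", org.label):
            if not org.counts:
                raise ValueError(f"no counts files provided for {org.label}")
            genes = coding_genes(genome)
            gene_ids = [g.gene_id for g in genes]
            reps = []
            for path in org.counts:
                s = read_counts_tsv(path)
                missing = set(gene_ids) - set(s.index)
                if missing:
                    raise ValueError(
                        f"{path}: missing counts for {len(missing)} coding genes"
                    )
                reps.append(s.loc[gene_ids].to_numpy())
            table = ExpressionTable(
                organism_label=org.label,
                gene_ids=gene_ids,
                gene_lengths=np.array([g.length for g in genes]),
                replicates=reps,
            )
            expression[org.label] = table
            if config.mass_metric == "tpm":
                metric = np.vstack(table.tpm_replicates).mean(axis=0)
            else:
                metric = table.mean_rpkm
            series = pd.Series(metric, index=gene_ids)
            mass_sets[org.label] = {
                p: mass_fraction_set(series, p) for p in config.mass_thresholds
            }
            df = table.to_frame()
            df["in_50_set"] = df["gene_id"].isin(mass_sets[org.label][lo_p])
            df["in_90_set"] = df["gene_id"].isin(mass_sets[org.label][hi_p])
            df.to_csv(outdir / f"{org.label}.expression.tsv", sep="\t", index=False)

    with _stage("core_transcriptome"):
        sets_90 = {org: set(ms[hi_p]) for org, ms in mass_sets.items()}
        ct = core_transcriptome(core_ids, sets_90, matrix)
        assert ct <= core_ids
        bundle["core_transcriptome"] = ct
        bundle["mass_sets"] = mass_sets
        pd.DataFrame(
            {
                "cluster_id": sorted(ct),
                "label": [
                    matrix.cluster_label(c, config.reference_label) for c in sorted(ct)
                ],
            }
        ).to_csv(outdir / "core_transcriptome.tsv", sep="\t", index=False)

    with _stage("stats_compare"):
        per_org = {}
        for genome in genomes:
            org = genome.organism_label
            df = metrics[org].copy()
            gene_index = {g: i for i, g in enumerate(expression[org].gene_ids)}
            df["mean_rpkm"] = [
                expression[org].mean_rpkm[gene_index[g]] for g in df["gene_id"]
            ]
            per_org[org] = df
        table2 = core_vs_noncore_table(per_org, core_gene_ids)
        table2.to_csv(outdir / "core_vs_noncore.tsv", sep="\t", index=False)
        bundle["core_vs_noncore"] = table2
        if len(genomes) >= 2 and core_ids:
            corr = _correlation_tables(genomes, matrix, core_ids, expression, metrics)
            corr.to_csv(outdir / "core_correlations.tsv", sep="\t", index=False)
            bundle["core_correlations"] = corr

    _write_manifest(config, bundle, outdir)
    summary_report(bundle, genomes, outdir)
    return bundle


def _correlation_tables(genomes, matrix, core_ids, expression, metrics) -> pd.DataFrame:
    """Pairwise core-cluster correlations of four gene attributes.

    Restricted to core clusters with exactly one member per organism so
    values are unambiguous.
    """
    single_copy = []
    for c in matrix.clusters:
        if c["cluster_id"] not in core_ids:
            continue
        per_org: dict[str, list[str]] = {}
        for genome, gene_id in c["members"]:
            per_org.setdefault(genome, []).append(gene_id)
        if all(len(v) == 1 for v in per_org.values()):
            single_copy.append(
                (c["cluster_id"], {g: ids[0] for g, ids in per_org.items()})
            )
    frames = []
    by_label = {g.organism_label: g for g in genomes}
    for attribute in ("expression_log10", "location_normalized", "gc", "cai"):
        values: dict[str, pd.Series] = {}
        for org, genome in by_label.items():
            gene_pos = {f.gene_id: f for f in coding_genes(genome)}
            gene_index = {g: i for i, g in enumerate(expression[org].gene_ids)}
            met = metrics[org].set_index("gene_id")
            idx, vals = [], []
            for cid, members in single_copy:
                gid = members[org]
                idx.append(cid)
                if attribute == "expression_log10":
                    vals.append(
                        float(log10_rpkm([expression[org].mean_rpkm[gene_index[gid]]])[0])
                    )
                elif attribute == "location_normalized":
                    vals.append(
                        float(
                            normalized_location(
                                [gene_pos[gid].midpoint], genome.length_bp
                            )[0]
                        )
                    )
                elif attribute == "gc":
                    vals.append(float(met.loc[gid, "gc_fraction"]))
                else:
                    vals.append(float(met.loc[gid, "cai"]))
            values[org] = pd.Series(vals, index=idx)
        frames.append(core_correlations(attribute, values))
    return pd.concat(frames, ignore_index=True)


def _write_manifest(config: RunConfig, bundle: dict, outdir: Path) -> None:
    inputs = {}
    for org in config.organisms:
        paths = [org.fasta, org.gff, *org.counts]
        inputs[org.label] = {str(p): _sha256(p) for p in paths}
    manifest = {
        "coreskew_version": __version__,
        "seed": config.seed,
        "identity_cutoff": config.identity_cutoff,
        "mass_thresholds": list(config.mass_thresholds),
        "inputs": inputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest


def summary_report(bundle: dict, genomes: list[AnnotatedGenome], outdir) -> pd.DataFrame:
    """Per-organism headline counts, written as TSV and markdown."""
    outdir = Path(outdir)
    core_n = len(bundle.get("core_cluster_ids", ()))
    ct_n = len(bundle.get("core_transcriptome", ()))
    if core_n == 0:
        logger.warning("empty core genome: core-transcriptome size is 0")
    mass_sets = bundle.get("mass_sets", {})
    rows = []
    for genome in genomes:
        org = genome.organism_label
        ms = mass_sets.get(org, {})
        ps = sorted(ms)
        rows.append(
            {
                "organism": org,
                "total_coding_genes": len(coding_genes(genome)),
                "genes_50pct_mass": len(ms[ps[0]]) if ps else None,
                "genes_90pct_mass": len(ms[ps[-1]]) if len(ps) > 1 else None,
                "core_families": core_n,
                "core_transcriptome": ct_n,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "summary.md", "w") as fh:
        fh.write("# Run summary\n\n")
        fh.write(df.to_markdown(index=False))
        fh.write("\n")
    bundle["summary"] = df
    return df
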