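"""Gene families, core/pan genome and rarefaction across a small clade.

Simulates three related genomes sharing 50 core families (~90% protein
identity within a family) plus accessory families in subsets, clusters
all genes at the 70% identity cutoff, and summarizes the pan-genome.
"""

from coreskew.pangenome import cluster_families, core_pan_counts, rarefaction
from coreskew.synthetic_data import SimulationConfig, generate_dataset

cfg = SimulationConfig(
    n_genomes=3,
    genome_length=250_000,
    n_core_families=50,
    n_accessory_families=80,
    accessory_presence=0.4,
    protein_length_range=(80, 250),
    family_identity=0.90,
    seed=19,
)
dataset = generate_dataset(cfg)

matrix = cluster_families(dataset.genomes, cutoff=0.70)
counts = core_pan_counts(matrix)
print(f"planted: {cfg.n_core_families} core + {cfg.n_accessory_families} accessory families")
print(f"recovered: core {counts['core']}, pan {counts['pan']}, "
      f"from {counts['total_genes']} genes")

# Rarefaction: how the pan genome grows as genomes are added in random
# order.  mean_new is the count of families first seen with the k-th
# genome; a curve still rising at k = G means the pan genome is open.
r = rarefaction(matrix, orderings=100, seed=1)
print("\nrarefaction (averaged over genome orderings):")
print(r.to_string(index=False))
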