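import itertools

import numpy as np
import pytest

from coreskew.genome_model import AnnotatedGenome
from coreskew.pangenome import (
    cluster_families,
    cluster_proteins,
    core_pan_counts,
    protein_identity,
    rarefaction,
)
from conftest import cds
from oracles import nw_affine_identity, single_linkage_clusters

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "M" + "".join(AAS[i] for i in rng.integers(20, size=n - 1))


def mutate(rng, prot, k):
    """Substitute exactly k positions (never the first Met)."""
    chars = list(prot)
    for i in rng.choice(np.arange(1, len(chars)), size=k, replace=False):
        chars[i] = AAS[(AAS.index(chars[i]) + 1 + rng.integers(19)) % 20]
    return "".join(chars)


class TestProteinIdentity:
    def test_identical(self):
        assert protein_identity("MKVLA", "MKVLA") == 1.0

    def test_quarter_identity_matches_dp_oracle(self):
        _score, ident = nw_affine_identity("MKKK", "MQQQ")
        assert ident == 0.25
        assert protein_identity("MKKK", "MQQQ") == pytest.approx(0.25)

    def test_gap_dominated_pair(self):
        _score, ident = nw_affine_identity("M", "MKKKKKKKKK")
        assert protein_identity("M", "MKKKKKKKKK") == pytest.approx(ident)
        assert protein_identity("M", "MKKKKKKKKK") <= 0.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            protein_identity("", "MK")

    def test_random_pairs_agree_with_dp_oracle(self, rng):
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(10, 50)))
            b = mutate(rng, a, int(rng.integers(1, max(2, len(a) // 3))))
            if rng.random() < 0.3:
                b = b[: int(rng.integers(5, len(b)))]
            assert protein_identity(a, b) == pytest.approx(
                nw_affine_identity(a, b)[1], abs=0.02
            )


def toy_genomes(proteins_per_genome):
    """Build AnnotatedGenomes whose CDS encode the given proteins."""
    from coreskew.codon_metrics import _FAMILIES

    codon_of = {aa: sorted(fam)[0] for aa, fam in _FAMILIES.items()}
    genomes = []
    for label, prots in proteins_per_genome.items():
        seq_parts, feats, pos = [], [], 0
        for i, p in enumerate(prots):
            nt = "".join(codon_of[aa] for aa in p) + "TAA"
            seq_parts.append(nt)
            feats.append(cds(f"{label}_g{i}", pos, pos + len(nt), +1, "toy"))
            pos += len(nt)
        genomes.append(
            AnnotatedGenome(organism_label=label, sequence="".join(seq_parts), features=feats)
        )
    return genomes


class TestClusterFamilies:
    def test_identical_genomes_all_core(self, rng):
        prots = [random_protein(rng, 40) for _ in range(5)]
        genomes = toy_genomes({g: prots for g in ("A", "B", "C")})
        matrix = cluster_families(genomes)
        counts = core_pan_counts(matrix)
        assert counts == {"core": 5, "pan": 5, "total_genes": 15}

    def test_diverged_gene_founds_new_cluster(self, rng):
        prots = [random_protein(rng, 40) for _ in range(5)]
        mutated = prots.copy()
        mutated[0] = mutate(rng, prots[0], 20)  # ~50% identity
        genomes = toy_genomes({"A": prots, "B": prots, "C": mutated})
        counts = core_pan_counts(cluster_families(genomes))
        assert counts == {"core": 4, "pan": 6, "total_genes": 15}

    def test_exact_cutoff_splits_any_mismatch(self, rng):
        prots = [random_protein(rng, 40) for _ in range(3)]
        other = [mutate(rng, p, 1) for p in prots]
        genomes = toy_genomes({"A": prots, "B": other})
        matrix = cluster_families(genomes, cutoff=1.0)
        assert core_pan_counts(matrix)["core"] == 0

    def test_genome_order_does_not_change_counts(self, rng):
        prots_a = [random_protein(rng, 30) for _ in range(4)]
        prots_b = prots_a[:2] + [random_protein(rng, 30) for _ in range(2)]
        genomes = toy_genomes({"A": prots_a, "B": prots_b})
        fwd = core_pan_counts(cluster_families(genomes))
        rev = core_pan_counts(cluster_families(genomes[::-1]))
        assert fwd == rev

    def test_single_genome_core_equals_pan(self, rng):
        genomes = toy_genomes({"A": [random_protein(rng, 30) for _ in range(4)]})
        counts = core_pan_counts(cluster_families(genomes))
        assert counts["core"] == counts["pan"] == 4

    def test_prefilter_never_changes_result(self, rng):
        records = []
        for g in ("A", "B"):
            base = [random_protein(rng, 35) for _ in range(6)]
            for i, p in enumerate(base):
                records.append((g, f"{g}_g{i}", mutate(rng, p, 3)))
        with_pf = cluster_proteins(records, ["A", "B"], prefilter_min_shared=0.2)
        without = cluster_proteins(records, ["A", "B"], prefilter_min_shared=0.0)
        members = lambda m: {frozenset(c["members"]) for c in m.clusters}
        assert members(with_pf) == members(without)

    def test_greedy_agrees_with_single_linkage_oracle(self, rng):
        """On <=50-gene instances with divergences >=10 identity points
        away from the cutoff, greedy centroid clustering and transitive
        single linkage over the full DP identity matrix coincide."""
        records = []
        for fam in range(8):
            n = int(rng.integers(25, 45))
            anc = random_protein(rng, n)
            for g in ("A", "B", "C"):
                if fam >= 5 and g == "C":
                    continue  # accessory families absent from C
                # ~5% substitutions -> identity ~0.9 or higher, far above 0.7
                records.append((g, f"{g}_f{fam}", mutate(rng, anc, max(1, n // 20))))
        assert len(records) <= 50
        greedy = cluster_proteins(records, ["A", "B", "C"], cutoff=0.70)
        greedy_sets = {frozenset(c["members"]) for c in greedy.clusters}
        oracle_sets = set(single_linkage_clusters(records, 0.70))
        assert greedy_sets == oracle_sets


class TestRarefaction:
    def _matrix(self, presence_rows, labels):
        records = []
        rng = np.random.default_rng(7)
        prots = {}
        for i, row in enumerate(presence_rows):
            prots[i] = random_protein(rng, 30)
            for j, present in enumerate(row):
                if present:
                    records.append((labels[j], f"{labels[j]}_f{i}", prots[i]))
        return cluster_proteins(records, labels)

    def test_identical_genomes_add_nothing_new(self):
        m = self._matrix([[1, 1, 1]] * 4, ["A", "B", "C"])
        r = rarefaction(m, orderings=10, seed=0)
        assert list(r["mean_new"]) == [4, 0, 0]

    def test_disjoint_genomes_grow_linearly(self):
        rows = [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1], [0, 0, 1]]
        m = self._matrix(rows, ["A", "B", "C"])
        r = rarefaction(m, orderings=10, seed=0)
        assert list(r["mean_pan"]) == [2, 4, 6]

    def test_matches_exhaustive_enumeration(self):
        rows = [[1, 1, 1], [1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 1, 1]]
        labels = ["A", "B", "C"]
        m = self._matrix(rows, labels)
        r = rarefaction(m, orderings=1000, seed=0)  # covers all 3! orderings
        presence = np.array(rows, dtype=bool)
        pans = np.zeros(3)
        for perm in itertools.permutations(range(3)):
            seen = np.zeros(len(rows), dtype=bool)
            for k, g in enumerate(perm):
                seen |= presence[:, g]
                pans[k] += seen.sum()
        assert np.allclose(r["mean_pan"], pans / 6)

    def test_pan_curve_monotone(self, rng):
        rows = (rng.random((12, 4)) < 0.5).astype(int)
        rows[rows.sum(axis=1) == 0, 0] = 1
        m = self._matrix(rows.tolist(), ["A", "B", "C", "D"])
        r = rarefaction(m, orderings=30, seed=1)
        assert (np.diff(r["mean_pan"]) >= 0).all()
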