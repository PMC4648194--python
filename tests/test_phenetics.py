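"""Phenetics: identity, UPGMA oracle checks, Newick, MSA, segregation."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from rhizoglob.align import global_align
from rhizoglob.phenetics import (
    DistanceMatrix,
    domain_split_identity,
    lineage_segregation,
    percent_identity,
    progressive_msa,
    to_newick,
    upgma,
)
from rhizoglob.synthetic_data import mutate_protein
from rhizoglob.synthetic_references import reference_by_id


def random_ultrametric_matrix(rng, n):
    """Random ultrametric distances via a random agglomeration history."""
    heights = np.sort(rng.uniform(1, 50, size=n - 1))
    clusters = [[i] for i in range(n)]
    m = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                m[a, b] = m[b, a] = 2 * h
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return m


class TestIdentity:
    def test_identical_sequences(self):
        assert percent_identity("MKVLH", "MKVLH") == 100.0

    def test_single_mismatch(self):
        assert percent_identity("ACDE", "ACDF") == 75.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            a = "".join(aa[i] for i in rng.integers(0, 20, rng.integers(10, 60)))
            b = "".join(aa[i] for i in rng.integers(0, 20, rng.integers(10, 60)))
            assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_shorter_denominator_option(self):
        aln_pct = percent_identity("MKVLHAG", "MKVLH", denominator="shorter")
        assert aln_pct == 100.0


class TestUpgma:
    def test_two_taxa_split_evenly(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        tree = upgma(dm)
        assert to_newick(tree) == "(A:2,B:2);"

    def test_three_taxon_hand_computed_tree(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]]),
        )
        assert to_newick(upgma(dm)) == "((A:1,B:1):3,C:4);"

    def test_ultrametric_output_for_arbitrary_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            m = rng.uniform(1, 90, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], m))
            assert tree.is_ultrametric(tol=1e-9)

    def test_cophenetic_round_trip_on_ultrametric_input(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            m = random_ultrametric_matrix(rng, n)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            _, coph = tree.cophenetic_matrix(labels)
            assert np.allclose(coph, m, atol=1e-9)

    def test_matches_scipy_average_linkage(self):
        """Independent oracle: scipy's average linkage cophenetic matrix."""
        rng = np.random.default_rng(12)
        for _ in range(15):
            n = int(rng.integers(3, 10))
            m = np.round(rng.uniform(1, 99, size=(n, n)), 3)
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            Z = sch.average(squareform(m, checks=False))
            scipy_coph = squareform(sch.cophenet(Z))
            _, mine = tree.cophenetic_matrix(labels)
            assert np.allclose(mine, scipy_coph, atol=1e-8)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError, match="two taxa"):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))


class TestNewick:
    def test_round_trip_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            m = random_ultrametric_matrix(rng, n)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            text = to_newick(tree)
            parsed = dendropy.Tree.get(data=text, schema="newick")
            assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(labels)
            pdm = parsed.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in parsed.taxon_namespace}
            _, mine = tree.cophenetic_matrix(labels)
            for i, la in enumerate(labels):
                for j, lb in enumerate(labels):
                    if i < j:
                        assert pdm.distance(taxa[la], taxa[lb]) == pytest.approx(
                            mine[i, j], abs=1e-6
                        )


class TestProgressiveMsa:
    def test_identical_triplicates_align_gap_free(self):
        seqs = {f"s{i}": "MKVLHEALTH" for i in range(3)}
        dm = DistanceMatrix(list(seqs), np.zeros((3, 3)))
        msa = progressive_msa(seqs, upgma(dm))
        assert all(row == "MKVLHEALTH" for row in msa.values())

    def test_two_sequences_reduce_to_pairwise_alignment(self):
        seqs = {"a": "MKVLHEALTH", "b": "MKVHEALTH"}
        msa = progressive_msa(seqs, upgma(DistanceMatrix.from_sequences(seqs)))
        aln = global_align(seqs["a"], seqs["b"])
        assert (msa["a"], msa["b"]) == (aln.aligned_a, aln.aligned_b)

    def test_rows_recover_inputs_and_insertion_stays_in_block(self):
        base = "MKVLHEALTHKVMRWYEQNA"
        seqs = {
            "a": base,
            "b": base,
            "c": base[:8] + "WWW" + base[8:],  # planted single insertion
        }
        msa = progressive_msa(seqs, upgma(DistanceMatrix.from_sequences(seqs)))
        lengths = {len(r) for r in msa.values()}
        assert lengths == {len(base) + 3}
        for label, row in msa.items():
            assert row.replace("-", "") == seqs[label]
        assert "WWW" in msa["c"]
        assert "---" in msa["a"] and "---" in msa["b"]

    def test_label_mismatch_rejected(self):
        seqs = {"a": "MKV", "b": "MKL"}
        tree = upgma(DistanceMatrix(["a", "x"], np.array([[0.0, 5.0], [5.0, 0.0]])))
        with pytest.raises(ValueError, match="labels"):
            progressive_msa(seqs, tree)


class TestSegregation:
    def _cohort_tree(self, refs, rate, n_copies=2):
        seqs = {}
        group = {}
        for ref in refs:
            if ref.type in ("protoglobin", "SSDgb"):
                continue  # types absent from rhizobial genomes
            for k in range(n_copies):
                label = f"{ref.type}_{k}"
                seqs[label] = mutate_protein(
                    ref.sequence, rate, seed=7000 + 13 * k, protected={ref.fold_positions["F8"]}
                )
                group[label] = ref.lineage
        tree = upgma(DistanceMatrix.from_sequences(seqs))
        return tree, group

    def test_two_main_lineages_segregate(self, refs):
        """Truncated hemoglobins form one pure clade; the fHb/SDgb/GCS
        lineage forms the other."""
        tree, group = self._cohort_tree(refs, rate=0.1)
        report = lineage_segregation(tree, group)
        assert report["tHb"]["monophyletic"]
        assert report["fHb/SDgb/GCS"]["monophyletic"]

    def test_mislabeled_leaf_lowers_purity(self, refs):
        tree, group = self._cohort_tree(refs, rate=0.1)
        wrong = dict(group)
        a_thb = next(l for l in wrong if l.startswith("tHb1"))
        wrong[a_thb] = "fHb/SDgb/GCS"
        report = lineage_segregation(tree, wrong)
        assert report["fHb/SDgb/GCS"]["purity"] < 1.0
        assert not report["fHb/SDgb/GCS"]["monophyletic"]

    def test_single_group_trivially_pure(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        report = lineage_segregation(upgma(dm), {"a": "g", "b": "g"})
        assert report["g"]["monophyletic"] and report["g"]["purity"] == 1.0


class TestDomainSplit:
    def test_identical_proteins_give_full_identity(self, refs):
        fhb = reference_by_id("ref_fhb").sequence
        gid, oid = domain_split_identity(fhb, fhb, "fHb", refs)
        assert gid == 100.0 and oid == 100.0

    def test_planted_asymmetric_divergence(self, refs):
        """A fusion of a slightly mutated globin domain and a heavily
        mutated flavin segment shows globin > flavin conservation."""
        fhb = reference_by_id("ref_fhb")
        boundary = 140
        a = fhb.sequence
        globin_mut = mutate_protein(a[:boundary], 0.05, seed=1, protected={fhb.fold_positions["F8"]})
        flavin_mut = mutate_protein(a[boundary:], 0.30, seed=2)
        b = globin_mut + flavin_mut
        gid, oid = domain_split_identity(a, b, "fHb", refs)
        assert gid > oid

    def test_single_domain_type_rejected(self, refs):
        sdgb = reference_by_id("ref_sdgb").sequence
        with pytest.raises(ValueError, match="single-domain"):
            domain_split_identity(sdgb, sdgb, "SDgb", refs)
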