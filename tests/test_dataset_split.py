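import numpy as np
import pytest
from rdkit import DataStructs

from bindgraph import (
    SyntheticSpec,
    assign_splits,
    audit_leakage,
    build_split,
    cluster_ligands,
    cluster_sequences,
    generate_split_benchmark,
    sequence_identity,
)
from bindgraph.dataset_split import ligand_fingerprint


@pytest.fixture(scope="module")
def benchmark():
    return generate_split_benchmark(SyntheticSpec(n_families=3, seed=31))


class TestSequenceClustering:
    def test_identical_sequences_share_a_cluster(self):
        cl = cluster_sequences({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL", "c": "WWWWWWWWWW"})
        assert cl["a"] == cl["b"] != cl["c"]

    def test_singleton_input_is_one_cluster(self):
        assert cluster_sequences({"only": "ACDEFG"}) == {"only": 0}

    def test_synthetic_families_recovered(self, benchmark):
        cl = cluster_sequences(benchmark["sequences"], 0.40)
        fam = benchmark["families"]
        # same family <=> same cluster
        for a in list(fam)[:20]:
            for b in list(fam)[:20]:
                assert (cl[a] == cl[b]) == (fam[a] == fam[b])
        assert len(set(cl.values())) == 3

    def test_identity_is_matches_over_alignment_length(self):
        assert sequence_identity("ACDE", "ACDE") == pytest.approx(1.0)
        assert sequence_identity("AAAA", "WWWW") == pytest.approx(0.0)
        # one mismatch in four aligned columns
        assert sequence_identity("ACDE", "ACDF") == pytest.approx(0.75)

    def test_pluggable_backend(self):
        sentinel = {"x": 42}
        out = cluster_sequences({"x": "AAAA"}, backend=lambda seqs, cut: sentinel)
        assert out is sentinel


class TestLigandClustering:
    def test_hand_computed_tanimoto(self):
        """Bit vectors 1100 and 0110: intersection 1, union 3 -> 1/3."""
        a = DataStructs.ExplicitBitVect(4)
        b = DataStructs.ExplicitBitVect(4)
        for bit in (0, 1):
            a.SetBit(bit)
        for bit in (1, 2):
            b.SetBit(bit)
        assert DataStructs.TanimotoSimilarity(a, b) == pytest.approx(1 / 3)

    def test_duplicate_smiles_cluster_together(self):
        cl, excluded = cluster_ligands({"a": "CCO", "b": "CCO", "c": "c1ccccc1"})
        assert not excluded
        assert cl["a"] == cl["b"] != cl["c"]

    def test_different_spellings_of_one_molecule_cluster_together(self):
        cl, _ = cluster_ligands({"kekule": "C1=CC=CC=C1", "aromatic": "c1ccccc1",
                                 "other": "CCCCCC"})
        assert cl["kekule"] == cl["aromatic"] != cl["other"]

    def test_unparseable_smiles_excluded_with_report(self):
        with pytest.warns(UserWarning, match="unparseable"):
            cl, excluded = cluster_ligands({"ok": "CCO", "bad": "notasmiles(("})
        assert excluded == ["bad"] and "ok" in cl

    def test_dissimilar_ligands_in_separate_clusters(self):
        cl, _ = cluster_ligands({"alkane": "CCCCCCC", "aromatic": "c1ccccc1"})
        assert cl["alkane"] != cl["aromatic"]

    def test_cross_cluster_pairs_never_exceed_cutoff(self, benchmark):
        """Single linkage at 40% similarity guarantees the audit property."""
        cl, _ = cluster_ligands(benchmark["smiles"], 0.40)
        fps = {k: ligand_fingerprint(s) for k, s in benchmark["smiles"].items()}
        for a in cl:
            for b in cl:
                if a < b and cl[a] != cl[b]:
                    assert DataStructs.TanimotoSimilarity(fps[a], fps[b]) <= 0.40


class TestAssignSplits:
    def test_single_sequence_cluster_is_atomic(self):
        seq_clusters = {"a": 0, "b": 0, "c": 0}
        asg = assign_splits(seq_clusters, {}, {}, seed=0)
        assert len(set(asg.membership.values())) == 1

    def test_val_chain_sharing_train_ligand_cluster_is_purged(self):
        seq_clusters = {"t1": 0, "t2": 0, "t3": 0, "v1": 1}
        ligand_map = {"t1": "L1", "t2": "L1", "t3": "L1", "v1": "L2"}
        ligand_clusters = {"L1": 0, "L2": 0}  # same ligand cluster
        for seed in range(5):
            asg = assign_splits(seq_clusters, ligand_map, ligand_clusters,
                                fractions=(0.75, 0.25, 0.0), seed=seed)
            splits = set(asg.membership.values())
            if "val" in splits:  # whenever both splits survive, no sharing
                lc_train = {0}
                assert all(ligand_clusters[ligand_map[c]] not in lc_train
                           for c, s in asg.membership.items() if s != "train")
        # the chain-count-weighted assignment sends cluster 0 to train when
        # it is drawn first; then v1 must be purged
        purged_seen = any(
            assign_splits(seq_clusters, ligand_map, ligand_clusters,
                          fractions=(0.75, 0.25, 0.0), seed=s).n_purged > 0
            for s in range(10))
        assert purged_seen

    def test_deterministic_for_fixed_seed(self, benchmark):
        cl = cluster_sequences(benchmark["sequences"])
        lig_cl, _ = cluster_ligands(benchmark["smiles"])
        a = assign_splits(cl, benchmark["ligand_map"], lig_cl, seed=4)
        b = assign_splits(cl, benchmark["ligand_map"], lig_cl, seed=4)
        assert a.membership == b.membership

    def test_cluster_atomicity(self, benchmark):
        cl = cluster_sequences(benchmark["sequences"])
        lig_cl, _ = cluster_ligands(benchmark["smiles"])
        asg = assign_splits(cl, benchmark["ligand_map"], lig_cl, seed=1)
        for a in asg.membership:
            for b in asg.membership:
                if cl[a] == cl[b]:
                    assert asg.membership[a] == asg.membership[b]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            assign_splits({"a": 0}, {}, {}, fractions=(0.5, 0.2, 0.2))


class TestAudit:
    def test_single_split_assignment_passes_vacuously(self):
        from bindgraph.dataset_split import SplitAssignment

        asg = SplitAssignment(membership={"a": "train", "b": "train"},
                              seq_clusters={"a": 0, "b": 0}, ligand_clusters={})
        audit = audit_leakage(asg, {"a": "ACDE", "b": "ACDE"}, {}, {})
        assert audit["pass"] and audit["max_cross_split_seq_identity"] == 0.0

    def test_planted_leaky_pair_fails_naming_the_pair(self):
        from bindgraph.dataset_split import SplitAssignment

        seqs = {"a": "ACDEFGHIKLMNPQRSTVWY", "b": "ACDEFGHIKLMNPQRSTVWY",
                "c": "WYWYWYWYWYWYWYWYWYWY"}
        asg = SplitAssignment(membership={"a": "train", "b": "test", "c": "test"},
                              seq_clusters={}, ligand_clusters={})
        audit = audit_leakage(asg, seqs, {}, {})
        assert not audit["pass"]
        assert set(audit["worst_sequence_pair"]) == {"a", "b"}
        assert audit["max_cross_split_seq_identity"] == pytest.approx(1.0)

    def test_audit_maxima_equal_brute_force_recomputation(self, benchmark):
        [asg] = build_split(benchmark["sequences"], benchmark["ligand_map"],
                            benchmark["smiles"], seed=2)
        member = asg.membership
        ids = list(member)
        best = 0.0
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if member[a] != member[b]:
                    best = max(best, sequence_identity(
                        benchmark["sequences"][a], benchmark["sequences"][b]))
        assert asg.audit["max_cross_split_seq_identity"] == pytest.approx(best)


def test_end_to_end_replicates_pass_audit(benchmark):
    assignments = build_split(benchmark["sequences"], benchmark["ligand_map"],
                              benchmark["smiles"], seed=10, replicates=3)
    for asg in assignments:
        assert asg.audit["pass"]
        assert asg.audit["max_cross_split_seq_identity"] <= 0.40
        assert asg.audit["max_cross_split_ligand_tanimoto"] <= 0.40
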