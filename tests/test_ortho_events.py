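"""Duplication calling, loss flags, sister filter, clade medians, KS test."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from ciloss.ortho_events import (
    ancestral_copy_number,
    annotate_duplications,
    filter_shared_with_sister,
    infer_family_loss,
    ks_association,
    ks_scan,
    node_medians,
)
from ciloss.trees import monophyletic_state_nodes

from oracles import ks_two_sample_exact


def gene_tree(newick):
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


class TestSpeciesOverlapDuplications:
    def test_within_species_duplication(self):
        tree = gene_tree("((a1@spX,a2@spX),b@spY);")
        dups, flags = annotate_duplications(tree)
        assert len(dups) == 1
        assert flags == {"spX": True, "spY": False}

    def test_one_gene_per_species_no_duplications(self):
        tree = gene_tree("((a@spX,b@spY),c@spZ);")
        dups, flags = annotate_duplications(tree)
        assert dups == set()
        assert flags == {"spX": False, "spY": False, "spZ": False}

    def test_root_duplication_flags_both_species(self):
        tree = gene_tree("((a@spX,a@spY),(b@spX,b@spY));")
        dups, flags = annotate_duplications(tree)
        assert len(dups) == 1  # the root: children overlap in {spX, spY}
        assert flags == {"spX": True, "spY": True}

    def test_unlabelled_tip_raises(self):
        tree = gene_tree("((a,b@spY),c@spZ);")
        with pytest.raises(ValueError, match="@species"):
            annotate_duplications(tree)

    def test_mapping_lookup(self):
        tree = gene_tree("((a,b),c);")
        dups, flags = annotate_duplications(
            tree, species_of={"a": "spX", "b": "spX", "c": "spY"}
        )
        assert len(dups) == 1
        assert flags["spX"] is True

    def test_matches_direct_overlap_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)

        def random_newick(labels):
            if len(labels) == 1:
                return labels[0]
            k = int(rng.integers(1, len(labels)))
            return f"({random_newick(labels[:k])},{random_newick(labels[k:])})"

        for _ in range(20):
            # random 8-tip gene tree over 4 species
            labels = [f"g{i}@sp{rng.integers(4)}" for i in range(8)]
            tree = gene_tree(random_newick(labels) + ";")
            dups, _ = annotate_duplications(tree)

            # independent recursive oracle
            def leaf_species(node):
                if node.is_leaf():
                    return {node.taxon.label.rsplit("@", 1)[1]}
                out = set()
                for c in node.child_nodes():
                    out |= leaf_species(c)
                return out

            expected = set()
            for node in tree.preorder_node_iter():
                kids = node.child_nodes()
                if len(kids) < 2:
                    continue
                sets = [leaf_species(c) for c in kids]
                if any(
                    sets[i] & sets[j]
                    for i in range(len(sets))
                    for j in range(i + 1, len(sets))
                ):
                    expected.add(node._ciloss_id)
            assert dups == expected


class TestFamilyLoss:
    def test_lost_in_focal_retained_in_sister(self):
        assert infer_family_loss({"f": 0, "s1": 1, "s2": 2}, "f", ["s1", "s2"])

    def test_present_in_focal_not_lost(self):
        assert not infer_family_loss({"f": 1, "s1": 1}, "f", ["s1"])

    def test_shared_absence_not_counted(self):
        assert not infer_family_loss({"f": 0, "s1": 0, "s2": 0}, "f", ["s1", "s2"])

    def test_errors(self):
        with pytest.raises(ValueError, match="sister"):
            infer_family_loss({"f": 0}, "f", [])
        with pytest.raises(ValueError, match="focal"):
            infer_family_loss({"s1": 1}, "f", ["s1"])


class TestSisterFilter:
    def make(self, focal_rows, sister_rows):
        cols = ["family_id", "species_id", "L", "D", "PS", "MR"]
        return (
            pd.DataFrame(focal_rows, columns=cols),
            pd.DataFrame(sister_rows, columns=cols),
        )

    def test_same_event_type_shared_discards(self):
        focal, sister = self.make(
            [["fam1", "ci1", False, True, False, False]],
            [["fam1", "sis1", False, True, False, False]],
        )
        keep = filter_shared_with_sister(focal, sister)
        assert not keep["fam1"]

    def test_focal_only_event_kept(self):
        focal, sister = self.make(
            [["fam1", "ci1", False, True, False, False]],
            [["fam1", "sis1", False, False, False, False]],
        )
        assert filter_shared_with_sister(focal, sister)["fam1"]

    def test_different_event_types_kept(self):
        focal, sister = self.make(
            [["fam1", "ci1", True, False, False, False]],  # L in CI-
            [["fam1", "sis1", False, True, False, False]],  # D in sister
        )
        assert filter_shared_with_sister(focal, sister)["fam1"]

    def test_family_absent_from_sister_table_kept(self):
        focal, sister = self.make(
            [["fam1", "ci1", False, False, True, False]], []
        )
        assert filter_shared_with_sister(focal, sister)["fam1"]


class TestNodeMedians:
    counts = pd.DataFrame(
        {"A": [1, 1], "B": [2, 2], "C": [4, 3]}, index=["famX", "famY"]
    )

    def test_odd_clade(self):
        prof = node_medians(self.counts, [("n1", frozenset("ABC"), "present")])
        assert prof.loc[prof.family_id == "famX", "median"].item() == 2

    def test_even_clade_mean_of_central(self):
        prof = node_medians(self.counts, [("n1", frozenset("AB"), "present")])
        assert prof.loc[prof.family_id == "famX", "median"].item() == 1.5

    def test_single_species_clade(self):
        prof = node_medians(self.counts, [("n1", frozenset("C"), "absent")])
        assert prof.loc[prof.family_id == "famY", "median"].item() == 3

    def test_empty_clade_raises(self):
        with pytest.raises(ValueError, match="no species"):
            node_medians(self.counts, [("n1", frozenset(["Z"]), "absent")])

    def test_median_invariant_to_relabeling(self):
        prof1 = node_medians(self.counts, [("n1", ("A", "B", "C"), "present")])
        prof2 = node_medians(self.counts, [("n1", ("C", "A", "B"), "present")])
        pd.testing.assert_frame_equal(prof1, prof2)


class TestKSAssociation:
    def test_identical_samples(self):
        res = ks_association("fam", [1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.pvalue == 1 and not res.significant

    def test_complete_separation_matches_enumeration_oracle(self):
        plus = [0.0, 0.0, 0.0, 0.0]
        minus = [3.0, 3.0, 3.0, 3.0]
        d_oracle, p_oracle = ks_two_sample_exact(plus, minus)
        res = ks_association("fam", plus, minus)
        assert res.statistic == pytest.approx(d_oracle) == 1.0
        assert res.pvalue == pytest.approx(p_oracle)  # 2 / C(8,4) = 1/35
        assert p_oracle == pytest.approx(2 / 70)
        assert res.direction == "higher"

    def test_partial_overlap_matches_enumeration_oracle(self):
        # tie-free samples: the permutation null and the continuous
        # exact null coincide
        plus = [0.0, 1.0, 2.5, 2.8, 3.0]
        minus = [2.0, 3.5, 4.0, 5.0]
        _, p_oracle = ks_two_sample_exact(plus, minus)
        res = ks_association("fam", plus, minus)
        assert res.pvalue == pytest.approx(p_oracle, rel=1e-9)

    def test_order_invariance(self):
        a = ks_association("fam", [1, 5, 2], [9, 3, 4])
        b = ks_association("fam", [2, 1, 5], [3, 4, 9])
        assert a == b

    def test_empty_side_raises(self):
        with pytest.raises(ValueError, match="medians"):
            ks_association("fam", [], [1.0])


def test_ks_scan_modes_agree_on_significant_shift(default_dataset):
    ds = default_dataset
    res = ks_scan(ds.family_data.counts, ds.tree, nodes="pooled")
    planted = ds.truth.assoc_family_ids
    sig = set(res.loc[res.significant, "family_id"])
    assert len(sig & planted) >= 0.5 * len(planted)
    directions = res.set_index("family_id").loc[sorted(planted), "direction"]
    assert (directions == "higher").all()


class TestAncestralCopyNumber:
    @pytest.mark.parametrize(
        "tips, counts, expected",
        [
            (["a", "b", "c"], {"a": 2, "b": 2, "c": 2}, 2),
            (["a", "b", "c"], {"a": 0, "b": 1, "c": 5}, 1),
            (["a", "b"], {"a": 1, "b": 3}, 2),
        ],
    )
    def test_examples(self, tips, counts, expected):
        assert ancestral_copy_number(tips, counts) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ancestral_copy_number([], {})


def test_monophyletic_state_nodes_partition(default_dataset):
    stree = default_dataset.tree
    nodes = monophyletic_state_nodes(stree)
    seen = [t for _, tips, _ in nodes for t in tips]
    known = [t for t, s in stree.status.items() if s in ("present", "absent")]
    assert sorted(seen) == sorted(known)  # maximal clades partition the tips
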