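import numpy as np
import pytest

from _oracles import brute_force_ted
from litmetrics import (
    ConlluError,
    DepTree,
    RelabeledTree,
    SentencePair,
    astred_change,
    gen_tree,
    merge_labels,
    read_conllu,
    tree_edit_distance,
)

CONLLU_3 = """# sent_id = s1
1\tThe\tthe\tDET\tDT\t_\t2\tdet\t_\t_
2\tcat\tcat\tNOUN\tNN\t_\t3\tnsubj\t_\t_
3\tsleeps\tsleep\tVERB\tVBZ\t_\t0\troot\t_\t_
"""


def relabel(heads, labels):
    tree = DepTree.from_heads(heads)
    return RelabeledTree(tree, dict(enumerate(labels)))


class TestReadConllu:
    def test_reads_heads_deprels_and_forms(self):
        (tree,) = read_conllu(CONLLU_3)
        assert tree.root.token_index == 2
        assert [n.deprel for n in tree.nodes] == ["det", "nsubj", "root"]
        assert tree.nodes[0].head_index == 1
        assert tree.sent_id == "s1"

    def test_stream_of_two_sentences_gives_two_trees(self):
        trees = read_conllu(CONLLU_3 + "\n" + CONLLU_3.replace("s1", "s2"))
        assert [t.sent_id for t in trees] == ["s1", "s2"]

    def test_multiword_ranges_and_empty_nodes_are_skipped(self):
        text = (
            "1-2\tdel\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tde\t_\tADP\t_\t_\t3\tcase\t_\t_\n"
            "2\tel\t_\tDET\t_\t_\t3\tdet\t_\t_\n"
            "2.1\tnull\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "3\tmar\t_\tNOUN\t_\t_\t0\troot\t_\t_\n"
        )
        (tree,) = read_conllu(text)
        assert len(tree) == 3

    def test_head_cycle_is_a_parse_error(self):
        text = (
            "1\ta\t_\t_\t_\t_\t2\tdep\t_\t_\n"
            "2\tb\t_\t_\t_\t_\t1\tdep\t_\t_\n"
            "3\tc\t_\t_\t_\t_\t0\troot\t_\t_\n"
        )
        with pytest.raises(ConlluError, match="cycle"):
            read_conllu(text)

    def test_multi_root_sentence_is_rejected(self):
        text = (
            "1\ta\t_\t_\t_\t_\t0\troot\t_\t_\n"
            "2\tb\t_\t_\t_\t_\t0\troot\t_\t_\n"
        )
        with pytest.raises(ConlluError, match="root"):
            read_conllu(text)


class TestMergeLabels:
    def test_fully_aligned_pair_shares_n_distinct_labels(self):
        src = DepTree.from_heads([2, 3, 0])
        tgt = DepTree.from_heads([2, 3, 0])
        links = {(0, 0), (1, 1), (2, 2)}
        ra, rb = merge_labels(src, tgt, {l for l in map(tuple, links)})
        assert [ra.match_labels[i] for i in range(3)] == [
            rb.match_labels[i] for i in range(3)
        ]
        assert len(set(ra.match_labels.values())) == 3

    def test_unaligned_node_matches_nothing_across_trees(self):
        src = DepTree.from_heads([2, 0])
        tgt = DepTree.from_heads([2, 0])
        ra, rb = merge_labels(src, tgt, {(1, 1)})
        assert ra.match_labels[0] not in set(rb.match_labels.values())

    def test_mwg_component_shares_one_label_on_both_sides(self, example2_pair):
        src = DepTree.from_heads([0, 3, 1])  # called <- sentinels <- marine
        tgt = DepTree.from_heads([5, 1, 1, 1, 0])
        ra, rb = merge_labels(src, tgt, example2_pair.links)
        assert ra.match_labels[1] == ra.match_labels[2]
        assert {rb.match_labels[j] for j in range(4)} == {ra.match_labels[1]}

    def test_link_outside_trees_is_a_consistency_error(self):
        src = DepTree.from_heads([0])
        tgt = DepTree.from_heads([0])
        with pytest.raises(ValueError, match="absent"):
            merge_labels(src, tgt, {(0, 5)})


class TestTreeEditDistance:
    def test_identical_trees_cost_zero_all_match(self):
        a = relabel([2, 3, 0], "XYZ")
        b = relabel([2, 3, 0], "XYZ")
        script = tree_edit_distance(a, b)
        assert script.total_cost == 0
        assert {op.op for op in script.ops} == {"match"}

    def test_single_node_label_change_is_one_rename(self):
        script = tree_edit_distance(relabel([0], "A"), relabel([0], "B"))
        assert script.total_cost == 1
        assert script.ops == [type(script.ops[0])("rename", 0, 0)]

    def test_size_bounds(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = RelabeledTree(
                gen_tree(rng, na),
                {i: str(rng.choice(list("AB"))) for i in range(na)},
            )
            b = RelabeledTree(
                gen_tree(rng, nb),
                {i: str(rng.choice(list("AB"))) for i in range(nb)},
            )
            cost = tree_edit_distance(a, b).total_cost
            assert abs(na - nb) <= cost <= na + nb

    def test_matches_exhaustive_mapping_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = RelabeledTree(
                gen_tree(rng, na),
                {i: str(rng.choice(list("ABC"))) for i in range(na)},
            )
            b = RelabeledTree(
                gen_tree(rng, nb),
                {i: str(rng.choice(list("ABC"))) for i in range(nb)},
            )
            assert tree_edit_distance(a, b).total_cost == brute_force_ted(a, b)

    def test_cost_is_symmetric_under_tree_swap(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = RelabeledTree(
                gen_tree(rng, 5), {i: str(rng.choice(list("AB"))) for i in range(5)}
            )
            b = RelabeledTree(
                gen_tree(rng, 6), {i: str(rng.choice(list("AB"))) for i in range(6)}
            )
            assert (
                tree_edit_distance(a, b).total_cost
                == tree_edit_distance(b, a).total_cost
            )

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            trees = [
                RelabeledTree(
                    gen_tree(rng, int(rng.integers(2, 6))),
                    {},
                )
                for _ in range(3)
            ]
            for t in trees:
                t.match_labels.update(
                    {i: str(rng.choice(list("AB"))) for i in range(len(t.tree))}
                )
            d = lambda x, y: tree_edit_distance(x, y).total_cost
            a, b, c = trees
            assert d(a, c) <= d(a, b) + d(b, c)

    def test_insertions_only_on_target_side(self):
        a = relabel([0], "A")
        b = relabel([2, 0, 2], "XAY")
        script = tree_edit_distance(a, b)
        for op in script.ops:
            if op.op == "insert":
                assert op.src is None and op.tgt is not None
            if op.op == "delete":
                assert op.tgt is None and op.src is not None


class TestAstredChange:
    def test_label_isomorphic_fully_aligned_trees_are_all_false(self):
        src = DepTree.from_heads([2, 3, 0], ["det", "nsubj", "root"])
        tgt = DepTree.from_heads([2, 3, 0], ["det", "nsubj", "root"])
        pair = SentencePair.from_strings(
            ["The", "cat", "sleeps"], ["De", "kat", "slaapt"], [(i, i) for i in range(3)]
        )
        assert astred_change(pair, src, tgt) == {0: False, 1: False, 2: False}

    def test_unaligned_source_token_is_the_only_true(self):
        src = DepTree.from_heads([2, 3, 0])
        tgt = DepTree.from_heads([2, 3, 0])
        pair = SentencePair.from_strings(
            ["The", "cat", "sleeps"], ["De", "kat", "slaapt"], [(0, 0), (2, 2)]
        )
        flags = astred_change(pair, src, tgt)
        assert flags == {0: False, 1: True, 2: False}

    def test_extra_unaligned_modifier_is_deleted(self):
        # source has one extra modifier under the root; target lacks it
        src = DepTree.from_heads([2, 0, 2])  # tokens 0 and 2 modify root 1
        tgt = DepTree.from_heads([0, 1])  # root token 0, modifier token 1
        pair = SentencePair.from_strings(
            ["old", "runs", "fast"], ["rent", "vite"], [(1, 0), (2, 1)]
        )
        flags = astred_change(pair, src, tgt)
        assert flags == {0: True, 1: False, 2: False}

    def test_flags_match_brute_force_cost_difference(self):
        # the flagged tokens are exactly the non-matches of an optimal
        # script, so #True = optimal cost − #insertions
        rng = np.random.default_rng(31)
        for _ in range(40):
            n_src, n_tgt = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            src, tgt = gen_tree(rng, n_src), gen_tree(rng, n_tgt)
            links = {
                (i, j)
                for i in range(n_src)
                for j in range(n_tgt)
                if rng.random() < 0.3
            }
            pair = SentencePair.from_strings(
                [f"s{i}" for i in range(n_src)],
                [f"t{j}" for j in range(n_tgt)],
                links,
            )
            ra, rb = merge_labels(src, tgt, pair.links)
            script = tree_edit_distance(ra, rb)
            assert script.total_cost == brute_force_ted(ra, rb)
            flags = astred_change(pair, src, tgt)
            n_true = sum(flags.values())
            n_insert = sum(1 for op in script.ops if op.op == "insert")
            assert n_true == script.total_cost - n_insert
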