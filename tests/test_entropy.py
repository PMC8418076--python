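import math
from collections import Counter

import numpy as np
import pytest

from litmetrics import (
    SentencePair,
    SimConfig,
    Token,
    TranslationEnsemble,
    alignment_components,
    entropy_bits,
    gen_ensemble,
    hcross,
    hstc,
    htra,
)
from litmetrics.entropy import EventDistribution


def dist(counts):
    return EventDistribution(Counter({f"e{i}": c for i, c in enumerate(counts)}))


def make_ensemble(source, targets_and_links):
    """Versions as (target token list, link list) over a shared source."""
    src = [Token(i, f) for i, f in enumerate(source)]
    versions = [
        (f"P{k + 1}", SentencePair.from_strings(source, tgt, links))
        for k, (tgt, links) in enumerate(targets_and_links)
    ]
    return TranslationEnsemble(src, versions)


class TestEntropyBits:
    @pytest.mark.parametrize(
        "counts, expected",
        [([4], 0.0), ([1, 1], 1.0), ([2, 1, 1], 1.5), ([3, 1], 0.8112781244591328)],
    )
    def test_exact_values(self, counts, expected):
        assert entropy_bits(dist(counts)) == pytest.approx(expected, abs=1e-12)

    def test_empty_distribution_is_a_domain_error(self):
        with pytest.raises(ValueError):
            entropy_bits(dist([]))

    def test_bounded_by_log2_of_support(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(1, 30, size=int(rng.integers(1, 8))).tolist()
            h = entropy_bits(dist(counts))
            assert 0.0 <= h <= math.log2(len(counts)) + 1e-12


class TestHTra:
    def test_full_agreement_is_zero(self):
        ens = make_ensemble(
            ["house"], [(["huis"], [(0, 0)])] * 4
        )
        assert htra(ens, 0) == 0.0

    def test_even_split_is_one_bit(self):
        ens = make_ensemble(
            ["big"],
            [(["groot"], [(0, 0)])] * 2 + [(["fors"], [(0, 0)])] * 2,
        )
        assert htra(ens, 0) == 1.0

    def test_two_one_one_split_is_one_and_a_half_bits(self):
        ens = make_ensemble(
            ["w"],
            [(["a"], [(0, 0)])] * 2 + [(["b"], [(0, 0)]), (["c"], [(0, 0)])],
        )
        assert htra(ens, 0) == 1.5

    def test_casing_and_whitespace_variants_do_not_split_events(self):
        ens = make_ensemble(
            ["w"], [(["Huis"], [(0, 0)]), (["huis "], [(0, 0)])]
        )
        assert htra(ens, 0) == 0.0

    def test_multi_token_translation_joined_in_target_order(self):
        ens = make_ensemble(
            ["w"],
            [
                (["van", "zee"], [(0, 0), (0, 1)]),
                (["van", "zee"], [(0, 1), (0, 0)]),  # same link set, same event
            ],
        )
        assert htra(ens, 0) == 0.0

    def test_token_unaligned_everywhere_has_no_distribution(self):
        ens = make_ensemble(["w", "x"], [(["y"], [(1, 0)])] * 3)
        assert htra(ens, 0) is None

    def test_unaligned_versions_dropped_unless_requested(self):
        ens = make_ensemble(
            ["w"], [(["a"], [(0, 0)]), (["b"], []), (["a"], [(0, 0)])]
        )
        assert htra(ens, 0) == 0.0
        assert htra(ens, 0, include_unaligned=True) == pytest.approx(
            entropy_bits(dist([2, 1]))
        )


class TestHCross:
    def test_monotone_versions_agree_on_cross_one(self):
        ens = make_ensemble(
            ["a", "b"], [(["x", "y"], [(0, 0), (1, 1)])] * 4
        )
        assert hcross(ens, 0) == 0.0 and hcross(ens, 1) == 0.0

    def test_even_reordering_split_is_one_bit(self):
        monotone = (["x", "y"], [(0, 0), (1, 1)])
        swapped = (["y", "x"], [(0, 1), (1, 0)])
        ens = make_ensemble(["a", "b"], [monotone] * 2 + [swapped] * 2)
        assert hcross(ens, 0) == 1.0

    def test_three_one_split(self):
        monotone = (["x", "y"], [(0, 0), (1, 1)])
        swapped = (["y", "x"], [(0, 1), (1, 0)])
        ens = make_ensemble(["a", "b"], [monotone] * 3 + [swapped])
        assert hcross(ens, 0) == pytest.approx(0.8112781244591328)


class TestAlignmentComponents:
    def test_monotone_pair_gives_degenerate_components(self):
        pair = SentencePair.from_strings("abc", "xyz", [(i, i) for i in range(3)])
        comps = alignment_components(pair)
        assert [c.group_cross for c in comps] == [1, 1, 1]
        assert [sorted(c.src_indices) for c in comps] == [[0], [1], [2]]

    def test_example2_mwg_is_one_component(self, example2_pair):
        comps = alignment_components(example2_pair)
        assert len(comps) == 2
        mwg = comps[1]
        assert sorted(mwg.src_indices) == [1, 2]
        assert sorted(mwg.tgt_indices) == [0, 1, 2, 3]

    def test_chain_merges_into_single_component(self):
        pair = SentencePair.from_strings(
            "ab", "xy", [(0, 0), (1, 0), (1, 1)]
        )
        comps = alignment_components(pair)
        assert len(comps) == 1
        assert sorted(comps[0].src_indices) == [0, 1]
        assert sorted(comps[0].tgt_indices) == [0, 1]

    def test_every_aligned_token_in_exactly_one_component(self):
        from conftest import random_pair

        rng = np.random.default_rng(5)
        for _ in range(50):
            pair = random_pair(rng)
            comps = alignment_components(pair)
            src = [i for c in comps for i in c.src_indices]
            assert sorted(src) == sorted(pair.aligned_src())
            tgt = [j for c in comps for j in c.tgt_indices]
            assert sorted(tgt) == sorted(pair.aligned_tgt())


class TestHstc:
    def test_identical_triplets_give_zero(self):
        ens = make_ensemble(
            ["a", "b"], [(["x", "y"], [(0, 0), (1, 1)])] * 5
        )
        assert hstc(ens, 0) == 0.0

    def test_distinct_triplets_give_one_bit(self):
        ens = make_ensemble(
            ["a"], [(["x"], [(0, 0)]), (["z"], [(0, 0)])]
        )
        assert hstc(ens, 0) == 1.0

    def test_collapses_to_hcross_when_only_c_varies(self):
        # same lexical rendering, different reordering: the triplet
        # distribution equals the Cross-value marginal
        monotone = (["x", "y"], [(0, 0), (1, 1)])
        swapped = (["y", "x"], [(0, 1), (1, 0)])
        ens = make_ensemble(["a", "b"], [monotone] * 2 + [swapped] * 2)
        assert hstc(ens, 1) == hcross(ens, 1) == 1.0


class TestEnsembleProperties:
    def test_entropies_bounded_by_log2_n_versions(self):
        for seed in range(5):
            ens, _ = gen_ensemble(
                SimConfig(seed=seed, n_src=6, reorder_rate=0.3, n_versions=9)
            )
            bound = math.log2(ens.n_versions) + 1e-12
            for i in range(6):
                for metric in (htra, hcross, hstc):
                    h = metric(ens, i)
                    assert h is not None and 0.0 <= h <= bound

    def test_version_permutation_and_relabeling_invariance(self):
        ens, _ = gen_ensemble(SimConfig(seed=2, n_src=5, n_versions=8))
        relabeled = TranslationEnsemble(
            ens.source,
            [(f"X{k}", pair) for k, (_, pair) in enumerate(reversed(ens.versions))],
        )
        for i in range(5):
            assert htra(ens, i) == htra(relabeled, i)
            assert hcross(ens, i) == hcross(relabeled, i)
            assert hstc(ens, i) == hstc(relabeled, i)

    def test_joint_entropy_dominates_marginals(self):
        # HSTC's triplet distribution refines both the lexical events and
        # the Cross events, so its entropy can never be smaller
        for seed in range(5):
            ens, _ = gen_ensemble(
                SimConfig(seed=seed + 10, n_src=6, reorder_rate=0.4, n_versions=10)
            )
            for i in range(6):
                joint = hstc(ens, i)
                for marginal in (htra(ens, i), hcross(ens, i)):
                    assert joint >= marginal - 1e-9

    def test_htra_recovers_generating_entropy_at_large_n(self):
        # law of large numbers: empirical entropy approaches the generating
        # distribution's entropy as the number of versions grows
        errs = []
        for seed in range(10):
            ens, gold = gen_ensemble(
                SimConfig(
                    seed=seed,
                    n_src=3,
                    reorder_rate=0.0,
                    n_versions=5000,
                    translation_dist=[[0.5, 0.25, 0.25]] * 3,
                )
            )
            assert gold[0] == pytest.approx(1.5)
            errs.append(abs(htra(ens, 0) - gold[0]))
        assert max(errs) < 0.05
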