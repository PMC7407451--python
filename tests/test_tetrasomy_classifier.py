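"""Anchored kNN classification, cross-validated k selection, and the
rank-sum contrast between predicted inheritance classes."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rediploid as rd
from rediploid.tetrasomy_classifier import (
    DISOMIC,
    TETRASOMIC,
    _vote,
    cross_validate_k,
)


def sims(medians, species="sp", start_pk=1):
    return [
        rd.PairSimilarity(species, pk, float(m), 5, 5000)
        for pk, m in enumerate(medians, start_pk)
    ]


def rank_sum_enumeration_p(a, b):
    """Exact two-sided p by brute-force enumeration of all C(n, n_a) ways to
    assign the pooled ranks to group A (tie-free data only)."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in a)
    n = len(pooled)
    center = len(a) * (n + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), len(a)):
        total += 1
        if abs(sum(combo) - center) >= abs(observed - center) - 1e-9:
            count += 1
    return count / total


class TestAnchorSet:
    def test_order_statistic_example(self):
        panel = sims([75, 80, 85, 86, 90, 95, 96, 97, 99])
        anchors = rd.build_anchor_set(panel)
        assert {m for _, m in anchors.tetrasomic_anchors} == {99, 97, 96, 95}
        assert {m for _, m in anchors.disomic_anchors} == {75, 80, 85, 86}

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 9"):
            rd.build_anchor_set(sims(range(8)))

    def test_matches_sort_oracle_on_random_panels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            medians = rng.permutation(np.linspace(80, 99, 25))
            anchors = rd.build_anchor_set(sims(medians))
            ordered = np.sort(medians)
            assert sorted(m for _, m in anchors.disomic_anchors) == list(ordered[:4])
            assert sorted(m for _, m in anchors.tetrasomic_anchors) == list(ordered[-4:])

    def test_ties_at_cut_break_by_pk(self):
        anchors = rd.build_anchor_set(sims([90, 90, 90, 90, 90, 95, 95, 95, 95, 95]))
        assert [pk for pk, _ in anchors.disomic_anchors] == [1, 2, 3, 4]
        assert [pk for pk, _ in anchors.tetrasomic_anchors] == [6, 7, 8, 9]

    def test_inverted_anchorset_rejected(self):
        with pytest.raises(ValueError, match="dominate"):
            rd.AnchorSet(
                tetrasomic_anchors=((1, 80.0),), disomic_anchors=((2, 90.0),)
            )


class TestKnnClassify:
    def _anchors(self):
        return rd.AnchorSet(
            tetrasomic_anchors=((21, 96.0), (22, 97.0), (23, 98.0), (24, 99.0)),
            disomic_anchors=((11, 80.0), (12, 81.0), (13, 83.0), (14, 84.0)),
        )

    def test_exact_match_at_k1(self):
        anchors = self._anchors()
        [res] = [
            c
            for c in rd.knn_classify(sims([97.0], start_pk=5), anchors, k=1)
        ]
        assert (res.label, res.vote_proportion) == (TETRASOMIC, 1.0)

    def test_hand_enumerated_k5_vote(self):
        # query 97: nearest five of eight anchors are the four tetrasomic
        # (96..99) plus disomic 84 -> 4/5 tetrasomic
        anchors = self._anchors()
        [res] = rd.knn_classify(sims([97.0], start_pk=5), anchors, k=5)
        assert res.label == TETRASOMIC
        assert res.votes_for_label == 4 and res.vote_proportion == 0.8

    def test_k5_vote_proportions_limited_to_two_values(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            medians = rng.uniform(78, 100, size=25)
            panel = sims(medians)
            anchors = rd.build_anchor_set(panel)
            for c in rd.knn_classify(panel, anchors, k=5):
                if not c.label.startswith("anchor_"):
                    assert c.vote_proportion in (0.6, 0.8)

    def test_k8_all_queries_tie_to_disomic_flagged(self):
        anchors = self._anchors()
        results = rd.knn_classify(sims([90.0, 95.0], start_pk=5), anchors, k=8)
        for c in results:
            assert c.label == DISOMIC and c.tie_flagged
            assert c.vote_proportion == 0.5

    def test_anchors_reported_and_never_self_vote(self):
        anchors = self._anchors()
        panel = sims([96.0], start_pk=21)  # pk 21 is itself an anchor
        [res] = rd.knn_classify(panel, anchors, k=5)
        assert res.label == f"anchor_{TETRASOMIC}"
        # its 5 nearest among the OTHER 7 anchors: 3 tetrasomic + 2 disomic
        assert res.votes_for_label == 3 and res.vote_proportion == 0.6

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rd.knn_classify(sims([90.0], start_pk=5), self._anchors(), k=9)

    def test_distance_ties_break_by_anchor_pk(self):
        # query equidistant from tetrasomic 96 (pk 21) and disomic 84 (pk 14):
        # stable order prefers the smaller pk -> disomic anchor wins the slot
        anchors = self._anchors()
        label, votes, tie = _vote(90.0, anchors.labeled(), 1)
        assert label == DISOMIC and votes == 1 and not tie


class TestSelectK:
    def _separated(self):
        return sims(list(np.linspace(80, 84, 13)) + list(np.linspace(96, 99, 12)))

    def test_clean_separation_returns_largest_k(self):
        panel = self._separated()
        cfg = rd.CVConfig(n_repeats=5, seed=1)
        table = cross_validate_k(panel, rd.build_anchor_set(panel), cfg)
        assert np.allclose(table["accuracy"], 1.0)
        assert rd.select_k(panel, rd.build_anchor_set(panel), cfg) == 10

    def test_degenerate_identical_medians_tie_to_max_k(self):
        panel = sims([90.0] * 25)
        anchors = rd.AnchorSet(
            tetrasomic_anchors=tuple((pk, 90.0) for pk in (22, 23, 24, 25)),
            disomic_anchors=tuple((pk, 90.0) for pk in (1, 2, 3, 4)),
        )
        cfg = rd.CVConfig(n_repeats=3, seed=0)
        assert rd.select_k(panel, anchors, cfg) == 10

    def test_selection_consistent_with_reported_table(self, fast_panel):
        panel = rd.panel_pair_similarities(fast_panel)
        anchors = rd.build_anchor_set(panel)
        cfg = rd.CVConfig(n_repeats=10, seed=4)
        table = cross_validate_k(panel, anchors, cfg)
        chosen = rd.select_k(panel, anchors, cfg)
        best = table["accuracy"].max()
        assert chosen == int(table.loc[table["accuracy"] >= best - 1e-12, "k"].max())

    def test_invariant_to_input_permutation(self):
        panel = self._separated()
        anchors = rd.build_anchor_set(panel)
        cfg = rd.CVConfig(n_repeats=5, seed=9)
        rng = np.random.default_rng(0)
        shuffled = list(panel)
        rng.shuffle(shuffled)
        assert rd.select_k(panel, anchors, cfg) == rd.select_k(shuffled, anchors, cfg)

    def test_repeats_extend_without_perturbing_earlier_draws(self):
        # fold shuffles come from per-repeat substreams: the 5-repeat table is
        # a prefix average, so a clean panel gives identical accuracies
        panel = self._separated()
        anchors = rd.build_anchor_set(panel)
        t5 = cross_validate_k(panel, anchors, rd.CVConfig(n_repeats=5, seed=2))
        t9 = cross_validate_k(panel, anchors, rd.CVConfig(n_repeats=9, seed=2))
        assert np.allclose(t5["accuracy"], t9["accuracy"])

    def test_anchors_only_mode_caps_folds(self, caplog):
        panel = self._separated()
        anchors = rd.build_anchor_set(panel)
        cfg = rd.CVConfig(n_repeats=3, seed=1, mode="anchors_only")
        with caplog.at_level("WARNING"):
            k = rd.select_k(panel, anchors, cfg)
        assert 1 <= k <= 10
        assert any("reducing folds" in r.message for r in caplog.records)


class TestWilcoxon:
    def test_reference_exact_p(self):
        res = rd.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 6.0  # ranks 1+2+3

    def test_identical_groups_show_no_evidence(self):
        res = rd.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "normal_approx"  # ties force the approximation
        assert res.p_value >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rd.wilcoxon_rank_sum([], [1.0])

    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=80)
    def test_exact_branch_agrees_with_enumeration(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.choice(np.arange(100), size=n_a + n_b, replace=False).astype(float)
        a, b = list(pooled[:n_a]), list(pooled[n_a:])
        res = rd.wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(rank_sum_enumeration_p(a, b))

    def test_statistic_within_rank_sum_extremes(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=8), rng.normal(size=12)
        res = rd.wilcoxon_rank_sum(a, b)
        n_a, n = 8, 20
        assert n_a * (n_a + 1) / 2 <= res.statistic <= n_a * (2 * n - n_a + 1) / 2

    def test_detects_true_location_shift(self):
        rng = np.random.default_rng(12)
        tet = rng.normal(97.0, 1.0, size=200)
        dis = rng.normal(88.0, 1.0, size=200)
        res = rd.wilcoxon_rank_sum(tet, dis, alpha=0.01)
        assert res.method == "normal_approx"
        assert res.significant and res.p_value < 1e-10


class TestModelFrontend:
    def test_fit_classifies_and_summarizes(self, fast_panel):
        summaries = rd.panel_pair_similarities(fast_panel)
        identities = {
            p.pk: [b.identity_pct for b in rd.windowed_identity(p, 1000)]
            for p in fast_panel.pairs
        }
        model = rd.TetrasomyKNN(summaries, alignment_identities=identities)
        results = model.fit(k=5)
        assert results.k == 5
        assert len(results.classifications) == 25
        assert results.wilcoxon is not None and results.wilcoxon.significant
        text = results.summary()
        assert "k: 5" in text and "Wilcoxon" in text
        frame = results.frame()
        assert set(frame.columns) >= {"pk", "label", "vote_proportion"}

    def test_auto_k_reports_cv_table(self, fast_panel):
        summaries = rd.panel_pair_similarities(fast_panel)
        model = rd.TetrasomyKNN(summaries)
        results = model.fit(k="auto", cv=rd.CVConfig(n_repeats=5, seed=3))
        assert results.cv_table is not None and len(results.cv_table) == 10
        assert results.k in range(1, 11)

    def test_from_dataframe(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"pk": range(1, 26), "weighted_median": np.linspace(80, 99, 25)}
        )
        model = rd.TetrasomyKNN.from_dataframe(frame, species="sp")
        results = model.fit(k=5)
        assert results.tetrasomic_pks()[-1] == 25
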