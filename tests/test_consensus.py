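"""Consensus engines: DM / FDM / MOFD agreement, thresholds, retention."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fuzzydelphi.consensus import (
    MethodConfig,
    apply_threshold,
    compare_methods,
    dm_consensus,
    evaluate_round,
    fdm_agreement,
    mofd_agreement,
    next_round_items,
    retained_set,
    suggest_threshold,
)
from fuzzydelphi.survey_io import Expert, Panel, ResponseRecord, build_round_dataset

FDM = MethodConfig(method="fdm")
MOFD = MethodConfig(method="mofd")


def mofd_oracle(ratings, weights, beta=0.5, gamma=0.5):
    """Straight-line recomputation of the MOFD agreement from raw formulas.

    Deliberately independent of the package's fuzzy-number types: plain
    tuples and floats only.
    """
    scale = {
        1: (0.00, 0.00, 0.25),
        2: (0.00, 0.25, 0.50),
        3: (0.25, 0.50, 0.75),
        4: (0.50, 0.75, 1.00),
        5: (0.75, 1.00, 1.00),
    }
    tfns = [scale[r] for r in ratings]
    g = tuple(sum(w * t[i] for w, t in zip(weights, tfns)) for i in range(3))
    total = 0.0
    for w, t in zip(weights, tfns):
        sim = 1.0 - (abs(t[0] - g[0]) + abs(t[1] - g[1]) + abs(t[2] - g[2])) / 3.0
        ham = 0.25 * abs(t[0] - g[0]) + 0.5 * abs(t[1] - g[1]) + 0.25 * abs(t[2] - g[2])
        inf = max(0.0, max(t[0], g[0]) - min(t[2], g[2]))
        c = beta * sim + (1.0 - beta) * (1.0 - (gamma * ham + (1.0 - gamma) * inf))
        total += w * c
    return 100.0 * total


class TestDM:
    def test_unanimous_agreement(self):
        r = dm_consensus("x", [5, 5, 5], [1 / 3] * 3)
        assert r.agreement == pytest.approx(100.0)
        assert r.accepted

    def test_tie_at_threshold_rejected(self):
        r = dm_consensus("x", [5, 5, 4, 2], [0.25] * 4, threshold=75.0)
        assert r.agreement == pytest.approx(75.0)
        assert not r.accepted  # strict >

    def test_unanimous_disagreement(self):
        r = dm_consensus("x", [1, 1, 1, 1], [0.25] * 4)
        assert r.agreement == 0.0
        assert not r.accepted

    def test_reports_median_iqr(self):
        r = dm_consensus("x", [1, 2, 3, 4, 5], [0.2] * 5)
        assert r.median == 3.0
        assert r.iqr == 2.0

    def test_single_expert_rejected(self):
        with pytest.raises(ValueError):
            dm_consensus("x", [5], [1.0])


class TestFDM:
    @pytest.mark.parametrize("level", [1, 2, 3, 4, 5])
    def test_unanimity_gives_full_agreement(self, level):
        r = fdm_agreement("x", [level] * 4, [0.1, 0.2, 0.3, 0.4], FDM)
        assert r.agreement == pytest.approx(100.0)

    def test_polarized_pair_no_agreement(self):
        # each expert sits 0.4208 from the midpoint group opinion, > delta
        r = fdm_agreement("x", [1, 5], [0.5, 0.5], FDM)
        assert r.agreement == 0.0
        assert r.mean_distance == pytest.approx(0.4208, abs=5e-5)

    def test_dominant_consistent_expert(self):
        r = fdm_agreement("x", [4, 1], [0.9, 0.1], FDM)
        assert r.agreement >= 90.0


class TestMOFD:
    @pytest.mark.parametrize("level", [1, 2, 3, 4, 5])
    def test_unanimity_gives_full_agreement(self, level):
        r = mofd_agreement("x", [level] * 3, [0.2, 0.3, 0.5], MOFD)
        assert r.agreement == pytest.approx(100.0)

    def test_polarized_pair_value(self):
        # frozen from the straight-line oracle
        r = mofd_agreement("x", [1, 5], [0.5, 0.5], MOFD)
        assert r.agreement == pytest.approx(65.1042, abs=1e-3)
        assert r.agreement == pytest.approx(mofd_oracle([1, 5], [0.5, 0.5]), abs=1e-9)

    def test_beta_one_reduces_to_similarity(self):
        cfg = MethodConfig(method="mofd", beta=1.0)
        r = mofd_agreement("x", [2, 4, 5], [0.3, 0.3, 0.4], cfg)
        assert r.agreement == pytest.approx(
            mofd_oracle([2, 4, 5], [0.3, 0.3, 0.4], beta=1.0), abs=1e-9
        )

    @given(
        ratings=st.lists(st.integers(1, 5), min_size=2, max_size=4),
        years=st.lists(st.integers(3, 11), min_size=4, max_size=4),
    )
    def test_matches_oracle_on_random_panels(self, ratings, years):
        w = np.array(years[: len(ratings)], dtype=float)
        w /= w.sum()
        r = mofd_agreement("x", ratings, w, MOFD)
        assert r.agreement == pytest.approx(mofd_oracle(ratings, w), abs=1e-9)

    @given(
        ratings=st.lists(st.integers(1, 5), min_size=3, max_size=8),
        idx=st.integers(0, 7),
    )
    def test_moving_toward_panel_mean_never_decreases_agreement(self, ratings, idx):
        """One Likert step toward the panel's mean rating cannot lower consensus."""
        idx %= len(ratings)
        mean = float(np.mean(ratings))
        old = ratings[idx]
        if abs(old - mean) < 1:
            return
        closer = old + (1 if mean > old else -1)
        w = [1.0 / len(ratings)] * len(ratings)
        before = mofd_agreement("x", ratings, w, MOFD).agreement
        moved = list(ratings)
        moved[idx] = closer
        after = mofd_agreement("x", moved, w, MOFD).agreement
        assert after >= before - 1e-9

    @given(
        ratings=st.lists(st.integers(1, 5), min_size=2, max_size=6),
        seed=st.integers(0, 10_000),
    )
    def test_agreement_in_range_and_permutation_invariant(self, ratings, seed):
        rng = np.random.default_rng(seed)
        w = rng.random(len(ratings)) + 0.1
        w /= w.sum()
        r = mofd_agreement("x", ratings, w, MOFD)
        assert 0.0 <= r.agreement <= 100.0 + 1e-9
        perm = rng.permutation(len(ratings))
        r2 = mofd_agreement("x", [ratings[i] for i in perm], w[perm], MOFD)
        assert r.agreement == pytest.approx(r2.agreement, abs=1e-9)


class TestThresholding:
    def test_round1_counts_from_published_tables(self, round1_table, catalog):
        fdm = apply_threshold(round1_table["fdm_consensus"].to_dict(), 64, catalog)
        mofd = apply_threshold(round1_table["mofd_consensus"].to_dict(), 53, catalog)
        assert len(fdm) == 16
        assert len(mofd) == 12

    def test_round2_counts_from_published_tables(self, round2_table, catalog):
        fdm = apply_threshold(round2_table["fdm_consensus"].to_dict(), 70, catalog)
        mofd = apply_threshold(round2_table["mofd_consensus"].to_dict(), 56, catalog)
        assert len(fdm) == 5
        assert len(mofd) == 8

    def test_all_below_threshold(self):
        assert apply_threshold({"a": 10.0, "b": 20.0}, 50) == []

    def test_strictness_at_boundary(self):
        assert apply_threshold({"a": 64.0, "b": 64.001}, 64) == ["b"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            apply_threshold({"a": 50.0}, 120)

    def test_suggest_threshold_is_rounded_median(self):
        assert suggest_threshold([10.0, 20.0, 30.6]) == 20.0
        assert suggest_threshold([10.0, 20.6, 30.0, 40.0]) == 25.0


class TestRetention:
    def test_carried_forward_matches_second_round_items(
        self, round1_table, round2_table, catalog
    ):
        mofd1 = apply_threshold(round1_table["mofd_consensus"].to_dict(), 53, catalog)
        carried = [i for i in catalog.indicator_ids() if i not in mofd1]
        assert len(carried) == 17
        assert set(carried) == set(round2_table.index)

    def test_retained_unions(self, round1_table, round2_table, catalog):
        fdm = retained_set(
            [
                apply_threshold(round1_table["fdm_consensus"].to_dict(), 64, catalog),
                apply_threshold(round2_table["fdm_consensus"].to_dict(), 70, catalog),
            ]
        )
        mofd = retained_set(
            [
                apply_threshold(round1_table["mofd_consensus"].to_dict(), 53, catalog),
                apply_threshold(round2_table["mofd_consensus"].to_dict(), 56, catalog),
            ]
        )
        assert len(fdm) == 21
        assert len(mofd) == 20
        assert len(compare_methods(fdm, mofd, catalog).common) == 18

    def test_single_round(self):
        assert retained_set([["a", "b"]]) == ["a", "b"]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="more than one round"):
            retained_set([["a", "b"], ["b", "c"]])

    def test_compare_identical_and_disjoint(self):
        same = compare_methods(["a", "b"], ["a", "b"])
        assert same.common == ["a", "b"] and not same.only_a and not same.only_b
        disjoint = compare_methods(["a"], ["b"])
        assert disjoint.common == []


class TestEvaluateRound:
    def make_study(self, ratings_by_item):
        experts = tuple(
            Expert(f"e{i}", "s", 3 + i) for i in range(len(next(iter(ratings_by_item.values()))))
        )
        panel = Panel(experts)
        records = [
            ResponseRecord(1, f"e{i}", item, r)
            for item, rs in ratings_by_item.items()
            for i, r in enumerate(rs)
        ]
        return panel, records

    def test_accepted_and_carried_partition(self):
        # "a" is unanimous; "b" and "c" are dispersed panels below the bar
        panel, records = self.make_study({"a": [5, 5, 5], "b": [1, 3, 5], "c": [1, 2, 5]})
        ds = build_round_dataset(records, panel, 1, ["a", "b", "c"])
        cfg = MethodConfig(method="mofd", thresholds={1: 90.0})
        out = evaluate_round(ds, panel.weights(), cfg)
        assert out.accepted == ["a"]
        assert next_round_items(out) == ["b", "c"]
        assert set(out.accepted) | set(out.carried_forward) == {"a", "b", "c"}
        assert not set(out.accepted) & set(out.carried_forward)

    def test_all_accepted_converges(self):
        panel, records = self.make_study({"a": [5, 5, 5], "b": [5, 5, 5]})
        ds = build_round_dataset(records, panel, 1, ["a", "b"])
        cfg = MethodConfig(method="fdm", thresholds={1: 50.0})
        out = evaluate_round(ds, panel.weights(), cfg)
        assert next_round_items(out) == []

    def test_median_threshold_fallback_used(self):
        panel, records = self.make_study({"a": [5, 5, 5], "b": [1, 3, 5], "c": [1, 1, 2]})
        ds = build_round_dataset(records, panel, 1, ["a", "b", "c"])
        out = evaluate_round(ds, panel.weights(), MethodConfig(method="mofd"))
        agreements = [r.agreement for r in out.results.values()]
        assert out.threshold == suggest_threshold(agreements)


class TestOracleGridSample:
    def test_four_expert_grid_subsample(self):
        """Spot-check the brute-force equivalence on a structured subgrid."""
        w = np.array([3, 5, 7, 11], dtype=float)
        w /= w.sum()
        for combo in itertools.product([1, 3, 5], repeat=4):
            got = mofd_agreement("x", combo, w, MOFD).agreement
            assert got == pytest.approx(mofd_oracle(combo, w), abs=1e-9)
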