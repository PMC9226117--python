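"""Timeline, sorting, swap-error and generalization-bias analyses."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from seqrsa.behavior import (
    accuracy_metrics,
    assign_sorted_groups,
    brain_behavior_correlation,
    chi_square_uniformity,
    generalization_bias,
    generalization_predictor,
    swap_error_test,
    timeline_regression,
    TimelineModel,
)
from seqrsa.exceptions import DegeneratePredictorError, DesignValidationError
from seqrsa.simulate import SimulationConfig, simulate_behavior, simulate_dataset


def _perfect_behavior(design, n_subjects=1):
    ev = design.events.sort_values("event_id")
    return pd.concat([
        pd.DataFrame({
            "subject_id": s,
            "event_id": ev.event_id,
            "remembered_time": ev.virtual_time,
            "sorted_group": ev.sequence_id,
        })
        for s in range(1, n_subjects + 1)
    ], ignore_index=True)


class TestTimeline:
    def test_perfect_responses_hit_permutation_cap(self, design):
        res = timeline_regression(_perfect_behavior(design, 2), design,
                                  n_perm=100, seed=0, n_flips=200)
        subj = res.subject_results[1]
        # perfect fit: the observed t tops every shuffle, Z at the n_perm cap
        assert subj.pvalues_right["virtual_time"] == pytest.approx(1 / 101)
        assert subj.zvalues["virtual_time"] == pytest.approx(2.33, abs=0.01)

    def test_model_object_equivalent(self, design):
        beh = _perfect_behavior(design, 2)
        a = TimelineModel(beh, design).fit(n_perm=100, seed=4, n_flips=200)
        b = timeline_regression(beh, design, n_perm=100, seed=4, n_flips=200)
        assert a.subject_z.equals(b.subject_z)

    def test_too_few_distinct_responses(self, design):
        beh = _perfect_behavior(design)
        beh["remembered_time"] = 12.0
        beh.loc[:1, "remembered_time"] = [6.0, 7.0]
        with pytest.raises(DegeneratePredictorError):
            timeline_regression(beh, design, n_perm=100, seed=0)


class TestAccuracy:
    def test_perfect_is_zero(self, design):
        acc = accuracy_metrics(_perfect_behavior(design), design)
        assert acc["per_subject"]["mae"].iloc[0] == 0.0

    def test_single_error_arithmetic(self, design):
        beh = _perfect_behavior(design)
        beh.loc[beh.event_id == 7, "remembered_time"] += 2.0
        acc = accuracy_metrics(beh, design)
        assert acc["per_subject"]["mae"].iloc[0] == pytest.approx(0.1)  # 2/20

    def test_sequence_relabel_invariance(self, design):
        beh = _perfect_behavior(design)
        beh["remembered_time"] += np.linspace(-1, 1, 20)
        base = accuracy_metrics(beh, design)["per_subject"]["mae"].iloc[0]
        relabeled = design.events.copy()
        relabeled["sequence_id"] = relabeled["sequence_id"].map({1: 3, 2: 1, 3: 4, 4: 2})
        from seqrsa.design import ExperimentDesign

        again = accuracy_metrics(beh, ExperimentDesign(relabeled))["per_subject"]["mae"].iloc[0]
        assert base == pytest.approx(again)


class TestSorting:
    def test_perfect_sorting(self, design):
        labels = design.events.set_index("event_id")["sequence_id"]
        res = assign_sorted_groups(labels, design)
        assert res["percent_correct"] == 100.0
        assert res["n_errors"] == 0

    def test_swapped_pair_is_90_percent(self, design):
        ev = design.events.set_index("event_id")
        labels = ev["sequence_id"].copy()
        e1 = ev[(ev.sequence_id == 1) & (ev.position == 3)].index[0]
        e2 = ev[(ev.sequence_id == 2) & (ev.position == 3)].index[0]
        labels[e1], labels[e2] = 2, 1
        res = assign_sorted_groups(labels, design)
        assert res["percent_correct"] == pytest.approx(90.0)

    def test_group_relabeling_is_recovered(self, design):
        # arbitrary group names still map optimally back to sequences
        labels = design.events.set_index("event_id")["sequence_id"].map(
            {1: 40, 2: 10, 3: 30, 4: 20}
        )
        res = assign_sorted_groups(labels, design)
        assert res["percent_correct"] == 100.0

    def test_matches_brute_force_over_mappings(self, design, rng):
        ev = design.events.set_index("event_id")
        truth = ev["sequence_id"].to_numpy()
        for _ in range(50):
            labels = pd.Series(rng.integers(1, 5, size=20), index=ev.index)
            if labels.nunique() != 4:
                continue
            res = assign_sorted_groups(labels, design)
            groups = sorted(labels.unique())
            best = max(
                sum(
                    mapping[groups.index(g)] == s
                    for g, s in zip(labels.to_numpy(), truth)
                )
                for mapping in permutations(range(1, 5))
            )
            assert res["percent_correct"] == pytest.approx(100 * best / 20)

    def test_wrong_group_count_rejected(self, design):
        labels = design.events.set_index("event_id")["sequence_id"].copy()
        labels[:] = 1
        with pytest.raises(DesignValidationError):
            assign_sorted_groups(labels, design)


class TestSwapErrors:
    def _sample(self, design, n_subjects, swap_pairs=0, random_moves=0, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        ev = design.events.set_index("event_id")
        for s in range(1, n_subjects + 1):
            labels = ev["sequence_id"].copy()
            for _ in range(swap_pairs):
                s1, s2 = rng.choice(4, 2, replace=False) + 1
                p = rng.integers(1, 6)
                e1 = ev[(ev.sequence_id == s1) & (ev.position == p)].index[0]
                e2 = ev[(ev.sequence_id == s2) & (ev.position == p)].index[0]
                labels[e1], labels[e2] = labels[e2], labels[e1]
            for _ in range(random_moves):
                e = ev.index[rng.integers(20)]
                wrong = [g for g in (1, 2, 3, 4) if g != labels[e]]
                labels[e] = wrong[rng.integers(3)]
            frames.append(pd.DataFrame({
                "subject_id": s, "event_id": ev.index,
                "remembered_time": ev.virtual_time, "sorted_group": labels.to_numpy(),
            }))
        return pd.concat(frames, ignore_index=True)

    def test_all_swaps_give_proportion_one(self, design):
        beh = self._sample(design, 6, swap_pairs=1)
        res = swap_error_test(beh, design, n_iter=300, seed=1)
        assert res["observed_proportion"] == 1.0
        assert res["z"] > 2.0

    def test_zero_errors_undefined(self, design):
        beh = self._sample(design, 4)
        res = swap_error_test(beh, design, n_iter=100, seed=1)
        assert res["undefined"]
        assert np.isnan(res["z"])

    def test_surrogate_matches_single_move_enumeration(self, design):
        # one random move per subject: the chance that a lone misplacement
        # forms a mutual swap is zero, so the null mean must be ~0
        beh = self._sample(design, 10, random_moves=1, seed=3)
        res = swap_error_test(beh, design, n_iter=500, seed=2)
        assert res["null_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_null_mean_matches_enumeration_two_moves(self, design):
        # two moved events can swap only if they are the reciprocal pair:
        # P = P(second event is the same-position event of the group the
        # first was moved into, and it moves into the first's sequence)
        beh = self._sample(design, 200, random_moves=2, seed=5)
        res = swap_error_test(beh, design, n_iter=400, seed=6)
        p_pair = (1 / 19) * (1 / 3) * 2 / 2  # see derivation in comment
        # expected proportion = 2 * P(pair swaps) * 2 events / 2 errors
        assert res["null_mean"] == pytest.approx(p_pair, abs=0.01)

    def test_monotone_in_swap_count(self, design):
        # adding one more mutual swap never lowers the observed proportion
        low = self._sample(design, 8, swap_pairs=1, random_moves=1, seed=7)
        ev = design.events.set_index("event_id")
        high = low.copy()
        sub1 = high.subject_id == 1
        labels = high.loc[sub1].set_index("event_id")["sorted_group"]
        for p in range(1, 6):
            e1 = ev[(ev.sequence_id == 3) & (ev.position == p)].index[0]
            e2 = ev[(ev.sequence_id == 4) & (ev.position == p)].index[0]
            if labels[e1] == 3 and labels[e2] == 4:  # untouched pair
                labels[e1], labels[e2] = 4, 3
                break
        high.loc[sub1, "sorted_group"] = labels.to_numpy()
        r_low = swap_error_test(low, design, n_iter=100, seed=8)
        r_high = swap_error_test(high, design, n_iter=100, seed=8)
        assert r_high["observed_proportion"] >= r_low["observed_proportion"]

    def test_surrogate_proportions_in_unit_interval(self, design):
        beh = self._sample(design, 6, swap_pairs=1, random_moves=1, seed=9)
        res = swap_error_test(beh, design, n_iter=300, seed=10)
        assert 0.0 <= res["null_mean"] <= 1.0
        assert 0.0 < res["p"] <= 1.0


class TestChiSquare:
    def test_uniform_counts(self):
        res = chi_square_uniformity([4, 4, 4, 4, 4])
        assert res["chi2"] == 0.0
        assert res["p"] == 1.0

    def test_concentrated_counts_hand_value(self):
        # 20 errors in one of five cells, expected 4 per cell: chi2 = 80
        res = chi_square_uniformity([20, 0, 0, 0, 0])
        assert res["chi2"] == pytest.approx(80.0)
        assert res["df"] == 4

    def test_permutation_invariance(self):
        a = chi_square_uniformity([7, 1, 0, 3, 2])
        b = chi_square_uniformity([2, 3, 0, 1, 7])
        assert a["chi2"] == pytest.approx(b["chi2"])

    def test_zero_total_undefined(self):
        assert chi_square_uniformity([0, 0, 0, 0, 0])["undefined"]


class TestGeneralizationBias:
    def test_other_mean_time_arithmetic(self, grid_design):
        pred = generalization_predictor(grid_design)
        # position-1 events sit at 7.0, 7.25, 7.5, 7.75 across sequences
        row = pred[pred.event_id == 1].iloc[0]
        assert row.other_mean_time == pytest.approx((7.25 + 7.5 + 7.75) / 3)
        assert row.deviation == pytest.approx(row.other_mean_time - 7.0)

    def test_slope_invariant_to_constant_shift(self, design):
        cfg = SimulationConfig(gamma_bias=0.4, behavior_noise_sd=0.3)
        beh = pd.concat([
            simulate_behavior(design, cfg, seed=3, subject_id=1),
            simulate_behavior(design, cfg, seed=4, subject_id=2),
        ], ignore_index=True)
        r1 = generalization_bias(beh, design, n_perm=150, seed=1, n_flips=200)
        shifted = beh.copy()
        shifted["remembered_time"] += 1.5
        r2 = generalization_bias(shifted, design, n_perm=150, seed=1, n_flips=200)
        assert r2.subject_coef.iloc[0] == pytest.approx(r1.subject_coef.iloc[0])

    def test_degenerate_identical_sequences(self):
        import pandas as pd

        from seqrsa.design import ExperimentDesign
        from seqrsa.behavior import generalization_bias as gb

        rows = []
        eid = 1
        for s in range(4):
            for p in range(5):
                rows.append({
                    "event_id": eid, "sequence_id": s + 1, "position": p + 1,
                    "virtual_time": 7.0 + 3.0 * p, "real_time": 10.0 * p + 1e-6 * s * 0,
                })
                eid += 1
        # identical times across sequences: deviation predictor is all zero
        design = ExperimentDesign(pd.DataFrame(rows))
        beh = _perfect_behavior(design)
        with pytest.raises(DegeneratePredictorError):
            gb(beh, design, n_perm=100, seed=0)


class TestBrainBehavior:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert brain_behavior_correlation(x, x ** 3)["rho"] == pytest.approx(1.0)
        assert brain_behavior_correlation(x, -x)["rho"] == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) on a 5-point toy without ties
        x = np.array([3.0, 1, 4, 2, 5])
        y = np.array([2.0, 1, 5, 3, 4])
        rx = x.argsort().argsort() + 1
        ry = y.argsort().argsort() + 1
        rho_hand = 1 - 6 * ((rx - ry) ** 2).sum() / (5 * 24)
        assert brain_behavior_correlation(x, y)["rho"] == pytest.approx(rho_hand)

    def test_constant_vector_flag(self):
        assert brain_behavior_correlation(np.ones(6), np.arange(6.0))["undefined"]

    def test_short_input_rejected(self):
        with pytest.raises(DesignValidationError):
            brain_behavior_correlation(np.arange(4.0), np.arange(4.0))
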