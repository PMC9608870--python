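"""Critical-region selection, regional activity, and Spearman correlation."""

import numpy as np
import pandas as pd
import pytest

from cortexlrp.preprocess import WindowedTrialSet
from cortexlrp.stats import (
    build_correlation_table,
    region_activity,
    spearman,
    top_fraction_mask,
)
from cortexlrp.synthdata import CLINICAL_SCORES, ClinicalTable


def make_windowed(data, subject_id, group=None):
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if group is None:
        group = np.array(["patient"] * n)
    return WindowedTrialSet(
        data=data,
        subject_id=np.asarray(subject_id),
        group=np.asarray(group, dtype=str),
        rejected_trials=np.empty(0, dtype=int),
        window_ms=(150.0, 250.0),
    )


class TestTopFractionMask:
    def test_three_percent_of_100_is_3(self, rng):
        crs = top_fraction_mask(rng.normal(size=100), 0.03)
        assert len(crs.selected) == 3

    def test_fraction_one_selects_everything(self, rng):
        crs = top_fraction_mask(rng.normal(size=57), 1.0)
        assert len(crs.selected) == 57

    def test_descending_relevance_selects_largest(self):
        relevance = np.arange(10, 0, -1, dtype=float)  # 10, 9, ..., 1
        crs = top_fraction_mask(relevance, 0.2)
        assert sorted(crs.selected) == [0, 1]

    def test_ties_at_cutoff_broken_by_vertex_id(self):
        relevance = np.array([1.0, 5.0, 5.0, 5.0, 0.0])
        crs = top_fraction_mask(relevance, 0.4)
        assert sorted(crs.selected) == [1, 2]

    def test_all_equal_relevance_warns(self):
        with pytest.warns(UserWarning, match="equal"):
            crs = top_fraction_mask(np.ones(10), 0.2)
        assert sorted(crs.selected) == [0, 1]

    @pytest.mark.parametrize("n", [10, 33, 100, 1234])
    @pytest.mark.parametrize("fraction", [0.01, 0.03, 0.5, 1.0])
    def test_selection_size_is_rounded_fraction(self, n, fraction, rng):
        crs = top_fraction_mask(rng.normal(size=n), fraction)
        assert len(crs.selected) == int(np.floor(fraction * n + 0.5))

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            top_fraction_mask(rng.normal(size=10), 0.0)


class TestRegionActivity:
    def test_constant_data_gives_constant_activity(self):
        w = make_windowed(np.full((4, 6), 2.5), [0, 0, 1, 1])
        act = region_activity(w, np.array([True] * 6))
        assert np.allclose(act.to_numpy(), 2.5)

    def test_trial_means_averaged_per_subject(self):
        data = np.zeros((2, 4))
        data[0, :2] = 1.0  # region mean 1
        data[1, :2] = 3.0  # region mean 3
        w = make_windowed(data, [7, 7])
        act = region_activity(w, np.array([True, True, False, False]))
        assert act.loc[7] == pytest.approx(2.0)

    def test_hand_case_two_subjects(self):
        # 2 subjects x 2 trials x 2 masked vertices, explicit averaging
        data = np.array(
            [[1.0, 2.0, 9.0], [3.0, 4.0, 9.0], [10.0, 20.0, 9.0], [30.0, 40.0, 9.0]]
        )
        w = make_windowed(data, [0, 0, 1, 1])
        act = region_activity(w, np.array([True, True, False]))
        assert act.loc[0] == pytest.approx((1 + 2 + 3 + 4) / 4)
        assert act.loc[1] == pytest.approx((10 + 20 + 30 + 40) / 4)

    def test_empty_mask_rejected(self):
        w = make_windowed(np.ones((2, 3)), [0, 1])
        with pytest.raises(ValueError):
            region_activity(w, np.zeros(3, dtype=bool))


class TestSpearman:
    def test_monotone_sequences_give_plus_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        rho, p, n = spearman(x, np.exp(x))
        assert (rho, p, n) == (1.0, 0.0, 5)
        rho, p, _ = spearman(x, -(x**3))
        assert (rho, p) == (-1.0, 0.0)

    def test_worked_five_point_example(self):
        # d = (1, -1, 1, -1, 0): rho = 1 - 6*4/(5*24) = 0.8
        rho, p, n = spearman(np.arange(1, 6), np.array([2, 1, 4, 3, 5]))
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_invariant_under_strictly_monotone_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho0, _, _ = spearman(x, y)
        rho1, _, _ = spearman(np.exp(x), y)
        rho2, _, _ = spearman(x, 3.0 * y - 7.0)
        assert rho0 == pytest.approx(rho1) == pytest.approx(rho2)

    def test_ties_use_midranks(self):
        rho, _, _ = spearman(np.array([1.0, 1.0, 2.0, 3.0]), np.array([1.0, 1.0, 2.0, 3.0]))
        assert rho == pytest.approx(1.0)

    def test_zero_variance_flagged_as_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rho, p, _ = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestBuildCorrelationTable:
    def make_clinical(self, scores_by_subject):
        rows = []
        for sid, overrides in scores_by_subject.items():
            row = {"subject_id": sid, **{s: 10.0 for s in CLINICAL_SCORES}}
            row.update(overrides)
            rows.append(row)
        return ClinicalTable(pd.DataFrame(rows, columns=["subject_id", *CLINICAL_SCORES]))

    def test_table_shape_is_regions_by_seven_scores(self, rng):
        activities = {
            f"left region_{i}": pd.Series(rng.normal(size=5), index=range(5)) for i in range(6)
        }
        clinical = self.make_clinical(
            {s: {"PSQI": float(rng.normal())} for s in range(5)}
        )
        table = build_correlation_table(activities, clinical)
        assert table.rho.shape == (6, 7)

    def test_perfect_coupling_recovered_and_flagged(self, rng):
        activity = pd.Series(rng.normal(size=8), index=range(8))
        clinical = self.make_clinical(
            {s: {"PSQI": 2.0 * activity.loc[s] + 5.0} for s in range(8)}
        )
        table = build_correlation_table({"left insular": activity}, clinical)
        assert table.rho.loc["left insular", "PSQI"] == pytest.approx(1.0)
        assert bool(table.flagged.loc["left insular", "PSQI"])

    def test_negative_coupling_has_negative_sign(self, rng):
        activity = pd.Series(rng.normal(size=8), index=range(8))
        clinical = self.make_clinical(
            {s: {"ESS": -3.0 * activity.loc[s]} for s in range(8)}
        )
        table = build_correlation_table({"right superior_temporal": activity}, clinical)
        assert table.rho.loc["right superior_temporal", "ESS"] == pytest.approx(-1.0)

    def test_uncoupled_noise_rarely_flagged(self, rng):
        # permutation-style sanity check: independent scores should mostly
        # produce non-significant cells
        flags = []
        for _ in range(20):
            activity = pd.Series(rng.normal(size=9), index=range(9))
            clinical = self.make_clinical(
                {s: {sc: float(rng.normal()) for sc in CLINICAL_SCORES} for s in range(9)}
            )
            table = build_correlation_table({"left insular": activity}, clinical)
            flags.append(table.flagged.to_numpy().mean())
        assert np.mean(flags) < 0.3

    def test_fewer_than_three_patients_rejected(self, rng):
        activity = pd.Series([1.0, 2.0], index=[0, 1])
        clinical = self.make_clinical({0: {}, 1: {}})
        with pytest.raises(ValueError):
            build_correlation_table({"left insular": activity}, clinical)
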