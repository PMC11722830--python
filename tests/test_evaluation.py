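import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

from liftzones.evaluation import (
    TrialRecord,
    agreement_grid,
    confusion_counts,
    f_score,
    mean_error,
    metrics,
    vh_band_accuracy,
    zone12_accuracy,
)
from liftzones.zoning import RISK_LEVELS


def balanced_records(predict, n_subjects=10, reps=3):
    """Full 12-zone design with predictions given by ``predict(subject,
    zone, rep) -> predicted zone``."""
    return [
        TrialRecord(subject=f"S{s:02d}", repetition=r, true_zone=z,
                    predicted_zone=predict(s, z, r))
        for s in range(1, n_subjects + 1)
        for z in range(1, 13)
        for r in range(1, reps + 1)
    ]


class TestAgreementGrid:
    def test_perfect_agreement(self):
        grid = agreement_grid(balanced_records(lambda s, z, r: z))
        assert (grid.counts.to_numpy() == 3).all()
        assert grid.total_matches == 360

    def test_no_agreement(self):
        grid = agreement_grid(balanced_records(lambda s, z, r: z % 12 + 1))
        assert (grid.counts.to_numpy() == 0).all()

    def test_grid_total_consistent_with_accuracy(self):
        # each subject gets rep 1 right only
        records = balanced_records(lambda s, z, r: z if r == 1 else z % 12 + 1)
        grid = agreement_grid(records)
        assert grid.total_matches == 120
        assert zone12_accuracy(records) == pytest.approx(120 / 360)

    def test_more_than_three_reps_rejected(self):
        records = [
            TrialRecord(subject="S01", repetition=r, true_zone=1, predicted_zone=1)
            for r in (1, 2, 3, 1)
        ]
        with pytest.raises(ValueError, match="repetitions"):
            agreement_grid(records)


class TestZone12Accuracy:
    @pytest.mark.parametrize("matches, pct", [(15, 4), (78, 22), (360, 100)])
    def test_reported_percentages(self, matches, pct):
        records = balanced_records(
            lambda s, z, r: z if (s - 1) * 36 + (z - 1) * 3 + r <= matches else z % 12 + 1
        )
        # construction: exactly `matches` of the 360 trials agree
        assert sum(r.true_zone == r.predicted_zone for r in records) == matches
        assert round(100 * zone12_accuracy(records)) == pct

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zone12_accuracy([])


class TestVhBandAccuracy:
    def test_all_correct(self):
        v, h = vh_band_accuracy(balanced_records(lambda s, z, r: z))
        assert (v, h) == (1.0, 1.0)

    def test_v_right_h_off_by_one_band(self):
        def shift_h(s, z, r):  # same V band, neighbouring H band
            h_band = (z - 1) % 3 + 1
            return z + 1 if h_band < 3 else z - 1

        v, h = vh_band_accuracy(balanced_records(shift_h))
        assert (v, h) == (1.0, 0.0)

    def test_constructed_mixed_rates(self):
        # V correct on 61% of trials, H on 34%, via deterministic assignment
        records = []
        k = 0
        for s in range(1, 11):
            for z in (5,) * 10:  # V2,H2 reference
                k += 1
                v_ok = k <= 61
                h_ok = k <= 34
                pred_v_band = 2 if v_ok else 3
                pred_h_band = 2 if h_ok else 1
                records.append(
                    TrialRecord(subject=f"S{s:02d}", repetition=(k - 1) % 3 + 1,
                                true_zone=z,
                                predicted_zone=3 * (pred_v_band - 1) + pred_h_band)
                )
        v, h = vh_band_accuracy(records)
        assert round(100 * v) == 61
        assert round(100 * h) == 34


class TestConfusionCounts:
    def test_diagonal_only(self):
        counts = confusion_counts(balanced_records(lambda s, z, r: z))
        off_diag = counts.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag == 0).all()

    def test_single_cross_classification(self):
        records = [TrialRecord(subject="S01", repetition=1, true_zone=4,
                               predicted_zone=12)]
        counts = confusion_counts(records)
        assert counts.loc["low", "high"] == 1
        assert counts.to_numpy().sum() == 1

    def test_full_design_row_totals(self):
        # brute-force tally oracle on a design with known mispredictions
        rng = np.random.default_rng(11)
        preds = {}

        def predict(s, z, r):
            preds[(s, z, r)] = int(rng.integers(1, 13))
            return preds[(s, z, r)]

        records = balanced_records(predict)
        counts = confusion_counts(records)
        assert counts.sum(axis=1).tolist() == [60, 120, 180]
        # independent tally
        from liftzones.zoning import DEFAULT_GROUPING
        tally = {(a, b): 0 for a in RISK_LEVELS for b in RISK_LEVELS}
        for rec in records:
            tally[(DEFAULT_GROUPING[rec.true_zone], DEFAULT_GROUPING[rec.predicted_zone])] += 1
        for a in RISK_LEVELS:
            for b in RISK_LEVELS:
                assert counts.loc[a, b] == tally[(a, b)]


class TestMetrics:
    def test_harmonic_mean_worked_examples(self):
        assert round(f_score(0.22, 0.07), 2) == 0.11
        assert round(f_score(0.86, 0.51), 2) == 0.64
        assert f_score(0.0, 0.0) == 0.0

    def test_identity_counts_are_perfect(self):
        counts = pd.DataFrame(np.diag([60, 120, 180]), index=list(RISK_LEVELS),
                              columns=list(RISK_LEVELS))
        m = metrics(counts)
        assert (m.precision == 1.0).all()
        assert (m.recall == 1.0).all()
        assert (m.f_score == 1.0).all()
        assert m.macro_recall == m.weighted_recall == 1.0

    def test_precision_from_raw_counts(self):
        # 7 correct low predictions of 31 low calls; 51 of 59 in a second case
        counts = pd.DataFrame(
            [[7, 50, 3], [10, 40, 70], [14, 30, 136]],
            index=list(RISK_LEVELS), columns=list(RISK_LEVELS),
        )
        # 7/31 = 0.2258, printed as 0.22 (truncated at 2 decimals)
        assert metrics(counts).precision["low"] == pytest.approx(7 / 31)
        assert metrics(counts).precision["low"] == pytest.approx(0.22, abs=0.01)
        counts2 = pd.DataFrame(
            [[51, 9, 0], [5, 54, 61], [3, 9, 168]],
            index=list(RISK_LEVELS), columns=list(RISK_LEVELS),
        )
        assert metrics(counts2).precision["low"] == pytest.approx(51 / 59)
        assert round(metrics(counts2).precision["low"], 2) == 0.86

    def test_row_rates_sum_to_one(self):
        counts = pd.DataFrame(
            [[4, 53, 3], [4, 40, 76], [40, 50, 90]],
            index=list(RISK_LEVELS), columns=list(RISK_LEVELS),
        )
        m = metrics(counts)
        np.testing.assert_allclose(m.row_rates.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_column_flagged_not_crashed(self):
        counts = pd.DataFrame(
            [[0, 30, 30], [0, 60, 60], [0, 90, 90]],
            index=list(RISK_LEVELS), columns=list(RISK_LEVELS),
        )
        m = metrics(counts)
        assert m.precision["low"] == 0.0
        assert "low" in m.undefined_precision

    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_sklearn_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 40, size=(3, 3))
        counts = pd.DataFrame(mat, index=list(RISK_LEVELS), columns=list(RISK_LEVELS))
        if counts.to_numpy().sum() == 0:
            return
        y_true, y_pred = [], []
        for i, a in enumerate(RISK_LEVELS):
            for j, b in enumerate(RISK_LEVELS):
                y_true += [a] * mat[i, j]
                y_pred += [b] * mat[i, j]
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list(RISK_LEVELS), zero_division=0
        )
        m = metrics(counts)
        np.testing.assert_allclose(m.precision.to_numpy(), p, atol=1e-12)
        np.testing.assert_allclose(m.recall.to_numpy(), r, atol=1e-12)
        np.testing.assert_allclose(m.f_score.to_numpy(), f, atol=1e-12)
        # macro recall == mean of row-rate diagonal; weighted == trace/total
        assert m.macro_recall == pytest.approx(np.diag(m.row_rates).mean())
        assert m.weighted_recall == pytest.approx(np.trace(mat) / mat.sum())


class TestMeanError:
    def _frame(self, true_v, pred_v, true_h=None, pred_h=None, v_band=None):
        n = len(true_v)
        return pd.DataFrame(
            {
                "true_v": true_v,
                "pred_v": pred_v,
                "true_h": true_h if true_h is not None else np.zeros(n),
                "pred_h": pred_h if pred_h is not None else np.zeros(n),
                **({"true_v_band": v_band} if v_band is not None else {}),
            }
        )

    def test_identical_predictions_zero_error(self):
        df = self._frame([1.0, 0.5], [1.0, 0.5])
        out = mean_error(df)
        assert out["v"] == 0.0 and out["h"] == 0.0

    def test_constant_offset_every_band(self):
        v_true = [1.5, 1.2, 0.7, 0.3]
        df = self._frame(v_true, [v - 0.10 for v in v_true], v_band=[1, 2, 3, 4])
        out = mean_error(df)
        assert out["v"] == pytest.approx(-0.10)
        for band in (1, 2, 3, 4):
            assert out["v_by_band"][band] == pytest.approx(-0.10)

    def test_mixed_offsets_match_brute_force(self):
        rng = np.random.default_rng(5)
        true_v = rng.uniform(0, 1.7, 50)
        offs = rng.normal(0, 0.2, 50)
        df = self._frame(true_v, true_v + offs)
        assert mean_error(df)["v"] == pytest.approx(float(np.mean(offs)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_error(pd.DataFrame(columns=["true_v", "true_h", "pred_v", "pred_h"]))
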