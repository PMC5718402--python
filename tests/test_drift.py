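"""Drift-segment extraction, classification, screening, and spline fitting."""

import numpy as np
import pandas as pd
import pytest

from sealforage import drift as dr
from sealforage.config import SimConfig
from sealforage.synthetic import simulate_dataset
from tests.test_dives import make_dive


def brute_force_candidates(dive_row, min_frac=0.30, window=(0.01, 1.2)):
    """Independent per-segment scan."""
    t = [dive_row[f"t_{i}"] for i in range(6)]
    d = [dive_row[f"d_{i}"] for i in range(6)]
    dur = t[5] - t[0]
    found = []
    for j in range(1, 4):                      # interior legs only
        dt = t[j + 1] - t[j]
        if dt <= 0:
            continue
        slope = (d[j + 1] - d[j]) / dt
        if dt / dur >= min_frac and window[0] <= abs(slope) <= window[1]:
            found.append(j)
    return found


class TestExtraction:
    def test_v_dive_has_no_candidates(self):
        d = pd.DataFrame([make_dive([0, 100, 200, 260, 320, 420],
                                    [0, 200, 400, 280, 160, 0])])
        assert len(dr.extract_drift_candidates(d)) == 0

    def test_constructed_drift_segment_found(self):
        # 40%-duration mid-segment sinking at 0.30 m/s -> rate -0.30
        d = pd.DataFrame([make_dive([0, 100, 500, 600, 700, 1000],
                                    [0, 150, 270, 270, 260, 0])])
        out = dr.extract_drift_candidates(d)
        assert len(out) == 1
        assert out.drift_rate.iloc[0] == pytest.approx(-0.30)
        assert out.segment.iloc[0] == 1

    def test_first_and_last_legs_never_candidates(self):
        # slow 40% descent leg would qualify on duration/rate but is leg 0
        d = pd.DataFrame([make_dive([0, 400, 500, 600, 700, 1000],
                                    [0, 120, 130, 130, 120, 0])])
        out = dr.extract_drift_candidates(d)
        assert (out.segment != 0).all() and (out.segment != 5).all()

    def test_counts_match_bruteforce_oracle(self, small_dataset):
        dives = small_dataset.dives.sample(300, random_state=1)
        out = dr.extract_drift_candidates(dives)
        expected = sum(len(brute_force_candidates(r))
                       for _, r in dives.iterrows())
        assert len(out) == expected


@pytest.fixture(scope="module")
def trained():
    cfg = SimConfig(n_animals=2, class_mix=(0.5, 0.5, 0),
                    duration_days=25, drift_dive_prob=0.25, seed=21)
    ds = simulate_dataset(cfg)
    cands = dr.extract_drift_candidates(ds.dives)
    labels = cands.dive_id.map(
        ds.dives.set_index("dive_id").is_drift).to_numpy()
    rng = np.random.default_rng(0)
    test_mask = rng.uniform(size=len(cands)) < 0.3
    clf = dr.DriftClassifier(random_state=0).fit(cands[~test_mask],
                                                 labels[~test_mask])
    return clf, cands, labels, test_mask


class TestClassifier:
    @staticmethod
    def _auc(scores, labels):
        order = np.argsort(scores)
        ranks = np.empty(len(scores))
        ranks[order] = np.arange(1, len(scores) + 1)
        pos = labels.astype(bool)
        n1, n0 = pos.sum(), (~pos).sum()
        return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    def test_resubstitution_auc(self, trained):
        clf, cands, labels, test_mask = trained
        p = clf.predict_proba(cands[~test_mask])
        assert self._auc(p, labels[~test_mask]) > 0.95

    def test_holdout_auc(self, trained):
        clf, cands, labels, test_mask = trained
        assert labels[test_mask].sum() > 10
        p = clf.predict_proba(cands[test_mask])
        assert self._auc(p, labels[test_mask]) >= 0.90

    def test_unfitted_classifier_raises(self):
        with pytest.raises(RuntimeError, match="fit"):
            dr.DriftClassifier().predict_proba(pd.DataFrame())

    def test_dive_without_candidates_has_zero_probability(self, trained):
        clf, *_ = trained
        # no candidates -> empty probability vector -> dive prob 0 by def.
        assert len(clf.predict_proba(
            pd.DataFrame(columns=dr.FEATURES))) == 0

    def test_roundtrip_serialization(self, trained, tmp_path):
        clf, cands, labels, test_mask = trained
        path = tmp_path / "clf.joblib"
        clf.save(path)
        clf2 = dr.DriftClassifier.load(path)
        assert np.allclose(clf.predict_proba(cands[:20]),
                           clf2.predict_proba(cands[:20]))


class TestScreening:
    def _segments(self, times_days, rates, animal="a"):
        t0 = pd.Timestamp("2008-04-01")
        return pd.DataFrame({
            "dive_id": [f"d{i}" for i in range(len(rates))],
            "animal_id": animal,
            "start_time": [t0 + pd.Timedelta(days=float(d))
                           for d in times_days],
            "drift_rate": rates})

    def test_isolated_positive_segment_excluded(self):
        seg = self._segments([0, 1, 2, 10], [-0.3, -0.25, -0.31, 0.05])
        out = dr.screen_positive_drifts(seg)
        assert out.excluded_positive.iloc[3]

    def test_clustered_positive_segments_retained(self):
        seg = self._segments([0, 1, 3, 4], [0.04, 0.05, 0.03, -0.3])
        out = dr.screen_positive_drifts(seg)
        assert not out[out.positive].excluded_positive.any()

    def test_flag_counts_match_neighborhood_oracle(self, rng):
        days = rng.uniform(0, 40, 60)
        rates = rng.normal(-0.2, 0.2, 60)
        seg = self._segments(days, rates)
        out = dr.screen_positive_drifts(seg, k=2, window_days=5.0)
        for r in out[out.positive].itertuples():
            t = (r.start_time - pd.Timestamp("2008-04-01")).total_seconds() \
                / 86400.0
            others = [(pd.Timestamp(s) - pd.Timestamp("2008-04-01"))
                      .total_seconds() / 86400.0
                      for s, rr in zip(out.start_time, out.drift_rate)
                      if rr > 0]
            n_near = sum(abs(o - t) <= 5.0 for o in others) - 1
            assert r.excluded_positive == (n_near < 2)


class TestTripInclusion:
    @pytest.mark.parametrize("days,n,expected", [
        (10, 5, True),       # boundary: 1 per 2 days
        (10, 4, False),
        (30, 15, True),
        (1, 0, False),
    ])
    def test_rule(self, days, n, expected):
        assert dr.trip_inclusion(days, n) is expected


class TestSpline:
    def _segments(self, times_days, rates, weights=None, animal="a"):
        t0 = pd.Timestamp("2008-04-01")
        n = len(rates)
        return pd.DataFrame({
            "dive_id": [f"d{i}" for i in range(n)],
            "animal_id": animal,
            "start_time": [t0 + pd.Timedelta(days=float(d))
                           for d in times_days],
            "drift_rate": rates,
            "combined_weight": weights if weights is not None
            else np.ones(n)})

    def test_constant_rates_recovered_flat(self, rng):
        seg = self._segments(np.sort(rng.uniform(0, 20, 30)),
                             np.full(30, -0.30),
                             rng.uniform(0.2, 1.0, 30))
        fit = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                  pd.Timestamp("2008-04-21"))
        assert np.allclose(fit.daily.predicted_rate, -0.30, atol=1e-6)
        assert np.allclose(fit.daily.daily_change, 0.0, atol=1e-6)

    def test_zero_weight_segments_have_no_influence(self, rng):
        t = np.sort(rng.uniform(0, 20, 25))
        rates = -0.3 + 0.005 * t + rng.normal(0, 0.01, 25)
        seg = self._segments(t, rates)
        spiked = pd.concat([seg, self._segments([10.0], [0.9], [0.0])],
                           ignore_index=True)
        a = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                pd.Timestamp("2008-04-21"))
        b = dr.fit_drift_spline(spiked, "t", pd.Timestamp("2008-04-01"),
                                pd.Timestamp("2008-04-21"))
        assert np.allclose(a.daily.predicted_rate, b.daily.predicted_rate)

    def test_duplicate_segment_half_weight_invariance(self, rng):
        t = np.sort(rng.uniform(0, 20, 25))
        rates = -0.3 + 0.005 * t + rng.normal(0, 0.01, 25)
        w = rng.uniform(0.3, 1.0, 25)
        seg = self._segments(t, rates, w)
        dup = pd.concat([self._segments(t, rates, w / 2),
                         self._segments(t, rates, w / 2)],
                        ignore_index=True)
        a = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                pd.Timestamp("2008-04-21"))
        b = dr.fit_drift_spline(dup, "t", pd.Timestamp("2008-04-01"),
                                pd.Timestamp("2008-04-21"))
        assert np.allclose(a.daily.predicted_rate, b.daily.predicted_rate,
                           atol=1e-9)

    def test_predictions_respect_observed_envelope(self, rng):
        t = np.sort(rng.uniform(0, 30, 40))
        rates = rng.uniform(-0.5, -0.1, 40)
        seg = self._segments(t, rates)
        fit = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                  pd.Timestamp("2008-05-01"))
        assert (fit.daily.predicted_rate >= rates.min() - 0.05 - 1e-12).all()
        assert (fit.daily.predicted_rate <= rates.max() + 0.05 + 1e-12).all()

    def test_daily_change_integrates_to_net_change(self, rng):
        t = np.sort(rng.uniform(0, 30, 60))
        rates = -0.35 + 0.005 * t + rng.normal(0, 0.01, 60)
        seg = self._segments(t, rates)
        fit = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                  pd.Timestamp("2008-05-01"))
        pred = fit.daily.predicted_rate.to_numpy()
        total = fit.daily.daily_change.sum()
        assert total == pytest.approx(pred[-1] - pred[0]
                                      + (pred[1] - pred[0]) / 2
                                      + (pred[-1] - pred[-2]) / 2, abs=0.01)

    def test_too_few_segments_rejected(self):
        seg = self._segments([0, 5, 10], [-0.3, -0.3, -0.3])
        with pytest.raises(ValueError):
            dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                pd.Timestamp("2008-04-11"))

    def test_rising_trajectory_gives_positive_daily_change(self, rng):
        t = np.sort(rng.uniform(0, 30, 80))
        rates = -0.35 + 0.005 * t + rng.normal(0, 0.02, 80)
        seg = self._segments(t, rates)
        fit = dr.fit_drift_spline(seg, "t", pd.Timestamp("2008-04-01"),
                                  pd.Timestamp("2008-05-01"))
        frac_pos = (fit.daily.daily_change > 0).mean()
        assert frac_pos >= 0.8
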