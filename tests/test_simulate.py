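"""Tests for the synthetic chamber generator and ground-truth scoring."""

import io

import numpy as np
import pandas as pd
import pytest

import chamberqc as cq
from chamberqc.simulate import DetectionMetrics


def trial_3d(**kw):
    defaults = dict(
        trial_id="T1", day_setpoint=30.0, night_setpoint=24.0,
        day_hours=16.5, night_hours=7.5,
        window=("2021-03-01", "2021-03-04"),
    )
    defaults.update(kw)
    return cq.TrialConfig(**defaults)


def serialize(result):
    buf = io.StringIO()
    cq.write_sensor_log(result.series, buf)
    ev = io.StringIO()
    cq.write_event_log(result.events, ev)
    return buf.getvalue(), ev.getvalue(), result.labels.to_csv(index=False)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = lambda: cq.SimConfig(  # noqa: E731
            trials=[trial_3d()],
            sensors=[cq.SensorSpec("A", noise_sd=0.2),
                     cq.SensorSpec("B", bias=0.5, noise_sd=0.1)],
            anomalies=[cq.AnomalyEvent("occupancy_bump", "2021-03-02T10:00", 30, 2.0)],
            seed=5,
        )
        assert serialize(cq.simulate_chamber(cfg())) == serialize(
            cq.simulate_chamber(cfg())
        )

    def test_distinct_seeds_differ(self):
        mk = lambda seed: cq.SimConfig(  # noqa: E731
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.2)], seed=seed
        )
        a = cq.simulate_chamber(mk(1)).series[0].values
        b = cq.simulate_chamber(mk(2)).series[0].values
        assert not np.array_equal(a, b)

    def test_adding_sensor_preserves_existing_streams(self):
        base = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.2)], seed=3
        )
        extended = cq.SimConfig(
            trials=[trial_3d()],
            sensors=[cq.SensorSpec("A", noise_sd=0.2), cq.SensorSpec("NEW", noise_sd=0.2)],
            seed=3,
        )
        a0 = cq.simulate_chamber(base).series[0].values
        a1 = cq.simulate_chamber(extended).series[0].values
        np.testing.assert_array_equal(a0, a1)


class TestBaseSignal:
    def test_photoperiod_fraction(self):
        cfg = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.0)], seed=0
        )
        s = cq.simulate_chamber(cfg).series[0]
        frac_day = np.mean(s.values == 30.0)
        assert frac_day == pytest.approx(16.5 / 24)  # 0.6875
        assert np.mean(s.values == 24.0) == pytest.approx(7.5 / 24)

    def test_bias_added(self):
        cfg = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", bias=0.7, noise_sd=0.0)],
            seed=0,
        )
        s = cq.simulate_chamber(cfg).series[0]
        assert set(np.unique(s.values)) == {24.7, 30.7}

    def test_transition_lag_smooths_steps(self):
        sharp = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.0)], seed=0
        )
        lagged = cq.SimConfig(
            trials=[trial_3d()],
            sensors=[cq.SensorSpec("A", noise_sd=0.0, transition_lag_min=20)],
            seed=0,
        )
        v_sharp = cq.simulate_chamber(sharp).series[0].values
        v_lag = cq.simulate_chamber(lagged).series[0].values
        assert np.max(np.abs(np.diff(v_lag))) < np.max(np.abs(np.diff(v_sharp)))
        # lagged signal stays within the setpoint band
        assert v_lag.min() >= 24.0 - 1e-9 and v_lag.max() <= 30.0 + 1e-9

    def test_zero_noise_no_anomaly_round_trip_null(self):
        cfg = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.0)], seed=0
        )
        s = cq.simulate_chamber(cfg).series[0]
        prof = cq.build_surrogate(s)
        alt = cq.alt_decompose(cq.coalesce(s, prof), prof)
        np.testing.assert_array_equal(alt.residuals, 0.0)

    def test_surrogate_matches_noiseless_pattern(self):
        cfg = cq.SimConfig(
            trials=[trial_3d()], sensors=[cq.SensorSpec("A", noise_sd=0.0)], seed=0
        )
        s = cq.simulate_chamber(cfg).series[0]
        prof = cq.build_surrogate(s)
        np.testing.assert_array_equal(prof.slots, s.values[:1440])


class TestAnomalies:
    def _sim(self, anomalies, noise=0.1, seed=7, sensors=None):
        cfg = cq.SimConfig(
            trials=[trial_3d()],
            sensors=sensors or [cq.SensorSpec("A", noise_sd=noise)],
            anomalies=anomalies,
            seed=seed,
        )
        return cq.simulate_chamber(cfg)

    def test_spike_labelled_and_superposed(self):
        ev = cq.AnomalyEvent("power_surge_spike", "2021-03-02T12:00", 1, 5.0)
        clean = self._sim([], noise=0.0)
        spiked = self._sim([ev], noise=0.0)
        i = list(spiked.series[0].timestamps).index(pd.Timestamp("2021-03-02T12:00"))
        assert spiked.series[0].values[i] == clean.series[0].values[i] + 5.0
        assert len(spiked.labels) == 1
        assert spiked.labels.iloc[0]["kind"] == "power_surge_spike"

    def test_outage_masks_block(self):
        ev = cq.AnomalyEvent("power_outage", "2021-03-02T00:00", 120, 0.0)
        res = self._sim([ev])
        s = res.series[0]
        assert s.n_missing == 120
        assert (res.labels["kind"] == "power_outage").sum() == 120

    def test_drift_ramps_linearly(self):
        ev = cq.AnomalyEvent("sensor_drift", "2021-03-02T00:00", 100, 2.0)
        clean = self._sim([], noise=0.0)
        drifted = self._sim([ev], noise=0.0)
        delta = drifted.series[0].values - clean.series[0].values
        lo = list(clean.series[0].timestamps).index(pd.Timestamp("2021-03-02T00:00"))
        np.testing.assert_allclose(delta[lo:lo + 100], np.linspace(0, 2.0, 100),
                                   atol=1e-12)
        assert np.all(delta[:lo] == 0) and np.all(delta[lo + 100:] == 0)

    def test_occupancy_bump_generates_person_event(self):
        ev = cq.AnomalyEvent("occupancy_bump", "2021-03-02T10:00", 30, 1.5)
        res = self._sim([ev])
        person = next(l for l in res.events if l.channel == "person_1")
        assert person.intervals() == [
            (pd.Timestamp("2021-03-02T10:00"), pd.Timestamp("2021-03-02T10:30"))
        ]

    def test_door_bump_generates_door_event(self):
        ev = cq.AnomalyEvent("door_bump", "2021-03-02T09:00", 10, 1.0)
        res = self._sim([ev])
        door = next(l for l in res.events if l.channel == "door")
        assert len(door.intervals()) == 1

    def test_ac_delay_shifts_transition(self):
        # delay the 06:00 day transition on 2021-03-02 by 15 minutes
        ev = cq.AnomalyEvent("ac_delay", "2021-03-02T05:55", 30, 15.0)
        clean = self._sim([], noise=0.0)
        delayed = self._sim([ev], noise=0.0)
        ts = clean.series[0].timestamps
        i = list(ts).index(pd.Timestamp("2021-03-02T06:05"))
        assert clean.series[0].values[i] == 30.0
        assert delayed.series[0].values[i] == 24.0  # still at night setpoint
        assert (delayed.labels["kind"] == "ac_delay").any()

    def test_affected_sensors_respected(self):
        ev = cq.AnomalyEvent("power_surge_spike", "2021-03-02T12:00", 1, 5.0,
                             sensors=("A",))
        res = self._sim(
            [ev],
            noise=0.0,
            sensors=[cq.SensorSpec("A", noise_sd=0.0), cq.SensorSpec("B", noise_sd=0.0)],
        )
        a = res.get_series("A", "T1")
        b = res.get_series("B", "T1")
        assert not np.array_equal(a.values, b.values)
        assert set(res.labels["sensor_id"]) == {"A"}

    def test_full_slot_outage_warns(self):
        # knock out 02:00-03:00 on all three days -> zero-support slots
        evs = [
            cq.AnomalyEvent("power_outage", f"2021-03-0{d}T02:00", 60, 0.0)
            for d in (1, 2, 3)
        ]
        with pytest.warns(UserWarning, match="missing on every day"):
            self._sim(evs)


class TestDetectionMetrics:
    def _pipeline(self, res):
        s = res.series[0]
        prof = cq.build_surrogate(s)
        alt = cq.alt_decompose(cq.coalesce(s, prof), prof)
        table = cq.zscore_outliers(alt)
        rows = table.rows.assign(sensor_id=s.sensor_id)
        return cq.labels_to_truth(res.labels, rows)

    def test_clean_run_false_rate_near_alpha(self):
        cfg = cq.SimConfig(
            trials=[cq.TrialConfig("T1", 30, 24, 16.5, 7.5,
                                   ("2021-03-01", "2021-03-29"))],
            sensors=[cq.SensorSpec("A", noise_sd=0.2)],
            seed=42,
        )
        m = self._pipeline(cq.simulate_chamber(cfg))
        alpha = 0.001
        se = np.sqrt(alpha * (1 - alpha) / m.n_clean)
        assert abs(m.false_flag_rate - alpha) <= 4 * se
        assert np.isnan(m.recall_overall)  # nothing planted

    def test_planted_spikes_recalled(self):
        rng = np.random.default_rng(0)
        spikes = [
            cq.AnomalyEvent(
                "power_surge_spike",
                pd.Timestamp("2021-03-01") + pd.Timedelta(minutes=int(m)), 1, 2.0,
            )
            for m in rng.choice(3 * 1440, 10, replace=False)
        ]
        cfg = cq.SimConfig(
            trials=[trial_3d()],
            sensors=[cq.SensorSpec("A", noise_sd=0.1)],
            anomalies=spikes,
            seed=8,
        )
        m = self._pipeline(cq.simulate_chamber(cfg))
        assert m.n_anomalous == 10
        assert m.recall_overall == 1.0
        assert m.recall_by_kind["power_surge_spike"] == 1.0


class TestStabilitySignRecovery:
    def test_planted_severity_trend_recovered(self):
        """Occupancy bumps whose magnitude decays over the trial produce a
        negative log|z| vs cumulative-ops slope; sign must be recovered in
        >= 95% of seeded replicates."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            start = pd.Timestamp("2021-03-01")
            bumps = [
                cq.AnomalyEvent(
                    "occupancy_bump",
                    start + pd.Timedelta(days=d, hours=10 + 3 * (k % 2)),
                    20,
                    3.0 * np.exp(-0.25 * d),  # severity decays over days
                )
                for d in range(7)
                for k in range(2)
            ]
            cfg = cq.SimConfig(
                trials=[cq.TrialConfig("T1", 30, 24, 16.5, 7.5,
                                       ("2021-03-01", "2021-03-08"))],
                sensors=[cq.SensorSpec("A", noise_sd=0.15)],
                anomalies=bumps,
                seed=1000 + rep,
            )
            res = cq.simulate_chamber(cfg)
            s = res.series[0]
            prof = cq.build_surrogate(s)
            alt = cq.alt_decompose(cq.coalesce(s, prof), prof)
            table = cq.zscore_outliers(alt)
            mins = cq.events_to_minutes(res.events, ("2021-03-01", "2021-03-08"))
            ops = cq.cumulative_agr_ops(mins)
            cum = pd.Series(ops.cumulative, index=ops.timestamps)
            out = table.outliers()
            if len(out) < 10:
                continue
            df = pd.DataFrame(
                {
                    "abs_z": out["z"].abs().to_numpy(),
                    "agr_ops": cum.reindex(out["timestamp"]).to_numpy(),
                    "sensor_id": "A",
                }
            )
            fit = cq.fit_stability_glm(df)
            if fit.coef("Agr_Ops") < 0:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestTruthEdgeCases:
    def test_no_planted_recall_nan(self):
        rows = pd.DataFrame(
            {
                "timestamp": pd.date_range("2021-03-01", periods=5, freq="min"),
                "sensor_id": "A",
                "is_outlier": [False, True, False, False, False],
            }
        )
        empty = pd.DataFrame(columns=["timestamp", "sensor_id", "trial_id", "kind"])
        m = cq.labels_to_truth(empty, rows)
        assert np.isnan(m.recall_overall)
        assert m.false_flag_rate == pytest.approx(0.2)
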