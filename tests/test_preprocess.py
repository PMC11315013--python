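import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bedtherm.preprocess import (FLAG_BED_ABSENT, FLAG_MISSING,
                                 FLAG_NEGATIVE, FLAG_NULL, FLAG_OSCILLATION,
                                 FLAG_VALID, aggregate_minute,
                                 build_feature_table, flag_invalid_minutes,
                                 mask_bed_absence, pooled_strip_mask,
                                 select_top3, select_top3_series,
                                 session_quality_gate, smooth_reference,
                                 QualityMask)
from bedtherm.simulate import (ArtifactSpec, RawStream, inject_artifacts,
                               simulate_subject_night, PhysioParams)


def stream_1hz(values, channel="T1"):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size, dtype=float) + 0.5
    return RawStream(channel, t, values, 1.0, 0.1)


class TestAggregateMinute:
    def test_constant_minute(self):
        ms = aggregate_minute(stream_1hz(np.full(60, 30.0)))
        assert ms.values[0] == pytest.approx(30.0)

    def test_alternating_symmetry(self):
        v = np.tile([29.9, 30.1], 30)
        ms = aggregate_minute(stream_1hz(v))
        assert ms.values[0] == pytest.approx(30.0)

    def test_windowed_mean_oracle(self):
        """Per-minute values equal an independently computed mean over the
        half-open window [60(n-1), 60n)."""
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 600, size=580))
        t = t[np.diff(t, prepend=-1) > 0]
        v = rng.normal(30, 1, size=t.size)
        ms = aggregate_minute(RawStream("T1", t, v, 1.0, 0.1), n_minutes=10)
        for n in range(1, 11):
            inwin = (t >= 60 * (n - 1)) & (t < 60 * n)
            if inwin.sum() >= 30:
                assert ms.values[n - 1] == pytest.approx(v[inwin].mean(),
                                                         abs=1e-9)
            else:
                assert np.isnan(ms.values[n - 1])

    def test_sparse_minute_is_missing(self):
        v = np.full(150, 30.0)
        t = np.concatenate([np.arange(60.0),           # minute 1 complete
                            60 + np.arange(20.0),      # minute 2: 20 samples
                            120 + np.arange(70)[:60]])  # minute 3 complete
        ms = aggregate_minute(RawStream("T1", t, v[:t.size], 1.0, 0.1))
        assert np.isfinite(ms.values[0]) and np.isfinite(ms.values[2])
        assert np.isnan(ms.values[1])

    @given(c=st.floats(min_value=0.1, max_value=10.0,
                       allow_nan=False, allow_infinity=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_aggregation_linearity(self, c):
        rng = np.random.default_rng(5)
        v = rng.normal(30, 1, size=180)
        base = aggregate_minute(stream_1hz(v)).values
        scaled = aggregate_minute(stream_1hz(c * v)).values
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)

    def test_empty_stream(self):
        ms = aggregate_minute(RawStream("T1", np.array([]), np.array([]), 1.0, 0.1))
        assert len(ms) == 0


class TestQualityFlags:
    def test_clean_minute_valid(self):
        s = stream_1hz(np.full(120, 30.0))
        mask = flag_invalid_minutes(aggregate_minute(s), s)
        assert list(mask.flags) == [FLAG_VALID, FLAG_VALID]

    def test_negative_sample_flags_minute(self):
        v = np.full(120, 30.0)
        v[70] = -1.0
        s = stream_1hz(v)
        mask = flag_invalid_minutes(aggregate_minute(s), s)
        assert mask.flags[1] == FLAG_NEGATIVE and mask.flags[0] == FLAG_VALID

    def test_null_sample_flags_minute(self):
        v = np.full(60, 30.0)
        v[10] = np.nan
        s = stream_1hz(v)
        assert flag_invalid_minutes(aggregate_minute(s), s).flags[0] == FLAG_NULL

    def test_oscillation_range_rule(self):
        v = np.full(60, 30.0)
        v[20], v[40] = 31.5, 28.5  # intra-minute range 3.0
        s = stream_1hz(v)
        mask = flag_invalid_minutes(aggregate_minute(s), s,
                                    oscillation_threshold=2.0)
        assert mask.flags[0] == FLAG_OSCILLATION

    def test_mask_conservation(self, small_study):
        """Flag counts over all categories sum to the total minutes."""
        rec = small_study.sessions_for("home")[0]
        raw = rec.streams["T1"]
        mask = mask_bed_absence(
            flag_invalid_minutes(aggregate_minute(
                raw, n_minutes=int(rec.duration_minutes)), raw),
            rec.presence_intervals)
        counts = {f: int(np.sum(mask.flags == f))
                  for f in (FLAG_VALID, FLAG_MISSING, FLAG_NULL, FLAG_NEGATIVE,
                            FLAG_OSCILLATION, FLAG_BED_ABSENT)}
        assert sum(counts.values()) == len(mask.flags)


class TestBedAbsence:
    def _valid_mask(self, n):
        return QualityMask(np.arange(1, n + 1),
                           np.full(n, FLAG_VALID, dtype=object))

    def test_full_presence_unchanged(self):
        mask = mask_bed_absence(self._valid_mask(30), [[0.0, 1800.0]])
        assert np.all(mask.flags == FLAG_VALID)

    def test_empty_presence_all_absent(self):
        mask = mask_bed_absence(self._valid_mask(30), [])
        assert np.all(mask.flags == FLAG_BED_ABSENT)

    def test_interval_overlap_rule(self):
        """Presence covering exactly minutes 10-20 keeps only those valid."""
        mask = mask_bed_absence(self._valid_mask(30), [[540.0, 1200.0]])
        valid_minutes = mask.minute_index[mask.flags == FLAG_VALID]
        np.testing.assert_array_equal(valid_minutes, np.arange(10, 21))


class TestQualityGate:
    def _mask(self, frac, n=100):
        flags = np.full(n, FLAG_VALID, dtype=object)
        flags[int(round(frac * n)):] = FLAG_MISSING
        return QualityMask(np.arange(1, n + 1), flags)

    @pytest.mark.parametrize("tss,ref,included", [
        (0.95, 0.95, True),
        (0.80, 0.80, True),   # 'at least 80 %' is inclusive
        (0.81, 0.79, False),
        (0.79, 0.95, False),
    ])
    def test_gate_decisions(self, tss, ref, included):
        gate = session_quality_gate(self._mask(tss), self._mask(ref))
        assert gate.included is included

    def test_zero_length_distinct_signal(self):
        empty = QualityMask(np.array([], dtype=int), np.array([], dtype=object))
        gate = session_quality_gate(empty, empty)
        assert not gate.included and gate.reason == "zero-length session"

    def test_gate_monotone_in_artifact_rate(self, clean_session):
        """Raising artifact rates never flips a session from excluded to
        included (same seed, nested contamination)."""
        prev_included = True
        for scale in (0.0, 1.0, 4.0, 16.0):
            spec = ArtifactSpec(p_null=0.002 * scale, p_negative=0.0,
                                p_oscillation_minute=0.02 * scale,
                                n_absence_segments=0)
            rec, _ = inject_artifacts(clean_session, spec, seed=3)
            _, gate = build_feature_table(rec)
            assert not (gate.included and not prev_included)
            prev_included = gate.included


class TestTop3:
    def test_example_sort(self):
        triple = select_top3((20.1, 31.2, 30.0, 33.4, 29.5), minute_index=7)
        assert triple.values == (33.4, 31.2, 30.0)
        assert triple.sources == (4, 2, 3)

    def test_all_equal_tie_break(self):
        triple = select_top3((30.0,) * 5)
        assert triple.values == (30.0, 30.0, 30.0)
        assert triple.sources == (1, 2, 3)

    def test_descending_identity(self):
        triple = select_top3((34.0, 33.0, 32.0, 31.0, 30.0))
        assert triple.values == (34.0, 33.0, 32.0)
        assert triple.sources == (1, 2, 3)

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError):
            select_top3((30.0, np.nan, 29.0, 28.0, 27.0))

    @given(st.permutations(range(5)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_permutation_invariance(self, perm):
        """Relabelling the five strip channels leaves (V1, V2, V3) unchanged."""
        rng = np.random.default_rng(13)
        m = rng.uniform(25, 35, size=(20, 5))
        V_ref, _ = select_top3_series(m)
        V_perm, _ = select_top3_series(m[:, list(perm)])
        np.testing.assert_array_equal(V_ref, V_perm)


class TestSmoothReference:
    def _wrist(self, values, rate=4.0):
        t = np.arange(values.size) / rate
        return RawStream("wrist", t, np.asarray(values, float), rate, 0.02)

    def test_constant_preserved(self):
        ref = smooth_reference(self._wrist(np.full(4 * 60 * 20, 33.0)))
        assert np.allclose(ref.values[np.isfinite(ref.values)], 33.0, atol=1e-9)

    def test_linear_ramp_reproduced(self):
        n = 4 * 60 * 30
        ramp = np.round((30.0 + 0.001 * np.arange(n) / 4.0) / 0.02) * 0.02
        ref = smooth_reference(self._wrist(ramp))
        per_min = aggregate_minute(self._wrist(ramp)).values
        mid = slice(3, len(ref.values) - 3)
        np.testing.assert_allclose(ref.values[mid], per_min[mid], atol=0.01)

    def test_spike_downweighted(self):
        """A 2-second +3 degC excursion on a (quantized, as emitted by the
        wrist device) ramp is robust-downweighted to < 0.2 degC."""
        n = 4 * 60 * 30
        ramp = np.round((30.0 + 0.001 * np.arange(n) / 4.0) / 0.02) * 0.02
        spiked = ramp.copy()
        spiked[2400:2408] = ramp[2400:2408] + 3.0  # +3 degC for 2 s
        ref = smooth_reference(self._wrist(spiked))
        clean = aggregate_minute(self._wrist(ramp)).values
        assert np.nanmax(np.abs(ref.values - clean)) < 0.2

    def test_variance_not_inflated(self, clean_session):
        wrist = clean_session.streams["wrist"]
        ref = smooth_reference(wrist)
        raw_per_min = aggregate_minute(wrist).values
        ok = np.isfinite(ref.values) & np.isfinite(raw_per_min)
        assert np.var(ref.values[ok]) <= np.var(raw_per_min[ok]) * (1 + 1e-9)

    def test_all_invalid_empty(self):
        v = np.full(4 * 60 * 15, np.nan)
        ref = smooth_reference(self._wrist(v))
        assert len(ref.values) == 0


class TestFeatureTable:
    def test_pooled_mask_requires_all_five(self):
        n = 10
        masks = [QualityMask(np.arange(1, n + 1),
                             np.full(n, FLAG_VALID, dtype=object))
                 for _ in range(5)]
        masks[3].flags[4] = FLAG_NULL
        pooled = pooled_strip_mask(masks)
        assert pooled.flags[4] == FLAG_NULL
        assert pooled.good_fraction == pytest.approx(0.9)

    def test_feature_table_shape(self, clean_session):
        df, gate = build_feature_table(clean_session)
        assert gate.included
        assert {"n", "V1", "V2", "V3", "S", "valid"}.issubset(df.columns)
        v = df[df["valid"]]
        assert (v["V1"] >= v["V2"]).all() and (v["V2"] >= v["V3"]).all()
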