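"""Tag/control pairing, subtraction and QUIPSS II quantification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoperf import (
    AcqParams,
    AslSeries,
    M0Image,
    PerfusionImage,
    compute_brain_mask,
    estimate_m0,
    quantify_cbf,
    quantify_series,
    split_pairs,
    subtract_pairs,
)
from hypoperf.asl_quant import CBF_VALID_RANGE, ML_G_S_TO_ML_100G_MIN


def quipss2_scalar(dm, m0, acq):
    """Independent scalar evaluation of the closed form (test oracle)."""
    f = acq.lam * dm / (2.0 * acq.alpha * m0 * acq.ti1 * math.exp(-acq.ti2 / acq.t1a))
    return f * 6000.0


def make_series(n_frames, shape=(4, 4, 2), tag_order="tag_first", fill=100.0):
    cycle = ("tag", "control") if tag_order == "tag_first" else ("control", "tag")
    labels = tuple(cycle[i % 2] for i in range(n_frames))
    data = np.full((*shape, n_frames), fill)
    return AslSeries(data=data, frame_labels=labels, acq=AcqParams(tag_order=tag_order))


class TestSplitPairs:
    @pytest.mark.parametrize("n_frames,n_pairs", [(140, 70), (2, 1), (8, 4)])
    def test_pair_count(self, n_frames, n_pairs):
        assert len(split_pairs(make_series(n_frames))) == n_pairs

    def test_odd_frame_count_rejected(self):
        series = make_series(4)
        series.data = series.data[..., :3]
        series.frame_labels = series.frame_labels[:3]
        with pytest.raises(ValueError, match="odd"):
            split_pairs(series)

    def test_inconsistent_labels_name_first_offender(self):
        series = make_series(4)
        series.frame_labels = ("tag", "control", "control", "tag")
        with pytest.raises(ValueError, match="frame 2"):
            split_pairs(series)

    def test_control_first_order(self):
        series = make_series(4, tag_order="control_first")
        series.data[..., 0] = 7.0  # first frame is a control frame
        tag, control = split_pairs(series)[0]
        assert control[0, 0, 0] == 7.0

    def test_order_preserved_and_each_frame_once(self):
        series = make_series(6)
        for k in range(6):
            series.data[..., k] = k
        pairs = split_pairs(series)
        assert [(t[0, 0, 0], c[0, 0, 0]) for t, c in pairs] == [(0, 1), (2, 3), (4, 5)]


class TestSubtractPairs:
    def test_null_perfusion(self):
        frame = np.ones((3, 3, 2))
        out = subtract_pairs([(frame, frame)] * 4)
        assert np.all(out.delta_m == 0.0)
        assert out.n_pairs == 4

    def test_constant_difference(self):
        tag = np.zeros((3, 3, 2))
        out = subtract_pairs([(tag, tag + 2.5)])
        assert np.all(out.delta_m == 2.5)

    def test_mean_over_pairs(self):
        tag = np.zeros((2, 2, 1))
        pairs = [(tag, tag + 1.0), (tag, tag + 3.0)]
        assert np.all(subtract_pairs(pairs).delta_m == 2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            subtract_pairs([])


class TestEstimateM0:
    def test_identical_controls(self):
        series = make_series(4, fill=250.0)
        assert np.all(estimate_m0(series).m0 == 250.0)

    def test_user_supplied_passthrough(self):
        series = make_series(4)
        user = np.full((4, 4, 2), 9.0)
        assert np.array_equal(estimate_m0(series, m0=user).m0, user)

    def test_no_controls_rejected(self):
        series = make_series(2)
        series.frame_labels = ("tag", "tag")
        with pytest.raises(ValueError, match="control"):
            estimate_m0(series)


class TestQuantifyCbf:
    def test_matches_scalar_oracle_at_study_parameters(self, rng):
        acq = AcqParams()  # alpha=0.98, lam=0.9, t1a=1.6, ti1=0.7, ti2=1.8
        m0 = np.full((5, 5, 3), 1000.0)
        dm = m0 * rng.uniform(0.002, 0.008, size=m0.shape)
        out = quantify_cbf(PerfusionImage(dm, 10), M0Image(m0), acq)
        expected = quipss2_scalar(dm, m0, acq)
        assert np.allclose(out.cbf, expected, rtol=1e-12)

    def test_reference_signal_fraction_value(self):
        # dM/M0 = 0.005 at the study parameters -> ~60.6 mL/100 g/min
        acq = AcqParams()
        m0 = np.full((2, 2, 2), 1000.0)
        out = quantify_cbf(PerfusionImage(0.005 * m0, 1), M0Image(m0), acq)
        assert out.cbf[0, 0, 0] == pytest.approx(60.6165, abs=1e-3)

    def test_zero_dm_gives_zero(self):
        m0 = np.full((3, 3, 3), 500.0)
        out = quantify_cbf(PerfusionImage(np.zeros_like(m0), 1), M0Image(m0), AcqParams())
        assert np.all(out.cbf == 0.0)
        assert not out.valid_mask.any()  # 0 is below the physiological floor

    def test_linearity_in_dm(self):
        m0 = np.full((3, 3, 3), 500.0)
        dm = np.full_like(m0, 1.5)
        one = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), AcqParams())
        two = quantify_cbf(PerfusionImage(2 * dm, 1), M0Image(m0), AcqParams())
        assert np.allclose(two.cbf, 2 * one.cbf)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_covariance(self, scale):
        # Scaling the whole acquisition (dM and M0 together) leaves CBF fixed
        m0 = np.full((2, 2, 2), 800.0)
        dm = np.full_like(m0, 4.0)
        base = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), AcqParams())
        scaled = quantify_cbf(
            PerfusionImage(dm * scale, 1), M0Image(m0 * scale), AcqParams()
        )
        assert np.allclose(scaled.cbf, base.cbf, rtol=1e-9)

    @pytest.mark.parametrize(
        "param,delta,direction",
        [("lam", 0.05, +1), ("alpha", -0.05, -1), ("ti1", 0.05, -1), ("ti2", 0.1, +1)],
    )
    def test_parameter_monotonicity(self, param, delta, direction):
        # increasing lam raises f; increasing alpha or ti1 lowers it;
        # increasing ti2 shrinks exp(-TI2/T1a) in the denominator, raising f
        m0 = np.full((2, 2, 2), 1000.0)
        dm = 0.005 * m0
        base_acq = AcqParams()
        bumped = AcqParams(**{**base_acq.__dict__, param: getattr(base_acq, param) + delta})
        f0 = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), base_acq).cbf[0, 0, 0]
        f1 = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), bumped).cbf[0, 0, 0]
        sign = np.sign(f1 - f0) * np.sign(delta)
        assert sign == direction

    def test_m0_floor_zeroes_air(self):
        m0 = np.zeros((4, 4, 4))
        m0[1:3, 1:3, 1:3] = 1000.0
        dm = np.full_like(m0, 5.0)
        out = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), AcqParams())
        assert np.all(out.cbf[m0 == 0] == 0.0)
        assert not out.valid_mask[0, 0, 0]

    def test_validity_range_flags(self):
        lo, hi = CBF_VALID_RANGE
        m0 = np.full((3, 1, 1), 1000.0)
        # craft dM giving CBF below, inside and above the mappable range
        acq = AcqParams()
        denom = 2 * acq.alpha * acq.ti1 * math.exp(-acq.ti2 / acq.t1a)
        dm = np.array([5.0, 60.0, 200.0]).reshape(3, 1, 1) / ML_G_S_TO_ML_100G_MIN
        dm = dm * denom * m0 / acq.lam
        out = quantify_cbf(PerfusionImage(dm, 1), M0Image(m0), acq)
        assert list(out.valid_mask.ravel()) == [False, True, False]

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            quantify_cbf(
                PerfusionImage(np.zeros((2, 2, 2)), 1),
                M0Image(np.zeros((3, 3, 3))),
                AcqParams(),
            )


class TestBrainMask:
    def test_binary_phantom_recovered_exactly(self, m0_map, labels):
        mask = compute_brain_mask(m0_map, 0.5)
        assert np.array_equal(mask, labels > 0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_brain_mask(np.zeros((4, 4, 4)), 0.5)

    def test_noisy_phantom_dice(self, m0_map, labels, rng):
        noisy = m0_map + rng.normal(0, 30.0, m0_map.shape)
        mask = compute_brain_mask(noisy, 0.5)
        brain = labels > 0
        dice = 2 * (mask & brain).sum() / (mask.sum() + brain.sum())
        assert dice >= 0.99

    def test_threshold_fraction_validated(self, m0_map):
        with pytest.raises(ValueError):
            compute_brain_mask(m0_map, 1.5)

    def test_largest_component_kept(self):
        m0 = np.zeros((8, 8, 4))
        m0[1:6, 1:6, 1:3] = 1000.0  # brain
        m0[7, 7, 3] = 1000.0  # disconnected speck
        mask = compute_brain_mask(m0, 0.5)
        assert not mask[7, 7, 3]
        assert mask[2, 2, 1]


class TestAcqParams:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 0.0}, {"alpha": 1.2}, {"ti1": -1.0}, {"ti2": 0.5},
                   {"lam": 0.0}, {"t1a": 0.0}, {"tag_order": "zigzag"}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcqParams(**kwargs)

    def test_series_label_count_must_match(self):
        with pytest.raises(ValueError):
            AslSeries(data=np.zeros((2, 2, 2, 4)), frame_labels=("tag", "control"))


def test_quantify_series_end_to_end(spec, truth_eu, m0_map, rng):
    """Pooled quantification of a noiseless forward simulation is exact."""
    from hypoperf import simulate_asl_series

    series = simulate_asl_series(truth_eu, m0_map, spec.acq, 0.0, 20, rng)
    out = quantify_series(series)
    brain = m0_map > 0
    assert np.allclose(out.cbf[brain], truth_eu.cbf[brain], rtol=1e-9, atol=1e-9)
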