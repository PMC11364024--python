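"""Frame reduction: subtraction, averaging, absolute scale, merge, alignment."""

import numpy as np
import pytest

from secswaxs.curves import ScatteringCurve
from secswaxs.errors import (AlignmentError, GridError, MergeError,
                             SelectionError)
from secswaxs.reduction import (WATER_ABS_CM, align_traces, average_frames,
                                merge_saxs_waxs, scale_to_absolute,
                                subtract_buffer)
from secswaxs.species_data import builtin_species
from secswaxs.synthetic import GroundTruth, simulate_sec_run

Q = np.linspace(0.01, 0.5, 120)


def _shape(q):
    return np.exp(-2.0 * q) + 0.01


def _noisy_frame(seed, rel=0.01):
    I = _shape(Q)
    sig = rel * I
    rng = np.random.default_rng(seed)
    return ScatteringCurve(Q, I + rng.normal(0, sig), sig)


class TestSubtractBuffer:
    def test_values_and_error_propagation(self):
        s = ScatteringCurve(Q, 2 * _shape(Q), 0.03 * _shape(Q), absolute=True)
        b = ScatteringCurve(Q, _shape(Q), 0.04 * _shape(Q))
        d = subtract_buffer(s, b)
        np.testing.assert_allclose(d.I, _shape(Q))
        np.testing.assert_allclose(d.sigma, 0.05 * _shape(Q), rtol=1e-12)
        assert d.absolute is True

    def test_grid_mismatch_raises(self):
        s = ScatteringCurve(Q, _shape(Q), np.zeros_like(Q))
        b = ScatteringCurve(Q + 1e-3, _shape(Q), np.zeros_like(Q))
        with pytest.raises(GridError, match="q grids differ"):
            subtract_buffer(s, b)


class TestAverageFrames:
    def test_noiseless_unweighted_mean(self):
        f1 = ScatteringCurve(Q, _shape(Q), np.zeros_like(Q))
        f2 = ScatteringCurve(Q, 3 * _shape(Q), np.zeros_like(Q))
        avg = average_frames([f1, f2])
        np.testing.assert_allclose(avg.I, 2 * _shape(Q))

    def test_consistent_frames_all_kept(self):
        frames = [_noisy_frame(k) for k in range(6)]
        avg = average_frames(frames)
        assert avg.metadata["n_averaged"] == 6
        assert avg.metadata["rejected"] == []
        # averaged sigma smaller than single-frame sigma
        assert np.all(avg.sigma < frames[0].sigma)

    def test_outlier_rejected_not_good_frames(self):
        frames = [_noisy_frame(k) for k in range(5)]
        bad = ScatteringCurve(Q, 2 * _shape(Q), 0.01 * _shape(Q))
        avg = average_frames(frames + [bad])
        assert avg.metadata["rejected"] == [5]
        assert avg.metadata["n_averaged"] == 5

    def test_empty_input(self):
        with pytest.raises(SelectionError, match="no frames"):
            average_frames([])

    def test_mixed_sigma_rejected(self):
        f1 = _noisy_frame(0)
        f2 = ScatteringCurve(Q, _shape(Q), np.zeros_like(Q))
        with pytest.raises(SelectionError, match="mixed"):
            average_frames([f1, f2])


class TestScaleToAbsolute:
    def test_factor_and_flag(self):
        c = ScatteringCurve(Q, _shape(Q), 0.01 * _shape(Q))
        out = scale_to_absolute(c, water_plateau=0.005)
        k = WATER_ABS_CM / 0.005
        np.testing.assert_allclose(out.I, k * c.I)
        np.testing.assert_allclose(out.sigma, k * c.sigma)
        assert out.absolute is True

    def test_nonpositive_plateau(self):
        c = ScatteringCurve(Q, _shape(Q), np.zeros_like(Q))
        with pytest.raises(ValueError):
            scale_to_absolute(c, water_plateau=0.0)


class TestMerge:
    def _pair(self, scale=3.7):
        qs = np.linspace(0.01, 0.5, 100)
        qw = np.linspace(0.3, 2.0, 150)
        saxs = ScatteringCurve(qs, _shape(qs), 0.01 * _shape(qs),
                               absolute=True)
        waxs = ScatteringCurve(qw, scale * _shape(qw), 0.01 * _shape(qw))
        return saxs, waxs

    def test_scale_recovered_and_grid_monotone(self):
        saxs, waxs = self._pair()
        m = merge_saxs_waxs(saxs, waxs, (0.3, 0.5))
        # small bias from interpolating the curved WAXS profile onto the
        # SAXS overlap grid; exact ratio is 1/3.7
        assert m.metadata["waxs_scale"] == pytest.approx(1 / 3.7, rel=2e-4)
        assert np.all(np.diff(m.q) > 0)
        # merged high-q matches the SAXS-normalized truth
        assert np.interp(1.5, m.q, m.I) == pytest.approx(_shape(1.5),
                                                         rel=1e-3)
        assert m.absolute is True

    def test_insufficient_overlap(self):
        saxs, waxs = self._pair()
        with pytest.raises(MergeError, match="fewer than 5"):
            merge_saxs_waxs(saxs, waxs, (0.49, 0.5))


class TestAlignTraces:
    def _run(self, noise=0.0, seed=11):
        spec = builtin_species("SERF1a")
        truth = GroundTruth(species_ids=["SERF1a"], stoich=(1, 0),
                            c_max=0.2, noise_scale=noise, seed=seed)
        run, truth = simulate_sec_run([spec], truth)
        return run, truth

    def test_recovers_delay_and_broadening(self):
        run, truth = self._run()
        out = align_traces(run)
        fit = out.metadata["trace_alignment"]
        assert fit["dri"]["shift_s"] == pytest.approx(truth.dri_delay_s,
                                                      abs=0.1)
        assert fit["dri"]["broadening_s"] == pytest.approx(
            truth.dri_broadening_s, abs=0.5)
        assert abs(fit["uv"]["shift_s"]) < 0.1

    def test_aligned_apex_values_accurate(self):
        run, truth = self._run()
        out = align_traces(run)
        apex = truth.derived["apex"]
        k = int(np.argmax(truth.derived["i0_profile"]))
        uv_apex = out.uv_trace[k, 1]
        ri_apex = out.dri_trace[k, 1]
        assert uv_apex == pytest.approx(apex["A214"], rel=5e-3)
        assert ri_apex == pytest.approx(apex["dn"], rel=5e-3)

    def test_traces_resampled_on_frame_axis(self):
        run, _ = self._run()
        out = align_traces(run)
        np.testing.assert_allclose(out.uv_trace[:, 0], run.time_s)
        np.testing.assert_allclose(out.dri_trace[:, 0], run.time_s)

    def test_flat_trace_raises(self):
        run, _ = self._run()
        flat = run.uv_trace.copy()
        flat[:, 1] = 1e-6
        bad = type(run)(run.time_s, run.frames, flat, run.dri_trace,
                        frame_time_s=run.frame_time_s)
        with pytest.raises(AlignmentError, match="no dominant peak"):
            align_traces(bad)
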