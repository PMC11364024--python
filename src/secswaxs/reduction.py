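"""Reduction of raw elution frames to merged absolute-scale SWAXS curves.

Buffer subtraction and frame averaging operate strictly on matching q grids
(no silent interpolation — rebinning would smooth the counting statistics);
interpolation happens only inside the SAXS/WAXS merge.  Absolute scaling
uses the flat water scattering level as the intensity standard.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .curves import ScatteringCurve, SECRun
from .errors import AlignmentError, GridError, MergeError, SelectionError

__all__ = ["subtract_buffer", "average_frames", "scale_to_absolute",
           "merge_saxs_waxs", "align_traces", "WATER_ABS_CM"]

#: Absolute scattering level of water at 283 K, 1/cm (configurable).
WATER_ABS_CM = 0.0162

GRID_TOL = 1e-6


def _check_grids(a: ScatteringCurve, b: ScatteringCurve):
    if len(a) != len(b) or np.max(np.abs(a.q - b.q)) > GRID_TOL:
        raise GridError("q grids differ; reduce on the native grid "
                        "(no silent interpolation)")


def subtract_buffer(sample: ScatteringCurve,
                    buffer: ScatteringCurve) -> ScatteringCurve:
    """Pointwise I_s - I_b with uncertainties added in quadrature."""
    _check_grids(sample, buffer)
    return ScatteringCurve(
        sample.q, sample.I - buffer.I,
        np.sqrt(sample.sigma ** 2 + buffer.sigma ** 2),
        absolute=sample.absolute,
        metadata=dict(sample.metadata, buffer_subtracted=True))


def average_frames(frames: list, similarity_p: float = 0.01):
    """Inverse-variance weighted mean of statistically consistent frames.

    Each frame is tested against the running mean with a reduced-chi2 test;
    frames whose survival probability falls below ``similarity_p`` are
    excluded and reported in the metadata (``rejected`` indices).  For
    zero-sigma (noiseless synthetic) input the frames are averaged
    unweighted and no test is applied.
    """
    if not frames:
        raise SelectionError("no frames to average")
    for f in frames[1:]:
        _check_grids(frames[0], f)
    n = len(frames)
    I = np.array([f.I for f in frames])
    S = np.array([f.sigma for f in frames])
    if np.all(S == 0):
        mean = ScatteringCurve(frames[0].q, I.mean(axis=0), np.zeros(len(I[0])),
                               absolute=frames[0].absolute,
                               metadata={"n_averaged": n, "rejected": []})
        return mean
    if np.any(S <= 0):
        raise SelectionError("mixed zero/non-zero sigma across frames")
    keep = np.ones(n, dtype=bool)
    # leave-one-out test, worst frame first: each kept frame is compared
    # against the weighted mean of the *other* kept frames, and only the
    # single worst offender is dropped per pass.  Testing against a mean
    # that includes an outlier would let it mask the good frames.
    for _ in range(n - 1):
        worst = None
        for k in np.nonzero(keep)[0]:
            others = keep.copy()
            others[k] = False
            if not others.any():
                continue
            w = 1.0 / S[others] ** 2
            wsum = w.sum(axis=0)
            mean_I = (w * I[others]).sum(axis=0) / wsum
            var = S[k] ** 2 + 1.0 / wsum
            chi2 = float(np.sum((I[k] - mean_I) ** 2 / var))
            p = chi2_dist.sf(chi2, len(I[k]))
            if p < similarity_p and (worst is None or chi2 > worst[0]):
                worst = (chi2, k)
        if worst is None:
            break
        keep[worst[1]] = False
    if not keep.any():
        raise SelectionError("all frames rejected by the similarity test")
    w = 1.0 / S[keep] ** 2
    wsum = w.sum(axis=0)
    mean_I = (w * I[keep]).sum(axis=0) / wsum
    return ScatteringCurve(frames[0].q, mean_I, 1.0 / np.sqrt(wsum),
                           absolute=frames[0].absolute,
                           metadata={"n_averaged": int(keep.sum()),
                                     "rejected": [int(k) for k in np.nonzero(~keep)[0]]})


def scale_to_absolute(curve: ScatteringCurve, water_plateau: float,
                      water_ref_cm: float = WATER_ABS_CM) -> ScatteringCurve:
    """Rescale to 1/cm using the measured flat water level as standard."""
    if water_plateau <= 0:
        raise ValueError("water plateau must be positive")
    k = water_ref_cm / water_plateau
    return ScatteringCurve(curve.q, k * curve.I, k * curve.sigma,
                           absolute=True,
                           metadata=dict(curve.metadata, abs_scale_factor=k))


def merge_saxs_waxs(saxs: ScatteringCurve, waxs: ScatteringCurve,
                    overlap: tuple) -> ScatteringCurve:
    """Merge a SAXS and a WAXS curve on their overlap window.

    The WAXS curve is rescaled by the inverse-variance-weighted ratio of the
    two curves over the overlap (WAXS interpolated onto the SAXS overlap
    grid); the output takes SAXS below the overlap midpoint and rescaled
    WAXS above it.
    """
    q_lo, q_hi = overlap
    m_s = (saxs.q >= q_lo) & (saxs.q <= q_hi)
    m_w = (waxs.q >= q_lo) & (waxs.q <= q_hi)
    if m_s.sum() < 5 or m_w.sum() < 5:
        raise MergeError(f"overlap [{q_lo}, {q_hi}] holds fewer than 5 points "
                         "of one curve")
    Iw_on_s = np.interp(saxs.q[m_s], waxs.q, waxs.I)
    sw_on_s = np.interp(saxs.q[m_s], waxs.q, waxs.sigma)
    var = saxs.sigma[m_s] ** 2 + sw_on_s ** 2
    w = 1.0 / np.where(var > 0, var, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = float((w * saxs.I[m_s] * Iw_on_s).sum()
                      / (w * Iw_on_s ** 2).sum())
    q_mid = 0.5 * (q_lo + q_hi)
    lo = saxs.q <= q_mid
    hi = waxs.q > q_mid
    q = np.concatenate([saxs.q[lo], waxs.q[hi]])
    I = np.concatenate([saxs.I[lo], scale * waxs.I[hi]])
    s = np.concatenate([saxs.sigma[lo], scale * waxs.sigma[hi]])
    order = np.argsort(q)
    q, I, s = q[order], I[order], s[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    return ScatteringCurve(q[keep], I[keep], s[keep],
                           absolute=saxs.absolute,
                           metadata={"waxs_scale": scale,
                                     "overlap": (q_lo, q_hi)})


def _baseline(v):
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return med, mad


def _peak_profile(run: SECRun) -> np.ndarray:
    """Baseline-subtracted X-ray elution proxy: low-q mean per frame."""
    n_low = max(5, len(run.frames[0]) // 10)
    prox = np.array([f.I[:n_low].mean() for f in run.frames])
    med, _ = _baseline(prox)
    return prox - med


def _shift_broaden(t_src, v_src, t_out, shift, width):
    """Evaluate the shifted, Gaussian-broadened source on t_out."""
    if width < 1e-9:
        return np.interp(t_out, t_src + shift, v_src, left=0.0, right=0.0)
    dt = np.median(np.diff(t_src))
    half = int(np.ceil(4 * width / dt))
    kt = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (kt / width) ** 2)
    kernel /= kernel.sum()
    v = np.convolve(v_src, kernel, mode="same")
    return np.interp(t_out, t_src + shift, v, left=0.0, right=0.0)


def _fit_trace(t_x, prof_x, trace, frame_time):
    """Fit shift and broadening of the X-ray profile onto one optical trace."""
    t_tr, v_tr = trace[:, 0], trace[:, 1]
    med, mad = _baseline(v_tr)
    if v_tr.max() - med < 5 * max(mad, 1e-30):
        raise AlignmentError("no dominant peak in optical trace "
                             "(max < 5x baseline MAD)")
    v0 = v_tr - med
    area_tr = np.trapezoid(np.maximum(v0, 0.0), t_tr)
    v_unit = v0 / area_tr
    area_x = np.trapezoid(np.maximum(prof_x, 0.0), t_x)
    px_unit = prof_x / area_x

    def objective(params):
        shift, width = params[0], abs(params[1])
        pred = _shift_broaden(t_x, px_unit, t_tr, shift, width)
        return float(np.sum((pred - v_unit) ** 2))

    # coarse grid then simplex refinement
    shifts = np.arange(-30.0, 30.0 + 1e-9, frame_time)
    widths = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
    best = min(((objective((s, w)), s, w) for s in shifts for w in widths))
    res = minimize(objective, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 400})
    return float(res.x[0]), float(abs(res.x[1])), med


def _deconvolve_shift(trace, shift, width, t_out):
    """Undo the fitted delay and Gaussian broadening of a trace.

    Wiener-regularized Fourier deconvolution on the trace's uniform grid,
    then resampling onto ``t_out``.  Exact for Gaussian peaks, stable for
    anything smooth.
    """
    t_tr, v = trace[:, 0], trace[:, 1]
    dt = np.median(np.diff(t_tr))
    if width > 1e-9:
        n = len(v)
        freq = np.fft.rfftfreq(n, d=dt)
        H = np.exp(-2.0 * (np.pi * freq * width) ** 2)
        lam = 1e-6
        V = np.fft.rfft(v)
        v = np.fft.irfft(V * H / (H ** 2 + lam), n=n)
    return np.interp(t_out, t_tr - shift, v, left=v[0], right=v[-1])


def align_traces(run: SECRun) -> SECRun:
    """Align UV and dRI traces onto the X-ray frame time axis.

    Per trace, a time shift and a Gaussian broadening width are fitted by
    least squares between the unit-area trace and the unit-area X-ray
    elution profile; the inverse transform is applied and the corrected
    trace resampled at the frame times.  The fitted parameters are recorded
    in the run metadata.
    """
    prof_x = _peak_profile(run)
    if prof_x.max() <= 0:
        raise AlignmentError("no X-ray elution peak found")
    t_x = run.time_s
    out_traces = []
    fitted = {}
    for name, trace in (("uv", run.uv_trace), ("dri", run.dri_trace)):
        shift, width, baseline = _fit_trace(t_x, prof_x, trace,
                                            run.frame_time_s)
        base_removed = trace.copy()
        base_removed[:, 1] = trace[:, 1] - baseline
        v_aligned = _deconvolve_shift(base_removed, shift, width, t_x)
        out_traces.append(np.column_stack([t_x, v_aligned]))
        fitted[name] = {"shift_s": shift, "broadening_s": width,
                        "baseline": baseline}
    return SECRun(run.time_s, run.frames, out_traces[0], out_traces[1],
                  flow_rate_ml_min=run.flow_rate_ml_min,
                  frame_time_s=run.frame_time_s,
                  metadata=dict(run.metadata, trace_alignment=fitted))
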