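"""Automatic Guinier analysis and the Kratky transform.

At low q the scattering of a monodisperse particle follows
``ln I(q) = ln I0 - q^2 Rg^2 / 3``.  :func:`autorg` scans candidate fitting
windows, keeps those satisfying the validity bounds ``qmax*Rg <= 1.3``
(disordered-chain practice; compact particles usually use 1.3 as well) and
``qmin*Rg <= 0.8``, and returns the window maximizing length times fit
quality (``exp(-chi2_red)`` against measurement plus a small systematic
error floor) — a deterministic re-specification of ATSAS AUTORG-style
window selection that penalizes systematic Guinier curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve
from .errors import GuinierError

__all__ = ["GuinierResult", "autorg", "kratky"]

MIN_WINDOW = 6  # points


@dataclass
class GuinierResult:
    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    window: tuple
    qmin_Rg: float
    qmax_Rg: float
    fit_quality: float  # weighted R^2 of the linear fit

    def summary(self) -> str:
        return (f"Rg = {self.Rg:.2f} +/- {self.Rg_err:.2f} A   "
                f"I0 = {self.I0:.4g} +/- {self.I0_err:.2g}\n"
                f"window points {self.window}, qmin*Rg = {self.qmin_Rg:.2f}, "
                f"qmax*Rg = {self.qmax_Rg:.2f}, R^2 = {self.fit_quality:.4f}")


def _window_fits(x, y, w, i, j_arr):
    """Weighted LS of y = a + b x on windows [i, j] for a vector of j.

    Uses prefix sums so each window costs O(1).  Returns a, b, var_a, var_b,
    R2, ok, chi2red arrays aligned with j_arr, where chi2red is the reduced
    chi^2 of the fitted line evaluated over all points [0, j].
    """
    cums = {}

    def ps(key, v, lo):
        if key not in cums:
            cums[key] = np.concatenate([[0.0], np.cumsum(v)])
        return cums[key][j_arr + 1] - cums[key][lo]

    W = ps("w", w, i)
    Sx = ps("x", w * x, i)
    Sy = ps("y", w * y, i)
    Sxx = ps("xx", w * x * x, i)
    Sxy = ps("xy", w * x * y, i)
    Syy = ps("yy", w * y * y, i)
    n = (j_arr - i + 1).astype(float)
    xm = Sx / W
    ym = Sy / W
    sxx = Sxx - W * xm ** 2
    sxy = Sxy - W * xm * ym
    syy = Syy - W * ym ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        b = sxy / sxx
        a = ym - b * xm
        sse = np.maximum(syy - b * sxy, 0.0)
        r2 = np.where(syy > 0, 1.0 - sse / syy, 0.0)
        s2 = sse / np.maximum(n - 2, 1.0)
        var_b = s2 / sxx
        var_a = s2 * (1.0 / W + xm ** 2 / sxx)
        # quality is judged over [0, j]: the Guinier law holds ever better
        # toward q = 0, so a genuine window's line must also describe every
        # point below it; this vetoes short high-q windows whose small
        # fitted Rg would otherwise satisfy the qRg bounds
        W0 = ps("w", w, 0)
        Sx0 = ps("x", w * x, 0)
        Sy0 = ps("y", w * y, 0)
        Sxx0 = ps("xx", w * x * x, 0)
        Sxy0 = ps("xy", w * x * y, 0)
        Syy0 = ps("yy", w * y * y, 0)
        sse_full = (Syy0 - 2.0 * a * Sy0 - 2.0 * b * Sxy0
                    + a * a * W0 + 2.0 * a * b * Sx0 + b * b * Sxx0)
        chi2red = np.maximum(sse_full, 0.0) / (j_arr + 1.0)
    ok = sxx > 0
    return a, b, var_a, var_b, r2, ok, chi2red


def autorg(curve: ScatteringCurve, qmax_rg: float = 1.3,
           qmin_rg: float = 0.8, q_limit: float = 0.3,
           max_points: int = 400, sys_floor: float = 1e-3) -> GuinierResult:
    """Find the best Guinier window and return Rg, I0 with uncertainties.

    Only the contiguous run of positive intensities below ``q_limit`` is
    considered.  Window quality is ``exp(-chi2_red)`` against an effective
    log-intensity uncertainty ``sqrt((sigma/I)^2 + sys_floor^2)``: the
    ``sys_floor`` (default 0.1%, the practical limit of subtraction and
    calibration systematics) makes systematic curvature count against a
    window even for noiseless curves, which keeps the fit inside the truly
    linear Guinier region instead of stretching to the qRg bound.
    """
    mask = curve.q <= q_limit
    q = curve.q[mask][:max_points]
    I = curve.I[mask][:max_points]
    sigma = curve.sigma[mask][:max_points]
    pos = I > 0
    if not pos.any():
        raise GuinierError("no positive intensities at low q")
    # first contiguous positive stretch
    start = int(np.argmax(pos))
    end = start
    while end < len(I) and pos[end]:
        end += 1
    q, I, sigma = q[start:end], I[start:end], sigma[start:end]
    n = len(q)
    if n < MIN_WINDOW:
        raise GuinierError(f"only {n} usable low-q points")

    x = q ** 2
    y = np.log(I)
    # effective var(ln I) = (sigma/I)^2 + sys_floor^2; with these weights the
    # windowed SSE is directly a chi^2 against measurement + systematic error
    rel_var = np.where(sigma > 0, (sigma / I) ** 2, 0.0)
    w = 1.0 / (rel_var + sys_floor ** 2)

    best = None
    for i in range(0, n - MIN_WINDOW + 1):
        j_arr = np.arange(i + MIN_WINDOW - 1, n)
        a, b, var_a, var_b, r2, ok, chi2red = _window_fits(x, y, w, i, j_arr)
        with np.errstate(invalid="ignore"):
            rg = np.sqrt(np.maximum(-3.0 * b, 0.0))
        valid = ok & (b < 0) & (q[j_arr] * rg <= qmax_rg) & (q[i] * rg <= qmin_rg)
        if not valid.any():
            continue
        score = (j_arr - i + 1) * np.exp(-chi2red)
        score[~valid] = -np.inf
        k = int(np.argmax(score))
        # ties across i broken toward lower qmin (lower i), then longer windows
        key = (score[k], -i, j_arr[k] - i)
        if best is None or key > best[0]:
            best = (key, i, int(j_arr[k]), a[k], b[k], var_a[k], var_b[k],
                    r2[k], rg[k])
    if best is None:
        raise GuinierError("no window satisfies the qRg bounds")
    _, i, j, a, b, var_a, var_b, r2, rg = best
    rg_err = 3.0 * np.sqrt(var_b) / (2.0 * rg)
    i0 = float(np.exp(a))
    return GuinierResult(Rg=float(rg), Rg_err=float(rg_err), I0=i0,
                         I0_err=float(i0 * np.sqrt(var_a)),
                         window=(i, j),
                         qmin_Rg=float(q[i] * rg), qmax_Rg=float(q[j] * rg),
                         fit_quality=float(r2))


def kratky(curve: ScatteringCurve) -> ScatteringCurve:
    """Kratky transform (q, q^2 I); sigma scales with q^2.

    A compact globule shows a bell-shaped peak (at q = sqrt(3)/Rg in the
    Guinier regime); an expanded coil rises to a plateau without falling.
    """
    return ScatteringCurve(curve.q, curve.q ** 2 * curve.I,
                           curve.q ** 2 * curve.sigma,
                           absolute=False,
                           metadata=dict(curve.metadata, transform="kratky"))
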