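"""Per-frame elution analysis: Rg(t), I0(t), C(t) and aggregation number N(t).

Mirrors the standard SEC-SAXS QC panels: a flat Rg(t) and N(t) ~ 1 across
the peak indicate a monodisperse monomer; N(t) ~ 2 a dimer; for a mixture
the per-species concentrations from the UV/dRI pair reveal the molar ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import (SolutionConditions, aggregation_number,
                          solve_concentrations)
from .curves import SECRun
from .errors import GuinierError, SelectionError
from .guinier import autorg
from .reduction import average_frames, subtract_buffer

__all__ = ["ElutionSeries", "elution_profiles"]


@dataclass
class ElutionSeries:
    """Per-frame results table plus the QC flags.

    ``table`` columns: time_s, Rg, Rg_err, I0, I0_err, C (mg/ml), N, cA, cB
    (mol/l, two-species runs), flag (empty string = passed QC).
    """

    table: pd.DataFrame
    buffer_window: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def good(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == ""]

    def summary(self) -> str:
        g = self.good
        if not len(g):
            return "no frames passed QC"
        return (f"{len(g)}/{len(self.table)} frames pass QC; "
                f"apex Rg = {g.loc[g['I0'].idxmax(), 'Rg']:.1f} A, "
                f"median N = {g['N'].median():.2f}")


def _interp_trace(trace, t):
    return float(np.interp(t, trace[:, 0], trace[:, 1]))


def elution_profiles(run: SECRun, buffer_window: tuple, specs: list,
                     cond: SolutionConditions | None = None,
                     i0_threshold: float = 0.05) -> ElutionSeries:
    """Reduce every frame of an (aligned) run to Rg/I0/C/N profiles.

    ``buffer_window`` is a frame-index range (lo, hi) averaged into the
    background; it must not overlap the detected elution peak.  Frames whose
    buffer-subtracted signal is below ``i0_threshold`` times the apex, or
    whose Guinier fit fails, are flagged rather than dropped.

    With one species C(t) comes from the dRI trace alone; with two, the
    UV/dRI pair is solved per frame and C(t) is the summed mass
    concentration.
    """
    if cond is None:
        cond = SolutionConditions()
    lo, hi = buffer_window
    if not (0 <= lo < hi <= run.n_frames):
        raise SelectionError("buffer window outside the run")
    n_low = max(5, len(run.frames[0]) // 10)
    proxy = np.array([f.I[:n_low].mean() for f in run.frames])
    peak_idx = int(np.argmax(proxy))
    if lo <= peak_idx < hi:
        raise SelectionError("buffer window overlaps the elution peak")
    buffer_curve = average_frames(run.frames[lo:hi])

    two_species = len(specs) >= 2
    rows = []
    sub_apex = None
    subtracted = [subtract_buffer(f, buffer_curve) for f in run.frames]
    apex_signal = max(s.I[:n_low].mean() for s in subtracted)
    for k, s in enumerate(subtracted):
        t = run.time_s[k]
        row = {"time_s": t, "Rg": np.nan, "Rg_err": np.nan, "I0": np.nan,
               "I0_err": np.nan, "C": np.nan, "N": np.nan,
               "cA": np.nan, "cB": np.nan, "flag": ""}
        signal = s.I[:n_low].mean()
        if apex_signal <= 0 or signal < i0_threshold * apex_signal:
            row["flag"] = "low-signal"
            rows.append(row)
            continue
        try:
            g = autorg(s)
            row.update(Rg=g.Rg, Rg_err=g.Rg_err, I0=g.I0, I0_err=g.I0_err)
        except GuinierError as exc:
            row["flag"] = f"guinier:{exc}"
            rows.append(row)
            continue
        uv = _interp_trace(run.uv_trace, t)
        dn = _interp_trace(run.dri_trace, t)
        try:
            if two_species:
                cA, cB, _ = solve_concentrations(max(uv, 0.0), max(dn, 0.0),
                                                 specs[0], specs[1], cond)
                C = (cA * specs[0].M + cB * specs[1].M)      # g/l = mg/ml
                row.update(cA=cA, cB=cB, C=C)
            else:
                C = max(dn, 0.0) / specs[0].dndc * 1e3       # g/ml -> mg/ml
                row.update(C=C)
            if C > 0 and s.absolute:
                row["N"] = aggregation_number(g.I0, C, specs[0], cond)
        except Exception as exc:   # concentration failures flag, not break
            row["flag"] = f"composition:{exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    return ElutionSeries(table=table, buffer_window=buffer_window,
                         metadata={"peak_frame": peak_idx,
                                   "n_species": len(specs)})
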