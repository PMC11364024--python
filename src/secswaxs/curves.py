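"""Scattering-curve and SEC-run containers plus the three-column ``.dat`` dialect.

A :class:`ScatteringCurve` is the single reduced 1-D curve: an ascending
momentum-transfer grid ``q`` (1/Å), intensities ``I`` (arbitrary detector
units, or 1/cm once the ``absolute`` flag is set by water calibration) and
1-sigma uncertainties.  A :class:`SECRun` bundles the per-frame curves of one
size-exclusion elution with the synchronized UV absorbance and differential
refractive index (dRI) detector traces.

The ``.dat`` reader/writer follows the SASBDB/ATSAS dialect: ``#``- (or
text-) prefixed header lines, then 2 or 3 numeric columns (q, I[, sigma]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["ScatteringCurve", "SECRun", "read_dat", "write_dat",
           "read_traces_csv", "write_traces_csv"]


@dataclass
class ScatteringCurve:
    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    absolute: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I and sigma must have equal length")
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self):
        return len(self.q)

    def copy(self, **changes) -> "ScatteringCurve":
        out = replace(self, **changes)
        out.metadata = dict(self.metadata, **changes.get("metadata", {}))
        return out

    def crop(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringCurve":
        m = (self.q >= qmin) & (self.q <= qmax)
        return ScatteringCurve(self.q[m], self.I[m], self.sigma[m],
                               absolute=self.absolute, metadata=dict(self.metadata))


@dataclass
class SECRun:
    """One elution: frame timestamps, per-frame curves, optical traces.

    ``uv_trace`` and ``dri_trace`` are ``(time_s, signal)`` arrays of shape
    (n, 2); UV in OD at 214 nm, dRI in refractive-index units.
    """

    time_s: np.ndarray
    frames: list
    uv_trace: np.ndarray
    dri_trace: np.ndarray
    flow_rate_ml_min: float = 0.35
    frame_time_s: float = 2.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.uv_trace = np.asarray(self.uv_trace, dtype=float)
        self.dri_trace = np.asarray(self.dri_trace, dtype=float)
        if len(self.time_s) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.time_s) > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def read_dat(path) -> ScatteringCurve:
    """Read a SASBDB/ATSAS-style column file.

    Two-column files are accepted with all-zero sigma (a warning is issued,
    as the uncertainties are then unusable for weighting).
    """
    header = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header.append(stripped.lstrip("# "))
                continue
            parts = stripped.split()
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                # Tolerate non-numeric preamble before any data row
                if not rows:
                    header.append(stripped)
                    continue
                raise ParseError(f"{path}: non-numeric data at line {lineno}")
            if len(vals) < 2:
                raise ParseError(f"{path}: fewer than 2 columns at line {lineno}")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no numeric data found")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    if ncol == 2:
        warnings.warn(f"{path}: 2-column file, sigma set to zero")
        sigma = np.zeros(len(arr))
    else:
        sigma = arr[:, 2]
    meta = {"path": str(path)}
    if header:
        meta["header"] = header
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, metadata=meta)


def write_dat(curve: ScatteringCurve, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        unit = "1/cm" if curve.absolute else "arb"
        fh.write(f"# q(1/A)  I({unit})  sigma\n")
        for q, i, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.8e} {i:.8e} {s:.8e}\n")


def write_traces_csv(run: SECRun, path) -> None:
    """Write the UV/dRI traces on their native (possibly distinct) time axes."""
    t_uv, v_uv = run.uv_trace[:, 0], run.uv_trace[:, 1]
    t_ri, v_ri = run.dri_trace[:, 0], run.dri_trace[:, 1]
    if len(t_uv) == len(t_ri) and np.allclose(t_uv, t_ri):
        df = pd.DataFrame({"time_s": t_uv, "uv_au": v_uv, "dri_riu": v_ri})
    else:
        df = pd.concat([
            pd.DataFrame({"time_s": t_uv, "uv_au": v_uv}),
            pd.DataFrame({"time_s": t_ri, "dri_riu": v_ri}),
        ])
    df.to_csv(path, index=False)


def read_traces_csv(path):
    """Return ``(uv_trace, dri_trace)`` arrays from a traces CSV."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing time_s column")
    uv = df.dropna(subset=["uv_au"])[["time_s", "uv_au"]].to_numpy() \
        if "uv_au" in df.columns else None
    ri = df.dropna(subset=["dri_riu"])[["time_s", "dri_riu"]].to_numpy() \
        if "dri_riu" in df.columns else None
    if uv is None or ri is None:
        raise ParseError(f"{path}: need uv_au and dri_riu columns")
    return uv, ri
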