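"""Synthetic SEC-SWAXS elutions with exact ground truth.

The generator is the exact forward model of the analysis chain: a Gaussian
elution peak of a single complex species, Beer-Lambert UV and mass-weighted
dRI responses (with inter-detector delay and broadening), and per-frame
scattering ``I(q,t) = n0(t) (f_t - rho_w V_t)^2 P(q) + background`` with the
complex form factor P(q) from a coarse atomic model via the Debye sum.
Because every stage of the reduction/composition pipeline inverts one piece
of this model, a noiseless synthetic run is recoverable exactly.

The coil chain generator is a self-avoiding random walk, not a physical
ensemble — it only needs to produce form factors with realistic Rg, not
Boltzmann statistics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .atoms import AtomicModel
from .composition import (SolutionConditions, SpeciesSpec, forward_signals)
from .curves import ScatteringCurve, SECRun, write_dat, write_traces_csv
from .debye import debye_intensity
from .errors import GenerationError
from .residues import RESIDUE_ELECTRONS

__all__ = ["GroundTruth", "make_chain", "simulate_sec_run", "write_run_dir",
           "complex_model"]

STEP_LENGTH = 3.8       # A, virtual C-alpha bond
MIN_SEPARATION = 3.5    # A, non-bonded excluded distance
HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # A


@dataclass
class GroundTruth:
    """Generator parameters; everything the analysis should recover.

    ``derived`` is filled by :func:`simulate_sec_run` with the exact
    (pre-noise, pre-delay) signals: apex I0/UV/dRI, per-frame concentration
    profile, the buffer level and the complex form factor.
    """

    species_ids: list
    stoich: tuple = (1, 0)
    peak_center_s: float = 240.0
    peak_sigma_s: float = 30.0
    c_max: float = 0.25                 # mg/ml at the apex
    dilution_factor: float = 3.0        # injection-to-apex dilution
    uv_delay_s: float = 0.0             # UV cell at the X-ray capillary
    dri_delay_s: float = 5.0            # ~40 cm downstream at 0.35 ml/min
    dri_broadening_s: float = 2.0
    noise_scale: float = 0.0
    seed: int = 0
    frame_time_s: float = 2.0
    buffer_level: float = 0.0162        # flat water-level background, 1/cm
    derived: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.peak_sigma_s <= 0:
            raise ValueError("peak_sigma_s must be positive")
        if self.c_max < 0:
            raise ValueError("c_max must be non-negative")
        n_a, n_b = self.stoich
        if n_a < 0 or n_b < 0 or n_a + n_b < 1:
            raise ValueError("stoichiometry must have N_A,N_B >= 0 and "
                             "N_A+N_B >= 1")


def _electron_counts(n_residues: int, sequence: str | None) -> np.ndarray:
    if sequence is None:
        return np.full(n_residues, 60.0)  # ~average residue
    if len(sequence) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    return np.array([RESIDUE_ELECTRONS[a] for a in sequence.upper()],
                    dtype=float)


def make_chain(n_residues: int, mode: str = "coil", seed: int = 0,
               sequence: str | None = None) -> AtomicModel:
    """One pseudo-atom (C-alpha level) chain model.

    ``coil`` is a self-avoiding random walk with 3.8 A steps and a 3.5 A
    non-bonded exclusion; ``helix`` is an ideal alpha-helix (1.5 A rise,
    100 deg twist, 2.3 A radius).  Each bead carries the residue's full
    electron count so scattering operations apply unchanged.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if mode not in ("coil", "helix"):
        raise ValueError(f"unknown chain mode {mode!r}")
    if mode == "helix":
        i = np.arange(n_residues)
        ang = np.deg2rad(HELIX_TWIST) * i
        coords = np.column_stack([HELIX_RADIUS * np.cos(ang),
                                  HELIX_RADIUS * np.sin(ang),
                                  HELIX_RISE * i])
    else:
        rng = np.random.default_rng(seed)
        coords = None
        for _restart in range(30):
            pts = [np.zeros(3)]
            failed = False
            for _ in range(n_residues - 1):
                for _attempt in range(60):
                    v = rng.normal(size=3)
                    v *= STEP_LENGTH / np.linalg.norm(v)
                    cand = pts[-1] + v
                    if len(pts) < 2:
                        break
                    d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                    if np.all(d >= MIN_SEPARATION):
                        break
                else:
                    failed = True
                    break
                pts.append(cand)
            if not failed:
                coords = np.array(pts)
                break
        if coords is None:
            raise GenerationError(
                f"self-avoiding walk failed for n={n_residues}, seed={seed}")
    return AtomicModel(coords,
                       elements=np.array(["X"] * n_residues, dtype=object),
                       residue_index=np.arange(n_residues),
                       electron_counts=_electron_counts(n_residues, sequence),
                       metadata={"mode": mode, "seed": seed})


def complex_model(specs: list, stoich: tuple, seed: int = 0,
                  mode: str = "coil") -> AtomicModel:
    """Assemble N_A + N_B coil chains into one touching, non-overlapping blob."""
    chains = []
    sub = 0
    for spec, copies in zip(specs, stoich):
        for _ in range(copies):
            chains.append(make_chain(len(spec.sequence), mode=mode,
                                     seed=seed * 1000 + sub,
                                     sequence=spec.sequence))
            sub += 1
    placed, offset_x = [], 0.0
    for k, ch in enumerate(chains):
        com = ch.coords.mean(axis=0)
        radius = np.linalg.norm(ch.coords - com, axis=1).max()
        if k == 0:
            offset_x = 0.0
            prev_r = radius
        else:
            offset_x += prev_r + radius + 2.0
            prev_r = radius
        placed.append(ch.coords - com + np.array([offset_x, 0.0, 0.0]))
    coords = np.vstack(placed)
    counts = np.concatenate([c.electron_counts for c in chains])
    return AtomicModel(coords,
                       elements=np.array(["X"] * len(coords), dtype=object),
                       residue_index=np.concatenate(
                           [c.residue_index for c in chains]),
                       electron_counts=counts,
                       metadata={"n_chains": len(chains), "seed": seed})


def simulate_sec_run(specs: list, truth: GroundTruth,
                     cond: SolutionConditions | None = None,
                     q_grid: np.ndarray | None = None,
                     model: AtomicModel | None = None):
    """Generate a full SEC-SWAXS run; returns ``(SECRun, GroundTruth)``.

    The returned truth object is the input one with ``derived`` populated:
    exact apex channel values, per-frame concentration and I0 profiles, the
    complex form factor and the buffer level.  Identical inputs (including
    seed) give bit-identical output.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if cond is None:
        cond = SolutionConditions()
    if q_grid is None:
        q_grid = np.linspace(0.008, 0.35, 150)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be strictly increasing")
    for s in specs:
        if min(s.eps214, s.dndc) <= 0:
            raise ValueError("optical constants must be positive")
    N_A, N_B = truth.stoich
    specA = specs[0]
    specB = specs[1] if len(specs) > 1 else None
    if N_B > 0 and specB is None:
        raise ValueError("stoichiometry includes B but only one species given")

    rng = np.random.default_rng(truth.seed)
    if model is None:
        model = complex_model(specs, truth.stoich, seed=truth.seed)
    P = debye_intensity(model.coords, model.electron_weights(), q_grid)
    P = P / P[0] if P[0] > 0 else P

    # frame time axis: apex exactly on-grid, +/- 8 sigma span
    half = truth.frame_time_s * np.ceil(8 * truth.peak_sigma_s
                                        / truth.frame_time_s)
    t = np.arange(truth.peak_center_s - half, truth.peak_center_s + half
                  + 0.5 * truth.frame_time_s, truth.frame_time_s)

    gauss = np.exp(-0.5 * ((t - truth.peak_center_s) / truth.peak_sigma_s) ** 2)
    C_t = truth.c_max * gauss                                   # mg/ml
    apex = forward_signals(N_A, N_B, truth.c_max, specA, specB, cond) \
        if truth.c_max > 0 else {"I0": 0.0, "A214": 0.0, "dn": 0.0,
                                 "cA": 0.0, "cB": 0.0, "n0": 0.0}
    I0_t = apex["I0"] * gauss

    frames = []
    for k in range(len(t)):
        I = I0_t[k] * P + truth.buffer_level
        sigma = truth.noise_scale * np.sqrt(np.maximum(I, 0.0)
                                            * truth.buffer_level)
        noisy = I + rng.normal(size=len(I)) * sigma if truth.noise_scale > 0 \
            else I
        frames.append(ScatteringCurve(q_grid, noisy, sigma, absolute=True,
                                      metadata={"time_s": float(t[k])}))

    # optical traces on a finer axis; Gaussian peaks stay Gaussian under the
    # detector delay and broadening, so the transform is applied analytically
    t_tr = np.arange(t[0] - 30.0, t[-1] + 30.0, 0.5)

    def trace(apex_val, delay, broaden):
        s_eff = np.sqrt(truth.peak_sigma_s ** 2 + broaden ** 2)
        amp = apex_val * truth.peak_sigma_s / s_eff
        v = amp * np.exp(-0.5 * ((t_tr - truth.peak_center_s - delay)
                                 / s_eff) ** 2)
        if truth.noise_scale > 0 and apex_val > 0:
            v = v + rng.normal(size=len(v)) * truth.noise_scale * 0.01 * apex_val
        return np.column_stack([t_tr, v])

    uv = trace(apex["A214"], truth.uv_delay_s, 0.0)
    dri = trace(apex["dn"], truth.dri_delay_s, truth.dri_broadening_s)

    run = SECRun(t, frames, uv, dri, frame_time_s=truth.frame_time_s,
                 metadata={"synthetic": True, "seed": truth.seed})
    truth.derived = {
        "apex": apex,
        "c_profile": C_t,
        "i0_profile": I0_t,
        "time_s": t,
        "form_factor": P,
        "q_grid": q_grid,
        "buffer_level": truth.buffer_level,
        "model_rg": model.rg(),
        "conditions": {"L": cond.L, "rho_w": cond.rho_w},
    }
    return run, truth


def write_run_dir(run: SECRun, truth: GroundTruth, directory) -> None:
    """Write one .dat per frame plus traces.csv and truth.json."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(run.frames):
        write_dat(frame, d / f"frame_{k:04d}.dat",
                  comment=f"t = {run.time_s[k]:.1f} s")
    write_traces_csv(run, d / "traces.csv")
    payload = asdict(truth)
    payload["derived"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                          for k, v in truth.derived.items()
                          if k not in ("model",)}
    payload["derived"].pop("q_grid", None)
    with open(d / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
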