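"""End-to-end orchestration: simulate/load -> reduce -> elution -> composition.

A :class:`RunConfig` (YAML-serializable, every field defaulted) drives
:func:`run_full_analysis`, which writes machine-readable outputs (per-frame
elution CSV, stoichiometry JSON, provenance log) into a run directory.
Deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .composition import SolutionConditions, solve_concentrations, \
    solve_stoichiometry
from .curves import SECRun, read_dat, read_traces_csv
from .elution import elution_profiles
from .errors import SecSwaxsError
from .reduction import align_traces
from .species_data import builtin_species
from .synthetic import GroundTruth, simulate_sec_run, write_run_dir

log = logging.getLogger("secswaxs")

__all__ = ["RunConfig", "run_full_analysis", "read_run_dir"]


@dataclass
class RunConfig:
    input_dir: str | None = None        # None -> simulate
    output_dir: str = "secswaxs_run"
    species: list = field(default_factory=lambda: ["SERF1a", "NT17"])
    stoich: tuple = (1, 2)
    c_max: float = 0.25
    noise_scale: float = 0.0
    seed: int = 0
    buffer_frames: tuple = (0, 10)
    qmax_rg: float = 1.3
    similarity_p: float = 0.01
    path_length_cm: float = 0.2
    rho_w: float = 9.42e10
    fit_pdbs: list = field(default_factory=list)
    nsd_pdbs: list = field(default_factory=list)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.stoich = tuple(cfg.stoich)
        cfg.buffer_frames = tuple(cfg.buffer_frames)
        return cfg

    def resolve_species(self):
        out = []
        for s in self.species:
            if isinstance(s, str):
                out.append(builtin_species(s))
            else:
                from .composition import SpeciesSpec, species_from_sequence
                if "M" in s:
                    out.append(SpeciesSpec(**s))
                else:
                    spec = species_from_sequence(s["name"], s["sequence"],
                                                 s["eps214"], s["dndc"])
                    if "V" in s:
                        spec.V = s["V"]
                    out.append(spec)
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def read_run_dir(directory) -> SECRun:
    """Load a run directory written by :func:`~secswaxs.synthetic.write_run_dir`."""
    d = Path(directory)
    if not d.is_dir():
        raise SecSwaxsError(f"input directory not found: {d}")
    paths = sorted(d.glob("frame_*.dat"))
    if not paths:
        raise SecSwaxsError(f"no frame_*.dat files in {d}")
    frames = [read_dat(p) for p in paths]
    for f in frames:
        f.absolute = True
    uv, dri = read_traces_csv(d / "traces.csv")
    times = []
    for k, f in enumerate(frames):
        header = " ".join(f.metadata.get("header", []))
        t = None
        for tok in header.replace("=", " ").split():
            try:
                t = float(tok)
                break
            except ValueError:
                continue
        times.append(t if t is not None else float(k))
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float)
    frame_time = float(np.median(np.diff(times))) if len(times) > 1 else 2.0
    return SECRun(times, frames, uv, dri, frame_time_s=frame_time)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the pipeline; returns the report bundle as a dict.

    Outputs written to ``config.output_dir``: ``elution.csv``,
    ``stoichiometry.json``, ``provenance.json`` (plus ``simulated/`` when
    the input is synthetic).  Stage failures raise with the stage name;
    partial outputs are kept.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = config.resolve_species()
    cond = SolutionConditions(L=config.path_length_cm, rho_w=config.rho_w)
    report = {"config_digest": config.digest(), "version": __version__,
              "seed": config.seed}

    stage = "input"
    try:
        if config.input_dir is None:
            truth = GroundTruth(species_ids=[s.name for s in specs],
                                stoich=tuple(config.stoich),
                                c_max=config.c_max,
                                noise_scale=config.noise_scale,
                                seed=config.seed)
            run, truth = simulate_sec_run(specs, truth, cond)
            write_run_dir(run, truth, out / "simulated")
            report["simulated"] = True
            log.info("simulated %d frames", run.n_frames)
        else:
            run = read_run_dir(config.input_dir)
            report["simulated"] = False

        stage = "alignment"
        run = align_traces(run)
        report["trace_alignment"] = run.metadata.get("trace_alignment")

        stage = "elution"
        series = elution_profiles(run, config.buffer_frames, specs, cond)
        series.table.to_csv(out / "elution.csv", index=False)
        report["n_frames"] = int(run.n_frames)
        report["n_good_frames"] = int(len(series.good))

        stage = "composition"
        good = series.good
        if len(good) and len(specs) >= 2:
            apex = good.loc[good["I0"].idxmax()]
            cA, cB, diag = solve_concentrations(
                max(float(np.interp(apex["time_s"], run.uv_trace[:, 0],
                                    run.uv_trace[:, 1])), 0.0),
                max(float(np.interp(apex["time_s"], run.dri_trace[:, 0],
                                    run.dri_trace[:, 1])), 0.0),
                specs[0], specs[1], cond)
            result = solve_stoichiometry(float(apex["I0"]), cA, cB,
                                         specs[0], specs[1], cond)
            stoich_payload = {
                "N_A": result.N_A, "N_B": result.N_B,
                "chi_BA": result.chi_BA, "n0_per_cm3": result.n0,
                "C_mg_ml": result.C, "M_t": result.M_t,
                "phi_A": result.phi_A, "phi_B": result.phi_B,
                "I0_misfit": result.residuals["I0"],
                "condition_number": diag["condition_number"],
            }
            with open(out / "stoichiometry.json", "w") as fh:
                json.dump(stoich_payload, fh, indent=1)
            report["stoichiometry"] = stoich_payload
        elif len(good):
            report["median_N"] = float(good["N"].median())

        stage = "fit"
        if config.fit_pdbs:
            from .atoms import load_pdb
            from .debye import fit_profile
            # fit against the averaged apex curve
            from .reduction import average_frames, subtract_buffer
            buf = average_frames(
                run.frames[config.buffer_frames[0]:config.buffer_frames[1]])
            apex_idx = int(good["I0"].idxmax())
            data = subtract_buffer(run.frames[apex_idx], buf)
            fits = {}
            for p in config.fit_pdbs:
                fr = fit_profile(load_pdb(p), data)
                fits[str(p)] = {"chi2": fr.chi2, "scale": fr.scale,
                                "r0_adjust": fr.r0_adjust,
                                "drho_shell": fr.drho_shell}
            with open(out / "fits.json", "w") as fh:
                json.dump(fits, fh, indent=1)
            report["fits"] = fits

        stage = "nsd"
        if config.nsd_pdbs:
            from .atoms import load_pdb
            from .nsd import ensemble_nsd
            res = ensemble_nsd([load_pdb(p) for p in config.nsd_pdbs])
            payload = {"value": res.value, "converged": res.converged,
                       "n_models": res.n_models,
                       "pairwise": res.pairwise.tolist()}
            with open(out / "nsd.json", "w") as fh:
                json.dump(payload, fh, indent=1)
            report["nsd"] = payload
    except SecSwaxsError as exc:
        raise SecSwaxsError(f"stage {stage!r} failed: {exc}") from exc

    report["elapsed_s"] = round(time.time() - t_start, 3)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
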