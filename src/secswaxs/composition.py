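"""Complex stoichiometry from the triple detector readout (I0, UV214, dRI).

For a two-component complex A:B eluting as a single species, three
simultaneously measured channels determine the composition analytically:

* UV absorbance at 214 nm (Beer-Lambert):  ``A214 = L (eps_A cA + eps_B cB)``
* differential refractive index:           ``dn = (dn/dc)_A wA + (dn/dc)_B wB``
  with ``w = M c`` the mass concentrations,
* absolute zero-angle X-ray intensity:     ``I0 = n0 (f_t - rho_w V_t)^2``

where ``n0 = C N_Av / M_t`` is the complex number density, ``f_t = (N_A E_A +
N_B E_B) f_e`` the total X-ray scattering length, and ``V_t = N_A V_A + N_B
V_B`` the solvent-displaced volume.  The UV/dRI pair yields the molar
concentrations ``cA, cB`` and hence the association ratio ``chi_BA = cB/cA``;
scanning integer ``N_A`` with ``N_B = round(chi_BA N_A)`` and selecting the
pair whose predicted I0 best matches the measured one resolves the absolute
stoichiometry, because the predicted I0 scales linearly with ``N_A`` at fixed
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as sc

from . import residues
from .errors import IllConditionedError, StoichiometryError

__all__ = ["SpeciesSpec", "SolutionConditions", "StoichiometryResult",
           "species_from_sequence", "solve_concentrations",
           "solve_stoichiometry", "aggregation_number"]

#: Thomson scattering length of the electron, in cm (2.8179e-5 Å).
F_E_CM = 2.8179e-13
F_E_A = 2.8179e-5
N_AVOGADRO = sc.Avogadro


@dataclass
class SpeciesSpec:
    """One molecular species and its detector response constants.

    M in g/mol, E in electrons/molecule, V in cubic angstroms (Jacrot sum),
    eps214 in 1/(M cm), dndc in ml/g.
    """

    name: str
    sequence: str
    M: float
    E: float
    V: float
    eps214: float
    dndc: float

    def __post_init__(self):
        if min(self.M, self.E, self.V, self.eps214) <= 0:
            raise ValueError("M, E, V and eps214 must be positive")
        if not (0.1 < self.dndc < 0.3):
            warnings.warn(
                f"{self.name}: dn/dc = {self.dndc} ml/g outside the usual "
                "0.1-0.3 ml/g window for peptides")
        if self.sequence:
            n = len(self.sequence)
            # Plausibility guard: ~110 Da and ~60 electrons per residue.
            if not (60 * n < self.M < 200 * n):
                warnings.warn(f"{self.name}: M inconsistent with sequence length")

    def excess_length_cm(self, rho_w: float) -> float:
        """Per-molecule excess scattering length E*f_e - rho_w*V, in cm."""
        return self.E * F_E_CM - rho_w * self.V * 1e-24


@dataclass
class SolutionConditions:
    """Capillary path length and buffer contrast constants.

    L: cm (2 mm capillary -> 0.2 cm).  rho_w: buffer scattering length
    density in 1/cm^2 (water electron density 0.3342 e/A^3 times f_e).
    """

    L: float = 0.2
    rho_w: float = 9.42e10

    def __post_init__(self):
        if self.L <= 0 or self.rho_w <= 0:
            raise ValueError("L and rho_w must be positive")


@dataclass
class StoichiometryResult:
    N_A: int
    N_B: int
    n0: float                 # complexes per cm^3
    chi_BA: float             # molar ratio cB/cA before integer rounding
    C: float                  # complex mass concentration, mg/ml
    M_t: float                # complex molar mass, g/mol
    phi_A: float
    phi_B: float
    f_t: float                # total scattering length, cm
    V_t: float                # complex volume, A^3
    residuals: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"stoichiometry  N_A={self.N_A}  N_B={self.N_B}  "
            f"(chi_BA={self.chi_BA:.3f})",
            f"M_t = {self.M_t:.1f} g/mol   C = {self.C:.4g} mg/ml   "
            f"n0 = {self.n0:.4g} /cm^3",
            f"phi_A = {self.phi_A:.3f}  phi_B = {self.phi_B:.3f}   "
            f"V_t = {self.V_t:.0f} A^3",
            f"I0 relative misfit = {self.residuals.get('I0', float('nan')):.3g}",
        ]
        return "\n".join(lines)


def species_from_sequence(name: str, sequence: str, eps214: float,
                          dndc: float) -> SpeciesSpec:
    """Build a :class:`SpeciesSpec` with M, E and V computed from sequence.

    M is the average-mass sum minus (n-1) waters (i.e. residue masses plus
    one terminal water), E the electron sum for the neutral chain, V the
    Jacrot (1976) residue-volume sum.
    """
    seq = residues.validate_sequence(sequence)
    return SpeciesSpec(
        name=name,
        sequence=seq,
        M=residues.chain_mass(seq),
        E=residues.chain_electrons(seq),
        V=residues.chain_volume(seq),
        eps214=eps214,
        dndc=dndc,
    )


def forward_signals(N_A: int, N_B: int, C_mg_ml: float, specA: SpeciesSpec,
                    specB: SpeciesSpec | None,
                    cond: SolutionConditions) -> dict:
    """Noise-free detector readout for a complex at mass concentration C.

    The exact forward model the solver inverts; the synthetic generator and
    the round-trip tests share this single implementation.
    Returns I0 (1/cm), A214 (OD), dn (RIU), cA/cB (mol/l) and n0 (1/cm^3).
    """
    if specB is None:
        if N_B:
            raise ValueError("N_B > 0 requires a B species")
        M_B = E_B = V_B = eps_B = dndc_B = 0.0
    else:
        M_B, E_B, V_B = specB.M, specB.E, specB.V
        eps_B, dndc_B = specB.eps214, specB.dndc
    M_t = N_A * specA.M + N_B * M_B
    V_t = N_A * specA.V + N_B * V_B
    f_t = (N_A * specA.E + N_B * E_B) * F_E_CM
    n0 = 1e-3 * C_mg_ml * N_AVOGADRO / M_t          # 1/cm^3
    cA = N_A * n0 * 1e3 / N_AVOGADRO                # mol/l
    cB = N_B * n0 * 1e3 / N_AVOGADRO
    delta_f = f_t - cond.rho_w * V_t * 1e-24
    I0 = n0 * delta_f ** 2
    A214 = cond.L * (specA.eps214 * cA + eps_B * cB)
    dn = (specA.dndc * specA.M * cA + dndc_B * M_B * cB) / 1e3
    return {"I0": I0, "A214": A214, "dn": dn, "cA": cA, "cB": cB,
            "n0": n0, "M_t": M_t, "V_t": V_t, "f_t": f_t, "delta_f": delta_f}


def solve_concentrations(A214: float, dn: float, specA: SpeciesSpec,
                         specB: SpeciesSpec, cond: SolutionConditions,
                         noise_sigma: tuple = (0.0, 0.0)):
    """Invert the 2x2 UV/dRI linear system for molar concentrations.

    Returns ``(cA, cB, diagnostics)`` with concentrations in mol/l.  Small
    negative solutions (within 2 sigma of zero, per ``noise_sigma`` expressed
    in concentration units) are clamped to zero with a warning; larger
    negativity raises.
    """
    if A214 < 0 or dn < 0:
        raise ValueError("A214 and dn must be non-negative")
    mat = np.array([
        [cond.L * specA.eps214, cond.L * specB.eps214],
        [specA.dndc * specA.M / 1e3, specB.dndc * specB.M / 1e3],
    ])
    cond_number = np.linalg.cond(mat)
    if cond_number > 1e6:
        raise IllConditionedError(
            "UV and dRI responses are collinear for these species "
            f"(condition number {cond_number:.3g})")
    c = np.linalg.solve(mat, np.array([A214, dn]))
    tol = 2.0 * np.asarray(noise_sigma, dtype=float)
    for k in range(2):
        if c[k] < 0:
            if -c[k] <= max(tol[k], 1e-12 * (abs(c[0]) + abs(c[1]))):
                warnings.warn("negative concentration within noise, clamped to 0")
                c[k] = 0.0
            else:
                raise ValueError(
                    f"solved concentration {k} is negative beyond noise: {c[k]}")
    diag = {"condition_number": cond_number}
    return float(c[0]), float(c[1]), diag


def solve_stoichiometry(I0: float, cA: float, cB: float, specA: SpeciesSpec,
                        specB: SpeciesSpec | None,
                        cond: SolutionConditions | None = None,
                        N_max: int = 6,
                        misfit_tol: float = 0.30) -> StoichiometryResult:
    """Resolve (N_A, N_B, n0) from absolute I0 and molar concentrations.

    Scans N_A = 1..N_max with N_B fixed by the measured association ratio,
    predicts I0 for each candidate and keeps the best; raises
    :class:`StoichiometryError` with the misfit table when no candidate comes
    within ``misfit_tol`` relative.
    """
    if cond is None:
        cond = SolutionConditions()
    if cA <= 0:
        raise ValueError("cA must be positive (A defined as the host species)")
    if I0 < 0:
        raise ValueError("I0 must be non-negative")
    chi = cB / cA
    misfits = {}
    best = None
    for N_A in range(1, N_max + 1):
        N_B = int(round(chi * N_A)) if specB is not None else 0
        n0 = cA * N_AVOGADRO / 1e3 / N_A              # 1/cm^3
        E_B = specB.E if specB is not None else 0.0
        V_B = specB.V if specB is not None else 0.0
        f_t = (N_A * specA.E + N_B * E_B) * F_E_CM
        V_t = N_A * specA.V + N_B * V_B
        delta_f = f_t - cond.rho_w * V_t * 1e-24
        I0_pred = n0 * delta_f ** 2
        misfit = abs(I0_pred - I0) / I0 if I0 > 0 else np.inf
        misfits[(N_A, N_B)] = misfit
        if best is None or misfit < best[0]:
            best = (misfit, N_A, N_B, n0, f_t, V_t)
    misfit, N_A, N_B, n0, f_t, V_t = best
    if misfit > misfit_tol:
        raise StoichiometryError(
            f"best integer stoichiometry misfits I0 by {misfit:.1%}",
            misfits=misfits)
    M_B = specB.M if specB is not None else 0.0
    M_t = N_A * specA.M + N_B * M_B
    C = n0 * M_t / N_AVOGADRO * 1e3                   # mg/ml
    return StoichiometryResult(
        N_A=N_A, N_B=N_B, n0=n0, chi_BA=chi, C=C, M_t=M_t,
        phi_A=N_A * specA.M / M_t, phi_B=N_B * M_B / M_t,
        f_t=f_t, V_t=V_t,
        residuals={"I0": misfit},
        diagnostics={"misfit_table": misfits, "N_max": N_max},
    )


def aggregation_number(I0: float, C_mg_ml: float, spec: SpeciesSpec,
                       cond: SolutionConditions | None = None) -> float:
    """Observed particle mass over monomer mass, from I0/C.

    ``N = I0_observed / I0_monomer(C)`` where the denominator is the forward
    prediction for monomers at the same mass concentration.  A rigid dimer
    doubles the excess scattering length while halving the number density,
    hence N = 2.
    """
    if cond is None:
        cond = SolutionConditions()
    if C_mg_ml <= 0:
        raise ValueError("C must be positive")
    if I0 == 0:
        return 0.0
    I0_monomer = forward_signals(1, 0, C_mg_ml, spec, None, cond)["I0"]
    return I0 / I0_monomer
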