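"""Debye engine: form factors, grouped sums, profile fitting, scoring."""

import numpy as np
import pytest

from secswaxs.atoms import AtomicModel
from secswaxs.curves import ScatteringCurve
from secswaxs.debye import (DebyeCalculator, atomic_form_factor,
                            debye_intensity, fit_profile,
                            hydration_shell_beads, score_term,
                            theoretical_profile)
from secswaxs.composition import F_E_CM
from secswaxs.errors import FitError, SizeError
from secswaxs.synthetic import make_chain

Q = np.linspace(0.01, 0.7, 60)


def _atomic_model(n=40, seed=0, spread=6.0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, spread, (n, 3))
    elements = np.array((["C", "N", "O", "C", "S"] * ((n + 4) // 5))[:n],
                        dtype=object)
    hyd = np.array(([1, 1, 0, 2, 0] * ((n + 4) // 5))[:n])
    return AtomicModel(coords=coords, elements=elements, hydrogens=hyd,
                       residue_index=np.arange(n) // 4)


class TestFormFactors:
    @pytest.mark.parametrize("elem,z", [("H", 1), ("C", 6), ("N", 7),
                                        ("O", 8), ("S", 16), ("P", 15)])
    def test_f0_equals_electron_count(self, elem, z):
        assert atomic_form_factor(elem, np.array([0.0]))[0] == \
            pytest.approx(z, abs=0.05)

    def test_monotone_decay(self):
        f = atomic_form_factor("C", np.linspace(0, 2, 50))
        assert np.all(np.diff(f) < 0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            atomic_form_factor("Au", Q)


class TestDebyeSum:
    def test_grouped_equals_naive_oracle(self):
        """Grouped-cache evaluation == brute-force double loop to 1e-12."""
        m = _atomic_model(30)
        calc = DebyeCalculator(m, Q, with_shell=False)
        I_grouped = calc.intensity(1.0, 0.0)
        # independent naive double loop with the same amplitude definition
        amps = calc._group_amplitudes(1.0, 0.0)
        g = np.empty((len(m), len(Q)))
        for a, idx in enumerate(calc._group_idx):
            for i in idx:
                g[i] = amps[a]
        naive = np.zeros(len(Q))
        for i in range(len(m)):
            for j in range(len(m)):
                r = np.linalg.norm(m.coords[i] - m.coords[j])
                s = np.ones(len(Q)) if r == 0 else np.sin(Q * r) / (Q * r)
                naive += g[i] * g[j] * s
        naive *= F_E_CM ** 2
        np.testing.assert_allclose(I_grouped, naive, rtol=1e-12)

    def test_i0_identity(self):
        """I(0) equals the squared total excess scattering length to 1e-8."""
        m = _atomic_model(25)
        q = np.array([0.0, 0.01])
        calc = DebyeCalculator(m, q, with_shell=True)
        I = calc.intensity(1.0, 0.02)
        f_tot = calc.total_excess_length(1.0, 0.02)
        assert I[0] == pytest.approx(f_tot ** 2, rel=1e-8)

    def test_rotation_invariance(self):
        m = _atomic_model(30)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [31, 57, -12], degrees=True).as_matrix()
        I1 = DebyeCalculator(m, Q, with_shell=False).intensity()
        I2 = DebyeCalculator(m.transformed(rotation=R, translation=(4, -2, 7)),
                             Q, with_shell=False).intensity()
        np.testing.assert_allclose(I1, I2, rtol=1e-10)

    def test_coarse_bead_weights(self):
        m = make_chain(20, mode="helix", sequence="G" * 20)
        I = debye_intensity(m.coords, m.electron_weights(), np.array([0.0]))
        assert I[0] == pytest.approx((20 * 30) ** 2, rel=1e-12)

    def test_size_limit(self):
        coords = np.random.default_rng(0).normal(0, 50, (50_001, 3))
        with pytest.raises(SizeError, match="Debye limit"):
            debye_intensity(coords, np.ones(len(coords)), Q)


class TestHydrationShell:
    def test_all_atoms_of_small_cluster_exposed(self):
        m = _atomic_model(8, spread=8.0)
        beads = hydration_shell_beads(m)
        assert len(beads) == len(m)

    def test_buried_center_atom_has_no_bead(self):
        # one atom at the origin enclosed by a dense shell of atoms
        phi = np.arccos(1 - 2 * (np.arange(60) + 0.5) / 60)
        th = np.pi * (1 + 5 ** 0.5) * (np.arange(60) + 0.5)
        shell = 4.0 * np.stack([np.sin(phi) * np.cos(th),
                                np.sin(phi) * np.sin(th), np.cos(phi)], 1)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        m = AtomicModel(coords, np.array(["C"] * len(coords), dtype=object),
                        np.arange(len(coords)))
        beads = hydration_shell_beads(m)
        d_origin = np.linalg.norm(beads, axis=1)
        assert d_origin.min() > 3.0  # no bead near the buried center


class TestTheoreticalProfile:
    def test_decaying_and_positive(self):
        m = _atomic_model(30)
        tc = theoretical_profile(m, Q)
        assert np.all(tc.I > 0)
        assert tc.I[0] > tc.I[-1]

    def test_shell_contrast_raises_intensity(self):
        m = _atomic_model(30)
        base = theoretical_profile(m, Q, with_shell=True)
        wet = theoretical_profile(m, Q, drho_shell=0.03)
        assert wet.I[0] > base.I[0]


class TestFitProfile:
    def test_parameter_recovery(self):
        m = _atomic_model(40)
        truth_r0, truth_dr = 1.02, 0.025
        calc = DebyeCalculator(m, Q, with_shell=True)
        I = calc.intensity(truth_r0, truth_dr)
        data = ScatteringCurve(Q, I, 0.005 * I, absolute=True)
        fr = fit_profile(m, data)
        assert fr.r0_adjust == pytest.approx(truth_r0, abs=1e-3)
        assert fr.drho_shell == pytest.approx(truth_dr, abs=1e-3)
        assert fr.scale == pytest.approx(1.0, rel=1e-3)
        assert fr.chi2 < 1e-3

    def test_coarse_model_pins_r0(self):
        m = make_chain(30, mode="coil", seed=5)
        tc = theoretical_profile(m, Q)
        data = ScatteringCurve(Q, tc.I, 0.01 * tc.I, absolute=True)
        fr = fit_profile(m, data)
        assert fr.r0_adjust == 1.0
        assert fr.chi2 < 1e-6

    def test_zero_sigma_rejected(self):
        m = _atomic_model(20)
        tc = theoretical_profile(m, Q)
        with pytest.raises(FitError, match="sigma"):
            fit_profile(m, ScatteringCurve(Q, tc.I, np.zeros_like(Q)))

    def test_too_few_points(self):
        m = _atomic_model(20)
        tc = theoretical_profile(m, Q)
        data = ScatteringCurve(Q, tc.I, 0.01 * tc.I)
        with pytest.raises(FitError, match="fewer than 10"):
            fit_profile(m, data, q_cut=0.05)


class TestScoreTerm:
    def _fit(self):
        m = _atomic_model(25)
        tc = theoretical_profile(m, Q)
        data = ScatteringCurve(Q, tc.I, 0.01 * tc.I)
        return fit_profile(m, data)

    def test_score_is_weight_times_chi2(self):
        fr = self._fit()
        s = score_term(fr, weight=100.0)
        assert s == pytest.approx(100.0 * fr.score / fr.weight)
        assert fr.weight == 100.0

    def test_weight_bounds(self):
        fr = self._fit()
        with pytest.raises(ValueError, match="weight"):
            score_term(fr, weight=0.5)
        with pytest.raises(ValueError, match="weight"):
            score_term(fr, weight=501.0)

    def test_q_cut_beyond_range_warns(self):
        fr = self._fit()
        with pytest.warns(UserWarning, match="beyond data range"):
            score_term(fr, weight=10.0, q_cut=5.0)
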