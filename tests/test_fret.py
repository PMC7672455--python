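"""The (ratio)_A algebra and spectral unmixing.

Frozen expected values are computed by hand from the tabulated extinction
coefficients, e.g. (ratio)_A at zero transfer is ε^A(515)/ε^A(610) =
6078/161103 for the H1 labels; the unmixing oracle is the normal-equations
solution evaluated independently of the implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h1fret.constants import (DNA_PAIR, H1_PAIR, LabelingStoichiometry)
from h1fret.fret import (UnmixingError, compute_ratio_A, delta_E,
                         efficiency_from_ratio_A, ratio_A_forward,
                         unmix_acceptor_component)
from h1fret.simulate import SimulationParams, reference_lineshapes
from h1fret.spectra import DONOR_EXC_GRID, EmissionSpectrum, ScanPair

D66 = LabelingStoichiometry(0.66)
D100 = LabelingStoichiometry(1.0)


def _refs():
    return reference_lineshapes(SimulationParams())


def _mix_scan(a_D, a_A, noise_sd=0.0, rng=None):
    donor_ref, acceptor_ref = _refs()
    y = a_D * donor_ref.intensities + a_A * acceptor_ref.intensities
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return EmissionSpectrum(DONOR_EXC_GRID.copy(), y, 515.0), donor_ref, acceptor_ref


class TestForwardInverse:
    # frozen arithmetic from the tabulated coefficients
    @pytest.mark.parametrize("E, stoich, pair, expected", [
        (0.0, D66, H1_PAIR, 6078 / 161103),                       # 0.03773
        (0.4, D66, H1_PAIR, (0.4 * 92058 * 0.66 + 6078) / 161103),  # 0.18858
        (0.0, D100, DNA_PAIR, 3749 / 118400),                     # 0.03166
        (1.0, D100, DNA_PAIR, (53160 + 3749) / 118400),           # 0.48065
    ])
    def test_forward_values(self, E, stoich, pair, expected):
        assert ratio_A_forward(E, stoich, pair) == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_inverse_recovers_efficiency(self):
        rA = ratio_A_forward(0.4, D66, H1_PAIR)
        assert efficiency_from_ratio_A(rA, D66, H1_PAIR) == pytest.approx(
            0.400, abs=1e-12)

    def test_zero_transfer_point_maps_to_zero(self):
        assert efficiency_from_ratio_A(H1_PAIR.zero_transfer_ratio, D66,
                                       H1_PAIR) == pytest.approx(0.0, abs=1e-12)

    def test_known_mid_efficiency(self):
        rA = ratio_A_forward(0.55, D66, H1_PAIR)
        assert rA == pytest.approx(0.24515, abs=5e-6)
        assert efficiency_from_ratio_A(0.24515, D66, H1_PAIR) == pytest.approx(
            0.550, abs=1e-4)

    @given(E=st.floats(0.0, 1.0), d_plus=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_mutual_inverse_property(self, E, d_plus):
        stoich = LabelingStoichiometry(d_plus)
        for pair in (H1_PAIR, DNA_PAIR):
            assert efficiency_from_ratio_A(
                ratio_A_forward(E, stoich, pair), stoich, pair
            ) == pytest.approx(E, abs=1e-12)

    def test_strictly_monotone_in_E_and_d_plus(self):
        Es = np.linspace(0, 1, 50)
        vals = [ratio_A_forward(e, D66, H1_PAIR) for e in Es]
        assert np.all(np.diff(vals) > 0)
        dps = np.linspace(0.05, 1.0, 50)
        vals = [ratio_A_forward(0.5, LabelingStoichiometry(d), H1_PAIR)
                for d in dps]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ratio_A_forward(1.2, D66, H1_PAIR)
        with pytest.raises(ValueError):
            efficiency_from_ratio_A(-0.1, D66, H1_PAIR)
        with pytest.raises(ValueError):
            LabelingStoichiometry(0.0)


class TestDeltaE:
    def test_equal_ratios_give_zero(self):
        rA = ratio_A_forward(0.3, D66, H1_PAIR)
        assert delta_E(rA, rA, 0.3, H1_PAIR) == 0.0

    def test_frozen_example_wt_scale(self):
        # E 0.15 -> 0.55 corresponds to the assay's WT ΔE of 0.40
        rA_exp = ratio_A_forward(0.55, D66, H1_PAIR)
        rA_ref = ratio_A_forward(0.15, D66, H1_PAIR)
        assert delta_E(rA_exp, rA_ref, 0.15, H1_PAIR) == pytest.approx(
            0.400, abs=1e-10)

    def test_d_plus_independence(self):
        out = []
        for d in (0.66, 0.9):
            stoich = LabelingStoichiometry(d)
            out.append(delta_E(ratio_A_forward(0.55, stoich, H1_PAIR),
                               ratio_A_forward(0.15, stoich, H1_PAIR),
                               0.15, H1_PAIR))
        assert out[0] == pytest.approx(out[1], abs=1e-12)

    @given(e_ref=st.floats(0.01, 0.99), e_exp=st.floats(0.0, 1.0),
           d_plus=st.floats(0.05, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_identity_with_direct_difference(self, e_ref, e_exp, d_plus):
        stoich = LabelingStoichiometry(d_plus)
        dE = delta_E(ratio_A_forward(e_exp, stoich, H1_PAIR),
                     ratio_A_forward(e_ref, stoich, H1_PAIR),
                     e_ref, H1_PAIR)
        assert dE == pytest.approx(e_exp - e_ref, abs=1e-10)

    def test_zero_transfer_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            delta_E(0.2, H1_PAIR.zero_transfer_ratio, 0.1, H1_PAIR)


class TestUnmixing:
    def test_construct_and_recover_exact(self):
        scan, d_ref, a_ref = _mix_scan(2.0, 0.5)
        a_D, a_A, resid = unmix_acceptor_component(scan, d_ref, a_ref)
        assert a_D == pytest.approx(2.0, abs=1e-10)
        assert a_A == pytest.approx(0.5, abs=1e-10)
        assert resid < 1e-10

    def test_pure_acceptor_scan(self):
        scan, d_ref, a_ref = _mix_scan(0.0, 1.0)
        a_D, a_A, _ = unmix_acceptor_component(scan, d_ref, a_ref)
        assert a_D == pytest.approx(0.0, abs=1e-10)
        assert a_A == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_matches_normal_equations_oracle(self, rng):
        d_ref, a_ref = _refs()
        peak = max(d_ref.intensities.max(), a_ref.intensities.max())
        scan, *_ = _mix_scan(1.3, 0.7, noise_sd=0.01 * 1.3 * peak, rng=rng)
        a_D, a_A, _ = unmix_acceptor_component(scan, d_ref, a_ref,
                                               nonnegative=False)
        # independent oracle: solve the normal equations directly
        X = np.column_stack([d_ref.intensities, a_ref.intensities])
        beta = np.linalg.solve(X.T @ X, X.T @ scan.intensities)
        assert a_D == pytest.approx(beta[0], abs=1e-9)
        assert a_A == pytest.approx(beta[1], abs=1e-9)
        assert abs(a_D - 1.3) < 0.02 and abs(a_A - 0.7) < 0.02

    def test_nnls_matches_lstsq_when_interior(self, rng):
        scan, d_ref, a_ref = _mix_scan(1.3, 0.7, noise_sd=1e-4, rng=rng)
        free = unmix_acceptor_component(scan, d_ref, a_ref, nonnegative=False)
        constrained = unmix_acceptor_component(scan, d_ref, a_ref)
        assert free[0] == pytest.approx(constrained[0], abs=1e-8)
        assert free[1] == pytest.approx(constrained[1], abs=1e-8)

    def test_collinear_references_rejected(self):
        d_ref, _ = _refs()
        twin = EmissionSpectrum(d_ref.wavelengths_nm.copy(),
                                2.0 * d_ref.intensities, 515.0)
        scan, *_ = _mix_scan(1.0, 1.0)
        with pytest.raises(UnmixingError, match="collinear"):
            unmix_acceptor_component(scan, d_ref, twin)


class TestComputeRatioA:
    def _pair_for(self, E, scale=1.0):
        params = SimulationParams(noise_model="none", background_level=0.0)
        from h1fret.simulate import simulate_scan_pair_at_efficiency
        sp = simulate_scan_pair_at_efficiency(
            params, E, np.random.default_rng(0))
        if scale != 1.0:
            sp = ScanPair(
                EmissionSpectrum(sp.donor_exc_scan.wavelengths_nm,
                                 scale * sp.donor_exc_scan.intensities, 515.0,
                                 sample_id=sp.sample_id),
                EmissionSpectrum(sp.acceptor_exc_scan.wavelengths_nm,
                                 scale * sp.acceptor_exc_scan.intensities,
                                 610.0, sample_id=sp.sample_id),
                sp.sample_id)
        return sp

    def test_scale_invariance(self):
        d_ref, a_ref = _refs()
        r1 = compute_ratio_A(self._pair_for(0.4), d_ref, a_ref).ratio_A
        r10 = compute_ratio_A(self._pair_for(0.4, scale=10.0), d_ref,
                              a_ref).ratio_A
        assert r1 == pytest.approx(r10, rel=1e-12)

    def test_reference_normalization_cancels(self):
        d_ref, a_ref = _refs()
        a_ref_rescaled = EmissionSpectrum(a_ref.wavelengths_nm.copy(),
                                          3.7 * a_ref.intensities, 515.0)
        sp = self._pair_for(0.4)
        r = compute_ratio_A(sp, d_ref, a_ref).ratio_A
        r2 = compute_ratio_A(sp, d_ref, a_ref_rescaled).ratio_A
        assert r == pytest.approx(r2, rel=1e-10)

    def test_peak_window_mode_close_to_unmixing(self):
        d_ref, a_ref = _refs()
        sp = self._pair_for(0.4)
        r_unmix = compute_ratio_A(sp, d_ref, a_ref, mode="unmix").ratio_A
        r_window = compute_ratio_A(sp, d_ref, a_ref, mode="peak_window").ratio_A
        assert r_window == pytest.approx(r_unmix, rel=0.05)

    def test_no_acceptor_signal_rejected(self):
        d_ref, a_ref = _refs()
        sp = self._pair_for(0.4)
        dead = ScanPair(
            sp.donor_exc_scan,
            EmissionSpectrum(sp.acceptor_exc_scan.wavelengths_nm,
                             np.zeros_like(sp.acceptor_exc_scan.intensities),
                             610.0, sample_id=sp.sample_id),
            sp.sample_id)
        with pytest.raises(UnmixingError, match="no acceptor signal"):
            compute_ratio_A(dead, d_ref, a_ref)
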