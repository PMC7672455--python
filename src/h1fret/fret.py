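"""The acceptor-normalized (ratio)_A method for ensemble FRET efficiency.

The measured quantity is

    (ratio)_A = [acceptor emission under donor excitation (λ′)]
                / [acceptor emission under direct excitation (λ″)]

which for a mixed labeling population with donor fraction d⁺ obeys

    (ratio)_A = (E · ε^D(λ′) · d⁺ + ε^A(λ′)) / ε^A(λ″)

so that E = (ε^A(λ″)·(ratio)_A − ε^A(λ′)) / (ε^D(λ′)·d⁺).  Normalizing by
direct acceptor excitation makes the ratio independent of acceptor
concentration and of all emission-side instrument factors.

The transfer term is written with ε^D evaluated at λ′ throughout.  Some
printed forms of the ratio carry ε^D(λ″) in the numerator, but the
inversion to E uses ε^D(λ′) and only ε^D at λ′ is ever tabulated; using λ′
consistently makes the forward and inverse maps exact mutual inverses,
which is the property every downstream statistic relies on.

The efficiency *difference* between a bound and a free state,

    ΔE = E_ref · ((ratio)_A,exp − (ratio)_A,ref)
               / ((ratio)_A,ref − ε^A(λ′)/ε^A(λ″)),

is algebraically equal to E_exp − E_ref and cancels d⁺, so only one
accurately determined reference efficiency is needed.

Acceptor emission under donor excitation is isolated by two-component
linear unmixing of the scan against donor-only and acceptor-only reference
lineshapes (nonnegativity-constrained by default); a simpler peak-window
mode (integral over 660–680 nm after scaled donor-reference subtraction)
is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy.optimize import nnls

from .constants import FluorophorePair, LabelingStoichiometry
from .spectra import EmissionSpectrum, ScanPair, SpectrumValidationError

#: Condition-number ceiling above which the two reference lineshapes are
#: treated as collinear and unmixing refuses to proceed.
COLLINEARITY_LIMIT = 1e8

PEAK_WINDOW_NM = (660.0, 680.0)


class UnmixingError(ValueError):
    """Reference lineshapes unusable or no acceptor signal to normalize by."""


@dataclass(frozen=True)
class FretResult:
    """(ratio)_A, E and ΔE for one sample, with unmixing diagnostics."""

    sample_id: str
    ratio_A: float
    E: float
    delta_E: float | None
    E_reference: float | None
    donor_amplitude: float
    acceptor_amplitude: float
    residual_norm: float
    qc_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc_flags"] = list(self.qc_flags)
        return d


def _common_grid(scan: EmissionSpectrum, donor_ref: EmissionSpectrum,
                 acceptor_ref: EmissionSpectrum) -> np.ndarray:
    lo = max(scan.range_nm[0], donor_ref.range_nm[0], acceptor_ref.range_nm[0])
    hi = min(scan.range_nm[1], donor_ref.range_nm[1], acceptor_ref.range_nm[1])
    if lo > hi:
        raise UnmixingError("scan and reference spectra have no common wavelength range")
    mask = (scan.wavelengths_nm >= lo) & (scan.wavelengths_nm <= hi)
    grid = scan.wavelengths_nm[mask]
    if grid.size < 2:
        raise UnmixingError("fewer than 2 common wavelength points for unmixing")
    return grid


def unmix_acceptor_component(
    scan: EmissionSpectrum,
    donor_ref: EmissionSpectrum,
    acceptor_ref: EmissionSpectrum,
    nonnegative: bool = True,
) -> tuple[float, float, float]:
    """Least-squares decomposition scan ≈ a_D·donor_ref + a_A·acceptor_ref.

    Returns ``(a_D, a_A, residual_norm)``.  With ``nonnegative`` (default)
    the fit is solved by NNLS; otherwise by unconstrained least squares.
    Raises :class:`UnmixingError` when the reference lineshapes are
    collinear on the common grid.
    """
    grid = _common_grid(scan, donor_ref, acceptor_ref)
    design = np.column_stack([donor_ref.interp(grid), acceptor_ref.interp(grid)])
    if np.linalg.cond(design) > COLLINEARITY_LIMIT:
        raise UnmixingError(
            "donor and acceptor reference lineshapes are collinear "
            f"(condition number > {COLLINEARITY_LIMIT:g})")
    y = scan.interp(grid)
    if nonnegative:
        coeffs, rnorm = nnls(design, y)
    else:
        coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
        rnorm = float(np.linalg.norm(design @ coeffs - y))
    return float(coeffs[0]), float(coeffs[1]), float(rnorm)


def _acceptor_amplitude_single(scan: EmissionSpectrum,
                               acceptor_ref: EmissionSpectrum) -> float:
    """Amplitude of the acceptor lineshape in a scan assumed acceptor-only
    (the direct-excitation scan: λ″ barely excites the donor)."""
    lo = max(scan.range_nm[0], acceptor_ref.range_nm[0])
    hi = min(scan.range_nm[1], acceptor_ref.range_nm[1])
    if lo > hi:
        raise UnmixingError("scan and acceptor reference share no wavelength range")
    mask = (scan.wavelengths_nm >= lo) & (scan.wavelengths_nm <= hi)
    grid = scan.wavelengths_nm[mask]
    x = acceptor_ref.interp(grid)
    denom = float(x @ x)
    if denom == 0.0:
        raise UnmixingError("acceptor reference is zero on the common grid")
    return float(x @ scan.interp(grid)) / denom


def _peak_window_amplitude(scan: EmissionSpectrum, donor_ref: EmissionSpectrum,
                           acceptor_ref: EmissionSpectrum) -> float:
    """Sensitivity-check mode: subtract the donor reference scaled to match
    the scan on the donor-dominated side, then integrate 660–680 nm and
    express it in acceptor-reference units."""
    grid = _common_grid(scan, donor_ref, acceptor_ref)
    d = donor_ref.interp(grid)
    a = acceptor_ref.interp(grid)
    y = scan.interp(grid)
    donor_side = grid <= 600.0
    if not donor_side.any() or float(d[donor_side] @ d[donor_side]) == 0.0:
        scale = 0.0
    else:
        scale = float(d[donor_side] @ y[donor_side]) / float(
            d[donor_side] @ d[donor_side])
    resid = y - scale * d
    win = (grid >= PEAK_WINDOW_NM[0]) & (grid <= PEAK_WINDOW_NM[1])
    if not win.any():
        raise UnmixingError("peak window 660-680 nm not covered by scan")
    num = float(np.trapezoid(resid[win], grid[win]))
    den = float(np.trapezoid(a[win], grid[win]))
    if den == 0.0:
        raise UnmixingError("acceptor reference vanishes in the peak window")
    return num / den


def compute_ratio_A(
    pair_scans: ScanPair,
    donor_ref: EmissionSpectrum,
    acceptor_ref: EmissionSpectrum,
    mode: Literal["unmix", "peak_window"] = "unmix",
    nonnegative: bool = True,
) -> FretResult:
    """Compute (ratio)_A for one background-subtracted scan pair.

    The acceptor amplitude unmixed from the donor-excitation scan is divided
    by the acceptor amplitude fit to the direct-excitation scan.  Both
    amplitudes are expressed in units of the same acceptor reference
    lineshape, so its normalization cancels, as does any common intensity
    rescaling of the two scans (acceptor-concentration independence).
    """
    if mode == "unmix":
        a_D, a_A, rnorm = unmix_acceptor_component(
            pair_scans.donor_exc_scan, donor_ref, acceptor_ref,
            nonnegative=nonnegative)
    elif mode == "peak_window":
        a_A = _peak_window_amplitude(pair_scans.donor_exc_scan, donor_ref,
                                     acceptor_ref)
        a_D, rnorm = float("nan"), float("nan")
    else:
        raise ValueError(f"unknown extraction mode {mode!r}")

    direct = _acceptor_amplitude_single(pair_scans.acceptor_exc_scan, acceptor_ref)
    if direct <= 0.0:
        raise UnmixingError(
            f"no acceptor signal under direct excitation for sample "
            f"{pair_scans.sample_id!r} (amplitude {direct:g})")
    return FretResult(
        sample_id=pair_scans.sample_id,
        ratio_A=a_A / direct,
        E=float("nan"), delta_E=None, E_reference=None,
        donor_amplitude=a_D, acceptor_amplitude=a_A, residual_norm=rnorm,
    )


def ratio_A_forward(E: float, stoich: LabelingStoichiometry,
                    pair: FluorophorePair) -> float:
    """Forward map E → (ratio)_A; strictly increasing in E and in d⁺."""
    if not 0.0 <= E <= 1.0:
        raise ValueError(f"E must be in [0, 1], got {E}")
    return (E * pair.eps_D_donor_exc * stoich.d_plus
            + pair.eps_A_donor_exc) / pair.eps_A_acceptor_exc


def efficiency_from_ratio_A(ratio_A: float, stoich: LabelingStoichiometry,
                            pair: FluorophorePair) -> float:
    """Invert (ratio)_A to a FRET efficiency; exact inverse of
    :func:`ratio_A_forward`."""
    if ratio_A <= 0.0:
        raise ValueError(f"ratio_A must be positive, got {ratio_A}")
    return (pair.eps_A_acceptor_exc * ratio_A
            - pair.eps_A_donor_exc) / (pair.eps_D_donor_exc * stoich.d_plus)


def delta_E(ratio_A_exp: float, ratio_A_reference: float,
            E_reference: float, pair: FluorophorePair) -> float:
    """Efficiency difference vs the free-label reference state, from the two
    ratios alone — independent of d⁺.

    Equals E_exp − E_reference exactly whenever both ratios arise from the
    forward model with a common d⁺.
    """
    denom = ratio_A_reference - pair.zero_transfer_ratio
    if denom <= 0.0:
        raise ValueError(
            "reference (ratio)_A is at or below the zero-transfer level "
            f"{pair.zero_transfer_ratio:.5f}; reference FRET indistinguishable "
            "from zero")
    return E_reference * (ratio_A_exp - ratio_A_reference) / denom


def qc_flags_for_efficiency(E: float) -> tuple[str, ...]:
    """Efficiencies slightly outside [0,1] are tolerated with a flag;
    grossly unphysical values get a stronger flag."""
    if 0.0 <= E <= 1.0:
        return ()
    if -0.05 <= E <= 1.05:
        return ("E_outside_unit_interval",)
    return ("E_outside_unit_interval", "E_unphysical")
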