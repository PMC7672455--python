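"""Fluorophore constants for the Cy3/Cy5 (ratio)_A method.

A :class:`FluorophorePair` bundles the extinction coefficients that enter the
acceptor-normalized FRET ratio: the donor and acceptor coefficients at the
donor excitation wavelength λ′ and the acceptor coefficient at the direct
(acceptor) excitation wavelength λ″, plus the Förster radius used for
distance conversion.  Two measured sets are shipped as module constants:
one for Cy3/Cy5 maleimide labels on the H1 C-terminal domain termini and one
for Cy3/Cy5 incorporated at nucleosomal linker-DNA ends.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluorophorePair:
    """Extinction coefficients (cm^-1 M^-1) and excitation wavelengths (nm).

    Attributes
    ----------
    eps_D_donor_exc : float
        ε^D(λ′) — donor extinction at the donor excitation wavelength.
    eps_A_donor_exc : float
        ε^A(λ′) — acceptor extinction at the donor excitation wavelength
        (direct acceptor excitation bleed at λ′).
    eps_A_acceptor_exc : float
        ε^A(λ″) — acceptor extinction at the acceptor excitation wavelength.
    donor_exc_nm, acceptor_exc_nm : float
        λ′ and λ″ in nm.
    forster_radius_nm : float
        R0 for the pair, used by :mod:`h1fret.distance`.
    """

    eps_D_donor_exc: float
    eps_A_donor_exc: float
    eps_A_acceptor_exc: float
    donor_exc_nm: float = 515.0
    acceptor_exc_nm: float = 610.0
    forster_radius_nm: float = 6.0

    def __post_init__(self) -> None:
        if min(self.eps_D_donor_exc, self.eps_A_donor_exc,
               self.eps_A_acceptor_exc) <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.eps_A_acceptor_exc <= self.eps_A_donor_exc:
            raise ValueError(
                "acceptor must absorb more strongly at its own excitation "
                "wavelength than at the donor's")
        if self.donor_exc_nm >= self.acceptor_exc_nm:
            raise ValueError("donor excitation must be blue of acceptor excitation")

    @property
    def zero_transfer_ratio(self) -> float:
        """(ratio)_A at E = 0: ε^A(λ′)/ε^A(λ″), pure direct-excitation bleed."""
        return self.eps_A_donor_exc / self.eps_A_acceptor_exc


@dataclass(frozen=True)
class LabelingStoichiometry:
    """d⁺ — fraction of donor-labeled molecules among the acceptor-bearing
    population that normalizes (ratio)_A."""

    d_plus: float

    def __post_init__(self) -> None:
        if not 0.0 < self.d_plus <= 1.0:
            raise ValueError(f"d_plus must be in (0, 1], got {self.d_plus}")


#: Cy3/Cy5 on the H1 CTD termini (G101C / K195C maleimide labels).
H1_PAIR = FluorophorePair(
    eps_D_donor_exc=92_058.0,
    eps_A_donor_exc=6_078.0,
    eps_A_acceptor_exc=161_103.0,
)

#: Cy3/Cy5 incorporated at linker-DNA ends of reconstituted nucleosomes.
DNA_PAIR = FluorophorePair(
    eps_D_donor_exc=53_160.0,
    eps_A_donor_exc=3_749.0,
    eps_A_acceptor_exc=118_400.0,
)

#: Measured donor-label fraction for the doubly-labeled H1 preparation.
H1_D_PLUS = LabelingStoichiometry(0.66)

#: DNA-end labels are placed site-specifically, so every acceptor-bearing
#: molecule also carries the donor.
DNA_D_PLUS = LabelingStoichiometry(1.0)

PAIRS = {"h1_pair": H1_PAIR, "dna_pair": DNA_PAIR}
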