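"""Förster conversion between FRET efficiency and fluorophore separation.

Under the single-fixed-distance assumption, E = 1 / (1 + (r/R0)^6).  The
default Förster radius for Cy3/Cy5 is 6.0 nm; it is a config input, always
echoed into outputs, because reported distances are only as good as the R0
they assume.  No orientation-factor (κ²) modelling is attempted: converted
values are averages under the fixed-distance idealization, not ensemble
distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ForsterModel:
    forster_radius_nm: float = 6.0
    #: distances outside this window are flagged as unreliable (E too close
    #: to 0 or 1 for the sixth-power law to resolve)
    valid_range_nm: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.forster_radius_nm <= 0:
            raise ValueError("Förster radius must be positive")
        if self.valid_range_nm is None:
            object.__setattr__(self, "valid_range_nm",
                               (0.5 * self.forster_radius_nm,
                                2.0 * self.forster_radius_nm))


def distance_to_efficiency(r_nm: float, model: ForsterModel) -> float:
    """E = 1/(1 + (r/R0)^6); strictly decreasing in r."""
    if r_nm <= 0:
        raise ValueError(f"distance must be positive, got {r_nm}")
    return 1.0 / (1.0 + (r_nm / model.forster_radius_nm) ** 6)


def efficiency_to_distance(E: float, model: ForsterModel) -> tuple[float, bool]:
    """r = R0·((1−E)/E)^(1/6), with a flag for r outside the model's
    trustworthy range.  Returns ``(r_nm, in_valid_range)``."""
    if not 0.0 < E < 1.0:
        raise ValueError(
            f"E must be strictly inside (0, 1) for a finite distance, got {E}")
    r = model.forster_radius_nm * ((1.0 - E) / E) ** (1.0 / 6.0)
    lo, hi = model.valid_range_nm
    return r, lo <= r <= hi
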