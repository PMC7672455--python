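"""Reading, validation and preprocessing of fluorometer emission scans.

A scan is a two-column CSV (wavelength_nm, intensity_au) as exported by
bench-top spectrofluorometers; a sample is measured twice, once under donor
excitation (λ′ = 515 nm for Cy3) and once under direct acceptor excitation
(λ″ = 610 nm for Cy5).  This module provides the containers
(:class:`EmissionSpectrum`, :class:`ScanPair`, :class:`ScanManifest`),
buffer-blank background subtraction and linear regridding.

Design notes: interpolation is always linear and never extrapolates;
negative intensities after background subtraction are kept (clipping would
bias downstream amplitude fits) but counted for QC.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ROLES = ("sample", "blank", "donor_only_ref", "acceptor_only_ref")

#: Canonical analysis grids (nm): donor-excitation scans bracket both emission
#: bands (Cy3 ~560 nm, Cy5 ~670 nm) while staying red of 515-nm scatter;
#: acceptor-excitation scans cover only the Cy5 band, red of 610-nm scatter.
DONOR_EXC_GRID = np.arange(530.0, 751.0, 1.0)
ACCEPTOR_EXC_GRID = np.arange(620.0, 751.0, 1.0)


class SpectrumParseError(ValueError):
    """Malformed scan file (bad row, duplicate wavelength, ...)."""


class SpectrumValidationError(ValueError):
    """Structurally valid file that violates a spectrum invariant."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan: a strictly increasing wavelength grid with
    intensities in arbitrary units, tagged with its excitation wavelength."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float
    sample_id: str = ""
    role: str = "sample"
    slit_nm: float | None = None
    scatter_flag: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectrumValidationError("need at least 2 wavelength points")
        if inten.shape != wl.shape:
            raise SpectrumValidationError(
                f"length mismatch: {wl.size} wavelengths vs {inten.size} intensities")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumValidationError("wavelengths must be strictly increasing")
        if self.role not in ROLES:
            raise SpectrumValidationError(f"unknown role {self.role!r}")
        # scatter guard: excitation line inside the recorded emission window
        if wl[0] <= self.excitation_nm <= wl[-1]:
            object.__setattr__(self, "scatter_flag", True)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of intensities onto *grid* (no extrapolation)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.range_nm
        bad = grid[(grid < lo) | (grid > hi)]
        if bad.size:
            raise SpectrumValidationError(
                f"grid extends outside spectrum range [{lo}, {hi}] nm at "
                f"{bad[:5].tolist()}{'...' if bad.size > 5 else ''}")
        return np.interp(grid, self.wavelengths_nm, self.intensities)


@dataclass(frozen=True)
class ScanPair:
    """The two scans of one sample: donor excitation and direct acceptor
    excitation."""

    donor_exc_scan: EmissionSpectrum
    acceptor_exc_scan: EmissionSpectrum
    sample_id: str

    def __post_init__(self) -> None:
        d, a = self.donor_exc_scan, self.acceptor_exc_scan
        if d.sample_id != a.sample_id:
            raise SpectrumValidationError(
                f"scan pair mixes samples {d.sample_id!r} and {a.sample_id!r}")
        if not d.excitation_nm < a.excitation_nm:
            raise SpectrumValidationError(
                "donor-excitation scan must use the bluer excitation wavelength")


@dataclass(frozen=True)
class ManifestEntry:
    condition: str
    ratio: float
    replicate: int
    donor_scan_path: str
    acceptor_scan_path: str


@dataclass
class ScanManifest:
    """Groups scan files into (condition, titration ratio, replicate) cells,
    with buffer blanks per excitation wavelength and optional single-label
    reference scans."""

    entries: list[ManifestEntry]
    blank_paths: dict[str, str]            # excitation (nm, as str) -> path
    reference_paths: dict[str, str] = field(default_factory=dict)
    reference_condition: str = "H1_alone"
    fluorophore_pair: str = "h1_pair"
    d_plus: float = 0.66
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        keys = [(e.condition, e.ratio, e.replicate) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SpectrumValidationError(
                f"duplicate (condition, ratio, replicate) triples: {dupes}")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.root / p

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanManifest":
        path = Path(path)
        with open(path) as fh:
            doc = json.load(fh)
        entries = [ManifestEntry(
            condition=e["condition"], ratio=float(e["ratio"]),
            replicate=int(e["replicate"]),
            donor_scan_path=e["donor_scan"], acceptor_scan_path=e["acceptor_scan"],
        ) for e in doc["entries"]]
        man = cls(
            entries=entries,
            blank_paths={str(k): v for k, v in doc["blanks"].items()},
            reference_paths=doc.get("references", {}),
            reference_condition=doc.get("reference_condition", "H1_alone"),
            fluorophore_pair=doc.get("fluorophore_pair", "h1_pair"),
            d_plus=float(doc.get("d_plus", 0.66)),
            root=path.parent,
        )
        missing = [str(p) for p in man.iter_paths() if not man.resolve(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")
        return man

    def iter_paths(self) -> Iterable[str]:
        for e in self.entries:
            yield e.donor_scan_path
            yield e.acceptor_scan_path
        yield from self.blank_paths.values()
        yield from self.reference_paths.values()


def read_spectrum(source: str | Path | io.TextIOBase, excitation_nm: float,
                  role: str = "sample", sample_id: str = "") -> EmissionSpectrum:
    """Parse a two-column CSV scan (wavelength_nm, intensity_au).

    A single header line is auto-detected by a non-numeric first token.
    Rows are sorted by wavelength; duplicate wavelengths are rejected.
    """
    if isinstance(source, (str, Path)):
        name = str(source)
        with open(source) as fh:
            lines = fh.readlines()
    else:
        name = getattr(source, "name", "<stream>")
        lines = source.readlines()

    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if lineno == 1:
            try:
                float(parts[0])
            except ValueError:
                continue  # header line
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{name}, line {lineno}: expected 2 comma-separated fields, "
                f"got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumParseError(f"{name}, line {lineno}: {exc}") from None

    if len(rows) < 2:
        raise SpectrumParseError(f"{name}: need at least 2 data rows, got {len(rows)}")
    rows.sort(key=lambda r: r[0])
    wl = np.array([r[0] for r in rows])
    if np.any(np.diff(wl) == 0):
        dup = wl[:-1][np.diff(wl) == 0]
        raise SpectrumValidationError(
            f"{name}: duplicate wavelengths {sorted(set(dup.tolist()))}")
    inten = np.array([r[1] for r in rows])
    if not sample_id:
        sample_id = Path(name).stem
    return EmissionSpectrum(wl, inten, excitation_nm, sample_id=sample_id, role=role)


def write_spectrum(spectrum: EmissionSpectrum, path: str | Path,
                   header: bool = True) -> None:
    """Write a scan CSV that round-trips bit-identically through
    :func:`read_spectrum` (floats serialized with shortest-repr)."""
    with open(path, "w") as fh:
        if header:
            fh.write("wavelength_nm,intensity_au\n")
        for wl, inten in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{float(wl)!r},{float(inten)!r}\n")


def subtract_background(sample: EmissionSpectrum,
                        blank: EmissionSpectrum) -> EmissionSpectrum:
    """Subtract a buffer-blank scan from a sample scan.

    The blank is linearly interpolated onto the sample grid where the grids
    differ; the result is restricted to the overlapping wavelength range.
    Negative outcomes are kept, not clipped.
    """
    if sample.excitation_nm != blank.excitation_nm:
        raise SpectrumValidationError(
            f"excitation mismatch: sample {sample.excitation_nm} nm vs "
            f"blank {blank.excitation_nm} nm")
    lo = max(sample.range_nm[0], blank.range_nm[0])
    hi = min(sample.range_nm[1], blank.range_nm[1])
    if lo > hi:
        raise SpectrumValidationError(
            f"disjoint wavelength ranges {sample.range_nm} vs {blank.range_nm}")
    mask = (sample.wavelengths_nm >= lo) & (sample.wavelengths_nm <= hi)
    wl = sample.wavelengths_nm[mask]
    corrected = sample.intensities[mask] - blank.interp(wl)
    return replace(sample, wavelengths_nm=wl, intensities=corrected)


def count_negative(spectrum: EmissionSpectrum) -> int:
    """Number of negative intensity points (post-subtraction QC metric)."""
    return int(np.sum(spectrum.intensities < 0))


def resample_to_grid(spectrum: EmissionSpectrum,
                     grid: Sequence[float] | np.ndarray) -> EmissionSpectrum:
    """Linear interpolation onto *grid*; refuses to extrapolate."""
    grid = np.asarray(grid, dtype=float)
    return replace(spectrum, wavelengths_nm=grid, intensities=spectrum.interp(grid))
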