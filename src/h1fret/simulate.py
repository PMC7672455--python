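"""Forward simulation of fluorometer scan pairs and titration datasets.

No raw spectra are deposited with the study this package analyzes, so every
analysis stage is exercised against synthetic scans generated from the same
measurement model the (ratio)_A method assumes.  A labeled molecule
population is a mixture of dual-labeled (D+A), donor-only, acceptor-only and
unlabeled species; ensemble spectroscopy is linear in species
concentrations, so each scan is a species-weighted sum of donor and acceptor
emission bands plus buffer background:

donor excitation (λ′):
    I(λ) = bg + B·[ D(λ)·ε^D(λ′)·(f_D + f_DA·(1−E))
                  + A(λ)·(ε^A(λ′)·(f_A + f_DA) + ε^D(λ′)·E·f_DA) ]
direct acceptor excitation (λ″):
    I(λ) = bg + B·[ A(λ)·ε^A(λ″)·(f_A + f_DA) ]

where D, A are unit-area emission lineshapes, B a brightness constant
absorbing quantum yields and detector response (the ratio method cancels
them), and E the per-molecule transfer efficiency.  Running the analysis
pipeline on a noiseless pair returns exactly
(ratio)_A = (E·ε^D(λ′)·d⁺ + ε^A(λ′))/ε^A(λ″) with d⁺ = f_DA/(f_DA + f_A).

Noise is Gaussian with variance proportional to intensity (shot-noise-like):
sd(λ) = scale·sqrt(I(λ)·I_peak), i.e. "scale" is the relative noise at the
scan peak.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import lognorm

from .constants import (H1_PAIR, PAIRS, FluorophorePair, LabelingStoichiometry)
from .spectra import (ACCEPTOR_EXC_GRID, DONOR_EXC_GRID, EmissionSpectrum,
                      ScanPair, write_spectrum)

#: Nominal ΔE (bound minus free H1) used when emulating the study's
#: nucleosome conditions: wild-type H3, tailless H3 (gH3), and the
#: six-lysine acetylation mimic (6KQ).
CONDITION_DELTA_E = {"WT": 0.40, "gH3": 0.18, "6KQ": 0.28}


@dataclass(frozen=True)
class Lineshape:
    """Parametric emission band: gaussian or lognormal (red-tailed).

    ``width_nm`` is the gaussian sigma, or the lognormal scale; ``skew`` is
    the lognormal shape parameter (ignored for gaussian).  When
    ``normalized``, the band integrates to 1 (trapezoid rule) over the
    canonical donor-excitation grid.
    """

    kind: str = "gaussian"
    peak_nm: float = 560.0
    width_nm: float = 18.0
    skew: float = 0.35
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown lineshape kind {self.kind!r}")
        if self.width_nm <= 0:
            raise ValueError("width_nm must be positive")

    def _raw(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        if self.kind == "gaussian":
            return np.exp(-0.5 * ((grid - self.peak_nm) / self.width_nm) ** 2)
        # shifted lognormal with its mode at peak_nm
        onset = self.peak_nm - self.width_nm * np.exp(-self.skew ** 2)
        u = (grid - onset) / self.width_nm
        out = np.zeros_like(grid)
        pos = u > 0
        out[pos] = lognorm.pdf(u[pos], s=self.skew)
        return out

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        vals = self._raw(grid)
        if self.normalized:
            vals = vals / np.trapezoid(self._raw(DONOR_EXC_GRID), DONOR_EXC_GRID)
        return vals


@dataclass(frozen=True)
class LabelingMixture:
    """Species fractions of a stochastically labeled two-site protein."""

    frac_dual: float
    frac_donor_only: float
    frac_acceptor_only: float
    frac_unlabeled: float

    def __post_init__(self) -> None:
        fracs = (self.frac_dual, self.frac_donor_only,
                 self.frac_acceptor_only, self.frac_unlabeled)
        if any(f < -1e-12 for f in fracs):
            raise ValueError(f"negative species fraction in {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {sum(fracs)}")

    @property
    def d_plus(self) -> float:
        """Donor-labeled fraction of the acceptor-bearing population."""
        denom = self.frac_dual + self.frac_acceptor_only
        if denom == 0.0:
            raise ValueError("no acceptor-bearing species; d_plus undefined")
        return self.frac_dual / denom

    def stoichiometry(self) -> LabelingStoichiometry:
        return LabelingStoichiometry(self.d_plus)


def mixture_from_site_probabilities(p_cy3: float, p_cy5: float) -> LabelingMixture:
    """Species fractions for two cysteine sites labeled independently.

    Each site receives Cy3 with probability ``p_cy3``, Cy5 with ``p_cy5``,
    or stays unlabeled; the 3×3 outcome space is enumerated exactly.  A
    50/50 dye mix at full labeling (0.5, 0.5) gives d⁺ = 2/3.
    """
    for name, p in (("p_cy3", p_cy3), ("p_cy5", p_cy5)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if p_cy3 + p_cy5 > 1.0 + 1e-12:
        raise ValueError(f"p_cy3 + p_cy5 = {p_cy3 + p_cy5} exceeds 1")

    site = {"D": p_cy3, "A": p_cy5, "-": 1.0 - p_cy3 - p_cy5}
    fracs = {"dual": 0.0, "donor": 0.0, "acceptor": 0.0, "none": 0.0}
    for s1, s2 in itertools.product(site, repeat=2):
        p = site[s1] * site[s2]
        has_d = "D" in (s1, s2)
        has_a = "A" in (s1, s2)
        if has_d and has_a:
            fracs["dual"] += p
        elif has_d:
            fracs["donor"] += p
        elif has_a:
            fracs["acceptor"] += p
        else:
            fracs["none"] += p
    return LabelingMixture(fracs["dual"], fracs["donor"],
                           fracs["acceptor"], fracs["none"])


#: Full two-site labeling with a 50/50 Cy3/Cy5 maleimide mix — the labeling
#: scheme used for the doubly-mutant H1 (d⁺ = 2/3).
FIFTY_FIFTY_MIX = mixture_from_site_probabilities(0.5, 0.5)


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth and nuisance parameters for scan simulation.

    Efficiencies may alternatively be given as distances (with the pair's
    Förster radius), the natural parameterization for DNA-end labels.
    """

    true_E_free: float = 0.15
    true_E_bound: float = 0.55
    mixture: LabelingMixture = FIFTY_FIFTY_MIX
    pair: FluorophorePair = H1_PAIR
    donor_lineshape: Lineshape = Lineshape("gaussian", 560.0, 18.0)
    acceptor_lineshape: Lineshape = Lineshape("gaussian", 670.0, 20.0)
    brightness: float = 1.0
    background_level: float = 20.0
    noise_model: str = "none"            # none | gaussian_shot
    noise_scale: float = 0.01
    donor_leakage: float = 0.0           # donor excitation efficiency at λ″
    n_replicates: int = 3
    titration_ratios: tuple[float, ...] = (0.4, 0.6, 0.8, 1.0, 1.1, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("true_E_free", "true_E_bound"):
            e = getattr(self, name)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {e}")
        if self.noise_model not in ("none", "gaussian_shot"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if any(r < 0 for r in self.titration_ratios):
            raise ValueError("titration ratios must be nonnegative")

    @classmethod
    def from_distances(cls, free_nm: float, bound_nm: float,
                       **kwargs) -> "SimulationParams":
        from .distance import ForsterModel, distance_to_efficiency
        pair = kwargs.get("pair", H1_PAIR)
        model = ForsterModel(pair.forster_radius_nm)
        return cls(true_E_free=distance_to_efficiency(free_nm, model),
                   true_E_bound=distance_to_efficiency(bound_nm, model),
                   **kwargs)


def _add_noise(intensities: np.ndarray, params: SimulationParams,
               rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "none":
        return intensities
    peak = float(np.max(intensities))
    if peak <= 0:
        return intensities
    sd = params.noise_scale * np.sqrt(np.clip(intensities, 0, None) * peak)
    return intensities + rng.normal(0.0, 1.0, intensities.shape) * sd


def simulate_scan_pair_at_efficiency(
    params: SimulationParams, E: float, rng: np.random.Generator,
    sample_id: str = "sim") -> ScanPair:
    """Simulate the donor-excitation / direct-excitation scan pair of one
    sample whose dual-labeled molecules transfer with efficiency ``E``."""
    mix, pair = params.mixture, params.pair
    D = params.donor_lineshape.evaluate(DONOR_EXC_GRID)
    A_donor_grid = params.acceptor_lineshape.evaluate(DONOR_EXC_GRID)
    A_acc_grid = params.acceptor_lineshape.evaluate(ACCEPTOR_EXC_GRID)
    D_acc_grid = params.donor_lineshape.evaluate(ACCEPTOR_EXC_GRID)

    donor_amp = pair.eps_D_donor_exc * (mix.frac_donor_only
                                        + mix.frac_dual * (1.0 - E))
    sensitized = (pair.eps_A_donor_exc * (mix.frac_acceptor_only + mix.frac_dual)
                  + pair.eps_D_donor_exc * E * mix.frac_dual)
    donor_exc = (params.background_level
                 + params.brightness * (D * donor_amp + A_donor_grid * sensitized))

    direct_amp = pair.eps_A_acceptor_exc * (mix.frac_acceptor_only + mix.frac_dual)
    acc_exc = (params.background_level
               + params.brightness * (A_acc_grid * direct_amp
                                      + params.donor_leakage * D_acc_grid * donor_amp))

    donor_exc = _add_noise(donor_exc, params, rng)
    acc_exc = _add_noise(acc_exc, params, rng)
    return ScanPair(
        EmissionSpectrum(DONOR_EXC_GRID.copy(), donor_exc, pair.donor_exc_nm,
                         sample_id=sample_id),
        EmissionSpectrum(ACCEPTOR_EXC_GRID.copy(), acc_exc, pair.acceptor_exc_nm,
                         sample_id=sample_id),
        sample_id,
    )


def simulate_scan_pair(params: SimulationParams, state: str,
                       rng: np.random.Generator | None = None,
                       sample_id: str | None = None) -> ScanPair:
    """Simulate one scan pair in the ``free`` or ``bound`` state."""
    if state not in ("free", "bound"):
        raise ValueError(f"state must be 'free' or 'bound', got {state!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    E = params.true_E_free if state == "free" else params.true_E_bound
    return simulate_scan_pair_at_efficiency(
        params, E, rng, sample_id or f"sim_{state}")


def reference_lineshapes(params: SimulationParams
                         ) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """Clean single-fluorophore reference spectra on the donor-excitation
    grid, for unmixing synthetic scans."""
    d = EmissionSpectrum(DONOR_EXC_GRID.copy(),
                         params.donor_lineshape.evaluate(DONOR_EXC_GRID),
                         params.pair.donor_exc_nm,
                         sample_id="donor_ref", role="donor_only_ref")
    a = EmissionSpectrum(DONOR_EXC_GRID.copy(),
                         params.acceptor_lineshape.evaluate(DONOR_EXC_GRID),
                         params.pair.donor_exc_nm,
                         sample_id="acceptor_ref", role="acceptor_only_ref")
    return d, a


def bound_fraction(ratio: float, saturation_ratio: float) -> float:
    """Fraction of labeled H1 bound at a given nucleosome:H1 ratio, under
    stoichiometric (tight) binding saturating at ``saturation_ratio``."""
    if saturation_ratio <= 0:
        raise ValueError("saturation_ratio must be positive")
    return min(ratio / saturation_ratio, 1.0)


def simulate_titration_dataset(params: SimulationParams,
                               saturation_ratio: float = 1.0,
                               out_dir: str | Path = ".",
                               condition: str = "WT") -> Path:
    """Write a full synthetic titration: scan CSVs for every
    (ratio, replicate) cell plus free-H1 reference replicates, buffer
    blanks, reference lineshapes, a JSON manifest and a ground-truth JSON.

    Partially bound points are population mixtures, linear in bound
    fraction, so the ensemble efficiency at ratio r is
    E(r) = f_b(r)·E_bound + (1−f_b(r))·E_free.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    pair = params.pair

    # buffer blanks: flat background, one per excitation wavelength
    blanks = {}
    for tag, grid, exc in (("515", DONOR_EXC_GRID, pair.donor_exc_nm),
                           ("610", ACCEPTOR_EXC_GRID, pair.acceptor_exc_nm)):
        blank = EmissionSpectrum(
            grid.copy(),
            _add_noise(np.full(grid.shape, params.background_level), params, rng),
            exc, sample_id=f"blank_{tag}", role="blank")
        fname = f"blank_{tag}.csv"
        write_spectrum(blank, out / fname)
        blanks[tag] = fname

    donor_ref, acceptor_ref = reference_lineshapes(params)
    write_spectrum(donor_ref, out / "donor_ref.csv")
    write_spectrum(acceptor_ref, out / "acceptor_ref.csv")

    entries = []

    def emit(cond: str, ratio: float, rep: int, E: float) -> None:
        sid = f"{cond}_r{ratio:g}_rep{rep}"
        sp = simulate_scan_pair_at_efficiency(params, E, rng, sample_id=sid)
        dpath, apath = f"{sid}_exc515.csv", f"{sid}_exc610.csv"
        write_spectrum(sp.donor_exc_scan, out / dpath)
        write_spectrum(sp.acceptor_exc_scan, out / apath)
        entries.append({"condition": cond, "ratio": ratio, "replicate": rep,
                        "donor_scan": dpath, "acceptor_scan": apath})

    for rep in range(1, params.n_replicates + 1):
        emit("H1_alone", 0.0, rep, params.true_E_free)
    truth_per_ratio = {}
    for ratio in params.titration_ratios:
        fb = bound_fraction(ratio, saturation_ratio)
        E_mix = fb * params.true_E_bound + (1.0 - fb) * params.true_E_free
        truth_per_ratio[f"{ratio:g}"] = E_mix - params.true_E_free
        for rep in range(1, params.n_replicates + 1):
            emit(condition, ratio, rep, E_mix)

    manifest = {
        "fluorophore_pair": next(
            (name for name, p in PAIRS.items() if p == pair), "custom"),
        "d_plus": params.mixture.d_plus,
        "reference_condition": "H1_alone",
        "blanks": blanks,
        "references": {"donor_only": "donor_ref.csv",
                       "acceptor_only": "acceptor_ref.csv"},
        "entries": entries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")

    truth = {
        "seed": params.seed,
        "condition": condition,
        "true_E_free": params.true_E_free,
        "true_E_bound": params.true_E_bound,
        "d_plus": params.mixture.d_plus,
        "saturation_ratio": saturation_ratio,
        "true_delta_E_per_ratio": truth_per_ratio,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return manifest_path
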