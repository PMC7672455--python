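"""End-to-end orchestration: manifest → background subtraction → unmixing →
(ratio)_A → E/ΔE → distances → statistics.

`run_analysis` consumes a scan manifest and writes a deterministic results
bundle (per-sample FRET results, per-condition titration tables, condition
comparisons, a distance table for DNA-end-labeled runs, QC and provenance
records).  `run_simulation_study` is the Monte-Carlo harness that measures
how well the full pipeline recovers known ground truth under the synthetic
generator, and `power_study` / `type_i_study` characterize the t-test at
the replicate scale of the assay.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import (DNA_PAIR, H1_PAIR, PAIRS, FluorophorePair,
                        LabelingStoichiometry)
from .distance import ForsterModel, efficiency_to_distance
from .fret import (compute_ratio_A, delta_E, efficiency_from_ratio_A,
                   qc_flags_for_efficiency, ratio_A_forward, UnmixingError)
from .simulate import (SimulationParams, reference_lineshapes,
                       simulate_scan_pair_at_efficiency)
from .spectra import (EmissionSpectrum, ScanManifest, ScanPair,
                      count_negative, read_spectrum, subtract_background)
from .stats import (TitrationSeries, compare_conditions, detect_saturation,
                    students_t_test, summarize_series)

log = logging.getLogger("h1fret")


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; defaults encode the Cy3/Cy5 H1-labeling setup."""

    pair_name: str = "h1_pair"
    custom_pair: FluorophorePair | None = None
    d_plus: float = 0.66
    forster_radius_nm: float = 6.0
    unmix_mode: str = "unmix"            # unmix | peak_window
    nonnegative_unmixing: bool = True
    t_variant: str = "pooled"            # pooled | welch
    aggregate: str = "pooled_saturated"  # pooled_saturated | per_ratio
    flatness_tol: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.custom_pair is None and self.pair_name not in PAIRS:
            raise ValueError(f"unknown fluorophore pair {self.pair_name!r}")
        if self.flatness_tol <= 0:
            raise ValueError("flatness_tol must be positive")

    @property
    def pair(self) -> FluorophorePair:
        if self.custom_pair is not None:
            return self.custom_pair
        base = PAIRS[self.pair_name]
        if base.forster_radius_nm != self.forster_radius_nm:
            base = replace(base, forster_radius_nm=self.forster_radius_nm)
        return base

    @property
    def stoichiometry(self) -> LabelingStoichiometry:
        return LabelingStoichiometry(self.d_plus)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        sec = doc.get("analysis", doc)
        custom = None
        if "custom_pair" in sec:
            custom = FluorophorePair(**sec.pop("custom_pair"))
        known = {f for f in cls.__dataclass_fields__ if f != "custom_pair"}
        unknown = set(sec) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(custom_pair=custom, **sec)

    def fingerprint(self) -> str:
        blob = json.dumps(
            {k: (v if not isinstance(v, FluorophorePair) else vars(v))
             for k, v in vars(self).items()}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _load_scan_pair(man: ScanManifest, entry, pair: FluorophorePair,
                    blanks: dict[float, EmissionSpectrum]) -> ScanPair:
    sid = f"{entry.condition}_r{entry.ratio:g}_rep{entry.replicate}"
    d = read_spectrum(man.resolve(entry.donor_scan_path), pair.donor_exc_nm,
                      sample_id=sid)
    a = read_spectrum(man.resolve(entry.acceptor_scan_path),
                      pair.acceptor_exc_nm, sample_id=sid)
    d = subtract_background(d, blanks[pair.donor_exc_nm])
    a = subtract_background(a, blanks[pair.acceptor_exc_nm])
    return ScanPair(d, a, sid)


def run_analysis(manifest: ScanManifest | str | Path, config: RunConfig,
                 out_dir: str | Path) -> dict:
    """Run the full FRET analysis over a scan manifest.

    Writes ``fret_results.json``, ``titration_summary.tsv``,
    ``comparisons.tsv``, ``distances.json`` (DNA-pair runs), ``qc.json`` and
    ``provenance.json`` into *out_dir*; returns the bundle as a dict.
    Samples whose unmixing fails are flagged and skipped rather than
    aborting the run; the ``n_failed`` count in the QC report is nonzero in
    that case.
    """
    t0 = time.perf_counter()
    if not isinstance(manifest, ScanManifest):
        manifest = ScanManifest.from_json(manifest)
    if not manifest.entries:
        raise PipelineError("manifest contains no scan entries")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = config.pair
    stoich = LabelingStoichiometry(manifest.d_plus or config.d_plus)

    blanks = {}
    for exc in (pair.donor_exc_nm, pair.acceptor_exc_nm):
        key = f"{exc:g}"
        if key not in manifest.blank_paths:
            raise PipelineError(
                f"no blank scan for excitation {key} nm; affected samples: "
                f"{[e.condition for e in manifest.entries]}")
        blanks[exc] = read_spectrum(manifest.resolve(manifest.blank_paths[key]),
                                    exc, role="blank")

    if {"donor_only", "acceptor_only"} <= set(manifest.reference_paths):
        donor_ref = read_spectrum(
            manifest.resolve(manifest.reference_paths["donor_only"]),
            pair.donor_exc_nm, role="donor_only_ref")
        acceptor_ref = read_spectrum(
            manifest.resolve(manifest.reference_paths["acceptor_only"]),
            pair.donor_exc_nm, role="acceptor_only_ref")
    else:
        # fall back to the generator's parametric lineshapes
        donor_ref, acceptor_ref = reference_lineshapes(
            SimulationParams(pair=pair))
    log.info("loaded %d entries, blanks and references in %.2fs",
             len(manifest.entries), time.perf_counter() - t0)

    # pass 1: (ratio)_A per sample
    records, failed, neg_counts = [], [], 0
    for entry in manifest.entries:
        sp = _load_scan_pair(manifest, entry, pair, blanks)
        neg_counts += count_negative(sp.donor_exc_scan)
        neg_counts += count_negative(sp.acceptor_exc_scan)
        try:
            res = compute_ratio_A(sp, donor_ref, acceptor_ref,
                                  mode=config.unmix_mode,
                                  nonnegative=config.nonnegative_unmixing)
        except UnmixingError as exc:
            log.warning("sample %s failed unmixing: %s", sp.sample_id, exc)
            failed.append({"sample_id": sp.sample_id, "error": str(exc)})
            continue
        records.append((entry, res))

    ref_ratios = [r.ratio_A for e, r in records
                  if e.condition == manifest.reference_condition]
    if not ref_ratios:
        raise PipelineError(
            f"no reference-condition ({manifest.reference_condition!r}) "
            "samples; cannot anchor ΔE")
    ratio_A_ref = float(np.mean(ref_ratios))
    E_ref = efficiency_from_ratio_A(ratio_A_ref, stoich, pair)

    # pass 2: E and ΔE per sample
    results = []
    for entry, res in records:
        E = efficiency_from_ratio_A(res.ratio_A, stoich, pair)
        dE = delta_E(res.ratio_A, ratio_A_ref, E_ref, pair)
        results.append({
            "sample_id": res.sample_id, "condition": entry.condition,
            "ratio": entry.ratio, "replicate": entry.replicate,
            "ratio_A": res.ratio_A, "E": E, "delta_E": dE,
            "E_reference": E_ref,
            "donor_amplitude": res.donor_amplitude,
            "acceptor_amplitude": res.acceptor_amplitude,
            "residual_norm": res.residual_norm,
            "qc_flags": list(qc_flags_for_efficiency(E)),
        })

    # per-condition titration series over the non-reference conditions
    series_list = []
    conditions = sorted({r["condition"] for r in results
                         if r["condition"] != manifest.reference_condition})
    for cond in conditions:
        data: dict[float, list[float]] = {}
        for r in results:
            if r["condition"] == cond:
                data.setdefault(r["ratio"], []).append(r["delta_E"])
        series_list.append(TitrationSeries.from_mapping(cond, data))

    summary = (pd.concat([summarize_series(s) for s in series_list])
               if series_list else pd.DataFrame())
    saturation = {}
    for s in series_list:
        try:
            sat, plateau = detect_saturation(s, config.flatness_tol)
        except ValueError:
            sat, plateau = None, None
        saturation[s.condition] = {"saturation_ratio": sat,
                                   "plateau_delta_E": plateau}

    comparisons = pd.DataFrame()
    if len(series_list) >= 2:
        reference_cond = conditions[0] if "WT" not in conditions else "WT"
        try:
            comparisons = compare_conditions(
                series_list, reference_cond, aggregate=config.aggregate,
                variant=config.t_variant, flatness_tol=config.flatness_tol)
        except ValueError as exc:
            log.warning("condition comparison skipped: %s", exc)

    # distances only make sense for single-distance labels (DNA ends)
    distances = {}
    if config.pair_name == "dna_pair" or pair == DNA_PAIR:
        model = ForsterModel(pair.forster_radius_nm)
        for cond in conditions + [manifest.reference_condition]:
            Es = [r["E"] for r in results if r["condition"] == cond]
            if not Es:
                continue
            E_mean = float(np.mean(Es))
            if 0.0 < E_mean < 1.0:
                r_nm, ok = efficiency_to_distance(E_mean, model)
                distances[cond] = {"mean_E": E_mean, "distance_nm": r_nm,
                                   "in_valid_range": ok,
                                   "forster_radius_nm": model.forster_radius_nm}

    qc = {"n_samples": len(manifest.entries), "n_failed": len(failed),
          "failed": failed, "negative_intensity_points": neg_counts,
          "reference_ratio_A": ratio_A_ref, "reference_E": E_ref,
          "saturation": saturation}
    provenance = {"package_version": __version__,
                  "config_fingerprint": config.fingerprint(),
                  "seed": config.seed,
                  "d_plus": stoich.d_plus,
                  "pair": vars(pair)}

    _dump_json(out / "fret_results.json", results)
    summary.to_csv(out / "titration_summary.tsv", sep="\t", index=False)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    _dump_json(out / "distances.json", distances)
    _dump_json(out / "qc.json", qc)
    _dump_json(out / "provenance.json", provenance)
    log.info("analysis of %d samples done in %.2fs (%d failed)",
             len(manifest.entries), time.perf_counter() - t0, len(failed))
    return {"results": results, "summary": summary, "comparisons": comparisons,
            "distances": distances, "qc": qc, "provenance": provenance}


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float)
                    + "\n")


def recover_efficiency(params: SimulationParams, true_E: float,
                       rng: np.random.Generator) -> float:
    """Simulate one scan pair at a known efficiency and push it through the
    full analysis chain (blank subtraction → unmixing → (ratio)_A → E)."""
    from .simulate import _add_noise
    from .spectra import ACCEPTOR_EXC_GRID, DONOR_EXC_GRID

    sp = simulate_scan_pair_at_efficiency(params, true_E, rng)
    blanks = {}
    for grid, exc in ((DONOR_EXC_GRID, params.pair.donor_exc_nm),
                      (ACCEPTOR_EXC_GRID, params.pair.acceptor_exc_nm)):
        blanks[exc] = EmissionSpectrum(
            grid.copy(),
            _add_noise(np.full(grid.shape, params.background_level), params, rng),
            exc, role="blank")
    d = subtract_background(sp.donor_exc_scan, blanks[params.pair.donor_exc_nm])
    a = subtract_background(sp.acceptor_exc_scan,
                            blanks[params.pair.acceptor_exc_nm])
    donor_ref, acceptor_ref = reference_lineshapes(params)
    res = compute_ratio_A(ScanPair(d, a, sp.sample_id), donor_ref, acceptor_ref)
    return efficiency_from_ratio_A(res.ratio_A,
                                   params.mixture.stoichiometry(), params.pair)


def run_simulation_study(
    efficiency_grid=tuple(np.round(np.arange(0.1, 0.85, 0.1), 2)),
    noise_scales=(0.01,),
    n_replicates: int = 100,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo parameter-recovery study over a grid of true
    efficiencies and noise levels; returns per-cell bias and RMSE."""
    base = params or SimulationParams()
    rows = []
    for noise in noise_scales:
        cell_params = replace(
            base, noise_scale=noise,
            noise_model="none" if noise == 0 else "gaussian_shot")
        for E in efficiency_grid:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(round(1e6 * noise)),
                                        int(round(1e6 * E))]))
            rec = np.array([recover_efficiency(cell_params, float(E), rng)
                            for _ in range(n_replicates)])
            rows.append({"true_E": float(E), "noise_scale": noise,
                         "n": n_replicates,
                         "mean_recovered_E": float(rec.mean()),
                         "bias": float(rec.mean() - E),
                         "rmse": float(np.sqrt(np.mean((rec - E) ** 2)))})
    return pd.DataFrame(rows)


def power_study(delta_E_a: float, delta_E_b: float, sd: float, n: int,
                n_runs: int, alpha: float, seed: int = 0,
                variant: str = "pooled") -> float:
    """Fraction of simulated experiments in which two conditions with the
    given true ΔE values, replicate SD and group size reach p < alpha."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    hits = 0
    for _ in range(n_runs):
        a = rng.normal(delta_E_a, sd, n)
        b = rng.normal(delta_E_b, sd, n)
        if students_t_test(a, b, variant=variant).p_value < alpha:
            hits += 1
    return hits / n_runs


def assay_power_study(delta_E_a: float, delta_E_b: float, sd: float,
                      n_replicates: int = 3, n_saturated_ratios: int = 3,
                      n_runs: int = 500, alpha: float = 0.001, seed: int = 0,
                      variant: str = "pooled") -> float:
    """Power of the assay's condition contrast as actually tested: replicate
    ΔE values drawn at each saturated titration ratio are pooled per
    condition before the t-test (n_replicates × n_saturated_ratios values
    per group).  At saturation the draws share one true ΔE, so pooling is
    exact, not an approximation."""
    return power_study(delta_E_a, delta_E_b, sd,
                       n_replicates * n_saturated_ratios, n_runs, alpha,
                       seed=seed, variant=variant)


def type_i_study(delta_E: float, sd: float, n: int, n_runs: int,
                 alpha: float = 0.05, seed: int = 0,
                 variant: str = "pooled") -> float:
    """False-positive rate under the null (both conditions share true ΔE)."""
    return power_study(delta_E, delta_E, sd, n, n_runs, alpha,
                       seed=seed + 1, variant=variant)
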