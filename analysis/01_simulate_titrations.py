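#!/usr/bin/env python
"""Simulate the three nucleosome conditions as full titration datasets.

Writes synthetic fluorometer scan CSVs, manifests and ground truth under
results/data/<condition>/ for wild-type H3 (ΔE 0.40), tailless H3 "gH3"
(ΔE 0.18) and the six-lysine acetylation mimic "6KQ" (ΔE 0.28), each with
3 replicates per nucleosome:H1 ratio and 1% shot noise.
"""

from pathlib import Path

from h1fret.simulate import (CONDITION_DELTA_E, SimulationParams,
                             simulate_titration_dataset)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    for i, (condition, d_e) in enumerate(sorted(CONDITION_DELTA_E.items())):
        params = SimulationParams(
            true_E_free=0.15, true_E_bound=0.15 + d_e,
            noise_model="gaussian_shot", noise_scale=0.01,
            n_replicates=3, seed=100 + i)
        manifest = simulate_titration_dataset(
            params, saturation_ratio=1.0, out_dir=OUT / condition,
            condition=condition)
        n = len(params.titration_ratios) * params.n_replicates + params.n_replicates
        print(f"{condition}: true plateau ΔE = {d_e:.2f}, "
              f"{n} scan pairs -> {manifest}")


if __name__ == "__main__":
    main()
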