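#!/usr/bin/env python
"""Compare H1 CTD condensation across nucleosome conditions.

Pools replicate ΔE values over the saturated titration ratios for each
condition and tests every condition against wild type with a two-tailed
pooled-variance Student's t-test, starring significance at
***<0.001, **<0.01, *<0.05.  Writes results/comparisons.tsv.
"""

import json
from pathlib import Path

from h1fret.stats import TitrationSeries, compare_conditions

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series_list = []
    for path in sorted(ROOT.glob("analysis/*/fret_results.json")):
        results = json.loads(path.read_text())
        data: dict[float, list[float]] = {}
        condition = path.parent.name
        for r in results:
            if r["condition"] == condition:
                data.setdefault(r["ratio"], []).append(r["delta_E"])
        series_list.append(TitrationSeries.from_mapping(condition, data))

    table = compare_conditions(series_list, reference="WT",
                               aggregate="pooled_saturated")
    table.to_csv(ROOT / "comparisons.tsv", sep="\t", index=False)
    for _, row in table.iterrows():
        print(f"{row['condition']} vs WT (pooled saturated ratios, "
              f"n={row['n_a']}+{row['n_b']}): t={row['t']:.2f}, "
              f"p={row['p']:.2e} {row['stars']}")


if __name__ == "__main__":
    main()
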