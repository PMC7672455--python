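"""Replicate statistics for ΔE titrations: summaries, saturation detection
and condition comparisons.

Conventions follow common practice for this assay: error bars are sample
standard deviations (n−1 denominator), conditions are compared with a
two-tailed Student's t-test (pooled variance by default, Welch available),
and significance is starred at strict thresholds ***<0.001, **<0.01,
*<0.05, else NS.  Comparisons with fewer than 3 replicates per group are
flagged.  No multiple-testing correction is applied by default (raw
per-comparison p values are reported); a Holm adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class RatioPoint:
    ratio: float
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise ValueError(f"ratio {self.ratio}: need at least one replicate")


@dataclass(frozen=True)
class TitrationSeries:
    """Replicate ΔE values across nucleosome:H1 ratios for one condition."""

    condition: str
    points: tuple[RatioPoint, ...]

    def __post_init__(self) -> None:
        ratios = [p.ratio for p in self.points]
        if len(set(ratios)) != len(ratios):
            raise ValueError(f"{self.condition}: duplicate ratios")
        object.__setattr__(
            self, "points",
            tuple(sorted(self.points, key=lambda p: p.ratio)))

    @classmethod
    def from_mapping(cls, condition: str,
                     data: dict[float, list[float]]) -> "TitrationSeries":
        return cls(condition, tuple(
            RatioPoint(float(r), tuple(v)) for r, v in data.items()))

    def ratios(self) -> list[float]:
        return [p.ratio for p in self.points]


@dataclass(frozen=True)
class ConditionComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    stars: str
    variant: str
    qc_flags: tuple[str, ...] = ()


def summarize_series(series: TitrationSeries) -> pd.DataFrame:
    """Per-ratio mean, sample SD and n.

    SD is reported as NaN with a QC flag for single-replicate points rather
    than silently as zero.
    """
    rows = []
    for p in series.points:
        vals = np.asarray(p.replicates)
        n = vals.size
        rows.append({
            "condition": series.condition,
            "ratio": p.ratio,
            "n": n,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else np.nan,
            "qc": "" if n >= 3 else ("single_replicate" if n == 1 else "n_below_3"),
        })
    return pd.DataFrame(rows)


def students_t_test(a, b, variant: str = "pooled",
                    label_a: str = "A", label_b: str = "B") -> ConditionComparison:
    """Two-sample two-tailed t-test on replicate sets.

    ``variant`` is ``pooled`` (classic Student, equal-variance) or
    ``welch``.  Two identical-mean zero-variance sets give p = 1 by
    convention rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 replicates per group, got {a.size} and {b.size}")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    flags = [] if min(a.size, b.size) >= 3 else ["n_below_3"]
    equal_var = variant == "pooled"
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p, df = 0.0, float(a.size + b.size - 2)
            flags.append("zero_variance")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return ConditionComparison(label_a, label_b, a.size, b.size, t, df, p,
                               significance_stars(p), variant, tuple(flags))


def significance_stars(p: float) -> str:
    """Star code at strict thresholds: ***<0.001, **<0.01, *<0.05, else NS."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (optional; raw p values are the default)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def detect_saturation(series: TitrationSeries, flatness_tol: float = 0.1
                      ) -> tuple[float | None, float | None]:
    """Find the titration ratio beyond which ΔE has plateaued.

    Returns ``(saturation_ratio, plateau_mean)`` — the smallest ratio from
    which every successive pair of per-ratio means differs by less than
    ``flatness_tol`` times the plateau mean — or ``(None, None)`` when no
    plateau of at least two ratios exists.
    """
    if len(series.points) < 3:
        raise ValueError("need at least 3 titration ratios to assess saturation")
    if flatness_tol <= 0:
        raise ValueError("flatness_tol must be positive")
    ratios = np.array(series.ratios())
    means = np.array([np.mean(p.replicates) for p in series.points])
    for start in range(len(ratios) - 1):
        plateau = means[start:]
        plateau_mean = float(plateau.mean())
        if plateau_mean == 0.0:
            continue
        if np.all(np.abs(np.diff(plateau)) < flatness_tol * abs(plateau_mean)):
            return float(ratios[start]), plateau_mean
    return None, None


def pooled_saturated_replicates(series: TitrationSeries,
                                flatness_tol: float = 0.1) -> np.ndarray:
    """All replicate ΔE values at ratios in the detected plateau."""
    sat, _ = detect_saturation(series, flatness_tol)
    if sat is None:
        raise ValueError(f"{series.condition}: no saturation plateau detected")
    vals = [v for p in series.points if p.ratio >= sat for v in p.replicates]
    return np.asarray(vals)


def compare_conditions(series_list: list[TitrationSeries], reference: str,
                       aggregate: str = "pooled_saturated",
                       variant: str = "pooled",
                       flatness_tol: float = 0.1) -> pd.DataFrame:
    """Compare every condition against the reference condition.

    ``aggregate='pooled_saturated'`` pools replicates across saturated
    ratios before testing (one test per condition pair);
    ``aggregate='per_ratio'`` tests at each shared ratio.
    """
    by_label = {s.condition: s for s in series_list}
    if reference not in by_label:
        raise ValueError(f"reference condition {reference!r} not among "
                         f"{sorted(by_label)}")
    ref = by_label[reference]
    rows = []
    for label, series in by_label.items():
        if label == reference:
            continue
        if aggregate == "pooled_saturated":
            cmp = students_t_test(
                pooled_saturated_replicates(series, flatness_tol),
                pooled_saturated_replicates(ref, flatness_tol),
                variant=variant, label_a=label, label_b=reference)
            rows.append({"condition": label, "reference": reference,
                         "ratio": "pooled", "n_a": cmp.n_a, "n_b": cmp.n_b,
                         "t": cmp.t_statistic, "df": cmp.df, "p": cmp.p_value,
                         "stars": cmp.stars, "qc": ";".join(cmp.qc_flags)})
        elif aggregate == "per_ratio":
            shared = sorted(set(series.ratios()) & set(ref.ratios()))
            if not shared:
                raise ValueError(f"{label} and {reference} share no ratios")
            pts_a = {p.ratio: p for p in series.points}
            pts_b = {p.ratio: p for p in ref.points}
            for r in shared:
                cmp = students_t_test(
                    pts_a[r].replicates, pts_b[r].replicates,
                    variant=variant, label_a=label, label_b=reference)
                rows.append({"condition": label, "reference": reference,
                             "ratio": r, "n_a": cmp.n_a, "n_b": cmp.n_b,
                             "t": cmp.t_statistic, "df": cmp.df,
                             "p": cmp.p_value, "stars": cmp.stars,
                             "qc": ";".join(cmp.qc_flags)})
        else:
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return pd.DataFrame(rows)
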