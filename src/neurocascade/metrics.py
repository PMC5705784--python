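"""Descriptive statistics of the BrdU+ cascade.

Normalisation to the 2 h progenitor pool, per-day and peak-relative interval
losses, and the neurogenic / astrogenic yields of the proliferating
progenitors (30 d newborn neurons or astrocytes per 2 h BrdU+ cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "YieldResult",
    "normalize_to_2h",
    "loss_per_day",
    "loss_rate_of_peak",
    "yields",
    "yields_table",
]


@dataclass(frozen=True)
class YieldResult:
    """Neurogenic and astrogenic yield of the 2 h progenitor pool at one age.

    ``ratio`` is neuronal over astrocytic yield; the shared 2 h denominator
    cancels, so it equals the 30 d neuron/astrocyte count ratio.  A zero
    astrocytic yield leaves the ratio NaN with ``ratio_defined`` False.
    """

    age_months: float
    neuronal_yield: float
    astrocytic_yield: float

    @property
    def ratio_defined(self) -> bool:
        return self.astrocytic_yield > 0

    @property
    def ratio(self) -> float:
        if not self.ratio_defined:
            return float("nan")
        return self.neuronal_yield / self.astrocytic_yield


def normalize_to_2h(counts: dict[str, float]) -> dict[str, float]:
    """Express each timepoint count as a percentage of the 2 h count."""
    if "2h" not in counts:
        raise ValueError("counts must include the 2h timepoint")
    base = counts["2h"]
    if base <= 0:
        raise ValueError(f"2h count must be > 0 to normalize, got {base}")
    return {tp: 100.0 * c / base for tp, c in counts.items()}


def loss_per_day(count_t1: float, count_t2: float, t1: float, t2: float) -> float:
    """Cells lost per day over [t1, t2]; negative means net gain."""
    if t2 <= t1:
        raise ValueError(f"t2 must exceed t1, got t1={t1}, t2={t2}")
    return (count_t1 - count_t2) / (t2 - t1)


def loss_rate_of_peak(count_t1: float, count_t2: float, count_2d: float) -> float:
    """Interval loss as a percentage of the 2 d peak count."""
    if count_2d <= 0:
        raise ValueError(f"2d peak count must be > 0, got {count_2d}")
    return 100.0 * (count_t1 - count_t2) / count_2d


def yields(mean_2h: float, mean_neun_30d: float, mean_gfap_30d: float,
           age_months: float = float("nan")) -> YieldResult:
    """Neurogenic and astrogenic yield from group means."""
    if mean_2h <= 0:
        raise ValueError(f"2h mean must be > 0, got {mean_2h}")
    if mean_neun_30d < 0 or mean_gfap_30d < 0:
        raise ValueError("30d marker means must be >= 0")
    return YieldResult(
        age_months=age_months,
        neuronal_yield=mean_neun_30d / mean_2h,
        astrocytic_yield=mean_gfap_30d / mean_2h,
    )


def yields_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-age yields and neuron-to-astrocyte ratio from a summary table."""
    rows = []
    for age in sorted(summaries["age_months"].unique()):
        sub = summaries[summaries["age_months"] == age]

        def mean_of(tp, marker):
            r = sub[(sub["timepoint"] == tp) & (sub["marker"] == marker)]
            return float(r.iloc[0]["mean"]) if not r.empty else np.nan

        m2h = mean_of("2h", "total")
        neun = mean_of("30d", "NeuN")
        gfap = mean_of("30d", "GFAP")
        if np.isnan(m2h) or np.isnan(neun) or np.isnan(gfap):
            continue
        yr = yields(m2h, neun, gfap, age_months=age)
        rows.append(
            {
                "age_months": age,
                "neuronal_yield": yr.neuronal_yield,
                "astrocytic_yield": yr.astrocytic_yield,
                "ratio": yr.ratio,
            }
        )
    return pd.DataFrame(rows)
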