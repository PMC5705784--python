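"""Extra-survival scenario decomposition and allocation search.

Mature ages (6, 12 m) show more 30 d survivors than the young (1 m) survival
and differentiation pattern predicts.  The 30 d net survival at a mature age
is decomposed as

    n30d(a) = baseline + extra,   baseline = n2d(a) * n30d(ref) / n2d(ref)

with the baseline split into neurons and astrocytes by the reference age's
30 d marker fractions.  A scenario assigns a fraction ``p_neuron`` of the
extra survival to neurons (the rest to astrocytes) and yields the
neuron-to-astrocyte ratio

    R(p) = (N_b + p E) / (A_b + (1 - p) E).

The allocation that reproduces a target ratio is found by the iterative
midpoint (bisection) comparison of scenario pairs, starting from the 50:50
and 0:100 pair, expanding the bracket beyond [0, 1] in 0.25 steps up to
[-1, 2] when needed (negative neuron allocations are meaningful: the mature
niche can fall below the young baseline).  Every bisection answer is
cross-checked against the closed form

    p* = (R (A_b + E) - N_b) / (E (1 + R)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SurvivalDecomposition",
    "ScenarioResult",
    "decompose",
    "scenario_ratio",
    "closed_form_allocation",
    "find_allocation",
]


@dataclass(frozen=True)
class SurvivalDecomposition:
    """Baseline vs extra 30 d net survival at one age, against a reference age."""

    age_months: float
    baseline_neurons: float
    baseline_astrocytes: float
    extra: float
    reference_age: float = 1.0

    def __post_init__(self):
        if self.baseline_neurons < 0 or self.baseline_astrocytes < 0:
            raise ValueError("baseline counts must be >= 0")


@dataclass
class ScenarioResult:
    """Outcome of the allocation search for one decomposition and target."""

    p_neuron: float
    achieved_ratio: float
    target_ratio: float
    iterations: int
    converged: bool
    trace: list[tuple[float, float]] = field(default_factory=list)
    degenerate: bool = False
    target_source: str = "unspecified"


def _mean(summaries: pd.DataFrame, age, timepoint, marker) -> float:
    row = summaries[
        (summaries["age_months"] == age)
        & (summaries["timepoint"] == timepoint)
        & (summaries["marker"] == marker)
    ]
    if row.empty:
        raise ValueError(
            f"missing summary: age {age} m, {timepoint}, {marker}"
        )
    return float(row.iloc[0]["mean"])


def decompose(
    summaries: pd.DataFrame, age: float, reference_age: float = 1.0
) -> SurvivalDecomposition:
    """Split an age's 30 d survival into reference-pattern baseline and extra.

    The baseline anchors on the 2 d peak: the age's 2 d count times the
    reference age's 2d→30d survival fraction, partitioned by the reference
    age's 30 d NeuN/GFAP percentages.  ``extra`` is the observed 30 d count
    minus that baseline (any sign).
    """
    n2d_a = _mean(summaries, age, "2d", "total")
    n30d_a = _mean(summaries, age, "30d", "total")
    n2d_ref = _mean(summaries, reference_age, "2d", "total")
    n30d_ref = _mean(summaries, reference_age, "30d", "total")
    if n2d_ref == 0:
        raise ValueError(f"reference age {reference_age} m has zero 2d count")
    neun_frac = _mean(summaries, reference_age, "30d", "NeuN_pct") / 100.0
    gfap_frac = _mean(summaries, reference_age, "30d", "GFAP_pct") / 100.0
    baseline_total = n2d_a * (n30d_ref / n2d_ref)
    return SurvivalDecomposition(
        age_months=age,
        baseline_neurons=baseline_total * neun_frac,
        baseline_astrocytes=baseline_total * gfap_frac,
        extra=n30d_a - baseline_total,
        reference_age=reference_age,
    )


def scenario_ratio(dec: SurvivalDecomposition, p_neuron: float) -> float:
    """Neuron-to-astrocyte ratio when fraction p of the extra goes to neurons."""
    denom = dec.baseline_astrocytes + (1.0 - p_neuron) * dec.extra
    if denom <= 0:
        return float("nan")
    return (dec.baseline_neurons + p_neuron * dec.extra) / denom


def closed_form_allocation(dec: SurvivalDecomposition, target_ratio: float) -> float:
    """Exact allocation solving R(p*) = target (independent of the search)."""
    if dec.extra == 0:
        raise ValueError("extra survival is zero; allocation is undefined")
    return (
        target_ratio * (dec.baseline_astrocytes + dec.extra) - dec.baseline_neurons
    ) / (dec.extra * (1.0 + target_ratio))


def find_allocation(
    dec: SurvivalDecomposition,
    target_ratio: float,
    tolerance: float = 1e-6,
    max_iter: int = 200,
    target_source: str = "unspecified",
) -> ScenarioResult:
    """Iterative midpoint search for the allocation matching a target ratio.

    Brackets the target between two scenarios (initially p = 0.5 and p = 0),
    repeatedly evaluates the midpoint and keeps the half that still encloses
    the target; the bracket grows in 0.25 steps up to [-1, 2] when the target
    lies outside the current pair.  The converged p is cross-checked against
    :func:`closed_form_allocation`; disagreement beyond tolerance is an
    internal error.
    """
    if target_ratio < 0:
        raise ValueError(f"target_ratio must be >= 0, got {target_ratio}")
    if dec.extra == 0:
        base = scenario_ratio(dec, 0.0)
        if abs(base - target_ratio) <= tolerance:
            return ScenarioResult(
                p_neuron=0.0, achieved_ratio=base, target_ratio=target_ratio,
                iterations=0, converged=True, degenerate=True,
                target_source=target_source,
            )
        raise ValueError(
            "extra survival is zero and the baseline ratio "
            f"{base:.6g} does not match the target {target_ratio:.6g}"
        )

    trace: list[tuple[float, float]] = []

    def ratio(p):
        r = scenario_ratio(dec, p)
        if not (r == r):  # past the denominator pole: ratio diverges to +inf
            r = float("inf")
        trace.append((p, r))
        return r

    # the ratio is monotone in p (increasing for extra > 0); bracket the
    # target starting from the 50:50 / 0:100 scenario pair
    lo, hi = 0.0, 0.5
    f_lo, f_hi = ratio(lo) - target_ratio, ratio(hi) - target_ratio
    while f_lo * f_hi > 0:
        expanded = False
        if lo > -1.0 + 1e-12:
            lo = max(lo - 0.25, -1.0)
            f_lo = ratio(lo) - target_ratio
            expanded = True
            if f_lo * f_hi <= 0:
                break
        if hi < 2.0 - 1e-12:
            hi = min(hi + 0.25, 2.0)
            f_hi = ratio(hi) - target_ratio
            expanded = True
        if not expanded:
            raise ValueError(
                f"target ratio {target_ratio:.6g} not reachable for "
                f"p in [-1, 2] (ratio range [{min(f_lo, f_hi) + target_ratio:.6g}, "
                f"{max(f_lo, f_hi) + target_ratio:.6g}])"
            )

    # converge on both the ratio residual and the bracket width, so the
    # returned p itself is within tolerance of the exact allocation
    converged = False
    p_mid = (lo + hi) / 2
    for it in range(1, max_iter + 1):
        p_mid = (lo + hi) / 2
        f_mid = ratio(p_mid) - target_ratio
        if abs(f_mid) <= tolerance and (hi - lo) / 2 <= tolerance:
            converged = True
            break
        if f_lo * f_mid <= 0:
            hi, f_hi = p_mid, f_mid
        else:
            lo, f_lo = p_mid, f_mid

    achieved = scenario_ratio(dec, p_mid)
    p_exact = closed_form_allocation(dec, target_ratio)
    if converged and abs(p_mid - p_exact) > 2 * tolerance:
        raise RuntimeError(
            f"bisection allocation {p_mid:.8g} disagrees with closed form "
            f"{p_exact:.8g}"
        )
    return ScenarioResult(
        p_neuron=p_mid,
        achieved_ratio=achieved,
        target_ratio=target_ratio,
        iterations=it,
        converged=converged,
        trace=trace,
        target_source=target_source,
    )
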