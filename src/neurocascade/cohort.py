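"""Constrained Marsaglia-polar simulation of nested BrdU+ cohorts.

For each animal age the simulator draws pseudo-animals (replicate nested
vectors 2h…30d plus the 30 d marker split) from the experimentally estimated
group means and SDs, subject to the biological restrictions

    2h <= 2d >= 4d >= 10d >= 30d >= (GFAP + NeuN)

with GFAP + NeuN = 30d exactly under either locked strategy: GFAP-locked
draws the astrocyte percentage from its normal law and assigns the 30 d
remainder to neurons; NeuN-locked is symmetric.

Constraint enforcement is sequential forward rejection (draw 2h, redraw 2d
until >= 2h, then redraw each later timepoint until <= its predecessor,
all floored at 0); a joint-rejection mode — draw the whole unconstrained
vector and discard it on any violation — is available for sensitivity
analysis.  Counts stay real-valued inside the simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marsaglia import MarsagliaRNG, InfeasibleIntervalError
from .synthetic import TIMEPOINTS

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "direct_simulation",
    "deviation_from_experiment",
    "MarsagliaCohortSimulator",
]

_JOINT_CAP = 10**6


@dataclass
class SimulationConfig:
    """Configuration of one Marsaglia cohort simulation run.

    ``summaries`` must cover, for every age, the total count at all five
    timepoints plus the 30 d ``NeuN_pct`` and ``GFAP_pct`` rows.
    ``n_replicates`` defaults to 1000 pseudorandom cells per age group.
    """

    summaries: pd.DataFrame
    n_replicates: int = 1000
    strategy: str = "gfap-locked"
    seed: int = 0
    mode: str = "sequential"  # or "joint"

    def __post_init__(self):
        if self.strategy not in ("gfap-locked", "neun-locked"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.mode not in ("sequential", "joint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _require(summaries: pd.DataFrame, age: float, timepoint: str, marker: str):
    row = summaries[
        (summaries["age_months"] == age)
        & (summaries["timepoint"] == timepoint)
        & (summaries["marker"] == marker)
    ]
    if row.empty:
        raise ValueError(
            f"missing summary row: age {age} m, timepoint {timepoint}, marker {marker}"
        )
    r = row.iloc[0]
    return float(r["mean"]), float(r["sd"])


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Run the constrained simulation; one row per replicate pseudo-animal.

    Returns a DataFrame with columns ``age_months, replicate, n2h, n2d, n4d,
    n10d, n30d, n_gfap, n_neun, strategy``.  Every emitted record satisfies
    the nested ordering and the locked-marker identity by construction.
    """
    rng = MarsagliaRNG(config.seed)
    ages = sorted(config.summaries["age_months"].unique())
    records = []
    for age in ages:
        laws = {tp: _require(config.summaries, age, tp, "total") for tp in TIMEPOINTS}
        gfap_pct = _require(config.summaries, age, "30d", "GFAP_pct")
        neun_pct = _require(config.summaries, age, "30d", "NeuN_pct")
        means = [laws[tp][0] for tp in TIMEPOINTS]
        if not (
            means[0] <= means[1] >= means[2] >= means[3] >= means[4]
        ):
            warnings.warn(
                f"experimental means at age {age} m do not satisfy the nested "
                "ordering; rejection rates may be high",
                stacklevel=2,
            )
        for rep in range(config.n_replicates):
            if config.mode == "sequential":
                vec = _draw_sequential(rng, laws, age)
            else:
                vec = _draw_joint(rng, laws, age)
            n30d = vec["30d"]
            if config.strategy == "gfap-locked":
                frac = rng.truncated_normal(gfap_pct[0] / 100, gfap_pct[1] / 100, 0.0, 1.0)
                n_gfap = frac * n30d
                n_neun = n30d - n_gfap
            else:
                frac = rng.truncated_normal(neun_pct[0] / 100, neun_pct[1] / 100, 0.0, 1.0)
                n_neun = frac * n30d
                n_gfap = n30d - n_neun
            records.append(
                (age, rep, vec["2h"], vec["2d"], vec["4d"], vec["10d"], vec["30d"],
                 n_gfap, n_neun, config.strategy)
            )
    return pd.DataFrame(
        records,
        columns=["age_months", "replicate", "n2h", "n2d", "n4d", "n10d", "n30d",
                 "n_gfap", "n_neun", "strategy"],
    )


_VECTOR_RESTART_CAP = 1000


def _draw_sequential(rng: MarsagliaRNG, laws, age):
    # an extreme early draw can leave a later timepoint with almost no mass
    # below it; pure rejection would stall there, so vectors whose next step
    # holds < 1e-3 acceptance mass are abandoned and redrawn whole
    last: InfeasibleIntervalError | None = None
    mm = 1e-3
    for _ in range(_VECTOR_RESTART_CAP):
        try:
            n2h = rng.truncated_normal(*laws["2h"], 0.0, np.inf, min_mass=mm)
            n2d = rng.truncated_normal(*laws["2d"], n2h, np.inf, min_mass=mm)
            n4d = rng.truncated_normal(*laws["4d"], 0.0, n2d, min_mass=mm)
            n10d = rng.truncated_normal(*laws["10d"], 0.0, n4d, min_mass=mm)
            n30d = rng.truncated_normal(*laws["30d"], 0.0, n10d, min_mass=mm)
        except InfeasibleIntervalError as e:
            last = e
            continue
        return {"2h": n2h, "2d": n2d, "4d": n4d, "10d": n10d, "30d": n30d}
    raise InfeasibleIntervalError(
        f"age {age} m: sequential draw infeasible after "
        f"{_VECTOR_RESTART_CAP} vector restarts ({last})"
    )


def _draw_joint(rng: MarsagliaRNG, laws, age):
    for _ in range(_JOINT_CAP):
        v = {tp: rng.normal(*laws[tp]) for tp in TIMEPOINTS}
        ok = (
            0 <= v["2h"] <= v["2d"]
            and v["2d"] >= v["4d"] >= v["10d"] >= v["30d"] >= 0
        )
        if ok:
            return v
    raise InfeasibleIntervalError(
        f"age {age} m: joint rejection failed to satisfy the ordering"
    )


class MarsagliaCohortSimulator:
    """Thin object wrapper: build from summaries, ``simulate()`` per config."""

    def __init__(self, summaries: pd.DataFrame):
        self.summaries = summaries

    def simulate(self, n_replicates=1000, strategy="gfap-locked", seed=0,
                 mode="sequential") -> pd.DataFrame:
        return simulate_cohort(
            SimulationConfig(self.summaries, n_replicates, strategy, seed, mode)
        )


def records_to_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise simulated cohort records into the GroupSummary schema.

    Emits total-count rows per timepoint, 30 d NeuN/GFAP count rows, and the
    NeuN_pct/GFAP_pct rows (per-replicate marker percentage of n30d), so the
    simulated population can feed the same metrics, decomposition and
    scenario-search code paths as experimental summaries.
    """
    col_tp = [("n2h", "2h", "total"), ("n2d", "2d", "total"), ("n4d", "4d", "total"),
              ("n10d", "10d", "total"), ("n30d", "30d", "total"),
              ("n_neun", "30d", "NeuN"), ("n_gfap", "30d", "GFAP")]
    rows = []
    for age, grp in records.groupby("age_months"):
        for col, tp, marker in col_tp:
            s = grp[col]
            rows.append((age, tp, marker, s.mean(), s.std(ddof=1), len(s)))
        for col, marker in (("n_neun", "NeuN_pct"), ("n_gfap", "GFAP_pct")):
            pct = 100.0 * grp[col] / grp["n30d"].replace(0, np.nan)
            pct = pct.dropna()
            rows.append((age, "30d", marker, pct.mean(),
                         pct.std(ddof=1) if len(pct) > 1 else 0.0, len(pct)))
    return pd.DataFrame(
        rows, columns=["age_months", "timepoint", "marker", "mean", "sd", "n"]
    )


def direct_simulation(
    counts_2h: np.ndarray | pd.Series,
    survival_rate: float,
    neun_fraction: float,
    gfap_fraction: float,
) -> pd.DataFrame:
    """Mean-rate simulation: per-animal 30 d neurons and astrocytes.

    Applies the age's mean 2h→30d net survival rate and the 30 d
    differentiation fractions to each animal's 2 h progenitor count:
    ``neurons = n2h * survival_rate * neun_fraction`` and likewise for
    astrocytes.  No stochasticity — this is the paper-style direct estimate
    from group means.
    """
    counts = np.asarray(counts_2h, dtype=float)
    if (counts < 0).any():
        raise ValueError("2 h counts must be non-negative")
    if survival_rate < 0:
        raise ValueError(f"survival_rate must be >= 0, got {survival_rate}")
    for name, f in (("neun_fraction", neun_fraction), ("gfap_fraction", gfap_fraction)):
        if not (0 <= f <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    survivors = counts * survival_rate
    return pd.DataFrame(
        {
            "n2h": counts,
            "neurons": survivors * neun_fraction,
            "astrocytes": survivors * gfap_fraction,
        }
    )


def deviation_from_experiment(
    records: pd.DataFrame, summaries: pd.DataFrame
) -> float:
    """Mean absolute relative deviation (%) of simulated from experimental means.

    Averaged over every (age x population) cell, populations being the five
    total-count timepoints plus the 30 d GFAP and NeuN counts when the
    experimental summaries carry them.  Cells whose experimental mean is 0
    are excluded with a warning.
    """
    col_for = {"2h": "n2h", "2d": "n2d", "4d": "n4d", "10d": "n10d", "30d": "n30d",
               "GFAP": "n_gfap", "NeuN": "n_neun"}
    devs = []
    for age, grp in records.groupby("age_months"):
        for pop, col in col_for.items():
            tp = "30d" if pop in ("GFAP", "NeuN") else pop
            marker = pop if pop in ("GFAP", "NeuN") else "total"
            row = summaries[
                (summaries["age_months"] == age)
                & (summaries["timepoint"] == tp)
                & (summaries["marker"] == marker)
            ]
            if row.empty:
                continue
            exp_mean = float(row.iloc[0]["mean"])
            if exp_mean == 0:
                warnings.warn(
                    f"experimental mean 0 for age {age} m {pop}; cell excluded",
                    stacklevel=2,
                )
                continue
            sim_mean = float(grp[col].mean())
            devs.append(abs(sim_mean - exp_mean) / exp_mean * 100.0)
    if not devs:
        raise ValueError("no comparable (age x population) cells")
    return float(np.mean(devs))
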