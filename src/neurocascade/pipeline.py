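"""End-to-end orchestration of the cascade analysis.

Runs, in order: group summaries → longitudinal plateau-decay fits per age →
transversal exponential fits per population → direct mean-rate simulation
with cross-age regression → constrained Marsaglia simulation under both
locked strategies with deviation scoring → yield/ratio tables → extra-
survival scenario search at the mature ages.  Writes one JSON report plus
per-stage CSVs; identical config and seed reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import (
    TIMEPOINT_DAYS,
    DAYS_PER_MONTH,
    summarize,
)
from .cohort import (
    SimulationConfig,
    simulate_cohort,
    records_to_summaries,
    direct_simulation,
    deviation_from_experiment,
)
from .decay import (
    PlateauDecayModel,
    ExponentialDecayModel,
    linear_regression,
)
from .metrics import yields_table
from .scenario import decompose, find_allocation

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original error."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


@dataclass
class RunConfig:
    """Reproducible configuration of one full analysis run."""

    n_replicates: int = 1000
    seed: int = 0
    strategy: str = "gfap-locked"
    reference_age: float = 1.0
    days_per_month: float = DAYS_PER_MONTH
    scenario_tolerance: float = 1e-6
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _longitudinal_points(observations: pd.DataFrame, age: float):
    sub = observations[
        (observations["age_months"] == age)
        & (observations["marker"] == "total")
        & (observations["timepoint"] != "2h")  # 2d-30d window only
    ]
    t = sub["timepoint"].map(TIMEPOINT_DAYS).to_numpy(dtype=float)
    return t, sub["count"].to_numpy(dtype=float)


def run_full_pipeline(observations: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Execute the whole analysis on a tidy observation table.

    Returns the report as a nested dict (also written to ``config.outdir``
    when set, as ``report.json`` plus per-stage CSVs).  Raises
    :class:`PipelineError` naming the failing stage; outputs of completed
    stages are preserved in ``err.partial`` when an outdir is set.
    """
    config = config or RunConfig()
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str):
        if outdir is not None:
            df.to_csv(outdir / name, index=False)

    stage = "summarize"
    try:
        summaries = summarize(observations)
        save(summaries, "summaries.csv")
        ages = sorted(summaries["age_months"].unique())
        report["ages"] = [float(a) for a in ages]

        stage = "longitudinal_fits"
        long_fits = {}
        for age in ages:
            t, y = _longitudinal_points(observations, age)
            fit = PlateauDecayModel(t, y, anchor_t=2.0).fit()
            long_fits[age] = fit
        report["longitudinal"] = {
            f"{age:g}m": f.to_dict() for age, f in long_fits.items()
        }

        stage = "transversal_fits"
        trans_fits = {}
        pops = [("2h", "total", "progenitors_2h"),
                ("30d", "NeuN", "neurons_30d"),
                ("30d", "GFAP", "astrocytes_30d")]
        for tp, marker, name in pops:
            sub = observations[
                (observations["timepoint"] == tp) & (observations["marker"] == marker)
            ]
            x = sub["age_months"].to_numpy(dtype=float) * config.days_per_month
            fit = ExponentialDecayModel(x, sub["count"].to_numpy(dtype=float)).fit()
            trans_fits[name] = fit
        report["transversal"] = {k: f.to_dict() for k, f in trans_fits.items()}

        stage = "direct_simulation"
        direct_rows = []
        for age in ages:
            sub = summaries[summaries["age_months"] == age]

            def smean(tp, marker, _sub=sub):
                r = _sub[(_sub["timepoint"] == tp) & (_sub["marker"] == marker)]
                return float(r.iloc[0]["mean"]) if not r.empty else np.nan

            m2h, m30d = smean("2h", "total"), smean("30d", "total")
            neun_f = smean("30d", "NeuN_pct") / 100.0
            gfap_f = smean("30d", "GFAP_pct") / 100.0
            counts_2h = observations[
                (observations["age_months"] == age)
                & (observations["timepoint"] == "2h")
                & (observations["marker"] == "total")
            ]["count"].to_numpy(dtype=float)
            sim = direct_simulation(counts_2h, m30d / m2h, neun_f, gfap_f)
            sim.insert(0, "age_months", age)
            direct_rows.append(sim)
        direct = pd.concat(direct_rows, ignore_index=True)
        save(direct, "direct_simulation.csv")
        reg_n = linear_regression(direct["n2h"], direct["neurons"])
        reg_a = linear_regression(direct["n2h"], direct["astrocytes"])
        report["direct_regression"] = {
            "neurons": asdict(reg_n),
            "astrocytes": asdict(reg_a),
        }

        stage = "cohort_sim"
        sim_records = {}
        deviations = {}
        for strategy in ("gfap-locked", "neun-locked"):
            records = simulate_cohort(
                SimulationConfig(
                    summaries,
                    n_replicates=config.n_replicates,
                    strategy=strategy,
                    seed=config.seed,
                )
            )
            sim_records[strategy] = records
            deviations[strategy] = deviation_from_experiment(records, summaries)
            save(records, f"cohort_{strategy}.csv")
        report["deviation_pct"] = deviations
        chosen = sim_records[config.strategy]
        sim_summaries = records_to_summaries(chosen)
        save(sim_summaries, "simulated_summaries.csv")

        stage = "marsaglia_regression"
        reg_sim_n = linear_regression(chosen["n2h"], chosen["n_neun"])
        reg_sim_a = linear_regression(chosen["n2h"], chosen["n_gfap"])
        report["marsaglia_regression"] = {
            "neurons": asdict(reg_sim_n),
            "astrocytes": asdict(reg_sim_a),
        }

        stage = "yields"
        exp_yields = yields_table(summaries)
        sim_yields = yields_table(sim_summaries)
        save(exp_yields, "yields_experimental.csv")
        save(sim_yields, "yields_simulated.csv")
        report["yields"] = {
            "experimental": exp_yields.to_dict(orient="records"),
            "simulated": sim_yields.to_dict(orient="records"),
        }

        stage = "scenario_search"
        scenarios = []
        mature = [a for a in ages if a > config.reference_age]
        for source, table, summ in (
            ("experimental", exp_yields, summaries),
            ("simulated", sim_yields, sim_summaries),
        ):
            for age in mature:
                row = table[table["age_months"] == age]
                if row.empty or not np.isfinite(row.iloc[0]["ratio"]):
                    continue
                target = float(row.iloc[0]["ratio"])
                dec = decompose(summ, age, reference_age=config.reference_age)
                res = find_allocation(
                    dec, target, tolerance=config.scenario_tolerance,
                    target_source=source,
                )
                scenarios.append(
                    {
                        "age_months": float(age),
                        "target_source": source,
                        "target_ratio": target,
                        "p_neuron": res.p_neuron,
                        "pct_neurons": 100.0 * res.p_neuron,
                        "pct_astrocytes": 100.0 * (1 - res.p_neuron),
                        "achieved_ratio": res.achieved_ratio,
                        "iterations": res.iterations,
                        "converged": res.converged,
                        "extra": dec.extra,
                    }
                )
        report["scenarios"] = scenarios
        save(pd.DataFrame(scenarios), "scenarios.csv")
    except Exception as e:  # noqa: BLE001 - stage name is the contract
        err = PipelineError(stage, e)
        raise err from e

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
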