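"""Synthetic per-animal BrdU+ cascade datasets with known ground truth.

The generator emulates a cross-sectional BrdU pulse-and-chase design: at each
animal age, independent groups of animals are sacrificed 2 h, 2 d, 4 d, 10 d
or 30 d after a saturating BrdU pulse and the BrdU+ cells per hippocampus are
counted.  The labelled cohort expands between 2 h and 2 d (net proliferation
peak) and declines monotonically afterwards (net survival); at 30 d the
survivors split into NeuN+ newborn neurons and GFAP+ newborn astrocytes.

Observations are carried as a tidy :class:`pandas.DataFrame` with columns

    age_months, timepoint, animal_id, marker, count

(markers: ``total``, ``NeuN``, ``GFAP``, ``Ki67``), group summaries as a
DataFrame with columns ``age_months, timepoint, marker, mean, sd, n`` where
marker additionally admits ``NeuN_pct`` / ``GFAP_pct`` rows (per-animal 30 d
marker percentages) needed by the cohort simulator.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "TIMEPOINT_DAYS",
    "MARKERS",
    "DAYS_PER_MONTH",
    "CascadeTruth",
    "default_truths",
    "generate_dataset",
    "summarize",
    "load_raw_counts",
    "write_dataset",
]

TIMEPOINTS = ("2h", "2d", "4d", "10d", "30d")
TIMEPOINT_DAYS = {"2h": 0.0833, "2d": 2.0, "4d": 4.0, "10d": 10.0, "30d": 30.0}
MARKERS = ("total", "NeuN", "GFAP", "Ki67")
#: age conversion constant; 1 month = 30.44 days
DAYS_PER_MONTH = 30.44

OBS_COLUMNS = ["age_months", "timepoint", "animal_id", "marker", "count"]
SUMMARY_COLUMNS = ["age_months", "timepoint", "marker", "mean", "sd", "n"]


@dataclass(frozen=True)
class CascadeTruth:
    """Ground-truth cascade parameters for one animal age.

    ``mu_2h``/``sigma_2h`` set the 2 h proliferating-progenitor count law;
    ``expansion`` is the net 2h→2d multiplicative increase (>= 1);
    ``surv_4d``, ``surv_10d``, ``surv_30d`` are interval net-survival
    fractions (2d→4d, 4d→10d, 10d→30d) in (0, 1]; ``frac_neun``/``frac_gfap``
    split the 30 d survivors into newborn neurons and astrocytes;
    ``noise_cv`` is the per-step multiplicative log-normal CV.
    """

    age_months: float
    mu_2h: float
    sigma_2h: float
    expansion: float
    surv_4d: float
    surv_10d: float
    surv_30d: float
    frac_neun: float
    frac_gfap: float
    noise_cv: float = 0.0
    p_ki67: float = 0.35

    def __post_init__(self):
        if self.age_months <= 0:
            raise ValueError(f"age_months must be > 0, got {self.age_months}")
        if self.mu_2h < 0:
            raise ValueError(f"mu_2h must be >= 0, got {self.mu_2h}")
        if self.sigma_2h < 0:
            raise ValueError(f"sigma_2h must be >= 0, got {self.sigma_2h}")
        if self.expansion < 1:
            raise ValueError(f"expansion must be >= 1, got {self.expansion}")
        for name in ("surv_4d", "surv_10d", "surv_30d"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("frac_neun", "frac_gfap", "p_ki67"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_neun + self.frac_gfap > 1 + 1e-12:
            raise ValueError(
                f"frac_neun + frac_gfap must be <= 1, got "
                f"{self.frac_neun + self.frac_gfap}"
            )
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")

    def expected_counts(self) -> dict[str, float]:
        """Noise-free expected total count at each timepoint (cascade product)."""
        n2h = self.mu_2h
        n2d = n2h * self.expansion
        n4d = n2d * self.surv_4d
        n10d = n4d * self.surv_10d
        n30d = n10d * self.surv_30d
        return {"2h": n2h, "2d": n2d, "4d": n4d, "10d": n10d, "30d": n30d}


def _plateau_interval_survivals(half_life_d: float, plateau_frac: float):
    """Interval survival fractions implied by a plateau decay anchored at 2 d."""
    k = np.log(2) / half_life_d

    def y(t):
        return plateau_frac + (1 - plateau_frac) * np.exp(-k * (t - 2.0))

    return y(4) / y(2), y(10) / y(4), y(30) / y(10)


def default_truths(noise_cv: float = 0.12) -> list[CascadeTruth]:
    """The package's stated synthetic world: four ages, 1–12 months.

    2 h means decay transversally with a 53 d half-life from 8000 cells per
    hippocampus at 1 m.  Longitudinal interval survivals follow the young
    (half-life 2.75 d, plateau 11.5% of the 2 d peak) and mature (1.1 d, 25%)
    plateau-decay laws.  The 30 d marker split shifts from strongly neurogenic
    (80N:18G at 1 m) to mixed neuro-astrogenic (51N:44G at 12 m).
    """
    young = _plateau_interval_survivals(2.75, 0.115)
    mature = _plateau_interval_survivals(1.1, 0.25)
    fracs = {1: (0.80, 0.18), 2: (0.79, 0.19), 6: (0.56, 0.40), 12: (0.51, 0.44)}
    out = []
    for age in (1, 2, 6, 12):
        mu = 8000.0 * 2 ** (-(age - 1) * DAYS_PER_MONTH / 53.0)
        s4, s10, s30 = young if age <= 2 else mature
        neun, gfap = fracs[age]
        out.append(
            CascadeTruth(
                age_months=age,
                mu_2h=mu,
                sigma_2h=noise_cv * mu,
                expansion=1.7,
                surv_4d=s4,
                surv_10d=s10,
                surv_30d=s30,
                frac_neun=neun,
                frac_gfap=gfap,
                noise_cv=noise_cv,
            )
        )
    return out


def _group_rng(master_seed: int, age: float, timepoint: str) -> np.random.Generator:
    # per-group stream: master seed + CRC32 of the group label, so each
    # (age, timepoint) group is reproducible independently of the others
    tag = zlib.crc32(f"{age}|{timepoint}".encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, tag))))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _trunc01(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return x
    return mean


def generate_dataset(
    truths: list[CascadeTruth],
    n_per_group: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CascadeTruth]]:
    """Generate a tidy per-animal observation table from cascade truths.

    Each animal's count is the cascade product up to its sacrifice timepoint
    with an independent multiplicative log-normal factor (CV = ``noise_cv``)
    applied at every step, rounded half-up and floored at 0.  The 2 h base is
    N(mu_2h, sigma_2h) truncated at 0.  30 d animals additionally carry NeuN
    and GFAP marker counts (frac * total); 2 d animals a binomial Ki67 count.

    Returns the observations and the truths (ground truth for recovery tests).
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if not truths:
        raise ValueError("truths must be non-empty")

    # lognormal multiplier with unit mean and given CV
    def step_noise(rng, cv):
        if cv == 0:
            return 1.0
        s2 = np.log(1 + cv**2)
        return float(rng.lognormal(-s2 / 2, np.sqrt(s2)))

    rows = []
    for truth in truths:
        steps = [
            ("2d", truth.expansion),
            ("4d", truth.surv_4d),
            ("10d", truth.surv_10d),
            ("30d", truth.surv_30d),
        ]
        for tp_idx, tp in enumerate(TIMEPOINTS):
            rng = _group_rng(seed, truth.age_months, tp)
            for i in range(n_per_group):
                animal = f"a{truth.age_months:g}m_{tp}_{i:03d}"
                base = truth.mu_2h
                if truth.sigma_2h > 0:
                    while True:
                        base = rng.normal(truth.mu_2h, truth.sigma_2h)
                        if base >= 0:
                            break
                value = base
                for step_tp, factor in steps[:tp_idx]:
                    value *= factor * step_noise(rng, truth.noise_cv)
                total = max(_round_half_up(value), 0)
                rows.append((truth.age_months, tp, animal, "total", total))
                if tp == "30d":
                    # between-animal marker-expression variability: each
                    # fraction jittered with CV = noise_cv, kept in [0, 1];
                    # markers are scored independently (adjacent sections),
                    # so only each marker count <= total is enforced
                    fg, fn = truth.frac_gfap, truth.frac_neun
                    if truth.noise_cv > 0:
                        fg = _trunc01(rng, truth.frac_gfap,
                                      truth.noise_cv * truth.frac_gfap)
                        fn = _trunc01(rng, truth.frac_neun,
                                      truth.noise_cv * truth.frac_neun)
                    n_gfap = min(max(_round_half_up(fg * value), 0), total)
                    n_neun = min(max(_round_half_up(fn * value), 0), total)
                    rows.append((truth.age_months, tp, animal, "GFAP", n_gfap))
                    rows.append((truth.age_months, tp, animal, "NeuN", n_neun))
                elif tp == "2d":
                    ki67 = int(rng.binomial(total, truth.p_ki67))
                    rows.append((truth.age_months, tp, animal, "Ki67", ki67))
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return obs, list(truths)


def summarize(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-(age, timepoint, marker) mean, sample SD (ddof=1) and N.

    Emits additional ``NeuN_pct`` / ``GFAP_pct`` rows at 30 d — the summary of
    per-animal marker percentages of the total count — which the cohort
    simulator consumes as the marker-fraction law.  Groups with a single
    animal get sd = 0 and are flagged in the ``degenerate`` column.
    """
    if observations.empty:
        raise ValueError("cannot summarize an empty observation set")
    g = observations.groupby(["age_months", "timepoint", "marker"])["count"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
    out = out.reset_index()

    # per-animal 30d marker percentages
    pct_rows = []
    d30 = observations[observations["timepoint"] == "30d"]
    if not d30.empty:
        wide = d30.pivot_table(
            index=["age_months", "animal_id"], columns="marker", values="count"
        )
        for marker in ("NeuN", "GFAP"):
            if marker in wide.columns and "total" in wide.columns:
                pct = 100.0 * wide[marker] / wide["total"].replace(0, np.nan)
                pct = pct.dropna()
                for age, grp in pct.groupby(level="age_months"):
                    pct_rows.append(
                        (
                            age,
                            "30d",
                            f"{marker}_pct",
                            grp.mean(),
                            grp.std(ddof=1) if len(grp) > 1 else 0.0,
                            len(grp),
                        )
                    )
    if pct_rows:
        out = pd.concat(
            [out, pd.DataFrame(pct_rows, columns=SUMMARY_COLUMNS)], ignore_index=True
        )
    out["degenerate"] = out["n"] == 1
    return out.sort_values(["age_months", "timepoint", "marker"]).reset_index(drop=True)


def load_raw_counts(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Load and validate a raw-count CSV into the observation schema.

    Unknown extra columns are ignored.  Rows with unknown timepoint or marker
    labels, or negative counts, are rejected; the second return value lists
    one human-readable report line per rejected row.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw-count file {path} lacks columns: {missing}")
    df = df[OBS_COLUMNS].copy()

    report: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    bad_marker = ~df["marker"].isin(MARKERS)
    count_num = pd.to_numeric(df["count"], errors="coerce")
    bad_count = count_num.isna() | (count_num < 0)
    for i in df.index[bad_tp]:
        report.append(f"row {i}: unknown timepoint {df.at[i, 'timepoint']!r}")
    for i in df.index[bad_marker & ~bad_tp]:
        report.append(f"row {i}: unknown marker {df.at[i, 'marker']!r}")
    for i in df.index[bad_count & ~bad_tp & ~bad_marker]:
        report.append(f"row {i}: invalid count {df.at[i, 'count']!r}")
    keep &= ~(bad_tp | bad_marker | bad_count).to_numpy()
    out = df[keep].copy()
    out["count"] = count_num[keep].astype(int)
    out["age_months"] = pd.to_numeric(out["age_months"])
    return out.reset_index(drop=True), report


def write_dataset(
    observations: pd.DataFrame,
    path: str | Path,
    truths: list[CascadeTruth] | None = None,
) -> None:
    """Write observations as CSV; ground-truth sidecar JSON next to it."""
    path = Path(path)
    observations.to_csv(path, index=False)
    if truths is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps([asdict(t) for t in truths], indent=2))
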