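"""Decay-curve models for BrdU+ cohort dynamics.

Two model forms, organised as statsmodels-style model/results pairs:

* :class:`PlateauDecayModel` — longitudinal decay of a labelled cohort after
  its 2 d peak, ``Y(t) = plateau + (Y0 - plateau) * exp(-K (t - anchor))``:
  exponential loss toward a surviving plateau, fitted over t in [2, 30] d.
* :class:`ExponentialDecayModel` — transversal decay of a population across
  animal ages, ``Y(x) = Y0 * exp(-k x)``.

Both report the half-life ln(2)/K, R^2, and the finite-sample corrected
Akaike criterion AICc = n ln(RSS/n) + 2K' + 2K'(K'+1)/(n - K' - 1) with
K' = number of fitted parameters + 1 (the error variance), the convention
used by common curve-fitting software, so models with different parameter
counts can be ranked on the same data.

Internal parametrisation of the plateau model uses the decay amplitude
amp = Y0 - plateau >= 0, which enforces plateau <= Y0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DecayFitResult",
    "RegressionResult",
    "PlateauDecayModel",
    "ExponentialDecayModel",
    "fit_plateau_decay",
    "fit_exponential_decay",
    "compare_aicc",
    "linear_regression",
    "validate_against_curve",
    "split_age_fit",
    "aicc",
]

_K_FLOOR = 1e-12


def aicc(rss: float, n: int, n_params: int) -> float:
    """Corrected Akaike criterion; K' counts the fitted params plus sigma^2."""
    kp = n_params + 1
    if n <= kp + 1:
        raise ValueError(
            f"AICc undefined: n = {n} <= K' + 1 = {kp + 1} (correction denominator)"
        )
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1)


def _aicc_or_nan(rss: float, n: int, n_params: int) -> float:
    # a minimal legal fit (e.g. 4 points, 3 params) has no defined AICc;
    # carry NaN and let compare_aicc reject it
    try:
        return aicc(rss, n, n_params)
    except ValueError:
        return float("nan")


@dataclass
class DecayFitResult:
    """Fitted decay curve with parameters, uncertainties and diagnostics."""

    model: str  # "plateau-decay" | "pure-exponential"
    params: dict[str, float]
    bse: dict[str, float]
    K: float
    half_life: float
    R2: float
    AICc: float
    n_points: int
    residuals: np.ndarray
    rss: float
    anchor_t: float = 0.0
    half_life_infinite: bool = False
    fit_target: str = "points"  # "points" (per-animal) | "means"

    @property
    def Y0(self) -> float:
        return self.params["Y0"]

    @property
    def plateau(self) -> float | None:
        return self.params.get("plateau")

    @property
    def plateau_pct(self) -> float | None:
        """Survival plateau as % of the fitted value at the anchor (2 d peak)."""
        p = self.params.get("plateau")
        return None if p is None else 100.0 * p / self.params["Y0"]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "plateau-decay":
            p, y0 = self.params["plateau"], self.params["Y0"]
            return p + (y0 - p) * np.exp(-self.K * (t - self.anchor_t))
        return self.params["Y0"] * np.exp(-self.K * t)

    def summary(self) -> str:
        lines = [
            f"{self.model} fit ({self.fit_target}, n = {self.n_points})",
            "-" * 46,
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:>10s} {value:14.6g}  (se {se:.3g})")
        hl = "inf" if self.half_life_infinite else f"{self.half_life:.4g} d"
        lines.append(f"{'half-life':>10s} {hl:>14s}")
        if self.plateau_pct is not None:
            lines.append(f"{'plateau %':>10s} {self.plateau_pct:14.4g}")
        lines.append(f"{'R^2':>10s} {self.R2:14.6g}")
        lines.append(f"{'AICc':>10s} {self.AICc:14.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "params": self.params,
            "bse": self.bse,
            "K": self.K,
            "half_life": None if self.half_life_infinite else self.half_life,
            "half_life_infinite": self.half_life_infinite,
            "plateau_pct": self.plateau_pct,
            "R2": self.R2,
            "AICc": self.AICc,
            "n_points": self.n_points,
            "residuals": list(map(float, self.residuals)),
        }
        return d


@dataclass
class RegressionResult:
    """Ordinary least-squares line with fit quality and F-test p-value."""

    slope: float
    intercept: float
    R2: float
    p_value: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    if tss == 0:
        return 1.0 if rss == 0 else 0.0
    return 1.0 - rss / tss


class _CurveModel:
    """Shared curve_fit machinery: bounded fit with jittered restarts."""

    n_params: int
    model_name: str

    def __init__(self, t, y, fit_target: str = "points"):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.fit_target = fit_target
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, t_col: str = "t", y_col: str = "value",
                       **kwargs):
        return cls(df[t_col].to_numpy(), df[y_col].to_numpy(), **kwargs)

    def _func(self, t, *params):  # pragma: no cover - overridden
        raise NotImplementedError

    def _p0(self):
        raise NotImplementedError

    def _bounds(self):
        raise NotImplementedError

    def fit(self, restarts: int = 5) -> DecayFitResult:
        p0 = np.asarray(self._p0(), dtype=float)
        lo, hi = self._bounds()
        jitter_rng = np.random.default_rng(0)
        last_err: Exception | None = None
        for attempt in range(restarts + 1):
            start = p0 if attempt == 0 else np.clip(
                p0 * jitter_rng.lognormal(0.0, 0.3, size=p0.size), lo, hi
            )
            try:
                popt, pcov = optimize.curve_fit(
                    self._func, self.t, self.y, p0=start, bounds=(lo, hi),
                    maxfev=20000,
                )
                return self._package(popt, pcov)
            except (RuntimeError, optimize.OptimizeWarning) as e:
                last_err = e
        raise RuntimeError(
            f"{self.model_name} fit failed after {restarts} restarts: {last_err}"
        )

    def _package(self, popt, pcov) -> DecayFitResult:
        raise NotImplementedError


class PlateauDecayModel(_CurveModel):
    """Exponential decay toward a plateau, anchored at the 2 d peak.

    Fits ``Y(t) = plateau + amp * exp(-K (t - anchor_t))`` with amp, plateau,
    K >= 0 to (t in days, count) points with t >= anchor_t; reports
    Y0 = plateau + amp (the fitted value at the anchor), the half-life
    ln(2)/K and the plateau as a percentage of Y0.
    """

    n_params = 3
    model_name = "plateau-decay"

    def __init__(self, t, y, anchor_t: float = 2.0, fit_target: str = "points"):
        super().__init__(t, y, fit_target)
        self.anchor_t = float(anchor_t)
        if len(self.t) < 4:
            raise ValueError(f"plateau-decay fit needs >= 4 points, got {len(self.t)}")
        if (self.t < self.anchor_t - 1e-9).any():
            raise ValueError(f"all t must be >= anchor_t = {self.anchor_t}")
        if (self.y < 0).any():
            raise ValueError("values must be >= 0")

    def _func(self, t, amp, plateau, K):
        return plateau + amp * np.exp(-K * (t - self.anchor_t))

    def _p0(self):
        y0 = float(self.y.max())
        plateau = float(self.y.min())
        t_range = float(self.t.max() - self.t.min()) or 1.0
        return [max(y0 - plateau, 1e-6), plateau, np.log(2) / (t_range / 4)]

    def _bounds(self):
        return np.array([0.0, 0.0, _K_FLOOR]), np.array([np.inf, np.inf, np.inf])

    def _package(self, popt, pcov):
        amp, plateau, K = popt
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        resid = self.y - self._func(self.t, *popt)
        rss = float(np.sum(resid**2))
        y0 = amp + plateau
        return DecayFitResult(
            model=self.model_name,
            params={"Y0": y0, "plateau": plateau},
            bse={"Y0": float(np.hypot(se[0], se[1])), "plateau": float(se[1]),
                 "K": float(se[2])},
            K=float(K),
            half_life=float(np.log(2) / K),
            R2=_r2(self.y, resid),
            AICc=_aicc_or_nan(rss, len(self.y), self.n_params),
            n_points=len(self.y),
            residuals=resid,
            rss=rss,
            anchor_t=self.anchor_t,
            fit_target=self.fit_target,
        )


class ExponentialDecayModel(_CurveModel):
    """Pure exponential decay ``Y(x) = Y0 * exp(-k x)`` (x in days).

    Used for transversal decays across animal ages.  Flat data drive k to its
    lower bound; the result is then flagged ``half_life_infinite``.
    """

    n_params = 2
    model_name = "pure-exponential"

    def __init__(self, t, y, fit_target: str = "points"):
        super().__init__(t, y, fit_target)
        if len(self.t) < 3:
            raise ValueError(f"exponential fit needs >= 3 points, got {len(self.t)}")

    def _func(self, t, y0, k):
        return y0 * np.exp(-k * t)

    def _p0(self):
        y0 = float(self.y.max()) or 1.0
        t_range = float(self.t.max() - self.t.min()) or 1.0
        # crude log-slope start when values are positive
        pos = self.y > 0
        if pos.sum() >= 2:
            slope = np.polyfit(self.t[pos], np.log(self.y[pos]), 1)[0]
            k0 = max(-slope, 1e-6)
        else:
            k0 = np.log(2) / (t_range / 2)
        return [y0, k0]

    def _bounds(self):
        return np.array([0.0, _K_FLOOR]), np.array([np.inf, np.inf])

    def _package(self, popt, pcov):
        y0, k = popt
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        resid = self.y - self._func(self.t, *popt)
        rss = float(np.sum(resid**2))
        # no measurable decay over the observed span (< 0.1%) -> flat
        t_span = float(self.t.max() - self.t.min()) or 1.0
        infinite = k * t_span < 1e-3
        return DecayFitResult(
            model=self.model_name,
            params={"Y0": float(y0)},
            bse={"Y0": float(se[0]), "K": float(se[1])},
            K=float(k),
            half_life=float(np.log(2) / k),
            R2=_r2(self.y, resid),
            AICc=_aicc_or_nan(rss, len(self.y), self.n_params),
            n_points=len(self.y),
            residuals=resid,
            rss=rss,
            half_life_infinite=bool(infinite),
            fit_target=self.fit_target,
        )


def fit_plateau_decay(points, anchor_t: float = 2.0,
                      fit_target: str = "points") -> DecayFitResult:
    """Fit the longitudinal plateau-decay law to (t days, value) points."""
    t, y = zip(*points)
    return PlateauDecayModel(t, y, anchor_t=anchor_t, fit_target=fit_target).fit()


def fit_exponential_decay(points, fit_target: str = "points") -> DecayFitResult:
    """Fit the transversal pure-exponential law to (x days, value) points."""
    t, y = zip(*points)
    return ExponentialDecayModel(t, y, fit_target=fit_target).fit()


def compare_aicc(fits: list[DecayFitResult]) -> pd.DataFrame:
    """Rank fits of the same data by AICc (lowest wins; ties to fewer params).

    Returns a DataFrame sorted by AICc with a ``delta_aicc`` column; the
    ranking depends only on AICc differences, so it is invariant to adding a
    constant to every AICc.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n_points for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different data sizes: {sorted(ns)}")
    nparams = {"plateau-decay": 3, "pure-exponential": 2}
    rows = [
        {
            "model": f.model,
            "n_params": nparams.get(f.model, len(f.params) + 1),
            "AICc": f.AICc,
            "R2": f.R2,
            "half_life": f.half_life,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    df["delta_aicc"] = df["AICc"] - df["AICc"].min()
    df = df.sort_values(["AICc", "n_params"], kind="stable").reset_index(drop=True)
    return df


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R^2 and the F-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"regression needs >= 3 points, got {len(x)}")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    # constant y gives an undefined correlation; report no explained variance
    r2 = 0.0 if np.isnan(res.rvalue) else res.rvalue**2
    # for simple regression the slope t-test and the model F-test coincide
    p = float(res.pvalue)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R2=float(r2),
        p_value=1.0 if np.isnan(p) else p,
        n=len(x),
    )


def validate_against_curve(fit: DecayFitResult, independent_means) -> dict:
    """Test independent timepoint means against a fitted decay curve.

    Computes observed - predicted residuals at each timepoint and a two-tailed
    one-sample t-test of the residuals against 0; all-zero residuals (within
    1e-9) give p = 1 by convention.  Returns the p-value and residual table.
    """
    pts = list(independent_means)
    if len(pts) < 3:
        raise ValueError(f"validation needs >= 3 timepoints, got {len(pts)}")
    t = np.array([p[0] for p in pts], dtype=float)
    obs = np.array([p[1] for p in pts], dtype=float)
    pred = fit.predict(t)
    resid = obs - pred
    if np.all(np.abs(resid) < 1e-9):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_1samp(resid, 0.0).pvalue)
    table = pd.DataFrame({"t": t, "observed": obs, "predicted": pred,
                          "residual": resid})
    return {"p_value": p_value, "residuals": table}


def split_age_fit(points, split_age: float) -> tuple[DecayFitResult, DecayFitResult]:
    """Independent exponential fits below and at-or-above a split age.

    ``points`` are (age in days, density) pairs; both sides need >= 3 points.
    Used for populations whose decay rate changes at a maturation benchmark
    (e.g. human neuroblast density around 2 years of age).
    """
    pts = [(float(a), float(v)) for a, v in points]
    young = [p for p in pts if p[0] < split_age]
    old = [p for p in pts if p[0] >= split_age]
    if len(young) < 3:
        raise ValueError(f"insufficient points below split ({len(young)} < 3)")
    if len(old) < 3:
        raise ValueError(f"insufficient points at/above split ({len(old)} < 3)")
    return fit_exponential_decay(young), fit_exponential_decay(old)
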