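"""Logistic growth modeling of viability time courses.

MTT-style viability readouts (absorbance-proportional cell numbers) from
2D monolayers and 3D tissue-engineered constructs are fitted with the
three-parameter logistic law

    N(t) = C0 * Cmax / (C0 + (Cmax - C0) * exp(-d t))

where ``C0`` is the population size at t=0, ``Cmax`` the carrying
capacity (same arbitrary units as N) and ``d`` the intrinsic growth rate
in 1/day.  A linear fit is provided for subpopulations that grow
linearly (near-surface cells), and a comparison report contrasts growth
rates between cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .vasculometry import mann_whitney

__all__ = [
    "ViabilityTimeSeries",
    "LogisticFit",
    "logistic",
    "fit_logistic",
    "fit_linear",
    "compare_growth",
]


@dataclass
class ViabilityTimeSeries:
    """A viability time course with replicates.

    ``times_days`` holds the distinct time points (strictly increasing);
    ``values`` is a list of 1-D replicate arrays, one per time point.
    """

    times_days: np.ndarray
    values: list[np.ndarray]
    culture: str = "2D"

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.values = [np.atleast_1d(np.asarray(v, dtype=float)) for v in self.values]
        if self.times_days.ndim != 1 or len(self.values) != self.times_days.size:
            raise ValueError("times and per-time replicate values must align")
        if np.any(np.diff(self.times_days) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any([np.any(v < 0) for v in self.values]):
            raise ValueError("viability values must be >= 0")

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All (t, N) observation pairs, replicates expanded."""
        t = np.concatenate(
            [np.full(v.size, ti) for ti, v in zip(self.times_days, self.values)]
        )
        n = np.concatenate(self.values)
        return t, n

    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])


@dataclass
class LogisticFit:
    c0: float
    cmax: float
    d: float
    rss: float
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    message: str = ""
    n_obs: int = 0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return logistic(t, self.c0, self.cmax, self.d)


def logistic(t, c0: float, cmax: float, d: float):
    """Evaluate the logistic growth law, stable for large ``d*t``.

    At t=0 this is exactly ``c0``; for d>0 it saturates at ``cmax``.
    """
    if c0 <= 0 or cmax <= 0:
        raise ValueError("C0 and Cmax must be positive")
    t = np.asarray(t, dtype=float)
    # exp(-d t) underflows harmlessly to 0 for large d*t -> N = cmax
    with np.errstate(over="ignore"):
        denom = c0 + (cmax - c0) * np.exp(-d * t)
    out = c0 * cmax / denom
    if out.ndim == 0:
        return float(out)
    return out


def fit_logistic(
    series: ViabilityTimeSeries,
    init: tuple[float, float, float] | None = None,
    on_means: bool = False,
) -> LogisticFit:
    """Nonlinear least-squares fit of the logistic law to a time course.

    All replicate points are fitted jointly by default (``on_means=True``
    fits the per-time means instead).  Positivity of (C0, Cmax, d) is
    enforced by optimizing in log-parameter space, with wide bounds that
    keep the parameters on a sane scale relative to the data; several
    growth-rate initializations are tried and the lowest-residual
    solution kept, since noisy slow-growth series have a spurious
    flat-line basin.  Degenerate flat series are returned with ``d ~ 0``
    flagged as unidentifiable.
    """
    if series.times_days.size < 3:
        raise ValueError("need >= 3 distinct time points to fit")
    if on_means:
        t, n = series.times_days, series.means()
    else:
        t, n = series.flatten()

    scale = max(float(n.max()), 1e-12)
    if init is None:
        c0_0 = max(float(series.values[0].mean()), scale * 1e-6)
        cmax_0 = max(float(max(v.max() for v in series.values)), c0_0 * (1 + 1e-6))
        inits = [(c0_0, cmax_0, d0) for d0 in (0.1, 0.5, 2.0)]
    else:
        inits = [init]

    def residuals(logp):
        c0, cmax, d = np.exp(logp)
        with np.errstate(over="ignore"):
            pred = c0 * cmax / (c0 + (cmax - c0) * np.exp(-d * t))
        return pred - n

    lo = np.log([scale * 1e-9, scale * 1e-9, 1e-9])
    hi = np.log([scale * 1e6, scale * 1e6, 1e3])
    best = None
    for ini in inits:
        x0 = np.clip(np.log(np.maximum(ini, 1e-300)), lo, hi)
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            ftol=1e-10, xtol=1e-12, max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best
    c0, cmax, d = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))

    stderr: dict[str, float] = {}
    dof = t.size - 3
    unidentifiable = False
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(jtj) * (rss / dof if rss > 0 else 1e-30)
            # delta method back to natural scale: var(p) = p^2 var(log p)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0))
            for name, p, sl in zip(("c0", "cmax", "d"), (c0, cmax, d), se_log):
                stderr[name] = float(p * sl)
            if stderr.get("d", 0) > 10 * max(d, 1e-12):
                unidentifiable = True
        except np.linalg.LinAlgError:
            unidentifiable = True
            stderr = {k: float("inf") for k in ("c0", "cmax", "d")}
    # a flat series makes d unidentifiable regardless of the optimizer path
    if np.ptp(n) == 0:
        unidentifiable = True
        stderr = {k: float("inf") for k in ("c0", "cmax", "d")}

    msg = sol.message
    if unidentifiable:
        msg = "growth rate unidentifiable (flat or degenerate series); " + msg
    return LogisticFit(
        c0=float(c0),
        cmax=float(cmax),
        d=float(d),
        rss=rss,
        stderr=stderr,
        converged=bool(sol.success),
        message=msg,
        n_obs=int(t.size),
    )


def fit_linear(series: ViabilityTimeSeries) -> tuple[float, float, float]:
    """OLS of N on t over all replicate points -> (slope, intercept, R^2)."""
    if series.times_days.size < 2:
        raise ValueError("need >= 2 time points")
    t, n = series.flatten()
    slope, intercept = np.polyfit(t, n, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((n - pred) ** 2))
    ss_tot = float(np.sum((n - n.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def compare_growth(
    fit2d: LogisticFit,
    fit3d: LogisticFit,
    series2d: ViabilityTimeSeries | None = None,
    series3d: ViabilityTimeSeries | None = None,
) -> dict:
    """Contrast growth rates between two cultures.

    Returns the growth-rate ratio d_2D/d_3D and, when the raw series are
    supplied, a per-time-point Mann-Whitney comparison of replicate
    viabilities.
    """
    if not (fit2d.converged and fit3d.converged):
        raise ValueError("both fits must have converged")
    report: dict = {
        "d_2d": fit2d.d,
        "d_3d": fit3d.d,
        "d_ratio": fit2d.d / fit3d.d,
    }
    if series2d is not None and series3d is not None:
        per_time = []
        common = set(series2d.times_days.tolist()) & set(series3d.times_days.tolist())
        for tp in sorted(common):
            i2 = int(np.where(series2d.times_days == tp)[0][0])
            i3 = int(np.where(series3d.times_days == tp)[0][0])
            u, p = mann_whitney(series2d.values[i2], series3d.values[i3])
            per_time.append({"time_days": tp, "U": u, "p": p})
        report["per_time_tests"] = per_time
    return report
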