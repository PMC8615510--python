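"""Hill dose-response pharmacodynamics with error-propagated dead fractions.

Absorbance readouts from an MTT cytotoxicity assay are converted to the
percentage of dead cells relative to the untreated control,

    E = (1 - A/A0) * 100 %,    sigma_E = (100 / A0) * sigma_A,

and the dose-effect relationship is fitted with the Hill sigmoid on the
log10-dose axis,

    E(x) = Emax / (1 + 10^((EC50 - x) * h)),   x = log10(dose in ug/mL),

by inverse-error-weighted least squares.  The zero-dose control, which
cannot be log-transformed, is anchored at a pseudo-dose several decades
below the smallest nonzero dose with an elevated weight.  IC50 (the dose
giving 50% cell death) is obtained by inverting the fitted curve and is
reported as "not reached" when the fitted maximum effect stays at or
below 50% or the crossing lies beyond the tested dose range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .vasculometry import mann_whitney

__all__ = [
    "DoseResponseTable",
    "HillFit",
    "dead_fraction",
    "hill",
    "fit_hill",
    "ic50",
    "resistance_report",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"


@dataclass
class DoseResponseTable:
    """Per-dose mean dead fraction with its uncertainty.

    ``doses_ug_ml`` must include the zero-dose control (E = 0 there by
    normalization).  ``sigma_e`` carries whatever spread the input
    declares (replicate s.d. by default).
    """

    doses_ug_ml: np.ndarray
    e_percent: np.ndarray
    sigma_e: np.ndarray
    n: np.ndarray | None = None
    culture: str = "2D"
    formulation: str = "free"

    def __post_init__(self) -> None:
        self.doses_ug_ml = np.asarray(self.doses_ug_ml, dtype=float)
        self.e_percent = np.asarray(self.e_percent, dtype=float)
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n)
        if np.any(self.doses_ug_ml < 0):
            raise ValueError("doses must be >= 0")
        if not (self.doses_ug_ml.shape == self.e_percent.shape == self.sigma_e.shape):
            raise ValueError("dose, E and sigma_E columns must align")
        if not np.all(np.isfinite(self.e_percent)):
            raise ValueError("E must be finite")

    @property
    def has_control(self) -> bool:
        return bool(np.any(self.doses_ug_ml == 0))


@dataclass
class HillFit:
    emax: float
    ec50_log10: float
    h: float
    rss: float
    converged: bool = True
    message: str = ""
    ic50_ug_ml: float | None = None
    dose_range_ug_ml: tuple[float, float] = (0.0, float("inf"))
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def ec50_linear(self) -> float:
        """EC50 back on the linear ug/mL scale."""
        return float(10.0**self.ec50_log10)

    @property
    def ic50_label(self) -> str:
        return NOT_REACHED if self.ic50_ug_ml is None else f"{self.ic50_ug_ml:g}"

    def predict(self, dose_log10):
        return hill(dose_log10, self.emax, self.ec50_log10, self.h)


def dead_fraction(a_mean: float, a0_mean: float, sigma_a: float) -> tuple[float, float]:
    """Dead-cell percentage and its propagated uncertainty.

    Negative E (viability above control) is reported unclipped; callers
    may flag it but the propagation itself is linear.
    """
    if a0_mean <= 0:
        raise ValueError("control absorbance A0 must be > 0")
    if a_mean < 0:
        raise ValueError("absorbance must be >= 0")
    e = (1.0 - a_mean / a0_mean) * 100.0
    sigma_e = (100.0 / a0_mean) * sigma_a
    return float(e), float(sigma_e)


def hill(dose_log10, emax: float, ec50_log10: float, h: float):
    """Hill sigmoid on the log10-dose axis; E(EC50) = Emax/2."""
    x = np.asarray(dose_log10, dtype=float)
    with np.errstate(over="ignore"):
        out = emax / (1.0 + 10.0 ** ((ec50_log10 - x) * h))
    if out.ndim == 0:
        return float(out)
    return out


def _anchor_dose_log10(doses: np.ndarray, decades_below: float = 4.0) -> float:
    nz = doses[doses > 0]
    return float(np.log10(nz.min()) - decades_below)


def fit_hill(
    table: DoseResponseTable,
    constrained: bool = True,
    control_weight: float = 10.0,
    control_decades_below: float = 4.0,
    weight_cap_pct: float = 95.0,
    init: tuple[float, float, float] | None = None,
) -> HillFit:
    """Weighted nonlinear least-squares fit of the Hill sigmoid.

    Weights are 1/sigma_E per point, clipped at the ``weight_cap_pct``
    percentile so a single near-zero-sigma point cannot dominate; when
    every sigma_E is zero, unit weights are used with a warning.  The
    zero-dose control is included at a pseudo-dose
    ``min nonzero dose / 10^control_decades_below`` with its weight
    multiplied by ``control_weight``.  ``constrained`` (default) bounds
    0 < Emax <= 100 and h > 0; the unconstrained mode reproduces a fully
    free fit.
    """
    doses = table.doses_ug_ml
    nz = doses > 0
    if np.unique(doses[nz]).size < 4:
        raise ValueError("need >= 4 distinct nonzero doses to fit")

    x = np.log10(doses[nz])
    e = table.e_percent[nz]
    se = table.sigma_e[nz]
    if table.has_control:
        x = np.append(x, _anchor_dose_log10(doses, control_decades_below))
        e = np.append(e, 0.0)
        se = np.append(se, np.median(se) if np.any(se > 0) else 0.0)

    if np.all(se == 0):
        warnings.warn("all sigma_E are zero: falling back to unit weights", stacklevel=2)
        w = np.ones_like(e)
    else:
        floor = np.min(se[se > 0])
        w = 1.0 / np.maximum(se, floor)
        w = np.minimum(w, np.percentile(w, weight_cap_pct))
    if table.has_control:
        w[-1] *= control_weight

    if init is None:
        emax0 = float(np.clip(e.max(), 1.0, 100.0))
        half = emax0 / 2.0
        k = int(np.argmin(np.abs(e[:-1] - half))) if table.has_control else int(
            np.argmin(np.abs(e - half))
        )
        init = (emax0, float(x[k]), 1.0)

    if constrained:
        # smooth reparameterization keeping 0 < Emax <= 100 and h > 0
        def pack(emax, ec50, h):
            return np.array([_logit(emax / 100.0), ec50, np.log(h)])

        def unpack(p):
            return 100.0 * _expit(p[0]), p[1], np.exp(p[2])
    else:
        def pack(emax, ec50, h):
            return np.array([emax, ec50, h])

        def unpack(p):
            return p[0], p[1], p[2]

    def residuals(p):
        emax, ec50, h = unpack(p)
        return w * (hill(x, emax, ec50, h) - e)

    e0 = min(max(init[0], 1e-3), 99.999) if constrained else init[0]
    h0 = max(init[2], 1e-3) if constrained else init[2]
    sol = least_squares(residuals, pack(e0, init[1], h0), ftol=1e-12, xtol=1e-12,
                        max_nfev=50000)
    emax, ec50, h = (float(v) for v in unpack(sol.x))
    rss = float(np.sum(sol.fun**2))

    fit = HillFit(
        emax=emax,
        ec50_log10=ec50,
        h=h,
        rss=rss,
        converged=bool(sol.success),
        message=sol.message,
        dose_range_ug_ml=(float(doses[nz].min()), float(doses[nz].max())),
    )
    fit.ic50_ug_ml = ic50(fit, fit.dose_range_ug_ml)
    return fit


def _expit(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _logit(q):
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return np.log(q / (1 - q))


def ic50(fit: HillFit, dose_range_ug_ml: tuple[float, float] | None = None) -> float | None:
    """Invert the fitted curve at 50% dead cells.

    Closed form: log10(IC50) = EC50 - log10(Emax/50 - 1)/h, defined only
    when Emax > 50.  Returns None ("not reached") when the asymptote
    never exceeds 50% or the crossing lies above the tested range.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.h == 0:
        raise ValueError("flat curve (h = 0): IC50 undefined")
    if fit.emax <= 50.0:
        return None
    x50 = fit.ec50_log10 - np.log10(fit.emax / 50.0 - 1.0) / fit.h
    value = float(10.0**x50)
    rng = dose_range_ug_ml or fit.dose_range_ug_ml
    if rng is not None and value > rng[1]:
        return None
    return value


def resistance_report(fits: dict[tuple[str, str], HillFit]) -> dict:
    """EC50 fold-shifts between 3D and 2D cultures per formulation.

    ``fits`` maps (culture, formulation) -> HillFit, cultures "2D"/"3D",
    formulations e.g. "free"/"nano".  Returns linear-scale EC50 ratios
    (3D over 2D) and the IC50 of every group; missing pairs yield a
    partial report with a warning.
    """
    if sum(f.converged for f in fits.values()) < 2:
        raise ValueError("need >= 2 converged fits")
    formulations = sorted({k[1] for k in fits})
    ratios = {}
    for fm in formulations:
        f2, f3 = fits.get(("2D", fm)), fits.get(("3D", fm))
        if f2 is None or f3 is None:
            warnings.warn(f"formulation {fm!r}: missing 2D or 3D fit", stacklevel=2)
            continue
        ratios[fm] = f3.ec50_linear / f2.ec50_linear
    return {
        "ec50_ratio_3d_over_2d": ratios,
        "ec50_linear": {f"{c}/{fm}": fit.ec50_linear for (c, fm), fit in fits.items()},
        "ic50_ug_ml": {f"{c}/{fm}": fit.ic50_label for (c, fm), fit in fits.items()},
    }


def per_dose_comparison(replicates_a: dict[float, np.ndarray],
                        replicates_b: dict[float, np.ndarray]) -> list[dict]:
    """Mann-Whitney comparison of per-dose effect replicates."""
    out = []
    for dose in sorted(set(replicates_a) & set(replicates_b)):
        u, p = mann_whitney(replicates_a[dose], replicates_b[dose])
        out.append({"dose_ug_ml": dose, "U": u, "p": p})
    return out
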