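"""Force-binned Bell-model fits and cross-construct comparisons.

Per-molecule rate measurements k(F) are pooled, binned into equally
spaced force bins (bin count = round(sqrt(number of measurements))), and
the Bell relation

    ln k(F) = ln k0 - F * dx / kBT

is fitted by weighted least squares through the binned (F, mean ln k)
points.  Each bin is weighted by 1/sigma^2 where sigma^2 is the larger of
the spread of ln k within the bin and the mean propagated variance of the
member lifetime fits.  Fitted parameters from two conditions are compared
with a two-tailed Welch's t test using Welch-Satterthwaite degrees of
freedom, with the bin count as the effective sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dwell_kinetics import RateMeasurement

__all__ = ["ForceBin", "BellFit", "FitParameter", "WelchResult",
           "bin_rates", "fit_bell", "predict_rate", "welch_compare"]


@dataclass(frozen=True)
class ForceBin:
    """Aggregated rate measurements inside one force interval."""

    force_center: float   # pN
    mean_ln_k: float
    weight_sigma2: float  # variance used for 1/sigma^2 weighting
    n_points: int


@dataclass(frozen=True)
class FitParameter:
    """A fitted parameter with its variance and effective sample size."""

    value: float
    variance: float
    n: int


@dataclass
class BellFit:
    """Weighted linear fit of ln k against force."""

    ln_k0: float
    delta_x: float        # nm
    var_ln_k0: float
    var_delta_x: float
    covariance: float     # cov(ln_k0, delta_x)
    n_bins: int
    fit_r2: float
    kBT: float

    @property
    def ln_k0_param(self) -> FitParameter:
        return FitParameter(self.ln_k0, self.var_ln_k0, self.n_bins)

    @property
    def delta_x_param(self) -> FitParameter:
        return FitParameter(self.delta_x, self.var_delta_x, self.n_bins)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        """Two-tailed significance at the conventional 0.05 level."""
        return self.p < 0.05


def bin_rates(measurements: list[RateMeasurement]) -> list[ForceBin]:
    """Bin rate measurements into round(sqrt(n)) equal-width force bins.

    Per bin the mean of ln k is recorded together with the weighting
    variance: the larger of the within-bin variance of ln k and the mean
    propagated variance from the member lifetime fits.  Empty bins are
    dropped (with a warning); if all measurements share one force a single
    degenerate bin is returned.
    """
    n = len(measurements)
    if n < 4:
        raise ValueError("need at least 4 rate measurements to bin")
    forces = np.array([m.mean_force for m in measurements])
    ln_k = np.log([m.rate for m in measurements])
    # variance of ln k propagated from the per-measurement rate SE
    var_ln_k = np.array([(m.rate_se / m.rate) ** 2 for m in measurements])
    f_lo, f_hi = float(forces.min()), float(forces.max())
    if f_hi == f_lo:
        warnings.warn("all measurements at a single force; returning one bin")
        sigma2 = max(float(np.var(ln_k, ddof=1)) if n > 1 else 0.0,
                     float(np.mean(var_ln_k)))
        return [ForceBin(f_lo, float(ln_k.mean()), sigma2, n)]
    n_bins = int(round(math.sqrt(n)))
    edges = np.linspace(f_lo, f_hi, n_bins + 1)
    idx = np.clip(np.digitize(forces, edges) - 1, 0, n_bins - 1)
    bins: list[ForceBin] = []
    n_empty = 0
    for b in range(n_bins):
        mask = idx == b
        m = int(mask.sum())
        if m == 0:
            n_empty += 1
            continue
        spread = float(np.var(ln_k[mask], ddof=1)) if m > 1 else 0.0
        fit_var = float(np.mean(var_ln_k[mask]))
        bins.append(ForceBin(
            force_center=float(0.5 * (edges[b] + edges[b + 1])),
            mean_ln_k=float(ln_k[mask].mean()),
            weight_sigma2=max(spread, fit_var),
            n_points=m,
        ))
    if n_empty:
        warnings.warn(f"{n_empty} empty force bin(s) dropped")
    return bins


def fit_bell(bins: list[ForceBin], kBT: float = 4.11) -> BellFit:
    """Weighted least-squares Bell fit through binned (F, ln k) points.

    The slope is -dx/kBT and the intercept ln k0; parameter variances come
    from the weighted fit with the residual scale estimated from the data,
    so the weights need only be proportional to inverse variances.
    """
    if len(bins) < 2:
        raise ValueError("need at least 2 non-empty bins for a Bell fit")
    import statsmodels.api as sm

    f = np.array([b.force_center for b in bins])
    y = np.array([b.mean_ln_k for b in bins])
    sigma2 = np.array([b.weight_sigma2 for b in bins])
    floor = max(sigma2[sigma2 > 0].min() if np.any(sigma2 > 0) else 1.0, 1e-12)
    w = 1.0 / np.maximum(sigma2, 1e-3 * floor)
    X = sm.add_constant(f)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = res.params
    cov = res.cov_params()
    return BellFit(
        ln_k0=float(intercept),
        delta_x=float(-slope * kBT),
        var_ln_k0=float(cov[0, 0]),
        var_delta_x=float(cov[1, 1] * kBT ** 2),
        covariance=float(-cov[0, 1] * kBT),
        n_bins=len(bins),
        fit_r2=float(res.rsquared) if len(bins) > 2 else float("nan"),
        kBT=kBT,
    )


def predict_rate(fit: BellFit, force, kBT: float | None = None):
    """Bell-model rate k(F) = exp(ln_k0 - F dx / kBT)."""
    kBT = fit.kBT if kBT is None else kBT
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    out = np.exp(fit.ln_k0 - f * fit.delta_x / kBT)
    return float(out) if np.isscalar(force) else out


def welch_compare(a: FitParameter, b: FitParameter) -> WelchResult:
    """Two-tailed Welch's t test between two fitted parameters.

    Degrees of freedom follow the Welch-Satterthwaite equation; each
    variance estimate carries the residual degrees of freedom of its
    two-parameter linear fit (bin count minus 2).  Identical parameters
    give t = 0, p = 1.
    """
    va, vb = a.variance, b.variance
    if va < 0 or vb < 0:
        raise ValueError("variances must be >= 0")
    if va == 0 and vb == 0:
        if a.value == b.value:
            return WelchResult(0.0, float(a.n + b.n - 2), 1.0)
        raise ValueError("both variances are zero with unequal values")
    t = (a.value - b.value) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        (va ** 2 / max(a.n - 2, 1)) + (vb ** 2 / max(b.n - 2, 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))
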