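"""Model fits and comparison for the pre-folding delay distribution.

The measured delays tau between reaching the folding-competent codon and
the first folding transition are fitted by least squares of a model CDF to
the empirical CDF (plotting position i/n).  Three families are supported:

* ``exponential`` — 1 - exp(-t/tau_delay): a single stochastic
  equilibration step;
* ``double_exponential`` — w (1 - exp(-t/tau1)) + (1-w)(1 - exp(-t/tau2)):
  two ribosome populations, one slowed;
* ``erlang2`` — 1 - (1 + lambda t) exp(-lambda t): two sequential steps of
  similar rate (shape fixed at 2).

Nested families are compared with an extra-sum-of-squares F test, with the
exponential as the null hypothesis (it is the simplest model); families of
equal parameter count are compared by a variance-ratio F on the residual
mean squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["DelayFit", "fit_delay_cdf", "f_test_model_comparison",
           "FAMILY_N_PARAMS"]

FAMILY_N_PARAMS = {"exponential": 1, "double_exponential": 3, "erlang2": 1}


@dataclass
class DelayFit:
    """Least-squares CDF fit of one delay-distribution family."""

    family: str
    params: dict
    rss: float
    r2: float
    n: int

    @property
    def n_params(self) -> int:
        return FAMILY_N_PARAMS[self.family]

    @property
    def mean_delay(self) -> float:
        """Mean of the fitted distribution, seconds."""
        p = self.params
        if self.family == "exponential":
            return p["tau_delay"]
        if self.family == "double_exponential":
            return p["w"] * p["tau1"] + (1.0 - p["w"]) * p["tau2"]
        return 2.0 / p["rate"]

    def cdf(self, t):
        return _family_cdf(self.family, np.asarray(t, dtype=float), self.params)


def _family_cdf(family: str, t, params: dict):
    if family == "exponential":
        return 1.0 - np.exp(-t / params["tau_delay"])
    if family == "double_exponential":
        w, t1, t2 = params["w"], params["tau1"], params["tau2"]
        return w * (1.0 - np.exp(-t / t1)) + (1.0 - w) * (1.0 - np.exp(-t / t2))
    if family == "erlang2":
        lam = params["rate"]
        return 1.0 - (1.0 + lam * t) * np.exp(-lam * t)
    raise ValueError(f"unknown delay family: {family!r}")


def _ls_fit(t: np.ndarray, ecdf: np.ndarray, family: str,
            x0_list, bounds) -> tuple[np.ndarray, float]:
    best_x, best_rss = None, np.inf
    for x0 in x0_list:
        res = optimize.least_squares(
            lambda x: _family_cdf(family, t, _unpack(family, x)) - ecdf,
            x0=np.asarray(x0, dtype=float), bounds=bounds)
        rss = float(2.0 * res.cost)
        if rss < best_rss:
            best_x, best_rss = res.x, rss
    return best_x, best_rss


def _unpack(family: str, x) -> dict:
    if family == "exponential":
        return {"tau_delay": float(x[0])}
    if family == "double_exponential":
        return {"w": float(x[0]), "tau1": float(x[1]), "tau2": float(x[2])}
    return {"rate": float(x[0])}


def fit_delay_cdf(taus, family: str = "exponential") -> DelayFit:
    """Least-squares fit of a delay-family CDF to the empirical CDF.

    Censored observations must be excluded by the caller; the order of the
    input is irrelevant.  The double-exponential fit uses several starting
    points (including the degenerate single-exponential solution) so its
    residual sum of squares never exceeds the exponential fit's.
    """
    t = np.sort(np.asarray(taus, dtype=float))
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 uncensored delays")
    ecdf = np.arange(1, n + 1) / n
    mean = float(np.mean(t))
    tiny = 1e-9
    if family == "exponential":
        x, rss = _ls_fit(t, ecdf, family, [[mean]], ([tiny], [np.inf]))
    elif family == "erlang2":
        x, rss = _ls_fit(t, ecdf, family, [[2.0 / max(mean, tiny)]],
                         ([tiny], [np.inf]))
    elif family == "double_exponential":
        exp_fit = fit_delay_cdf(t, "exponential")
        tau = exp_fit.params["tau_delay"]
        starts = [[0.5, tau, tau], [0.5, 0.3 * tau, 2.0 * tau],
                  [0.2, tau, 3.0 * tau], [0.8, 0.5 * tau, tau]]
        x, rss = _ls_fit(t, ecdf, family, starts,
                         ([0.0, tiny, tiny], [1.0, np.inf, np.inf]))
        if rss > exp_fit.rss:  # nested model can never fit worse
            x, rss = np.array([1.0, tau, tau]), exp_fit.rss
    else:
        raise ValueError(f"unknown delay family: {family!r}")
    params = _unpack(family, x)
    ss_tot = float(np.sum((ecdf - ecdf.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
    return DelayFit(family=family, params=params, rss=rss, r2=r2, n=n)


def f_test_model_comparison(null_fit: DelayFit, alt_fit: DelayFit
                            ) -> tuple[float, float]:
    """F test of a delay-model fit against the exponential null.

    For a nested alternative with more parameters the extra-sum-of-squares
    statistic F = ((RSS0 - RSS1)/dp) / (RSS1/(n - p1)) is used; for an
    alternative with the same parameter count, the variance ratio of the
    residual mean squares.  Returns (F, p); a perfect alternative fit
    (RSS1 = 0) is degenerate and reported as (inf, 0).
    """
    if null_fit.n != alt_fit.n:
        raise ValueError("fits must use the same data")
    n = null_fit.n
    p0, p1 = null_fit.n_params, alt_fit.n_params
    if p1 < p0:
        raise ValueError("alternative must have at least as many parameters")
    if alt_fit.rss == 0.0:
        return float("inf"), 0.0
    if p1 > p0:
        dp = p1 - p0
        F = ((null_fit.rss - alt_fit.rss) / dp) / (alt_fit.rss / (n - p1))
        F = max(F, 0.0)
        p = float(stats.f.sf(F, dp, n - p1))
    else:
        F = (null_fit.rss / (n - p0)) / (alt_fit.rss / (n - p1))
        p = float(stats.f.sf(F, n - p0, n - p1))
    return float(F), p
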