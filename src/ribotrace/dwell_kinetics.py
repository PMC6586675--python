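"""State assignment, dwell times and per-force rates from hopping traces.

A passive-mode trace is segmented with a Gaussian-emission hidden Markov
model fitted on force (not extension, which carries bead-pair offsets).
The number of states is selected by the lowest Bayesian information
criterion, BIC = -2 logL + p ln(n) with p the count of free HMM
parameters.  The decoded most-probable (Viterbi) path is run-length
encoded into dwells; boundary dwells are censored and excluded from
lifetime fits.  State lifetimes are obtained by least-squares fitting of
the exponential cumulative distribution 1 - exp(-t/tau) to the empirical
dwell-time CDF (plotting position i/n), which yields one rate measurement
per (state, trace).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trace import ForceTrace

__all__ = ["HMMResult", "RateMeasurement", "fit_hmm", "extract_dwells",
           "fit_lifetime_cdf"]


@dataclass
class HMMResult:
    """Force-ordered Gaussian HMM fit of one trace.

    States are sorted by increasing mean force; on these tethers the
    lowest force level is the unfolded state.
    """

    n_states: int
    state_means: np.ndarray       # pN, increasing
    state_sds: np.ndarray         # pN
    transition_matrix: np.ndarray  # per-sample probabilities, rows sum to 1
    state_path: np.ndarray        # most-probable state label per sample
    bic: float
    log_likelihood: float
    fs: float


@dataclass
class RateMeasurement:
    """One fitted exit rate of one state at one mean force."""

    state_pair: tuple[str, str]
    rate: float        # 1/s
    rate_se: float     # 1/s
    mean_force: float  # pN
    n_events: int
    molecule_id: str = ""
    gof_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def _n_free_params(k: int) -> int:
    # start probabilities (k-1) + transition rows (k(k-1)) + mean & var per state
    return (k - 1) + k * (k - 1) + 2 * k


def fit_hmm(trace: ForceTrace, candidate_state_counts=(1, 2, 3, 4),
            n_iter: int = 200, random_state: int = 0,
            min_covar: float = 1e-4) -> HMMResult:
    """Fit Gaussian-emission HMMs and select the state count by lowest BIC.

    Each candidate count is fitted by EM.  Means are initialised by k-means
    with a fixed random state (deterministic) and the transition matrix is
    initialised sticky (self-transition 0.98), reflecting that dwells span
    many samples; a uniform initial transition matrix makes EM collapse all
    states onto the global mean on sparsely visited traces.  Candidates
    that fail to converge are skipped with a warning.  The
    returned result carries the Viterbi-decoded state path, relabelled so
    state 0 has the lowest mean force.
    """
    from hmmlearn.hmm import GaussianHMM

    x = np.asarray(trace.force, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < 100:
        raise ValueError("trace must contain at least 100 samples")
    if not set(candidate_state_counts) <= {1, 2, 3, 4}:
        raise ValueError("candidate state counts must be within 1..4")
    best: HMMResult | None = None
    for k in candidate_state_counts:
        try:
            model = GaussianHMM(n_components=k, covariance_type="diag",
                                n_iter=n_iter, random_state=random_state,
                                min_covar=min_covar, init_params="smc")
            stick = 0.98
            model.transmat_ = (np.full((k, k), (1 - stick) / max(k - 1, 1))
                               if k > 1 else np.ones((1, 1)))
            if k > 1:
                np.fill_diagonal(model.transmat_, stick)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
                logl = float(model.score(x))
                path = model.predict(x)
        except Exception as exc:  # noqa: BLE001 - degenerate EM is expected
            warnings.warn(f"HMM with {k} states failed: {exc}")
            continue
        if not np.isfinite(logl):
            warnings.warn(f"HMM with {k} states returned non-finite likelihood")
            continue
        bic = -2.0 * logl + _n_free_params(k) * np.log(n)
        if best is None or bic < best.bic:
            order = np.argsort(model.means_.ravel())
            relabel = np.empty(k, dtype=int)
            relabel[order] = np.arange(k)
            best = HMMResult(
                n_states=k,
                state_means=model.means_.ravel()[order],
                state_sds=np.sqrt(model.covars_.ravel()[order]),
                transition_matrix=model.transmat_[np.ix_(order, order)],
                state_path=relabel[path],
                bic=bic,
                log_likelihood=logl,
                fs=trace.fs,
            )
    if best is None:
        raise RuntimeError("no HMM candidate converged")
    return best


def extract_dwells(result: HMMResult, fs: float | None = None,
                   force: np.ndarray | None = None) -> pd.DataFrame:
    """Run-length encode a state path into a dwell table.

    Returns a DataFrame with columns ``state`` (force-ordered label),
    ``duration_s``, ``mean_force_pN`` and ``censored``.  The first and
    last dwell of the trace are censored (their true start/end was not
    observed).  Per-dwell mean force comes from the raw samples when
    ``force`` is given, otherwise from the fitted state mean.
    """
    fs = result.fs if fs is None else fs
    path = np.asarray(result.state_path)
    if path.size == 0:
        return pd.DataFrame(columns=["state", "duration_s", "mean_force_pN",
                                     "censored"])
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    rows = []
    for i, (a, b) in enumerate(zip(starts, ends)):
        state = int(path[a])
        f_mean = (float(np.mean(force[a:b])) if force is not None
                  else float(result.state_means[state]))
        rows.append({
            "state": state,
            "duration_s": (b - a) / fs,
            "mean_force_pN": f_mean,
            "censored": i == 0 or i == len(starts) - 1,
        })
    return pd.DataFrame(rows)


def fit_lifetime_cdf(dwells: pd.DataFrame, state: int,
                     to_state: int | None = None,
                     molecule_id: str = "",
                     min_dwells: int = 5) -> RateMeasurement:
    """Exit rate of ``state`` from a least-squares exponential CDF fit.

    Uncensored dwell durations are sorted and the empirical CDF (plotting
    position i/n) is fitted with 1 - exp(-t/tau); the rate is 1/tau.  The
    reported standard error is the asymptotic exponential-sampling error
    rate/sqrt(n): the naive covariance of the CDF fit is not a valid
    sampling variance because empirical-CDF residuals are strongly
    correlated, and it understates the error severalfold.  The coefficient
    of determination of the CDF fit is kept as a goodness-of-fit statistic
    so non-exponential dwell sets can be flagged.
    """
    sub = dwells[dwells["state"] == state]
    n_censored = int(sub["censored"].sum())
    durations = np.sort(sub.loc[~sub["censored"], "duration_s"].to_numpy())
    if durations.size < min_dwells:
        raise ValueError(
            f"need >= {min_dwells} uncensored dwells of state {state}, "
            f"got {durations.size} ({n_censored} censored excluded)")
    ecdf = np.arange(1, durations.size + 1) / durations.size

    def model(t, tau):
        return 1.0 - np.exp(-t / tau)

    popt, _ = curve_fit(model, durations, ecdf,
                        p0=[float(np.mean(durations))],
                        bounds=(1e-12, np.inf))
    tau = float(popt[0])
    resid = ecdf - model(durations, tau)
    ss_tot = float(np.sum((ecdf - ecdf.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    mean_force = float(sub.loc[~sub["censored"], "mean_force_pN"].mean())
    return RateMeasurement(
        state_pair=(str(state), "exit" if to_state is None else str(to_state)),
        rate=1.0 / tau,
        rate_se=(1.0 / tau) / np.sqrt(durations.size),
        mean_force=mean_force,
        n_events=int(durations.size),
        molecule_id=molecule_id,
        gof_r2=r2,
    )
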