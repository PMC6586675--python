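"""Real-time translation trajectory fitting and folding-onset detection.

Because a single amino-acid step (about -0.006 pN) is far below the
instrument noise, per-codon steps cannot be scored individually.  The
codon-position series obtained from the force conversion is instead fitted
with an isotonic (monotone non-decreasing) regression, which assumes only
that translation is unidirectional; individual fitted steps are not
interpreted.  The elongation rate is reported as 10 amino acids divided by
the median time to cross a 10-amino-acid window, with the spread derived
from the standard deviation of the crossing times.

The first folding event after the chain becomes folding-competent is
detected on the force trace by two methods: (1) the data are divided into
1-s windows, block-averaged by a factor of 10, and each point is compared
with a Gaussian CDF built from the rest of its window; upper-tail
probabilities below 1e-5 in the folding direction (force increase) score
an event; (2) any window whose standard deviation exceeds 0.13 pN is
flagged, catching long-lived events or rapid hopping that skew the window
statistics.  The earlier of the two is the onset, and the delay tau is the
onset time minus the arrival time at the threshold codon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tether_mechanics import DEFAULT_MODEL, TetherModel, aa_to_contour, \
    series_compliance, wlc_extension
from .trace import ForceTrace

__all__ = ["TranslationFit", "FoldingEvent", "DelayObservation",
           "fit_monotone", "elongation_rate", "arrival_time",
           "detect_onset", "measure_delay"]


@dataclass
class TranslationFit:
    """Monotone codon-position-vs-time fit of one translation trace."""

    time: np.ndarray              # s, samples used in the fit
    fitted_position: np.ndarray   # aa, non-decreasing step function
    residual_sd: float            # aa
    window_crossing_times: np.ndarray  # s per complete 10-aa window
    window_aa: float = 10.0
    position: np.ndarray | None = None  # aa, raw input positions


@dataclass(frozen=True)
class FoldingEvent:
    """A detected folding onset."""

    time: float
    method: str                   # "cdf_outlier" or "sd_flag"
    window_index: int
    point_probability: float | None = None


@dataclass
class DelayObservation:
    """Delay between reaching the folding-competent codon and first folding."""

    tau: float
    onset_kind: str | None        # misfolded | c_domain | equilibrium_like
    molecule_id: str = ""
    censored: bool = False
    onset: FoldingEvent | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


def fit_monotone(time, position, window_aa: float = 10.0,
                 window_range: tuple[float | None, float | None] = (None, None),
                 min_samples: int = 20) -> TranslationFit:
    """Least-squares monotone (non-decreasing) fit via pool-adjacent-violators.

    NaN positions (samples flagged by the force conversion) are dropped
    before fitting.  Window crossing times are measured on the fitted curve
    for consecutive complete ``window_aa`` windows starting at the fitted
    initial position; ``window_range`` restricts them to a position interval
    (useful to exclude the post-translation plateau, where the fit no
    longer advances by synthesis).
    """
    time = np.asarray(time, dtype=float)
    position = np.asarray(position, dtype=float)
    ok = np.isfinite(position)
    time, position = time[ok], position[ok]
    if time.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples for a "
                         "monotone fit")
    from sklearn.isotonic import IsotonicRegression

    fitted = IsotonicRegression(increasing=True).fit_transform(time, position)
    resid_sd = float(np.std(position - fitted, ddof=1))
    crossings = _window_crossing_times(time, fitted, window_aa, window_range)
    return TranslationFit(time, fitted, resid_sd, crossings, window_aa,
                          position=position)


def _window_crossing_times(time: np.ndarray, fitted: np.ndarray,
                           window_aa: float,
                           window_range=(None, None)) -> np.ndarray:
    lo, hi = window_range
    start = fitted[0] if lo is None else max(fitted[0], lo)
    stop = fitted[-1] if hi is None else min(fitted[-1], hi)
    n_windows = int(math.floor((stop - start) / window_aa))
    if n_windows < 1:
        return np.array([])
    # first time the fit reaches each window boundary
    bounds = np.asarray(start) + window_aa * np.arange(n_windows + 1)
    idx = np.searchsorted(fitted, bounds, side="left")
    idx = np.clip(idx, 0, time.size - 1)
    t_bounds = time[idx]
    return np.diff(t_bounds)


def elongation_rate(fit: TranslationFit) -> tuple[float, float]:
    """Elongation rate (aa/s) and spread from 10-aa window crossing times.

    rate = window / median(crossing times); the spread is the standard
    deviation of the crossing times propagated to rate units.
    """
    T = fit.window_crossing_times
    if T.size < 2:
        raise ValueError("need at least 2 complete windows")
    med = float(np.median(T))
    rate = fit.window_aa / med
    spread = fit.window_aa * float(np.std(T, ddof=1)) / med ** 2
    return rate, spread


def arrival_time(fit: TranslationFit, codon: float) -> float | None:
    """Earliest sample time at which the fitted position exceeds ``codon``.

    Returns None when the fit never reaches the codon.
    """
    above = fit.fitted_position > codon
    if not above.any():
        return None
    return float(fit.time[int(np.argmax(above))])


def detect_onset(trace: ForceTrace, t_start: float,
                 threshold: float = 1e-5, sd_flag: float = 0.13,
                 window_s: float = 1.0, downsample: int = 10
                 ) -> FoldingEvent | None:
    """First folding event after ``t_start``, or None.

    Method 1: per 1-s window, non-overlapping block means of ``downsample``
    samples; each point's upper-tail probability under a Gaussian with the
    leave-one-out mean and SD of its window; the first point below
    ``threshold`` in the folding direction (force increase) is the event.
    Method 2: the first window whose SD of downsampled points exceeds
    ``sd_flag`` (pN) is flagged.  The earlier event wins.
    """
    sub = trace.slice_time(t_start)
    per_window = int(round(window_s * trace.fs))
    if len(sub) < per_window:
        raise ValueError("trace spans less than one window after t_start")
    n_windows = len(sub) // per_window
    m = per_window // downsample  # downsampled points per window
    if m < 3:
        raise ValueError("window too short after downsampling")
    best: FoldingEvent | None = None
    for w in range(n_windows):
        seg = sub.force[w * per_window:(w + 1) * per_window]
        t0 = sub.time[w * per_window]
        v = seg[:m * downsample].reshape(m, downsample).mean(axis=1)
        t_v = t0 + (np.arange(m) + 0.5) * downsample / trace.fs
        # leave-one-out mean and sample SD for each candidate point
        s, ss = v.sum(), np.dot(v, v)
        mean_loo = (s - v) / (m - 1)
        var_loo = ((ss - v ** 2) - (m - 1) * mean_loo ** 2) / (m - 2)
        sd_loo = np.sqrt(np.maximum(var_loo, 1e-300))
        p = stats.norm.sf((v - mean_loo) / sd_loo)
        hits = np.flatnonzero(p < threshold)
        cand: FoldingEvent | None = None
        if hits.size:
            i = int(hits[0])
            cand = FoldingEvent(float(t_v[i]), "cdf_outlier", w, float(p[i]))
        if float(np.std(v, ddof=1)) > sd_flag:
            flag = FoldingEvent(float(t0), "sd_flag", w)
            if cand is None or flag.time < cand.time:
                cand = flag
        if cand is not None:
            best = cand
            break
    return best


def _safe_detect(trace: ForceTrace, t_start: float,
                 onset_kwargs: dict) -> FoldingEvent | None:
    try:
        return detect_onset(trace, t_start, **onset_kwargs)
    except ValueError:  # less than one window left after t_start
        return None


def _refine_onset_and_arrival(trace: ForceTrace, fit: TranslationFit,
                              folding_codon: float, arrive: float,
                              onset_kwargs: dict, max_iter: int = 6
                              ) -> tuple[float, FoldingEvent | None]:
    """Jointly refine the arrival time and the folding onset.

    Once folding starts, the sequestration dips drag the monotone fit
    below the true trajectory and bias the apparent arrival late.  The
    arrival is therefore refit on pre-onset data only, and the onset
    rescanned from the refined arrival, until the pair is stable.  If the
    pre-onset fit never reaches the codon (folding began essentially at
    arrival), the onset time itself is taken as the arrival (tau = 0).
    """
    onset = _safe_detect(trace, arrive, onset_kwargs)
    for _ in range(max_iter):
        if onset is None:
            break
        mask = fit.time < onset.time
        if fit.position is not None and mask.sum() >= 20:
            pre = fit_monotone(fit.time[mask], fit.position[mask])
            a = arrival_time(pre, folding_codon)
            new_arrive = a if a is not None else onset.time
        else:
            new_arrive = onset.time
        if abs(new_arrive - arrive) <= 1.0 / trace.fs:
            break
        arrive = new_arrive
        onset = _safe_detect(trace, arrive, onset_kwargs)
    return arrive, onset


def _step_size_aa(trace: ForceTrace, onset_time: float, model: TetherModel,
                  half_window_s: float = 0.4) -> float:
    """Rough size (aa) of the force step at the onset, via local compliance."""
    before = trace.slice_time(onset_time - half_window_s, onset_time)
    after = trace.slice_time(onset_time, onset_time + half_window_s)
    if len(before) < 3 or len(after) < 3:
        return float("nan")
    f0 = float(np.median(before.force))
    # folded level: upper part of the post-onset window (the chain hops)
    f1 = float(np.quantile(after.force, 0.8))
    d_force = f1 - f0
    # contour change per unit force at fixed separation:
    # dF = r dL / c_total with r the protein fractional extension
    probe = aa_to_contour(100.0, model.nm_per_aa)
    r = wlc_extension(f0, model.protein_params(probe), model.kBT) / probe
    c = series_compliance(model, f0, probe)
    d_contour = d_force * c / r
    return d_contour / model.nm_per_aa


def measure_delay(trace: ForceTrace, fit: TranslationFit, folding_codon: float,
                  model: TetherModel = DEFAULT_MODEL,
                  molecule_id: str = "",
                  tau_unfold_equilibrium: float = 1.5,
                  equilibrium_factor: float = 3.0,
                  size_boundary_aa: float = 100.0,
                  **onset_kwargs) -> DelayObservation:
    """Delay from reaching ``folding_codon`` to the first folding event.

    If no onset occurs before the end of the trace, the observation is
    right-censored at the remaining trace span.  Onsets are classified as
    ``equilibrium_like`` when tau falls within ``equilibrium_factor`` times
    the equilibrium unfolded lifetime, otherwise by the size of the force
    step: at least ``size_boundary_aa`` amino acids is ``misfolded``
    (approximately 130-aa class), smaller steps are ``c_domain``
    (approximately 75-aa class).
    """
    arrive = arrival_time(fit, folding_codon)
    if arrive is None:
        raise ValueError(f"fit never reaches codon {folding_codon}")
    arrive, onset = _refine_onset_and_arrival(trace, fit, folding_codon,
                                              arrive, onset_kwargs)
    if onset is None:
        return DelayObservation(tau=float(trace.time[-1] - arrive),
                                onset_kind=None, molecule_id=molecule_id,
                                censored=True)
    tau = max(0.0, onset.time - arrive)
    if tau <= equilibrium_factor * tau_unfold_equilibrium:
        kind = "equilibrium_like"
    else:
        size = _step_size_aa(trace, onset.time, model)
        kind = "misfolded" if size >= size_boundary_aa else "c_domain"
    return DelayObservation(tau=tau, onset_kind=kind, molecule_id=molecule_id,
                            censored=False, onset=onset)
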