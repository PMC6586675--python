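"""Synthetic passive-mode force traces with known ground truth.

The experimental raw traces are not publicly deposited, so every analysis
stage in this package is validated against traces generated here.  Two
kinds of record are emulated:

* **Equilibrium hopping traces** — a stalled ribosome-nascent-chain (RNC)
  or free protein hopping between conformational states.  State-to-state
  kinetics follow the Bell model ``ln k(F) = ln k0 +/- F dx/kBT`` and are
  simulated in continuous time (Gillespie); each state sits at its own
  equilibrium force, obtained from the series force balance of
  :mod:`ribotrace.tether_mechanics`, and the emitted trace is the
  piecewise-constant force path plus white Gaussian instrument noise.

* **Real-time translation traces** — force decays as contour is added one
  amino acid at a time (per-codon exponential waits), and folding becomes
  possible after the ribosome passes a threshold codon, optionally gated
  by an exponential equilibration delay.

Default kinetic parameters reproduce the behaviour measured on stalled
complexes: the unfolded-state lifetime before misfolding is 1.5 s at
4.0 pN and 6e-4 s at zero force, and the misfolded state survives 1.9 s
at 4.0 pN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tether_mechanics import (DEFAULT_MODEL, TetherModel, aa_to_contour,
                               equilibrium_force, total_extension,
                               ForceToContourTable)
from .trace import ForceTrace

__all__ = [
    "KineticScheme", "Transition", "NoiseModel", "GroundTruth",
    "rnc_misfold_scheme", "c_domain_scheme",
    "simulate_hopping_trace", "simulate_translation_trace", "sample_delays",
]


@dataclass(frozen=True)
class Transition:
    """One Bell-model transition: ln k(F) = ln_k0 + sign * F * delta_x / kBT.

    ``sign=+1`` for force-accelerated transitions (unfolding), ``-1`` for
    force-decelerated ones (folding).
    """

    source: str
    target: str
    ln_k0: float    # ln(1/s) at zero force
    delta_x: float  # nm, distance to the transition state
    sign: int

    def rate(self, force: float, kBT: float) -> float:
        return math.exp(self.ln_k0 + self.sign * force * self.delta_x / kBT)


@dataclass(frozen=True)
class KineticScheme:
    """States (with sequestered contour) and Bell transitions between them.

    ``states`` maps each state name to the number of amino acids of
    contour it sequesters relative to the fully unfolded chain; the
    unfolded state sequesters 0 and defines the reference force level.
    """

    states: tuple[tuple[str, float], ...]
    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        for _, seq in self.states:
            if seq < 0:
                raise ValueError("sequestered contour must be >= 0")
        for tr in self.transitions:
            if tr.source not in names or tr.target not in names:
                raise ValueError(f"transition references unknown state: {tr}")
            if tr.sign not in (-1, 1):
                raise ValueError("transition sign must be +1 or -1")

    @property
    def state_names(self) -> list[str]:
        return [name for name, _ in self.states]

    def sequestered_aa(self, state: str) -> float:
        return dict(self.states)[state]

    def exit_transitions(self, state: str) -> list[Transition]:
        return [tr for tr in self.transitions if tr.source == state]

    def rate_matrix(self, forces: dict[str, float], kBT: float) -> np.ndarray:
        """Generator matrix with each row evaluated at that state's force."""
        names = self.state_names
        idx = {n: i for i, n in enumerate(names)}
        Q = np.zeros((len(names), len(names)))
        for tr in self.transitions:
            Q[idx[tr.source], idx[tr.target]] = tr.rate(forces[tr.source], kBT)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


@dataclass(frozen=True)
class NoiseModel:
    """White Gaussian instrument noise, specified at a reference bandwidth.

    The standard deviation scales as sqrt(bandwidth); the measured value on
    this instrument class is 0.25 pN at 1333 Hz (near 4 pN).
    """

    sd_at_reference: float = 0.25   # pN
    reference_bandwidth: float = 1333.0  # Hz
    kind: str = "white_gaussian"

    def sd_at(self, fs: float) -> float:
        return self.sd_at_reference * math.sqrt(fs / self.reference_bandwidth)


#: zero-noise sentinel, useful for exactness tests
QUIET = NoiseModel(sd_at_reference=0.0)


@dataclass
class GroundTruth:
    """True latent paths behind a synthetic trace.

    ``state_path`` and ``aa_position_path`` are change-point lists
    (time, value), piecewise-constant and time-ordered.  ``clean_force``
    is the per-sample noiseless force level; subtracting it from the trace
    recovers the injected noise exactly.
    """

    state_path: list[tuple[float, str]]
    aa_position_path: list[tuple[float, int]] | None = None
    true_delay: float | None = None
    clean_force: np.ndarray | None = None

    def dwell_durations(self, state: str, t_end: float) -> np.ndarray:
        """Complete (uncensored) true dwell durations in ``state``."""
        times = [t for t, _ in self.state_path] + [t_end]
        names = [s for _, s in self.state_path]
        out = [times[i + 1] - times[i] for i in range(len(names))
               if names[i] == state and 0 < i < len(names) - 1]
        return np.asarray(out)


# ---------------------------------------------------------------------------
# reference kinetic schemes
# ---------------------------------------------------------------------------

def _bell_from_two_points(rate_at_force: float, at_force: float,
                          rate_at_zero: float, kBT: float) -> tuple[float, float]:
    """(ln_k0, delta_x) of a force-decelerated Bell law through two rates."""
    delta_x = kBT * math.log(rate_at_zero / rate_at_force) / at_force
    return math.log(rate_at_zero), delta_x


def rnc_misfold_scheme(tau_unfolded: float = 1.5,
                       tau_folded: float = 1.9,
                       at_force: float = 4.0,
                       tau_unfolded_zero_force: float = 6e-4,
                       delta_x_unfold: float = 2.0,
                       sequestered_aa: float = 130.0,
                       kBT: float = 4.11) -> KineticScheme:
    """Two-state unfolded <-> misfolded scheme of a stalled RNC.

    Defaults give an unfolded-state lifetime of 1.5 s at 4.0 pN
    extrapolating to 6e-4 s at zero force, a misfolded-state lifetime of
    1.9 s at 4.0 pN, and a 130-aa misfolded state.  ``delta_x_unfold`` is
    a representative transition-state distance for the force-accelerated
    escape from the misfolded state.
    """
    ln_k0_fold, dx_fold = _bell_from_two_points(
        1.0 / tau_unfolded, at_force, 1.0 / tau_unfolded_zero_force, kBT)
    ln_k0_unfold = math.log(1.0 / tau_folded) - at_force * delta_x_unfold / kBT
    return KineticScheme(
        states=(("U", 0.0), ("M", sequestered_aa)),
        transitions=(
            Transition("U", "M", ln_k0_fold, dx_fold, sign=-1),
            Transition("M", "U", ln_k0_unfold, delta_x_unfold, sign=+1),
        ),
    )


def c_domain_scheme(tau_unfolded: float = 1.5,
                    tau_folded: float = 1.9,
                    at_force: float = 4.0,
                    tau_unfolded_zero_force: float = 6e-4,
                    delta_x_unfold: float = 2.0,
                    sequestered_aa: float = 75.0,
                    kBT: float = 4.11) -> KineticScheme:
    """Two-state unfolded <-> folded-C-domain scheme (75-aa transition)."""
    scheme = rnc_misfold_scheme(tau_unfolded, tau_folded, at_force,
                                tau_unfolded_zero_force, delta_x_unfold,
                                sequestered_aa, kBT)
    return KineticScheme(
        states=(("U", 0.0), ("C", sequestered_aa)),
        transitions=(
            Transition("U", "C", scheme.transitions[0].ln_k0,
                       scheme.transitions[0].delta_x, -1),
            Transition("C", "U", scheme.transitions[1].ln_k0,
                       scheme.transitions[1].delta_x, +1),
        ),
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _state_forces(scheme: KineticScheme, model: TetherModel,
                  baseline_force: float, unfolded_aa_out: float
                  ) -> dict[str, float]:
    """Equilibrium force of each state at fixed trap separation."""
    contour_out = aa_to_contour(unfolded_aa_out, model.nm_per_aa)
    forces = {}
    for name, seq in scheme.states:
        try:
            forces[name] = equilibrium_force(
                model, baseline_force, contour_out,
                -aa_to_contour(seq, model.nm_per_aa))
        except (ValueError, ArithmeticError) as exc:
            raise ArithmeticError(
                f"could not solve equilibrium force for state {name!r}: {exc}"
            ) from exc
    return forces


def _emit(change_times: np.ndarray, levels: np.ndarray, duration: float,
          fs: float, noise: NoiseModel, rng: np.random.Generator,
          metadata: dict) -> tuple[ForceTrace, np.ndarray]:
    """Sample a piecewise-constant force path on a uniform grid, add noise."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    seg = np.searchsorted(change_times, t, side="right") - 1
    clean = levels[seg]
    sd = noise.sd_at(fs)
    force = clean + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    return ForceTrace(t, force, fs, metadata), clean


def simulate_hopping_trace(scheme: KineticScheme, model: TetherModel,
                           baseline_force: float, duration: float, fs: float,
                           noise: NoiseModel, seed: int,
                           unfolded_aa_out: float = 164.0,
                           start_state: str | None = None,
                           ) -> tuple[ForceTrace, GroundTruth]:
    """Passive-mode hopping trace of a stalled complex.

    A continuous-time Markov (Gillespie) simulation of ``scheme`` with each
    state's exit rates evaluated at that state's own equilibrium force.
    ``baseline_force`` is the force of the fully unfolded state;
    ``unfolded_aa_out`` the polypeptide length outside the exit tunnel.
    """
    if duration * fs < 10:
        raise ValueError("trace must contain at least 10 samples")
    rng = np.random.default_rng(seed)
    forces = _state_forces(scheme, model, baseline_force, unfolded_aa_out)
    exit_rates = {
        name: [(tr.target, tr.rate(forces[name], model.kBT))
               for tr in scheme.exit_transitions(name)]
        for name in scheme.state_names
    }
    state = start_state if start_state is not None else scheme.state_names[0]
    t = 0.0
    change_times = [0.0]
    states = [state]
    while t < duration:
        outs = exit_rates[state]
        total = sum(rate for _, rate in outs)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        u = rng.uniform(0.0, total)
        acc = 0.0
        for target, rate in outs:
            acc += rate
            if u < acc:
                state = target
                break
        change_times.append(t)
        states.append(state)
    levels = np.array([forces[s] for s in states])
    meta = {
        "kind": "hopping", "seed": seed, "baseline_force_pN": baseline_force,
        "scheme": "/".join(scheme.state_names),
        "unfolded_aa_out": unfolded_aa_out,
        "extension_at_10pN_nm": total_extension(
            model, 10.0, aa_to_contour(unfolded_aa_out, model.nm_per_aa)),
    }
    trace, clean = _emit(np.asarray(change_times), levels, duration, fs,
                         noise, rng, meta)
    truth = GroundTruth(
        state_path=list(zip(change_times, states)), clean_force=clean)
    return trace, truth


def simulate_translation_trace(model: TetherModel, elongation_rate: float,
                               fold_scheme: KineticScheme,
                               folding_start_codon: int, delay_tau: float,
                               total_codons: int, fs: float,
                               noise: NoiseModel, seed: int,
                               initial_force: float = 4.5,
                               linker_aa_out: float = 37.0,
                               post_translation_s: float = 30.0,
                               max_duration: float = 1500.0,
                               ) -> tuple[ForceTrace, GroundTruth]:
    """Real-time translation trace with delayed folding onset.

    The ribosome adds one amino acid of out-of-tunnel contour per codon,
    with per-codon waits exponential at ``elongation_rate``; the force is
    re-solved from the series balance after every event (the trap
    separation is fixed by ``initial_force`` with ``linker_aa_out`` amino
    acids outside the tunnel before restart).  After the ribosome passes
    ``folding_start_codon``, an exponential delay of mean ``delay_tau``
    (0 disables the delay) gates entry into ``fold_scheme`` hopping;
    folded states sequester their contour, raising the force.

    Translation halts at ``total_codons``; the record continues for
    ``post_translation_s`` after both translation and the first folding
    event (right-censoring the delay if ``max_duration`` is hit first).
    """
    if folding_start_codon > total_codons:
        raise ValueError("folding_start_codon must be <= total_codons")
    rng = np.random.default_rng(seed)
    contour0 = aa_to_contour(linker_aa_out, model.nm_per_aa)
    separation = total_extension(model, initial_force, contour0)
    max_contour = aa_to_contour(linker_aa_out + total_codons, model.nm_per_aa)
    table = ForceToContourTable(model, separation, max_contour + 1.0)

    def force_at(codons_done: int, state: str) -> float:
        contour = aa_to_contour(
            linker_aa_out + codons_done - fold_scheme.sequestered_aa(state),
            model.nm_per_aa)
        # invert the tabulated force(contour) relation
        return float(np.interp(contour, table._contour_desc[::-1],
                               table._force_desc[::-1]))

    unfolded = fold_scheme.state_names[0]
    state = unfolded
    codons = 0
    t = 0.0
    gate: float | None = None  # time folding becomes possible
    true_delay: float | None = None
    first_fold_t: float | None = None
    change_times = [0.0]
    levels = [force_at(0, state)]
    state_path = [(0.0, state)]
    aa_path = [(0.0, 0)]
    if folding_start_codon == 0:
        true_delay = rng.exponential(delay_tau) if delay_tau > 0 else 0.0
        gate = true_delay
    while t < max_duration:
        rates: list[tuple[str, float]] = []
        if codons < total_codons and elongation_rate > 0:
            rates.append(("step", elongation_rate))
        folding_open = gate is not None and t >= gate
        if state != unfolded or folding_open:
            for tr in fold_scheme.exit_transitions(state):
                rates.append((f"fold:{tr.target}",
                              tr.rate(force_at(codons, state), model.kBT)))
        total_rate = sum(r for _, r in rates)
        if total_rate <= 0:
            if gate is not None and t < gate:
                t = gate  # idle until the delay gate opens
                continue
            break
        wait = rng.exponential(1.0 / total_rate)
        if gate is not None and t < gate and t + wait >= gate:
            t = gate  # rates change when the gate opens; restart the clock
            continue
        t += wait
        if t >= max_duration:
            break
        u = rng.uniform(0.0, total_rate)
        acc = 0.0
        for label, rate in rates:
            acc += rate
            if u < acc:
                break
        if label == "step":
            codons += 1
            aa_path.append((t, codons))
            if codons == folding_start_codon and gate is None:
                true_delay = rng.exponential(delay_tau) if delay_tau > 0 else 0.0
                gate = t + true_delay
        else:
            state = label.split(":", 1)[1]
            state_path.append((t, state))
            if state != unfolded and first_fold_t is None:
                first_fold_t = t
        change_times.append(t)
        levels.append(force_at(codons, state))
        if (codons >= total_codons and first_fold_t is not None
                and t >= first_fold_t + post_translation_s
                and t >= (aa_path[-1][0] + post_translation_s)):
            break
    if first_fold_t is None:
        t_end = max_duration
    else:
        # record ends after both translation and the first folding event
        # have been followed for post_translation_s (hopping continues)
        t_end = min(max_duration,
                    max(first_fold_t, aa_path[-1][0]) + post_translation_s)
    meta = {
        "kind": "translation", "seed": seed,
        "initial_force_pN": initial_force, "linker_aa_out": linker_aa_out,
        "total_codons": total_codons,
        "folding_start_codon": folding_start_codon,
        "extension_at_10pN_nm": total_extension(model, 10.0, contour0),
    }
    trace, clean = _emit(np.asarray(change_times), np.asarray(levels),
                         t_end, fs, noise, rng, meta)
    truth = GroundTruth(state_path=state_path, aa_position_path=aa_path,
                        true_delay=true_delay, clean_force=clean)
    return trace, truth


def sample_delays(model_kind: str, params: dict, n: int, seed: int) -> np.ndarray:
    """Draw i.i.d. delay times (s) from a named family.

    Families: ``exponential`` (``mean``), ``double_exponential``
    (``w``, ``tau1``, ``tau2``; mixture weight ``w`` on ``tau1``), and
    ``erlang2`` (``rate``; sum of two exponentials of that rate).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if model_kind == "exponential":
        return rng.exponential(params["mean"], size=n)
    if model_kind == "double_exponential":
        pick = rng.uniform(size=n) < params["w"]
        taus = np.where(pick, params["tau1"], params["tau2"])
        return rng.exponential(1.0, size=n) * taus
    if model_kind == "erlang2":
        return rng.exponential(1.0 / params["rate"], size=(2, n)).sum(axis=0)
    raise ValueError(f"unknown delay family: {model_kind!r}")
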