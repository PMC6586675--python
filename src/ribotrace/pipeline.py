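"""End-to-end orchestration of the stalled-RNC and real-time analyses.

``run_stalled_pipeline`` chains HMM segmentation, dwell extraction,
lifetime fitting and the force-binned Bell fit over a cohort of passive
hopping traces.  ``run_realtime_pipeline`` chains the force-to-codon
conversion, isotonic trajectory fit, folding-onset detection and delay
measurement over a cohort of translation traces, fits the delay
distribution, and overlays the measured delays against simulated
equilibrium and delayed cohorts.

Quality control follows the tether screen: molecules whose total length at
10 pN falls outside 1350--1450 nm are excluded (the tether is probably not
the designed single molecule), and real-time molecules must additionally
show C-domain folding by the end of the record.  Excluded molecules never
enter cohort statistics; every exclusion carries a reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bell_analysis, delay_distribution, dwell_kinetics
from .cotranslational_simulator import SimConfig, first_fold_cdf, simulate_cohort
from .elongation_analysis import elongation_rate, fit_monotone, measure_delay
from .tether_mechanics import DEFAULT_MODEL, TetherModel, force_trace_to_aa
from .trace import ForceTrace, read_trace_tsv

__all__ = ["MoleculeRecord", "qc_tether", "qc_realtime",
           "run_stalled_pipeline", "run_realtime_pipeline",
           "TETHER_WINDOW_NM"]

#: acceptable total tether length at 10 pN, nm
TETHER_WINDOW_NM = (1350.0, 1450.0)


@dataclass
class MoleculeRecord:
    """Per-molecule QC status and analysis products."""

    molecule_id: str
    construct: str = ""
    trace_path: str | None = None
    qc_pass: bool = False
    qc_reasons: list[str] = field(default_factory=list)
    products: dict = field(default_factory=dict)


def qc_tether(extension_at_10pN: float | None) -> tuple[bool, str | None]:
    """Tether length screen: pass iff 1350 <= extension(10 pN) <= 1450 nm."""
    if extension_at_10pN is None:
        return False, "no 10 pN extension estimate"
    lo, hi = TETHER_WINDOW_NM
    if not lo <= extension_at_10pN <= hi:
        return False, (f"tether length {extension_at_10pN:.0f} nm at 10 pN "
                       f"outside [{lo:.0f}, {hi:.0f}]")
    return True, None


def qc_realtime(record: MoleculeRecord) -> tuple[bool, list[str]]:
    """Real-time screen: tether length in window and C-domain folding seen.

    A molecule with no detected folding onset (censored delay) has no
    C-domain folding signature at trace end and is excluded.
    """
    reasons: list[str] = []
    ok, reason = qc_tether(record.products.get("extension_at_10pN_nm"))
    if not ok:
        reasons.append(reason)
    delay = record.products.get("delay")
    if delay is None or delay.censored:
        reasons.append("no C domain folding")
    return not reasons, reasons


def _extension_estimate(trace: ForceTrace) -> float | None:
    val = trace.metadata.get("extension_at_10pN_nm")
    return float(val) if val is not None else None


def _load_traces(traces) -> list[tuple[str, ForceTrace]]:
    out = []
    for item in traces:
        if isinstance(item, (str, Path)):
            tr = read_trace_tsv(item)
            out.append((Path(item).stem, tr))
        else:
            out.append(item)
    return out


def run_stalled_pipeline(traces, model: TetherModel = DEFAULT_MODEL,
                         candidate_state_counts=(1, 2, 3),
                         min_dwells: int = 5,
                         out_dir: str | Path | None = None) -> dict:
    """Equilibrium kinetics pipeline: traces -> dwells -> rates -> Bell fits.

    ``traces`` is an iterable of (molecule_id, ForceTrace) pairs or TSV
    paths; one molecule may contribute several traces at different forces.
    Returns a report dict with per-molecule records, the pooled rate table,
    and Bell fits for the folding (exit from the lowest-force state) and
    unfolding (exit from the highest-force state) branches.  Per-molecule
    failures are recorded, not fatal; an empty input yields an empty report.
    """
    records: list[MoleculeRecord] = []
    fold_rates: list[dwell_kinetics.RateMeasurement] = []
    unfold_rates: list[dwell_kinetics.RateMeasurement] = []
    for mol_id, trace in _load_traces(traces):
        rec = MoleculeRecord(molecule_id=mol_id,
                             construct=str(trace.metadata.get("construct", "")))
        records.append(rec)
        ok, reason = qc_tether(_extension_estimate(trace))
        if not ok:
            rec.qc_reasons.append(reason)
            continue
        try:
            hmm = dwell_kinetics.fit_hmm(trace, candidate_state_counts)
            dwells = dwell_kinetics.extract_dwells(hmm, force=trace.force)
            rec.products["hmm_n_states"] = hmm.n_states
            rec.products["dwells"] = dwells
            if hmm.n_states >= 2:
                low, high = 0, hmm.n_states - 1
                fold_rates.append(dwell_kinetics.fit_lifetime_cdf(
                    dwells, low, to_state=high, molecule_id=mol_id,
                    min_dwells=min_dwells))
                unfold_rates.append(dwell_kinetics.fit_lifetime_cdf(
                    dwells, high, to_state=low, molecule_id=mol_id,
                    min_dwells=min_dwells))
            rec.qc_pass = True
        except (ValueError, RuntimeError) as exc:
            rec.qc_reasons.append(f"analysis failed: {exc}")
    report: dict = {"molecules": records, "rates": {
        "folding": fold_rates, "unfolding": unfold_rates}}
    for branch, rates in report["rates"].items():
        if len(rates) >= 4:
            bins = bell_analysis.bin_rates(rates)
            if len(bins) >= 2:
                report.setdefault("bell_fits", {})[branch] = \
                    bell_analysis.fit_bell(bins, model.kBT)
    if out_dir is not None:
        _persist_stalled(report, Path(out_dir))
    return report


def run_realtime_pipeline(traces, model: TetherModel = DEFAULT_MODEL,
                          endpoint_codon: int = 259,
                          folding_codon: float = 167.0,
                          sim_n: int = 10_000, seed: int = 0,
                          out_dir: str | Path | None = None,
                          **delay_kwargs) -> dict:
    """Real-time pipeline: traces -> trajectories -> delays -> model fits.

    ``endpoint_codon`` is the construct's final chain length used as the
    internal length anchor for the force conversion.  The cohort's
    uncensored delays are fitted with the exponential, double-exponential
    and Erlang(2) CDFs, compared by F test against the exponential null,
    and overlaid against simulated equilibrium and delayed cohorts.
    """
    records: list[MoleculeRecord] = []
    rates, spreads = [], []
    delays = []
    for mol_id, trace in _load_traces(traces):
        rec = MoleculeRecord(molecule_id=mol_id,
                             construct=str(trace.metadata.get("construct", "")))
        records.append(rec)
        rec.products["extension_at_10pN_nm"] = _extension_estimate(trace)
        try:
            aa = force_trace_to_aa(trace, model, endpoint_codon)
            # exclude the post-translation plateau from the rate windows
            fit = fit_monotone(trace.time, aa,
                               window_range=(None, endpoint_codon - 10))
            rate, spread = elongation_rate(fit)
            rec.products["elongation_rate_aa_s"] = rate
            rec.products["elongation_spread_aa_s"] = spread
            obs = measure_delay(trace, fit, folding_codon, model=model,
                                molecule_id=mol_id, **delay_kwargs)
            rec.products["delay"] = obs
        except (ValueError, RuntimeError) as exc:
            rec.qc_reasons.append(f"analysis failed: {exc}")
            continue
        rec.qc_pass, reasons = qc_realtime(rec)
        rec.qc_reasons.extend(reasons)
        if rec.qc_pass:
            rates.append(rate)
            spreads.append(spread)
            delays.append(obs)
    report: dict = {"molecules": records}
    if rates:
        report["elongation"] = {
            "cohort_mean_rate_aa_s": float(np.mean(rates)),
            "cohort_rate_sd_aa_s": float(np.std(rates, ddof=1)) if len(rates) > 1
            else 0.0,
            "mean_within_molecule_spread_aa_s": float(np.mean(spreads)),
        }
    taus = np.array([d.tau for d in delays if not d.censored])
    n_censored = sum(d.censored for d in delays)
    if taus.size >= 3:
        fits = {fam: delay_distribution.fit_delay_cdf(taus, fam)
                for fam in ("exponential", "double_exponential", "erlang2")}
        tests = {}
        for fam in ("double_exponential", "erlang2"):
            F, p = delay_distribution.f_test_model_comparison(
                fits["exponential"], fits[fam])
            tests[fam] = {"F": F, "p": p}
        tau_hat = fits["exponential"].params["tau_delay"]
        eq = simulate_cohort(SimConfig(
            n_ribosomes=sim_n, folding_start_codon=int(folding_codon),
            delay_tau=0.0, seed=seed))
        ne = simulate_cohort(SimConfig(
            n_ribosomes=sim_n, folding_start_codon=int(folding_codon),
            delay_tau=tau_hat, seed=seed + 1))
        report["delay"] = {
            "taus": taus, "n_censored": n_censored,
            "fits": fits, "f_tests": tests,
            "fraction_equilibrium_like": float(np.mean(
                [d.onset_kind == "equilibrium_like" for d in delays
                 if not d.censored])),
            "onset_kinds": {k: int(sum(d.onset_kind == k for d in delays))
                            for k in ("misfolded", "c_domain",
                                      "equilibrium_like")},
            "sim_equilibrium_cdf_time": first_fold_cdf(eq, "time"),
            "sim_delay_cdf_time": first_fold_cdf(ne, "time"),
            "sim_equilibrium_cdf_codon": first_fold_cdf(eq, "codon"),
            "sim_delay_cdf_codon": first_fold_cdf(ne, "codon"),
        }
    if out_dir is not None:
        _persist_realtime(report, Path(out_dir))
    return report


# ---------------------------------------------------------------------------
# persistence: machine-readable JSON + human-readable TSV
# ---------------------------------------------------------------------------

def _records_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": r.molecule_id, "construct": r.construct,
        "qc_pass": r.qc_pass, "qc_reasons": "; ".join(r.qc_reasons),
    } for r in records])


def _persist_stalled(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _records_frame(report["molecules"]).to_csv(
        out_dir / "molecules.tsv", sep="\t", index=False)
    rows = []
    for branch, rates in report["rates"].items():
        for m in rates:
            rows.append({"branch": branch, "molecule_id": m.molecule_id,
                         "rate_per_s": m.rate, "rate_se_per_s": m.rate_se,
                         "mean_force_pN": m.mean_force,
                         "n_events": m.n_events, "gof_r2": m.gof_r2})
    pd.DataFrame(rows).to_csv(out_dir / "rates.tsv", sep="\t", index=False)
    for rec in report["molecules"]:
        if "dwells" in rec.products:
            rec.products["dwells"].to_csv(
                out_dir / f"dwells_{rec.molecule_id}.tsv", sep="\t",
                index=False)
    summary = {}
    for branch, fit in report.get("bell_fits", {}).items():
        summary[branch] = {
            "ln_k0": fit.ln_k0, "delta_x_nm": fit.delta_x,
            "var_ln_k0": fit.var_ln_k0, "var_delta_x": fit.var_delta_x,
            "n_bins": fit.n_bins, "fit_r2": fit.fit_r2,
        }
    (out_dir / "bell_fits.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))


def _persist_realtime(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _records_frame(report["molecules"]).to_csv(
        out_dir / "molecules.tsv", sep="\t", index=False)
    rows = []
    for rec in report["molecules"]:
        obs = rec.products.get("delay")
        rows.append({
            "molecule_id": rec.molecule_id,
            "rate_aa_s": rec.products.get("elongation_rate_aa_s"),
            "spread_aa_s": rec.products.get("elongation_spread_aa_s"),
            "tau_s": obs.tau if obs is not None else None,
            "onset_kind": obs.onset_kind if obs is not None else None,
            "censored": obs.censored if obs is not None else None,
        })
    pd.DataFrame(rows).to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    if "delay" in report:
        d = report["delay"]
        summary = {
            "n_delays": int(len(d["taus"])),
            "n_censored": int(d["n_censored"]),
            "fraction_equilibrium_like": d["fraction_equilibrium_like"],
            "onset_kinds": d["onset_kinds"],
            "fits": {fam: {"params": fit.params, "rss": fit.rss,
                           "r2": fit.r2, "n": fit.n}
                     for fam, fit in d["fits"].items()},
            "f_tests": d["f_tests"],
        }
        if "elongation" in report:
            summary["elongation"] = report["elongation"]
        (out_dir / "delay_report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        for name in ("sim_equilibrium_cdf_time", "sim_delay_cdf_time",
                     "sim_equilibrium_cdf_codon", "sim_delay_cdf_codon"):
            x, c = d[name]
            pd.DataFrame({"x": x, "cdf": c}).to_csv(
                out_dir / f"{name}.tsv", sep="\t", index=False)
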