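# ribotrace

Analysis pipeline for single-molecule optical-tweezers measurements of
co-translational protein folding.

In a dual-trap passive-mode experiment a ribosome-nascent-chain complex is
tethered between two beads through DNA handles. Folding and unfolding of
the nascent polypeptide appear as sudden force jumps; active translation
appears as a slow force decay as the chain lengthens one amino acid at a
time. `ribotrace` turns such force-versus-time records into physical
quantities — polypeptide contour length, state lifetimes, force-dependent
rates, elongation rates, and the delay between reaching a folding-competent
length and the first folding event — and simulates ribosome cohorts to ask
whether observed folding is consistent with equilibrium kinetics.

## Models at the core

**Tether mechanics.** Traps, DNA handles, and unfolded polypeptide are
springs in series, all carrying the same force at fixed trap separation.
The polypeptide is a worm-like chain in the Marko–Siggia interpolation,

    F = (k_BT / P) [ 1/(4(1 − x/L)²) − 1/4 + x/L ],   P = 0.6 nm,

with 0.365 nm of contour per amino acid; the DNA handles use the extensible
variant (x/L → x/L − F/S; P = 35 nm, S = 1200 pN); the two 0.25 pN/nm traps
combine to 0.125 pN/nm. Inverting the series force balance converts force
into nascent-chain length, anchored at the well-defined endpoint of
translation.

**Dwell kinetics.** Hopping traces are segmented with a Gaussian-emission
hidden Markov model (state count chosen by BIC), dwell lifetimes are fitted
with exponential cumulative distributions, and rates follow the Bell model

    ln k(F) = ln k₀ − F·Δx‡ / k_BT,

fitted as a weighted line through force-binned ln k with √n bins. Fitted
parameters are compared across constructs with two-tailed Welch's t tests.

**Real-time translation.** The converted amino-acid trajectory is fitted by
isotonic regression (pool-adjacent-violators); the elongation rate is 10 aa
divided by the median 10-aa window crossing time. Folding onsets are scored
per 1-s window on 10× block-averaged data against a Gaussian CDF with a
1 × 10⁻⁵ tail threshold, plus a 0.13 pN window-SD flag. The delays τ from
codon-167 arrival to first folding are fitted with exponential,
double-exponential and Erlang(2) CDFs compared by F test.

**Cohort simulation.** 10,000 ribosomes draw per-codon exponential waits
(1.0 aa/s); from codon 167 folding competes as an exponential process at
k_fold = 1/1.5 s⁻¹, optionally gated by an exponential delay (τ_delay =
63 s); translation stops at codon 222 while the folding clock keeps running.

Because raw instrument traces for this system are not publicly deposited,
the package ships a synthetic-data generator (`ribotrace.synthetic_data`)
that produces hopping and translation traces with Bell-model kinetics,
series-compliance force levels and white instrument noise (0.25 pN at
1333 Hz), providing ground truth for every analysis stage.

## Worked example

Simulate a stalled-complex hopping trace at 4.0 pN and recover the
unfolded-state lifetime:

```python
import numpy as np
from ribotrace.synthetic_data import NoiseModel, rnc_misfold_scheme, \
    simulate_hopping_trace
from ribotrace.dwell_kinetics import fit_hmm, extract_dwells, fit_lifetime_cdf
from ribotrace.tether_mechanics import DEFAULT_MODEL

model = DEFAULT_MODEL
scheme = rnc_misfold_scheme()          # unfolded lifetime 1.5 s at 4.0 pN
trace, truth = simulate_hopping_trace(scheme, model, baseline_force=4.0,
                                      duration=300.0, fs=2500.0,
                                      noise=NoiseModel(), seed=1)
hmm = fit_hmm(trace, candidate_state_counts=(1, 2, 3))
dwells = extract_dwells(hmm, force=trace.force)
rate = fit_lifetime_cdf(dwells, state=0, to_state=1)
print(f"states selected by BIC : {hmm.n_states}")
print(f"state mean forces (pN) : {np.round(hmm.state_means, 2)}")
print(f"unfolded-state lifetime: {1/rate.rate:.2f} +/- "
      f"{rate.rate_se/rate.rate**2:.2f} s "
      f"({rate.n_events} dwells at {rate.mean_force:.1f} pN)")
```

Output:

```
states selected by BIC : 2
state mean forces (pN) : [4.   4.63]
unfolded-state lifetime: 1.82 +/- 0.18 s (99 dwells at 4.0 pN)
```

The BIC correctly selects two states; the unfolded state sits at the
4.0 pN baseline and the misfolded state 0.63 pN higher (130 amino acids of
sequestered contour at this tether compliance). The fitted lifetime agrees
with the generating 1.5 s within its sampling error.

A command-line interface wraps the pipelines:

```sh
ribotrace simulate --kind translation --n 12 --seed 0 --out traces/
ribotrace analyze-realtime traces/*.tsv --out report/ --endpoint-codon 259
ribotrace simulate --kind cohort --seed 1 --out sim/
```

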