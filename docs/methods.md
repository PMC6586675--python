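# Methods

## Tether model

The dumbbell is treated as four mechanical elements in series — two
Hookean optical traps and two polymer segments — all carrying the same
tension F at fixed trap separation:

* **Traps.** Each trap is a spring of κ = 0.25 pN/nm; acting on opposite
  beads of the dumbbell they combine in series to 0.125 pN/nm. This
  effective stiffness is what reproduces the calculated single-amino-acid
  step sizes (−0.0055 pN at 4.5 pN with a linker-only chain, −0.0031 pN at
  3.5 pN with 224 residues out); a single-trap stiffness does not.
* **DNA handles.** Two 2-kb handles, 4000 bp × 0.338 nm/bp = 1352 nm of
  contour, described by the extensible worm-like chain: the Marko–Siggia
  interpolation with the enthalpic substitution x/L → x/L − F/S, with
  P = 35 nm and S = 1200 pN. At 10 pN this gives 1290 nm of extension.
* **Polypeptide.** The out-of-tunnel nascent chain is an inextensible WLC
  with P = 0.6 nm and 0.365 nm of contour per amino acid. Folded states
  sequester contour; the exit tunnel sequesters 40 residues by default
  (configurable 30–40).
* **Thermal energy** k_BT = 4.11 pN·nm (25 °C), configurable.

Solving the force balance at fixed separation is a bracketed scalar root
find (Brent, tolerance 1e−10 pN). The force→contour inversion used for
whole traces is pre-tabulated on a 512-point contour grid and inverted by
monotone interpolation; it matches the direct solve to well below 0.01
amino acid.

**Length screen.** Tethers whose total series extension at 10 pN falls
outside 1350–1450 nm are rejected as miss-assembled. In the forward model
the designed construct family spans 1377 nm (folded full-length protein
plus tags) to 1414 nm (fully unfolded chain plus full linker), comfortably
inside the window, while a double tether (~2× DNA) falls far outside. The
estimate includes the trap displacement (~80 nm at 10 pN), i.e. it is the
trap-separation-based operational length.

**Endpoint anchoring.** Converting a real-time translation trace to codon
positions assumes constant tunnel occupancy only through its anchor: the
unfolded force level over the last 10 s of the record is assigned the
construct's final chain length and everything earlier is back-calculated.
Because the record ends while the C domain hops, the anchor level is found
by a two-means split of the block-averaged final window; if the two levels
differ by less than 0.15 pN the window is treated as quiescent and its
mean is used.

## Synthetic traces

The generator emulates what the analysis assumes and no more:

* Conformational kinetics follow the Bell model,
  ln k(F) = ln k₀ ± F·Δx‡/k_BT, simulated in continuous time (Gillespie)
  with each state's exit rates held at that state's own equilibrium force.
  The default stalled-complex scheme has an unfolded→misfolded lifetime of
  1.5 s at 4.0 pN extrapolating to 6 × 10⁻⁴ s at zero force
  (Δx‡ = 8.04 nm), a misfolded-state lifetime of 1.9 s at 4.0 pN with a
  representative Δx‡ = 2 nm for the force-accelerated escape, and a 130-aa
  misfolded state (75 aa for the C-domain variant).
* Translation adds one amino acid of out-of-tunnel contour per codon with
  i.i.d. exponential waits (default 1.0 aa/s); after the folding-competent
  codon an exponential delay (default τ = 63 s; 0 disables it) gates entry
  into the folding scheme.
* Instrument noise is white Gaussian, 0.25 pN at 1333 Hz, scaled as
  √bandwidth. Noise is added after the state path, so subtracting the
  ground-truth levels recovers it exactly.

Not modelled: bead/instrument relaxation (transitions are instantaneous at
the sampling grid — adequate above the ~8 ms detection limit), baseline
flow shifts (the real analysis removes them manually; a trace-slicing mask
is the supported interface), codon-specific elongation rates, and
chaperone binding. Tests passing on these traces therefore verify the
inference machinery under the stated statistical model, not robustness to
every instrumental artifact.

## Dwell kinetics

Gaussian-emission HMMs are fitted on force (extension carries bead-pair
offsets), with the state count chosen by the lowest
BIC = −2 logL + p ln(n), p counted from free HMM parameters. EM is
initialised with k-means means and a sticky transition matrix
(self-transition 0.98): dwells span many samples, and a uniform initial
transition matrix lets EM collapse all states onto the global mean on
traces that visit a state only a handful of times. Decoding uses the
Viterbi path so that dwell durations come from one consistent path; states
are relabelled by increasing mean force (the lowest level is the unfolded
state). Boundary dwells are censored and excluded from lifetime fits;
dwells shorter than two samples are retained but flagged; no missed-event
correction is applied.

Lifetimes come from least-squares fits of 1 − exp(−t/τ) to the empirical
dwell-time CDF (plotting position i/n). The reported rate uncertainty is
the asymptotic exponential sampling error k/√n, **not** the covariance of
the CDF fit: empirical-CDF residuals are strongly positively correlated,
and the naive fit covariance understates the sampling error severalfold
(measured directly in the recovery tests). The maximum-likelihood estimate
1/mean is kept as a cross-check oracle in the tests.

## Bell analysis

Rates are pooled over molecules, binned into round(√n) equal-width force
bins, and ln k is fitted against force by weighted least squares
(slope = −Δx‡/k_BT, intercept = ln k₀). Per-bin weights are 1/σ² with
σ² the larger of the within-bin spread of ln k and the mean propagated
lifetime-fit variance — whichever source of variation dominates. The
residual scale is estimated from the fit, so the weights need only be
proportional to inverse variances. Parameters are compared with two-tailed
Welch's t tests; each variance carries the residual degrees of freedom of
its two-parameter fit (bins − 2) in the Welch–Satterthwaite formula, which
calibrates the simulated type-I rate to ~0.06 at α = 0.05. Non-linear
(cusp/catastrophe-type) rate laws are deliberately excluded: over a ~2 pN
force range they are not identifiable.

## Real-time analysis

Single 1-aa steps (−0.006 pN) are ~40× below the per-sample noise, so the
codon trajectory is fitted with isotonic regression — monotone
non-decreasing, no step-size assumption; individual fitted steps are not
interpreted. The elongation rate is 10 aa over the median 10-aa window
crossing time, with the spread propagated from the standard deviation of
the crossing times; windows are restricted to below the endpoint position
so the post-translation plateau does not enter.

Folding onsets are detected per 1-s window after 10× block averaging
(133 points per window at 1333 Hz, ~8 ms resolution): each point's
upper-tail probability under a Gaussian with the leave-one-out mean/SD of
its window scores an event below 1 × 10⁻⁵ (per-point; ≈0.13% of noise-only
windows produce a false event — both rates are verified in the tests), and
any window SD above 0.13 pN is flagged as a long-lived event or rapid
hopping. The test is one-sided in the folding direction (force increase).

The delay τ is the onset time minus the arrival time at the
folding-competent codon (first fit sample past the codon). Arrival and
onset are refined jointly: folding dips drag the monotone fit and bias the
raw arrival late by tens of seconds when the delay is short, so the
arrival is refit on pre-onset samples only and the onset rescanned until
the pair is stable (≤6 fixed-point rounds). Onsets are classified
equilibrium-like when τ falls within three equilibrium unfolded lifetimes
(default 3 × 1.5 s; with a 63-s delay scale this labels ~7% of molecules),
otherwise by the converted transition size (boundary 100 aa between the
~75-aa C-domain class and the ~130-aa misfolded class; both configurable).

## Delay distribution and model comparison

Uncensored delays are fitted by least squares of the family CDF to the
empirical CDF (i/n), for the exponential (one equilibration step),
double-exponential mixture (two ribosome populations) and Erlang shape-2
(two sequential similar-rate steps) families; censored observations are
excluded with counts reported. The double-exponential fit starts from
several points including the degenerate single-exponential solution, so
its RSS never exceeds the exponential's. Nested families are compared by
the extra-sum-of-squares F statistic ((RSS₀−RSS₁)/Δp)/(RSS₁/(n−p₁)) with
the exponential as the null; equal-parameter families by the variance
ratio of residual mean squares.

**Known limitation.** The F test's iid-residual assumption is broken by
construction when the fit is to an empirical CDF: residuals are positively
correlated, and the test is anti-conservative — on exponential-null
cohorts of n = 12 the measured rejection rate is ≈0.16 at nominal
α = 0.05 (the package's own calibration test computes this; the same
machinery on iid Gaussian residuals rejects at ≈0.02). p-values from
small-n CDF-based F comparisons should be read as descriptive, not
calibrated; the power side behaves as expected (Erlang-generated cohorts
of n = 200 reject the exponential null essentially always).

## Cohort simulation

Per-ribosome translation waits are exponential; the folding clock runs
from arrival at the folding-competent codon (completion of that codon's
wait) plus the optional delay, at constant k_fold independent of
translation (competing risks, not fold-between-steps; at these rates the
two variants agree within Monte-Carlo error). Translation halts at the
stop codon while folding continues, so every ribosome eventually folds and
the codon-axis CDF piles up at the final codon. `first_fold_codon` is the
number of codons completed when folding fires — the convention under which
the non-folding fraction at codon 177 equals the closed form
(r/(r+k))¹⁰ = 0.6¹⁰ ≈ 0.60%. In the equilibrium scenario the first-fold
time from arrival is exactly Exp(k_fold), giving the analytic 90th
percentile 1.5·ln 10 ≈ 3.45 s.

## Problem sizes and numerical choices

Tests use 10,000-ribosome cohorts (seconds), 100-seed recovery studies for
the Bell fit and BIC selection, 24 hopping traces at 250 Hz/150 s for the
dwell-rate recovery, 20 translation traces at 1333 Hz for the elongation
cohort, and 1000-replicate calibrations for the Welch and F tests; the
whole suite runs in about a minute. All randomness flows through
numpy's `default_rng` with explicit seeds; generators are byte-reproducible
given (seed, parameters). Ties in arrival times resolve to the earliest
qualifying sample; degenerate inputs (single-force bins, all-censored
dwell sets, never-reached codons) raise or flag rather than silently
proceeding.
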