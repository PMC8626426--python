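# Methods

## The model

After a diet switch from heavy (Lys8) to light (Lys0) lysine at day 0,
`turnoverkit` models the unlabeled-lysine fraction of three pools — the free
amino-acid pool `A(t)`, the bulk "all proteins" pool `B(t)`, and each protein
of interest `F_i(t)` — as a linear compartment system:

```
dA/dt  = k_st (1 − A) + k_a0 (B − A)
dB/dt  = k_bt (A − B)
dF_i/dt = k_bi (A − F_i)          A(0) = B(0) = F_i(0) = 0
```

`k_st` (per day) is dietary influx of new lysine into the free pool, `k_bt`
is bulk-proteome turnover — the source of *recycled* labeled lysine — and
`k_a0` is the exchange of that recycled lysine back into the free pool;
waste outflux balances influx so pool sizes stay constant. `k_bi` is the
replacement rate of the protein of interest and the only peptide-specific
parameter; the half-life is defined as `ln 2 / k_bi` (first-order
replacement), not the time at which `F_i` crosses 0.5 — the two differ
because the precursor lags.

The free pool solves in closed form: `A(t) = 1 − c1 e^(−λ1 t) − c2 e^(−λ2 t)`
with `λ1, λ2` the roots of `λ² − (k_st + k_a0 + k_bt) λ + k_st k_bt = 0`,
`c1 = (k_st − λ2)/(λ1 − λ2)`, `c1 + c2 = 1`. `F_i` is the convolution of `A`
with the exponential age distribution of the protein's molecules. Both
lysines of a missed-cleavage (two-lysine) peptide are drawn independently
from the precursor at the molecule's synthesis time, which gives the
three label-combination fractions in closed form and yields the exact
identities `p00 + p08 + p88 = 1` and `p00 + p08/2 = F_i`.

Model assumptions worth keeping in mind: steady-state pool sizes (no tissue
growth), a single well-mixed precursor per tissue, synthesis and degradation
entirely inside the analyzed tissue, and single-exponential replacement per
peptide. Plasma proteins diffused into a tissue violate the third
assumption and betray themselves by ratios above the free-lysine curve
(the package flags observations above `A(t) + 0.05` and calls a peptide
exogenous-suspect when half its observations are flagged); very long-lived
proteins violate the first and show wide confidence intervals and poor
fits.

## Numerical evaluation

All closed forms are evaluated through the stable kernel
`G(μ) = ∫₀ᵗ k e^(−k(t−s)) e^(−μ s) ds = k (e^(−μt) − e^(−kt))/(k − μ)`,
switched to its confluent limit `k t e^(−kt)(1 + x/2 + x²/6)` when
`|x| = |(k − μ)t| < 1e-7`, so near-degenerate rates (`k_bi ≈ λ_j`) are exact
and continuous rather than perturbed. With `k_a0 > 0` the eigenvalues are
provably distinct, but `λ2` is still computed as `k_st k_bt / λ1` to avoid
cancellation. Rates are bounded to half-lives in [0.01, 5000] days, which
brackets everything a 60-day chase can express.

## Fitting

The loss is the mean squared error between observed ratios
`Lys0/(Lys0+Lys8)` and `F_i(t)`. Because the model value at a timepoint is
a single number, each peptide's MSE reduces to sufficient statistics per
unique timepoint (count, mean, within-timepoint scatter); all rate fits run
on that 5-row table regardless of replicate count.

* **Rate profiling.** `k_bi` is optimized on a 400-point log grid over the
  rate bounds followed by four nested 17-point refinements (16× bracket
  shrink each), leaving log-rate accurate to ~5e-7 at full depth.
  Deterministic and vectorized across peptides and bootstrap replicates.
* **Training-set selection.** Provisional half-lives at the default
  coefficients (`k_st = 1.0`, `k_bt = 0.05`, `k_a0 = 0.5` per day) define
  the inner-quartile band [Q1, Q3] (linear-interpolation percentiles);
  peptides inside it are ranked by valid-ratio count, then total intensity,
  then sequence (a deterministic tie-break), and the top 100 seed training.
  Missed-cleavage peptides are excluded from training throughout.
* **Coordinate descent.** Each tissue coefficient moves multiplicatively
  (±5% initially, halved on failure to ±0.1%), and every candidate step
  re-optimizes every peptide's `k_bi` — freezing the rates produces a
  sawtooth objective that stalls prematurely (exposed by an ablation test).
  A move is accepted only if it improves the average MSE by more than
  1e-5 relative: without a relative threshold, chains of ~1e-9
  improvements walk the coefficients along a degenerate ridge (below)
  without bound.
* **Coefficient bounds.** `k_st, k_a0 ∈ [1e-3, 50]`, `k_bt ∈ [1e-4, 3]` per
  day. The MSE surface has a flat ridge toward an instantaneously
  equilibrating free pool (`k_bt, k_a0 → ∞`) that slow peptides cannot rule
  out; the bounds encode that a bulk proteome cannot turn over with a
  half-life under ~6 h and cut the ridge off.
* **Schedule.** Round 1 fits each training peptide independently
  (coarse settings; only the medians are kept). Round 2 jointly fits the
  top set twice — once from the round-1 medians and once from a start
  seeded by a factorial grid sweep around the defaults — keeping the
  better optimum; single-peptide medians are weakly identified and can
  seed the wrong basin, which greedy coordinate moves cannot leave even on
  noise-free data. Round 3 refits all inner-quartile peptides. Peptides
  with any absolute residual above 0.1 ("messy") are then dropped once and
  the joint fit repeated. Finally, factorial grid sweeps (each coefficient
  scaled by 0.1, 0.2, 0.33, 0.5, 0.75, 0.9, 1.0, 1.1, 1.25, 1.5, 2, 4 —
  12 factors, hence 1728 triples per sweep) run until no triple improves
  the loss, re-descending from any winner.

## Uncertainty

Per timepoint, the model-error standard deviation is
`s = sqrt(Σ(x_i − x̄)²/(N−1))` with `x̄` the *fitted* value (for `N = 1`,
the absolute residual). Each of 200 simulations resamples each timepoint's
ratios with replacement to the original count, perturbs them with Gaussian
noise of that timepoint's `s` (clamped to [0, 1]; configurable), and refits
the rate with coefficients fixed. The peptide 95% CI is the 5th-shortest to
5th-longest simulated half-life. Proteins pool all constituent peptides'
simulations: the median is the protein half-life and the 2.5th–97.5th
percentiles its CI. Shared-peptide groups ("A|B") aggregate separately and
never feed their constituent proteins. Randomness comes from one seed plus
a CRC32 of the peptidoform sequence per peptide, so results are independent
of processing order. Because the bootstrap adds timepoint noise *on top of*
resampling, intervals are mildly conservative; measured coverage at
σ = 0.03 is ~94–96%.

## Comparisons

Tissues sit at different points of their labeling curves at any calendar
time, so observed ratios are shifted to a common normalization timepoint
`t*` where the mean predicted fraction of the two groups (at the average of
their rates) crosses 0.5 (bisection to 1e-9); the shift is constant within
a tissue-timepoint and preserves all per-timepoint standard deviations. A
two-tailed Welch t-test (Student's behind a flag) on the pooled normalized
ratios gives the p-value; the fold change is `log2` of the half-life
ratio. Proteoform pairs (modified vs unmodified peptidoform, same base
sequence, protein and tissue) use the same machinery; pairs involving
methionine oxidation or a half-life under 3 days are omitted, and a
difference is called significant at |log2 FC| > 0.25 and p < 1e-4. Raw
p-values are reported as the method defines them (fixed thresholds, no
multiplicity correction); Benjamini–Hochberg q-values are available as a
clearly labeled extension.

## Synthetic data

The generator emulates the targeted study design: chase timepoints 3, 7,
14, 30, 60 days with 5/4/4/4/5 replicates (22 animals); log-normal protein
half-lives (median 5 d, log-SD 0.8); additive Gaussian ratio noise
σ = 0.03 clamped to [0, 1]; log-normal total intensities split as
`light = ratio × total`; 10% missingness (one channel zeroed, so the
observation drops at ingest); 5% missed-cleavage peptides with three-way
label intensities; 3% shared peptides placed in two protein sequences; 2%
exogenous plasma-like proteins whose ratios follow a separate fast
precursor (`k_st = 5, k_bt = 0.1, k_a0 = 0.5` per day) — the
impossible-region signature. Default tissue coefficients are
`k_st = 0.5, k_bt = 0.08, k_a0 = 0.2` per day, i.e. the free pool is ~64%
unlabeled by day 3 with a visible recycling lag. Protein sequences are
concatenations of their K-terminated peptides, so substring remapping and
Lys-C consistency hold by construction. A blood-like variant draws
half-lives from a 50/50 mixture (medians 2 and 15 d) to reproduce the
bimodal plasma/cell distribution.

What the generator does *not* emulate: intensity-dependent
(heteroscedastic) noise beyond an optional flag, within-animal correlation
across timepoints, isotope-envelope interference, chromatographic missing
structure, or non-exponential ("two-phase") degradation. Passing tests on
these fixtures therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to every artifact of real
LC-MS data.

## Known limitations and measured behavior

* **Profile-likelihood bias in the precursor curve.** Re-optimizing each
  peptide's rate at every coefficient step is required to avoid the
  sawtooth, but it also makes the shared coefficients a profile-likelihood
  estimate with thousands of incidental parameters fitted from ~22
  observations each. At σ_ratio = 0.03 the recovered free-lysine curve is
  systematically high by ~0.03–0.06 absolute around days 2–6; the bias
  scales with σ², does not shrink with more peptides, and disappears
  (max deviation ~0.007) when rates are held at truth. Peptide half-lives
  remain accurate (median relative error ~7% for half-lives of 1–30 d)
  because the rate fit partially compensates the curve shift.
* **Type-I error** of the normalize-and-t-test pipeline measures ~5% at
  nominal α = 0.05 on null comparisons with the study's replicate
  structure, despite pooling ratios across timepoints.
* Half-lives far beyond the 60-day window are reported at face value but
  carry wide CIs and poor fits, as expected for a method whose information
  ends at day 60.

## Problem sizes used by tests and the acceptance script

Simulation-based checks use 120 synthetic proteins (~290 peptides) per
tissue for the 20-tissue recovery study, 500 peptides for CI calibration,
1000 null comparisons for error control, and 10⁶ molecules for the
Monte-Carlo missed-cleavage oracle — sizes chosen so the full suite runs
in minutes on one core while keeping every Monte-Carlo margin comfortably
away from its threshold.
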