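# Methods

This note documents the model, the estimator conventions, every default
that matters, and the reasoning behind the genuinely open design choices.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synapse model

Time is discrete at 0.5 ms per step (2 steps per ms). A single
postsynaptic unit receives `n_excitatory` (default 3) excitatory inputs —
each feeding one AMPA and one NMDA shift register — and `n_inhibitory`
(default 1) GABA inputs. A register holds the scheduled future deflections
of its input; registers store deflections *relative to* the resting
potential ReP, so a freshly initialised bank encodes "membrane at rest"
and the summed potential is S(i) = ReP + Σ current-slot deflections. This
makes initialisation, superposition and the comparison of S against
millivolt thresholds all consistent.

The postsynaptic waveform is piecewise linear: zero during the synaptic
delay `t_sd`, linear rise over `t_r` to the peak `A_MAX`, linear decay
over `t_d` back to zero. The rise branch covers `(t_sd, t_sd + t_r]` and
the decay branch `(t_sd + t_r, t_sd + t_r + t_d]`; under this convention
the peak equals `A_MAX` exactly at `t_sd + t_r` and the support is
`t_sd + t_r + t_d` (the only reading consistent with the parameters'
stated roles). Defaults: AMPA (5 mV, 1, 2, 13 ms), NMDA (1 mV, 1, 2,
13 ms), GABA (−2.5 mV, 1, 2, 10 ms). The NMDA register contributes to
S(i) like the AMPA one; only its role in gating differs.

### Plasticity

LTP induction requires a presynaptic spike on an excitatory input *while*
S exceeds the Mg²⁺-unblock threshold (`Ca_threshold`, −68 mV untreated).
The induction increment is `power · dt · ltp_gain` with
`power = power_coefficient · (S − ReP)` (clamped at 0 below rest) and
`ltp_gain = 1`. Without induction, C decays multiplicatively by the
forgetting coefficient (default 0.999 per step, a ~500 ms time constant),
returning the weight to baseline in the absence of maintenance. The weight
multiplier `M = 1 + ln(C + 1)/(6 · clog)` with `clog = 2.3026` is applied
to both registers of the potentiated input on subsequent deliveries. The
denominator is read as the single factor `6 · clog ≈ 6 ln 10`, under which
M reaches 2.0 at C = 10⁶ − 1, matching the ~1.8–1.9 LTP magnitudes the
model is meant to produce. Two different quantities called "M" in the
formulation — the synaptic-function voltage entering the power rule and
the dimensionless weight multiplier — are kept apart here as `M_sf`
(= S at the induction step) and `weight_multiplier`.

Summary metrics per run: `n_spikes`; `LTP` = max M over the run;
`LTP_time_ms` = milliseconds during which any synapse holds
M ≥ 1 + `ltp_margin` (default margin 0.05). These summary definitions are
this package's conventions.

### Firing and excitotoxic injury

Output spiking is intentionally minimal: a spike is emitted when S reaches
the effective firing threshold outside an absolute refractory period
(defaults −55 mV, 2 ms). The effective threshold is

```
θ_eff(t) = firing_threshold + injury_gain · Ca_load(t)
```

where `Ca_load` is the accumulated calcium drive (`power · dt` summed over
induction events). With the default `injury_gain = 0` the threshold is
constant. Grid runs enable `injury_gain = 2.5e-4` mV per drive unit for
*every* cell (control included), modelling excitotoxic excitability loss
(depolarisation block / energy failure): pathological calcium overload
silences the cell, and treatments that cut the calcium load protect
spiking. A threshold-plus-refractory model without any injury term cannot
express excitotoxic spike loss at all — more drive can then only mean more
spikes — which is why the injury term exists. The gain is sized so the
control-stage load of the canonical 10 s protocol shifts the threshold by
only a few mV while the advanced stage (15× the drive gain) is strongly
suppressed; the qualitative ordering of conditions does not depend on the
exact value, because the load ordering across conditions is monotone in
the drive gain and antitone in the unblock threshold.

Note that injury affects *only* spike emission. The gating/LTP pathway has
no feedback from output spikes, so raising the unblock threshold can only
remove induction events — the accumulated calcium load is provably
non-increasing in `Ca_threshold` at fixed stimulus, which the tests assert.

## Pathology and therapy encoding

Excitotoxicity stages map to the calcium-drive coefficient
{control 9, mild 56.7, moderate 63, advanced 135}; memantine doses map to
the unblock threshold {untreated −68, 3 µM −65, 10 µM −63, 30 µM −55} mV.
A condition config is the base config with exactly these two fields
overridden. The default reproduction grid has seven cells: the four stages
untreated plus the three doses applied to the *moderate* pathological
background — which stage underlies the published therapy rows is not
stated, so moderate (the middle stage) was adopted and is config-exposed;
stage × dose combinations are available via the factorial mode. Dose →
threshold is a fixed lookup; no pharmacokinetics are modelled.

## Stimulation

No stimulation protocol is published for the original experiments, so the
generator here defines this package's study conditions and is first-class,
tested code. The canonical protocol (`default_protocol`) gives every
excitatory input an independent 5 Hz Poisson background plus one mid-run
tetanus of 3 bursts × 10 pulses at 200 Hz (5 ms intra-burst interval,
200 ms between bursts); inhibitory inputs get 2 Hz Poisson. 200 Hz was
chosen because, with the 1 ms delay / 2 ms rise / 13 ms decay EPSP
kinetics, a 100 Hz train leaves only ~8 mV of residual depolarisation at
each pulse arrival — below the −68 mV unblock threshold — so a slower
tetanus cannot induce LTP in this model at all; 200 Hz is within the
standard high-frequency-stimulation range. Events are quantised to the
0.5 ms grid with at most one event per step (collisions merged). One
master seed spawns per-input streams by input index, so adding an input
never perturbs existing ones. Runs are bit-reproducible given
(config, protocol).

What the generator does *not* emulate: naturalistic spike statistics
(burstiness, rate adaptation, correlations between inputs), biological
noise in the membrane, and any receptor kinetics beyond the fixed
waveform. Passing tests therefore demonstrate the internal consistency and
the qualitative pharmacology of the model under these synthetic
conditions, not quantitative agreement with hippocampal recordings.

## Nonlinear-dynamics estimators

All analyses run on the S(i) series, decimated to at most 2000 samples
(every k-th step) for the quadratic-cost estimators; information measures
use the full-resolution series.

* **Delay (τ):** first local minimum of the lagged histogram auto-MI
  (16 bins). Two guards make this well-defined on edge cases: (a) if the
  lag-1 auto-MI is already at the estimator's bias floor
  ((B−1)²/(2N ln 2) bits), the series is treated as uncorrelated and the
  fallback — first 1/e crossing of the autocorrelation — applies, so white
  noise yields τ = 1 instead of a spurious minimum; (b) flat valleys
  (noiseless periodic signals) are widened to a tolerance plateau and
  resolved to the central lag, while valleys that never rise again
  (map-like signals whose AMI decays to a floor) resolve to the first lag
  on the floor.
* **Minimum embedding dimension (m\*):** Kennel false-nearest-neighbour
  test (rtol = 15, atol = 2, threshold 1%), nearest neighbours outside a
  Theiler window (τ) so temporal neighbours don't masquerade as geometric
  ones. Stochastic series that never fall below the threshold are reported
  as m\* = max_m (default 6) with a no-saturation flag. When saturation
  fails at the auto-selected τ, the analysis retries at τ = 1 (the natural
  embedding for maps) and notes the fallback.
* **RQA:** maximum-norm recurrence matrix, Theiler window τ·m (≥1, main
  diagonal always excluded), radius chosen as the distance quantile
  hitting a 5% recurrence rate (fixed-ε mode available). Diagonal lines of
  length ≥ 2; the Shannon line-length entropy (bits) uses only *interior*
  lines — runs truncated by the matrix border are excluded (border-effect
  correction), without which a strictly periodic signal would score
  log₂(number of period offsets) instead of ~0. L_max keeps border lines
  (divergence convention). Degenerate matrices (all/none recurrent) are
  flagged; a constant series reports recurrence rate 1 and entropy 0.
* **Lyapunov exponent:** `direct` is a nearest-neighbour divergence-slope
  estimator (mean log distance of initially neighbouring trajectories vs
  look-ahead, slope fitted over steps 1–6); `rqa_divergence` is the
  1/L_max convention. Both are reported; the Lyapunov time is
  round(1/λ) for λ > 0 and "not estimable" otherwise.
* **Correlation dimension (D2):** Grassberger–Procaccia with maximum norm
  and Theiler exclusion, radii log-spaced between the 0.5% and 60%
  distance quantiles (the lower bound sits above the near-duplicate pair
  scale that trajectory sampling creates), scaling region selected as the
  most linear sliding window of 8 grid points below C = 0.35, preferring
  the smallest radii among near-equally linear windows; a quality warning
  is attached when the best window's R² < 0.98.

Entropy is measured in bits everywhere. Because it is genuinely unclear
whether a published "Shannon entropy" column refers to the RQA
diagonal-line entropy or a binned signal entropy, both are computed and
reported under distinct names (`shannon_rqa_bits`, `h_signal_bits`).

## Information-theoretic estimators

Plug-in (maximum-likelihood) histogram estimators on symbolised series; no
bias correction by default. Potentials are discretised into 4 uniform-width
bins; spike indicators stay native binary. Quantile binning is available
but degenerates on resting-dominated potentials (most samples sit exactly
at ReP, so most quantile edges coincide), which is why uniform bins are
the default for traces. MI is computed as H(x) + H(y) − H(x,y); TE with
target/source history lengths k = l = 1 and a source→target delay of
6 steps (3 ms) — the EPSP peak latency t_sd + t_r, the shortest lag at
which a presynaptic spike can influence S at all (the waveform is
identically zero for the first two steps). Significance uses circular-shift
surrogates of the source (default 100), which destroy the coupling while
preserving both marginals; p = (1 + #{TE_surr ≥ TE})/(1 + n_surr). The
canonical pairing for simulation traces is source = pooled excitatory
spike indicator, target = S(i).

## Statistics and reports

Groups (control / AD stages / memantine doses) are summarised by
unweighted means with t-based 95% CIs, reported as "NE" (not estimable)
when the variance is zero or n < 2. Between-group differences use
Kruskal–Wallis omnibus tests at α = 0.05 with pairwise Mann–Whitney post
hoc tests only after a significant omnibus. Dose–response is the Spearman
(default; Pearson available) correlation of memantine concentration
against a metric, with an exact permutation p-value for n ≤ 10 — note
that with only three dose levels the exact two-sided p for a perfect
monotone trend is 1/3, so small grids can show |R| = 1 with a
non-significant p; published correlation p-values of the order 10⁻³ at
three concentrations imply replicate structure that is not reproduced
here, and this package computes p from its own n. Report tables round
entropies/exponents to 3 decimals and Lyapunov times/spike counts to
integers.

## Problem sizes

Defaults were chosen so the full suite runs comfortably on one CPU: 10 s
simulated time (20 000 steps) for condition runs, 2000-sample decimation
for embedding-based estimators, 5 seeds for the directional comparisons,
5000-point / 10-seed logistic-map runs and 10⁵-sample binary series for
the estimator oracles. These sizes are the package's reproducibility
conventions; all are config-exposed.

## Known limitations

* One postsynaptic unit; no conductances, no compartments, no network.
* Injury is a single scalar excitability loss; no synapse loss, no cell
  death, no recovery dynamics.
* The plug-in TE/MI estimators are positively biased at small sample
  sizes; the surrogate test, not the raw magnitude, carries the evidential
  weight.
* Absolute metric values depend on the (synthetic) stimulation protocol
  and estimator hyperparameters; only within-package comparisons across
  conditions are meaningful.
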