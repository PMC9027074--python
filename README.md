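# nmdasim

A discrete-time simulator of a single glutamatergic postsynaptic unit —
AMPA and NMDA receptors with Mg²⁺-block gating, GABAergic inhibition,
long-term potentiation (LTP) with forgetting — together with "virtual
therapy" machinery for modelling excitotoxic neurodegeneration
(Alzheimer-type stages) and treatment with the noncompetitive NMDA
antagonist memantine, and an analysis suite of nonlinear-dynamics and
information-theory measures for the resulting membrane-potential time
series.

It is aimed at computational neuroscientists who want a small, fully
reproducible in-silico test bed for questions like *how does excitotoxic
calcium overload change the complexity and the directed information flow
of synaptic transmission, and what does raising the NMDA unblock
threshold (a memantine surrogate) restore?*

## Model

**Shift-register synapse.** Each excitatory input owns two registers (AMPA
and NMDA), each inhibitory input a GABA register. A register is a circular
buffer of scheduled future potential deflections; when a presynaptic
action potential arrives, a piecewise-linear postsynaptic waveform

```
SF(t) = 0                                    t ≤ t_sd
        A_MAX/t_r · (t − t_sd)               t_sd < t ≤ t_sd + t_r
        A_MAX/t_d · (t_d − (t − t_r − t_sd)) t_sd + t_r < t ≤ t_sd + t_r + t_d
```

is superposed onto the buffer (AMPA: A_MAX = 5 mV, t_sd = 1 ms, t_r = 2 ms,
t_d = 13 ms; NMDA: 1 mV with the same kinetics; GABA: −2.5 mV, decay
10 ms). One simulation step is 0.5 ms. The summed potential is
S(i) = ReP + Σ current deflections, with resting potential ReP = −80 mV.

**LTP and forgetting.** When a presynaptic spike arrives while
S(i) exceeds the Mg²⁺-unblock threshold CaMT = −68 mV (open NMDA channel),
the synapse's memory counter C grows by the calcium drive
`power = powerA · (S − ReP)` (times dt); otherwise C decays by a
forgetting coefficient. The synaptic weight multiplier is

```
M = 1 + ln(C + 1) / (6 · clog),        clog = 2.3026
```

and scales every subsequent excitatory delivery — a logarithmic,
saturating potentiation with M ∈ [1, ~2].

**Excitotoxicity and virtual memantine.** Alzheimer-stage excitotoxicity
is modelled by raising the calcium-drive gain from powerA = 9 (control) to
powerB ∈ {56.7, 63, 135} (mild / moderate / advanced); accumulated calcium
drive additionally erodes the cell's excitability (rising effective firing
threshold — excitotoxic silencing). Memantine raises the unblock threshold
concentration-dependently: CaMem ∈ {−65, −63, −55} mV for 3 / 10 / 30 µM,
which removes pathological induction events, lowers the calcium load and
thereby protects spiking output.

**Analysis suite.** For each run the package computes: trace metrics
(spike count, LTP = max M, LTP time), delay-embedding parameters
(auto-mutual-information delay, false-nearest-neighbour dimension),
recurrence quantification (recurrence rate, diagonal-line Shannon entropy,
L_max), the maximal Lyapunov exponent (direct divergence-slope estimator
and the 1/L_max recurrence convention) with its Lyapunov time round(1/λ),
the Grassberger–Procaccia correlation dimension D2, and discrete Shannon
entropy / mutual information / bidirectional transfer entropy between the
pooled presynaptic spike train and S(i), with circular-shift surrogate
significance tests.

## Worked example

```python
from nmdasim import (NeuronConfig, condition_config, default_protocol,
                     simulate, PATHOLOGY_INJURY_GAIN)

base = NeuronConfig(duration_ms=10_000, injury_gain=PATHOLOGY_INJURY_GAIN)
protocol = default_protocol(10_000, seed=1)   # 5 Hz background + 200 Hz tetanus
for stage, dose in [("control", "none"), ("advanced", "none"), ("moderate", "10uM")]:
    trace = simulate(condition_config(stage, dose, base), protocol)
    s = trace.summary()
    print(f"{stage:9s} {dose:5s} spikes={s['n_spikes']:3d}  LTP={s['LTP']:.3f}  "
          f"LTP_time={s['LTP_time_ms']:.0f} ms  Ca_load={s['ca_accum']:.0f}")
```

prints

```
control   none  spikes= 58  LTP=1.576  LTP_time=4510 ms  Ca_load=12941
advanced  none  spikes= 25  LTP=1.781  LTP_time=5262 ms  Ca_load=219062
moderate  10uM  spikes= 48  LTP=1.722  LTP_time=5258 ms  Ca_load=96038
```

Advanced excitotoxicity accumulates ~17× the control calcium load and
loses half its spike output to excitotoxic silencing; 10 µM memantine on
the pathological (moderate) background halves the calcium load and largely
restores spiking. `Ca_load` is the accumulated calcium drive (power · dt
summed over induction events), the model's excitotoxic burden.

The same experiment from the shell, over a full stage × dose grid with
group summaries and report tables:

```
nmdasim experiment --seeds 1,2,3 --out-dir results/
nmdasim report --results results/grid_results.csv --out-dir results/
nmdasim simulate --seed 1 --duration 10000 --out-dir results/run1/
nmdasim analyze --input results/run1/trace.csv --out results/run1/nldyn.json
```

All stimulation is synthetic and seeded (`default_protocol` master seed
20220414; per-input streams are spawned deterministically, so runs are
bit-reproducible).

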