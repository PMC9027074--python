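"""Discrete-time shift-register model of one postsynaptic neuron.

Each excitatory input feeds two registers (an AMPA and an NMDA template),
each inhibitory input one GABA register. A register holds the scheduled
future potential deflections of that input; every simulation step (0.5 ms)
all registers shift by one slot and the membrane potential is the resting
potential plus the sum of the current slots. NMDA-dependent plasticity:
when a presynaptic action potential arrives while the summed potential
exceeds the Mg2+-unblock threshold, the calcium drive increments that
synapse's memory counter C, whose logarithmic readout M >= 1 multiplies all
subsequent excitatory deliveries (long-term potentiation); otherwise C
decays geometrically (forgetting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DT_MS,
    STEPS_PER_MS,
    NeuronConfig,
    WaveformParams,
    config_hash,
)

log = logging.getLogger("nmdasim")

__all__ = [
    "waveform_value",
    "waveform_kernel",
    "RegisterBank",
    "SynapseState",
    "memory_multiplier",
    "calcium_power",
    "ltp_step",
    "NeuronTrace",
    "simulate",
]


# ----------------------------------------------------------------------
# synaptic waveform

def waveform_value(params: WaveformParams, t: float) -> float:
    """Deflection (mV) of the EPSP/IPSP template at time ``t`` ms after the
    presynaptic spike.

    Zero up to the synaptic delay, linear rise over ``t_r`` to the peak
    ``a_max``, linear decay over ``t_d`` back to zero, zero afterwards.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if t < 0:
        raise ValueError("t must be >= 0")
    t_sd, t_r, t_d = params.t_sd, params.t_r, params.t_d
    if t <= t_sd:
        return 0.0
    if t <= t_sd + t_r:
        return params.a_max / t_r * (t - t_sd)
    if t <= t_sd + t_r + t_d:
        return params.a_max / t_d * (t_d - (t - (t_r + t_sd)))
    return 0.0


def waveform_kernel(params: WaveformParams) -> np.ndarray:
    """Waveform sampled on the 0.5 ms step grid over its support.

    Length equals ``2 * (t_sd + t_r + t_d)`` steps; entry ``k`` is the
    deflection ``k`` steps after spike arrival.
    """
    n = params.support_steps
    return np.array([waveform_value(params, k * DT_MS) for k in range(n)])


# ----------------------------------------------------------------------
# registers

class RegisterBank:
    """Circular buffers of scheduled deflections, one row per register.

    Excitatory inputs own an AMPA and an NMDA row; inhibitory inputs a GABA
    row. A fresh bank encodes zero deflection, i.e. the membrane sits at
    the resting potential.
    """

    def __init__(self, config: NeuronConfig):
        self.config = config
        self.input_rows: dict[str, list[int]] = {}
        kernels: list[np.ndarray] = []
        for i in range(config.n_excitatory):
            self.input_rows[f"exc{i}"] = [len(kernels), len(kernels) + 1]
            kernels.append(waveform_kernel(config.ampa))
            kernels.append(waveform_kernel(config.nmda))
        for i in range(config.n_inhibitory):
            self.input_rows[f"inh{i}"] = [len(kernels)]
            kernels.append(waveform_kernel(config.gaba))
        self._L = max(len(k) for k in kernels)
        self._kernels = np.zeros((len(kernels), self._L))
        for r, k in enumerate(kernels):
            self._kernels[r, : len(k)] = k
        self._buf = np.zeros_like(self._kernels)
        self._head = 0

    @property
    def input_ids(self) -> list[str]:
        return list(self.input_rows)

    def deliver_spike(self, input_id: str, weight: float = 1.0) -> None:
        """Superpose the (weight-scaled) waveform onto the input's buffers
        starting at the current step."""
        if input_id not in self.input_rows:
            raise KeyError(f"unknown input_id {input_id!r}; known: {self.input_ids}")
        idx = (self._head + np.arange(self._L)) % self._L
        for r in self.input_rows[input_id]:
            self._buf[r, idx] += weight * self._kernels[r]

    def advance_and_sum(self) -> float:
        """Shift every register one step and return the summed potential
        S = ReP + sum of current-slot deflections (mV)."""
        s = self.config.ReP + float(self._buf[:, self._head].sum())
        self._buf[:, self._head] = 0.0
        self._head = (self._head + 1) % self._L
        return s


# ----------------------------------------------------------------------
# plasticity

@dataclass(frozen=True)
class SynapseState:
    """LTP state of one excitatory synapse: memory counter C (step units)
    and the weight multiplier M = 1 + ln(C+1)/(6*clog)."""

    C: float = 0.0
    M: float = 1.0


def memory_multiplier(C: float, clog: float = 2.3026) -> float:
    """Synaptic weight multiplier M = 1 + ln(C + 1) / (6 * clog).

    Strictly increasing and concave in C; M(0) = 1. With clog = 2.3026
    (= ln 10) the multiplier reaches 2 at C = 1e6 - 1.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    return 1.0 + math.log(C + 1.0) / (6.0 * clog)


def calcium_power(M_sf: float, power_coefficient: float, ReP: float) -> float:
    """Calcium drive of the potentiation cascade: power = coeff * (M_sf − ReP).

    ``M_sf`` is the momentary synaptic-function voltage (the summed
    potential in this implementation). Values below the resting potential
    clamp to zero drive.
    """
    if M_sf < ReP:
        log.warning("calcium_power: potential %.3f below ReP %.3f; clamped to 0", M_sf, ReP)
        return 0.0
    return power_coefficient * (M_sf - ReP)


def ltp_step(
    state: SynapseState, S: float, pre_spike: bool, config: NeuronConfig
) -> SynapseState:
    """One plasticity update for one excitatory synapse.

    Induction requires a presynaptic spike while the summed potential
    exceeds the Mg2+-unblock threshold; then C grows by
    ``calcium_power(S) * dt * ltp_gain``. Otherwise C decays by the
    forgetting coefficient. M is recomputed from C either way.
    """
    if pre_spike and S > config.Ca_threshold:
        C = state.C + calcium_power(S, config.power_coefficient, config.ReP) * DT_MS * config.ltp_gain
    else:
        C = state.C * config.forgetting_coefficient
    return SynapseState(C=C, M=memory_multiplier(C, config.clog))


# ----------------------------------------------------------------------
# full simulation

@dataclass
class NeuronTrace:
    """Per-step record of one simulation run plus summary metrics.

    S is the summed membrane potential (mV), ``spikes`` the output spike
    flags; C and M are (n_excitatory, n_steps) plasticity trajectories.
    ``ca_accum`` is the total accumulated calcium drive (power * dt summed
    over induction events) — the excitotoxic load of the run.
    """

    S: np.ndarray
    spikes: np.ndarray
    C: np.ndarray
    M: np.ndarray
    config: NeuronConfig
    config_hash: str
    n_spikes: int = 0
    LTP: float = 1.0
    LTP_time_ms: float = 0.0
    ca_accum: float = 0.0

    def summary(self) -> dict:
        return {
            "n_spikes": self.n_spikes,
            "LTP": self.LTP,
            "LTP_time_ms": self.LTP_time_ms,
            "ca_accum": self.ca_accum,
        }

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.S)
        data: dict = {
            "step": np.arange(n),
            "time_ms": np.arange(n) * DT_MS,
            "S_mV": self.S,
            "spike": self.spikes.astype(int),
        }
        for j in range(self.C.shape[0]):
            data[f"C_exc{j}"] = self.C[j]
            data[f"M_exc{j}"] = self.M[j]
        return pd.DataFrame(data)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(config: NeuronConfig, stimulus) -> NeuronTrace:
    """Run the shift-register neuron for ``config.duration_ms``.

    ``stimulus`` maps input ids (``exc0..``, ``inh0..``) to spike trains
    (objects with integer ``steps``, or arrays of step indices). Inputs
    without a train stay silent. The run is fully deterministic given
    (config, stimulus).

    Output spikes fire when S reaches the effective firing threshold
    outside the refractory period. The effective threshold is the
    configured one plus ``injury_gain * accumulated calcium drive``,
    modelling excitotoxic excitability loss; with the default
    ``injury_gain = 0`` it is constant.
    """
    n_steps = config.duration_steps
    if n_steps <= 0:
        raise ValueError("empty duration")

    bank = RegisterBank(config)
    exc_ids = [f"exc{i}" for i in range(config.n_excitatory)]
    inh_ids = [f"inh{i}" for i in range(config.n_inhibitory)]

    trains = getattr(stimulus, "trains", stimulus)
    spike_in = {iid: np.zeros(n_steps, dtype=bool) for iid in exc_ids + inh_ids}
    for iid, train in trains.items():
        if iid not in spike_in:
            raise KeyError(f"unknown input_id {iid!r}; known: {exc_ids + inh_ids}")
        steps = np.asarray(getattr(train, "steps", train), dtype=int)
        if steps.size and (steps.min() < 0 or steps.max() >= n_steps):
            raise ValueError(f"stimulus events for {iid!r} outside [0, {n_steps})")
        spike_in[iid][steps] = True

    S = np.empty(n_steps)
    out_spikes = np.zeros(n_steps, dtype=bool)
    C = np.empty((config.n_excitatory, n_steps))
    M = np.empty((config.n_excitatory, n_steps))
    states = [SynapseState() for _ in exc_ids]

    refractory = 0
    ca_accum = 0.0
    n_spikes = 0
    exc_spikes = [spike_in[i] for i in exc_ids]
    inh_spikes = [spike_in[i] for i in inh_ids]

    for i in range(n_steps):
        for j, iid in enumerate(exc_ids):
            if exc_spikes[j][i]:
                bank.deliver_spike(iid, weight=states[j].M)
        for j, iid in enumerate(inh_ids):
            if inh_spikes[j][i]:
                bank.deliver_spike(iid, weight=1.0)

        s = bank.advance_and_sum()
        S[i] = s

        for j in range(config.n_excitatory):
            prev_C = states[j].C
            states[j] = ltp_step(states[j], s, bool(exc_spikes[j][i]), config)
            if states[j].C > prev_C:
                # increment equals power*dt*gain; track raw power*dt as Ca load
                ca_accum += (states[j].C - prev_C) / max(config.ltp_gain, 1e-300)
            C[j, i] = states[j].C
            M[j, i] = states[j].M

        threshold_eff = config.firing_threshold + config.injury_gain * ca_accum
        if refractory > 0:
            refractory -= 1
        elif s >= threshold_eff:
            out_spikes[i] = True
            n_spikes += 1
            refractory = config.refractory_steps

    max_M = M.max(axis=0) if config.n_excitatory else np.ones(n_steps)
    trace = NeuronTrace(
        S=S,
        spikes=out_spikes,
        C=C,
        M=M,
        config=config,
        config_hash=config_hash(config),
        n_spikes=n_spikes,
        LTP=float(M.max()) if M.size else 1.0,
        LTP_time_ms=float(np.count_nonzero(max_M >= 1.0 + config.ltp_margin)) * DT_MS,
        ca_accum=ca_accum,
    )
    log.info(
        "simulate: seed=%s hash=%s %s", config.seed, trace.config_hash, trace.summary()
    )
    return trace
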