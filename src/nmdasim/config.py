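"""Configuration objects shared across the simulator and the analysis suite.

Times are stored in milliseconds at the interface and as integer half-
millisecond steps internally (2 steps per ms). Voltages are millivolts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

log = logging.getLogger("nmdasim")

#: simulation step resolution: 1 ms = 2 steps
STEPS_PER_MS: int = 2
DT_MS: float = 1.0 / STEPS_PER_MS

RECEPTORS = ("AMPA", "NMDA", "GABA")


@dataclass(frozen=True)
class WaveformParams:
    """Piecewise-linear EPSP/IPSP template parameters.

    a_max : peak deflection in mV (positive for AMPA/NMDA, negative for GABA)
    t_sd  : synaptic delay in ms
    t_r   : rise time in ms
    t_d   : decay time in ms
    """

    a_max: float
    t_sd: float
    t_r: float
    t_d: float
    receptor: str

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"receptor must be one of {RECEPTORS}, got {self.receptor!r}")
        if not (self.t_sd >= 0 and self.t_r > 0 and self.t_d > 0):
            raise ValueError("require t_sd >= 0, t_r > 0, t_d > 0")
        if self.receptor in ("AMPA", "NMDA") and not self.a_max > 0:
            raise ValueError(f"{self.receptor} waveform needs a_max > 0")
        if self.receptor == "GABA" and not self.a_max < 0:
            raise ValueError("GABA waveform needs a_max < 0")

    @property
    def support_ms(self) -> float:
        """Total support of the waveform: t_sd + t_r + t_d."""
        return self.t_sd + self.t_r + self.t_d

    @property
    def support_steps(self) -> int:
        return int(round(STEPS_PER_MS * self.support_ms))


AMPA_DEFAULT = WaveformParams(5.0, 1.0, 2.0, 13.0, "AMPA")
NMDA_DEFAULT = WaveformParams(1.0, 1.0, 2.0, 13.0, "NMDA")
GABA_DEFAULT = WaveformParams(-2.5, 1.0, 2.0, 10.0, "GABA")


@dataclass(frozen=True)
class NeuronConfig:
    """All constants of the single-neuron shift-register model.

    ReP                   : resting potential (mV)
    Ca_threshold          : Mg2+-unblock threshold for the NMDA channel (mV);
                            −68 in the control condition, raised under memantine
    power_coefficient     : gain of the calcium drive for LTP induction
                            (9 in control, 56.7/63/135 for excitotoxic stages)
    clog                  : logarithm constant of the weight multiplier
    firing_threshold      : output spike threshold (mV)
    refractory_ms         : absolute refractory period (ms)
    forgetting_coefficient: per-step multiplicative decay of the LTP memory C
    ltp_gain              : scale of the C increment per induction event
                            (increment = calcium_power * dt * ltp_gain)
    ltp_margin            : M >= 1 + ltp_margin counts toward LTP time
    injury_gain           : excitotoxic excitability loss — mV added to the
                            firing threshold per unit of accumulated calcium
                            drive; 0 disables the mechanism
    duration_ms           : simulated time
    n_excitatory          : number of AMPA+NMDA input pairs
    n_inhibitory          : number of GABA inputs
    seed                  : master seed recorded with every trace
    """

    ReP: float = -80.0
    Ca_threshold: float = -68.0
    power_coefficient: float = 9.0
    clog: float = 2.3026
    firing_threshold: float = -55.0
    refractory_ms: float = 2.0
    forgetting_coefficient: float = 0.999
    ltp_gain: float = 1.0
    ltp_margin: float = 0.05
    injury_gain: float = 0.0
    duration_ms: float = 10_000.0
    n_excitatory: int = 3
    n_inhibitory: int = 1
    seed: int = 0
    ampa: WaveformParams = AMPA_DEFAULT
    nmda: WaveformParams = NMDA_DEFAULT
    gaba: WaveformParams = GABA_DEFAULT

    def __post_init__(self) -> None:
        if not self.clog > 0:
            raise ValueError("clog must be > 0")
        if not self.ReP < self.firing_threshold:
            raise ValueError("require ReP < firing_threshold")
        if not (0 < self.forgetting_coefficient <= 1):
            raise ValueError("forgetting_coefficient must lie in (0, 1]")
        if self.n_excitatory < 1 or self.n_inhibitory < 0:
            raise ValueError("need >= 1 excitatory and >= 0 inhibitory inputs")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be positive")
        if self.refractory_ms < 0 or self.injury_gain < 0 or self.ltp_gain < 0:
            raise ValueError("refractory_ms, injury_gain and ltp_gain must be >= 0")

    @property
    def duration_steps(self) -> int:
        return int(round(self.duration_ms * STEPS_PER_MS))

    @property
    def refractory_steps(self) -> int:
        return int(round(self.refractory_ms * STEPS_PER_MS))

    def replace(self, **kwargs: Any) -> "NeuronConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class AnalysisParams:
    """Hyperparameters of the nonlinear-dynamics and information estimators.

    tau / m / theiler default to None = choose automatically (auto-MI delay,
    false-nearest-neighbour dimension, theiler = tau * m). The recurrence
    radius is picked to hit ``rr_target`` unless ``eps`` is given. Potentials
    are discretised into ``n_bins`` uniform-width bins for the discrete
    information estimators (quantile binning, also available, degenerates
    on resting-dominated potentials where most samples coincide at ReP);
    spike indicators stay binary. ``delay`` is the source→target latency
    of the transfer-entropy pairing; the default of 6 steps (3 ms) is the
    EPSP peak latency t_sd + t_r of the synaptic waveform — at shorter
    lags the waveform has not risen yet and no coupling is measurable.
    """

    tau: int | None = None
    m: int | None = None
    theiler: int | None = None
    rr_target: float = 0.05
    eps: float | None = None
    l_min: int = 2
    max_tau: int = 50
    max_m: int = 6
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    fnn_threshold: float = 0.01
    n_bins: int = 4
    bin_strategy: str = "uniform"
    k: int = 1
    l: int = 1
    delay: int = 6
    n_surrogates: int = 100
    decimate_to: int = 2000

    def replace(self, **kwargs: Any) -> "AnalysisParams":
        return dataclasses.replace(self, **kwargs)


# ----------------------------------------------------------------------
# serialisation helpers

def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    return obj


def config_to_dict(config: Any) -> dict:
    """Flatten a config dataclass into plain YAML/JSON-serialisable types."""
    return _to_plain(config)


def config_hash(config: Any) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode("utf-8")).hexdigest()[:12]


def neuron_config_from_dict(d: dict) -> NeuronConfig:
    d = dict(d)
    for key, recc in (("ampa", "AMPA"), ("nmda", "NMDA"), ("gaba", "GABA")):
        if key in d and isinstance(d[key], dict):
            wf = dict(d[key])
            wf.setdefault("receptor", recc)
            d[key] = WaveformParams(**wf)
    return NeuronConfig(**d)


def load_config(path: str) -> dict:
    """Read a YAML config file with optional ``neuron`` / ``analysis`` /
    ``stimulus`` / ``grid`` sections into the corresponding objects."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {"raw": raw}
    out["neuron"] = neuron_config_from_dict(raw.get("neuron", {}))
    out["analysis"] = AnalysisParams(**raw.get("analysis", {}))
    out["stimulus"] = dict(raw.get("stimulus", {}))
    out["grid"] = dict(raw.get("grid", {}))
    return out


def dump_config(config: Any, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
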