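"""Synthetic presynaptic spike-train generation.

All trains are quantised to the 0.5 ms step grid with at most one event per
step. Seeding uses one master seed from which per-input streams are spawned
deterministically, so adding an input never perturbs the others.

The canonical stimulation protocol of this package (``default_protocol``)
is: per excitatory input, 5 Hz Poisson background plus one mid-run tetanus
(3 bursts of 10 pulses at 100 Hz, 200 ms between bursts); inhibitory inputs
receive 2 Hz Poisson background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DT_MS, STEPS_PER_MS

log = logging.getLogger("nmdasim")

__all__ = [
    "SpikeTrain",
    "Protocol",
    "poisson_train",
    "periodic_train",
    "tetanus_protocol",
    "merge_trains",
    "default_protocol",
    "DEFAULT_PROTOCOL_SEED",
]

#: master seed of the canonical protocol (documented in the README)
DEFAULT_PROTOCOL_SEED = 20220414


@dataclass(frozen=True)
class SpikeTrain:
    """Event times of one synaptic input, as integer step indices."""

    input_id: str
    steps: np.ndarray
    duration_steps: int

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=int)
        object.__setattr__(self, "steps", steps)
        if steps.size:
            if np.any(np.diff(steps) <= 0):
                raise ValueError("spike steps must be strictly increasing and unique")
            if steps.min() < 0 or steps.max() >= self.duration_steps:
                raise ValueError("spike steps must lie in [0, duration)")

    @property
    def times_ms(self) -> np.ndarray:
        return self.steps * DT_MS

    def __len__(self) -> int:
        return int(self.steps.size)


@dataclass(frozen=True)
class Protocol:
    """A full stimulation protocol: one spike train per input."""

    trains: dict
    duration_ms: float
    seed: int | None = None
    description: str = ""

    def pooled_excitatory_indicator(self, n_steps: int | None = None) -> np.ndarray:
        """Binary per-step indicator of any excitatory presynaptic spike
        (the source series of the information-flow analysis)."""
        n = n_steps or int(round(self.duration_ms * STEPS_PER_MS))
        ind = np.zeros(n, dtype=int)
        for iid, tr in self.trains.items():
            if iid.startswith("exc"):
                ind[tr.steps] = 1
        return ind

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (iid, t)
            for iid, tr in sorted(self.trains.items())
            for t in tr.times_ms
        ]
        return pd.DataFrame(rows, columns=["input_id", "time_ms"])

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _quantize(times_ms: np.ndarray, duration_ms: float, input_id: str) -> np.ndarray:
    steps = np.floor(np.asarray(times_ms) * STEPS_PER_MS).astype(int)
    steps = steps[(steps >= 0) & (steps < int(round(duration_ms * STEPS_PER_MS)))]
    uniq = np.unique(steps)
    if uniq.size < steps.size:
        log.debug(
            "stimulus %s: dropped %d step-collision events", input_id, steps.size - uniq.size
        )
    return uniq


def poisson_train(
    rate_hz: float, duration_ms: float, seed, input_id: str = "exc0"
) -> SpikeTrain:
    """Homogeneous Poisson train quantised to 0.5 ms steps.

    Colliding events (same step) are merged, so the realised rate is
    marginally below nominal at high rates.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n_steps = int(round(duration_ms * STEPS_PER_MS))
    if rate_hz == 0:
        return SpikeTrain(input_id, np.empty(0, dtype=int), n_steps)
    rng = np.random.default_rng(seed)
    mean_gap_ms = 1000.0 / rate_hz
    # draw enough exponential gaps to cover the run, extend if short
    n_draw = max(16, int(1.5 * duration_ms / mean_gap_ms) + 10)
    times = np.cumsum(rng.exponential(mean_gap_ms, size=n_draw))
    while times.size and times[-1] < duration_ms:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.exponential(mean_gap_ms, size=n_draw))]
        )
    return SpikeTrain(input_id, _quantize(times[times < duration_ms], duration_ms, input_id), n_steps)


def periodic_train(
    interval_ms: float, duration_ms: float, onset_ms: float = 0.0, input_id: str = "exc0"
) -> SpikeTrain:
    """Regular train with fixed inter-spike interval."""
    if interval_ms <= 0:
        raise ValueError("interval must be positive")
    n_steps = int(round(duration_ms * STEPS_PER_MS))
    times = np.arange(onset_ms, duration_ms, interval_ms)
    return SpikeTrain(input_id, _quantize(times, duration_ms, input_id), n_steps)


def tetanus_protocol(
    bursts: int,
    pulses: int,
    intra_ms: float,
    gap_ms: float,
    onset_ms: float = 0.0,
    duration_ms: float | None = None,
    input_id: str = "exc0",
) -> SpikeTrain:
    """Deterministic tetanic burst train: ``bursts`` bursts of ``pulses``
    pulses at intra-burst interval ``intra_ms``, separated by ``gap_ms``
    (last-pulse to first-pulse), starting at ``onset_ms``.
    """
    if bursts < 1 or pulses < 1:
        raise ValueError("bursts and pulses must be >= 1")
    if intra_ms <= 0:
        raise ValueError("intra_ms must be positive")
    if bursts > 1 and gap_ms <= 0:
        raise ValueError("bursts overlap: gap_ms must be positive")
    burst_span = (pulses - 1) * intra_ms
    starts = onset_ms + np.arange(bursts) * (burst_span + gap_ms)
    times = (starts[:, None] + np.arange(pulses) * intra_ms).ravel()
    if duration_ms is None:
        duration_ms = times[-1] + 1.0
    if times[-1] >= duration_ms:
        raise ValueError("tetanus extends past the protocol duration")
    n_steps = int(round(duration_ms * STEPS_PER_MS))
    return SpikeTrain(input_id, _quantize(times, duration_ms, input_id), n_steps)


def merge_trains(*trains: SpikeTrain) -> SpikeTrain:
    """Union of several trains on the same input (collisions merged)."""
    if not trains:
        raise ValueError("need at least one train")
    n_steps = max(t.duration_steps for t in trains)
    steps = np.unique(np.concatenate([t.steps for t in trains]))
    return SpikeTrain(trains[0].input_id, steps, n_steps)


def _child_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def default_protocol(
    duration_ms: float,
    n_excitatory: int = 3,
    n_inhibitory: int = 1,
    seed: int = DEFAULT_PROTOCOL_SEED,
) -> Protocol:
    """Canonical protocol: excitatory 5 Hz Poisson background + one mid-run
    tetanus (3 x 10 pulses at 100 Hz, 200 ms inter-burst gap) on every
    excitatory input; inhibitory 2 Hz Poisson.

    The stimulation parameters are this package's convention; they are not
    taken from any published protocol.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    trains: dict[str, SpikeTrain] = {}
    tet_span = 2 * (9 * 5.0 + 200.0) + 9 * 5.0  # 3 bursts of 10 @ 200 Hz, 200 ms gaps
    onset = max(0.0, duration_ms / 2.0 - tet_span / 2.0)
    for i in range(n_excitatory):
        iid = f"exc{i}"
        background = poisson_train(5.0, duration_ms, _child_seed(seed, i), iid)
        if onset + tet_span < duration_ms:
            tet = tetanus_protocol(
                3, 10, 5.0, 200.0, onset_ms=onset, duration_ms=duration_ms, input_id=iid
            )
            trains[iid] = merge_trains(background, tet)
        else:
            trains[iid] = background
    for i in range(n_inhibitory):
        iid = f"inh{i}"
        trains[iid] = poisson_train(2.0, duration_ms, _child_seed(seed, 1000 + i), iid)
    return Protocol(
        trains=trains,
        duration_ms=duration_ms,
        seed=seed,
        description="5 Hz Poisson background + mid-run tetanus (3x10 @ 100 Hz); GABA 2 Hz",
    )
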