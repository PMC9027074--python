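"""Excitotoxicity stages, virtual memantine doses, and the condition grid.

Alzheimer-type excitotoxicity is modelled by raising the calcium-drive
coefficient (9 in control up to 135 in the advanced stage); memantine by
raising the Mg2+-unblock threshold of the NMDA channel in a
concentration-dependent way (−68 mV untreated up to −55 mV at 30 µM).
Grid runs additionally enable the excitotoxic-injury mechanism (calcium
load raises the effective firing threshold), so that pathological calcium
overload depresses spike output as excitotoxic silencing does in vivo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import STEPS_PER_MS, AnalysisParams, NeuronConfig, config_hash
from .infotheory import SymbolSeries, as_symbols, discretize, info_summary, shannon_entropy
from .nldyn import analyze_series
from .stimulus import default_protocol
from .synapse import simulate

log = logging.getLogger("nmdasim")

__all__ = [
    "AD_STAGES",
    "MEMANTINE_DOSES",
    "DOSE_CONCENTRATION_UM",
    "GROUP_LABELS",
    "PATHOLOGY_INJURY_GAIN",
    "condition_config",
    "ConditionResult",
    "run_condition",
    "run_grid",
    "table1_cells",
]

#: excitotoxicity stage -> calcium-drive coefficient (powerA/powerB)
AD_STAGES: dict[str, float] = {
    "control": 9.0,
    "mild": 56.7,
    "moderate": 63.0,
    "advanced": 135.0,
}

#: memantine dose -> Mg2+-unblock threshold CaMem (mV); "none" keeps CaMT
MEMANTINE_DOSES: dict[str, float] = {
    "none": -68.0,
    "3uM": -65.0,
    "10uM": -63.0,
    "30uM": -55.0,
}

#: numeric concentration for dose–response analyses
DOSE_CONCENTRATION_UM: dict[str, float] = {"none": 0.0, "3uM": 3.0, "10uM": 10.0, "30uM": 30.0}

GROUP_LABELS = {
    "control": "Control model",
    "ad": "AD model",
    "memantine": "Memantine treatment model",
}

#: default excitotoxic-injury gain of grid runs: mV of firing-threshold
#: shift per unit of accumulated calcium drive (power * dt). Sized so the
#: control-stage load of the canonical 10 s protocol shifts the threshold
#: by only a few mV while the advanced stage (15x the drive gain) largely
#: silences the cell.
PATHOLOGY_INJURY_GAIN: float = 2.5e-4

#: stage underlying the therapy conditions (the paper applies memantine to
#: the pathological model; which stage is unstated — moderate adopted)
DEFAULT_THERAPY_STAGE = "moderate"


def _check_label(label: str, table: dict[str, float], kind: str) -> float:
    try:
        return table[label]
    except KeyError:
        raise ValueError(
            f"unknown {kind} label {label!r}; valid: {sorted(table)}"
        ) from None


def condition_config(stage: str, dose: str, base: NeuronConfig) -> NeuronConfig:
    """Return ``base`` with the stage's power coefficient and the dose's
    unblock threshold applied; everything else untouched."""
    power = _check_label(stage, AD_STAGES, "AD stage")
    threshold = _check_label(dose, MEMANTINE_DOSES, "memantine dose")
    return base.replace(power_coefficient=power, Ca_threshold=threshold)


def _group_of(stage: str, dose: str) -> str:
    if dose != "none":
        return GROUP_LABELS["memantine"]
    if stage == "control":
        return GROUP_LABELS["control"]
    return GROUP_LABELS["ad"]


@dataclass
class ConditionResult:
    """One (stage, dose, seed) cell of the condition grid."""

    stage: str
    dose: str
    seed: int
    config_hash: str
    metrics: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def group(self) -> str:
        return _group_of(self.stage, self.dose)

    @property
    def condition(self) -> str:
        return self.stage if self.dose == "none" else f"{self.stage}+{self.dose}"

    def to_row(self) -> dict:
        row = {
            "condition": self.condition,
            "group": self.group,
            "stage": self.stage,
            "dose": self.dose,
            "concentration_uM": DOSE_CONCENTRATION_UM[self.dose],
            "seed": self.seed,
            "config_hash": self.config_hash,
            "error": self.error or "",
        }
        row.update(self.metrics)
        return row


def _analyze_trace(trace, protocol, analyses, params: AnalysisParams, seed: int) -> dict:
    metrics: dict = dict(trace.summary())
    n_steps = len(trace.S)

    if "info" in analyses:
        source = as_symbols(protocol.pooled_excitatory_indicator(n_steps))
        if np.ptp(trace.S) == 0:
            target = SymbolSeries(np.zeros(n_steps, dtype=int), 1, "constant")
            metrics.update(
                h_signal_bits=0.0, mi_bits=0.0,
                te_in_to_s_bits=0.0, te_s_to_in_bits=0.0,
                p_te_in_to_s=None, p_te_s_to_in=None,
            )
        else:
            target = discretize(trace.S, params.n_bins, params.bin_strategy)
            info = info_summary(source, target, params, seed=seed)
            metrics.update(
                h_signal_bits=info.h_target_bits,
                mi_bits=info.mi_bits,
                te_in_to_s_bits=info.te_source_to_target_bits,
                te_s_to_in_bits=info.te_target_to_source_bits,
                p_te_in_to_s=info.p_te_source_to_target,
                p_te_s_to_in=info.p_te_target_to_source,
            )

    if "nldyn" in analyses:
        x = trace.S
        if len(x) > params.decimate_to:
            step = int(np.ceil(len(x) / params.decimate_to))
            x = x[::step]
        nl = analyze_series(x, params)
        metrics.update(
            tau=nl.tau,
            m_star=nl.m_star,
            d2=nl.d2,
            recurrence_rate=nl.recurrence_rate,
            shannon_rqa_bits=nl.shannon_rqa_bits,
            lyap_direct=nl.lyap_direct,
            lyap_rqa=nl.lyap_rqa,
            lyap_time=nl.lyap_time,
        )
    return metrics


def run_condition(
    config: NeuronConfig,
    seeds: list[int],
    stage: str = "control",
    dose: str = "none",
    protocol_factory=default_protocol,
    analyses: tuple[str, ...] = ("info", "nldyn"),
    analysis_params: AnalysisParams | None = None,
) -> list[ConditionResult]:
    """Simulate and analyse one condition once per seed.

    Per-seed failures are recorded in the result's ``error`` field and do
    not abort the remaining seeds. Trace metrics are always computed;
    ``analyses`` selects the optional information-theoretic and
    nonlinear-dynamics blocks.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    params = analysis_params or AnalysisParams()
    chash = config_hash(config)
    results = []
    for seed in seeds:
        try:
            protocol = protocol_factory(
                duration_ms=config.duration_ms,
                n_excitatory=config.n_excitatory,
                n_inhibitory=config.n_inhibitory,
                seed=seed,
            )
            trace = simulate(config.replace(seed=seed), protocol)
            metrics = _analyze_trace(trace, protocol, analyses, params, seed)
            results.append(ConditionResult(stage, dose, seed, chash, metrics))
        except Exception as exc:  # grid keeps going; failure is data
            log.exception("condition (%s, %s) seed %s failed", stage, dose, seed)
            results.append(ConditionResult(stage, dose, seed, chash, {}, str(exc)))
    return results


def table1_cells(
    stages=("control", "mild", "moderate", "advanced"),
    doses=("3uM", "10uM", "30uM"),
    therapy_stage: str = DEFAULT_THERAPY_STAGE,
) -> list[tuple[str, str]]:
    """The default reproduction grid: every stage untreated, plus the
    memantine doses applied to the pathological (therapy-stage) model.
    AD stages never combine with doses here; use ``run_grid(...,
    factorial=True)`` for combined cells."""
    cells = [(s, "none") for s in stages]
    cells += [(therapy_stage, d) for d in doses if d != "none"]
    return cells


def run_grid(
    stages=("control", "mild", "moderate", "advanced"),
    doses=("3uM", "10uM", "30uM"),
    seeds: list[int] = (1, 2, 3),
    base: NeuronConfig | None = None,
    protocol_factory=default_protocol,
    analyses: tuple[str, ...] = ("info", "nldyn"),
    analysis_params: AnalysisParams | None = None,
    therapy_stage: str = DEFAULT_THERAPY_STAGE,
    factorial: bool = False,
) -> pd.DataFrame:
    """Run the full condition grid and return one row per (cell, seed).

    The default base configuration enables the excitotoxic-injury
    mechanism (``PATHOLOGY_INJURY_GAIN``) for every cell, control
    included, so cells differ only through stage and dose.
    """
    if not stages and not doses:
        raise ValueError("stage and dose lists are both empty")
    if base is None:
        base = NeuronConfig(injury_gain=PATHOLOGY_INJURY_GAIN)
    if factorial:
        cells = [(s, d) for s in stages for d in (list(doses) or ["none"])]
    else:
        cells = table1_cells(stages, doses, therapy_stage)

    rows = []
    for stage, dose in cells:
        cfg = condition_config(stage, dose, base)
        for res in run_condition(
            cfg, list(seeds), stage, dose, protocol_factory, analyses, analysis_params
        ):
            rows.append(res.to_row())
    df = pd.DataFrame(rows)
    log.info("run_grid: %d cells x %d seeds -> %d rows", len(cells), len(seeds), len(df))
    return df
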