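"""Discrete Shannon entropy, mutual information and transfer entropy.

Plug-in (maximum-likelihood histogram) estimators over symbolised series,
in bits. Transfer entropy uses target history length k, source history
length l and a source-target delay, with circular-shift surrogates of the
source for significance testing. The canonical pairing for simulation
traces is: source = pooled excitatory presynaptic spike indicator,
target = discretised postsynaptic potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisParams

log = logging.getLogger("nmdasim")

__all__ = [
    "SymbolSeries",
    "discretize",
    "as_symbols",
    "shannon_entropy",
    "mutual_information",
    "transfer_entropy",
    "transfer_entropy_conditional",
    "InfoResult",
    "info_summary",
]


@dataclass(frozen=True)
class SymbolSeries:
    """Integer symbols in [0, alphabet) with their provenance."""

    symbols: np.ndarray
    alphabet: int
    provenance: str = ""
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=int)
        object.__setattr__(self, "symbols", s)
        if s.size and (s.min() < 0 or s.max() >= self.alphabet):
            raise ValueError("symbols must lie in [0, alphabet)")

    def __len__(self) -> int:
        return int(self.symbols.size)


def discretize(series: np.ndarray, n_bins: int, strategy: str = "quantile") -> SymbolSeries:
    """Bin a real-valued series into ``n_bins`` symbols.

    ``uniform``: equal-width bins over [min, max]; ``quantile``: equal-mass
    bins (rejected for constant input). Bin edges are recorded.
    """
    x = np.asarray(series, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size == 0:
        raise ValueError("empty series")
    if strategy == "uniform":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    elif strategy == "quantile":
        if np.ptp(x) == 0:
            raise ValueError("constant series cannot be quantile-binned")
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 3:
            raise ValueError("series too degenerate for quantile binning")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    sym = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    return SymbolSeries(sym, int(len(edges) - 1), f"{strategy}:{n_bins}", edges)


def as_symbols(x) -> SymbolSeries:
    """Pass an already-discrete series (e.g. a binary spike indicator)
    through as symbols."""
    if isinstance(x, SymbolSeries):
        return x
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer) and not arr.dtype == bool:
        raise TypeError("as_symbols expects integer/boolean input; use discretize()")
    arr = arr.astype(int)
    return SymbolSeries(arr, int(arr.max()) + 1 if arr.size else 1, "native")


def _entropy_bits(columns: list[np.ndarray]) -> float:
    """Joint plug-in entropy of aligned integer columns."""
    code = np.zeros(len(columns[0]), dtype=np.int64)
    for col in columns:
        col = np.asarray(col)
        code = code * (int(col.max()) + 1) + col
    counts = np.bincount(code if code.min() >= 0 else code - code.min())
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def shannon_entropy(x: SymbolSeries) -> float:
    """Plug-in Shannon entropy (bits) of the empirical symbol frequencies."""
    if len(x) == 0:
        raise ValueError("empty series")
    return _entropy_bits([x.symbols])


def mutual_information(x: SymbolSeries, y: SymbolSeries, lag: int = 0) -> float:
    """MI(x; y shifted by ``lag``) = H(x) + H(y) − H(x, y), in bits.

    Positive lag pairs x[t] with y[t+lag]. Symmetric in (x, y) at lag 0.
    """
    xs, ys = x.symbols, y.symbols
    if lag > 0:
        xs, ys = xs[:-lag], ys[lag:]
    elif lag < 0:
        xs, ys = xs[-lag:], ys[:lag]
    if len(xs) != len(ys):
        raise ValueError("length mismatch after lag alignment")
    if len(xs) == 0:
        raise ValueError("no overlapping samples at this lag")
    return _entropy_bits([xs]) + _entropy_bits([ys]) - _entropy_bits([xs, ys])


def _te_blocks(
    source: np.ndarray, target: np.ndarray, k: int, l: int, delay: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aligned (future, target-past, source-past) blocks; pasts encoded as
    single integers per step."""
    n = len(target)
    start = max(k, l + delay - 1)
    t_idx = np.arange(start, n)
    fut = target[t_idx]
    tp = np.stack([target[t_idx - j] for j in range(1, k + 1)], axis=1)
    sp = np.stack([source[t_idx - delay - j] for j in range(0, l)], axis=1)

    def enc(block: np.ndarray) -> np.ndarray:
        out = np.zeros(len(block), dtype=np.int64)
        for c in range(block.shape[1]):
            out = out * (block[:, c].max() + 1 if block.size else 1) + block[:, c]
        return out

    return fut, enc(tp), enc(sp)


def _te_from_blocks(fut, tp, sp) -> float:
    """TE via the four-term joint-entropy combination."""
    return (
        _entropy_bits([fut, tp]) + _entropy_bits([tp, sp])
        - _entropy_bits([tp]) - _entropy_bits([fut, tp, sp])
    )


def transfer_entropy_conditional(
    source: SymbolSeries, target: SymbolSeries, k: int = 1, l: int = 1, delay: int = 1
) -> float:
    """TE as a difference of conditional entropies,
    H(future | target past) − H(future | target past, source past) —
    an algebraically independent route used as a cross-check of the
    joint-entropy form."""
    fut, tp, sp = _te_blocks(source.symbols, target.symbols, k, l, delay)
    h_f_given_tp = _entropy_bits([fut, tp]) - _entropy_bits([tp])
    h_f_given_tp_sp = _entropy_bits([fut, tp, sp]) - _entropy_bits([tp, sp])
    return h_f_given_tp - h_f_given_tp_sp


def transfer_entropy(
    source: SymbolSeries,
    target: SymbolSeries,
    k: int = 1,
    l: int = 1,
    delay: int = 1,
    n_surrogates: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Transfer entropy source → target in bits, with an optional
    circular-shift surrogate p-value.

    ``k``/``l`` are the target/source history lengths, ``delay`` the
    source-target latency in steps. Surrogate sources are full circular
    shifts of the original (coupling destroyed, marginals and
    autocorrelation preserved); p = (1 + #{TE_surr >= TE}) / (1 + n).
    """
    if k < 1 or l < 1 or delay < 0:
        raise ValueError("require k >= 1, l >= 1, delay >= 0")
    if len(source) != len(target):
        raise ValueError("source and target must have equal length")
    xs, ys = source.symbols, target.symbols
    n = len(ys)
    if n <= max(k, l + delay) + 1:
        raise ValueError("series too short for the requested histories")

    n_states = (
        source.alphabet**l * target.alphabet ** (k + 1)
    )
    if n_states > n / 10:
        log.warning(
            "transfer_entropy: %d joint states for %d samples — plug-in estimate "
            "is positively biased", n_states, n,
        )

    fut, tp, sp = _te_blocks(xs, ys, k, l, delay)
    te = _te_from_blocks(fut, tp, sp)

    p_value = None
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        shifts = rng.integers(1, n, size=n_surrogates)
        exceed = 0
        for s in shifts:
            xs_s = np.roll(xs, int(s))
            f2, tp2, sp2 = _te_blocks(xs_s, ys, k, l, delay)
            if _te_from_blocks(f2, tp2, sp2) >= te:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_surrogates)
    return float(te), p_value


@dataclass
class InfoResult:
    """Information-theoretic summary of one source/target pair."""

    h_source_bits: float
    h_target_bits: float
    mi_bits: float
    te_source_to_target_bits: float
    te_target_to_source_bits: float
    p_te_source_to_target: float | None
    p_te_target_to_source: float | None
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "h_source_bits": self.h_source_bits,
            "h_target_bits": self.h_target_bits,
            "mi_bits": self.mi_bits,
            "te_source_to_target_bits": self.te_source_to_target_bits,
            "te_target_to_source_bits": self.te_target_to_source_bits,
            "p_te_source_to_target": self.p_te_source_to_target,
            "p_te_target_to_source": self.p_te_target_to_source,
            "settings": self.settings,
        }


def info_summary(
    source: SymbolSeries,
    target: SymbolSeries,
    params: AnalysisParams | None = None,
    seed: int | None = None,
) -> InfoResult:
    """Entropy, MI and bidirectional TE between two aligned symbol series."""
    params = params or AnalysisParams()
    te_st, p_st = transfer_entropy(
        source, target, params.k, params.l, params.delay, params.n_surrogates, seed
    )
    te_ts, p_ts = transfer_entropy(
        target, source, params.k, params.l, params.delay, params.n_surrogates,
        None if seed is None else seed + 1,
    )
    return InfoResult(
        h_source_bits=shannon_entropy(source),
        h_target_bits=shannon_entropy(target),
        mi_bits=mutual_information(source, target, lag=0),
        te_source_to_target_bits=te_st,
        te_target_to_source_bits=te_ts,
        p_te_source_to_target=p_st,
        p_te_target_to_source=p_ts,
        settings={
            "k": params.k,
            "l": params.l,
            "delay": params.delay,
            "n_bins": params.n_bins,
            "n_surrogates": params.n_surrogates,
        },
    )
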