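"""Nonlinear characterisation of one-dimensional time series.

Implements the classical attractor-reconstruction pipeline: time-delay
embedding with an auto-mutual-information delay, false-nearest-neighbour
minimum embedding dimension, recurrence quantification (recurrence rate,
diagonal-line Shannon entropy, longest diagonal), maximal Lyapunov exponent
(recurrence 1/L_max convention and a direct nearest-neighbour divergence
estimator), the Lyapunov time, and the Grassberger–Procaccia correlation
dimension.

Conventions: maximum norm for recurrence distances; diagonal lines of
length >= 2; Theiler window tau*m by default; entropies in bits. Diagonal
lines truncated by the recurrence-matrix border are excluded from the
entropy histogram (border correction) so that strictly periodic signals
score zero line-length entropy; the longest line L_max keeps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .config import AnalysisParams

log = logging.getLogger("nmdasim")

__all__ = [
    "EmbeddingSpec",
    "embed",
    "auto_mutual_information",
    "select_delay",
    "fnn_min_dim",
    "RQAResult",
    "rqa_metrics",
    "line_histogram_entropy",
    "lyapunov_exponent",
    "lyapunov_time",
    "correlation_dimension",
    "NldynResult",
    "analyze_series",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: delay tau, dimension m, Theiler window
    (all in sample steps)."""

    tau: int = 1
    m: int = 2
    theiler: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ValueError("require tau >= 1 and m >= 1")

    @property
    def theiler_window(self) -> int:
        return self.theiler if self.theiler is not None else self.tau * self.m


def embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed ``series`` into R^m; returns (N - (m-1)*tau, m)."""
    x = np.asarray(series, dtype=float)
    n_vec = len(x) - (m - 1) * tau
    if n_vec <= 0:
        raise ValueError(f"series too short for m={m}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


# ----------------------------------------------------------------------
# delay selection

def _hist_mi_bits(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    h, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px[:, None] * py[None, :])[nz])))


def auto_mutual_information(series: np.ndarray, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """Histogram auto-MI (bits) at lags 1..max_lag."""
    x = np.asarray(series, dtype=float)
    return np.array([_hist_mi_bits(x[:-lag], x[lag:], n_bins) for lag in range(1, max_lag + 1)])


def select_delay(series: np.ndarray, max_tau: int, n_bins: int = 16) -> int:
    """Embedding delay: first local minimum of the lagged auto mutual
    information; falls back to the 1/e autocorrelation crossing.

    If the lag-1 auto-MI is already at the estimator's bias floor
    (~(B-1)^2/(2 N ln 2) bits) the series is treated as uncorrelated and
    the autocorrelation fallback (tau = 1 for white noise) applies —
    plug-in MI fluctuations on independent samples would otherwise create
    spurious local minima at arbitrary lags.
    """
    x = np.asarray(series, dtype=float)
    if max_tau < 1:
        raise ValueError("max_tau must be >= 1")
    if len(x) < 4 * max_tau:
        raise ValueError(f"series length {len(x)} < 4*max_tau = {4 * max_tau}")
    if np.ptp(x) == 0:
        raise ValueError("constant series: delay undefined (zero variance)")

    ami = auto_mutual_information(x, max_tau, n_bins)
    bias = (n_bins - 1) ** 2 / (2.0 * len(x) * np.log(2.0))
    if ami[0] > 3.0 * bias:
        for t in range(1, max_tau - 1):
            if ami[t] < ami[t - 1] and ami[t] <= ami[t + 1]:
                # flat valleys (noiseless periodic signals) make the exact
                # minimum arbitrary: widen to the tolerance plateau around
                # it and take the central lag
                delta = max(bias, 0.05 * float(np.ptp(ami)))
                lo = hi = t
                while lo > 0 and ami[lo - 1] <= ami[t] + delta:
                    lo -= 1
                while hi < max_tau - 1 and ami[hi + 1] <= ami[t] + delta:
                    hi += 1
                if hi >= max_tau - 1:
                    # decays to a floor and never rises again: first
                    # arrival at the floor, not the centre of the tail
                    return lo + 1
                return (lo + hi) // 2 + 1  # ami index -> lag

    # fallback: first lag where autocorrelation drops below 1/e
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    for lag in range(1, max_tau + 1):
        ac = float(np.dot(xc[:-lag], xc[lag:])) / denom
        if ac < 1.0 / np.e:
            return lag
    return max_tau


# ----------------------------------------------------------------------
# false nearest neighbours

def fnn_min_dim(
    series: np.ndarray,
    tau: int,
    max_m: int = 6,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    theiler: int | None = None,
) -> tuple[np.ndarray, int, bool]:
    """False-nearest-neighbour fractions for m = 1..max_m and the minimum
    embedding dimension.

    Returns ``(fractions, m_star, saturated)``. ``m_star`` is the smallest
    m whose FNN fraction drops below ``threshold``; for series that never
    saturate (e.g. stochastic signals) m_star = max_m and ``saturated`` is
    False. Nearest neighbours are sought outside a Theiler window
    (default tau) so temporally adjacent samples do not masquerade as
    geometric neighbours.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < (max_m + 1) * tau + 10:
        raise ValueError(
            f"series too short for max_m={max_m}: need >= {(max_m + 1) * tau + 10} points"
        )
    w = theiler if theiler is not None else tau
    sigma = float(np.std(x))
    if sigma == 0:
        raise ValueError("constant series")

    fractions = np.full(max_m, np.nan)
    m_star = max_m
    saturated = False
    for m in range(1, max_m + 1):
        emb = embed(x, m, tau)
        # need the (m+1)-th coordinate x[i + m*tau] for the test
        n_use = len(x) - m * tau
        emb = emb[:n_use]
        d = cdist(emb, emb)
        ii, jj = np.indices(d.shape)
        d[np.abs(ii - jj) <= w] = np.inf
        nn = np.argmin(d, axis=1)
        r_m = d[np.arange(n_use), nn]
        ok = np.isfinite(r_m)
        extra = np.abs(x[np.arange(n_use) + m * tau] - x[nn + m * tau])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_m > 0, extra / r_m, np.inf)
        false = (ratio > rtol) | (np.sqrt(r_m**2 + extra**2) / sigma > atol)
        false &= ~((r_m == 0) & (extra == 0))
        fractions[m - 1] = float(np.mean(false[ok])) if ok.any() else 1.0
        if fractions[m - 1] < threshold:
            m_star = m
            saturated = True
            break
    if not saturated:
        log.warning("fnn_min_dim: no saturation below %.1f%% up to m=%d", 100 * threshold, max_m)
    return fractions, m_star, saturated


# ----------------------------------------------------------------------
# recurrence quantification

@dataclass
class RQAResult:
    recurrence_rate: float
    entropy_bits: float
    l_max: int
    eps: float
    line_histogram: dict[int, int]
    degenerate: bool = False
    note: str = ""


def line_histogram_entropy(hist: dict[int, int]) -> float:
    """Shannon entropy (bits) of a diagonal line-length histogram."""
    counts = np.array([c for c in hist.values() if c > 0], dtype=float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _diagonal_lines(R: np.ndarray, offset: int, l_min: int) -> tuple[list[int], list[int]]:
    """Lengths of recurrent runs on one super-diagonal; returns
    (interior_lines, all_lines). Runs touching either end of the diagonal
    are border-truncated and excluded from the interior list."""
    diag = np.diagonal(R, offset=offset)
    if diag.size == 0:
        return [], []
    padded = np.concatenate([[0], diag.astype(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    interior, all_lines = [], []
    for s, e in zip(starts, ends):
        length = e - s
        if length < l_min:
            continue
        all_lines.append(int(length))
        if s > 0 and e < diag.size:
            interior.append(int(length))
    return interior, all_lines


def rqa_metrics(
    series: np.ndarray,
    spec: EmbeddingSpec,
    rr_target: float = 0.05,
    eps: float | None = None,
    l_min: int = 2,
) -> RQAResult:
    """Recurrence quantification with Theiler exclusion.

    The recurrence radius is either fixed (``eps``) or chosen as the
    ``rr_target`` quantile of the off-window distances. Entropy is the
    Shannon entropy of the border-corrected diagonal-line histogram
    (lengths >= l_min); L_max is the longest diagonal off the Theiler band
    (border lines included).
    """
    x = np.asarray(series, dtype=float)
    w = max(1, spec.theiler_window)
    if np.ptp(x) == 0:
        # all states identical: fully recurrent, single line class
        return RQAResult(1.0, 0.0, max(len(x) - w - 1, 0), 0.0, {}, True, "constant series")

    emb = embed(x, spec.m, spec.tau)
    n = len(emb)
    dist = cdist(emb, emb, metric="chebyshev")
    ii, jj = np.indices(dist.shape)
    off_window = np.abs(ii - jj) > w

    if eps is None:
        eps = float(np.quantile(dist[off_window], rr_target))
    R = (dist <= eps) & off_window
    rr = float(R[off_window].mean()) if off_window.any() else 0.0

    hist: dict[int, int] = {}
    l_max = 0
    for offset in range(w + 1, n):
        interior, all_lines = _diagonal_lines(R, offset, l_min)
        for length in interior:
            hist[length] = hist.get(length, 0) + 1
        if all_lines:
            l_max = max(l_max, max(all_lines))

    degenerate = rr in (0.0, 1.0)
    note = ""
    if degenerate:
        note = "degenerate recurrence matrix (all or none recurrent)"
    elif not hist:
        note = "no interior diagonal lines (periodic or too short)"
    return RQAResult(rr, line_histogram_entropy(hist), l_max, float(eps), hist, degenerate, note)


# ----------------------------------------------------------------------
# Lyapunov exponent

def _direct_lyapunov(
    series: np.ndarray, spec: EmbeddingSpec, fit_range: tuple[int, int]
) -> float:
    """Nearest-neighbour divergence-slope estimator (Rosenstein-style):
    mean log distance between initially neighbouring trajectories as a
    function of look-ahead k, slope fitted over ``fit_range``."""
    x = np.asarray(series, dtype=float)
    emb = embed(x, spec.m, spec.tau)
    n = len(emb)
    w = max(1, spec.theiler_window)
    k_max = fit_range[1]
    n_use = n - k_max
    if n_use < 10:
        raise ValueError("series too short for the direct Lyapunov estimator")
    d = cdist(emb[:n_use], emb[:n_use])
    ii, jj = np.indices(d.shape)
    d[np.abs(ii - jj) <= w] = np.inf
    d[d == 0] = np.inf  # skip exact duplicates
    nn = np.argmin(d, axis=1)
    valid = np.isfinite(d[np.arange(n_use), nn])

    ks = np.arange(0, k_max + 1)
    mean_log = np.empty(len(ks))
    for idx, k in enumerate(ks):
        di = np.linalg.norm(emb[np.arange(n_use) + k] - emb[nn + k], axis=1)
        sel = valid & (di > 0)
        mean_log[idx] = np.mean(np.log(di[sel])) if sel.any() else np.nan
    k_lo, k_hi = fit_range
    sel = slice(k_lo, k_hi + 1)
    kk = ks[sel]
    yy = mean_log[sel]
    good = np.isfinite(yy)
    if good.sum() < 2:
        raise ValueError("degenerate divergence curve")
    slope = np.polyfit(kk[good], yy[good], 1)[0]
    return float(slope)


def lyapunov_exponent(
    series: np.ndarray,
    spec: EmbeddingSpec,
    method: str = "direct",
    fit_range: tuple[int, int] = (1, 6),
    rr_target: float = 0.05,
) -> float | None:
    """Maximal Lyapunov exponent per sample step.

    ``direct``: nearest-neighbour divergence slope (sign meaningful,
    near zero for regular signals). ``rqa_divergence``: the 1/L_max
    recurrence convention (always >= 0; None when the recurrence
    structure is degenerate).
    """
    if method == "direct":
        return _direct_lyapunov(series, spec, fit_range)
    if method == "rqa_divergence":
        res = rqa_metrics(series, spec, rr_target=rr_target)
        if res.degenerate or res.l_max < 2:
            log.warning("lyapunov_exponent: degenerate recurrence structure; undefined")
            return None
        return 1.0 / res.l_max
    raise ValueError(f"unknown method {method!r}")


def lyapunov_time(lam: float | None) -> int | None:
    """Predictability horizon round(1/lambda) in steps; None ('NE') when
    the exponent is non-positive or undefined."""
    if lam is None or not np.isfinite(lam) or lam <= 0:
        return None
    return int(round(1.0 / lam))


# ----------------------------------------------------------------------
# correlation dimension

def correlation_dimension(
    series: np.ndarray,
    spec: EmbeddingSpec,
    eps_range: tuple[float, float] | None = None,
    n_eps: int = 28,
    window: int = 8,
    c_max: float = 0.35,
    max_points: int = 2500,
) -> tuple[float, dict]:
    """Grassberger–Procaccia correlation dimension D2.

    The correlation integral C(eps) (maximum norm, Theiler-excluded pairs)
    is evaluated on a log-spaced radius grid; the scaling region is chosen
    automatically as the most linear sliding window of ``window`` grid
    points in log C vs log eps (restricted to C <= ``c_max``, below
    saturation), preferring the smallest radii among windows of
    near-identical linearity. Returns (D2, diagnostics); diagnostics carry
    a quality warning when no clean scaling region exists.
    """
    x = np.asarray(series, dtype=float)
    emb = embed(x, spec.m, spec.tau)
    if len(emb) > max_points:
        emb = emb[np.linspace(0, len(emb) - 1, max_points).astype(int)]
    w = max(1, spec.theiler_window)
    dist = cdist(emb, emb, metric="chebyshev")
    ii, jj = np.indices(dist.shape)
    d = dist[(jj > ii + w)]
    if d.size == 0 or np.all(d == 0):
        return 0.0, {"note": "degenerate: all embedded points coincide", "quality": "degenerate"}

    pos = d[d > 0]
    if eps_range is None:
        # lower bound above the near-duplicate pair scale (trajectory
        # sampling puts a point mass of same-phase pairs at tiny radii)
        eps_range = (float(np.quantile(pos, 5e-3)), float(np.quantile(pos, 0.6)))
    lo, hi = eps_range
    if not (0 < lo < hi):
        lo = max(lo, float(pos.min()))
        hi = max(hi, lo * 10)
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_eps))
    C = np.array([np.mean(d <= e) for e in grid])

    usable = np.flatnonzero((C > 0) & (C <= c_max))
    if usable.size < 3:
        return 0.0, {"note": "correlation integral empty", "quality": "degenerate"}
    le = np.log(grid[usable])
    lc = np.log(C[usable])
    win = min(window, usable.size)
    best: list[tuple[int, float, float]] = []  # (start, r2, slope)
    for s in range(usable.size - win + 1):
        xs, ys = le[s : s + win], lc[s : s + win]
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        best.append((s, r2, float(slope)))
    r2_max = max(b[1] for b in best)
    # smallest radii among near-equally linear windows
    s, r2, slope = next(b for b in best if b[1] >= r2_max - 0.005)
    quality = "ok" if r2 >= 0.98 else f"no clean scaling region (best R2={r2:.3f})"
    if quality != "ok":
        log.warning("correlation_dimension: %s", quality)
    return float(max(slope, 0.0)), {
        "eps": grid,
        "C": C,
        "fit_start": int(usable[s]),
        "window": win,
        "r2": r2,
        "quality": quality,
    }


# ----------------------------------------------------------------------
# bundled analysis

@dataclass
class NldynResult:
    """Full nonlinear characterisation of one series."""

    tau: int
    m_star: int
    fnn_saturated: bool
    d2: float
    recurrence_rate: float
    shannon_rqa_bits: float
    l_max: int
    lyap_direct: float | None
    lyap_rqa: float | None
    lyap_time: int | None
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "m_star": self.m_star,
            "fnn_saturated": self.fnn_saturated,
            "d2": self.d2,
            "recurrence_rate": self.recurrence_rate,
            "shannon_rqa_bits": self.shannon_rqa_bits,
            "l_max": self.l_max,
            "lyap_direct": self.lyap_direct,
            "lyap_rqa": self.lyap_rqa,
            "lyap_time": self.lyap_time,
            "notes": self.notes,
        }


def analyze_series(series: np.ndarray, params: AnalysisParams | None = None) -> NldynResult:
    """Run the full nonlinear pipeline on one series with automatic
    delay/dimension selection (overridable through ``params``)."""
    params = params or AnalysisParams()
    x = np.asarray(series, dtype=float)
    notes = []

    tau = params.tau or select_delay(x, params.max_tau)
    if params.m is not None:
        m_star, saturated = params.m, True
    else:
        try:
            _, m_star, saturated = fnn_min_dim(
                x, tau, params.max_m, params.fnn_rtol, params.fnn_atol, params.fnn_threshold
            )
            if not saturated and params.tau is None and tau > 1:
                # over-decorrelated delay (map-like data): retry at tau=1
                _, m1, sat1 = fnn_min_dim(
                    x, 1, params.max_m, params.fnn_rtol, params.fnn_atol,
                    params.fnn_threshold,
                )
                if sat1:
                    tau, m_star, saturated = 1, m1, True
                    notes.append("fnn saturated only at tau=1; delay reset")
        except ValueError as exc:
            notes.append(f"fnn skipped: {exc}")
            m_star, saturated = 2, False
    spec = EmbeddingSpec(tau=tau, m=m_star, theiler=params.theiler)

    rqa = rqa_metrics(x, spec, rr_target=params.rr_target, eps=params.eps, l_min=params.l_min)
    if rqa.note:
        notes.append(rqa.note)

    try:
        lyap_direct = lyapunov_exponent(x, spec, method="direct")
    except ValueError as exc:
        lyap_direct = None
        notes.append(f"direct lyapunov failed: {exc}")
    lyap_rqa = None if rqa.degenerate or rqa.l_max < 2 else 1.0 / rqa.l_max

    d2, diag = correlation_dimension(x, spec)
    if diag.get("quality") not in ("ok", None):
        notes.append(f"d2: {diag['quality']}")

    return NldynResult(
        tau=tau,
        m_star=m_star,
        fnn_saturated=saturated,
        d2=d2,
        recurrence_rate=rqa.recurrence_rate,
        shannon_rqa_bits=rqa.entropy_bits,
        l_max=rqa.l_max,
        lyap_direct=lyap_direct,
        lyap_rqa=lyap_rqa,
        lyap_time=lyapunov_time(lyap_direct),
        notes="; ".join(notes),
    )
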