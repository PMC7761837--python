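"""Evaluation suite for original-vs-synthetic signal pairs.

Five metrics quantify how closely a synthetic segment S tracks its original
counterpart O of common length N:

* **RMSE** — ``sqrt(mean((O - S)^2))``, overall amplitude stability.
* **PRD** (%) — ``100 * sqrt(sum((O - S)^2) / sum(O^2))``, distortion
  normalised by the original's energy (asymmetric by construction).
* **MAE** — ``mean(|O - S|)``.
* **FD** — discrete Fréchet distance between the two curves: the minimum
  over monotone couplings of the maximum pointwise Euclidean distance
  ("dog-leash" distance), computed by dynamic programming.
* **PCC** — Pearson product-moment correlation in [-1, 1], with the
  conventional interpretation bands (|r| >= 0.9 "extensively correlated",
  down to |r| < 0.3 "negligibly correlated").

Curves for the Fréchet distance are formed as (time, amplitude) points with
the time index scaled to [0, 1]; pass ``parametrize="values"`` to treat the
raw sample values as 1-D points instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport", "rmse", "prd", "mae", "frechet_distance", "pcc",
    "pcc_band", "metric_report", "evaluate",
]

_BANDS = (
    (0.3, "Negligibly correlated"),
    (0.5, "Low correlation"),
    (0.7, "Moderately correlated"),
    (0.9, "Highly correlated"),
    (1.0 + 1e-12, "Extensively correlated"),
)


@dataclass
class MetricsReport:
    rmse: float
    prd: float
    mae: float
    fd: float
    pcc: float
    pcc_band: str


def _pair(o, s):
    o = np.asarray(o, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if o.shape != s.shape or o.ndim != 1 or o.size == 0:
        raise ValueError("O and S must be non-empty 1-D sequences of equal length")
    return o, s


def rmse(original, synthetic) -> float:
    o, s = _pair(original, synthetic)
    return float(np.sqrt(np.mean((o - s) ** 2)))


def prd(original, synthetic, literal_form: bool = False) -> float:
    """Percent root-mean-square difference, normalised by the original.

    ``literal_form=True`` omits the square root (the squared variant).
    """
    o, s = _pair(original, synthetic)
    energy = float(np.sum(o ** 2))
    if energy == 0.0:
        raise ValueError("original signal has zero energy")
    ratio = float(np.sum((o - s) ** 2)) / energy
    return 100.0 * (ratio if literal_form else np.sqrt(ratio))


def mae(original, synthetic) -> float:
    o, s = _pair(original, synthetic)
    return float(np.mean(np.abs(o - s)))


def _as_points(curve, parametrize: str) -> np.ndarray:
    c = np.asarray(curve, dtype=np.float64)
    if c.ndim == 2:
        return c
    if c.ndim != 1 or c.size == 0:
        raise ValueError("curve must be a non-empty 1-D value sequence or "
                         "(n, d) point array")
    if parametrize == "values":
        return c[:, None]
    t = np.zeros(c.size) if c.size == 1 else np.arange(c.size) / (c.size - 1)
    return np.column_stack([t, c])


def frechet_distance(curve1, curve2, parametrize: str = "indexed") -> float:
    """Discrete Fréchet distance between two curves.

    The minimum over monotone couplings (both endpoints covered, indices
    non-decreasing) of the maximum pointwise Euclidean distance, computed
    with the standard O(R*S) dynamic programme.
    """
    a = _as_points(curve1, parametrize)
    b = _as_points(curve2, parametrize)
    if a.shape[1] != b.shape[1]:
        raise ValueError("curves must have points of equal dimension")
    dist = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    R, S = dist.shape
    dp = np.empty((R, S))
    dp[0, 0] = dist[0, 0]
    for j in range(1, S):
        dp[0, j] = max(dp[0, j - 1], dist[0, j])
    for i in range(1, R):
        dp[i, 0] = max(dp[i - 1, 0], dist[i, 0])
        for j in range(1, S):
            dp[i, j] = max(min(dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1]),
                           dist[i, j])
    return float(dp[-1, -1])


def pcc(original, synthetic) -> float:
    """Pearson product-moment correlation coefficient."""
    o, s = _pair(original, synthetic)
    if o.size < 2:
        raise ValueError("PCC needs at least 2 samples")
    do, ds = o - o.mean(), s - s.mean()
    vo, vs = float(np.sum(do ** 2)), float(np.sum(ds ** 2))
    if vo == 0.0 or vs == 0.0:
        raise ValueError("PCC undefined for zero-variance input")
    r = float(np.sum(do * ds) / np.sqrt(vo * vs))
    return min(1.0, max(-1.0, r))


def pcc_band(r: float) -> str:
    """Map |r| onto the five qualitative correlation bands."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    a = abs(r)
    for upper, label in _BANDS:
        if a < upper:
            return label
    return _BANDS[-1][1]  # pragma: no cover


def metric_report(original, synthetic, **fd_kwargs) -> MetricsReport:
    """All five metrics for one original/synthetic pair."""
    r = pcc(original, synthetic)
    return MetricsReport(
        rmse=rmse(original, synthetic),
        prd=prd(original, synthetic),
        mae=mae(original, synthetic),
        fd=frechet_distance(original, synthetic, **fd_kwargs),
        pcc=r,
        pcc_band=pcc_band(r),
    )


def evaluate(pairs, **fd_kwargs) -> tuple[MetricsReport, list[MetricsReport]]:
    """Per-pair metrics plus their arithmetic means.

    ``pairs`` is an iterable of (original, synthetic) sequences; the summary
    report carries the mean of each metric (the mean PCC is what headline
    "mean correlation coefficient" summaries quote) and the band of the
    mean PCC.
    """
    reports = [metric_report(o, s, **fd_kwargs) for o, s in pairs]
    if not reports:
        raise ValueError("evaluate needs at least one pair")
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    mean_pcc = mean("pcc")
    summary = MetricsReport(mean("rmse"), mean("prd"), mean("mae"),
                            mean("fd"), mean_pcc, pcc_band(mean_pcc))
    return summary, reports
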