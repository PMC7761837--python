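"""Class-wise segmentation, Z-score normalisation, and length equalisation.

Signals are cut into per-class segments using their annotations (or a
median R-R window for beat-annotated recordings), each segment is Z-scored
to remove amplitude scale and offset, and every segment of a class is
brought to the class's minimum length by rational-ratio polyphase
resampling, producing the equal-length training matrix the adversarial
stage requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .io import SignalRecord

__all__ = [
    "SegmentSet", "SegmentMatrix", "segment_by_annotation",
    "segment_by_rr_median", "zscore", "zscore_set", "rational_approx",
    "resample_to_min",
]


@dataclass
class SegmentSet:
    """Per-class collections of (possibly unequal-length) segments."""

    classes: dict[str, list[np.ndarray]] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, np.ndarray]:
        return {c: np.array([len(s) for s in segs], dtype=int)
                for c, segs in self.classes.items()}

    @property
    def min_length(self) -> dict[str, int]:
        return {c: int(v.min()) for c, v in self.lengths.items()}

    @property
    def n(self) -> dict[str, int]:
        return {c: len(segs) for c, segs in self.classes.items()}

    def add(self, label: str, segment) -> None:
        self.classes.setdefault(label, []).append(
            np.asarray(segment, dtype=np.float64))


@dataclass
class SegmentMatrix:
    """Per-class matrices of equal-length rows ready for training.

    ``resampled[c][k]`` flags whether row ``k`` was length-altered.
    """

    matrices: dict[str, np.ndarray]
    resampled: dict[str, np.ndarray]

    @property
    def n(self) -> dict[str, int]:
        return {c: m.shape[0] for c, m in self.matrices.items()}


def segment_by_annotation(record: SignalRecord) -> SegmentSet:
    """Cut the record at annotation indices into half-open, labelled segments.

    Segment ``k`` spans ``[index_k, index_{k+1})``; the trailing segment
    runs to the end of the record, so the annotated region is partitioned
    exactly (samples before the first annotation, if any, are not part of
    any segment).
    """
    if not record.annotations:
        raise ValueError("record has no annotations; use a fixed-window "
                         "fallback (e.g. segment_by_rr_median on detected "
                         "beats) instead")
    out = SegmentSet()
    indices = [idx for idx, _ in record.annotations] + [len(record)]
    for (idx, label), nxt in zip(record.annotations, indices[1:]):
        if nxt > idx:
            out.add(label, record.samples[idx:nxt])
    return out


def segment_by_rr_median(record: SignalRecord) -> SegmentSet:
    """Window each beat to the median R-R interval, centred on its R index.

    The nominal heartbeat period T is the median of successive differences
    between beat annotation indices.  Windows clipped by a record edge are
    kept if at least T/2 samples survive, otherwise dropped.
    """
    if len(record.annotations) < 3:
        raise ValueError("median R-R segmentation needs >= 3 beat annotations")
    r = np.array([idx for idx, _ in record.annotations])
    T = int(round(float(np.median(np.diff(r)))))
    if T < 1:
        raise ValueError("degenerate R-R intervals (median < 1 sample)")
    out = SegmentSet()
    n = len(record)
    for (idx, label) in record.annotations:
        start = max(0, idx - T // 2)
        end = min(n, start + T)
        start = max(0, min(start, end - T))  # re-anchor at the right edge
        if end - start >= T / 2:
            out.add(label, record.samples[start:end])
    return out


def zscore(segment) -> np.ndarray:
    """Standardise to mean 0 and sample (ddof=1) standard deviation 1."""
    x = np.asarray(segment, dtype=np.float64)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant segment has zero variance")
    return (x - x.mean()) / sd


def zscore_set(segset: SegmentSet) -> SegmentSet:
    out = SegmentSet()
    for label, segs in segset.classes.items():
        for s in segs:
            out.add(label, zscore(s))
    return out


def rational_approx(x: float, tol: float = 1e-6) -> tuple[int, int]:
    """Smallest-denominator p/q with |p/q - x| <= tol, via continued fractions."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if x <= 0:
        raise ValueError("ratio must be positive")
    # walk the continued-fraction convergents; the first within tol wins
    h_prev, k_prev, h, k = 1, 0, int(x), 1
    rem = x - int(x)
    for _ in range(64):
        if abs(h / k - x) <= tol:
            break
        if rem == 0:
            break
        rem = 1.0 / rem
        a = int(rem)
        rem -= a
        h_prev, k_prev, h, k = h, k, a * h + h_prev, a * k + k_prev
    g = Fraction(h, k)  # reduce to lowest terms
    return g.numerator, g.denominator


def _fix_length(y: np.ndarray, target: int) -> np.ndarray:
    """Resolve the +-1 sample slack of polyphase resampling by trim/edge-pad."""
    if y.size > target:
        return y[:target]
    if y.size < target:
        return np.concatenate([y, np.full(target - y.size, y[-1])])
    return y


def resample_to_min(segset: SegmentSet, tol: float = 1e-6) -> SegmentMatrix:
    """Resample every segment of each class to the class minimum length.

    A segment of length ``l`` is kept verbatim when ``l == minL``; otherwise
    the ratio ``minL/l`` is approximated by a rational ``p/q`` within
    ``tol`` and the segment is polyphase-resampled (upsample by p, low-pass
    filter, downsample by q), then trimmed or edge-padded to exactly
    ``minL``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not segset.classes:
        raise ValueError("empty segment set")
    matrices, flags = {}, {}
    for label, segs in segset.classes.items():
        if not segs:
            raise ValueError(f"class {label!r} is empty")
        min_l = min(len(s) for s in segs)
        rows, res = [], []
        for s in segs:
            if len(s) == min_l:
                rows.append(np.asarray(s, dtype=np.float64))
                res.append(False)
            else:
                p, q = rational_approx(min_l / len(s), tol)
                rows.append(_fix_length(resample_poly(s, p, q), min_l))
                res.append(True)
        matrices[label] = np.vstack(rows)
        flags[label] = np.array(res, dtype=bool)
    return SegmentMatrix(matrices, flags)
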