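"""Motif hit detection in peak sequences.

Scanning works on the discretized integer scoring matrix so hit calls are
exactly consistent with the exact-p-value thresholds from
:mod:`synprom.motifs`.  Windows containing N are excluded (their score is
forced far below any threshold).  Minus-strand hits use the
reverse-complement matrix and are reported at the forward-strand offset of
the window start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import ScoringMatrix
from .formats import PeakSet

# Sentinel integer score for N; any window containing one scores below every
# reachable threshold (max |column score| is ~2^4 bits * scale << 2^40).
_N_SCORE = -(1 << 40)

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    """A single motif occurrence on a sequence window."""

    peak_name: str
    offset: int  # 0-based, forward-strand coordinate of the window start
    strand: str  # "+" or "-"
    score: float  # bits (discretized scale)
    motif_id: str


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _lut(sm: ScoringMatrix, rc: bool) -> np.ndarray:
    """(W, 5) integer score lookup; column 4 (N) is the sentinel.

    The reverse-complement matrix is the forward matrix with positions
    reversed and base columns A<->T, C<->G swapped.
    """
    ints = sm.int_scores
    if rc:
        ints = ints[::-1, ::-1]
    lut = np.full((sm.width, 5), _N_SCORE, dtype=np.int64)
    lut[:, :4] = ints
    return lut


def _window_scores(lut: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Integer scores for every window of one encoded sequence (1D)."""
    W = lut.shape[0]
    n = len(codes) - W + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, W)
    return lut[np.arange(W)[None, :], windows].sum(axis=1)


def scan_sequence(
    sm: ScoringMatrix,
    seq: str,
    threshold: float,
    both_strands: bool = True,
    peak_name: str = "",
) -> list[MotifHit]:
    """All windows of `seq` scoring at or above `threshold` (bits).

    Returns hits sorted by offset, forward strand before minus at equal
    offset.  A sequence shorter than the matrix width yields no hits.
    """
    codes = encode(seq)
    t_int = int(round(threshold * sm.scale))
    hits: list[MotifHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    per_strand = {}
    for strand in strands:
        scores = _window_scores(_lut(sm, rc=(strand == "-")), codes)
        per_strand[strand] = scores
        for off in np.nonzero(scores >= t_int)[0]:
            hits.append(
                MotifHit(
                    peak_name=peak_name,
                    offset=int(off),
                    strand=strand,
                    score=float(scores[off]) / sm.scale,
                    motif_id=sm.pwm_id,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_scores(
    sm: ScoringMatrix, peaks: PeakSet, both_strands: bool = True
) -> np.ndarray:
    """Best window score (bits) per peak, -inf where no window exists.

    Vectorized across peaks of equal length (the common simulated case);
    ragged peak sets fall back to per-sequence scanning.
    """
    if not peaks.has_sequences:
        raise ValueError(f"peak set {peaks.label!r} has no sequences attached")
    seqs = peaks.sequences
    n = len(seqs)
    out = np.full(n, -np.inf)
    if n == 0:
        return out
    luts = [_lut(sm, rc=False)] + ([_lut(sm, rc=True)] if both_strands else [])
    W = sm.width
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1 and lengths.pop() >= W:
        mat = np.vstack([encode(s) for s in seqs])
        windows = np.lib.stride_tricks.sliding_window_view(mat, W, axis=1)
        best = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
        idx = np.arange(W)[None, None, :]
        for lut in luts:
            scores = lut[idx, windows].sum(axis=2)  # (n, n_windows)
            np.maximum(best, scores.max(axis=1), out=best)
        valid = best > _N_SCORE // 2  # all-N-window rows stay -inf
        out[valid] = best[valid].astype(float) / sm.scale
        return out
    for i, s in enumerate(seqs):
        if len(s) < W:
            continue
        codes = encode(s)
        b = np.iinfo(np.int64).min
        for lut in luts:
            ws = _window_scores(lut, codes)
            if len(ws):
                b = max(b, int(ws.max()))
        if b > _N_SCORE // 2:
            out[i] = b / sm.scale
    return out


def peaks_with_hit(
    sm: ScoringMatrix,
    peaks: PeakSet,
    threshold: float,
    both_strands: bool = True,
) -> tuple[int, int]:
    """ZOOPS reduction: (number of peaks with >= 1 hit, total peaks).

    A peak counts once no matter how many windows exceed the threshold
    (zero-or-one occurrence per sequence), the statistic the enrichment
    contingency tables are built from.
    """
    t_int = int(round(threshold * sm.scale))
    best = best_scores(sm, peaks, both_strands=both_strands)
    finite = np.isfinite(best)
    n_hit = int(np.sum(np.round(best[finite] * sm.scale).astype(np.int64) >= t_int))
    return n_hit, len(peaks)
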