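"""Position-weight-matrix model for transcription factor binding motifs.

A :class:`Pwm` holds per-position base probabilities (columns over A, C, G, T).
From it a :class:`ScoringMatrix` of log2 odds against a background base
composition is built, together with a discretized integer copy from which the
*exact* distribution of scores of random background words is computed by
column-wise convolution.  That distribution turns a tail probability (the
per-window false-positive rate a user is willing to accept) into a concrete
score threshold for hit calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: Fixed base order used for all matrices in this package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degeneracy codes keyed by the set of bases they cover.
IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

#: Default discretization granularity: integer scores are round(bits * 1000),
#: i.e. a resolution of 0.001 bits.
DEFAULT_SCALE = 1000

#: Hard cap on the support size of the discretized score distribution.
MAX_DISTRIBUTION_SUPPORT = 20_000_000

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix with identity metadata.

    Parameters
    ----------
    id : str
        Unique motif identifier (e.g. a JASPAR matrix id).
    tf_name : str
        Name of the transcription factor the motif describes.
    prob : (W, 4) ndarray
        Per-position base probabilities in A, C, G, T order.  Every column
        must sum to 1 (within 1e-6) and be strictly positive.
    family : str, optional
        TF structural family (bZIP, IRF, ...), if known.
    source_dialect : str
        File dialect the motif was read from ("jaspar", "homer", ...).
    """

    id: str
    tf_name: str
    prob: np.ndarray
    family: str | None = None
    source_dialect: str = "unknown"

    def __post_init__(self) -> None:
        prob = np.asarray(self.prob, dtype=float)
        object.__setattr__(self, "prob", prob)
        if prob.ndim != 2 or prob.shape[1] != 4:
            raise ValueError(f"motif {self.id!r}: prob must be (W, 4), got {prob.shape}")
        if prob.shape[0] < 1:
            raise ValueError(f"motif {self.id!r}: width must be >= 1")
        if not np.all(prob > 0):
            raise ValueError(f"motif {self.id!r}: probabilities must be strictly positive")
        if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {self.id!r}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.prob.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pwm):
            return NotImplemented
        return (
            self.id == other.id
            and self.tf_name == other.tf_name
            and np.array_equal(self.prob, other.prob)
        )

    def __hash__(self) -> int:
        return hash((self.id, self.tf_name, self.prob.tobytes()))


@dataclass(frozen=True)
class ScoringMatrix:
    """Log-odds scores of a Pwm against a background composition.

    ``scores[i, b] = log2(prob[i, b] / background[b])`` (bits).  The
    discretized copy ``int_scores = round(scores * scale)`` supports exact
    score-distribution computation; scanning uses it so that hit calling is
    exactly consistent with the p-value machinery.
    """

    pwm_id: str
    scores: np.ndarray
    background: np.ndarray
    scale: int = DEFAULT_SCALE
    int_scores: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "background", background)
        if not np.isclose(background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(
            self, "int_scores", np.round(scores * self.scale).astype(np.int64)
        )

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.int_scores.max(axis=1).sum()) / self.scale

    @property
    def min_score(self) -> float:
        return float(self.int_scores.min(axis=1).sum()) / self.scale


def log_odds(
    pwm: Pwm,
    background: np.ndarray | None = None,
    scale: int = DEFAULT_SCALE,
) -> ScoringMatrix:
    """Build the log2-odds scoring matrix of `pwm` against `background`.

    Raises
    ------
    ValueError
        If any background frequency is zero or negative.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,):
        raise ValueError("background must have 4 frequencies (A, C, G, T)")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must all be strictly positive")
    scores = np.log2(pwm.prob / bg)
    return ScoringMatrix(pwm_id=pwm.id, scores=scores, background=bg, scale=scale)


def consensus_site(pwm: Pwm, mode: str = "strict") -> str:
    """Extract a consensus binding-site string from a Pwm.

    ``strict``: the argmax base per column, ties broken in A < C < G < T
    order (argmax returns the first maximal index, which is that order).
    ``iupac``: the smallest degeneracy code covering every base with
    probability >= 0.25.
    """
    if mode == "strict":
        return "".join(BASES[i] for i in np.argmax(pwm.prob, axis=1))
    if mode == "iupac":
        out = []
        for col in pwm.prob:
            covered = frozenset(BASES[i] for i in range(4) if col[i] >= 0.25)
            out.append(IUPAC_CODES[covered])
        return "".join(out)
    raise ValueError(f"unknown consensus mode {mode!r}")


def reverse_complement(pwm: Pwm) -> Pwm:
    """Reverse-complement a Pwm: columns reversed, A<->T and C<->G swapped.

    An involution: applying it twice returns the original matrix.
    """
    rc = pwm.prob[::-1, ::-1].copy()
    return Pwm(
        id=pwm.id,
        tf_name=pwm.tf_name,
        prob=rc,
        family=pwm.family,
        source_dialect=pwm.source_dialect,
    )


def _distribution_array(sm: ScoringMatrix) -> tuple[int, np.ndarray]:
    """Exact distribution of the integer score of a random background W-mer.

    Returns ``(lo, probs)`` where ``probs[s - lo]`` is the probability of
    integer score ``s``.  Computed by convolving the 4-point per-column
    distributions; bases are drawn column-independently from the background.
    """
    ints = sm.int_scores
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    support = hi - lo + 1
    if support > MAX_DISTRIBUTION_SUPPORT:
        raise ResourceWarning(
            f"score-distribution support {support} exceeds bound "
            f"{MAX_DISTRIBUTION_SUPPORT}; use a coarser scale"
        )
    # running support [cur_lo, cur_hi]; convolve in one preallocated buffer
    probs = np.zeros(support)
    cur_lo = int(ints[0].min())
    width0 = int(ints[0].max()) - cur_lo + 1
    first = np.zeros(width0)
    for b in range(4):
        first[ints[0, b] - cur_lo] += sm.background[b]
    cur = first
    for i in range(1, sm.width):
        col = ints[i]
        col_lo = int(col.min())
        new_lo = cur_lo + col_lo
        new = np.zeros(len(cur) + int(col.max()) - col_lo)
        for b in range(4):
            off = int(col[b]) - col_lo
            new[off : off + len(cur)] += sm.background[b] * cur
        cur = new
        cur_lo = new_lo
    probs[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return lo, probs


def score_distribution(sm: ScoringMatrix) -> dict[int, float]:
    """Exact integer-score distribution as a mapping score -> probability.

    Only scores with nonzero probability appear.  The probabilities sum to 1
    up to floating-point rounding (well within 1e-9).
    """
    lo, probs = _distribution_array(sm)
    nz = np.nonzero(probs)[0]
    return {int(lo + i): float(probs[i]) for i in nz}


class ThresholdResult(NamedTuple):
    """Score threshold achieving a requested tail probability.

    ``threshold`` is on the real (bits) scale, ``int_threshold`` on the
    discretized scale; ``tail`` is the achieved P(score >= threshold) under
    the background model.  ``attainable`` is False when alpha was so small
    that no achievable score qualifies (threshold then exceeds the maximum).
    """

    threshold: float
    int_threshold: int
    tail: float
    attainable: bool


def threshold_for_pvalue(sm: ScoringMatrix, alpha: float) -> ThresholdResult:
    """Smallest score threshold whose background tail probability is <= alpha.

    Parameters
    ----------
    sm : ScoringMatrix
    alpha : float
        Requested per-window tail probability, in (0, 1].  At alpha = 1 the
        minimum possible score is returned (every window is a hit).

    Returns
    -------
    ThresholdResult
        ``threshold`` (real scale), the achieved tail, and ``attainable``.
        If even the maximum achievable score has tail > alpha, the maximum
        score itself is returned (only perfect-scoring windows are hits)
        with the true tail at that score and ``attainable`` False.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    lo, probs = _distribution_array(sm)
    tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= lo + i)
    ok = np.nonzero(tail <= alpha)[0]
    if len(ok) == 0:
        i = len(probs) - 1
        return ThresholdResult((lo + i) / sm.scale, lo + i, float(tail[i]), False)
    i = int(ok[0])
    return ThresholdResult((lo + i) / sm.scale, lo + i, float(tail[i]), True)
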