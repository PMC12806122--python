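"""Cross-dataset intersection of enriched motifs.

After each dataset (e.g. each exhaustion model, possibly from different
species) has been analyzed independently, motifs significantly enriched in
*every* dataset form the conserved set — the multi-way Venn intersection.
Two matching modes are provided: exact (case-insensitive) motif-id equality
for homogeneous libraries, and PWM similarity matching (ungapped offset
sweep, both orientations, mean column-wise Pearson correlation) for
heterogeneous cross-species libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffenrich import EnrichmentResult
from .motifs import Pwm, reverse_complement

MIN_OVERLAP_COLUMNS = 4


@dataclass(frozen=True)
class MotifMatch:
    """Best ungapped alignment between two PWMs."""

    motif_a: str
    motif_b: str
    offset: int  # start of b relative to start of a (same-orientation frame)
    orientation: str  # "same" | "reverse_complement"
    similarity: float  # mean column-wise Pearson r over the overlap, in [-1, 1]


@dataclass(frozen=True)
class ConservedEntry:
    canonical_id: str
    dataset_motif_ids: tuple[str, ...]
    p_values: tuple[float, ...]
    q_values: tuple[float, ...]


@dataclass(frozen=True)
class ConservedMotifSet:
    """Motifs enriched in all k datasets, sorted by worst per-dataset p."""

    entries: tuple[ConservedEntry, ...]
    k: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def canonical_ids(self) -> list[str]:
        return [e.canonical_id for e in self.entries]


def _column_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r per aligned column pair of two (n, 4) probability blocks.

    Probability columns sum to 1, so each column's mean is exactly 0.25.
    A uniform column has zero variance: two uniform columns correlate 1,
    a uniform against a non-uniform column 0.
    """
    a = x - 0.25
    b = y - 0.25
    na = np.sqrt((a * a).sum(axis=1))
    nb = np.sqrt((b * b).sum(axis=1))
    num = (a * b).sum(axis=1)
    r = np.zeros(len(a))
    ok = (na > 0) & (nb > 0)
    r[ok] = num[ok] / (na[ok] * nb[ok])
    r[(na == 0) & (nb == 0)] = 1.0
    return r


def motif_similarity(a: Pwm, b: Pwm) -> MotifMatch:
    """Best ungapped match of `b` against `a` over all offsets and both
    orientations of b.

    The score at one placement is the mean column-wise Pearson correlation
    between the overlapping probability columns; at least
    ``MIN_OVERLAP_COLUMNS`` columns must overlap.  Ties prefer smaller
    |offset|, then the same orientation over the reverse complement.
    """
    if a.width < MIN_OVERLAP_COLUMNS or b.width < MIN_OVERLAP_COLUMNS:
        raise ValueError("motif widths must be >= 4 for similarity comparison")
    best: MotifMatch | None = None
    for orientation, bp in (("same", b), ("reverse_complement", reverse_complement(b))):
        for offset in range(-(bp.width - MIN_OVERLAP_COLUMNS),
                            a.width - MIN_OVERLAP_COLUMNS + 1):
            a_lo, a_hi = max(0, offset), min(a.width, offset + bp.width)
            if a_hi - a_lo < MIN_OVERLAP_COLUMNS:
                continue
            cols_a = a.prob[a_lo:a_hi]
            cols_b = bp.prob[a_lo - offset : a_hi - offset]
            sim = float(_column_corr(cols_a, cols_b).mean())
            cand = MotifMatch(a.id, b.id, offset, orientation, sim)
            if best is None or _better(cand, best):
                best = cand
    assert best is not None
    return best


def _better(cand: MotifMatch, best: MotifMatch) -> bool:
    if cand.similarity != best.similarity:
        return cand.similarity > best.similarity
    if abs(cand.offset) != abs(best.offset):
        return abs(cand.offset) < abs(best.offset)
    return cand.orientation == "same" and best.orientation == "reverse_complement"


def _enriched(results: list[EnrichmentResult], p_max: float) -> dict[str, EnrichmentResult]:
    return {r.motif_id: r for r in results if r.p_value < p_max}


def intersect_enriched(
    result_sets: list[list[EnrichmentResult]],
    libraries: list[list[Pwm]] | None = None,
    p_max: float = 0.05,
    match_mode: str = "by_id",
    sim_min: float = 0.80,
) -> ConservedMotifSet:
    """Motifs significantly enriched (p < p_max) in every dataset.

    by_id
        Case-insensitive motif_id equality across all K result sets;
        canonical id is the dataset-1 spelling.
    by_similarity
        Greedy best-first one-to-one matching of dataset-1 enriched motifs
        to each other dataset's enriched motifs, requiring PWM similarity
        >= `sim_min`; requires `libraries`.

    Output entries are sorted by their maximum (worst) per-dataset p-value,
    ascending, ties by canonical id.
    """
    k = len(result_sets)
    if k < 2:
        raise ValueError("intersection needs at least 2 result sets")
    if not 0 < sim_min <= 1:
        raise ValueError("sim_min must lie in (0, 1]")
    enriched = [_enriched(rs, p_max) for rs in result_sets]

    entries: list[ConservedEntry] = []
    if match_mode == "by_id":
        lower_maps = [{mid.lower(): mid for mid in e} for e in enriched]
        for mid, r0 in sorted(enriched[0].items()):
            key = mid.lower()
            if all(key in lm for lm in lower_maps[1:]):
                ids, ps, qs = [], [], []
                for d in range(k):
                    r = enriched[d][lower_maps[d][key]]
                    ids.append(r.motif_id)
                    ps.append(r.p_value)
                    qs.append(r.q_value)
                entries.append(ConservedEntry(mid, tuple(ids), tuple(ps), tuple(qs)))
    elif match_mode == "by_similarity":
        if libraries is None or len(libraries) != k:
            raise ValueError("by_similarity matching requires one library per dataset")
        pwms = [{p.id: p for p in lib} for lib in libraries]
        anchors = sorted(enriched[0])
        # matched[d][anchor] = motif_id matched in dataset d
        matched: list[dict[str, str]] = [{} for _ in range(k)]
        for d in range(1, k):
            pairs = []
            for aid in anchors:
                if aid not in pwms[0]:
                    continue
                for bid in sorted(enriched[d]):
                    if bid not in pwms[d]:
                        continue
                    m = motif_similarity(pwms[0][aid], pwms[d][bid])
                    if m.similarity >= sim_min:
                        pairs.append((-m.similarity, aid, bid))
            used_a: set[str] = set()
            used_b: set[str] = set()
            for negsim, aid, bid in sorted(pairs):
                if aid in used_a or bid in used_b:
                    continue
                used_a.add(aid)
                used_b.add(bid)
                matched[d][aid] = bid
        for aid in anchors:
            if all(aid in matched[d] for d in range(1, k)):
                ids = [aid] + [matched[d][aid] for d in range(1, k)]
                ps = [enriched[0][aid].p_value] + [
                    enriched[d][matched[d][aid]].p_value for d in range(1, k)
                ]
                qs = [enriched[0][aid].q_value] + [
                    enriched[d][matched[d][aid]].q_value for d in range(1, k)
                ]
                entries.append(ConservedEntry(aid, tuple(ids), tuple(ps), tuple(qs)))
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")

    entries.sort(key=lambda e: (max(e.p_values), e.canonical_id))
    return ConservedMotifSet(entries=tuple(entries), k=k)
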