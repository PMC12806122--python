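"""Synthetic promoter assembly from enriched motifs.

A selected motif is compiled into a tandem-array construct: its strict
consensus binding site repeated enough times to total roughly 120 bp of
binding sites, separated by 3 bp spacers, placed 5'->3' upstream of a
minimal core promoter.  Spacers are not arbitrary: every candidate spacer
is screened by rescanning the assembled array against the full motif
library, and is accepted only if the array contains exactly the intended
motif occurrences (one per repeat) and no spurious hit of any other library
motif.  The finished construct carries a validation report
(intended/unintended hit counts) and serializes to GenBank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .motifs import (
    Pwm,
    ScoringMatrix,
    consensus_site,
    log_odds,
    threshold_for_pvalue,
    UNIFORM_BACKGROUND,
)
from .scanning import scan_sequence

#: Placeholder minimal core promoter (synthetic stand-in for a minimal CMV
#: promoter fragment: TATA box + initiator-like 3' end).  Replace with the
#: exact minCMV sequence of the destination vector via DesignConfig.
DEFAULT_CORE_PROMOTER = (
    "AGGTCTATATAAGCAGAGCTCGTTTAGTGAACCGTCAGATCGCCTGGAGACGCCATCCAC"
)

DEFAULT_SCREEN_ALPHA = 1e-4


def _all_kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


@dataclass
class DesignConfig:
    """Tunable constants of the tandem-array layout.

    target_site_bp
        Total binding-site footprint to aim for; the repeat count is the
        nearest integer multiple of the site width (default 120 bp).
    spacer_len
        Length of the inter-repeat spacer (default 3 bp).
    core_promoter_seq / core_promoter_name
        Minimal core promoter appended 3' of the array.
    screen_alpha
        Per-window tail probability used to derive hit-calling thresholds
        when screening candidate spacers and validating constructs.
    spacer_candidates
        Ordered candidate spacers (default: all 4^spacer_len k-mers in
        lexicographic order); the first candidate passing the screen wins.
    """

    target_site_bp: int = 120
    spacer_len: int = 3
    core_promoter_seq: str = DEFAULT_CORE_PROMOTER
    core_promoter_name: str = "minCMV"
    screen_alpha: float = DEFAULT_SCREEN_ALPHA
    spacer_candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValueError("spacer_len must be >= 0")
        if not self.core_promoter_seq:
            raise ValueError("core_promoter_seq must be non-empty")
        if not self.spacer_candidates:
            self.spacer_candidates = _all_kmers(self.spacer_len) if self.spacer_len else [""]
        if any(len(s) != self.spacer_len for s in self.spacer_candidates):
            raise ValueError("every spacer candidate must have length spacer_len")


@dataclass
class PromoterDesign:
    """An assembled synthetic promoter construct.

    ``full_seq`` is site (spacer site)^(r-1) core, 5'->3'.  ``layout`` lists
    annotated (kind, start, end) spans in 0-based half-open coordinates,
    kind in {"site", "spacer", "core"}.  ``intended_hits`` /
    ``unintended_hits`` summarize the validation rescan.
    """

    tf_name: str
    motif_id: str
    site_seq: str
    repeats: int
    spacer_seqs: list[str]
    core_promoter_seq: str
    core_promoter_name: str
    full_seq: str = ""
    layout: list[tuple[str, int, int]] = field(default_factory=list)
    intended_hits: int = 0
    unintended_hits: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("a design needs at least one binding-site repeat")
        if len(self.spacer_seqs) != self.repeats - 1:
            raise ValueError("need exactly repeats-1 spacers")
        if not self.full_seq:
            self._assemble()

    def _assemble(self) -> None:
        parts: list[str] = []
        layout: list[tuple[str, int, int]] = []
        pos = 0
        for i in range(self.repeats):
            if i > 0:
                sp = self.spacer_seqs[i - 1]
                if sp:
                    layout.append(("spacer", pos, pos + len(sp)))
                    parts.append(sp)
                    pos += len(sp)
            layout.append(("site", pos, pos + len(self.site_seq)))
            parts.append(self.site_seq)
            pos += len(self.site_seq)
        layout.append(("core", pos, pos + len(self.core_promoter_seq)))
        parts.append(self.core_promoter_seq)
        self.full_seq = "".join(parts)
        self.layout = layout

    @property
    def site_spans(self) -> list[tuple[int, int]]:
        return [(s, e) for kind, s, e in self.layout if kind == "site"]

    @property
    def total_site_bp(self) -> int:
        return self.repeats * len(self.site_seq)


def repeat_count(site_len: int, target_site_bp: int = 120) -> int:
    """Number of tandem repeats so the total site footprint is closest to
    `target_site_bp` (half-up rounding, at least one repeat)."""
    if site_len < 4:
        raise ValueError("site length must be >= 4")
    if target_site_bp < site_len:
        raise ValueError("target_site_bp must be >= site length")
    return max(1, int(np.floor(target_site_bp / site_len + 0.5)))


@dataclass(frozen=True)
class ScreeningLibrary:
    """Scoring matrices + hit thresholds for every motif in a library."""

    matrices: dict[str, ScoringMatrix]
    thresholds: dict[str, float]

    @classmethod
    def from_pwms(
        cls,
        pwms: list[Pwm],
        alpha: float = DEFAULT_SCREEN_ALPHA,
        background: np.ndarray | None = None,
    ) -> "ScreeningLibrary":
        bg = UNIFORM_BACKGROUND if background is None else background
        mats, thrs = {}, {}
        for p in pwms:
            sm = log_odds(p, bg)
            mats[p.id] = sm
            thrs[p.id] = threshold_for_pvalue(sm, alpha).threshold
        return cls(mats, thrs)


def _dedup_hits(hits) -> list:
    """Collapse hits of one motif at the same window on both strands into a
    single occurrence (keep the higher-scoring strand)."""
    best = {}
    for h in hits:
        k = h.offset
        if k not in best or h.score > best[k].score:
            best[k] = h
    return [best[k] for k in sorted(best)]


def _assembled_array(site: str, spacers: list[str]) -> str:
    parts = [site]
    for sp in spacers:
        parts.append(sp)
        parts.append(site)
    return "".join(parts)


def _count_array_hits(
    array: str, motif_id: str, lib: ScreeningLibrary
) -> tuple[int, int]:
    """(intended, unintended) motif occurrences in a bare site/spacer array."""
    intended = unintended = 0
    for mid, sm in lib.matrices.items():
        hits = _dedup_hits(scan_sequence(sm, array, lib.thresholds[mid]))
        if mid == motif_id:
            intended = len(hits)
        else:
            unintended += len(hits)
    return intended, unintended


def choose_spacers(
    site_seq: str,
    r: int,
    library: ScreeningLibrary,
    cfg: DesignConfig,
    motif_id: str,
) -> tuple[list[str], list[str]]:
    """Pick r-1 spacers whose assembled array is clean under library rescan.

    Deterministic first-fit: each candidate from ``cfg.spacer_candidates``
    is tried as a uniform spacer at every junction; it is accepted iff the
    assembled array contains exactly r occurrences of the intended motif
    and none of any other library motif, judged by a full scan at the
    screening thresholds.  If no uniform candidate passes, junctions are
    filled left to right (earlier choices frozen); if some junction still
    has no clean candidate, the minimal-violation candidate is taken and a
    warning is recorded.

    Returns (spacers, warnings).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if r == 1:
        return [], []

    def violations(spacers: list[str]) -> int:
        intended, unintended = _count_array_hits(
            _assembled_array(site_seq, spacers), motif_id, library
        )
        return abs(intended - len(spacers) - 1) + unintended

    for cand in cfg.spacer_candidates:
        if violations([cand] * (r - 1)) == 0:
            return [cand] * (r - 1), []

    # per-junction left-to-right fallback
    warnings: list[str] = []
    chosen: list[str] = []
    for j in range(r - 1):
        best_cand, best_v = None, None
        for cand in cfg.spacer_candidates:
            trial = chosen + [cand]
            # score the partial array (j+2 sites); remaining junctions unknown
            intended, unintended = _count_array_hits(
                _assembled_array(site_seq, trial), motif_id, library
            )
            v = abs(intended - (j + 2)) + unintended
            if best_v is None or v < best_v:
                best_cand, best_v = cand, v
            if v == 0:
                break
        assert best_cand is not None
        chosen.append(best_cand)
        if best_v != 0:
            warnings.append(
                f"junction {j + 1}: no clean spacer candidate; picked "
                f"{best_cand!r} with {best_v} residual violation(s)"
            )
    return chosen, warnings


def validate_design(
    design: PromoterDesign, library: ScreeningLibrary
) -> tuple[int, int, dict[str, int]]:
    """Rescan the full construct (both strands) against the whole library.

    ``intended_hits`` counts occurrences of the design's own motif whose
    window coincides exactly with a binding-site span; every other
    occurrence — other motifs anywhere, or the own motif off-register —
    counts as unintended.  Occurrences are per window (forward/minus hits
    at the same window are one occurrence).
    """
    spans = set(design.site_spans)
    per_motif: dict[str, int] = {}
    intended = unintended = 0
    for mid, sm in library.matrices.items():
        hits = _dedup_hits(scan_sequence(sm, design.full_seq, library.thresholds[mid]))
        per_motif[mid] = len(hits)
        for h in hits:
            span = (h.offset, h.offset + sm.width)
            if mid == design.motif_id and span in spans:
                intended += 1
            else:
                unintended += 1
    return intended, unintended, per_motif


def build_promoter(
    pwm: Pwm,
    library: list[Pwm],
    cfg: DesignConfig | None = None,
) -> PromoterDesign:
    """Compile one motif into a validated tandem-array promoter design.

    The binding site is the strict consensus of `pwm`; the repeat count
    targets ``cfg.target_site_bp`` of total sites; spacers are screened
    against the full library (with `pwm` added if absent).
    """
    cfg = cfg or DesignConfig()
    if all(p.id != pwm.id for p in library):
        library = list(library) + [pwm]
    screen = ScreeningLibrary.from_pwms(library, cfg.screen_alpha)
    site = consensus_site(pwm, "strict")
    r = repeat_count(len(site), cfg.target_site_bp)
    spacers, warnings = choose_spacers(site, r, screen, cfg, pwm.id)
    design = PromoterDesign(
        tf_name=pwm.tf_name,
        motif_id=pwm.id,
        site_seq=site,
        repeats=r,
        spacer_seqs=spacers,
        core_promoter_seq=cfg.core_promoter_seq,
        core_promoter_name=cfg.core_promoter_name,
        warnings=warnings,
    )
    intended, unintended, _ = validate_design(design, screen)
    design.intended_hits = intended
    design.unintended_hits = unintended
    if unintended > 0 and not warnings:
        design.warnings.append(
            f"validation found {unintended} unintended library hit(s) in the "
            "assembled construct (core promoter included)"
        )
    return design
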