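"""Differential peak selection and motif enrichment testing.

Two stages of the state-comparison analysis:

* :func:`select_differential_peaks` takes a peaks x samples count matrix
  with target/reference condition labels, normalizes to counts per million,
  and calls state-specific peaks by a fold-change + FDR rule (defaults:
  fold change > 2, BH FDR < 0.05).  Significance comes from a pooled
  two-proportion chi-square test (per peak: this peak's pooled count versus
  the rest of the library, target pool versus reference pool, with Yates
  continuity correction).

* :func:`motif_enrichment` scores every library motif for over-representation
  in target versus background peaks under the ZOOPS (zero-or-one occurrence
  per sequence) reduction: a 2x2 table of peaks with/without a hit is tested
  with a one-sided Fisher exact test, and BH adjustment is applied across
  motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import CountMatrix, PeakSet
from .motifs import Pwm, log_odds, threshold_for_pvalue, UNIFORM_BACKGROUND
from .scanning import peaks_with_hit

DEFAULT_HIT_ALPHA = 1e-4


@dataclass(frozen=True)
class DiffPeakResult:
    peak_id: str
    mean_target: float  # CPM-normalized condition mean
    mean_reference: float
    log2_fc: float
    p_value: float
    q_value: float
    call: str  # target_specific | reference_specific | unchanged


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-motif 2x2 contingency summary for target vs background peaks."""

    motif_id: str
    tf_name: str
    n_target: int
    N_target: int
    n_bg: int
    N_bg: int
    fold_enrichment: float
    p_value: float  # one-sided (enrichment direction)
    q_value: float  # BH across the library


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order, clipped
    to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def _two_proportion_chi2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized chi-square test with Yates continuity correction on 2x2
    tables [[a, b], [c, d]]; returns two-sided p-values (1 where a margin
    is empty)."""
    a, b, c, d = (x.astype(float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.abs(a * d - b * c) - n / 2
        diff = np.maximum(diff, 0.0)
        stat = n * diff**2 / denom
    p = np.where(denom > 0, stats.chi2.sf(stat, df=1), 1.0)
    return p


def select_differential_peaks(
    cm: CountMatrix, fc_min: float = 2.0, fdr_max: float = 0.05
) -> list[DiffPeakResult]:
    """Call state-specific peaks from a two-condition count matrix.

    Counts are scaled to counts per million per sample; condition means get
    a +0.5 stabilizer before the log2 fold change.  Raw pooled counts feed
    the per-peak two-proportion chi-square; q-values are BH across peaks.
    A peak is ``target_specific`` iff log2_fc > log2(fc_min) and
    q < fdr_max (mirrored for ``reference_specific``).
    """
    counts = cm.counts
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("count matrix is all zero")
    libsizes = counts.sum(axis=0)
    if (libsizes == 0).any():
        raise ValueError(f"sample(s) with zero total counts: "
                         f"{list(libsizes.index[libsizes == 0])}")
    cpm = counts / libsizes.to_numpy()[None, :] * 1e6
    t_samples = cm.samples("target")
    r_samples = cm.samples("reference")
    mean_t = cpm[t_samples].mean(axis=1).to_numpy()
    mean_r = cpm[r_samples].mean(axis=1).to_numpy()
    log2_fc = np.log2((mean_t + 0.5) / (mean_r + 0.5))

    pooled_t = counts[t_samples].sum(axis=1).to_numpy()
    pooled_r = counts[r_samples].sum(axis=1).to_numpy()
    tot_t, tot_r = pooled_t.sum(), pooled_r.sum()
    p = _two_proportion_chi2(pooled_t, tot_t - pooled_t, pooled_r, tot_r - pooled_r)
    q = bh_adjust(p)

    lo = np.log2(fc_min)
    results = []
    for i, peak_id in enumerate(counts.index):
        if log2_fc[i] > lo and q[i] < fdr_max:
            call = "target_specific"
        elif log2_fc[i] < -lo and q[i] < fdr_max:
            call = "reference_specific"
        else:
            call = "unchanged"
        results.append(
            DiffPeakResult(
                peak_id=str(peak_id),
                mean_target=float(mean_t[i]),
                mean_reference=float(mean_r[i]),
                log2_fc=float(log2_fc[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                call=call,
            )
        )
    return results


def motif_enrichment(
    motifs: list[Pwm],
    target: PeakSet,
    background: PeakSet,
    hit_alpha: float = DEFAULT_HIT_ALPHA,
    bg_freqs: np.ndarray | None = None,
) -> list[EnrichmentResult]:
    """Test each motif for enrichment among target vs background peaks.

    For every motif, a per-window score threshold at tail probability
    `hit_alpha` is derived from the exact background score distribution,
    both peak sets are reduced to ZOOPS presence counts, and the 2x2 table
    is tested with the one-sided Fisher exact test (alternative: more hits
    in target).  Fold enrichment is the ratio of hit fractions, with a
    Haldane 0.5 correction applied when the background count is zero.
    Results are sorted by p ascending, ties by motif_id; q-values are BH
    across the library.
    """
    if not motifs:
        raise ValueError("motif library is empty")
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background peak sets must be non-empty")
    bg = UNIFORM_BACKGROUND if bg_freqs is None else np.asarray(bg_freqs, float)

    rows = []
    for pwm in motifs:
        sm = log_odds(pwm, bg)
        thr = threshold_for_pvalue(sm, hit_alpha)
        n_t, N_t = peaks_with_hit(sm, target, thr.threshold)
        n_b, N_b = peaks_with_hit(sm, background, thr.threshold)
        table = [[n_t, N_t - n_t], [n_b, N_b - n_b]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        if n_b == 0:
            fold = ((n_t + 0.5) / (N_t + 1)) / ((n_b + 0.5) / (N_b + 1))
        else:
            fold = (n_t / N_t) / (n_b / N_b)
        rows.append((pwm, n_t, N_t, n_b, N_b, fold, p))

    q = bh_adjust([r[6] for r in rows])
    results = [
        EnrichmentResult(
            motif_id=pwm.id,
            tf_name=pwm.tf_name,
            n_target=n_t,
            N_target=N_t,
            n_bg=n_b,
            N_bg=N_b,
            fold_enrichment=float(fold),
            p_value=p,
            q_value=float(qi),
        )
        for (pwm, n_t, N_t, n_b, N_b, fold, p), qi in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.motif_id))
    return results
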