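# Methods

## Scope and model

`synprom` operates downstream of alignment and peak calling: its inputs are
peak intervals (BED, 0-based half-open), peak or genome sequences (FASTA),
optional peaks × samples read counts (TSV) with a two-condition design, and
a motif library (JASPAR PFM counts or Homer probability matrices). All
internal coordinates are 0-based half-open; the only +1/inclusive
conversion happens at GenBank serialization, delegated to biopython.

The analysis chain is: (1) optional selection of state-specific peaks from
counts; (2) per-dataset motif enrichment in target versus background peak
sequences; (3) intersection of significantly enriched motifs across K
independent datasets; (4) compilation of each conserved motif into a
tandem-array synthetic promoter with validation.

## Motif model and exact hit thresholds

A motif is a position probability matrix over A,C,G,T with strictly
positive columns (JASPAR counts are smoothed with a pseudocount, default
1.0 per base: p = (c + 1)/(Σc + 4); Homer files already carry
probabilities and are only renormalized, with zeros floored at 1e-4).
Scoring is log₂(p/b) in bits against a background composition b (uniform
by default; a mononucleotide composition estimated from user background
peaks can be supplied).

Hit calling needs a score threshold with a known false-positive rate. The
scores are discretized to integers at scale 1000 (0.001-bit resolution) and
the exact distribution of the total score of a random background W-mer is
computed by convolving the four-point per-column distributions. The
threshold for tail probability α is the smallest integer score t with
P(score ≥ t) ≤ α. Scanning itself uses the same integer matrix, so hit
calls and tail probabilities are exactly consistent; windows containing N
receive a sentinel score below any threshold. Default α = 1e-4 per window
per strand — comparable stringency to common known-motif scanners — and
both strands are scanned, since TF binding is strand-agnostic.

Degenerate cases: if α is so small that even the maximum achievable score
has a larger tail (unavoidable for narrow motifs: a perfect width-4 match
has background probability 0.25⁴ ≈ 3.9e-3), the threshold clamps to the
maximum score, the true achieved tail is reported, and an `attainable`
flag is cleared. This keeps hit calling non-vacuous for narrow motifs
while reporting honestly that the requested rate was not met.

## Differential peaks

Counts are scaled to counts per million per sample; condition means get a
+0.5 stabilizer before log₂ fold change (so empty peaks are defined and
extreme ratios are damped — reported fold changes are the stabilized
values). Significance uses a pooled two-proportion χ² test with Yates
correction: per peak, the pooled target-condition count versus the rest of
the target pool, against the same split in the reference pool. This is
deliberately simpler than a replicate-dispersion model (negative binomial):
no dispersion information is assumed available, and the fold-change/FDR
call semantics stay exactly testable. Calls use log₂FC > log₂(2) and BH
q < 0.05 by default; with strong replicate structure, a dedicated
count-model package is the better tool and its peak calls can be fed in
directly as BED.

## Enrichment and intersection

Peaks reduce to ZOOPS presence/absence; each motif's 2×2 table is tested
with the one-sided Fisher exact test (enrichment direction), and BH
adjustment is applied across the library. Fold enrichment uses a Haldane
0.5 correction when the background count is zero. Results order is p
ascending, ties broken by motif id, for reproducibility.

Because the test is exact and the tables discrete, its null rejection rate
sits *below* the nominal level (P(p ≤ α) ≤ α, with the gap largest at small
hit counts; at the default α and 200 peaks/side the empirical fraction of
p < 0.05 under a motif-free simulation is ≈ 0.02). The test is therefore
valid but conservative; property tests assert the validity bound rather
than exact nominal calibration, which no discrete exact test attains.

Intersection across K datasets keeps motifs with p < 0.05 in every
dataset. `by_id` matches case-insensitive motif ids (homogeneous
libraries); `by_similarity` matches PWMs by their best ungapped alignment —
all offsets with ≥ 4 overlapping columns, both orientations, scored by the
mean column-wise Pearson correlation of probability columns (columns sum
to 1, so the per-column mean is exactly 0.25; two uniform columns
correlate 1, uniform against non-uniform 0). Matching is greedy
best-first one-to-one with a similarity floor (default 0.80, a
conventional PWM-correlation cutoff); greedy rather than optimal bipartite
matching is a documented simplification adequate at library scale.

## Promoter design

The binding site is the strict consensus of the PWM (per-column argmax,
ties broken A<C<G<T). The repeat count r = max(1, round(W·target/W)) —
half-up rounding of target_site_bp/W — targets 120 bp of total sites; the
spacer length is 3 bp; the array sits 5'→3' upstream of the minimal core
promoter. These layout constants are configurable.

Spacers are screened, not arbitrary: candidates (all 64 triplets,
lexicographic, first-fit) are tried uniformly at all junctions; a candidate
is accepted only if scanning the assembled array against every library
motif at its threshold yields exactly r intended-motif occurrences and
zero others. If no uniform candidate passes, junctions are filled left to
right; if a junction has no clean candidate the minimal-violation spacer
is taken and a warning recorded. Validation rescans the full construct
(core promoter included) on both strands; occurrences are counted per
window (a forward and reverse hit on the same window is one occurrence —
otherwise near-palindromic consensi would double-count every site), and
any own-motif occurrence off the site register counts as unintended.

The shipped default core promoter is a synthetic 60-mer placeholder with a
TATA box, clearly not a cloned minimal CMV fragment; real constructs
should supply the exact minCMV sequence of their destination vector via
`DesignConfig`/`--core-promoter`. Repeats are identical consensus copies;
PWM-sampled site variants are not implemented.

## Synthetic studies

The simulator draws peak sequences i.i.d. from a mononucleotide background
(order-0; sufficient for calibration and recovery testing, and simple to
reason about) and plants at most one motif instance per selected peak
(matching ZOOPS), each peak chosen independently with the configured
probability, the W-mer sampled column-wise from the PWM, offset uniform
among positions not overlapping earlier insertions, strand uniform. Truth
records store the exact inserted word and position. Reference conditions:
3 datasets, 200 peaks per side, 200 bp peaks, planting probability 0.6 in
target and 0.05 in background peaks; shared motifs go into every dataset,
private motifs into exactly one, so the expected intersection is exactly
the shared set. Dataset d uses derived seed (seed + d); all outputs are
pure functions of configuration, library and seed.

`random_library` generates well-separated high-information PWMs (peaked
Dirichlet columns, consensus probability floored at 0.75) — a stand-in for
curated motif collections. What the simulator does *not* model: GC
composition bias and higher-order sequence structure, peak-width and
coverage heterogeneity, Tn5 insertion bias, replicate dispersion in
counts, and correlated/overlapping motifs of real TF families. Passing
recovery tests therefore demonstrates correctness of the machinery, not
performance on real chromatin data.

## Numerical choices

- Discretization scale 1000 bounds the convolution support (hard cap 2e7
  entries; exceeding it raises with advice to coarsen the scale).
- BH is the standard step-up (q(i) = min over j ≥ i of p(j)·m/j, clipped
  to 1), returned in input order.
- The per-peak χ² is the closed-form Yates-corrected statistic, vectorized
  across peaks; it matches `scipy.stats.chi2_contingency` to 1e-10.
- Test problem sizes (200 peaks/side, 8–50 motifs, 20 replicates) were
  chosen as the smallest scales at which the statistical properties under
  test are well-resolved.

## Known limitations

- Absolute enrichment p-values are not comparable to Homer's (different
  background handling and statistic); rankings are.
- No GC-matched or resampled backgrounds; the background peak set carries
  that burden.
- Greedy similarity matching can be suboptimal when one motif matches
  several others near the similarity floor.
- Spacer screening guarantees cleanliness only at the screening thresholds
  and against the supplied library.
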