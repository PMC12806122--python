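"""Synthetic multi-dataset studies with known planted truth.

Emulates, at desk scale, a study comparing open-chromatin peak sets from K
independent models of the same cell state (e.g. mouse and human T cell
exhaustion models): for each dataset, target (state-specific) and background
peak sequences are drawn from an i.i.d. mononucleotide background, and motif
instances are planted into target peaks at a controlled per-peak probability
(one instance per selected peak, matching the ZOOPS statistic downstream).
"Shared" motifs are planted in every dataset's targets; "private" motifs in
exactly one dataset — so enrich + intersect has an exact expected answer.

Everything is a pure function of (configuration, library, seed): fixed seeds
give byte-identical FASTA/BED/TSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import CountMatrix, GenomicInterval, PeakSet, revcomp
from .motifs import BASES, Pwm


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted motif instance."""

    peak_name: str
    motif_id: str
    offset: int
    strand: str  # "+" | "-"
    word: str  # the sequence actually written into the peak (forward strand)


@dataclass
class SimConfig:
    """Study-generation parameters.

    Defaults describe the reference simulation conditions used throughout
    the test suite: 200 peaks per side of length 200 bp, uniform base
    composition, three datasets, motifs planted in 60% of target peaks and
    5% of background peaks.
    """

    n_peaks_target: int = 200
    n_peaks_background: int = 200
    peak_len: int = 200
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plant_prob_target: float = 0.6
    plant_prob_background: float = 0.05
    k_datasets: int = 3
    n_shared: int | None = None  # None: every library motif is shared
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.background_freqs, float)
        if f.shape != (4,) or np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-6):
            raise ValueError("background_freqs must be 4 non-negative values summing to 1")
        for p in (self.plant_prob_target, self.plant_prob_background):
            if not 0 <= p <= 1:
                raise ValueError("planting probabilities must lie in [0, 1]")
        if min(self.n_peaks_target, self.n_peaks_background, self.peak_len) < 1:
            raise ValueError("peak counts and length must be >= 1")
        if self.k_datasets < 1:
            raise ValueError("k_datasets must be >= 1")


@dataclass
class SimDataset:
    target: PeakSet
    background: PeakSet
    truth: list[PlantRecord]


@dataclass
class SimStudy:
    """K synthetic datasets plus planted truth and an optional count matrix."""

    datasets: list[SimDataset]
    shared_motif_ids: list[str]
    private_motif_ids: dict[str, int]  # motif id -> dataset index it belongs to
    counts: CountMatrix | None = None


def simulate_background(
    n: int,
    length: int,
    freqs=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    label: str = "sim",
) -> PeakSet:
    """n i.i.d. background sequences of the given length as a PeakSet.

    Peak names are ``<label>_<i>`` (1-based); intervals live on pseudo
    chromosomes named after each peak so BED/FASTA exports stay consistent.
    """
    f = np.asarray(freqs, float)
    if np.any(f < 0):
        raise ValueError("background frequencies must be non-negative")
    f = f / f.sum()
    rng = np.random.default_rng(seed)
    base_arr = np.array(list(BASES))
    intervals, seqs = [], []
    for i in range(n):
        seq = "".join(base_arr[rng.choice(4, size=length, p=f)])
        name = f"{label}_{i + 1}"
        intervals.append(GenomicInterval(name, 0, length, name))
        seqs.append(seq)
    return PeakSet(label=label, intervals=intervals, sequences=seqs)


def _sample_word(pwm: Pwm, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pwm.prob[i] / pwm.prob[i].sum()) for i in range(pwm.width)]
    return "".join(BASES[c] for c in cols)


def _free_offsets(length: int, w: int, occupied: list[tuple[int, int]]) -> np.ndarray:
    offs = np.arange(length - w + 1)
    if not occupied:
        return offs
    ok = np.ones(len(offs), bool)
    for s, e in occupied:
        ok &= (offs + w <= s) | (offs >= e)
    return offs[ok]


def plant_motifs(
    peaks: PeakSet,
    pwm: Pwm,
    prob: float,
    seed: int | np.random.Generator = 0,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[PeakSet, list[PlantRecord]]:
    """Plant at most one instance of `pwm` per peak, each peak selected
    independently with probability `prob`.

    In a selected peak, a W-mer is sampled column-wise from the PWM and
    written over the sequence at a uniformly chosen free offset and strand
    (minus strand: the reverse complement is written).  `occupied` (peak
    name -> list of spans) lets callers plant several motifs into the same
    peak set without overwriting earlier insertions; it is updated in
    place.  Peaks with no free offset are skipped.
    """
    if not peaks.has_sequences:
        raise ValueError("peaks need sequences before planting")
    w = pwm.width
    if any(len(s) < w for s in peaks.sequences):
        raise ValueError(f"peak shorter than motif width {w}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    occupied = occupied if occupied is not None else {}
    new_seqs: list[str] = []
    records: list[PlantRecord] = []
    for iv, seq in zip(peaks.intervals, peaks.sequences):
        if rng.random() >= prob:
            new_seqs.append(seq)
            continue
        spans = occupied.setdefault(iv.name, [])
        free = _free_offsets(len(seq), w, spans)
        if len(free) == 0:
            new_seqs.append(seq)
            continue
        off = int(rng.choice(free))
        strand = "+" if rng.random() < 0.5 else "-"
        word = _sample_word(pwm, rng)
        inserted = word if strand == "+" else revcomp(word)
        new_seqs.append(seq[:off] + inserted + seq[off + w :])
        spans.append((off, off + w))
        records.append(PlantRecord(iv.name, pwm.id, off, strand, inserted))
    out = PeakSet(label=peaks.label, intervals=list(peaks.intervals), sequences=new_seqs)
    return out, records


def random_library(
    n_motifs: int,
    width: int = 10,
    seed: int = 0,
    concentration: float = 0.3,
    info_floor: float = 0.75,
) -> list[Pwm]:
    """A library of random, well-separated, high-information PWMs.

    Columns are Dirichlet draws (small `concentration` gives peaked
    columns); columns whose maximum probability falls below `info_floor`
    are sharpened toward their argmax so planted instances are reliably
    recoverable by scanning.
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_motifs):
        prob = rng.dirichlet([concentration] * 4, size=width)
        prob = np.clip(prob, 1e-3, None)
        prob /= prob.sum(axis=1, keepdims=True)
        for j in range(width):
            if prob[j].max() < info_floor:
                arg = int(prob[j].argmax())
                boost = np.full(4, (1 - info_floor) / 3)
                boost[arg] = info_floor
                prob[j] = boost
        pwms.append(Pwm(id=f"SIM{i + 1:03d}", tf_name=f"TF{i + 1}", prob=prob,
                        source_dialect="synthetic"))
    return pwms


def simulate_counts(
    target_peak_names: list[str],
    stable_peak_names: list[str],
    fold: float = 4.0,
    base_mean: float = 50.0,
    n_reps: int = 2,
    seed: int = 0,
) -> CountMatrix:
    """Count matrix in which `target_peak_names` rows follow the given fold
    change (target over reference) and `stable_peak_names` rows are flat;
    counts are Poisson around the condition means."""
    rng = np.random.default_rng(seed)
    peaks = list(target_peak_names) + list(stable_peak_names)
    means_t = np.array([base_mean * fold] * len(target_peak_names) + [base_mean] * len(stable_peak_names))
    means_r = np.full(len(peaks), base_mean)
    data = {}
    cond = {}
    for rep in range(n_reps):
        s = f"target_{rep + 1}"
        data[s] = rng.poisson(means_t)
        cond[s] = "target"
    for rep in range(n_reps):
        s = f"reference_{rep + 1}"
        data[s] = rng.poisson(means_r)
        cond[s] = "reference"
    counts = pd.DataFrame(data, index=pd.Index(peaks, name="peak_id"))
    return CountMatrix(counts=counts, condition_of_sample=cond)


def simulate_study(
    cfg: SimConfig,
    library: list[Pwm],
    with_counts: bool = False,
    count_fold: float = 4.0,
) -> SimStudy:
    """Generate a K-dataset study with shared and dataset-private motifs.

    The first ``cfg.n_shared`` library motifs (all of them when None) are
    planted into every dataset's target peaks at ``plant_prob_target`` and
    into its background peaks at ``plant_prob_background``; the remaining
    motifs are assigned round-robin, one dataset each, and planted only
    there.  Dataset d uses the derived seed ``cfg.seed + d`` so single
    datasets are reproducible in isolation.
    """
    if not library:
        raise ValueError("motif library is empty")
    n_shared = len(library) if cfg.n_shared is None else cfg.n_shared
    if not 0 <= n_shared <= len(library):
        raise ValueError("n_shared out of range")
    shared = library[:n_shared]
    private = library[n_shared:]
    private_of = {p.id: i % cfg.k_datasets for i, p in enumerate(private)}

    datasets: list[SimDataset] = []
    for d in range(cfg.k_datasets):
        rng = np.random.default_rng(cfg.seed + d)
        target = simulate_background(
            cfg.n_peaks_target, cfg.peak_len, cfg.background_freqs,
            seed=rng.integers(2**31), label=f"ds{d + 1}_t",
        )
        background = simulate_background(
            cfg.n_peaks_background, cfg.peak_len, cfg.background_freqs,
            seed=rng.integers(2**31), label=f"ds{d + 1}_b",
        )
        truth: list[PlantRecord] = []
        occ_t: dict[str, list[tuple[int, int]]] = {}
        occ_b: dict[str, list[tuple[int, int]]] = {}
        planted_here = list(shared) + [p for p in private if private_of[p.id] == d]
        for pwm in planted_here:
            target, rec = plant_motifs(target, pwm, cfg.plant_prob_target, rng, occ_t)
            truth.extend(rec)
            background, rec = plant_motifs(
                background, pwm, cfg.plant_prob_background, rng, occ_b
            )
            truth.extend(rec)
        datasets.append(SimDataset(target=target, background=background, truth=truth))

    counts = None
    if with_counts:
        ds1 = datasets[0]
        counts = simulate_counts(
            [iv.name for iv in ds1.target.intervals],
            [iv.name for iv in ds1.background.intervals],
            fold=count_fold,
            seed=cfg.seed + 10_000,
        )
    return SimStudy(
        datasets=datasets,
        shared_motif_ids=[p.id for p in shared],
        private_motif_ids=private_of,
        counts=counts,
    )


def write_truth_tsv(records: list[PlantRecord], path) -> None:
    pd.DataFrame(
        [
            {"peak_name": r.peak_name, "motif_id": r.motif_id, "offset": r.offset,
             "strand": r.strand, "word": r.word}
            for r in records
        ],
        columns=["peak_name", "motif_id", "offset", "strand", "word"],
    ).to_csv(path, sep="\t", index=False)
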