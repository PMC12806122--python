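"""Readers and writers for every external representation the pipeline touches.

Plain-text genomics formats only: BED intervals, FASTA sequences, JASPAR PFM
and Homer ``.motif`` libraries, TSV count matrices and reports, and GenBank
flat files for assembled promoter constructs.  Internal coordinates are
0-based half-open throughout; the +1 inclusive conversion happens only at
GenBank serialization (and is handled by biopython).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .motifs import BASES, Pwm

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .design import PromoterDesign

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map non-ACGT characters to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class GenomicInterval:
    """A named genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Named genomic intervals with (optionally) attached sequences.

    The unit of chromatin-state evidence: one peak set per condition per
    dataset.  Interval names must be unique; when sequences are attached
    each must match the length of its interval.
    """

    label: str
    intervals: list[GenomicInterval]
    sequences: list[str] | None = None

    def __post_init__(self) -> None:
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError(f"peak set {self.label!r}: interval names not unique")
        if self.sequences is not None:
            if len(self.sequences) != len(self.intervals):
                raise ValueError("sequences/intervals length mismatch")
            for iv, seq in zip(self.intervals, self.sequences):
                if len(seq) != len(iv):
                    raise ValueError(
                        f"sequence length {len(seq)} != interval length "
                        f"{len(iv)} for peak {iv.name!r}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def has_sequences(self) -> bool:
        return self.sequences is not None


class BedParseError(ValueError):
    """Raised on a malformed BED line; carries the offending line number."""


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3/BED4(+score) file into a PeakSet (no sequences attached).

    Missing names are auto-generated as ``peak_<index>`` (1-based file
    order).  Coordinates are kept 0-based half-open as in the file.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{len(intervals) + 1}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=label or path.stem, intervals=intervals)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED4(+score when present)."""
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")


def attach_sequences(peaks: PeakSet, genome: Mapping[str, str]) -> PeakSet:
    """Attach genome subsequences to every interval of a PeakSet.

    `genome` is any mapping from chromosome name to sequence — a plain dict
    or a :class:`pyfaidx.Fasta` (whose records slice like strings).
    Sequences are uppercased with non-ACGT characters mapped to N.

    Raises
    ------
    KeyError
        If an interval's chromosome is absent or the interval runs past the
        chromosome end; the message names the offending interval.
    """
    seqs: list[str] = []
    for iv in peaks.intervals:
        if iv.chrom not in genome:
            raise KeyError(f"peak {iv.name!r}: chromosome {iv.chrom!r} not in genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise KeyError(
                f"peak {iv.name!r}: interval end {iv.end} beyond "
                f"{iv.chrom!r} length {len(chrom_seq)}"
            )
        seqs.append(clean_sequence(str(chrom_seq[iv.start : iv.end])))
    return PeakSet(label=peaks.label, intervals=list(peaks.intervals), sequences=seqs)


def read_fasta_peaks(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a FASTA of peak sequences as a PeakSet.

    Record ids become peak names; intervals are synthesized on a pseudo
    chromosome named after each record (start 0) so the set can round-trip
    through BED-style reports.
    """
    path = Path(path)
    intervals, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = clean_sequence(str(rec.seq))
        intervals.append(GenomicInterval(rec.id, 0, len(seq), rec.id))
        seqs.append(seq)
    return PeakSet(label=label or path.stem, intervals=intervals, sequences=seqs)


def write_fasta_peaks(peaks: PeakSet, path: str | Path, width: int = 80) -> None:
    """Write attached peak sequences as FASTA (names as headers)."""
    if not peaks.has_sequences:
        raise ValueError("peak set has no sequences attached")
    with open(path, "w") as fh:
        for iv, seq in zip(peaks.intervals, peaks.sequences):
            fh.write(f">{iv.name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Motif libraries


class MotifParseError(ValueError):
    pass


def _dedupe_ids(pwms: list[Pwm]) -> list[Pwm]:
    """Suffix duplicate motif ids with _2, _3, ... (merged libraries load)."""
    seen: dict[str, int] = {}
    out = []
    for p in pwms:
        n = seen.get(p.id, 0) + 1
        seen[p.id] = n
        if n == 1:
            out.append(p)
        else:
            out.append(Pwm(f"{p.id}_{n}", p.tf_name, p.prob, p.family, p.source_dialect))
    return out


def _read_jaspar(path: Path, pseudocount: float) -> list[Pwm]:
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise MotifParseError(f"{path}: not parseable as JASPAR PFM: {exc}") from exc
    pwms = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        if np.any(counts < 0):
            raise MotifParseError(f"{path}: motif {m.matrix_id}: negative count")
        sums = counts.sum(axis=1)
        if pseudocount <= 0 and np.any(sums == 0):
            raise MotifParseError(
                f"{path}: motif {m.matrix_id}: zero-sum column with pseudocount 0"
            )
        prob = (counts + pseudocount) / (sums + 4 * pseudocount)[:, None]
        pwms.append(
            Pwm(
                id=m.matrix_id or m.name,
                tf_name=m.name or m.matrix_id,
                prob=prob,
                source_dialect="jaspar",
            )
        )
    return pwms


def _read_homer(path: Path) -> list[Pwm]:
    """Parse a Homer .motif file: '>consensus name threshold' then
    per-position probability rows (A C G T)."""
    pwms: list[Pwm] = []
    header: list[str] | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if not rows:
            raise MotifParseError(f"{path}:{lineno}: motif {header[1]!r} has no rows")
        prob = np.array(rows)
        # Homer rows are probabilities already; renormalize only.  Zeros are
        # floored so downstream log-odds stay finite.
        prob = np.where(prob == 0, 1e-4, prob)
        prob = prob / prob.sum(axis=1, keepdims=True)
        name = header[1] if len(header) > 1 else header[0]
        tf = name.split("(")[0].split("/")[0]
        pwms.append(Pwm(id=name, tf_name=tf, prob=prob, source_dialect="homer"))
        header, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split("\t")
                if len(header) == 1:
                    header = line[1:].split()
            else:
                if header is None:
                    raise MotifParseError(f"{path}:{lineno}: probability row before header")
                parts = line.split()
                if len(parts) != 4:
                    raise MotifParseError(
                        f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                    )
                try:
                    vals = [float(x) for x in parts]
                except ValueError as exc:
                    raise MotifParseError(f"{path}:{lineno}: non-numeric entry") from exc
                if any(v < 0 for v in vals):
                    raise MotifParseError(f"{path}:{lineno}: negative entry")
                if sum(vals) == 0:
                    raise MotifParseError(f"{path}:{lineno}: zero-sum row")
                rows.append(vals)
    flush(-1)
    return pwms


def read_motifs(
    path: str | Path, dialect: str = "jaspar", pseudocount: float = 1.0
) -> list[Pwm]:
    """Read a motif library file into a list of Pwm.

    Parameters
    ----------
    path : path
        JASPAR PFM file (count blocks) or Homer .motif file.
    dialect : {"jaspar", "homer"}
    pseudocount : float
        Added per base to each JASPAR count column before normalization:
        ``p = (c + pc) / (sum + 4 pc)``.  Homer files carry probabilities,
        not counts, and are renormalized as-is (zeros floored at 1e-4).

    Duplicate motif ids are suffixed ``_2``, ``_3``, ... so merged
    (e.g. mouse + human) libraries load without collisions.
    """
    path = Path(path)
    if dialect == "jaspar":
        pwms = _read_jaspar(path, pseudocount)
    elif dialect == "homer":
        pwms = _read_homer(path)
    else:
        raise ValueError(f"unknown motif dialect {dialect!r}")
    return _dedupe_ids(pwms)


def write_jaspar(pwms: Iterable[Pwm], path: str | Path) -> None:
    """Write motifs in JASPAR PFM layout (probability-valued matrices).

    Reading the file back with ``pseudocount=0`` reproduces the
    probabilities to full float precision.
    """
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id}\t{p.tf_name}\n")
            for bi, b in enumerate(BASES):
                vals = " ".join(f"{x:.10g}" for x in p.prob[:, bi])
                fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Count matrices


@dataclass
class CountMatrix:
    """Peaks x samples read-count matrix with a two-condition design."""

    counts: pd.DataFrame  # index: peak ids, columns: sample ids
    condition_of_sample: dict[str, str]  # sample -> "target" | "reference"

    def __post_init__(self) -> None:
        conds = set(self.condition_of_sample.values())
        if not conds <= {"target", "reference"}:
            raise ValueError(f"conditions must be target/reference, got {conds}")
        missing = set(self.counts.columns) - set(self.condition_of_sample)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        for cond in ("target", "reference"):
            if not any(v == cond for v in self.condition_of_sample.values()):
                raise ValueError(f"no sample labeled {cond!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition_of_sample[s] == condition]


def read_count_matrix(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column peak_id) plus a two-column
    sample -> condition file."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(
        conditions_path, sep="\t", header=None, names=["sample", "condition"]
    )
    mapping = dict(zip(cond["sample"].astype(str), cond["condition"].astype(str)))
    return CountMatrix(counts=counts, condition_of_sample=mapping)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, conditions_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="peak_id")
    with open(conditions_path, "w") as fh:
        for s in cm.counts.columns:
            fh.write(f"{s}\t{cm.condition_of_sample[s]}\n")


# ---------------------------------------------------------------------------
# TSV reports

ENRICHMENT_COLUMNS = [
    "motif_id", "tf_name", "n_target", "N_target", "n_bg", "N_bg",
    "fold_enrichment", "p_value", "q_value",
]

DIFFPEAK_COLUMNS = [
    "peak_id", "mean_target", "mean_reference", "log2_fc", "p_value",
    "q_value", "call",
]


def write_enrichment_tsv(results, path: str | Path) -> None:
    """Write EnrichmentResult rows (fields in canonical order)."""
    pd.DataFrame(
        [{c: getattr(r, c) for c in ENRICHMENT_COLUMNS} for r in results],
        columns=ENRICHMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_enrichment_tsv(path: str | Path):
    """Read an enrichment report back into EnrichmentResult rows."""
    from .diffenrich import EnrichmentResult

    df = pd.read_csv(path, sep="\t")
    return [
        EnrichmentResult(
            motif_id=str(row.motif_id), tf_name=str(row.tf_name),
            n_target=int(row.n_target), N_target=int(row.N_target),
            n_bg=int(row.n_bg), N_bg=int(row.N_bg),
            fold_enrichment=float(row.fold_enrichment),
            p_value=float(row.p_value), q_value=float(row.q_value),
        )
        for row in df.itertuples()
    ]


def write_diffpeaks_tsv(results, path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in DIFFPEAK_COLUMNS} for r in results],
        columns=DIFFPEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_conserved_tsv(conserved, path: str | Path) -> None:
    """Conserved-set report: canonical id, then per-dataset id/p/q columns."""
    cols = ["canonical_id"]
    for d in range(conserved.k):
        cols += [f"dataset{d + 1}_id", f"dataset{d + 1}_p", f"dataset{d + 1}_q"]
    rows = []
    for e in conserved.entries:
        row: dict[str, object] = {"canonical_id": e.canonical_id}
        for d in range(conserved.k):
            row[f"dataset{d + 1}_id"] = e.dataset_motif_ids[d]
            row[f"dataset{d + 1}_p"] = e.p_values[d]
            row[f"dataset{d + 1}_q"] = e.q_values[d]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.6g")


DESIGN_COLUMNS = [
    "tf_name", "motif_id", "site_seq", "repeats", "total_site_bp",
    "full_length", "intended_hits", "unintended_hits", "warnings",
]


def write_designs_tsv(designs, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "tf_name": d.tf_name, "motif_id": d.motif_id,
                "site_seq": d.site_seq, "repeats": d.repeats,
                "total_site_bp": d.total_site_bp,
                "full_length": len(d.full_seq),
                "intended_hits": d.intended_hits,
                "unintended_hits": d.unintended_hits,
                "warnings": "; ".join(d.warnings),
            }
            for d in designs
        ],
        columns=DESIGN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenBank output for promoter designs


def write_genbank(design: "PromoterDesign", path: str | Path) -> None:
    """Serialize an assembled promoter construct as a single GenBank record.

    One ``misc_binding`` feature per binding-site repeat (label
    ``<TF>_site_<i>``), one ``misc_feature`` per spacer, and one
    ``promoter`` feature for the core promoter.  Internal 0-based half-open
    spans are rendered in GenBank's 1-based inclusive convention.
    """
    if design.repeats < 1 or not design.full_seq:
        raise ValueError("refusing to write an empty design (no repeats)")
    record = SeqRecord(
        Seq(design.full_seq),
        id=design.motif_id[:16] or "design",
        name=(design.tf_name or "design")[:16],
        description=f"synthetic promoter: {design.repeats}x {design.tf_name} "
        f"site upstream of {design.core_promoter_name}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    site_i = 0
    for kind, start, end in design.layout:
        loc = SimpleLocation(start, end, strand=1)
        if kind == "site":
            site_i += 1
            record.features.append(
                SeqFeature(loc, type="misc_binding",
                           qualifiers={"label": [f"{design.tf_name}_site_{site_i}"]})
            )
        elif kind == "spacer":
            record.features.append(
                SeqFeature(loc, type="misc_feature", qualifiers={"label": ["spacer"]})
            )
        elif kind == "core":
            record.features.append(
                SeqFeature(loc, type="promoter",
                           qualifiers={"label": [design.core_promoter_name]})
            )
    SeqIO.write([record], str(path), "genbank")


def read_genbank_features(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read back (type, start, end, label, subsequence) for every feature of
    a single-record GenBank file; coordinates 0-based half-open."""
    record = SeqIO.read(str(path), "genbank")
    out = []
    for f in record.features:
        label = f.qualifiers.get("label", [""])[0]
        s, e = int(f.location.start), int(f.location.end)
        out.append((f.type, s, e, label, str(record.seq[s:e])))
    return out
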