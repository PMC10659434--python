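"""Shared transcript-space data model and file formats.

Everything downstream works in transcript-local coordinates: 0-based,
half-open intervals on the spliced transcript, single (sense) strand.
External files use the field's conventions — GFF3 is 1-based inclusive,
wiggle fixedStep is 1-based — and the readers/writers convert at the
boundary.

The annotation unit is a :class:`Transcript` carrying its CDS interval,
the amino-acid sequence of the CDS (used by the elongation-pause
analysis), and any upstream open reading frames (:class:`UORF`) in its
5'UTR.  Count-level inputs are :class:`CountMatrix` (features x samples,
either ribosome footprints or total mRNA), and per-nucleotide footprint
3'-end tallies are :class:`OccupancyTrack` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationError",
    "CountError",
    "UORF",
    "Transcript",
    "Transcriptome",
    "SampleMeta",
    "CountMatrix",
    "OccupancyTrack",
    "read_annotation",
    "write_annotation",
    "read_counts",
    "write_counts",
    "read_wiggle",
    "write_wiggle",
]

#: near-cognate start codons: one nucleotide away from AUG
NCC_CODONS = frozenset(
    {"CUG", "GUG", "UUG", "ACG", "AGG", "AAG", "AUA", "AUC", "AUU"}
)
START_CLASSES = frozenset({"AUG"}) | NCC_CODONS
UORF_SOURCES = ("annotated", "conserved", "functional")
UORF_EFFECTS = ("inhibitory", "stimulatory", "none")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class AnnotationError(ValueError):
    """Malformed annotation; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CountError(ValueError):
    """Malformed count table or sample sheet."""


@dataclass
class UORF:
    """An upstream ORF in transcript coordinates (0-based, half-open).

    ``end`` excludes the stop codon by default (the translated codons
    only); whether counting windows include the stop is a reader option,
    not a property of the interval itself.
    """

    parent_id: str
    start: int
    end: int
    start_class: str = "AUG"
    source: str = "annotated"
    effect: str = "inhibitory"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"uORF of {self.parent_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if (self.end - self.start) % 3 != 0:
            raise AnnotationError(
                f"uORF of {self.parent_id}: length {self.end - self.start} "
                "not divisible by 3"
            )
        if self.start_class not in START_CLASSES:
            raise AnnotationError(
                f"uORF of {self.parent_id}: start_class {self.start_class!r} "
                "is neither AUG nor a near-cognate codon"
            )
        if self.source not in UORF_SOURCES:
            raise AnnotationError(
                f"uORF of {self.parent_id}: unknown source {self.source!r}"
            )
        if self.effect not in UORF_EFFECTS:
            raise AnnotationError(
                f"uORF of {self.parent_id}: unknown effect {self.effect!r}"
            )

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    @property
    def is_aug(self) -> bool:
        return self.start_class == "AUG"


@dataclass
class Transcript:
    """A spliced transcript with one main CDS and optional uORFs."""

    id: str
    length: int
    cds_start: int
    cds_end: int
    codon_seq: str
    uorfs: list[UORF] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise AnnotationError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"transcript of length {self.length}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise AnnotationError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        if len(self.codon_seq) != self.n_codons:
            raise AnnotationError(
                f"{self.id}: codon_seq length {len(self.codon_seq)} != "
                f"CDS codon count {self.n_codons}"
            )
        for u in self.uorfs:
            if u.parent_id != self.id:
                raise AnnotationError(
                    f"{self.id}: attached uORF has parent {u.parent_id!r}"
                )
            if u.start >= self.cds_start:
                raise AnnotationError(
                    f"{self.id}: uORF start {u.start} not upstream of CDS "
                    f"start {self.cds_start}"
                )
            if u.end > self.length:
                raise AnnotationError(
                    f"{self.id}: uORF end {u.end} beyond transcript"
                )

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3


class Transcriptome:
    """Ordered, id-indexed collection of transcripts."""

    def __init__(self, transcripts: Iterable[Transcript] = ()):
        self._tx: dict[str, Transcript] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.id in self._tx:
            raise AnnotationError(f"duplicate transcript id {t.id!r}")
        self._tx[t.id] = t

    def __len__(self) -> int:
        return len(self._tx)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._tx.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._tx

    def __getitem__(self, tid: str) -> Transcript:
        return self._tx[tid]

    @property
    def ids(self) -> list[str]:
        return list(self._tx)

    def uorfs(self) -> Iterator[tuple[str, int, UORF]]:
        """Yield (uorf_id, index-within-parent, UORF) for every uORF."""
        for t in self:
            for i, u in enumerate(t.uorfs):
                yield f"{t.id}.uORF{i + 1}", i, u


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: genotype x treatment x replicate x assay."""

    name: str
    genotype: str  # "WT" | "mutant"
    treatment: str  # "untreated" | "treated"
    replicate: int
    assay: str  # "RPF" | "RNA"

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "mutant"):
            raise CountError(f"{self.name}: genotype {self.genotype!r}")
        if self.treatment not in ("untreated", "treated"):
            raise CountError(f"{self.name}: treatment {self.treatment!r}")
        if self.assay not in ("RPF", "RNA"):
            raise CountError(f"{self.name}: assay {self.assay!r}")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.genotype, self.treatment)


class CountMatrix:
    """Features x samples count table for one assay (RPF or RNA).

    Counts are non-negative integers.  ``exact=True`` relaxes the
    integrality check for noise-free simulator output carrying exact
    expectations; file IO always enforces integers.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: Sequence[SampleMeta],
        assay: str,
        exact: bool = False,
    ):
        if assay not in ("RPF", "RNA"):
            raise CountError(f"unknown assay {assay!r}")
        names = [s.name for s in samples]
        if len(set(names)) != len(names):
            raise CountError("duplicate sample names")
        if list(counts.columns) != names:
            raise CountError("count columns do not match sample metadata")
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise CountError(f"duplicated feature id(s): {dupes}")
        values = counts.to_numpy()
        if np.any(values < 0):
            raise CountError("negative count")
        if not exact and not np.allclose(values, np.round(values)):
            raise CountError("non-integer count")
        for s in samples:
            if s.assay != assay:
                raise CountError(
                    f"sample {s.name} has assay {s.assay}, matrix is {assay}"
                )
        self.counts = counts.astype(float if exact else np.int64)
        self.samples = list(samples)
        self.assay = assay
        self.exact = exact

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_names(self) -> list[str]:
        return [s.name for s in self.samples]

    def columns_for(self, condition: tuple[str, str]) -> list[str]:
        return [s.name for s in self.samples if s.condition == condition]

    def subset(self, conditions: Sequence[tuple[str, str]]) -> "CountMatrix":
        keep = [s for s in self.samples if s.condition in set(conditions)]
        cols = [s.name for s in keep]
        return CountMatrix(self.counts[cols], keep, self.assay, self.exact)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


@dataclass
class OccupancyTrack:
    """Per-nucleotide footprint 3'-end counts for one transcript."""

    transcript_id: str
    counts: np.ndarray
    library_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("occupancy track must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.transcript_id}: negative occupancy")
        if self.library_total < 0:
            raise ValueError("library_total must be >= 0")

    def __len__(self) -> int:
        return len(self.counts)

    def rpm(self) -> np.ndarray:
        if self.library_total <= 0:
            raise ValueError(
                f"{self.transcript_id}: cannot scale to rpm with "
                "library_total <= 0"
            )
        return self.counts * (1e6 / self.library_total)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str, line: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise AnnotationError(f"malformed attribute {chunk!r}", line)
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def read_annotation(path) -> Transcriptome:
    """Read transcript/CDS/uORF annotation from a transcript-space GFF3.

    Coordinates in the file are 1-based inclusive (GFF3) and are
    converted to 0-based half-open.  The seqid column is the transcript
    id; ``transcript`` rows define length, ``CDS`` rows the main ORF
    (with a ``codon_seq`` attribute carrying the amino-acid sequence),
    and ``uORF`` rows carry ``start_class``/``source``/``effect``
    attributes and a ``Parent`` pointing at their transcript.
    """
    lengths: dict[str, int] = {}
    cds: dict[str, tuple[int, int, str]] = {}
    uorf_rows: list[tuple[str, UORF]] = []  # (parent, uorf); order preserved
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            seqid, _source, ftype, start_s, end_s, _score, _strand, _phase, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"non-integer coordinates {start_s!r}..{end_s!r}", lineno
                ) from None
            if start1 < 1 or end1 < start1:
                raise AnnotationError(
                    f"malformed coordinates {start1}..{end1}", lineno
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attrs_s, lineno)

            if ftype == "transcript":
                if seqid in lengths:
                    raise AnnotationError(
                        f"duplicate transcript row for {seqid!r}", lineno
                    )
                if start != 0:
                    raise AnnotationError(
                        f"transcript row for {seqid!r} must start at 1", lineno
                    )
                lengths[seqid] = end
                order.append(seqid)
            elif ftype == "CDS":
                if seqid in cds:
                    raise AnnotationError(
                        f"duplicate CDS row for {seqid!r}", lineno
                    )
                if "codon_seq" not in attrs:
                    raise AnnotationError(
                        f"CDS row for {seqid!r} lacks codon_seq attribute",
                        lineno,
                    )
                if (end - start) % 3 != 0:
                    raise AnnotationError(
                        f"CDS length {end - start} for {seqid!r} not "
                        "divisible by 3",
                        lineno,
                    )
                cds[seqid] = (start, end, attrs["codon_seq"])
            elif ftype == "uORF":
                parent = attrs.get("Parent", seqid)
                try:
                    u = UORF(
                        parent_id=parent,
                        start=start,
                        end=end,
                        start_class=attrs.get("start_class", "AUG"),
                        source=attrs.get("source", "annotated"),
                        effect=attrs.get("effect", "none"),
                    )
                except AnnotationError as exc:
                    raise AnnotationError(str(exc), lineno) from None
                uorf_rows.append((parent, u))
                if parent not in lengths:
                    # remember the line for the orphan check below
                    u._lineno = lineno  # type: ignore[attr-defined]
            else:
                raise AnnotationError(f"unknown feature type {ftype!r}", lineno)

    transcripts = []
    by_parent: dict[str, list[UORF]] = {}
    for parent, u in uorf_rows:
        if parent not in lengths:
            raise AnnotationError(
                f"orphan uORF: parent {parent!r} absent from file",
                getattr(u, "_lineno", None),
            )
        by_parent.setdefault(parent, []).append(u)
    for tid in order:
        if tid not in cds:
            raise AnnotationError(f"transcript {tid!r} has no CDS row")
        c0, c1, seq = cds[tid]
        transcripts.append(
            Transcript(
                id=tid,
                length=lengths[tid],
                cds_start=c0,
                cds_end=c1,
                codon_seq=seq,
                uorfs=by_parent.get(tid, []),
            )
        )
    return Transcriptome(transcripts)


def write_annotation(tx: Transcriptome, path) -> None:
    """Write a Transcriptome back to transcript-space GFF3 (inverse of
    :func:`read_annotation`, byte-identical round trip)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tx:
            fh.write(
                f"{t.id}\tribotekit\ttranscript\t1\t{t.length}\t.\t+\t.\t"
                f"ID={t.id}\n"
            )
            fh.write(
                f"{t.id}\tribotekit\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t"
                f"+\t0\tParent={t.id};codon_seq={t.codon_seq}\n"
            )
            for i, u in enumerate(t.uorfs):
                fh.write(
                    f"{t.id}\tribotekit\tuORF\t{u.start + 1}\t{u.end}\t.\t+\t"
                    f".\tID={t.id}.uORF{i + 1};Parent={t.id};"
                    f"start_class={u.start_class};source={u.source};"
                    f"effect={u.effect}\n"
                )


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleMeta]:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "genotype", "treatment", "replicate", "assay"}
    missing = required - set(sheet.columns)
    if missing:
        raise CountError(f"sample sheet lacks column(s): {sorted(missing)}")
    metas = []
    for _, row in sheet.iterrows():
        metas.append(
            SampleMeta(
                name=row["sample"],
                genotype=row["genotype"],
                treatment=row["treatment"],
                replicate=int(row["replicate"]),
                assay=row["assay"],
            )
        )
    return metas


def read_counts(path, sample_sheet, assay: str | None = None) -> CountMatrix:
    """Read a feature x sample count TSV, ordered per the sample sheet.

    ``sample_sheet`` is a path to a TSV with columns
    sample/genotype/treatment/replicate/assay, or an already-parsed list
    of :class:`SampleMeta`.  When the sheet mixes assays, pass ``assay``
    to select the one this table holds.
    """
    if isinstance(sample_sheet, (str, bytes)) or hasattr(sample_sheet, "__fspath__"):
        metas = read_sample_sheet(sample_sheet)
    else:
        metas = list(sample_sheet)
    if assay is not None:
        metas = [m for m in metas if m.assay == assay]
    if not metas:
        raise CountError("no samples selected from sample sheet")
    assays = {m.assay for m in metas}
    if len(assays) != 1:
        raise CountError(
            "sample sheet mixes assays; pass assay= to select one"
        )
    table = pd.read_csv(path, sep="\t", index_col=0)
    for m in metas:
        if m.name not in table.columns:
            raise CountError(f"sample {m.name!r} in sheet missing from TSV")
    table = table[[m.name for m in metas]]
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountError("non-numeric count cell")
    if not np.allclose(values, np.round(values)):
        bad = table.columns[np.where(~np.isclose(values, np.round(values)))[1][0]]
        raise CountError(f"non-integer count in column {bad!r}")
    return CountMatrix(table.round().astype(np.int64), metas, assays.pop())


def write_counts(matrix: CountMatrix, path, sheet_path=None) -> None:
    out = matrix.counts.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")
    if sheet_path is not None:
        pd.DataFrame(
            {
                "sample": [s.name for s in matrix.samples],
                "genotype": [s.genotype for s in matrix.samples],
                "treatment": [s.treatment for s in matrix.samples],
                "replicate": [s.replicate for s in matrix.samples],
                "assay": [s.assay for s in matrix.samples],
            }
        ).to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Wiggle (fixedStep)
# ---------------------------------------------------------------------------

def write_wiggle(tracks, path, normalize: bool = False) -> None:
    """Write occupancy tracks as fixedStep wiggle.

    With ``normalize`` the values are scaled to reads per million of the
    track's ``library_total`` (error if that total is zero); otherwise
    raw 3'-end counts are emitted.
    """
    if isinstance(tracks, OccupancyTrack):
        tracks = [tracks]
    with open(path, "w") as fh:
        for tr in tracks:
            vals = tr.rpm() if normalize else tr.counts
            fh.write(
                f"fixedStep chrom={tr.transcript_id} start=1 step=1\n"
            )
            for v in vals:
                fh.write(f"{v:.10g}\n")


def read_wiggle(path, library_total: int = 0) -> dict[str, OccupancyTrack]:
    """Read fixedStep wiggle back into per-transcript tracks."""
    tracks: dict[str, list[float]] = {}
    current: list[float] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                chrom = attrs["chrom"]
                if int(attrs.get("start", 1)) != 1 or int(attrs.get("step", 1)) != 1:
                    raise AnnotationError(
                        "only start=1 step=1 fixedStep supported", lineno
                    )
                current = tracks.setdefault(chrom, [])
            else:
                if current is None:
                    raise AnnotationError("value before fixedStep header", lineno)
                current.append(float(line))
    return {
        tid: OccupancyTrack(tid, np.array(vals), library_total)
        for tid, vals in tracks.items()
    }
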