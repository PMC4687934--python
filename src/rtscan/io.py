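"""Standard-format I/O and the internal coordinate model.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF3 I/O
converts to and from the 1-based inclusive convention on the fly.
"Downstream" is always strand-aware: increasing coordinates on ``+``,
decreasing on ``-``.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-")

#: closed set of transcript class labels
RNA_CLASSES = (
    "mRNA",
    "snoRNA",
    "snRNA",
    "CUT",
    "SUT",
    "tRNA",
    "rRNA",
    "ncRNA-other",
)

#: GFF3 feature type -> rna_class.  Unknown types fall back to ncRNA-other.
GFF3_TYPE_MAP = {
    "mRNA": "mRNA",
    "gene": "mRNA",
    "protein_coding_gene": "mRNA",
    "snoRNA": "snoRNA",
    "snoRNA_gene": "snoRNA",
    "snRNA": "snRNA",
    "snRNA_gene": "snRNA",
    "CUT": "CUT",
    "cut": "CUT",
    "SUT": "SUT",
    "sut": "SUT",
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "rRNA": "rRNA",
    "rRNA_gene": "rRNA",
    "ncRNA": "ncRNA-other",
    "ncRNA_gene": "ncRNA-other",
}

SNO_TRANSCRIPT_CLASSES = ("monocistronic", "polycistronic", "intronic")


class ParseError(ValueError):
    """Malformed input; message carries the offending line or row number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the first transcribed nucleotide."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Coordinate of the last transcribed nucleotide."""
        return self.end - 1 if self.strand == "+" else self.start

    def downstream(self, offset: int, length: int) -> "GenomicInterval":
        """Interval of ``length`` nt starting ``offset`` nt past the 3' end."""
        if self.strand == "+":
            return GenomicInterval(
                self.chrom, self.end + offset, self.end + offset + length, "+"
            )
        return GenomicInterval(
            self.chrom, self.start - offset - length, self.start - offset, "-"
        )

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript with a class label and optional polyA site.

    ``polyA`` is a genomic coordinate (0-based); when present it must be the
    strand-aware 3' terminus or lie within 300 nt of it.  Polycistronic
    snoRNA entries represent one transcription unit (the terminal snoRNA of
    the precursor), not individual cistrons.
    """

    interval: GenomicInterval
    id: str
    rna_class: str
    polyA: int | None = None
    sno_transcript_class: str | None = None
    introns: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.sno_transcript_class is not None and (
            self.sno_transcript_class not in SNO_TRANSCRIPT_CLASSES
        ):
            raise ValueError(
                f"unknown sno_transcript_class {self.sno_transcript_class!r}"
            )
        if self.polyA is not None and abs(self.polyA - self.interval.three_prime) > 300:
            raise ValueError(
                f"polyA {self.polyA} more than 300 nt from 3' end "
                f"{self.interval.three_prime} for {self.id}"
            )

    @property
    def length(self) -> int:
        return len(self.interval)


class TranscriptSet:
    """Ordered collection of transcripts with id lookup and interval queries."""

    def __init__(self, transcripts: Iterable[TranscriptAnnotation]):
        self.transcripts: list[TranscriptAnnotation] = list(transcripts)
        self._by_id = {t.id: t for t in self.transcripts}
        if len(self._by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript ids")

    def __iter__(self) -> Iterator[TranscriptAnnotation]:
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> TranscriptAnnotation:
        return self._by_id[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def by_class(self, classes: Iterable[str]) -> list[TranscriptAnnotation]:
        wanted = set(classes)
        return [t for t in self.transcripts if t.rna_class in wanted]

    def overlapping(
        self, interval: GenomicInterval, same_strand: bool = True
    ) -> list[TranscriptAnnotation]:
        return [
            t
            for t in self.transcripts
            if t.interval.overlaps(interval, same_strand=same_strand)
        ]

    def nearest_downstream(
        self,
        transcript: TranscriptAnnotation,
        same_strand: bool = True,
        horizon: int | None = None,
        classes: Iterable[str] | None = None,
    ) -> tuple[TranscriptAnnotation | None, int]:
        """Nearest feature past the 3' end of ``transcript`` (strand-aware).

        Distance is measured from the 3' end to the closest edge of the
        neighbour; returns ``(None, -1)`` when no neighbour lies within
        ``horizon`` (``None`` = unbounded).  ``same_strand=False`` searches
        both strands.
        """
        iv = transcript.interval
        wanted = set(classes) if classes is not None else None
        best: TranscriptAnnotation | None = None
        best_d = -1
        for t in self.transcripts:
            if t.id == transcript.id or t.interval.chrom != iv.chrom:
                continue
            if same_strand and t.interval.strand != iv.strand:
                continue
            if wanted is not None and t.rna_class not in wanted:
                continue
            if iv.strand == "+":
                d = t.interval.start - iv.end
            else:
                d = iv.start - t.interval.end
            if d < 0:
                continue
            if horizon is not None and d > horizon:
                continue
            if best is None or d < best_d:
                best, best_d = t, d
        return best, best_d


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_annotation(stream: IO[str] | str, warn: bool = True) -> TranscriptSet:
    """Parse a GFF3 stream or path into a :class:`TranscriptSet`.

    GFF3 is 1-based inclusive; intervals are converted to 0-based half-open.
    The class label comes from the feature type via :data:`GFF3_TYPE_MAP`,
    falling back to an explicit ``rna_class=`` attribute; unknown types are
    recorded as ``ncRNA-other`` with a warning on stderr.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream)
        close = True
    transcripts = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"GFF3 line {lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise ParseError(f"GFF3 line {lineno}: bad strand {strand!r}")
            attr = _parse_attributes(attrs)
            tid = attr.get("ID") or attr.get("Name")
            if tid is None:
                raise ParseError(f"GFF3 line {lineno}: missing ID attribute")
            rna_class = GFF3_TYPE_MAP.get(ftype) or attr.get("rna_class")
            if rna_class is None or rna_class not in RNA_CLASSES:
                if warn:
                    print(
                        f"warning: GFF3 line {lineno}: unknown feature type "
                        f"{ftype!r}; recording as ncRNA-other",
                        file=sys.stderr,
                    )
                rna_class = "ncRNA-other"
            polyA = attr.get("polyA_site")
            sno_class = attr.get("sno_class")
            transcripts.append(
                TranscriptAnnotation(
                    interval=GenomicInterval(chrom, start_i - 1, end_i, strand),
                    id=tid,
                    rna_class=rna_class,
                    polyA=int(polyA) - 1 if polyA is not None else None,
                    sno_transcript_class=sno_class,
                )
            )
    finally:
        if close:
            stream.close()
    return TranscriptSet(transcripts)


_CLASS_TO_GFF3_TYPE = {
    "mRNA": "mRNA",
    "snoRNA": "snoRNA_gene",
    "snRNA": "snRNA_gene",
    "CUT": "CUT",
    "SUT": "SUT",
    "tRNA": "tRNA_gene",
    "rRNA": "rRNA_gene",
    "ncRNA-other": "ncRNA",
}


def write_annotation(transcripts: TranscriptSet, stream: IO[str]) -> None:
    """Write GFF3 (1-based inclusive), inverse of :func:`read_annotation`."""
    stream.write("##gff-version 3\n")
    for t in transcripts:
        iv = t.interval
        attrs = [f"ID={t.id}"]
        if t.polyA is not None:
            attrs.append(f"polyA_site={t.polyA + 1}")
        if t.sno_transcript_class is not None:
            attrs.append(f"sno_class={t.sno_transcript_class}")
        stream.write(
            "\t".join(
                [
                    iv.chrom,
                    "rtscan",
                    _CLASS_TO_GFF3_TYPE[t.rna_class],
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------

class ProbeTrack:
    """Per-(chrom, strand) sorted probe centers with per-sample log2 intensity.

    Backed by sorted numpy arrays; range queries use binary search.  A probe
    belongs to a window when its *center* lies inside the window and its
    strand matches.
    """

    def __init__(
        self,
        samples: Sequence[str],
        data: Mapping[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    ):
        self.samples = list(samples)
        self._index = {s: i for i, s in enumerate(self.samples)}
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for key, (pos, intens) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            intens = np.asarray(intens, dtype=float)
            if intens.shape != (pos.size, len(self.samples)):
                raise ValueError(f"intensity shape mismatch for {key}")
            if not np.all(np.isfinite(intens)):
                raise ValueError(f"non-finite intensities for {key}")
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            if pos.size and np.any(np.diff(pos) == 0):
                raise ValueError(f"duplicate probe centers for {key}")
            self._data[key] = (pos, intens[order])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, samples: Sequence[str]) -> "ProbeTrack":
        for col in ("chrom", "position", "strand", *samples):
            if col not in df.columns:
                raise ParseError(f"missing column {col!r} in probe table")
        data = {}
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
            if strand not in STRANDS:
                raise ParseError(f"bad strand {strand!r} in probe table")
            data[(str(chrom), str(strand))] = (
                grp["position"].to_numpy(dtype=np.int64),
                grp[list(samples)].to_numpy(dtype=float),
            )
        return cls(samples, data)

    def query(
        self, chrom: str, start: int, end: int, strand: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Probes with ``start <= center < end`` on (chrom, strand).

        Returns ``(centers, intensities)`` with intensities shaped
        ``(n_probes, n_samples)``.
        """
        key = (chrom, strand)
        if key not in self._data:
            return np.empty(0, dtype=np.int64), np.empty((0, len(self.samples)))
        pos, intens = self._data[key]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return pos[lo:hi], intens[lo:hi]

    def query_interval(self, interval: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
        return self.query(interval.chrom, interval.start, interval.end, interval.strand)

    def sample_column(self, sample: str) -> int:
        return self._index[sample]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (chrom, strand), (pos, intens) in sorted(self._data.items()):
            frame = pd.DataFrame(intens, columns=self.samples)
            frame.insert(0, "strand", strand)
            frame.insert(0, "position", pos)
            frame.insert(0, "chrom", chrom)
            rows.append(frame)
        if not rows:
            return pd.DataFrame(columns=["chrom", "position", "strand", *self.samples])
        return pd.concat(rows, ignore_index=True)


DEFAULT_SAMPLES = ("wt_1", "wt_2", "mut_1", "mut_2")


def read_probe_table(
    stream: IO[str] | str, samples: Sequence[str] = DEFAULT_SAMPLES
) -> ProbeTrack:
    """Read a tab-delimited probe table (chrom, position, strand, samples...)."""
    df = pd.read_csv(stream, sep="\t")
    for col in ("chrom", "position", "strand", *samples):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in probe table")
    for s in samples:
        if not pd.api.types.is_numeric_dtype(df[s]):
            bad = df.index[pd.to_numeric(df[s], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric intensity in column {s!r}, first bad row "
                f"{int(bad[0]) + 2}"  # +2: header + 1-based
            )
    dup = df.duplicated(subset=["chrom", "position", "strand"])
    if dup.any():
        raise ParseError(
            f"duplicate probe at row {int(df.index[dup][0]) + 2}"
        )
    return ProbeTrack.from_dataframe(df, samples)


def write_probe_table(track: ProbeTrack, stream: IO[str]) -> None:
    track.to_dataframe().to_csv(stream, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

_TAIL_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class Read:
    """A mapped read: aligned interval plus optional unaligned 3' tail."""

    interval: GenomicInterval
    name: str = "."
    tail3: str = ""
    tc_substitutions: int | None = None

    def __post_init__(self) -> None:
        if set(self.tail3) - _TAIL_ALPHABET:
            raise ValueError(f"tail3 {self.tail3!r} not over ACGTN")


@dataclass
class ReadSet:
    """Collection of stranded aligned reads with a library-size denominator."""

    reads: list[Read] = field(default_factory=list)
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        if self.total_mapped is None:
            self.total_mapped = len(self.reads)
        if self.total_mapped < len(self.reads):
            raise ValueError("total_mapped below number of reads")

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def _read_bed6(stream: IO[str], contig_lengths: Mapping[str, int] | None) -> list[Read]:
    reads = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"BED line {lineno}: need >= 6 columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        tail3 = fields[6] if len(fields) > 6 and fields[6] != "." else ""
        tc = int(fields[7]) if len(fields) > 7 and fields[7] != "." else None
        iv = GenomicInterval(chrom, int(start), int(end), strand)
        if contig_lengths is not None:
            clen = contig_lengths.get(chrom)
            if clen is None or iv.end > clen:
                raise ParseError(f"BED line {lineno}: interval off contig {chrom}")
        reads.append(Read(iv, name=name, tail3=tail3, tc_substitutions=tc))
    return reads


def _read_alignments(path: str) -> list[Read]:
    """BAM/SAM via pysam; 3' soft clip (strand-aware) is captured as tail3."""
    import pysam

    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            tail3 = ""
            cigar = rec.cigartuples or []
            seq = rec.query_sequence or ""
            if strand == "+" and cigar and cigar[-1][0] == 4:  # trailing S
                n = cigar[-1][1]
                tail3 = seq[len(seq) - n :]
            elif strand == "-" and cigar and cigar[0][0] == 4:  # leading S
                n = cigar[0][1]
                tail3 = str(Seq(seq[:n]).reverse_complement())
            tc = None
            if rec.has_tag("tC"):
                tc = int(rec.get_tag("tC"))
            reads.append(
                Read(
                    GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        strand,
                    ),
                    name=rec.query_name,
                    tail3=tail3,
                    tc_substitutions=tc,
                )
            )
    return reads


def read_reads(
    source: IO[str] | str,
    fmt: str | None = None,
    total_mapped: int | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> ReadSet:
    """Read BED6 (optionally with tail3 / T->C columns 7-8) or BAM/SAM.

    ``fmt`` may be "bed", "bam" or None to sniff from the file extension.
    ``total_mapped`` overrides the record count as library size.
    """
    if fmt is None:
        if isinstance(source, str) and source.endswith((".bam", ".sam")):
            fmt = "bam"
        else:
            fmt = "bed"
    if fmt == "bam":
        if not isinstance(source, str):
            raise ValueError("BAM/SAM input requires a file path")
        reads = _read_alignments(source)
    else:
        close = False
        if isinstance(source, str):
            source = open(source)
            close = True
        try:
            reads = _read_bed6(source, contig_lengths)
        finally:
            if close:
                source.close()
    return ReadSet(reads, total_mapped=total_mapped)


def write_reads_bed(readset: ReadSet, stream: IO[str]) -> None:
    """BED6 + optional tail3/T->C columns; inverse of the BED reader."""
    for r in readset:
        iv = r.interval
        fields = [iv.chrom, str(iv.start), str(iv.end), r.name, "0", iv.strand]
        if r.tail3 or r.tc_substitutions is not None:
            fields.append(r.tail3 or ".")
        if r.tc_substitutions is not None:
            fields.append(str(r.tc_substitutions))
        stream.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    values: Mapping[tuple[str, str], Mapping[int, float]],
    strand: str,
    stream: IO[str],
) -> None:
    """Run-length-merged bedGraph for per-nucleotide values on one strand.

    ``values`` maps (chrom, strand) to {position: value}.  Mixing strands in
    one call is an error; zero values are omitted.
    """
    if strand not in STRANDS:
        raise ValueError(f"bad strand {strand!r}")
    for chrom, s in values:
        if s != strand:
            raise ValueError(f"mixed strands: asked for {strand!r}, got {s!r}")
    for (chrom, _s), per_nt in sorted(values.items()):
        positions = sorted(p for p, v in per_nt.items() if v != 0)
        run_start = None
        prev_pos = None
        prev_val = None
        for p in positions:
            v = per_nt[p]
            if not np.isfinite(v):
                raise ValueError(f"non-finite value at {chrom}:{p}")
            if run_start is not None and p == prev_pos + 1 and v == prev_val:
                prev_pos = p
                continue
            if run_start is not None:
                stream.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")
            run_start, prev_pos, prev_val = p, p, v
        if run_start is not None:
            stream.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")


def read_bedgraph(stream: IO[str], strand: str) -> dict[tuple[str, str], dict[int, float]]:
    """Inverse of :func:`write_bedgraph` (used as the round-trip oracle)."""
    out: dict[tuple[str, str], dict[int, float]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split("\t")
        per_nt = out.setdefault((chrom, strand), {})
        for p in range(int(start), int(end)):
            per_nt[p] = float(value)
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class Genome:
    """In-memory genome with strand-aware sequence fetch."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = {k: str(v).upper() for k, v in contigs.items()}

    @classmethod
    def from_fasta(cls, source: IO[str] | str) -> "Genome":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.contigs

    def length(self, chrom: str) -> int:
        return len(self.contigs[chrom])

    def contig_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.contigs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Sense-strand sequence (reverse-complemented for ``-``)."""
        seq = self.contigs[interval.chrom]
        if interval.start < 0 or interval.end > len(seq):
            raise ValueError(f"interval off contig {interval.chrom}")
        sub = seq[interval.start : interval.end]
        if interval.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub

    def write_fasta(self, stream: IO[str], width: int = 70) -> None:
        for name in sorted(self.contigs):
            stream.write(f">{name}\n")
            seq = self.contigs[name]
            for i in range(0, len(seq), width):
                stream.write(seq[i : i + width] + "\n")


__all__ = [
    "STRANDS",
    "RNA_CLASSES",
    "GFF3_TYPE_MAP",
    "ParseError",
    "GenomicInterval",
    "TranscriptAnnotation",
    "TranscriptSet",
    "read_annotation",
    "write_annotation",
    "ProbeTrack",
    "read_probe_table",
    "write_probe_table",
    "DEFAULT_SAMPLES",
    "Read",
    "ReadSet",
    "read_reads",
    "write_reads_bed",
    "write_bedgraph",
    "read_bedgraph",
    "Genome",
]
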