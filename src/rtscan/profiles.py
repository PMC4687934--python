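"""CRAC read analytics.

Coverage semantics throughout: a read contributes to every nucleotide it
covers.  Class assignment uses a fixed priority order and requires >= 50%
of the read length to fall within the feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rtscan.io import (
    Genome,
    GenomicInterval,
    Read,
    ReadSet,
    TranscriptAnnotation,
    TranscriptSet,
)

#: sense-strand class priority for reads overlapping several features
CLASS_PRIORITY = (
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "mRNA",
    "intron",
    "CUT",
    "SUT",
    "ncRNA-other",
)

MIN_OVERLAP_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Class assignment
# ---------------------------------------------------------------------------

def assign_read_class(read: Read, transcripts: TranscriptSet) -> str:
    """Assign one class label per read.

    Sense-strand overlaps (>= 50% of the read inside the feature) win by
    :data:`CLASS_PRIORITY`; a read mostly inside an annotated intron of an
    mRNA is "intron".  With no sense overlap, an antisense overlap gives
    "antisense"; otherwise "intergenic".
    """
    iv = read.interval
    need = MIN_OVERLAP_FRACTION * len(iv)
    sense: set[str] = set()
    antisense = False
    for t in transcripts:
        ov = t.interval.overlap_length(iv)
        if ov < need:
            continue
        if t.interval.strand == iv.strand:
            label = t.rna_class
            if t.rna_class == "mRNA" and any(
                intron.overlap_length(iv) >= need for intron in t.introns
            ):
                label = "intron"
            sense.add(label)
        else:
            antisense = True
    if sense:
        for label in CLASS_PRIORITY:
            if label in sense:
                return label
    if antisense:
        return "antisense"
    return "intergenic"


def class_tally(reads: ReadSet, transcripts: TranscriptSet) -> pd.DataFrame:
    """Read count and fraction of total per assigned class."""
    labels = [assign_read_class(r, transcripts) for r in reads]
    counts = pd.Series(labels).value_counts()
    df = counts.rename("count").to_frame()
    df["fraction"] = df["count"] / df["count"].sum()
    return df


# ---------------------------------------------------------------------------
# oligo(A) detection
# ---------------------------------------------------------------------------

def detect_oligoA(read: Read, genome: Genome) -> bool:
    """True iff the read carries a non-templated 3' oligo(A) tail (A2+).

    The tail must be non-empty, all-A and length >= 2.  It is *templated*
    (and rejected) when the genomic bases immediately downstream of the
    read's 3' end, read in transcript sense, are identical to the tail; a
    tail running past the contig end counts as non-templated.
    """
    tail = read.tail3
    if len(tail) < 2 or set(tail) != {"A"}:
        return False
    iv = read.interval
    n = len(tail)
    if iv.strand == "+":
        start, end = iv.end, iv.end + n
    else:
        start, end = iv.start - n, iv.start
    if start < 0 or end > genome.length(iv.chrom):
        return True
    genomic = genome.fetch(GenomicInterval(iv.chrom, start, end, iv.strand))
    return genomic != tail


def oligoA_fraction(
    reads: ReadSet,
    genome: Genome,
    transcripts: TranscriptSet | None = None,
    rna_class: str | None = None,
) -> float | None:
    """Fraction of reads flagged by :func:`detect_oligoA`.

    With ``rna_class`` set, only reads assigned to that class count.
    Returns ``None`` for an empty selection.
    """
    if rna_class is not None:
        if transcripts is None:
            raise ValueError("class filtering needs an annotation")
        selected = [
            r for r in reads if assign_read_class(r, transcripts) == rna_class
        ]
    else:
        selected = list(reads)
    if not selected:
        return None
    flagged = sum(detect_oligoA(r, genome) for r in selected)
    return flagged / len(selected)


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Per-offset signal anchored at a common landmark across genes.

    Offsets are in transcription direction: negative offsets are upstream
    of the anchor (outside the gene for TSS, inside for 3'-end anchors).
    """

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    normalization: str
    gene_set_size: int


def _anchor_position(t: TranscriptAnnotation, anchor: str) -> int:
    if anchor == "TSS":
        return t.interval.five_prime
    if anchor == "end3":
        return t.interval.three_prime
    if anchor == "polyA":
        if t.polyA is None:
            raise ValueError(f"{t.id} has no polyA site")
        return t.polyA
    raise ValueError(f"unknown anchor {anchor!r}")


def _gene_binding(reads: ReadSet, t: TranscriptAnnotation) -> int:
    return sum(
        1
        for r in reads
        if r.interval.strand == t.interval.strand and r.interval.overlaps(t.interval)
    )


def metagene_endpoint_profile(
    reads: ReadSet,
    transcripts: Iterable[TranscriptAnnotation],
    anchor: str = "TSS",
    flank_out: int = 100,
    flank_in: int = 100,
    min_len: int = 0,
    normalization: str = "sum_to_one",
    top_n: int | None = None,
) -> MetageneProfile:
    """Per-offset summed read coverage anchored at TSS / 3' end / polyA.

    For a TSS anchor the window spans ``[-flank_out, flank_in]`` offsets;
    for 3'-end anchors, ``[-flank_in, flank_out]``.  ``top_n`` keeps only
    the most-bound genes (by overlapping-read count).  Normalizations:
    ``per_million`` (divide by total_mapped / 1e6), ``sum_to_one``, or
    ``raw``.
    """
    genes = [t for t in transcripts if t.length > min_len]
    if not genes:
        raise ValueError("empty gene set after length filter")
    if top_n is not None and len(genes) > top_n:
        genes = sorted(genes, key=lambda t: _gene_binding(reads, t), reverse=True)[:top_n]

    if anchor == "TSS":
        lo, hi = -flank_out, flank_in
    else:
        lo, hi = -flank_in, flank_out
    offsets = np.arange(lo, hi + 1)
    values = np.zeros(offsets.size, dtype=float)

    anchors = {
        (t.interval.chrom, t.interval.strand, t.id): (_anchor_position(t, anchor), t)
        for t in genes
    }
    for r in reads:
        riv = r.interval
        for (chrom, strand, _tid), (a, _t) in anchors.items():
            if riv.chrom != chrom or riv.strand != strand:
                continue
            for pos in range(riv.start, riv.end):
                off = pos - a if strand == "+" else a - pos
                if lo <= off <= hi:
                    values[off - lo] += 1.0

    if normalization == "per_million":
        if not reads.total_mapped:
            raise ValueError("per_million needs total_mapped > 0")
        values = values / (reads.total_mapped / 1e6)
    elif normalization == "sum_to_one":
        total = values.sum()
        if total > 0:
            values = values / total
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return MetageneProfile(anchor, offsets, values, normalization, len(genes))


def smooth_profile(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered rolling mean with edge shrinkage (illustrative smoother)."""
    s = pd.Series(values).rolling(window, center=True, min_periods=1).mean()
    return s.to_numpy()


def length_normalized_profile(
    reads: ReadSet,
    transcripts: Iterable[TranscriptAnnotation],
    n_bins: int = 100,
) -> np.ndarray:
    """Coverage mapped to ``n_bins`` equal length fractions per transcript.

    Each covered nucleotide's mass is split across the bins it overlaps, so
    total binned mass equals total covered-nucleotide mass.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    out = np.zeros(n_bins, dtype=float)
    genes = list(transcripts)
    for t in genes:
        iv = t.interval
        L = len(iv)
        cov = np.zeros(L, dtype=float)
        for r in reads:
            riv = r.interval
            if riv.chrom != iv.chrom or riv.strand != iv.strand:
                continue
            s = max(riv.start, iv.start)
            e = min(riv.end, iv.end)
            if s < e:
                cov[s - iv.start : e - iv.start] += 1.0
        if iv.strand == "-":
            cov = cov[::-1]
        # nt j spans [j, j+1) of gene length; bin b spans [b*L/n, (b+1)*L/n)
        scale = n_bins / L
        for j in np.nonzero(cov)[0]:
            b_lo = j * scale
            b_hi = (j + 1) * scale
            first = int(np.floor(b_lo))
            last = min(int(np.ceil(b_hi)), n_bins)
            for b in range(first, last):
                frac = min(b + 1, b_hi) - max(b, b_lo)
                if frac > 0:
                    out[b] += cov[j] * frac / scale
    return out


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def pileup(reads: ReadSet, region: GenomicInterval, total_mapped: int | None = None) -> np.ndarray:
    """Hits per million mapped reads at each nucleotide of ``region``."""
    total = total_mapped if total_mapped is not None else reads.total_mapped
    if not total:
        raise ValueError("total_mapped must be > 0")
    out = np.zeros(len(region), dtype=float)
    for r in reads:
        riv = r.interval
        if riv.chrom != region.chrom or riv.strand != region.strand:
            continue
        s = max(riv.start, region.start)
        e = min(riv.end, region.end)
        if s < e:
            out[s - region.start : e - region.start] += 1.0
    return out * 1e6 / total


def pileup_per_nt(reads: ReadSet, region: GenomicInterval, total_mapped: int | None = None) -> dict[int, float]:
    """Pileup as a {genomic position: value} map (bedGraph-ready)."""
    vals = pileup(reads, region, total_mapped)
    return {region.start + i: v for i, v in enumerate(vals) if v != 0}


# ---------------------------------------------------------------------------
# Pol II 3'-end group profiles
# ---------------------------------------------------------------------------

def polii_3prime_group_profile(
    reads: ReadSet,
    gene_group: Iterable[TranscriptAnnotation],
    window_up: int = 500,
    window_down: int = 500,
) -> MetageneProfile:
    """Max-one-scaled per-gene coverage around 3' ends, summed over a group.

    Offsets run from ``-window_up`` (inside the gene) to ``+window_down``
    (downstream); each gene's coverage is linearly scaled so its maximum is
    1 before summing.  Genes with no hits in the window are dropped with a
    warning.
    """
    genes = list(gene_group)
    if not genes:
        raise ValueError("empty gene group")
    offsets = np.arange(-window_up, window_down + 1)
    total = np.zeros(offsets.size, dtype=float)
    used = 0
    for t in genes:
        iv = t.interval
        a = iv.three_prime
        if iv.strand == "+":
            region = GenomicInterval(iv.chrom, max(0, a - window_up), a + window_down + 1, "+")
            cov = np.zeros(offsets.size)
            vals = pileup(reads, region, total_mapped=10**6)  # raw counts
            cov[offsets.size - vals.size :] = vals
        else:
            region = GenomicInterval(iv.chrom, max(0, a - window_down), a + window_up + 1, "-")
            vals = pileup(reads, region, total_mapped=10**6)
            cov = np.zeros(offsets.size)
            # left clipping at the contig start removes the largest offsets
            cov[: vals.size] = vals[::-1]
        m = cov.max()
        if m <= 0:
            warnings.warn(f"gene {t.id} has no hits in its 3' window; dropped")
            continue
        total += cov / m
        used += 1
    if used == 0:
        raise ValueError("no gene in the group has hits in its 3' window")
    return MetageneProfile("end3", offsets, total, "max_one_then_sum", used)


# ---------------------------------------------------------------------------
# snoRNA flank ratios and tallies
# ---------------------------------------------------------------------------

@dataclass
class FlankRatio:
    """Per-snoRNA 3'-flank / body hit ratio in two strains and their fold."""

    gene: str
    body_wt: int
    flank_wt: int
    body_mut: int
    flank_mut: int

    @property
    def score_wt(self) -> float | None:
        return self.flank_wt / self.body_wt if self.body_wt > 0 else None

    @property
    def score_mut(self) -> float | None:
        return self.flank_mut / self.body_mut if self.body_mut > 0 else None

    @property
    def fold(self) -> float | None:
        swt, smut = self.score_wt, self.score_mut
        if swt is None or smut is None or swt == 0:
            return None
        return smut / swt


def _count_overlapping(reads: ReadSet, window: GenomicInterval) -> int:
    return sum(
        1
        for r in reads
        if r.interval.strand == window.strand and r.interval.overlaps(window)
    )


def snoRNA_flank_ratio(
    reads_wt: ReadSet,
    reads_mut: ReadSet,
    snoRNA: TranscriptAnnotation,
    flank_len: int = 500,
) -> FlankRatio:
    """Sum of polymerase hits in the 500-nt 3' flank over hits in the body,
    compared between strains (fold = mutant score / WT score)."""
    body = snoRNA.interval
    flank = body.downstream(0, flank_len)
    return FlankRatio(
        gene=snoRNA.id,
        body_wt=_count_overlapping(reads_wt, body),
        flank_wt=_count_overlapping(reads_wt, flank),
        body_mut=_count_overlapping(reads_mut, body),
        flank_mut=_count_overlapping(reads_mut, flank),
    )


def tally_snoRNA_readthrough(
    calls: Mapping[str, bool],
    snoRNAs: Sequence[TranscriptAnnotation],
) -> dict[str, tuple[int, int]]:
    """Count 3'-extension calls per snoRNA transcript class.

    ``calls`` maps snoRNA id to a readthrough flag.  Intronic snoRNAs are
    excluded from every denominator (they have no independent terminator);
    polycistronic entries are expected to be one per transcription unit.
    Returns {class: (flagged, evaluable)} with an "all" aggregate.
    """
    counts = {"monocistronic": [0, 0], "polycistronic": [0, 0]}
    for t in snoRNAs:
        if t.rna_class != "snoRNA":
            continue
        cls = t.sno_transcript_class
        if cls not in counts:  # intronic or unannotated: no denominator
            continue
        if t.id not in calls:
            continue
        counts[cls][1] += 1
        if calls[t.id]:
            counts[cls][0] += 1
    out = {k: (v[0], v[1]) for k, v in counts.items()}
    out["all"] = (
        out["monocistronic"][0] + out["polycistronic"][0],
        out["monocistronic"][1] + out["polycistronic"][1],
    )
    return out


__all__ = [
    "CLASS_PRIORITY",
    "MIN_OVERLAP_FRACTION",
    "assign_read_class",
    "class_tally",
    "detect_oligoA",
    "oligoA_fraction",
    "MetageneProfile",
    "metagene_endpoint_profile",
    "smooth_profile",
    "length_normalized_profile",
    "pileup",
    "pileup_per_nt",
    "polii_3prime_group_profile",
    "FlankRatio",
    "snoRNA_flank_ratio",
    "tally_snoRNA_readthrough",
]
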