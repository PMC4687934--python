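"""k-mer enrichment between readthrough quartiles near polyA sites.

Gene-level presence/absence of every k-mer in the -80..-20 region upstream
of the polyA site is compared between the low- and high-readthrough
quartiles with a pooled two-proportion z-score (positive = enriched among
low-readthrough genes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rtscan.io import Genome, GenomicInterval, Read, ReadSet, TranscriptAnnotation, TranscriptSet
from rtscan.readthrough import bh_fdr

RNA_ALPHABET = "ACGU"

DEFAULT_REGION = (-80, -20)
DEFAULT_BOTTOM_EXCLUDE = 250


@dataclass(frozen=True)
class MotifResult:
    motif: str
    n_low_with: int
    n_low: int
    n_high_with: int
    n_high: int
    z: float
    degenerate: bool = False  # pooled proportion was 0 or 1


# ---------------------------------------------------------------------------
# Gene-set construction
# ---------------------------------------------------------------------------

def build_motif_gene_set(
    records: pd.DataFrame,
    transcripts: TranscriptSet,
    bottom_exclude: int = DEFAULT_BOTTOM_EXCLUDE,
    quartile_by: str = "score",
) -> pd.DataFrame:
    """Rank genes and label quartiles for the motif comparison.

    ``records`` must carry ``mean_ratio`` and the per-sample scores (from
    the readthrough driver).  The ``bottom_exclude`` genes with the lowest
    mean ratio are dropped (their ratios are spuriously negative when the
    mutant over-expresses the gene), then genes without an annotated polyA
    site are dropped, then quartiles 1 (lowest) .. 4 (highest) are assigned
    by the chosen statistic: ``"score"`` (mean mutant readthrough score) or
    ``"ratio"`` (mean readthrough ratio).

    Returns a DataFrame indexed by gene with columns ``stat`` and
    ``quartile``; quartile 1 = low readthrough, 4 = high readthrough.
    """
    df = records.copy()
    if bottom_exclude > 0:
        df = df.sort_values("mean_ratio", ascending=False).iloc[
            : max(len(df) - bottom_exclude, 0)
        ]
    has_polyA = [g in transcripts and transcripts[g].polyA is not None for g in df.index]
    df = df.loc[has_polyA]
    if len(df) < 8:
        raise ValueError(f"too few genes ({len(df)}) for quartiles")
    if quartile_by == "score":
        stat = (df["score_mut_1"] + df["score_mut_2"]) / 2.0
    elif quartile_by == "ratio":
        stat = df["mean_ratio"]
    else:
        raise ValueError(f"unknown quartile_by {quartile_by!r}")
    order = stat.rank(method="first")
    quartile = pd.cut(order, 4, labels=[1, 2, 3, 4]).astype(int)
    return pd.DataFrame({"stat": stat, "quartile": quartile})


def extract_3prime_region(
    transcript: TranscriptAnnotation,
    genome: Genome,
    region: tuple[int, int] = DEFAULT_REGION,
) -> str:
    """RNA-sense sequence of the region upstream of the polyA site.

    ``region=(-80, -20)`` yields the 60-nt window ending 20 nt before the
    polyA site, reverse-complemented for ``-`` genes and written with U.
    """
    if transcript.polyA is None:
        raise ValueError(f"{transcript.id} has no polyA site")
    lo, hi = region
    if lo >= hi:
        raise ValueError("region must satisfy from < to")
    pa = transcript.polyA
    if transcript.interval.strand == "+":
        iv = GenomicInterval(transcript.interval.chrom, pa + lo, pa + hi, "+")
    else:
        iv = GenomicInterval(transcript.interval.chrom, pa - hi + 1, pa - lo + 1, "-")
    return genome.fetch(iv).replace("T", "U")


# ---------------------------------------------------------------------------
# k-mer counting and z-scores
# ---------------------------------------------------------------------------

def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


def kmer_gene_counts(
    sequences_by_group: Mapping[str, Sequence[str]], k: int = 6
) -> pd.DataFrame:
    """Per-motif, per-group counts of genes containing the motif.

    Presence/absence per gene: a gene counts once no matter how many
    occurrences.  Positions with ambiguous bases never match.  Rows are all
    4^k motifs; columns ``<group>_with`` and ``<group>_n``.
    """
    motifs = all_kmers(k)
    index = {m: i for i, m in enumerate(motifs)}
    out = pd.DataFrame(index=pd.Index(motifs, name="motif"))
    for group, seqs in sequences_by_group.items():
        counts = np.zeros(len(motifs), dtype=int)
        for seq in seqs:
            seen: set[int] = set()
            s = seq.upper().replace("T", "U")
            for i in range(len(s) - k + 1):
                sub = s[i : i + k]
                j = index.get(sub)
                if j is not None:
                    seen.add(j)
            for j in seen:
                counts[j] += 1
        out[f"{group}_with"] = counts
        out[f"{group}_n"] = len(seqs)
    return out


def enrichment_z(
    n_low_with: int, n_low: int, n_high_with: int, n_high: int
) -> tuple[float, bool]:
    """Pooled two-proportion z; positive = enriched in the low group.

    Returns ``(z, degenerate)``; when the pooled proportion is 0 or 1 the z
    is reported as 0 with the degenerate flag set.
    """
    if n_low <= 0 or n_high <= 0:
        raise ValueError("group sizes must be > 0")
    p_low = n_low_with / n_low
    p_high = n_high_with / n_high
    pooled = (n_low_with + n_high_with) / (n_low + n_high)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, True
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_low + 1.0 / n_high))
    return float((p_low - p_high) / se), False


def motif_enrichment_table(
    low_sequences: Sequence[str],
    high_sequences: Sequence[str],
    k: int = 6,
) -> pd.DataFrame:
    """Z-scores for every k-mer, low vs high readthrough gene groups.

    Sorted by decreasing z; also carries a one-sided Fisher-exact p
    (alternative: enriched in the low group) as an independent reference
    statistic ordered the same way as z.
    """
    counts = kmer_gene_counts({"low": low_sequences, "high": high_sequences}, k=k)
    zs, degen, fisher = [], [], []
    n_low = len(low_sequences)
    n_high = len(high_sequences)
    for motif, row in counts.iterrows():
        z, d = enrichment_z(row["low_with"], n_low, row["high_with"], n_high)
        zs.append(z)
        degen.append(d)
        _odds, p = stats.fisher_exact(
            [
                [row["low_with"], n_low - row["low_with"]],
                [row["high_with"], n_high - row["high_with"]],
            ],
            alternative="greater",
        )
        fisher.append(p)
    counts["z"] = zs
    counts["degenerate"] = degen
    counts["fisher_p"] = fisher
    return counts.sort_values("z", ascending=False)


# ---------------------------------------------------------------------------
# Positional coverage
# ---------------------------------------------------------------------------

def motif_positional_coverage(
    gene_group: Iterable[TranscriptAnnotation],
    genome: Genome,
    motif: str = "UAUAUA",
    window: tuple[int, int] = (-200, 100),
) -> tuple[np.ndarray, np.ndarray]:
    """Count, per offset from the polyA site, genes whose motif occurrence
    covers that offset.

    Returns ``(offsets, coverage)``; offsets are in transcription direction
    with 0 at the polyA site.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    coverage = np.zeros(offsets.size, dtype=float)
    k = len(motif)
    motif = motif.upper().replace("T", "U")
    for t in gene_group:
        if t.polyA is None:
            continue
        pa = t.polyA
        if t.interval.strand == "+":
            iv = GenomicInterval(t.interval.chrom, pa + lo, pa + hi + 1, "+")
        else:
            iv = GenomicInterval(t.interval.chrom, pa - hi, pa - lo + 1, "-")
        try:
            seq = genome.fetch(iv).replace("T", "U")
        except ValueError:
            continue
        covered = np.zeros(offsets.size, dtype=bool)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] == motif:
                covered[i : i + k] = True
        coverage += covered
    return offsets, coverage


# ---------------------------------------------------------------------------
# Crosslinked-read selection
# ---------------------------------------------------------------------------

def read_clusters(reads: Sequence[Read]) -> list[list[int]]:
    """Connected components of same-strand overlapping reads (indices)."""
    order = sorted(
        range(len(reads)),
        key=lambda i: (
            reads[i].interval.chrom,
            reads[i].interval.strand,
            reads[i].interval.start,
            reads[i].interval.end,
        ),
    )
    clusters: list[list[int]] = []
    current: list[int] = []
    cur_key = None
    cur_end = -1
    for i in order:
        iv = reads[i].interval
        key = (iv.chrom, iv.strand)
        if key != cur_key or iv.start >= cur_end:
            if current:
                clusters.append(current)
            current = [i]
            cur_key = key
            cur_end = iv.end
        else:
            current.append(i)
            cur_end = max(cur_end, iv.end)
    if current:
        clusters.append(current)
    return clusters


def select_crosslinked_reads(
    reads: ReadSet,
    min_cluster_reads: int = 5,
    fdr: float | None = None,
    background_rate: float | None = None,
) -> ReadSet:
    """Keep reads with >= 1 T->C substitution inside clusters of >=
    ``min_cluster_reads`` overlapping reads.

    With ``fdr`` and ``background_rate`` (expected reads per cluster under a
    uniform model) given, clusters additionally pass a BH-corrected Poisson
    enrichment test on their read counts.
    """
    for r in reads:
        if r.tc_substitutions is None:
            raise ValueError(f"read {r.name} lacks substitution annotation")
    clusters = read_clusters(reads.reads)
    big = [c for c in clusters if len(c) >= min_cluster_reads]
    if fdr is not None:
        if background_rate is None:
            raise ValueError("fdr filtering needs background_rate")
        pvals = np.array(
            [float(stats.poisson.sf(len(c) - 1, background_rate)) for c in big]
        )
        pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
        flags = bh_fdr(pvals, alpha=fdr)
        big = [c for c, keep in zip(big, flags) if keep]
    kept_idx = {i for c in big for i in c}
    kept = [
        r
        for i, r in enumerate(reads.reads)
        if i in kept_idx and (r.tc_substitutions or 0) >= 1
    ]
    return ReadSet(kept, total_mapped=reads.total_mapped)


__all__ = [
    "MotifResult",
    "DEFAULT_REGION",
    "DEFAULT_BOTTOM_EXCLUDE",
    "build_motif_gene_set",
    "extract_3prime_region",
    "all_kmers",
    "kmer_gene_counts",
    "enrichment_z",
    "motif_enrichment_table",
    "motif_positional_coverage",
    "read_clusters",
    "select_crosslinked_reads",
]
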