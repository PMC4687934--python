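"""Genomic-environment classification of down-regulated genes.

For each gene, the nearest mRNA past its 3' end (strand-aware, within a
horizon) determines the orientation: convergent (C) when that neighbour
transcribes towards the gene, tandem (T) when it runs the same way.  A gene
is attributed to transcriptional interference when a convergent mRNA
neighbour, a convergent ncRNA neighbour, or the upstream same-strand gene
shows termination readthrough.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from rtscan.io import TranscriptAnnotation, TranscriptSet

DEFAULT_HORIZON = 5000

NCRNA_CLASSES = ("CUT", "SUT", "snoRNA", "snRNA", "ncRNA-other")


@dataclass
class EnvironmentRecord:
    gene: str
    expression_change: float
    orientation: str | None  # "C", "T" or None when no neighbour in range
    conv_mRNA_RT: bool
    conv_ncRNA_RT: bool
    tandem_RT: bool

    @property
    def no_interference(self) -> bool:
        return not (self.conv_mRNA_RT or self.conv_ncRNA_RT or self.tandem_RT)


def classify_orientation(
    gene: TranscriptAnnotation,
    transcripts: TranscriptSet,
    horizon: int = DEFAULT_HORIZON,
) -> str | None:
    """Orientation w.r.t. the nearest mRNA beyond the gene's 3' end.

    "C" when the neighbour lies on the opposite strand with its 3' end
    facing the gene, "T" when on the same strand; ``None`` when no mRNA
    lies within ``horizon`` nt.
    """
    neighbour, _d = transcripts.nearest_downstream(
        gene, same_strand=False, horizon=horizon, classes=("mRNA",)
    )
    if neighbour is None:
        return None
    return "T" if neighbour.interval.strand == gene.interval.strand else "C"


def _upstream_same_strand(
    gene: TranscriptAnnotation,
    transcripts: TranscriptSet,
    horizon: int,
) -> TranscriptAnnotation | None:
    """Nearest same-strand gene whose 3' end precedes this gene's 5' end."""
    iv = gene.interval
    best = None
    best_d = None
    for t in transcripts:
        if t.id == gene.id or t.interval.chrom != iv.chrom:
            continue
        if t.interval.strand != iv.strand:
            continue
        d = iv.start - t.interval.end if iv.strand == "+" else t.interval.start - iv.end
        if d < 0 or d > horizon:
            continue
        if best is None or d < best_d:
            best, best_d = t, d
    return best


def annotate_environment(
    gene: TranscriptAnnotation,
    transcripts: TranscriptSet,
    readthrough_calls: Mapping[str, bool],
    de_table: pd.DataFrame,
    horizon: int = DEFAULT_HORIZON,
) -> EnvironmentRecord:
    """Build the environment record for one gene.

    ``readthrough_calls`` maps transcript id to a readthrough flag;
    ``de_table`` must be indexed by gene with a ``log2fc`` column.
    """
    if gene.id not in de_table.index:
        raise KeyError(f"gene {gene.id} absent from DE table")
    called = lambda t: bool(readthrough_calls.get(t.id, False))

    orientation = classify_orientation(gene, transcripts, horizon=horizon)

    conv_mRNA = False
    conv_ncRNA = False
    # any opposite-strand neighbour beyond the 3' end within the horizon
    for t in transcripts:
        if t.id == gene.id or t.interval.chrom != gene.interval.chrom:
            continue
        if t.interval.strand == gene.interval.strand:
            continue
        iv = gene.interval
        d = t.interval.start - iv.end if iv.strand == "+" else iv.start - t.interval.end
        if d < -len(t.interval) or d > horizon:  # allow partial overlap
            continue
        if called(t):
            if t.rna_class == "mRNA":
                conv_mRNA = True
            elif t.rna_class in NCRNA_CLASSES:
                conv_ncRNA = True

    upstream = _upstream_same_strand(gene, transcripts, horizon)
    tandem = upstream is not None and called(upstream)

    return EnvironmentRecord(
        gene=gene.id,
        expression_change=float(de_table.loc[gene.id, "log2fc"]),
        orientation=orientation,
        conv_mRNA_RT=conv_mRNA,
        conv_ncRNA_RT=conv_ncRNA,
        tandem_RT=tandem,
    )


def records_to_frame(records: list[EnvironmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.expression_change for r in records],
            "orientation": [r.orientation for r in records],
            "conv_mRNA_RT": [r.conv_mRNA_RT for r in records],
            "conv_ncRNA_RT": [r.conv_ncRNA_RT for r in records],
            "tandem_RT": [r.tandem_RT for r in records],
        }
    ).set_index("gene")


def tally_environments(
    records: pd.DataFrame,
    top_n: int = 30,
    exclude: tuple[str, ...] = (),
) -> dict[str, int]:
    """Category counts over the ``top_n`` most down-regulated genes.

    ``records`` needs columns ``log2fc``, ``orientation`` ("C"/"T"/missing)
    and the three readthrough flags.  ``exclude`` removes genes before
    ranking (e.g. the gene deleted in the mutant, which is trivially the
    most down-regulated).  Categories overlap except ``no_interference``,
    which is the complement of any readthrough flag.
    """
    df = records.drop(index=[g for g in exclude if g in records.index])
    df = df.sort_values("log2fc", ascending=True)
    if top_n > len(df):
        raise ValueError(f"top_n {top_n} exceeds {len(df)} records")
    df = df.iloc[:top_n]
    flags = df[["conv_mRNA_RT", "conv_ncRNA_RT", "tandem_RT"]].fillna(False).astype(bool)
    conv = df["orientation"] == "C"
    return {
        "n": int(len(df)),
        "convergent": int(conv.sum()),
        "convergent_mRNA_RT": int((conv & flags["conv_mRNA_RT"]).sum()),
        "conv_ncRNA_RT": int(flags["conv_ncRNA_RT"].sum()),
        "tandem_RT_only": int(
            (flags["tandem_RT"] & ~flags["conv_mRNA_RT"] & ~flags["conv_ncRNA_RT"]).sum()
        ),
        "no_interference": int((~flags.any(axis=1)).sum()),
    }


def load_example_environment_table() -> pd.DataFrame:
    """Curated environment annotations for the 30 most down-regulated genes
    of a published RNA-packaging-mutant tiling-array dataset (plus the
    deleted gene itself), shipped as a TSV for exact regression tests."""
    with resources.files("rtscan.data").joinpath("down_regulated_environment.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."])
    for col in ("conv_mRNA_RT", "conv_ncRNA_RT", "tandem_RT"):
        df[col] = df[col].fillna(False).astype(bool)
    return df.set_index("gene")


__all__ = [
    "DEFAULT_HORIZON",
    "EnvironmentRecord",
    "classify_orientation",
    "annotate_environment",
    "records_to_frame",
    "tally_environments",
    "load_example_environment_table",
]
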