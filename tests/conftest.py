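import numpy as np
import pytest

from rtscan.io import (
    Genome,
    GenomicInterval,
    ProbeTrack,
    Read,
    ReadSet,
    TranscriptAnnotation,
    TranscriptSet,
)


@pytest.fixture
def plus_gene():
    return TranscriptAnnotation(
        interval=GenomicInterval("chr1", 1000, 2000, "+"),
        id="GPLUS",
        rna_class="mRNA",
        polyA=1999,
    )


@pytest.fixture
def minus_gene():
    return TranscriptAnnotation(
        interval=GenomicInterval("chr1", 1000, 2000, "-"),
        id="GMINUS",
        rna_class="mRNA",
        polyA=1000,
    )


def make_track(probes, samples=("wt_1", "wt_2", "mut_1", "mut_2")):
    """Build a ProbeTrack from rows of (chrom, pos, strand, value...) where a
    scalar value is broadcast to all samples."""
    grouped = {}
    for row in probes:
        chrom, pos, strand, val = row[0], row[1], row[2], row[3:]
        if len(val) == 1:
            val = tuple(val) * len(samples)
        grouped.setdefault((chrom, strand), []).append((pos, val))
    data = {}
    for key, entries in grouped.items():
        entries.sort()
        pos = np.array([e[0] for e in entries], dtype=np.int64)
        intens = np.array([e[1] for e in entries], dtype=float)
        data[key] = (pos, intens)
    return ProbeTrack(list(samples), data)


@pytest.fixture
def uniform_track():
    """Probes every 10 nt on both strands of chr1[0, 3000), intensity 1.0."""
    rows = []
    for strand in "+-":
        for pos in range(0, 3000, 10):
            rows.append(("chr1", pos, strand, 1.0))
    return make_track(rows)


@pytest.fixture
def simple_reads():
    reads = [
        Read(GenomicInterval("chr1", 100, 130, "+"), name="a"),
        Read(GenomicInterval("chr1", 110, 140, "+"), name="b"),
        Read(GenomicInterval("chr1", 500, 530, "-"), name="c"),
    ]
    return ReadSet(reads, total_mapped=10**6)


@pytest.fixture
def toy_genome():
    return Genome({"chr1": "ACGT" * 1000})


def make_transcripts(specs):
    """specs: iterable of (id, chrom, start, end, strand, rna_class[, polyA])."""
    out = []
    for s in specs:
        polyA = s[6] if len(s) > 6 else None
        out.append(
            TranscriptAnnotation(
                interval=GenomicInterval(s[1], s[2], s[3], s[4]),
                id=s[0],
                rna_class=s[5],
                polyA=polyA,
            )
        )
    return TranscriptSet(out)
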