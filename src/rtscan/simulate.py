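"""Synthetic annotations, probe intensities and CRAC-like reads.

Ground truth is returned alongside every dataset so downstream statistics
can be validated offline: per-gene expression, injected 3'-extension flags
and deltas, and the realized genomic-environment label.

Randomness: each generator draws from ``default_rng([seed, offset])`` with a
fixed per-operation offset, so enlarging one component does not perturb the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rtscan.io import (
    DEFAULT_SAMPLES,
    Genome,
    GenomicInterval,
    ProbeTrack,
    Read,
    ReadSet,
    TranscriptAnnotation,
    TranscriptSet,
)

_OP_GENOME = 0
_OP_PROBES = 1
_OP_READS = 2
_OP_SEQUENCE = 3

CRAC_BIASES = ("five_prime", "three_prime", "uniform")


@dataclass
class SimConfig:
    """Knobs for the synthetic genome/array/read generators."""

    n_genes: int = 200
    chrom_length: int | None = None  # None: sized to fit the gene layout
    chrom_name: str = "chrS"
    probe_step: int = 8
    gene_length_mean_log: float = float(np.log(1200.0))
    gene_length_sd_log: float = 0.25
    min_gene_length: int = 300
    gap_mean_log: float = float(np.log(800.0))
    gap_sd_log: float = 0.3
    min_gap: int = 450
    fraction_readthrough_genes: float = 0.0
    readthrough_delta: float = 3.0  # log2 units over DN200 of affected genes
    readthrough_decay_halflength: float = 500.0  # nt
    noise_sd: float = 0.5  # log2 units
    background_intensity: float = -5.0  # log2 units
    expression_mean: float = 3.0
    expression_sd: float = 1.0
    fraction_convergent_pairs: float = 0.0  # fraction of *genes* in convergent pairs
    interference_knockdown: float = 0.0  # log2 drop in mutant expr of interfered genes
    class_fractions: dict = field(
        default_factory=lambda: {"mRNA": 0.85, "snoRNA": 0.05, "CUT": 0.05, "SUT": 0.05}
    )
    crac_bias: str = "five_prime"
    oligoA_fraction: float = 0.0
    reads_per_sample: int = 10_000
    read_length_mean: float = 30.0
    read_length_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_readthrough_genes",
            "fraction_convergent_pairs",
            "oligoA_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.probe_step < 1:
            raise ValueError("probe_step must be >= 1")
        if self.crac_bias not in CRAC_BIASES:
            raise ValueError(f"crac_bias must be one of {CRAC_BIASES}")
        if self.fraction_readthrough_genes > 0 and self.readthrough_delta <= 0:
            raise ValueError("readthrough_delta must be > 0 when readthrough genes exist")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")


def _rng(config: SimConfig, op: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), op])


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[TranscriptSet, pd.DataFrame]:
    """Lay out non-overlapping genes and draw per-gene ground truth.

    Returns the annotation plus a DataFrame with columns ``gene``,
    ``expression`` (log2), ``readthrough`` (bool), ``delta``, ``environment``
    ({convergent, tandem, isolated}) and ``interfered`` (bool: 3'-adjacent to
    an injected readthrough gene, used for the optional expression coupling).
    """
    rng = _rng(config, _OP_GENOME)
    n = config.n_genes
    lengths = np.maximum(
        config.min_gene_length,
        rng.lognormal(config.gene_length_mean_log, config.gene_length_sd_log, size=n),
    ).astype(int)
    gaps = np.maximum(
        config.min_gap,
        rng.lognormal(config.gap_mean_log, config.gap_sd_log, size=n + 1),
    ).astype(int)

    # unit layout: convergent pair (+ then -) with prob q, else a lone gene
    f = config.fraction_convergent_pairs
    q = f / (2.0 - f) if f > 0 else 0.0
    strands: list[str] = []
    pair_partner: list[int | None] = []  # index of convergent partner
    i = 0
    while i < n:
        if i + 1 < n and rng.random() < q:
            strands += ["+", "-"]
            pair_partner += [i + 1, i]
            i += 2
        else:
            strands.append(rng.choice(["+", "-"]))
            pair_partner.append(None)
            i += 1

    classes = rng.choice(
        list(config.class_fractions),
        size=n,
        p=list(config.class_fractions.values()),
    )

    cursor = int(gaps[0])
    transcripts = []
    for g in range(n):
        iv = GenomicInterval(
            config.chrom_name, cursor, cursor + int(lengths[g]), strands[g]
        )
        cursor = iv.end + int(gaps[g + 1])
        rna_class = str(classes[g])
        transcripts.append(
            TranscriptAnnotation(
                interval=iv,
                id=f"G{g:05d}",
                rna_class=rna_class,
                polyA=iv.three_prime,
                sno_transcript_class="monocistronic" if rna_class == "snoRNA" else None,
            )
        )
    if config.chrom_length is not None and cursor > config.chrom_length:
        raise ValueError(
            f"chrom_length {config.chrom_length} too short for {n} genes "
            f"(need >= {cursor})"
        )

    expression = rng.normal(config.expression_mean, config.expression_sd, size=n)
    rt_flags = rng.random(n) < config.fraction_readthrough_genes
    deltas = np.where(rt_flags, config.readthrough_delta, 0.0)

    # realized environment labels from the layout (5 kb horizon)
    tset = TranscriptSet(transcripts)
    env = []
    interfered = []
    for g, t in enumerate(transcripts):
        nb_same, _ = tset.nearest_downstream(t, same_strand=True, horizon=5000)
        nb_any, d_any = tset.nearest_downstream(t, same_strand=False, horizon=5000)
        if pair_partner[g] is not None:
            env.append("convergent")
        elif nb_same is not None and nb_any is not None and nb_any.id == nb_same.id:
            env.append("tandem")
        elif nb_any is not None and nb_any.interval.strand != t.interval.strand:
            # opposite-strand neighbour with 3' end facing this gene
            env.append("convergent")
        elif nb_same is not None:
            env.append("tandem")
        else:
            env.append("isolated")
        # interfered: convergent partner or *nearest* upstream same-strand
        # gene (within 5 kb) reads through
        hit = False
        if pair_partner[g] is not None and rt_flags[pair_partner[g]]:
            hit = True
        nearest_up = None
        nearest_d = None
        for h, other in enumerate(transcripts):
            if h == g:
                continue
            oiv = other.interval
            if oiv.strand != t.interval.strand:
                continue
            d = (
                t.interval.start - oiv.end
                if oiv.strand == "+"
                else oiv.start - t.interval.end
            )
            if 0 <= d <= 5000 and (nearest_d is None or d < nearest_d):
                nearest_up, nearest_d = h, d
        if nearest_up is not None and rt_flags[nearest_up]:
            hit = True
        interfered.append(hit)

    truth = pd.DataFrame(
        {
            "gene": [t.id for t in transcripts],
            "expression": expression,
            "readthrough": rt_flags,
            "delta": deltas,
            "environment": env,
            "interfered": interfered,
        }
    )
    return tset, truth


# ---------------------------------------------------------------------------
# Probe intensities
# ---------------------------------------------------------------------------

def simulate_probe_intensities(
    transcripts: TranscriptSet,
    truth: pd.DataFrame,
    config: SimConfig,
    samples: Sequence[str] = DEFAULT_SAMPLES,
) -> ProbeTrack:
    """Tiling-array model: background + gene expression + Gaussian noise.

    Mutant samples additionally carry ``delta * 2^(-d / halflength)`` on
    same-strand probes ``d`` nt downstream of each readthrough gene's 3'
    end; when ``interference_knockdown > 0``, mutant gene-body intensity of
    interfered genes is lowered by that amount.
    """
    rng = _rng(config, _OP_PROBES)
    chrom = config.chrom_name
    end = config.chrom_length
    if end is None:
        end = max(t.interval.end for t in transcripts) + 2000
    positions = np.arange(0, end, config.probe_step, dtype=np.int64)
    n_probes = positions.size
    by_gene = truth.set_index("gene")

    data = {}
    for strand in ("+", "-"):
        base = np.full(n_probes, config.background_intensity, dtype=float)
        mut_extra = np.zeros(n_probes, dtype=float)
        mut_body = np.zeros(n_probes, dtype=float)
        for t in transcripts:
            iv = t.interval
            if iv.strand != strand:
                continue
            row = by_gene.loc[t.id]
            lo = np.searchsorted(positions, iv.start, side="left")
            hi = np.searchsorted(positions, iv.end, side="left")
            base[lo:hi] = row["expression"]
            if config.interference_knockdown > 0 and bool(row["interfered"]):
                mut_body[lo:hi] = -config.interference_knockdown
            if bool(row["readthrough"]) and row["delta"] > 0:
                lam = config.readthrough_decay_halflength
                span = int(lam * np.log2(max(row["delta"], 1e-9) / 1e-3)) + 1
                if strand == "+":
                    lo2 = np.searchsorted(positions, iv.end, side="left")
                    hi2 = np.searchsorted(positions, iv.end + span, side="left")
                    d = positions[lo2:hi2] - iv.end
                else:
                    lo2 = np.searchsorted(positions, iv.start - span, side="left")
                    hi2 = np.searchsorted(positions, iv.start, side="left")
                    d = iv.start - 1 - positions[lo2:hi2]
                mut_extra[lo2:hi2] += row["delta"] * np.power(2.0, -d / lam)
        intens = np.empty((n_probes, len(samples)), dtype=float)
        for j, sample in enumerate(samples):
            noise = (
                rng.normal(0.0, config.noise_sd, size=n_probes)
                if config.noise_sd > 0
                else np.zeros(n_probes)
            )
            col = base + noise
            if sample.startswith("mut"):
                col = col + mut_extra + mut_body
            intens[:, j] = col
        data[(chrom, strand)] = (positions.copy(), intens)
    return ProbeTrack(list(samples), data)


# ---------------------------------------------------------------------------
# CRAC-like reads
# ---------------------------------------------------------------------------

def simulate_crac_reads(
    transcripts: TranscriptSet,
    truth: pd.DataFrame,
    config: SimConfig,
) -> ReadSet:
    """Stranded ~30 nt reads with configurable positional bias and oligo(A).

    Read abundance per gene is proportional to ``2^expression``; start
    positions follow a Beta(1,3) (5'-biased), Beta(3,1) (3'-biased) or
    uniform law along the gene; a configured fraction carries a
    non-templated ``"AA" + ...`` tail.
    """
    rng = _rng(config, _OP_READS)
    n_reads = config.reads_per_sample
    if n_reads == 0:
        return ReadSet([], total_mapped=0)
    genes = list(transcripts)
    weights = np.power(2.0, truth.set_index("gene").loc[[t.id for t in genes], "expression"].to_numpy())
    weights = weights / weights.sum()
    counts = rng.multinomial(n_reads, weights)

    if config.crac_bias == "five_prime":
        draw_u = lambda k: rng.beta(1.0, 3.0, size=k)
    elif config.crac_bias == "three_prime":
        draw_u = lambda k: rng.beta(3.0, 1.0, size=k)
    else:
        draw_u = lambda k: rng.random(k)

    reads: list[Read] = []
    idx = 0
    for t, k in zip(genes, counts):
        if k == 0:
            continue
        iv = t.interval
        gene_len = len(iv)
        rlens = np.clip(
            np.rint(rng.normal(config.read_length_mean, config.read_length_sd, size=k)),
            15,
            min(60, gene_len),
        ).astype(int)
        u = draw_u(k)
        # u is the fractional offset of the read 5' end from the gene 5' end
        max_off = np.maximum(gene_len - rlens, 0)
        offs = np.minimum((u * gene_len).astype(int), max_off)
        tails = rng.random(k) < config.oligoA_fraction
        extra = rng.poisson(1.5, size=k)
        for j in range(k):
            if iv.strand == "+":
                start = iv.start + int(offs[j])
                end = start + int(rlens[j])
            else:
                end = iv.end - int(offs[j])
                start = end - int(rlens[j])
            tail = "A" * (2 + int(extra[j])) if tails[j] else ""
            reads.append(
                Read(
                    GenomicInterval(iv.chrom, start, end, iv.strand),
                    name=f"r{idx:07d}",
                    tail3=tail,
                )
            )
            idx += 1
    return ReadSet(reads, total_mapped=n_reads)


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

def simulate_sequence(config: SimConfig, length: int | None = None) -> Genome:
    """Uniform-random ACGT contig matching the simulated layout."""
    rng = _rng(config, _OP_SEQUENCE)
    if length is None:
        length = config.chrom_length or 0
        if length == 0:
            raise ValueError("provide length or set config.chrom_length")
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(codes[rng.integers(0, 4, size=length)]).decode("ascii")
    return Genome({config.chrom_name: seq})


def plant_motif(
    genome: Genome,
    transcripts: TranscriptSet,
    gene_ids: Sequence[str],
    motif_dna: str,
    offset_from_polyA: int = -50,
) -> Genome:
    """Overwrite genomic sequence so ``motif_dna`` (sense strand) starts at
    ``offset_from_polyA`` nt relative to each gene's polyA site.

    Negative offsets place the motif upstream of the polyA site.  Returns a
    new :class:`Genome`.
    """
    contigs = dict(genome.contigs)
    for gid in gene_ids:
        t = transcripts[gid]
        iv = t.interval
        pa = t.polyA if t.polyA is not None else iv.three_prime
        m = motif_dna
        if iv.strand == "+":
            start = pa + offset_from_polyA
            seq = contigs[iv.chrom]
            contigs[iv.chrom] = seq[:start] + m + seq[start + len(m) :]
        else:
            from Bio.Seq import Seq

            start = pa - offset_from_polyA - len(m) + 1
            rc = str(Seq(m).reverse_complement())
            seq = contigs[iv.chrom]
            contigs[iv.chrom] = seq[:start] + rc + seq[start + len(m) :]
    return Genome(contigs)


def truth_de_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Differential-expression table implied by the generator.

    log2FC = mutant minus wild-type expression; only interfered genes move
    (by ``-interference_knockdown``).
    """
    log2fc = np.where(
        truth["interfered"].to_numpy(), -config.interference_knockdown, 0.0
    )
    return pd.DataFrame(
        {"gene": truth["gene"], "log2fc": log2fc, "adj_p": np.where(log2fc != 0, 0.01, 1.0)}
    )


__all__ = [
    "SimConfig",
    "CRAC_BIASES",
    "simulate_genome",
    "simulate_probe_intensities",
    "simulate_crac_reads",
    "simulate_sequence",
    "plant_motif",
    "truth_de_table",
]
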