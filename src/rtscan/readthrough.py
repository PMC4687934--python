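"""Genome-wide readthrough statistic on strand-specific tiling arrays.

Per transcript, three strand-aware windows are defined: DN100 (100 nt
immediately downstream of the 3' end), DN200 (the next 200 nt) and TRAN
(the transcript body minus the first and last 50 nt).  A per-sample
readthrough *score* is the median log2 probe intensity in DN200 minus that
in TRAN; the readthrough *ratio* of an experiment is mutant score minus
wild-type score.  Ratios of wild-type replicate 2 versus replicate 1 over
the same gene set form an empirical null; one-sided empirical p-values are
controlled with Benjamini-Hochberg at the chosen FDR.

The two replicate experiments are treated separately (experiment 1 pairs
mutant rep 1 with WT rep 1, experiment 2 the rep-2 samples) and a stringent
call set is obtained by intersecting their significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rtscan.io import (
    GenomicInterval,
    ProbeTrack,
    ReadSet,
    TranscriptAnnotation,
    TranscriptSet,
)

#: transcript classes entering the genome-wide analysis
ANALYSIS_CLASSES = ("mRNA", "snoRNA", "CUT", "SUT")

DN100_LEN = 100
DN200_LEN = 200
BODY_TRIM = 50
MIN_LENGTH = 200
MIN_CLEARANCE = 400
MIN_PROBES = 8

CBC1_MAX_READS = 10       # filter (i): pass iff DN100 Cbc1 reads < 10
TRAN_FLOOR = -4.88        # filter (ii)
DN100_TRAN_FRACTION = 0.7 # filter (iii)
MUT_WT_TRAN_FRACTION = 0.7  # filter (iv)


class InvalidWindowError(ValueError):
    """A scoring window has too few probes."""


@dataclass(frozen=True)
class WindowSet:
    """The three scoring windows of one transcript."""

    dn100: GenomicInterval
    dn200: GenomicInterval
    tran: GenomicInterval


def define_windows(transcript: TranscriptAnnotation | GenomicInterval) -> WindowSet:
    """Strand-aware DN100/DN200/TRAN windows for one transcript.

    Raises ``ValueError`` for transcripts of length <= 2 * BODY_TRIM, whose
    trimmed body would be empty.
    """
    iv = transcript.interval if isinstance(transcript, TranscriptAnnotation) else transcript
    if len(iv) <= 2 * BODY_TRIM:
        raise ValueError(
            f"transcript length {len(iv)} too short for a {2 * BODY_TRIM}-nt trim"
        )
    return WindowSet(
        dn100=iv.downstream(0, DN100_LEN),
        dn200=iv.downstream(DN100_LEN, DN200_LEN),
        tran=GenomicInterval(iv.chrom, iv.start + BODY_TRIM, iv.end - BODY_TRIM, iv.strand),
    )


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

def inclusion_filter(
    transcripts: TranscriptSet,
    probe_track: ProbeTrack,
    classes: tuple[str, ...] = ANALYSIS_CLASSES,
    min_length: int = MIN_LENGTH,
    min_clearance: int = MIN_CLEARANCE,
    min_probes: int = MIN_PROBES,
) -> pd.DataFrame:
    """Evaluate per-gene inclusion criteria; nothing is silently dropped.

    A transcript is eligible when it is >= ``min_length`` nt, has >=
    ``min_clearance`` nt of same-strand clearance downstream of its 3' end
    to the next annotated feature, and has >= ``min_probes`` probes in each
    of DN100, DN200 and TRAN.  Exception: an mRNA whose violating downstream
    feature is a CUT or SUT keeps its spacing flag (such ncRNAs typically
    are the upstream gene's own readthrough product).

    Returns a DataFrame indexed by gene id with boolean columns
    ``incl_length``, ``incl_spacing``, ``incl_probes`` and ``eligible``.
    """
    rows = []
    for t in transcripts.by_class(classes):
        ok_len = t.length >= min_length
        neighbour, dist = transcripts.nearest_downstream(
            t, same_strand=True, horizon=min_clearance - 1
        )
        ok_spacing = neighbour is None
        if not ok_spacing and t.rna_class == "mRNA" and neighbour.rna_class in ("CUT", "SUT"):
            ok_spacing = True
        ok_probes = False
        if t.length > 2 * BODY_TRIM:
            w = define_windows(t)
            ok_probes = all(
                probe_track.query_interval(win)[0].size >= min_probes
                for win in (w.dn100, w.dn200, w.tran)
            )
        rows.append(
            {
                "gene": t.id,
                "incl_length": ok_len,
                "incl_spacing": ok_spacing,
                "incl_probes": ok_probes,
                "eligible": ok_len and ok_spacing and ok_probes,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Scores, ratios, null
# ---------------------------------------------------------------------------

def window_median(
    window: GenomicInterval,
    probe_track: ProbeTrack,
    sample: str,
    min_probes: int = MIN_PROBES,
) -> float:
    pos, intens = probe_track.query_interval(window)
    if pos.size < min_probes:
        raise InvalidWindowError(
            f"window {window} has {pos.size} probes (< {min_probes})"
        )
    return float(np.median(intens[:, probe_track.sample_column(sample)]))


def readthrough_score(
    windows: WindowSet,
    probe_track: ProbeTrack,
    sample: str,
    min_probes: int = MIN_PROBES,
) -> float:
    """median(DN200) - median(TRAN) on the log2 scale, for one sample."""
    return window_median(windows.dn200, probe_track, sample, min_probes) - window_median(
        windows.tran, probe_track, sample, min_probes
    )


def readthrough_ratio(score_mut: float, score_wt: float) -> float:
    """Mutant readthrough score minus wild-type readthrough score."""
    return score_mut - score_wt


def empirical_null(
    probe_track: ProbeTrack,
    eligible: list[TranscriptAnnotation],
    wt_samples: tuple[str, str] = ("wt_1", "wt_2"),
) -> np.ndarray:
    """Null ratios: score(wt replicate 2) - score(wt replicate 1), per gene."""
    if not eligible:
        raise ValueError("empty eligible gene set")
    out = np.empty(len(eligible))
    for i, t in enumerate(eligible):
        w = define_windows(t)
        out[i] = readthrough_ratio(
            readthrough_score(w, probe_track, wt_samples[1]),
            readthrough_score(w, probe_track, wt_samples[0]),
        )
    return out


def empirical_pvalue(ratio: float, null: np.ndarray) -> float:
    """One-sided +1-corrected empirical p: (1 + #{null >= ratio}) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(ratio):
        raise ValueError(f"non-finite ratio {ratio}")
    return float((1 + np.count_nonzero(null >= ratio)) / (1 + null.size))


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``alpha``; flags in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= alpha * np.arange(1, n + 1) / n
    flags = np.zeros(n, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return flags


# ---------------------------------------------------------------------------
# Expression filters (i)-(iv)
# ---------------------------------------------------------------------------

def count_reads_in_window(reads: ReadSet, window: GenomicInterval) -> int:
    """Reads overlapping the window by >= 1 nt on the matching strand."""
    return sum(
        1
        for r in reads
        if r.interval.strand == window.strand and r.interval.overlaps(window)
    )


def expression_filters(
    windows: WindowSet,
    probe_track: ProbeTrack,
    cbc1_reads: ReadSet | None,
    cbc1_max: int = CBC1_MAX_READS,
    tran_floor: float = TRAN_FLOOR,
    dn100_fraction: float = DN100_TRAN_FRACTION,
    mut_fraction: float = MUT_WT_TRAN_FRACTION,
    missing_cbc1: str = "fail",
) -> dict[str, bool]:
    """Evaluate stringent expression filters for one gene.

    (i)   fewer than ``cbc1_max`` cap-binding-complex CRAC reads in DN100
          (evidence of independent downstream initiation);
    (ii)  mean-of-replicates TRAN median above ``tran_floor`` for both
          strains;
    (iii) mutant DN100 median exceeds ``dn100_fraction`` of the mutant TRAN
          median;
    (iv)  mutant TRAN median is at least ``mut_fraction`` of the WT TRAN
          median.

    Fractions are applied directly to the (log2-scale) median values; note
    these can be negative, which is documented behaviour.  Replicate means
    are used for (ii)-(iv).  ``missing_cbc1`` controls filter (i) without a
    read set: "fail" (closed) or "pass" (open).
    """
    def mean_median(win: GenomicInterval, samples: tuple[str, str]) -> float:
        return float(
            np.mean([window_median(win, probe_track, s) for s in samples])
        )

    wt_tran = mean_median(windows.tran, ("wt_1", "wt_2"))
    mut_tran = mean_median(windows.tran, ("mut_1", "mut_2"))
    mut_dn100 = mean_median(windows.dn100, ("mut_1", "mut_2"))

    if cbc1_reads is None:
        f_cbc1 = missing_cbc1 == "pass"
    else:
        f_cbc1 = count_reads_in_window(cbc1_reads, windows.dn100) < cbc1_max
    f_expr_floor = (wt_tran > tran_floor) and (mut_tran > tran_floor)
    f_dn100_frac = mut_dn100 > dn100_fraction * mut_tran
    f_tran_frac = mut_tran >= mut_fraction * wt_tran
    return {
        "f_cbc1": bool(f_cbc1),
        "f_expr_floor": bool(f_expr_floor),
        "f_dn100_frac": bool(f_dn100_frac),
        "f_tran_frac": bool(f_tran_frac),
        "pass_expression": bool(f_cbc1 and f_expr_floor and f_dn100_frac and f_tran_frac),
    }


# ---------------------------------------------------------------------------
# Ranking and correlations
# ---------------------------------------------------------------------------

def rank_genes(ratios) -> np.ndarray:
    """Rank 1 = largest mean ratio; ties share the average rank."""
    x = np.asarray(ratios, dtype=float)
    return stats.rankdata(-x, method="average")


def length_correlation(ratios, lengths) -> tuple[float, float]:
    """Spearman rank correlation of readthrough ratio against gene length."""
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 records")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("undefined correlation for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_readthrough(
    transcripts: TranscriptSet,
    probe_track: ProbeTrack,
    cbc1_reads: ReadSet | None = None,
    alpha: float = 0.05,
    classes: tuple[str, ...] = ANALYSIS_CLASSES,
    apply_expression_filters: bool = False,
    missing_cbc1: str = "fail",
) -> pd.DataFrame:
    """Full readthrough analysis; one row per considered transcript.

    Columns include the inclusion flags, per-sample scores, per-experiment
    ratios / empirical p-values / BH significance flags, the intersected
    ``sig_both`` flag, the expression-filter flags when requested, the mean
    ratio and the rank (defined over genes passing all requested filters).
    """
    incl = inclusion_filter(transcripts, probe_track, classes=classes)
    eligible_ids = incl.index[incl["eligible"]].tolist()
    eligible = [transcripts[g] for g in eligible_ids]
    if not eligible:
        raise ValueError("no eligible transcripts")

    records = []
    for t in eligible:
        w = define_windows(t)
        scores = {
            s: readthrough_score(w, probe_track, s)
            for s in ("wt_1", "wt_2", "mut_1", "mut_2")
        }
        ratio_1 = readthrough_ratio(scores["mut_1"], scores["wt_1"])
        ratio_2 = readthrough_ratio(scores["mut_2"], scores["wt_2"])
        rec = {
            "gene": t.id,
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.interval.strand,
            "length": t.length,
            "rna_class": t.rna_class,
            **{f"score_{s}": v for s, v in scores.items()},
            "ratio_1": ratio_1,
            "ratio_2": ratio_2,
            "null_ratio": readthrough_ratio(scores["wt_2"], scores["wt_1"]),
        }
        if apply_expression_filters:
            rec.update(
                expression_filters(
                    w, probe_track, cbc1_reads, missing_cbc1=missing_cbc1
                )
            )
        records.append(rec)
    df = pd.DataFrame(records).set_index("gene")

    null = df["null_ratio"].to_numpy()
    for exp in (1, 2):
        ratios = df[f"ratio_{exp}"].to_numpy()
        pvals = np.array([empirical_pvalue(r, null) for r in ratios])
        df[f"p_{exp}"] = pvals
        df[f"sig_{exp}"] = bh_fdr(pvals, alpha=alpha)
    df["sig_both"] = df["sig_1"] & df["sig_2"]
    df["mean_ratio"] = (df["ratio_1"] + df["ratio_2"]) / 2.0

    ranked_mask = (
        df["pass_expression"]
        if apply_expression_filters and "pass_expression" in df
        else pd.Series(True, index=df.index)
    )
    df["rank"] = np.nan
    if ranked_mask.any():
        df.loc[ranked_mask, "rank"] = rank_genes(df.loc[ranked_mask, "mean_ratio"])

    # carry inclusion flags for excluded genes too
    out = incl.join(df, how="left")
    return out


__all__ = [
    "ANALYSIS_CLASSES",
    "WindowSet",
    "InvalidWindowError",
    "define_windows",
    "inclusion_filter",
    "window_median",
    "readthrough_score",
    "readthrough_ratio",
    "empirical_null",
    "empirical_pvalue",
    "bh_fdr",
    "count_reads_in_window",
    "expression_filters",
    "rank_genes",
    "length_correlation",
    "run_readthrough",
]
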