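"""Retained-intron events, junction-read classification and splicing efficiency.

Splicing efficiency (SE) for an intron is estimated from two read classes:
reads spanning the excised exon-exon junction (N_EE, evidence of splicing)
and reads crossing an unprocessed intron-exon boundary (N_IE, evidence of
retention):

    SE = 100 * N_EE / (N_EE + N_IE)

All coordinates are 0-based half-open genomic intervals internally; GTF
input (1-based inclusive) is converted at the reader boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntronAnnotation",
    "Read",
    "extract_retained_intron_events",
    "read_gtf_transcripts",
    "classify_read",
    "count_junction_reads",
    "compute_se",
    "filter_low_coverage",
    "average_replicates",
    "coverage_to_counts",
    "annotate_intron_sequences",
]

logger = logging.getLogger(__name__)

BP_CONSENSUS = "TACTAAC"  # UACUAAC in RNA
FIVE_SS_STANDARD = "GTATGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IntronAnnotation:
    """One retained-intron event: a single intron of one transcript.

    ``exons`` and ``introns`` are genomic [start, end) intervals; introns
    are exactly the gaps between consecutive exons. ``intron_index`` is
    0-based in transcript order (5' to 3' on the coding strand).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    intron_index: int
    n_introns: int = 1
    bp_seq: str | None = None
    five_ss_seq: str | None = None
    is_rpg: bool = False
    primer_offset: int | None = None
    introns: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        exons = sorted(self.exons)
        self.exons = exons
        self.introns = [
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        ]
        if not 0 <= self.intron_index < len(self.introns):
            raise ValueError("intron_index out of range for exon structure")
        s, e = self.intron
        if e - s <= 0:
            raise ValueError("intron length must be positive")

    @property
    def intron(self) -> tuple[int, int]:
        return self.introns[self.intron_index]

    @property
    def intron_length(self) -> int:
        s, e = self.intron
        return e - s

    @property
    def event_id(self) -> str:
        return f"{self.gene_id}.i{self.intron_index + 1}"

    @property
    def bp_is_consensus(self) -> bool | None:
        if self.bp_seq is None:
            return None
        return self.bp_seq.upper().replace("U", "T") == BP_CONSENSUS

    @property
    def five_ss_is_standard(self) -> bool | None:
        if self.five_ss_seq is None:
            return None
        return self.five_ss_seq.upper().replace("U", "T") == FIVE_SS_STANDARD


def extract_retained_intron_events(
    transcripts,
) -> list[IntronAnnotation]:
    """Extract one retained-intron event per intron from transcript models.

    Parameters
    ----------
    transcripts : iterable of (gene_id, chrom, strand, exons)
        ``exons`` is a list of genomic [start, end) intervals. Intronless
        transcripts yield no events; a transcript with overlapping exons
        is rejected with a warning.
    """
    events: list[IntronAnnotation] = []
    for gene_id, chrom, strand, exons in transcripts:
        exons = sorted(tuple(e) for e in exons)
        if any(e[0] >= e[1] for e in exons):
            logger.warning("%s: empty or inverted exon interval; skipped", gene_id)
            continue
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            logger.warning("%s: overlapping exons; transcript rejected", gene_id)
            continue
        n_introns = len(exons) - 1
        for k in range(n_introns):
            events.append(
                IntronAnnotation(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=list(exons),
                    intron_index=k,
                    n_introns=n_introns,
                )
            )
    return events


def read_gtf_transcripts(path: str):
    """Read transcript models from a GTF file via gffutils.

    Yields (transcript_id, chrom, strand, exons) with exons converted to
    0-based half-open intervals.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    for tx in db.features_of_type("transcript"):
        exons = [
            (ex.start - 1, ex.end)  # GTF is 1-based inclusive
            for ex in db.children(tx, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        yield tx.id, tx.seqid, tx.strand, exons


def annotate_intron_sequences(
    events: list[IntronAnnotation], genome: dict[str, str]
) -> None:
    """Fill 5'SS and branch-point sequences from a chromosome-sequence dict.

    The 5'SS 6-mer is the first six intronic nucleotides (strand-aware).
    The branch-point 7-mer is the window within the intron that best
    matches the yeast consensus UACUAAC, preferring windows nearer the
    3' end on ties (the biologically typical BP location).
    """
    for ev in events:
        chrom_seq = genome.get(ev.chrom)
        if chrom_seq is None:
            continue
        s, e = ev.intron
        intron_seq = chrom_seq[s:e].upper()
        if ev.strand == "-":
            intron_seq = _revcomp(intron_seq)
        if len(intron_seq) >= 6:
            ev.five_ss_seq = intron_seq[:6]
        if len(intron_seq) >= 7:
            best_score, best_start = -1, 0
            for i in range(len(intron_seq) - 6):
                score = sum(a == b for a, b in zip(intron_seq[i : i + 7], BP_CONSENSUS))
                if score >= best_score:  # >= prefers 3'-most tie
                    best_score, best_start = score, i
            ev.bp_seq = intron_seq[best_start : best_start + 7]


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class Read:
    """Simplified alignment record: chromosome, 0-based start, CIGAR string."""

    chrom: str
    start: int
    cigar: str

    @property
    def blocks(self) -> list[tuple[int, int]]:
        """Aligned reference blocks [start, end); N opens a new block."""
        blocks = []
        pos = self.start
        block_start = pos
        for n, op in _CIGAR_RE.findall(self.cigar):
            n = int(n)
            if op in "M=XD":
                pos += n
            elif op == "N":
                if pos > block_start:
                    blocks.append((block_start, pos))
                pos += n
                block_start = pos
            # I, S, H, P consume no reference
        if pos > block_start:
            blocks.append((block_start, pos))
        return blocks

    @property
    def gaps(self) -> list[tuple[int, int]]:
        b = self.blocks
        return [(b[i][1], b[i + 1][0]) for i in range(len(b) - 1)]


def classify_read(
    read: Read, event: IntronAnnotation, overhang: int = 4
) -> str:
    """Classify a read against one intron event as 'EE', 'IE' or 'neither'.

    EE: the read has a splice gap whose ends coincide exactly with the
    intron boundaries (an exon-exon junction read).
    IE: a contiguous aligned block crosses the 5'SS or 3'SS boundary with
    at least ``overhang`` nt on both sides (an unprocessed boundary read);
    a read crossing both boundaries contiguously still counts once.
    """
    if read.chrom != event.chrom:
        return "neither"
    intron_start, intron_end = event.intron
    if (intron_start, intron_end) in read.gaps:
        return "EE"
    for bs, be in read.blocks:
        for boundary in (intron_start, intron_end):
            if bs <= boundary - overhang and be >= boundary + overhang:
                return "IE"
    return "neither"


def count_junction_reads(
    reads, events: list[IntronAnnotation], overhang: int = 4
) -> pd.DataFrame:
    """Tally N_EE / N_IE per event over an iterable of reads."""
    counts = {ev.event_id: {"N_EE": 0, "N_IE": 0} for ev in events}
    reads = list(reads)
    for ev in events:
        for read in reads:
            cat = classify_read(read, ev, overhang=overhang)
            if cat != "neither":
                counts[ev.event_id][f"N_{cat}"] += 1
    out = pd.DataFrame(
        [{"event_id": k, **v} for k, v in counts.items()]
    )
    return out


def compute_se(n_ee: float, n_ie: float) -> float:
    """Splicing efficiency in percent: 100 * N_EE / (N_EE + N_IE).

    Returns NaN when both counts are zero (event unquantifiable).
    """
    if n_ee < 0 or n_ie < 0:
        raise ValueError("junction counts must be non-negative")
    total = n_ee + n_ie
    if total == 0:
        return float("nan")
    return 100.0 * n_ee / total


def filter_low_coverage(
    records: pd.DataFrame, threshold: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop event/condition groups whose replicate-mean total count is low.

    A group (event_id x strain x treatment x dose) is kept iff the mean of
    N_EE + N_IE over its replicates is >= ``threshold``. Idempotent.

    Returns
    -------
    (kept, log) : the surviving records and a per-group log table with
        the mean total and the keep/remove decision.
    """
    df = records.copy()
    df["total"] = df["N_EE"] + df["N_IE"]
    keys = [
        c for c in ("event_id", "strain", "treatment", "dose_uM") if c in df.columns
    ]
    means = df.groupby(keys, sort=False)["total"].mean().rename("mean_total")
    log = means.reset_index()
    log["kept"] = log["mean_total"] >= threshold
    kept_keys = log.loc[log["kept"], keys]
    kept = records.merge(kept_keys, on=keys, how="inner")
    return kept, log


def average_replicates(
    records: pd.DataFrame, method: str = "mean"
) -> pd.DataFrame:
    """Collapse replicates to one splicing efficiency per event/condition.

    method='mean' computes SE per replicate then averages (the default);
    method='pooled' sums counts across replicates first, which weights
    replicates by depth.
    """
    if method not in ("mean", "pooled"):
        raise ValueError("method must be 'mean' or 'pooled'")
    df = records.copy()
    keys = [
        c for c in ("event_id", "strain", "treatment", "dose_uM") if c in df.columns
    ]
    df["total"] = df["N_EE"] + df["N_IE"]
    if method == "mean":
        df["SE_rep"] = [
            compute_se(a, b) for a, b in zip(df["N_EE"], df["N_IE"])
        ]
        out = (
            df.groupby(keys, sort=False)
            .agg(
                SE=("SE_rep", "mean"),
                mean_total_count=("total", "mean"),
                n_replicates=("total", "size"),
            )
            .reset_index()
        )
    else:
        grouped = (
            df.groupby(keys, sort=False)
            .agg(
                N_EE=("N_EE", "sum"),
                N_IE=("N_IE", "sum"),
                mean_total_count=("total", "mean"),
                n_replicates=("total", "size"),
            )
            .reset_index()
        )
        grouped["SE"] = [
            compute_se(a, b) for a, b in zip(grouped["N_EE"], grouped["N_IE"])
        ]
        out = grouped.drop(columns=["N_EE", "N_IE"])
    return out


def coverage_to_counts(
    exonic_coverage_sum: float, read_span: float = 240.0
) -> float:
    """Convert summed per-position exonic coverage to an estimated read count.

    Each aligned paired-end read covers ``read_span`` genomic positions
    (240 for 2x120 nt non-overlapping mates), so count = coverage / span.
    """
    cov = np.asarray(exonic_coverage_sum, dtype=float)
    if np.any(cov < 0):
        raise ValueError("coverage must be non-negative")
    out = cov / float(read_span)
    return float(out) if np.isscalar(exonic_coverage_sum) else out
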