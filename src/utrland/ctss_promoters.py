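"""CTSS ingestion, clustering, promoter width and TOP/PRTE scoring.

CAGE transcription start sites (CTSS) are single genomic positions with
tag counts of observed capped 5' ends.  This module normalizes tag
counts to tags-per-million, clusters CTSS positions by distance,
computes 0.1-0.9 quantile promoter widths with the sharp (<10 bp) /
broad (>=10 bp) classification, builds per-gene TSS profiles against a
genome, and derives gene-level TOPscores and PRTE scores.

Coordinates are 0-based half-open internally; CTSS files carry 1-based
positions and are converted at I/O time.  Minus-strand sequences are
reverse-complemented before any motif scan so that scans always run
5'->3' on the transcript strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .motif_features import (
    has_prte,
    normalize_sequence,
    pyrimidine_run_length,
    reverse_complement,
)

__all__ = [
    "CtssRecord",
    "CtssTable",
    "TagCluster",
    "PromoterWidth",
    "GeneTssProfile",
    "ScoreRecord",
    "normalize_tpm",
    "cluster_ctss",
    "quantile_width",
    "topscore",
    "filter_min_avg_reads",
    "prte_score",
    "window_read_fractions",
]

logger = logging.getLogger(__name__)

SHARP_WIDTH_CUT = 10  # bp; width < cut => sharp, else broad
TOPSCORE_CAP = 16
MIN_AVG_READS = 500
PRTE_READ_LENGTH = 75
PRTE_SCORE_THRESHOLD = 10.0


@dataclass(frozen=True, order=True)
class CtssRecord:
    """One CTSS: a capped 5' end position with a tag count.

    ``pos`` is the 0-based genomic coordinate of the 5' end.
    """

    chrom: str
    pos: int
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.count < 0:
            raise ValueError("tag count must be non-negative")


@dataclass
class CtssTable:
    """A per-sample CTSS table with condition and polysome-fraction labels."""

    sample_id: str
    records: list[CtssRecord]
    condition: str = ""
    fraction: str = "total"  # total, LP or HP

    def __post_init__(self) -> None:
        keys = {(r.chrom, r.pos, r.strand) for r in self.records}
        if len(keys) != len(self.records):
            raise ValueError(f"duplicate (chrom, pos, strand) in table {self.sample_id}")

    @property
    def library_size(self) -> int:
        return sum(r.count for r in self.records)

    def sorted_records(self) -> list[CtssRecord]:
        return sorted(self.records, key=lambda r: (r.chrom, r.strand, r.pos))


def normalize_tpm(table: CtssTable) -> dict[tuple[str, int, str], float]:
    """Tags-per-million per record: count / library_size * 1e6.

    Returns a mapping keyed by (chrom, pos, strand); values sum to 1e6.
    """
    lib = table.library_size
    if not table.records or lib <= 0:
        raise ValueError(f"table {table.sample_id} has no tags")
    scale = 1e6 / lib
    return {(r.chrom, r.pos, r.strand): r.count * scale for r in table.records}


@dataclass
class TagCluster:
    """A distance cluster of CTSS positions on one strand of one chromosome.

    ``span`` is 0-based half-open and covers exactly the member positions.
    """

    chrom: str
    strand: str
    positions: dict[int, int]  # pos -> tag count
    tpm: float = 0.0

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.positions), max(self.positions) + 1)

    @property
    def total_tags(self) -> int:
        return sum(self.positions.values())

    @property
    def dominant_pos(self) -> int:
        # deterministic tie-break: lowest coordinate among argmax
        best = max(self.positions.values())
        return min(p for p, c in self.positions.items() if c == best)


def cluster_ctss(records: Iterable[CtssRecord], maxdist: int = 20) -> list[TagCluster]:
    """Distance clustering ("distclu"): same-chrom same-strand positions
    chained together while consecutive gaps are <= maxdist.

    The resulting partition is maximal and independent of input order.
    """
    by_group: dict[tuple[str, str], list[CtssRecord]] = defaultdict(list)
    for r in records:
        by_group[(r.chrom, r.strand)].append(r)
    clusters: list[TagCluster] = []
    for (chrom, strand), recs in sorted(by_group.items()):
        recs.sort(key=lambda r: r.pos)
        current: dict[int, int] = {}
        prev_pos: Optional[int] = None
        for r in recs:
            if prev_pos is not None and r.pos - prev_pos > maxdist:
                clusters.append(TagCluster(chrom, strand, current))
                current = {}
            current[r.pos] = current.get(r.pos, 0) + r.count
            prev_pos = r.pos
        if current:
            clusters.append(TagCluster(chrom, strand, current))
    return clusters


@dataclass(frozen=True)
class PromoterWidth:
    """Quantile width of a tag cluster with the sharp/broad call."""

    q_low_pos: int
    q_high_pos: int
    width: int
    shape: str  # "sharp" or "broad"


def quantile_width(
    cluster: TagCluster,
    q_low: float = 0.1,
    q_high: float = 0.9,
    sharp_cut: int = SHARP_WIDTH_CUT,
) -> PromoterWidth:
    """Promoter quantile width between cumulative tag fractions q_low and q_high.

    Cumulative fractions run 5'->3' in transcription direction (descending
    genome coordinate on the minus strand).  ``q_low_pos`` is the first
    position whose cumulative fraction reaches ``q_low``; width is
    inclusive (a single-position cluster has width 1).  Widths below
    ``sharp_cut`` are sharp, others broad.
    """
    total = cluster.total_tags
    if total <= 0:
        raise ValueError("cannot compute quantile width of an empty cluster")
    ascending = cluster.strand != "-"
    positions = sorted(cluster.positions, reverse=not ascending)
    counts = np.array([cluster.positions[p] for p in positions], dtype=float)
    cum = np.cumsum(counts) / total
    lo_idx = int(np.searchsorted(cum, q_low - 1e-12))
    hi_idx = int(np.searchsorted(cum, q_high - 1e-12))
    q_low_pos = positions[lo_idx]
    q_high_pos = positions[hi_idx]
    width = abs(q_high_pos - q_low_pos) + 1
    return PromoterWidth(
        q_low_pos=q_low_pos,
        q_high_pos=q_high_pos,
        width=width,
        shape="sharp" if width < sharp_cut else "broad",
    )


@dataclass
class GeneTssProfile:
    """Per-gene TSS positions with tag fractions and pyrimidine run lengths.

    ``fractions[i]`` is the tag fraction of TSS i within the gene's TSS
    region (summing to 1); ``run_lengths[i]`` is the pyrimidine run
    length of the genomic sequence starting at that TSS on the
    transcript strand (0 when the +1 base is a purine or N).
    """

    gene_id: str
    strand: str
    positions: list[int]
    counts: list[int]
    fractions: list[float] = field(default_factory=list)
    run_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.counts)
        if not self.fractions:
            if total <= 0:
                raise ValueError(f"gene {self.gene_id}: profile has zero tags")
            self.fractions = [c / total for c in self.counts]
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"gene {self.gene_id}: TSS fractions do not sum to 1")


def tss_sequence(genome: Mapping[str, str], chrom: str, pos: int, strand: str, length: int) -> str:
    """Transcript-strand genomic sequence of ``length`` nt whose first base
    is the 5' end at ``pos`` (0-based)."""
    seq = str(genome[chrom])
    if strand == "+":
        return normalize_sequence(seq[pos : pos + length])
    return reverse_complement(seq[max(0, pos - length + 1) : pos + 1])


def build_profile(
    gene_id: str,
    strand: str,
    chrom: str,
    tss_counts: Mapping[int, int],
    genome: Mapping[str, str],
    cap: int = TOPSCORE_CAP,
) -> GeneTssProfile:
    """Build a GeneTssProfile, reading pyrimidine run lengths from the genome."""
    positions = sorted(tss_counts)
    counts = [tss_counts[p] for p in positions]
    run_lengths = []
    for p in positions:
        seq = tss_sequence(genome, chrom, p, strand, cap + 1)
        run_lengths.append(pyrimidine_run_length(seq, 0, cap=cap) if seq else 0)
    return GeneTssProfile(
        gene_id=gene_id,
        strand=strand,
        positions=positions,
        counts=counts,
        run_lengths=run_lengths,
    )


@dataclass
class ScoreRecord:
    """Gene-level score bundle: TOPscore and/or PRTE score with flags."""

    gene_id: str
    topscore: Optional[float] = None
    is_top_gt2: Optional[bool] = None
    avg_reads: Optional[float] = None
    passes_read_filter: Optional[bool] = None
    prte_score: Optional[float] = None
    prte_flag: Optional[bool] = None


def topscore(profile: GeneTssProfile, cap: int = TOPSCORE_CAP) -> ScoreRecord:
    """TOPscore = sum_i f_i * min(L_i, cap) over the gene's TSS positions.

    f_i are tag fractions and L_i pyrimidine run lengths at each TSS.
    """
    if len(profile.run_lengths) != len(profile.fractions):
        raise ValueError(f"gene {profile.gene_id}: run lengths missing")
    score = sum(
        f * min(l, cap) for f, l in zip(profile.fractions, profile.run_lengths)
    )
    return ScoreRecord(gene_id=profile.gene_id, topscore=score, is_top_gt2=score > 2)


def filter_min_avg_reads(
    gene_counts: Mapping[str, Sequence[float]],
    min_avg: float = MIN_AVG_READS,
) -> dict[str, float]:
    """Keep genes whose mean tag count across samples is strictly > min_avg.

    Returns the mean count for each retained gene.
    """
    kept = {}
    for gene, counts in gene_counts.items():
        avg = float(np.mean(counts))
        if avg > min_avg:
            kept[gene] = avg
    return kept


def prte_score(
    table: CtssTable,
    genome: Mapping[str, str],
    gene_intervals: Mapping[str, tuple[str, int, int, str]],
    read_len: int = PRTE_READ_LENGTH,
    threshold: float = PRTE_SCORE_THRESHOLD,
) -> list[ScoreRecord]:
    """Per-gene PRTE score: PRTE-containing reads per million mapped reads.

    Each CTSS tag is modeled as a ``read_len``-nt transcript-strand read
    starting at its 5' end; the tag's count contributes to its gene's
    PRTE count when that read contains at least one PRTE 9-mer.  Scores
    are the per-gene counts normalized to the table's library size
    (counts per million); ``prte_flag`` is strict (score > threshold).

    ``gene_intervals`` maps gene_id -> (chrom, start, end, strand),
    0-based half-open.  CTSS falling outside every gene are logged and
    skipped.
    """
    lib = table.library_size
    if lib <= 0:
        raise ValueError(f"table {table.sample_id} has no tags")
    # interval lookup per (chrom, strand)
    by_loc: dict[tuple[str, str], list[tuple[int, int, str]]] = defaultdict(list)
    for gid, (chrom, start, end, strand) in gene_intervals.items():
        by_loc[(chrom, strand)].append((start, end, gid))
    for ivs in by_loc.values():
        ivs.sort()

    prte_counts: dict[str, int] = defaultdict(int)
    n_skipped = 0
    for r in table.records:
        gid = None
        for start, end, g in by_loc.get((r.chrom, r.strand), ()):
            if start <= r.pos < end:
                gid = g
                break
        if gid is None:
            n_skipped += 1
            continue
        read = tss_sequence(genome, r.chrom, r.pos, r.strand, read_len)
        if has_prte(read):
            prte_counts[gid] += r.count
    if n_skipped:
        logger.info("prte_score: skipped %d CTSS outside any gene", n_skipped)
    return [
        ScoreRecord(
            gene_id=gid,
            prte_score=(score := prte_counts[gid] / lib * 1e6),
            prte_flag=score > threshold,
        )
        for gid in sorted(gene_intervals)
        if gid in prte_counts
    ]


def window_read_fractions(
    table: CtssTable,
    windows: Mapping[str, Sequence[tuple[str, int, int, str]]],
) -> dict[str, Optional[list[float]]]:
    """Per-gene read fraction in each TSS window.

    ``windows`` maps gene_id to an ordered sequence of non-overlapping
    (chrom, start, end, strand) intervals (0-based half-open).  The
    fraction of window w is tags(w) / tags(union of the gene's windows);
    genes with zero tags in every window get ``None``.
    """
    out: dict[str, Optional[list[float]]] = {}
    for gene, wins in windows.items():
        tags = []
        for chrom, start, end, strand in wins:
            t = sum(
                r.count
                for r in table.records
                if r.chrom == chrom and r.strand == strand and start <= r.pos < end
            )
            tags.append(t)
        total = sum(tags)
        out[gene] = [t / total for t in tags] if total > 0 else None
    return out
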