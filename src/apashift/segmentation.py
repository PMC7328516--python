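"""PAS-anchored gene segmentation and per-segment coverage quantification.

A gene's candidate poly(A)-site peaks are filtered (a peak must carry more
than five 3'-end reads and at least 5% of the gene's total 3'-end reads),
then peaks closer than 50 nt are merged iteratively at the stronger peak's
position, and the gene body is cut into ordered windows ("segments") each
ending at — and including — its delimiting PAS.  Segment 0 starts at the
annotated TSS; genes retaining fewer than two peaks are ineligible for
APA scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .iolib import GeneModel, PASPeak, SampleSheet, ValidationError

__all__ = [
    "GeneSegmentation",
    "SegmentCountMatrix",
    "filter_peaks",
    "merge_peaks",
    "segment_gene",
    "segment_genes",
    "segment_intervals",
    "quantify_segments",
    "write_segmentation_bed",
    "read_segment_counts",
    "write_segment_counts",
]


@dataclass
class GeneSegmentation:
    """Ordered windows of one gene delimited by retained PAS peaks.

    ``retained_peaks`` and ``segments`` are in transcription (5'->3')
    order; segment coordinates are genomic 0-based half-open.  The most
    proximal segment is index 0, the most distal the last.
    """

    gene_id: str
    chrom: str
    strand: str
    retained_peaks: list[PASPeak]
    segments: list[tuple[int, int]]
    eligible: bool

    proximal_index: int = 0

    @property
    def distal_index(self) -> int:
        return len(self.segments) - 1

    @property
    def proximal_site(self) -> Optional[int]:
        return self.retained_peaks[0].site if self.retained_peaks else None

    @property
    def distal_site(self) -> Optional[int]:
        return self.retained_peaks[-1].site if self.retained_peaks else None


@dataclass
class SegmentCountMatrix:
    """Segments x samples table of read counts and mean per-base depth.

    Rows are indexed by ``(gene_id, segment_index)``; ``counts`` holds
    integer (pseudo-)read counts for the binomial GLM, ``depth`` the mean
    per-base coverage used for ratio/score computation.  ``size_factors``
    is filled by the statistics layer.
    """

    counts: pd.DataFrame
    depth: pd.DataFrame
    lengths: pd.Series
    conditions: dict[str, str]
    baseline: str
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("segment counts must be non-negative")
        levels = sorted(set(self.conditions.values()))
        if len(levels) != 2:
            raise ValidationError(f"two condition levels required, got {levels}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def test_level(self) -> str:
        return next(c for c in sorted(set(self.conditions.values())) if c != self.baseline)

    def samples_of(self, level: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == level]

    def genes(self) -> list[str]:
        return list(self.counts.index.get_level_values(0).unique())


# ---------------------------------------------------------------------------
# Peak filtering and merging


def filter_peaks(
    peaks: Sequence[PASPeak], min_count: int = 6, min_frac: float = 0.05
) -> list[PASPeak]:
    """Keep peaks with count > 5 reads (i.e. >= ``min_count``) carrying at
    least ``min_frac`` of the gene's total 3'-end reads.

    The fraction denominator is the gene's total over *all* its peaks,
    computed before any filtering.  Input order is preserved.
    """
    if not peaks:
        return []
    total = sum(p.count for p in peaks)
    return [p for p in peaks if p.count >= min_count and p.count >= min_frac * total]


def merge_peaks(peaks: Sequence[PASPeak], min_dist: int = 50) -> list[PASPeak]:
    """Iteratively merge peaks closer than ``min_dist`` nt.

    The closest pair merges first (ties broken at the lower coordinate);
    the merged peak sits at the stronger member's position (count ties go
    to the more distal, i.e. 3'-most, position) and carries the summed
    count.  Iterates until no two peaks are closer than ``min_dist``.
    Distance exactly ``min_dist`` does not merge.
    """
    if not peaks:
        return []
    strand = peaks[0].strand
    merged = sorted(peaks, key=lambda p: p.site)
    while len(merged) > 1:
        gaps = [merged[i + 1].site - merged[i].site for i in range(len(merged) - 1)]
        i = int(np.argmin(gaps))  # argmin returns the first (lowest-coordinate) tie
        if gaps[i] >= min_dist:
            break
        a, b = merged[i], merged[i + 1]
        if a.count > b.count:
            site = a.site
        elif b.count > a.count:
            site = b.site
        else:  # equal strength: keep the more distal position
            site = b.site if strand == "+" else a.site
        merged[i : i + 2] = [replace(a, site=site, count=a.count + b.count)]
    return merged


# ---------------------------------------------------------------------------
# Segmentation


def segment_intervals(
    start: int, end: int, strand: str, sites: Sequence[int]
) -> list[tuple[int, int]]:
    """Genomic 0-based half-open windows delimited by 1-based PAS sites.

    ``sites`` must be in transcription order.  Window i runs from the
    previous boundary (TSS for i=0) to — and including — site i.
    """
    out: list[tuple[int, int]] = []
    if strand == "+":
        prev = start
        for s in sites:
            out.append((prev, s))
            prev = s
    else:
        prev = end
        for s in sites:
            out.append((s - 1, prev))
            prev = s - 1
    return out


def segment_gene(
    gene: GeneModel, merged_peaks: Sequence[PASPeak], fallback_window: int = 200
) -> GeneSegmentation:
    """Build the gene's segmentation from its retained, merged peaks.

    Peaks must lie within the gene (or at most ``fallback_window`` nt
    beyond its annotated 3' end).  Fewer than two peaks flags the gene
    ineligible for APA scoring.
    """
    tx_order = sorted(merged_peaks, key=lambda p: p.site, reverse=(gene.strand == "-"))
    for p in tx_order:
        lo = gene.start + 1
        hi = gene.end
        if gene.strand == "+":
            hi += fallback_window
        else:
            lo -= fallback_window
        if not (lo <= p.site <= hi):
            raise ValidationError(
                f"gene {gene.gene_id}: PAS site {p.site} outside gene bounds "
                f"[{gene.start},{gene.end}) + {fallback_window} nt downstream window"
            )
    segments = segment_intervals(gene.start, gene.end, gene.strand, [p.site for p in tx_order])
    return GeneSegmentation(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        retained_peaks=list(tx_order),
        segments=segments,
        eligible=len(segments) >= 2,
    )


def segment_genes(
    genes: Sequence[GeneModel],
    peaks: Sequence[PASPeak],
    min_count: int = 6,
    min_frac: float = 0.05,
    merge_dist: int = 50,
    order: str = "filter-first",
    fallback_window: int = 200,
) -> dict[str, GeneSegmentation]:
    """Filter, merge and segment every gene with at least one retained peak.

    ``order`` selects filter-then-merge (default, following the stated rule
    order) or ``"merge-first"``; the 5% denominator is always the
    pre-filtering gene total.
    """
    if order not in ("filter-first", "merge-first"):
        raise ValueError(f"unknown order {order!r}")
    by_gene: dict[str, list[PASPeak]] = {}
    for p in peaks:
        by_gene.setdefault(p.gene_id, []).append(p)
    out: dict[str, GeneSegmentation] = {}
    for gene in genes:
        gp = sorted(by_gene.get(gene.gene_id, []), key=lambda p: p.site)
        if order == "filter-first":
            retained = merge_peaks(filter_peaks(gp, min_count, min_frac), merge_dist)
        else:
            retained = filter_peaks(merge_peaks(gp, merge_dist), min_count, min_frac)
        if not retained:
            out[gene.gene_id] = GeneSegmentation(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                retained_peaks=[],
                segments=[],
                eligible=False,
            )
            continue
        out[gene.gene_id] = segment_gene(gene, retained, fallback_window)
    return out


# ---------------------------------------------------------------------------
# Quantification


def _interval_mass(
    track: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    chrom: str,
    start: int,
    end: int,
) -> float:
    """Sum of per-base depth over [start, end) from a bedGraph track."""
    if chrom not in track:
        return 0.0
    starts, ends, vals = track[chrom]
    i = int(np.searchsorted(ends, start, side="right"))
    j = int(np.searchsorted(starts, end, side="left"))
    if i >= j:
        return 0.0
    s = np.maximum(starts[i:j], start)
    e = np.minimum(ends[i:j], end)
    return float(np.sum((e - s) * vals[i:j]))


def quantify_segments(
    segmentations: Mapping[str, GeneSegmentation],
    tracks: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]],
    sheet: SampleSheet,
    read_length: int = 100,
) -> SegmentCountMatrix:
    """Integrate per-sample coverage over every segment of every eligible gene.

    Per segment and sample: coverage mass = sum of per-base depth; mean
    depth = mass / length; pseudo-read count = round(mass / read_length),
    ``read_length`` defaulting to 100 (2 x 100 bp paired-end sequencing).
    """
    samples = sheet.samples
    missing = [s for s in samples if s not in tracks]
    if missing:
        raise ValidationError(f"no coverage track supplied for sample(s) {missing}")
    rows = []
    index = []
    lengths = []
    for gene_id, seg in segmentations.items():
        if not seg.eligible:
            continue
        for i, (s, e) in enumerate(seg.segments):
            index.append((gene_id, i))
            lengths.append(e - s)
            rows.append([_interval_mass(tracks[smp], seg.chrom, s, e) for smp in samples])
    idx = pd.MultiIndex.from_tuples(index, names=["gene_id", "segment_index"])
    mass = pd.DataFrame(rows, index=idx, columns=samples, dtype=float)
    lengths_s = pd.Series(lengths, index=idx, name="length")
    depth = mass.div(lengths_s, axis=0)
    counts = np.rint(mass / read_length).astype(np.int64)
    return SegmentCountMatrix(
        counts=counts,
        depth=depth,
        lengths=lengths_s,
        conditions=dict(sheet.conditions),
        baseline=sheet.baseline,
    )


# ---------------------------------------------------------------------------
# Table I/O


def write_segmentation_bed(
    segmentations: Mapping[str, GeneSegmentation], path: str | Path
) -> None:
    """One BED row per segment, name=gene_id:segment_index, score=PAS count."""
    with open(path, "w") as fh:
        for gene_id, seg in segmentations.items():
            for i, (s, e) in enumerate(seg.segments):
                fh.write(
                    f"{seg.chrom}\t{s}\t{e}\t{gene_id}:{i}\t{seg.retained_peaks[i].count}\t{seg.strand}\n"
                )


def write_segment_counts(matrix: SegmentCountMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "length", matrix.lengths)
    df.reset_index().to_csv(path, sep="\t", index=False)


def read_segment_counts(
    tsv_path: str | Path, sheet: SampleSheet, read_length: int = 100
) -> SegmentCountMatrix:
    """Load a segment-count table (columns gene_id, segment_index, length,
    then one integer column per sample) against a sample sheet.

    Mean depth is reconstructed as count * read_length / length.
    """
    df = pd.read_csv(tsv_path, sep="\t")
    needed = {"gene_id", "segment_index", "length"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{tsv_path}: needs columns {sorted(needed)}")
    table_samples = [c for c in df.columns if c not in needed]
    for s in table_samples:
        if s not in sheet.conditions:
            raise ValidationError(f"{tsv_path}: sample {s!r} absent from sample sheet")
    for s in sheet.samples:
        if s not in table_samples:
            raise ValidationError(f"{tsv_path}: sample {s!r} missing from table")
    df = df.set_index(["gene_id", "segment_index"])
    counts = df[sheet.samples]
    if (counts.to_numpy() < 0).any():
        raise ValidationError(f"{tsv_path}: negative count encountered")
    lengths = df["length"]
    depth = counts.mul(float(read_length)).div(lengths, axis=0)
    return SegmentCountMatrix(
        counts=counts.astype(np.int64),
        depth=depth,
        lengths=lengths,
        conditions=dict(sheet.conditions),
        baseline=sheet.baseline,
    )
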