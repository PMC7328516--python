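"""Readers, writers and domain types for the APA pipeline.

Coordinate conventions
----------------------
Internally every genomic interval is 0-based half-open ``[start, end)``.
GFF3 keeps its native 1-based closed coordinates on disk, BED stays
0-based half-open, and a cleavage/poly(A) site (PAS) is a single 1-based
position: the last transcribed nucleotide of the isoform that terminates
there.  All conversions happen at the file boundary, never downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneModel",
    "PASPeak",
    "SampleSheet",
    "read_gene_models",
    "write_gene_models",
    "read_pas_peaks",
    "write_pas_peaks",
    "read_samplesheet",
    "write_samplesheet",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcription unit.

    ``start``/``end`` and the optional sub-intervals are 0-based half-open
    genomic coordinates.  ``biotype`` is ``"coding"`` (CDS present) or
    ``"ncRNA"``.  On the + strand the 5'UTR precedes the CDS precedes the
    3'UTR in genomic coordinate order; on the − strand the order is
    mirrored.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    utr5: Optional[Interval] = None
    cds: Optional[Interval] = None
    utr3: Optional[Interval] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = self.gene_id
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {g}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"gene {g}: start must be < end ({self.start} >= {self.end})")
        if self.biotype not in ("coding", "ncRNA"):
            raise ValidationError(f"gene {g}: unknown biotype {self.biotype!r}")
        subs = [("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)]
        if self.biotype == "ncRNA":
            if any(iv is not None for _, iv in subs):
                raise ValidationError(f"gene {g}: ncRNA genes carry no sub-intervals")
            return
        if self.cds is None:
            raise ValidationError(f"gene {g}: coding gene requires a CDS interval")
        present = [(name, iv) for name, iv in subs if iv is not None]
        for name, (s, e) in present:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {g}: {name} interval [{s},{e}) not nested in gene [{self.start},{self.end})"
                )
        # transcription order: utr5, cds, utr3 must be non-overlapping and
        # ordered 5'->3' along the strand
        by_coord = sorted(present, key=lambda item: item[1][0])
        order = by_coord if self.strand == "+" else list(reversed(by_coord))
        names = [n for n, _ in order]
        want = [n for n in ("utr5", "cds", "utr3") if n in names]
        if names != want:
            raise ValidationError(f"gene {g}: sub-intervals out of transcription order: {names}")
        for (n1, iv1), (n2, iv2) in zip(by_coord, by_coord[1:]):
            if iv1[1] > iv2[0]:
                raise ValidationError(f"gene {g}: {n1} overlaps {n2}")

    @property
    def tss(self) -> int:
        """Transcription start, as a 0-based position (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        """0-based position of the last annotated base."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class PASPeak:
    """One candidate cleavage/poly(A) site with its 3'-end-read count."""

    chrom: str
    strand: str
    site: int  # 1-based single-nucleotide position
    count: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"peak {self.gene_id}@{self.site}: bad strand {self.strand!r}")
        if self.site < 1:
            raise ValidationError(f"peak {self.gene_id}@{self.site}: site must be >= 1")
        if self.count < 0:
            raise ValidationError(f"peak {self.gene_id}@{self.site}: negative count")


@dataclass(frozen=True)
class SampleSheet:
    """Maps sample ids to a two-level condition factor (and optional file paths).

    ``baseline`` is the reference level (denominator of every ratio);
    ``"wt"``/``"control"`` are auto-detected, otherwise the
    lexicographically first level is used.
    """

    conditions: Mapping[str, str]  # sample_id -> condition
    paths: Optional[Mapping[str, str]] = None
    baseline: Optional[str] = None

    def __post_init__(self) -> None:
        levels = sorted(set(self.conditions.values()))
        if len(levels) != 2:
            raise ValidationError(f"exactly two condition levels required, got {levels}")
        if self.baseline is None:
            base = next((c for c in ("wt", "control") if c in levels), levels[0])
            object.__setattr__(self, "baseline", base)
        elif self.baseline not in levels:
            raise ValidationError(f"baseline {self.baseline!r} not among levels {levels}")

    @property
    def samples(self) -> list[str]:
        return list(self.conditions)

    @property
    def levels(self) -> tuple[str, str]:
        other = next(c for c in sorted(set(self.conditions.values())) if c != self.baseline)
        return (self.baseline, other)

    @property
    def test_level(self) -> str:
        return self.levels[1]

    def samples_of(self, level: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == level]


# ---------------------------------------------------------------------------
# GFF3


_SUB_TYPES = {"five_prime_UTR": "utr5", "CDS": "cds", "three_prime_UTR": "utr3"}


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if s < 1 or e < s:
                raise ParseError(f"{path}: line {lineno}: bad 1-based closed interval [{s},{e}]")
            if fields[6] not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: strand must be '+' or '-'")


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Genes without any CDS descendant become biotype ``ncRNA``.  Multiple
    rows of the same sub-feature type are collapsed to their genomic span.
    """
    path = Path(gff3_path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        spans: dict[str, Interval] = {}
        for child in db.children(g.id):
            key = _SUB_TYPES.get(child.featuretype)
            if key is None:
                continue
            s, e = child.start - 1, child.end
            if key in spans:
                spans[key] = (min(spans[key][0], s), max(spans[key][1], e))
            else:
                spans[key] = (s, e)
        biotype = "coding" if "cds" in spans else "ncRNA"
        if biotype == "ncRNA":
            spans = {}
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                biotype=biotype,
                utr5=spans.get("utr5"),
                cds=spans.get("cds"),
                utr3=spans.get("utr3"),
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], gff3_path: str | Path) -> None:
    """Write GeneModels back to GFF3 (1-based closed)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tapashift\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            if g.biotype == "ncRNA":
                fh.write(
                    f"{g.chrom}\tapashift\texon\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon1;Parent={g.gene_id}\n"
                )
                continue
            for ftype, iv in (
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds),
                ("three_prime_UTR", g.utr3),
            ):
                if iv is None:
                    continue
                phase = "0" if ftype == "CDS" else "."
                fh.write(
                    f"{g.chrom}\tapashift\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.{ftype};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED6 PAS peaks


def read_pas_peaks(
    bed_path: str | Path,
    genes: Sequence[GeneModel],
    positional_fallback: bool = False,
    fallback_window: int = 200,
) -> list[PASPeak]:
    """Read PAS peaks from BED6 (score column = 3'-end read count).

    Peaks are assigned to genes by the BED name column.  Peaks naming an
    unknown gene are skipped with a warning (unless ``positional_fallback``
    finds a same-strand gene containing the site or ending within
    ``fallback_window`` nt upstream of it).  A BED strand disagreeing with
    the gene's strand is a validation error.
    """
    path = Path(bed_path)
    by_id = {g.gene_id: g for g in genes}
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: not parseable as BED6: {exc}") from exc
    if df.shape[1] != 6 or df.isna().any().any():
        raise ParseError(f"{path}: BED6 requires 6 columns on every row")
    for col in ("start", "end", "score"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: line {lineno}: non-numeric {col} {df[col][bad].iloc[0]!r}")
        df[col] = converted.astype(int)

    peaks: list[PASPeak] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        site = int(row.start) + 1
        gene = by_id.get(row.name)
        if gene is None and positional_fallback:
            gene = _nearest_gene(genes, row.chrom, row.strand, site, fallback_window)
        if gene is None:
            n_skipped += 1
            continue
        if row.strand != gene.strand:
            raise ValidationError(
                f"{path}: peak at {row.chrom}:{site} strand {row.strand} "
                f"mismatches gene {gene.gene_id} strand {gene.strand}"
            )
        peaks.append(
            PASPeak(chrom=row.chrom, strand=row.strand, site=site, count=int(row.score), gene_id=gene.gene_id)
        )
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} peak(s) naming genes absent from the annotation",
            UserWarning,
            stacklevel=2,
        )
    return peaks


def _nearest_gene(
    genes: Sequence[GeneModel], chrom: str, strand: str, site: int, window: int
) -> Optional[GeneModel]:
    pos0 = site - 1
    for g in genes:
        if g.chrom != chrom or g.strand != strand:
            continue
        if g.start <= pos0 < g.end:
            return g
        if strand == "+" and g.end <= pos0 < g.end + window:
            return g
        if strand == "-" and g.start - window <= pos0 < g.start:
            return g
    return None


def write_pas_peaks(peaks: Iterable[PASPeak], bed_path: str | Path) -> None:
    """Write peaks as BED6, name=gene_id, score=read count."""
    with open(bed_path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.site - 1}\t{p.site}\t{p.gene_id}\t{p.count}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# Sample sheets


def read_samplesheet(tsv_path: str | Path, baseline: Optional[str] = None) -> SampleSheet:
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "condition"}
    if not required.issubset(df.columns):
        raise ParseError(f"{tsv_path}: sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{tsv_path}: duplicate sample_id {dup!r}")
    conditions = dict(zip(df["sample_id"], df["condition"]))
    paths = None
    if "path" in df.columns:
        # relative paths are taken relative to the sheet's own directory
        base = Path(tsv_path).parent
        paths = {
            s: str(p if Path(p).is_absolute() else base / p)
            for s, p in zip(df["sample_id"], df["path"])
        }
    return SampleSheet(conditions=conditions, paths=paths, baseline=baseline)


def write_samplesheet(sheet: SampleSheet, tsv_path: str | Path) -> None:
    cols: dict[str, list] = {
        "sample_id": sheet.samples,
        "condition": [sheet.conditions[s] for s in sheet.samples],
    }
    if sheet.paths is not None:
        cols["path"] = [sheet.paths[s] for s in sheet.samples]
    pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph coverage tracks


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Load a bedGraph into per-chromosome (starts, ends, values) arrays.

    Intervals are sorted per chromosome; absent intervals mean depth 0.
    Negative values are rejected.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if (df["value"] < 0).any():
        lineno = int(np.flatnonzero((df["value"] < 0).to_numpy())[0]) + 1
        raise ValidationError(f"{path}: line {lineno}: negative coverage value")
    track: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        track[str(chrom)] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(np.float64),
        )
    return track


def write_bedgraph(
    track: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom in track:
            starts, ends, vals = track[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file fully into memory."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
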