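"""Sequence analysis around proximal cleavage sites.

Extracts the 40-nt windows immediately upstream and downstream of each
cleavage site (sense strand, 5'->3' in transcription direction, reported
in the RNA alphabet), compares uridine content between affected and
control site groups, and runs a simplified discriminative k-mer
enrichment: exact k-mers (k = 4..7) counted by window presence and
scored with a one-sided exact hypergeometric test, BH-corrected across
all tested k-mers.  This k-mer scan is a deliberate simplification of
discriminative motif discovery — no IUPAC degeneracy, no position
weighting — so a degenerate motif surfaces as its constituent exact
words.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats

from .iolib import PASPeak
from .apa_stats import bh_fdr

__all__ = [
    "PASWindow",
    "CompositionResult",
    "extract_windows",
    "composition_test",
    "discriminative_kmers",
    "reverse_complement",
    "write_windows_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class PASWindow:
    """Flanking sequences of one cleavage site, in the RNA alphabet.

    ``upstream`` ends immediately 5' of the cleavage site, ``downstream``
    starts immediately 3' of it (the site nucleotide itself belongs to
    neither: cleavage occurs between nucleotides).  ``truncated`` marks
    windows clipped by a contig edge.
    """

    gene_id: str
    chrom: str
    strand: str
    site: int
    upstream: str
    downstream: str
    truncated: bool = False

    def region(self, which: str) -> str:
        if which == "upstream":
            return self.upstream
        if which == "downstream":
            return self.downstream
        if which == "both":
            return self.upstream + self.downstream
        raise ValueError(f"unknown region {which!r}")


def extract_windows(
    genome_fasta: str | Path,
    pas_list: Sequence[PASPeak],
    flank: int = 40,
) -> list[PASWindow]:
    """Cut ``flank``-nt windows around each cleavage site from the genome.

    Minus-strand windows are reverse-complemented so both sequences read
    5'->3' in transcription direction; T is reported as U.  Sites within
    ``flank`` of a contig edge yield truncated, flagged windows; sites off
    the contig raise.
    """
    fa = Fasta(str(genome_fasta))
    out: list[PASWindow] = []
    for p in pas_list:
        if p.chrom not in fa:
            raise ValueError(f"peak {p.gene_id}@{p.site}: contig {p.chrom!r} not in genome")
        contig_len = len(fa[p.chrom])
        if not 1 <= p.site <= contig_len:
            raise ValueError(
                f"peak {p.gene_id}@{p.site}: site off contig {p.chrom} (length {contig_len})"
            )
        # genomic 0-based half-open flanks around the 1-based site
        left = (max(0, p.site - 1 - flank), p.site - 1)
        right = (p.site, min(contig_len, p.site + flank))
        left_seq = str(fa[p.chrom][left[0] : left[1]])
        right_seq = str(fa[p.chrom][right[0] : right[1]])
        if p.strand == "+":
            up, down = left_seq, right_seq
        else:
            up, down = reverse_complement(right_seq), reverse_complement(left_seq)
        truncated = len(up) < flank or len(down) < flank
        out.append(
            PASWindow(
                gene_id=p.gene_id,
                chrom=p.chrom,
                strand=p.strand,
                site=p.site,
                upstream=_to_rna(up),
                downstream=_to_rna(down),
                truncated=truncated,
            )
        )
    return out


@dataclass(frozen=True)
class CompositionResult:
    base: str
    region: str
    mean_affected: float
    mean_control: float
    p_value: float
    underpowered: bool


def composition_test(
    affected: Sequence[PASWindow],
    control: Sequence[PASWindow],
    base: str = "U",
    region: str = "both",
    min_group: int = 5,
) -> CompositionResult:
    """Compare per-window base fractions between two site groups.

    The fraction of ``base`` is computed per window over the selected
    region and the groups are compared with a two-sided rank-sum
    (Mann-Whitney U) test.  Groups smaller than ``min_group`` are flagged
    underpowered.
    """
    if not affected or not control:
        raise ValueError("both window groups must be non-empty")
    base = base.upper().replace("T", "U")

    def fractions(windows: Sequence[PASWindow]) -> np.ndarray:
        vals = []
        for w in windows:
            seq = w.region(region)
            vals.append(seq.count(base) / len(seq) if seq else np.nan)
        return np.asarray(vals, dtype=float)

    fa, fc = fractions(affected), fractions(control)
    fa, fc = fa[~np.isnan(fa)], fc[~np.isnan(fc)]
    if len(fa) == 0 or len(fc) == 0:
        raise ValueError("no scorable windows in one of the groups")
    underpowered = min(len(fa), len(fc)) < min_group
    if np.ptp(np.concatenate([fa, fc])) == 0:
        p = 1.0  # all fractions identical: no evidence either way
    else:
        p = float(stats.mannwhitneyu(fa, fc, alternative="two-sided").pvalue)
    return CompositionResult(
        base=base,
        region=region,
        mean_affected=float(fa.mean()),
        mean_control=float(fc.mean()),
        p_value=p,
        underpowered=underpowered,
    )


def discriminative_kmers(
    affected: Sequence[PASWindow],
    control: Sequence[PASWindow],
    k_range: Iterable[int] = range(4, 8),
    region: str = "downstream",
) -> pd.DataFrame:
    """Exact-k-mer enrichment in affected vs control windows.

    For every k-mer observed in at least one window of either group, the
    number of windows containing it is compared between groups with a
    one-sided exact hypergeometric test (over-representation among
    affected windows); q-values are BH-adjusted across all tested k-mers.
    Returned sorted by (p, kmer).
    """
    if not affected or not control:
        raise ValueError("both window groups must be non-empty")
    ks = list(k_range)

    def presence(windows: Sequence[PASWindow]) -> Counter:
        tally: Counter = Counter()
        for w in windows:
            seq = w.region(region)
            found = {seq[i : i + k] for k in ks for i in range(len(seq) - k + 1)}
            tally.update(km for km in found if "N" not in km)
        return tally

    count_a = presence(affected)
    count_c = presence(control)
    kmers = sorted(set(count_a) | set(count_c))
    n_a, n_c = len(affected), len(control)
    a = np.array([count_a.get(km, 0) for km in kmers])
    c = np.array([count_c.get(km, 0) for km in kmers])
    # P(X >= a) for X ~ Hypergeom(N windows, a+c carriers, n_a draws)
    p = stats.hypergeom.sf(a - 1, n_a + n_c, a + c, n_a)
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "k": [len(km) for km in kmers],
            "n_affected": a,
            "n_control": c,
            "p": p,
        }
    )
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["p", "kmer"], kind="mergesort").reset_index(drop=True)


def write_windows_fasta(windows: Sequence[PASWindow], path: str | Path, region: str = "both") -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.gene_id}|{w.chrom}:{w.site}({w.strand})|{region}\n")
            fh.write(w.region(region) + "\n")
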