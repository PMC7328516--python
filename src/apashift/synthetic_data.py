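"""Synthetic input bundles with known ground truth.

From a seed and a :class:`SimulationConfig` this module writes a complete
pipeline input set — genome FASTA, GFF3 annotation, PAS-peak BED,
per-sample coverage bedGraphs, a segment-count TSV, a sample sheet — plus
a truth table, emulating the statistical structure the analysis assumes:
genes with 2–4 poly(A) sites, a configurable fraction of genes with a
condition-dependent proximal/distal usage shift of known log2-odds effect
(85% of shifts proximal by default), negative-binomial read counts with
library-size variation, and an optional U-rich motif embedded downstream
of the proximal PAS of affected genes.

Count model: each gene's total read count per sample is drawn
NB(mean = library_multiplier x reads_per_gene, dispersion), then
allocated to segments multinomially by usage fraction.  Binomial thinning
of a Gamma–Poisson mixture preserves the dispersion parameter, so every
segment count is marginally negative-binomial with mean proportional to
its usage — while segment proportions remain binomial given the gene
total, which is exactly the sampling model the binomial GLM assumes.

Coverage idealization: a segment's coverage mass is proportional to the
usage of its own delimiting PAS (piecewise-constant depth
count x read_length / length).  Real RNA-seq coverage is cumulative over
isoforms; see docs/methods.md for what this choice does and does not
exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import iolib
from .iolib import GeneModel, PASPeak, SampleSheet

__all__ = [
    "SimulationConfig",
    "SimulatedBundle",
    "simulate_bundle",
    "expected_counts",
    "library_multipliers",
    "simulate_windows",
]

_DEFAULT_MULTIPLIERS = (1.0, 1.25, 0.9, 1.15, 1.05, 0.95)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror the two-condition design the analysis targets:
    2 + 2 replicates, 2–4 PASs per gene, a log2 usage-odds effect of
    magnitude 2 injected into 10% of genes with 85% of shifts proximal,
    negative-binomial dispersion 0.05, 100-nt reads.
    """

    n_genes: int = 200
    pas_per_gene: tuple[int, int] = (2, 4)  # inclusive range
    baseline_distal_usage: float = 0.5
    shift_fraction: float = 0.1
    effect_size: float = 2.0  # |true score| in log2 usage-odds units
    proximal_fraction: float = 0.85  # fraction of shifts toward the proximal PAS
    reads_per_gene: float = 1000.0  # NB mean of a gene's RNA-seq read total
    threeprime_reads_per_gene: float = 200.0  # Poisson mean of 3'-end reads
    dispersion: float = 0.05  # NB dispersion (0 -> Poisson)
    replicates: tuple[int, int] = (2, 2)  # (baseline, test)
    library_multipliers: Optional[tuple[float, ...]] = None
    read_length: int = 100
    ncrna_fraction: float = 0.1
    decoy_fraction: float = 0.05  # genes given a near-duplicate peak (<50 nt)
    motif: str = "UUGUUG"
    motif_rate_affected: float = 0.5
    motif_rate_control: float = 0.05
    contig_length: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_distal_usage",
            "shift_fraction",
            "proximal_fraction",
            "ncrna_fraction",
            "decoy_fraction",
            "motif_rate_affected",
            "motif_rate_control",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not math.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.pas_per_gene[0] < 2 or self.pas_per_gene[1] < self.pas_per_gene[0]:
            raise ValueError(f"bad pas_per_gene range {self.pas_per_gene}")
        if min(self.replicates) < 1:
            raise ValueError("need at least one replicate per condition")


def library_multipliers(config: SimulationConfig) -> dict[str, float]:
    """Per-sample library-size multipliers (configured or default pattern)."""
    samples = _sample_ids(config)
    if config.library_multipliers is not None:
        if len(config.library_multipliers) != len(samples):
            raise ValueError(
                f"{len(config.library_multipliers)} multipliers for {len(samples)} samples"
            )
        return dict(zip(samples, config.library_multipliers))
    return {s: _DEFAULT_MULTIPLIERS[i % len(_DEFAULT_MULTIPLIERS)] for i, s in enumerate(samples)}


def _sample_ids(config: SimulationConfig) -> list[str]:
    n_wt, n_mut = config.replicates
    return [f"wt_{i + 1}" for i in range(n_wt)] + [f"mut_{i + 1}" for i in range(n_mut)]


@dataclass
class SimulatedBundle:
    """Paths and in-memory ground truth of one simulated input set."""

    outdir: Path
    config: SimulationConfig
    genes: list[GeneModel]
    peaks: list[PASPeak]
    truth: pd.DataFrame
    sheet: SampleSheet
    usage_wt: dict[str, np.ndarray]
    usage_mut: dict[str, np.ndarray]

    @property
    def genome_fasta(self) -> Path:
        return self.outdir / "genome.fa"

    @property
    def gff3(self) -> Path:
        return self.outdir / "annotation.gff3"

    @property
    def peaks_bed(self) -> Path:
        return self.outdir / "pas_peaks.bed"

    @property
    def counts_tsv(self) -> Path:
        return self.outdir / "segment_counts.tsv"

    @property
    def samplesheet_tsv(self) -> Path:
        return self.outdir / "samplesheet.tsv"

    @property
    def truth_tsv(self) -> Path:
        return self.outdir / "truth.tsv"


def _baseline_usage(k: int, distal: float) -> np.ndarray:
    """Usage fractions over k PASs in transcription order.

    The distal PAS carries ``distal``; with more than two PASs the
    proximal PAS takes 60% of the remainder and middle PASs share the
    rest equally.
    """
    if k == 2:
        return np.array([1.0 - distal, distal])
    prox = 0.6 * (1.0 - distal)
    middle = (1.0 - distal - prox) / (k - 2)
    return np.array([prox] + [middle] * (k - 2) + [distal])


def _shift_usage(usage: np.ndarray, signed_score: float) -> np.ndarray:
    """Multiply the distal/proximal usage odds by 2**signed_score, keeping
    middle-PAS usage and the proximal+distal mass fixed."""
    u = usage.copy()
    s = u[0] + u[-1]
    r = (u[-1] / u[0]) * 2.0**signed_score
    u[0] = s / (1.0 + r)
    u[-1] = s * r / (1.0 + r)
    return u


def expected_counts(
    config: SimulationConfig, usage_wt: np.ndarray, usage_mut: np.ndarray
) -> pd.DataFrame:
    """Closed-form NB segment-count means per sample for one gene."""
    mults = library_multipliers(config)
    cols = {}
    for s, m in mults.items():
        u = usage_wt if s.startswith("wt") else usage_mut
        cols[s] = m * config.reads_per_gene * np.asarray(u)
    return pd.DataFrame(cols)


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Generate and write a full input bundle plus its truth table.

    The same seed yields byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = _sample_ids(config)
    mults = library_multipliers(config)
    conditions = {s: ("wt" if s.startswith("wt") else "mut") for s in samples}

    # --- gene layout -------------------------------------------------------
    n = config.n_genes
    ks = rng.integers(config.pas_per_gene[0], config.pas_per_gene[1] + 1, size=n)
    strands = rng.choice(["+", "-"], size=n)
    is_nc = rng.random(n) < config.ncrna_fraction
    shifted = rng.random(n) < config.shift_fraction
    to_proximal = rng.random(n) < config.proximal_fraction
    has_decoy = rng.random(n) < config.decoy_fraction
    # proximal-PAS feature placement for coding genes
    feature_draw = rng.random(n)

    genes: list[GeneModel] = []
    peaks: list[PASPeak] = []
    usage_wt: dict[str, np.ndarray] = {}
    usage_mut: dict[str, np.ndarray] = {}
    truth_rows = []
    gene_segments: dict[str, list[tuple[int, int, int]]] = {}  # (start, end, tx_index)

    contigs: list[list[str]] = []
    contig_names: list[str] = []
    contig_len = 0
    contig_seq: Optional[list[str]] = None

    def new_contig() -> None:
        nonlocal contig_seq, contig_len
        contig_names.append(f"chr{len(contig_names) + 1}")
        contig_seq = []
        contigs.append(contig_seq)
        contig_len = 0

    new_contig()

    for gi in range(n):
        gene_id = f"g{gi + 1:05d}"
        k = int(ks[gi])
        seg_lens = rng.integers(150, 401, size=k)
        gap = int(rng.integers(300, 801))
        glen = int(seg_lens.sum())
        if glen + gap > config.contig_length:
            raise ValueError(
                f"gene {gene_id} (length {glen}) does not fit; increase contig_length"
            )
        if contig_len + gap + glen > config.contig_length:
            new_contig()
        assert contig_seq is not None
        contig_seq.append("".join(rng.choice(list("ACGT"), size=gap + glen)))
        chrom = contig_names[-1]
        start = contig_len + gap
        end = start + glen
        contig_len = end
        strand = str(strands[gi])

        # PAS transcript offsets (cumulative segment lengths) -> genomic sites
        tx_pas = np.cumsum(seg_lens)  # 1-based transcript position of each PAS
        if strand == "+":
            sites = [start + int(t) for t in tx_pas]  # 1-based genomic
        else:
            sites = [end - int(t) + 1 for t in tx_pas]
        segs = []
        if strand == "+":
            prev = start
            for i, s in enumerate(sites):
                segs.append((prev, s, i))
                prev = s
        else:
            prev = end
            for i, s in enumerate(sites):
                segs.append((s - 1, prev, i))
                prev = s - 1
        gene_segments[gene_id] = segs

        # annotation: feature placement of the proximal PAS
        if is_nc[gi]:
            gene = GeneModel(gene_id, chrom, strand, start, end, "ncRNA")
            feature_expected = "ncRNA"
        else:
            t1 = int(tx_pas[0])
            if feature_draw[gi] < 0.8:
                a, b = 60, t1 - 20
                feature_expected = "3UTR"
            elif feature_draw[gi] < 0.9:
                a, b = 60, t1 + 30
                feature_expected = "CDS"
            else:
                a, b = t1 + 20, t1 + 60
                feature_expected = "5UTR"
            iv5, ivc, iv3 = (0, a), (a, b), (b, glen)
            if strand == "+":
                tx2g = lambda iv: (start + iv[0], start + iv[1])
            else:
                tx2g = lambda iv: (end - iv[1], end - iv[0])
            gene = GeneModel(
                gene_id, chrom, strand, start, end, "coding",
                utr5=tx2g(iv5), cds=tx2g(ivc), utr3=tx2g(iv3),
            )
        genes.append(gene)

        # usage fractions and truth
        u_wt = _baseline_usage(k, config.baseline_distal_usage)
        if shifted[gi]:
            signed = -config.effect_size if to_proximal[gi] else config.effect_size
            u_mut = _shift_usage(u_wt, signed)
            true_class = "proximal" if to_proximal[gi] else "distal"
            true_score = signed
        else:
            u_mut = u_wt.copy()
            true_class = "null"
            true_score = 0.0
        usage_wt[gene_id] = u_wt
        usage_mut[gene_id] = u_mut

        # 3'READS peaks (wild-type usage), optional near-duplicate decoy
        n3 = int(rng.poisson(config.threeprime_reads_per_gene))
        p_counts = rng.multinomial(n3, u_wt) if n3 > 0 else np.zeros(k, dtype=int)
        decoy = None
        if has_decoy[gi] and p_counts[0] >= 9:
            decoy_count = int(p_counts[0] // 3)
            p_counts[0] -= decoy_count
            decoy_site = sites[0] - 20 if strand == "+" else sites[0] + 20
            decoy = PASPeak(chrom, strand, decoy_site, decoy_count, gene_id)
        for site, cnt in zip(sites, p_counts):
            peaks.append(PASPeak(chrom, strand, int(site), int(cnt), gene_id))
        if decoy is not None:
            peaks.append(decoy)

        truth_rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "n_pas": k,
                "true_class": true_class,
                "true_score": true_score,
                "wt_proximal": u_wt[0],
                "wt_distal": u_wt[-1],
                "mut_proximal": u_mut[0],
                "mut_distal": u_mut[-1],
                "feature_expected": feature_expected,
                "proximal_site": sites[0],
            }
        )

    truth = pd.DataFrame(truth_rows)

    # --- motif embedding ---------------------------------------------------
    motif_dna = config.motif.replace("U", "T").replace("u", "t")
    m = len(motif_dna)
    embedded = []
    chrom_index = {name: i for i, name in enumerate(contig_names)}
    contig_arrays = [list("".join(parts)) for parts in contigs]
    for row, gene in zip(truth_rows, genes):
        rate = (
            config.motif_rate_affected
            if row["true_class"] == "proximal"
            else config.motif_rate_control
        )
        do_embed = rng.random() < rate
        embedded.append(do_embed)
        if not do_embed:
            continue
        delta = int(rng.integers(5, 41 - m))
        s = row["proximal_site"]
        arr = contig_arrays[chrom_index[row["chrom"]]]
        if gene.strand == "+":
            pos = s + delta  # 0-based start of motif, downstream of the site
            arr[pos : pos + m] = list(motif_dna)
        else:
            pos = s - 1 - delta - m
            arr[pos : pos + m] = list(_revcomp(motif_dna))
    truth["motif_embedded"] = embedded

    # --- per-sample counts -------------------------------------------------
    r_shape = 1.0 / config.dispersion if config.dispersion > 0 else None
    count_cols: dict[str, list[int]] = {s: [] for s in samples}
    index_rows: list[tuple[str, int]] = []
    length_rows: list[int] = []
    for gene in genes:
        segs = gene_segments[gene.gene_id]
        for _, (gs, ge, ti) in enumerate(segs):
            index_rows.append((gene.gene_id, ti))
            length_rows.append(ge - gs)
    counts_by_gene: dict[tuple[str, str], np.ndarray] = {}
    for smp in samples:
        mean_base = mults[smp] * config.reads_per_gene
        for gene in genes:
            u = usage_wt[gene.gene_id] if conditions[smp] == "wt" else usage_mut[gene.gene_id]
            if r_shape is None:
                total = int(rng.poisson(mean_base))
            else:
                p = r_shape / (r_shape + mean_base)
                total = int(rng.negative_binomial(r_shape, p))
            seg_counts = rng.multinomial(total, u) if total > 0 else np.zeros(len(u), dtype=int)
            counts_by_gene[(gene.gene_id, smp)] = seg_counts
        for gene in genes:
            count_cols[smp].extend(int(c) for c in counts_by_gene[(gene.gene_id, smp)])

    counts_df = pd.DataFrame(
        count_cols, index=pd.MultiIndex.from_tuples(index_rows, names=["gene_id", "segment_index"])
    )
    lengths = pd.Series(length_rows, index=counts_df.index, name="length")

    # --- write files -------------------------------------------------------
    seqs = {name: "".join(arr) for name, arr in zip(contig_names, contig_arrays)}
    iolib.write_fasta(seqs, outdir / "genome.fa")
    iolib.write_gene_models(genes, outdir / "annotation.gff3")
    iolib.write_pas_peaks(peaks, outdir / "pas_peaks.bed")

    out_counts = counts_df.copy()
    out_counts.insert(0, "length", lengths)
    out_counts.reset_index().to_csv(outdir / "segment_counts.tsv", sep="\t", index=False)

    bedgraph_paths = {}
    for smp in samples:
        rows = []
        for gene in genes:
            segs = gene_segments[gene.gene_id]
            cs = counts_by_gene[(gene.gene_id, smp)]
            for gs, ge, ti in segs:
                depth = cs[ti] * config.read_length / (ge - gs)
                if depth > 0:
                    rows.append((gene.chrom, gs, ge, depth))
        rows.sort(key=lambda r: (chrom_index[r[0]], r[1]))
        path = outdir / f"coverage_{smp}.bedGraph"
        with open(path, "w") as fh:
            for chrom, gs, ge, depth in rows:
                fh.write(f"{chrom}\t{gs}\t{ge}\t{depth:.10g}\n")
        bedgraph_paths[smp] = path.name  # relative: bundles stay relocatable

    sheet = SampleSheet(conditions=conditions, paths=bedgraph_paths, baseline="wt")
    iolib.write_samplesheet(sheet, outdir / "samplesheet.tsv")

    truth_out = truth.copy()
    for col in ("true_score", "wt_proximal", "wt_distal", "mut_proximal", "mut_distal"):
        truth_out[col] = truth_out[col].map(lambda v: f"{v:.10g}")
    truth_out.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    return SimulatedBundle(
        outdir=outdir,
        config=config,
        genes=genes,
        peaks=peaks,
        truth=truth,
        sheet=sheet,
        usage_wt=usage_wt,
        usage_mut=usage_mut,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Window-level simulation (for sequence-analysis testing without a genome)


def simulate_windows(
    n: int,
    motif: str = "UUGUUG",
    embed_rate: float = 0.0,
    length: int = 40,
    u_bias: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
):
    """Random PAS windows with a motif embedded downstream at ``embed_rate``.

    Background bases are drawn i.i.d. with U probability ``u_bias`` and the
    other three bases equiprobable.  Returns a list of
    :class:`~apashift.pas_sequence.PASWindow`.
    """
    from .pas_sequence import PASWindow

    if rng is None:
        rng = np.random.default_rng(seed)
    probs = [(1 - u_bias) / 3] * 3 + [u_bias]
    alphabet = np.array(list("ACGU"))
    out = []
    for i in range(n):
        up = "".join(rng.choice(alphabet, size=length, p=probs))
        down = list(rng.choice(alphabet, size=length, p=probs))
        if rng.random() < embed_rate:
            pos = int(rng.integers(0, length - len(motif) + 1))
            down[pos : pos + len(motif)] = list(motif)
        out.append(
            PASWindow(
                gene_id=f"w{i}",
                chrom="synthetic",
                strand="+",
                site=1000 + i,
                upstream=up,
                downstream="".join(down),
            )
        )
    return out
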