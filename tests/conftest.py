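import numpy as np
import pytest

from apashift import iolib, segmentation
from apashift.iolib import GeneModel, PASPeak, SampleSheet
from apashift.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture
def gene_plus():
    return GeneModel(
        gene_id="gp",
        chrom="chr1",
        strand="+",
        start=1000,
        end=2000,
        biotype="coding",
        utr5=(1000, 1100),
        cds=(1100, 1700),
        utr3=(1700, 2000),
    )


@pytest.fixture
def gene_minus():
    return GeneModel(
        gene_id="gm",
        chrom="chr1",
        strand="-",
        start=3000,
        end=4000,
        biotype="coding",
        utr5=(3900, 4000),
        cds=(3300, 3900),
        utr3=(3000, 3300),
    )


@pytest.fixture
def ncrna_gene():
    return GeneModel(
        gene_id="gn", chrom="chr1", strand="+", start=5000, end=5600, biotype="ncRNA"
    )


def make_peak(site, count, gene_id="gp", chrom="chr1", strand="+"):
    return PASPeak(chrom=chrom, strand=strand, site=site, count=count, gene_id=gene_id)


@pytest.fixture
def two_by_two_sheet():
    return SampleSheet(
        conditions={"wt_1": "wt", "wt_2": "wt", "mut_1": "mut", "mut_2": "mut"}
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A modest simulated input set shared across tests (seed-fixed)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(n_genes=120, seed=3), outdir)


@pytest.fixture(scope="session")
def small_pipeline(small_bundle):
    """Segmentation + count matrix + APA results for the small bundle."""
    from apashift import apa_stats

    genes = iolib.read_gene_models(small_bundle.gff3)
    peaks = iolib.read_pas_peaks(small_bundle.peaks_bed, genes)
    segs = segmentation.segment_genes(genes, peaks)
    sheet = iolib.read_samplesheet(small_bundle.samplesheet_tsv)
    tracks = {s: iolib.read_bedgraph(p) for s, p in sheet.paths.items()}
    matrix = segmentation.quantify_segments(segs, tracks, sheet)
    results = apa_stats.run_apa_analysis(matrix, segmentations=segs)
    return {
        "genes": genes,
        "peaks": peaks,
        "segs": segs,
        "sheet": sheet,
        "matrix": matrix,
        "results": results,
    }
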