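"""Assign significant APA events to gene features and summarize them.

Each event is labelled by where its *proximal* PAS falls: 5UTR, CDS or
3UTR for coding genes (a site up to ``fallback_window`` nt beyond the
annotated 3' end still counts as 3UTR, since cleavage sites routinely
map slightly past annotated ends), or ncRNA for noncoding genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .iolib import GeneModel, ValidationError

__all__ = ["FEATURES", "locate_pas", "annotate_results", "summarize_features"]

FEATURES = ("3UTR", "5UTR", "CDS", "ncRNA")


def locate_pas(gene: GeneModel, site: int, fallback_window: int = 200) -> str:
    """Feature containing a 1-based cleavage site within ``gene``."""
    if gene.biotype == "ncRNA":
        return "ncRNA"
    pos = site - 1  # 0-based
    for name, iv in (("utr5", gene.utr5), ("cds", gene.cds), ("utr3", gene.utr3)):
        if iv is not None and iv[0] <= pos < iv[1]:
            return {"utr5": "5UTR", "cds": "CDS", "utr3": "3UTR"}[name]
    # site beyond the annotated 3' end (downstream fallback window) -> 3UTR
    if gene.strand == "+" and gene.end <= pos < gene.end + fallback_window:
        return "3UTR"
    if gene.strand == "-" and gene.start - fallback_window <= pos < gene.start:
        return "3UTR"
    # unannotated gap inside the gene body (e.g. missing UTR rows): a site
    # 3' of the CDS is a de-facto 3'UTR site, 5' of it a 5'UTR site
    if gene.cds is not None and gene.start <= pos < gene.end:
        cds = gene.cds
        after_cds = pos >= cds[1] if gene.strand == "+" else pos < cds[0]
        return "3UTR" if after_cds else "5UTR"
    raise ValidationError(
        f"gene {gene.gene_id}: site {site} falls in no annotated feature "
        f"and outside the {fallback_window}-nt downstream window"
    )


def annotate_results(
    results: pd.DataFrame,
    genes: Sequence[GeneModel],
    fallback_window: int = 200,
) -> pd.DataFrame:
    """Fill the ``feature`` column of an APA results table in place-safe copy."""
    by_id = {g.gene_id: g for g in genes}
    out = results.copy()
    feats = []
    for row in out.itertuples(index=False):
        gene = by_id.get(row.gene_id)
        if gene is None or row.proximal_pas_site is None or pd.isna(row.proximal_pas_site):
            feats.append(pd.NA)
        else:
            feats.append(locate_pas(gene, int(row.proximal_pas_site), fallback_window))
    out["feature"] = feats
    return out


def summarize_features(
    calls: pd.DataFrame, normalize: bool = False, directions: Iterable[str] = ("proximal", "distal")
) -> pd.DataFrame:
    """Contingency table of feature x shift direction for classified events.

    Rows are the feature categories, columns the directions; with
    ``normalize=True`` each column is converted to fractions summing to 1
    (all-zero columns stay zero).
    """
    directions = list(directions)
    table = pd.DataFrame(0, index=list(FEATURES), columns=directions, dtype=float)
    sig = calls[calls["class"].isin(directions)]
    for (feat, cls), n in sig.groupby(["feature", "class"]).size().items():
        table.loc[feat, cls] = n
    if normalize:
        totals = table.sum(axis=0)
        for c in directions:
            if totals[c] > 0:
                table[c] = table[c] / totals[c]
    else:
        table = table.astype(int)
    return table
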