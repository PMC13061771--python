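"""Cytogenetic-band over-representation analysis (hypergeometric + BH).

A flagged gene list is tested band by band against a gene universe: with
N annotated universe genes, K of them on a band, and n genes in the list,
the enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution, where k is the number of list genes on the band.  p-values
are Benjamini-Hochberg adjusted across all bands present in the universe.
The statistic is computed locally so the analysis is hermetic and
reproducible; no enrichment web service is involved.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import BandAnnotation, DataValidationError, GeneList

logger = logging.getLogger(__name__)

__all__ = ["cytoband_ora", "bh_adjust", "ORA_SCHEMA"]

#: columns of an over-representation record table
ORA_SCHEMA = ("band", "k", "K", "n", "N", "p", "fdr")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cytoband_ora(
    gene_list: GeneList,
    universe: GeneList,
    annotation: BandAnnotation,
    min_band_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene list on cytogenetic bands.

    List genes outside the universe are logged and dropped; universe genes
    without a band annotation are dropped from N with a warning.  One row
    per band with K >= ``min_band_size``, sorted by p ascending (band label
    breaks ties deterministically).
    """
    if len(gene_list) == 0:
        raise DataValidationError("empty input gene list")
    if len(universe) == 0:
        raise DataValidationError("empty universe")

    outside = gene_list.identifiers - universe.identifiers
    if outside:
        logger.warning(
            "%d list gene(s) outside the universe dropped: %s",
            len(outside),
            ", ".join(sorted(outside)[:10]),
        )
    universe_annotated = {g for g in universe.identifiers if annotation.band_of(g)}
    unannotated = len(universe.identifiers) - len(universe_annotated)
    if unannotated:
        logger.warning("%d universe gene(s) lack a band annotation and were dropped", unannotated)
    hits_all = (gene_list.identifiers & universe_annotated)

    N = len(universe_annotated)
    n = len(hits_all)
    if N == 0 or n == 0:
        raise DataValidationError("no annotated genes left to test")

    bands: dict[str, set[str]] = {}
    for g in universe_annotated:
        bands.setdefault(annotation.band_of(g), set()).add(g)

    rows = []
    for band in sorted(bands):
        members = bands[band]
        K = len(members)
        if K < min_band_size:
            continue
        k = len(members & hits_all)
        # upper tail P(X >= k); k=0 gives p=1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"band": band, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=list(ORA_SCHEMA[:-1]))
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["p", "band"], kind="mergesort").reset_index(drop=True)
    return result
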