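"""Gene-level aggregation of per-barcode screen results.

A gene disrupted by several independent transposon insertions, each of whose
barcodes shifts in the same direction under drug, is far stronger evidence
than any single barcode.  This module joins the differential results to the
barcode → site → gene links and ranks genes by the number of significant,
direction-consistent insertions, combining their P-values with Fisher's
method.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_FC_CUTOFF = 1.0
DEFAULT_P_CUTOFF = 0.05
DEFAULT_MIN_INSERTIONS = 2


def fisher_combined_p(pvalues) -> float:
    """Fisher's method: −2·Σ ln Pᵢ against chi-square with 2k d.f."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return 1.0
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))


def join_results(
    diff: pd.DataFrame,
    links: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join per-barcode test results to their integration sites and genes.

    Inner join on canonical barcode.  ``annotations`` (site rows with
    gene_id/gene_name, from :func:`bartrap.sites.annotate_sites`) is merged
    on the site key when provided.  Barcodes linked to more than one merged
    site keep their ambiguity flag and are excluded from gene tallies
    downstream; barcodes with counts but no mapping are returned separately
    as orphans.

    Returns ``(annotated, orphans)``.
    """
    joined = diff.merge(links, on="barcode", how="inner")
    orphans = diff[~diff["barcode"].isin(links["barcode"])].reset_index(drop=True)
    if annotations is not None:
        key = ["library", "end_label", "chrom", "strand", "pos"]
        gene_cols = annotations[key + ["gene_id", "gene_name"]].drop_duplicates()
        joined = joined.merge(gene_cols, on=key, how="left")
        joined[["gene_id", "gene_name"]] = joined[["gene_id", "gene_name"]].fillna("none")
    if len(orphans):
        log.info("join_results: %d barcode(s) with counts but no mapping", len(orphans))
    return joined.reset_index(drop=True), orphans


def call_gene_hits(
    annotated: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    min_insertions: int = DEFAULT_MIN_INSERTIONS,
    p_column: str = "PValue",
    combine_all: bool = False,
) -> pd.DataFrame:
    """Rank genes supported by multiple significant insertions.

    Per gene and direction, insertions passing both cutoffs
    (|logFC| ≥ ``fc_cutoff`` and ``p_column`` < ``p_cutoff``) are counted;
    genes with at least ``min_insertions`` such insertions are reported,
    ranked by (n_significant descending, Fisher combined P ascending).  By
    default Fisher's method combines the significant members only; with
    ``combine_all`` it combines every same-direction insertion in the gene.
    Ambiguous (multi-site) barcodes and intergenic insertions are excluded.
    """
    if fc_cutoff <= 0 or p_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    usable = annotated
    if "ambiguous" in usable.columns:
        usable = usable[~usable["ambiguous"].astype(bool)]
    usable = usable[usable["gene_id"] != "none"]
    hits = []
    for (gene_id, gene_name), grp in usable.groupby(["gene_id", "gene_name"], sort=True):
        n_total = len(grp)
        for direction, sign in (("depleted", -1), ("enriched", 1)):
            members = grp[np.sign(grp["logFC"]) == sign]
            sig = members[
                (members["logFC"].abs() >= fc_cutoff) & (members[p_column] < p_cutoff)
            ]
            if len(sig) < min_insertions:
                continue
            pool = members if combine_all else sig
            hits.append(
                {
                    "gene_id": gene_id,
                    "gene_name": gene_name,
                    "direction": direction,
                    "n_insertions_total": n_total,
                    "n_significant": len(sig),
                    "libraries": ",".join(sorted(set(sig["library"].astype(str)))),
                    "median_logFC": float(sig["logFC"].median()),
                    "combined_p": fisher_combined_p(pool[p_column]),
                }
            )
    out = pd.DataFrame(
        hits,
        columns=[
            "gene_id",
            "gene_name",
            "direction",
            "n_insertions_total",
            "n_significant",
            "libraries",
            "median_logFC",
            "combined_p",
        ],
    )
    return out.sort_values(
        ["n_significant", "combined_p", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
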