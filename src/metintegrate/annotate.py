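"""Annotation joins producing marker and target shortlists.

Three shortlists are drawn from the pool of top metastasis-upregulated
genes (default pool: the 300 highest-SNR genes):

* surfaceome — genes coding for cell-surface proteins, candidates for
  imaging or antibody-based diagnostics, with the surface-protein-atlas
  confidence category (1 = high confidence, 2 = putative, 3 = unspecific);
* secretome — genes whose products are likely secreted and hence
  candidates for minimally invasive serum markers; a gene passes if its
  curation tag contains "secreted (curated)", "secreted (highly
  likely)" or "secreted (likely)" (case-insensitive) OR its
  protein-atlas location indicates secretion — either line of evidence
  suffices;
* druggable — genes with at least one known inhibitor; approved drugs
  are flagged.

Genes absent from an annotation table are non-members, never errors.
Shortlists preserve the SNR ordering of the differential table.
"""

from __future__ import annotations

import pandas as pd

from .containers import AnnotationTables
from .errors import InvalidParameterError

DEFAULT_TOP_POOL = 300
_SECRETED_SUBSTRINGS = ("secreted (curated)", "secreted (highly likely)",
                        "secreted (likely)")

__all__ = ["surfaceome_shortlist", "secretome_shortlist", "druggable_shortlist"]


def _pool(diff: pd.DataFrame, top_pool: int, min_snr: float) -> pd.DataFrame:
    if top_pool < 1:
        raise InvalidParameterError("top_pool must be >= 1")
    pool = diff.nsmallest(min(top_pool, len(diff)), "rank")
    return pool[pool["snr"] >= min_snr]


def surfaceome_shortlist(
    diff: pd.DataFrame,
    tables: AnnotationTables,
    top_pool: int = DEFAULT_TOP_POOL,
    min_snr: float = 0.0,
) -> pd.DataFrame:
    """Top upregulated genes coding for surface-bound proteins.

    Columns: gene, uniprot_id, category, snr, fold_change, perm_p, rank;
    sorted by SNR descending (rank ascending).
    """
    pool = _pool(diff, top_pool, min_snr)
    surf = tables.surfaceome[["gene", "uniprot_id", "category"]]
    out = pool.merge(surf, on="gene", how="inner")
    cols = ["gene", "uniprot_id", "category", "snr", "fold_change", "perm_p", "rank"]
    return out[cols].sort_values("rank").reset_index(drop=True)


def _passes_secretion(metaz_tag: str, hpa_location: str) -> bool:
    tag = str(metaz_tag).lower()
    if any(s in tag for s in _SECRETED_SUBSTRINGS):
        return True
    return "secreted" in str(hpa_location).lower()


def secretome_shortlist(
    diff: pd.DataFrame,
    tables: AnnotationTables,
    top_pool: int = DEFAULT_TOP_POOL,
    min_snr: float = 0.0,
) -> pd.DataFrame:
    """Top upregulated genes with secreted-protein evidence.

    Both evidence columns (curation tag and protein-atlas location) are
    emitted so the reader can see which filter admitted each gene.
    """
    pool = _pool(diff, top_pool, min_snr)
    secr = tables.secretome[["gene", "metaz_tag", "hpa_location"]]
    out = pool.merge(secr, on="gene", how="inner")
    keep = [
        _passes_secretion(t, h)
        for t, h in zip(out["metaz_tag"], out["hpa_location"])
    ]
    out = out[keep]
    cols = ["gene", "metaz_tag", "hpa_location", "snr", "fold_change", "perm_p", "rank"]
    return out[cols].sort_values("rank").reset_index(drop=True)


def druggable_shortlist(
    diff: pd.DataFrame,
    tables: AnnotationTables,
    top_pool: int = DEFAULT_TOP_POOL,
    min_snr: float = 0.0,
) -> pd.DataFrame:
    """Top upregulated genes with at least one known inhibitor.

    One row per gene; inhibitors comma-joined in input order, approved
    ones marked with a trailing ``*``, plus a boolean ``any_approved``.
    """
    pool = _pool(diff, top_pool, min_snr)
    drugs = tables.drug_targets
    rows = []
    by_gene = {g: grp for g, grp in drugs.groupby("gene", sort=False)}
    for _, r in pool.iterrows():
        grp = by_gene.get(r["gene"])
        if grp is None or len(grp) == 0:
            continue
        names = [
            f"{n}*" if bool(a) else str(n)
            for n, a in zip(grp["inhibitor"], grp["approved"])
        ]
        rows.append(
            (r["gene"], ",".join(names), bool(grp["approved"].any()),
             r["snr"], r["fold_change"], r["perm_p"], r["rank"])
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "inhibitors", "any_approved", "snr", "fold_change",
                 "perm_p", "rank"],
    )
    return out.sort_values("rank").reset_index(drop=True) if len(out) else out
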