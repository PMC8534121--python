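"""Drug-response stratification and the responsive-vs-non-responsive signature.

Cell lines are split on viability log fold change (LFC vs vehicle):
responsive lines have LFC <= ``low`` (default -0.5, boundary included),
non-responsive lines fall in (low, high] (default high = 0.5), and
anything above ``high`` is excluded.  The expression signature of
response is then the SNR ranking of responsive vs non-responsive lines,
and its top genes feed over-representation analysis to name the
pathways that track sensitivity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, ResponseStrata
from .differential import DEFAULT_N_PERM, rank_table, top_n
from .enrichment import ora
from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

DEFAULT_LOW = -0.5
DEFAULT_HIGH = 0.5
DEFAULT_TOP_K = 150

__all__ = ["stratify", "response_signature", "signature_ora"]


def stratify(response: pd.Series, low: float = DEFAULT_LOW,
             high: float = DEFAULT_HIGH) -> ResponseStrata:
    """Partition cell lines by drug response.

    ``response`` maps cell line -> viability LFC.  Returns disjoint
    responsive / non-responsive / excluded lists covering every input
    line.  A line exactly at ``low`` counts as responsive; one exactly
    at ``high`` as non-responsive.
    """
    if low >= high:
        raise InvalidParameterError("low threshold must be below high threshold")
    lfc = response.to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise InvalidInputError("response vector contains non-finite values")
    ids = np.asarray(response.index)
    resp = lfc <= low
    nonr = (lfc > low) & (lfc <= high)
    return ResponseStrata(
        responsive=list(ids[resp]),
        non_responsive=list(ids[nonr]),
        excluded=list(ids[~resp & ~nonr]),
    )


def response_signature(
    expr: ExpressionMatrix,
    strata: ResponseStrata,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """SNR rank table of responsive vs non-responsive cell lines.

    Lines present in only one of (response, expression) are dropped
    with a logged count.  Positive SNR means higher expression in the
    responsive group.
    """
    have = set(expr.sample_ids)
    a = [s for s in strata.responsive if s in have]
    b = [s for s in strata.non_responsive if s in have]
    dropped = (len(strata.responsive) - len(a)) + (len(strata.non_responsive) - len(b))
    if dropped:
        logger.warning("response_signature: dropped %d lines without expression", dropped)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each stratum needs >= 2 lines with expression data")
    sub = expr.subset_samples(a + b)
    sub.sample_class = pd.Series(
        ["responsive"] * len(a) + ["non_responsive"] * len(b), index=a + b)
    return rank_table(sub, "responsive", "non_responsive", n_perm=n_perm, seed=seed)


def signature_ora(
    signature: pd.DataFrame,
    sets: GeneSetCollection,
    universe,
    top_k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """ORA of the top ``top_k`` signature genes against a set collection."""
    if top_k < 1:
        raise InvalidParameterError("top_k must be >= 1")
    if top_k > len(signature):
        raise InvalidParameterError(
            f"top_k={top_k} exceeds the {len(signature)} ranked genes")
    query = top_n(signature, top_k)["gene"].tolist()
    return ora(query, sets, universe)
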