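"""Gene-set enrichment: binomial over-representation and running-sum ES.

Two complementary procedures:

* ``ora`` — over-representation of gene sets in a discrete query list,
  tested with a one-sided upper-tail binomial: given n = |query ∩
  universe| submitted genes and a set covering T of the |universe| genes,
  the p-value is P(Bin(n, T/|U|) >= F) where F is the observed overlap.
  Benjamini-Hochberg step-up FDR is applied across the sets tested.

* ``gsea_es`` — the weighted Kolmogorov-Smirnov-like running-sum
  enrichment score over a ranked gene list.  Walking down the list, set
  members ("hits") increment the sum by |score|^weight normalised by the
  total in-set weight, non-members decrement by 1/(N - N_H).  The ES is
  the running sum at its maximum absolute deviation; the leading edge
  ("core enrichment genes") are the set members at or before the peak
  for a positive ES (at or after it for a negative one).

Significance for the ES uses phenotype-label permutation
(``gsea_perm_p``): labels are shuffled, genes re-ranked by SNR and the
ES recomputed, with the same add-one p convention as the differential
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection
from .differential import _snr_rows
from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 5
MAX_SET_SIZE = 2000

__all__ = ["ora", "bh_fdr", "gsea_es", "gsea_all_sets", "gsea_perm_p", "ESResult"]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    query,
    sets: GeneSetCollection,
    universe,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Binomial over-representation analysis of ``query`` against ``sets``.

    Returns a DataFrame with columns ``set_id``, ``found`` (F), ``total``
    (T), ``p_value`` and ``fdr``, sorted ascending by p-value.  Query ids
    outside the universe are dropped with a logged count; sets whose
    universe intersection falls outside [min_size, max_size] are not
    tested and the FDR is computed across tested sets only.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise InvalidInputError("universe must be non-empty")
    uni_set = set(uni)
    q = [g for g in dict.fromkeys(query)]
    q_in = [g for g in q if g in uni_set]
    dropped = len(q) - len(q_in)
    if dropped:
        logger.warning("ora: dropped %d query ids outside the universe", dropped)
    n = len(q_in)
    q_set = set(q_in)

    rows = []
    for set_id, (_desc, members) in sets.sets.items():
        in_uni = uni_set.intersection(members)
        t = len(in_uni)
        if t < min_size or t > max_size:
            continue
        f = len(q_set & in_uni)
        # upper tail P(X >= F); F = 0 gives p = 1 exactly
        p = float(stats.binom.sf(f - 1, n, t / len(uni))) if n > 0 else 1.0
        rows.append((set_id, f, t, min(p, 1.0)))

    out = pd.DataFrame(rows, columns=["set_id", "found", "total", "p_value"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


@dataclass
class ESResult:
    """Running-sum enrichment score for one gene set."""

    set_id: str
    es: float
    peak_rank: int  # 1-based rank at which |running sum| peaks
    leading_edge: list[str]
    n_hits: int
    perm_p: float | None = None


def _order_descending(genes, scores) -> tuple[list[str], np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    # stable sort: equal scores keep input order (deterministic tie rule)
    idx = np.argsort(-scores, kind="stable")
    return [genes[i] for i in idx], scores[idx]


def gsea_es(ranked_genes, scores, set_members, weight: float = 1.0,
            set_id: str = "") -> ESResult:
    """Weighted running-sum enrichment score with leading-edge genes.

    ``ranked_genes``/``scores`` need not be pre-sorted; they are ordered
    by score descending with a stable tie rule.  ``weight`` = 1 is the
    canonical weighted statistic; ``weight`` = 0 reduces to the classic
    Kolmogorov-Smirnov statistic on hit positions.
    """
    genes = list(ranked_genes)
    if len(set(genes)) != len(genes):
        raise InvalidInputError("ranked gene list contains duplicates")
    genes, s = _order_descending(genes, scores)
    n = len(genes)
    member_set = set(set_members)
    hit = np.fromiter((g in member_set for g in genes), dtype=bool, count=n)
    n_h = int(hit.sum())
    if n_h == 0:
        raise InvalidInputError("gene set has no overlap with the ranked list")
    if n_h == n:
        raise InvalidInputError("gene set covers the whole ranked list (degenerate ES)")

    w = np.abs(s) ** weight
    n_r = w[hit].sum()
    if n_r == 0.0:
        # all hit scores are exactly 0: fall back to unweighted increments
        incr = hit / n_h
    else:
        incr = np.where(hit, w / n_r, 0.0)
    decr = np.where(hit, 0.0, 1.0 / (n - n_h))
    running = np.cumsum(incr - decr)

    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        le = [g for i, g in enumerate(genes) if hit[i] and i <= peak]
    else:
        le = [g for i, g in enumerate(genes) if hit[i] and i >= peak]
    return ESResult(set_id=set_id, es=es, peak_rank=peak + 1, leading_edge=le,
                    n_hits=n_h)


def gsea_all_sets(
    ranked_genes,
    scores,
    sets: GeneSetCollection,
    weight: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """ES for every set with adequate overlap; skipped sets are logged.

    Returns columns ``set_id``, ``es``, ``peak_rank``, ``n_hits``,
    ``leading_edge`` (comma-joined), sorted by ES descending.
    """
    rows = []
    gene_pool = set(ranked_genes)
    for set_id, (_d, members) in sets.sets.items():
        overlap = len(gene_pool.intersection(members))
        if overlap < min_size or overlap > max_size or overlap == len(gene_pool):
            logger.warning("gsea: skipping set %s (overlap %d)", set_id, overlap)
            continue
        r = gsea_es(ranked_genes, scores, members, weight=weight, set_id=set_id)
        rows.append((set_id, r.es, r.peak_rank, r.n_hits, ",".join(r.leading_edge)))
    out = pd.DataFrame(rows, columns=["set_id", "es", "peak_rank", "n_hits",
                                      "leading_edge"])
    return out.sort_values(["es", "set_id"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


def gsea_perm_p(
    matrix: ExpressionMatrix,
    class_a: str,
    class_b: str,
    set_members,
    n_perm: int = 199,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[ESResult, float]:
    """Phenotype-permutation p-value for one gene set's ES.

    Class labels are permuted, genes re-ranked by SNR, and the ES
    recomputed; p = (#{|ES*| >= |ES_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    a_ids = matrix.class_samples(class_a)
    b_ids = matrix.class_samples(class_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise InvalidInputError("both classes need >= 2 samples")
    sub = matrix.values[a_ids + b_ids]
    x = sub.to_numpy(dtype=float)
    genes = list(sub.index)
    n_a, n_tot = len(a_ids), len(a_ids) + len(b_ids)

    obs_scores = _snr_rows(x, np.arange(n_a), np.arange(n_a, n_tot))
    res = gsea_es(genes, obs_scores, set_members, weight=weight)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        s = _snr_rows(x, perm[:n_a], perm[n_a:])
        es_star = gsea_es(genes, s, set_members, weight=weight).es
        if abs(es_star) >= abs(res.es):
            hits += 1
    res.perm_p = (hits + 1) / (n_perm + 1)
    return res, res.perm_p
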