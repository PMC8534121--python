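"""Aggregate CRISPR gene-dependency scores and triage targets vs markers.

Gene dependency (GD) is the probability that knocking out a gene
reduces a cell line's viability.  Averaged over cell-line subgroups it
separates two kinds of metastasis-upregulated genes:

* therapeutic candidates — upregulated AND broadly essential (mean GD
  close to 1): inhibiting them should hurt the tumor;
* marker candidates — upregulated but dispensable (mean GD close to 0):
  safe readouts for diagnostics (imaging, serum assays) since their
  level does not couple to viability selection.

Means are computed separately for primary-tumor-derived and
metastasis-derived lines; missing cells (not every line is screened for
every gene) are excluded from both numerator and denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CLASS_METASTASIS, CLASS_PRIMARY, DependencyMatrix
from .errors import InvalidInputError, InvalidParameterError

DEFAULT_HIGH_GD = 0.9
DEFAULT_LOW_GD = 0.1
DEFAULT_TOP_POOL = 300

THERAPEUTIC = "therapeutic_candidate"
MARKER = "marker_candidate"
OTHER = "other"

__all__ = ["mean_gd_by_origin", "triage", "THERAPEUTIC", "MARKER", "OTHER"]


def mean_gd_by_origin(dep: DependencyMatrix, lineage: str | None = None) -> pd.DataFrame:
    """Per-gene mean dependency within each origin group.

    Returns columns ``gene``, ``mean_gd_primary``, ``mean_gd_metastasis``,
    ``n_obs_primary``, ``n_obs_metastasis``.  ``lineage`` restricts the
    panel to one tissue (e.g. ``prostate``) before averaging.
    """
    origin = dep.origin
    cols = dep.values.columns
    if lineage is not None:
        keep = dep.lineage == lineage
        cols = cols[keep.to_numpy()]
        origin = origin[cols]
    p_cols = cols[(origin == CLASS_PRIMARY).to_numpy()]
    m_cols = cols[(origin == CLASS_METASTASIS).to_numpy()]
    if len(p_cols) == 0 or len(m_cols) == 0:
        raise InvalidInputError("both origin groups (primary, metastasis) must be non-empty")
    vp = dep.values[p_cols]
    vm = dep.values[m_cols]
    return pd.DataFrame(
        {
            "gene": dep.values.index,
            "mean_gd_primary": vp.mean(axis=1, skipna=True).to_numpy(),
            "mean_gd_metastasis": vm.mean(axis=1, skipna=True).to_numpy(),
            "n_obs_primary": vp.notna().sum(axis=1).to_numpy(),
            "n_obs_metastasis": vm.notna().sum(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)


def triage(
    diff: pd.DataFrame,
    gd_means: pd.DataFrame,
    snr_cut: float | None = None,
    high_gd: float = DEFAULT_HIGH_GD,
    low_gd: float = DEFAULT_LOW_GD,
    top_pool: int = DEFAULT_TOP_POOL,
) -> pd.DataFrame:
    """Classify genes as therapeutic candidates, marker candidates or other.

    A gene is a therapeutic candidate when its SNR reaches ``snr_cut``
    and its overall mean GD is >= ``high_gd``; a marker candidate when
    the SNR passes but the overall mean GD is <= ``low_gd``; anything
    else is ``other``.  The overall mean is the observation-count
    weighted mean of the two origin-group means.  When ``snr_cut`` is
    None it defaults to the SNR of the ``top_pool``-th ranked gene, i.e.
    the pool of top upregulated genes feeding the shortlists.
    """
    if not 0.0 <= low_gd < high_gd <= 1.0:
        raise InvalidParameterError("thresholds must satisfy 0 <= low_gd < high_gd <= 1")
    if snr_cut is None:
        pool = diff.nsmallest(min(top_pool, len(diff)), "rank")
        snr_cut = float(pool["snr"].min())

    merged = diff.merge(gd_means, on="gene", how="inner")
    n_p = merged["n_obs_primary"].to_numpy(dtype=float)
    n_m = merged["n_obs_metastasis"].to_numpy(dtype=float)
    gp = merged["mean_gd_primary"].to_numpy(dtype=float)
    gm = merged["mean_gd_metastasis"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        overall = np.where(
            n_p + n_m > 0,
            (np.nan_to_num(gp) * n_p + np.nan_to_num(gm) * n_m) / np.maximum(n_p + n_m, 1),
            np.nan,
        )
    merged["mean_gd_overall"] = overall

    passed = merged["snr"].to_numpy() >= snr_cut
    cls = np.full(len(merged), OTHER, dtype=object)
    cls[passed & (overall >= high_gd)] = THERAPEUTIC
    cls[passed & (overall <= low_gd)] = MARKER
    merged["triage_class"] = cls
    cols = ["gene", "snr", "rank", "mean_gd_primary", "mean_gd_metastasis",
            "mean_gd_overall", "n_obs_primary", "n_obs_metastasis", "triage_class"]
    return merged[cols].sort_values("rank").reset_index(drop=True)
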