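"""Signal-to-noise differential ranking with a label-permutation null.

The ranking statistic is the signal-to-noise ratio

    SNR = (mu_A - mu_B) / (sigma_A + sigma_B)

with the per-group standard deviation floored by the GenePattern
convention: sigma <- max(sigma, 0.2 * |mu|), and if that is still zero,
sigma <- 0.2.  The floor keeps genes with near-constant expression from
dominating the ranking and makes the statistic defined for constant
groups.  Fold changes are linear ratios, 2**(mu_A - mu_B), since the
input is log2 scale.

Significance is assessed by permuting sample class labels and
recomputing SNR; with the add-one convention the attainable p-value
floor at the default 499 permutations is 1/500 = 0.002.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import InvalidInputError, InvalidParameterError

DEFAULT_N_PERM = 499

__all__ = [
    "snr",
    "fold_change",
    "permutation_p",
    "rank_table",
    "top_n",
    "DEFAULT_N_PERM",
]


def _floored_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    floor = 0.2 * np.abs(mean)
    out = np.maximum(sd, floor)
    return np.where(out == 0.0, 0.2, out)


def _snr_rows(x: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """Row-wise SNR for a genes x samples matrix given column index sets."""
    xa, xb = x[:, a_idx], x[:, b_idx]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = _floored_sd(xa.std(axis=1, ddof=1), mu_a)
    sd_b = _floored_sd(xb.std(axis=1, ddof=1), mu_b)
    return (mu_a - mu_b) / (sd_a + sd_b)


def _check_group(g: np.ndarray, name: str) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise InvalidInputError(f"group {name} needs >= 2 values")
    if not np.isfinite(g).all():
        raise InvalidInputError(f"group {name} contains non-finite values")
    return g


def snr(group_a, group_b) -> float:
    """Signal-to-noise ratio between two sample groups.

    Positive when ``group_a`` has the higher mean.  The sample standard
    deviation (n-1 denominator) of each group is floored as described in
    the module docstring, so the result is always finite.
    """
    a = _check_group(group_a, "a")
    b = _check_group(group_b, "b")
    x = np.vstack([np.concatenate([a, b])])
    return float(_snr_rows(x, np.arange(a.size), np.arange(a.size, a.size + b.size))[0])


def fold_change(group_a, group_b) -> float:
    """Linear fold change ``2**(mean_a - mean_b)`` for log2-scale groups."""
    a = _check_group(group_a, "a")
    b = _check_group(group_b, "b")
    return float(2.0 ** (a.mean() - b.mean()))


def permutation_p(values, labels, n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> float:
    """Two-sided label-permutation p-value for a single gene's SNR.

    Permutations are drawn uniformly (with replacement across draws, no
    uniqueness enforced); p = (#{|SNR*| >= |SNR_obs|} + 1) / (n_perm + 1),
    which is never 0 and never exceeds 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise InvalidInputError("labels must contain exactly two classes")
    a_mask = labels == classes[0]
    n_a = int(a_mask.sum())
    if n_a < 2 or (values.size - n_a) < 2:
        raise InvalidInputError("both classes need >= 2 samples")
    x = values[np.newaxis, :]
    order = np.concatenate([np.flatnonzero(a_mask), np.flatnonzero(~a_mask)])
    obs = abs(_snr_rows(x, order[:n_a], order[n_a:])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(values.size)
        if abs(_snr_rows(x, perm[:n_a], perm[n_a:])[0]) >= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def rank_table(
    matrix: ExpressionMatrix,
    class_a: str,
    class_b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank all genes by SNR between two sample classes.

    Returns a DataFrame with columns ``gene``, ``snr``, ``fold_change``,
    ``perm_p`` and ``rank`` (1 = highest SNR), sorted by rank.  Ties in
    SNR are broken lexicographically by gene id so the ranking is
    deterministic.  All genes share one stream of label permutations,
    which is both fast and the convention of the phenotype-permutation
    ecosystem this statistic comes from.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    a_ids = matrix.class_samples(class_a)
    b_ids = matrix.class_samples(class_b)
    if len(a_ids) < 2:
        raise InvalidInputError(f"class {class_a!r} has {len(a_ids)} samples (need >= 2)")
    if len(b_ids) < 2:
        raise InvalidInputError(f"class {class_b!r} has {len(b_ids)} samples (need >= 2)")

    sub = matrix.values[a_ids + b_ids]
    x = sub.to_numpy(dtype=float)
    n_a, n_tot = len(a_ids), len(a_ids) + len(b_ids)
    a_idx, b_idx = np.arange(n_a), np.arange(n_a, n_tot)

    obs = _snr_rows(x, a_idx, b_idx)
    fc = 2.0 ** (x[:, a_idx].mean(axis=1) - x[:, b_idx].mean(axis=1))

    rng = np.random.default_rng(seed)
    hits = np.zeros(x.shape[0], dtype=np.int64)
    abs_obs = np.abs(obs)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        hits += np.abs(_snr_rows(x, perm[:n_a], perm[n_a:])) >= abs_obs
    perm_p = (hits + 1) / (n_perm + 1)

    out = pd.DataFrame(
        {
            "gene": sub.index,
            "snr": obs,
            "fold_change": fc,
            "perm_p": perm_p,
        }
    )
    out = out.sort_values(["snr", "gene"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def top_n(table: pd.DataFrame, n: int) -> pd.DataFrame:
    """First ``n`` rows of a rank table (fewer if the table is shorter)."""
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    return table.nsmallest(n, "rank") if "rank" in table else table.head(n)
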