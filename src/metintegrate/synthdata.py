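"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the real data sources the pipeline is built for:

* a merged tissue cohort (normal / primary tumor / metastasis) of
  RMA-like log2 expression, with a chosen number of genes upregulated in
  the metastasis class only — the primary-vs-normal contrast stays flat,
  mirroring a metastasis-specific signature;
* a cancer cell-line panel with expression, primary/metastatic origin
  labels and CRISPR knockout gene-dependency probabilities that are
  bimodal near 0 and 1 (Beta(1,20) for non-essential genes, Beta(20,1)
  for planted essentials);
* a drug-viability log-fold-change vector coupled to the expression of a
  planted signature (higher signature expression => more negative LFC,
  i.e. more responsive);
* surfaceome / secretome / drug-target annotation tables with known
  membership, and GMT-writable gene-set collections with planted
  coherent sets.

Each generator is fully deterministic given its seed.  The additive
noise is Gaussian on the log2 scale, appropriate for RMA-normalised
array data.  Probe-level effects, batch structure across cohorts, and
copy-number/mutation layers are deliberately not simulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CLASS_METASTASIS,
    CLASS_NORMAL,
    CLASS_PRIMARY,
    AnnotationTables,
    DependencyMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    SimulationTruth,
)
from .errors import InvalidParameterError

SECRETED_TAGS = ("secreted (curated)", "secreted (highly likely)", "secreted (likely)")
LINEAGES = ("prostate", "lung", "breast", "skin", "colon", "ovary")

__all__ = [
    "generate_tissue_expression",
    "generate_cellline_panel",
    "generate_drug_response",
    "generate_annotations",
    "generate_gene_sets",
    "SECRETED_TAGS",
]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_tissue_expression(
    n_genes: int = 8000,
    n_per_class: tuple[int, int, int] = (41, 140, 31),
    n_de: int = 300,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Three-class tissue cohort with genes upshifted in metastasis only.

    ``n_per_class`` is (normal, primary, metastasis).  Per-gene baseline
    means are drawn once from N(7, 1.5) on the log2 scale; the ``n_de``
    planted genes gain ``effect_size`` log2 units in the metastasis
    class.  The default class sizes match a merged two-cohort prostate
    study (41 normal, 140 primary, 31 metastasis).
    """
    n_n, n_pt, n_met = n_per_class
    if n_genes < 1 or min(n_n, n_pt, n_met) < 2:
        raise InvalidParameterError("n_genes >= 1 and every class size >= 2 required")
    if not (0 <= n_de <= n_genes):
        raise InvalidParameterError("n_de must satisfy 0 <= n_de <= n_genes")
    if effect_size == 0 and n_de > 0:
        raise InvalidParameterError("planted genes need a nonzero effect size")
    if noise_sd <= 0:
        raise InvalidParameterError("noise_sd must be > 0")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    baseline = rng.normal(7.0, 1.5, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)

    n_samples = n_n + n_pt + n_met
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    x[np.ix_(de_idx, np.arange(n_n + n_pt, n_samples))] += effect_size

    samples = (
        [f"N_{i:03d}" for i in range(1, n_n + 1)]
        + [f"PT_{i:03d}" for i in range(1, n_pt + 1)]
        + [f"MET_{i:03d}" for i in range(1, n_met + 1)]
    )
    classes = [CLASS_NORMAL] * n_n + [CLASS_PRIMARY] * n_pt + [CLASS_METASTASIS] * n_met
    em = ExpressionMatrix(
        values=pd.DataFrame(x, index=genes, columns=samples),
        sample_class=pd.Series(classes, index=samples),
        cohort=pd.Series("synthetic_tissue", index=samples),
    )
    truth = SimulationTruth(
        planted_de_genes=[(genes[i], float(effect_size)) for i in sorted(de_idx)],
        seed=seed,
    )
    return em, truth


def generate_cellline_panel(
    n_lines: int = 200,
    frac_metastatic_origin: float = 0.4,
    n_genes: int = 2000,
    n_essential: int = 50,
    seed: int = 0,
    expression_truth: SimulationTruth | None = None,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    n_signature: int = 0,
    signature_strength: float = 1.0,
) -> tuple[ExpressionMatrix, DependencyMatrix, SimulationTruth]:
    """Cell-line panel: expression, origin labels and gene dependencies.

    Dependencies for planted essential genes come from Beta(20, 1)
    (mean ~0.95), all others from Beta(1, 20) (mean ~0.05), reproducing
    the bimodal near-0 / near-1 structure of genome-wide knockout
    screens.  When ``expression_truth`` carries planted DE genes, those
    genes are also upshifted in the metastatic-origin lines so that
    expression and dependency layers can be analysed jointly.

    ``n_signature`` > 0 plants a co-expressed signature: a per-line
    latent activity a ~ N(0, 1) is added, scaled by
    ``signature_strength`` (log2 units), to the chosen signature genes.
    This emulates a pathway whose member genes rise and fall together
    across lines — the structure a drug response can couple to — and is
    recorded in ``truth.planted_response_signature``.
    """
    if not 0.0 <= frac_metastatic_origin <= 1.0:
        raise InvalidParameterError("frac_metastatic_origin must lie in [0, 1]")
    if n_lines < 4 or n_genes < 1:
        raise InvalidParameterError("need n_lines >= 4 and n_genes >= 1")
    if not 0 <= n_essential <= n_genes:
        raise InvalidParameterError("0 <= n_essential <= n_genes required")
    if not 0 <= n_signature <= n_genes:
        raise InvalidParameterError("0 <= n_signature <= n_genes required")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    lines = [f"LINE_{i:04d}" for i in range(1, n_lines + 1)]
    n_met = int(round(frac_metastatic_origin * n_lines))
    n_met = min(max(n_met, 2), n_lines - 2)  # both origin groups non-empty
    origin = np.array([CLASS_PRIMARY] * (n_lines - n_met) + [CLASS_METASTASIS] * n_met)
    rng.shuffle(origin)
    lineage = rng.choice(LINEAGES, size=n_lines)

    baseline = rng.normal(7.0, 1.5, size=n_genes)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_lines))
    if expression_truth is not None:
        de = [g for g in expression_truth.de_gene_ids if g in set(genes)]
        gi = {g: i for i, g in enumerate(genes)}
        met_cols = np.flatnonzero(origin == CLASS_METASTASIS)
        x[np.ix_([gi[g] for g in de], met_cols)] += effect_size

    sig_idx = (
        rng.choice(n_genes, size=n_signature, replace=False)
        if n_signature
        else np.array([], int)
    )
    if n_signature:
        activity = rng.normal(0.0, 1.0, size=n_lines)
        x[sig_idx, :] += signature_strength * activity[None, :]

    ess_idx = (
        rng.choice(n_genes, size=n_essential, replace=False)
        if n_essential
        else np.array([], int)
    )
    dep = rng.beta(1.0, 20.0, size=(n_genes, n_lines))
    if n_essential:
        dep[ess_idx, :] = rng.beta(20.0, 1.0, size=(n_essential, n_lines))

    em = ExpressionMatrix(
        values=pd.DataFrame(x, index=genes, columns=lines),
        sample_class=pd.Series(origin, index=lines),
        cohort=pd.Series("synthetic_celllines", index=lines),
    )
    dm = DependencyMatrix(
        values=pd.DataFrame(dep, index=genes, columns=lines),
        origin=pd.Series(origin, index=lines),
        lineage=pd.Series(lineage, index=lines),
    )
    truth = SimulationTruth(
        planted_essential_genes=[genes[i] for i in sorted(ess_idx)],
        planted_response_signature=[genes[i] for i in sorted(sig_idx)],
        seed=seed,
    )
    return em, dm, truth


def generate_drug_response(
    cellline_expression: ExpressionMatrix,
    signature_genes,
    coupling: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.Series:
    """Viability log fold change coupled to a planted expression signature.

    Per line: LFC = -coupling * z(mean signature expression) + noise,
    so lines expressing the signature highly are the most responsive
    (most negative LFC), matching a screen where invasion-signature-high
    lines respond to kinase inhibition.
    """
    sig = list(dict.fromkeys(signature_genes))
    if not sig:
        raise InvalidParameterError("signature must contain at least one gene")
    missing = set(sig) - set(cellline_expression.gene_ids)
    if missing:
        raise InvalidParameterError(f"signature genes absent from matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    score = cellline_expression.values.loc[sig].mean(axis=0)
    z = (score - score.mean()) / score.std(ddof=0)
    lfc = -coupling * z + rng.normal(0.0, noise_sd, size=len(z))
    return pd.Series(lfc.to_numpy(), index=cellline_expression.values.columns, name="lfc")


def generate_annotations(
    genes,
    frac_surface: float = 0.15,
    frac_secreted: float = 0.15,
    frac_druggable: float = 0.1,
    seed: int = 0,
) -> AnnotationTables:
    """Annotation tables with known membership fractions.

    Surfaceome rows carry a confidence category in {1, 2, 3}; secretome
    rows carry a curation tag and an independent protein-atlas location
    field, with every member guaranteed at least one line of evidence;
    drug-target rows map genes to synthetic inhibitor names with an
    approved flag.
    """
    for name, f in (("frac_surface", frac_surface), ("frac_secreted", frac_secreted),
                    ("frac_druggable", frac_druggable)):
        if not 0.0 <= f <= 1.0:
            raise InvalidParameterError(f"{name} must lie in [0, 1]")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    n = len(genes)

    def pick(frac):
        k = int(round(frac * n))
        return sorted(rng.choice(n, size=k, replace=False)) if k else []

    surf_idx = pick(frac_surface)
    surfaceome = pd.DataFrame(
        {
            "gene": [genes[i] for i in surf_idx],
            "uniprot_id": [f"P{90000 + i:05d}" for i in surf_idx],
            "category": rng.choice([1, 2, 3], size=len(surf_idx), p=[0.6, 0.3, 0.1]),
        }
    )

    sec_idx = set(pick(frac_secreted))
    tags, hpa = [], []
    for i in range(n):
        if i in sec_idx:
            # evidence pattern: metaz tag only / HPA only / both
            mode = rng.integers(3)
            tags.append(str(rng.choice(SECRETED_TAGS)) if mode != 1 else "none")
            hpa.append("Secreted" if mode != 0 else "")
        else:
            tags.append("none")
            hpa.append("")
    secretome = pd.DataFrame({"gene": genes, "metaz_tag": tags, "hpa_location": hpa})

    drug_idx = pick(frac_druggable)
    rows = []
    for i in drug_idx:
        for j in range(int(rng.integers(1, 4))):
            rows.append(
                (genes[i], f"inhib_{i:05d}_{j}", bool(rng.random() < 0.5))
            )
    drug_targets = pd.DataFrame(rows, columns=["gene", "inhibitor", "approved"])
    return AnnotationTables(surfaceome=surfaceome, secretome=secretome,
                            drug_targets=drug_targets)


def generate_gene_sets(
    genes,
    n_sets: int = 25,
    set_size_range: tuple[int, int] = (15, 60),
    n_planted: int = 1,
    seed: int = 0,
    planted_pool=None,
) -> tuple[GeneSetCollection, list[str]]:
    """Gene-set collection with planted coherent sets among random decoys.

    Planted sets draw their members from ``planted_pool`` (typically the
    planted DE genes of a tissue simulation) so that, composed with that
    simulation, they are genuinely enriched; decoy sets are uniform
    draws from the full gene universe.  Returns the collection and the
    planted set ids.
    """
    genes = list(genes)
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(genes):
        raise InvalidParameterError("need 1 <= min size <= max size <= n_genes")
    if n_planted > n_sets:
        raise InvalidParameterError("n_planted cannot exceed n_sets")
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    planted_ids: list[str] = []
    pool = list(planted_pool) if planted_pool is not None else []

    for k in range(n_planted):
        size = int(rng.integers(lo, hi + 1))
        if pool:
            size = min(size, len(pool))
            members = [pool[i] for i in sorted(rng.choice(len(pool), size, replace=False))]
        else:
            members = [genes[i] for i in sorted(rng.choice(len(genes), size, replace=False))]
        sid = f"SET_PLANTED_{k + 1:02d}"
        coll.add(sid, "planted coherent set", members)
        planted_ids.append(sid)

    for k in range(n_sets - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = [genes[i] for i in sorted(rng.choice(len(genes), size, replace=False))]
        coll.add(f"SET_DECOY_{k + 1:03d}", "random decoy set", members)
    return coll, planted_ids
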