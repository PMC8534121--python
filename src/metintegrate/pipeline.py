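"""End-to-end orchestration: merge -> differential -> enrichment ->
dependency triage -> pharmacogenomics -> annotation shortlists.

``run_pipeline`` reads every input named in a :class:`PipelineConfig`,
executes each stage, writes eight TSV outputs plus a JSON manifest and
returns the manifest.  Outputs are pure functions of (inputs, config,
seed): rerunning an identical configuration yields byte-identical files.

``demo`` generates a complete synthetic study (tissue cohorts, cell-line
panel with dependencies and a planted co-expressed signature, drug
response coupled to that signature, annotations, gene sets) into a
directory and runs the pipeline on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, dependency, io_merge, pharmaco, synthdata
from .containers import CLASS_METASTASIS, CLASS_PRIMARY
from .differential import DEFAULT_N_PERM, rank_table, top_n
from .enrichment import gsea_all_sets, ora
from .errors import InvalidParameterError, MetIntegrateError

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "diff.tsv", "ora.tsv", "gsea.tsv", "triage.tsv",
    "sig_ora.tsv", "surface.tsv", "secreted.tsv", "druggable.tsv",
)

__all__ = ["PipelineConfig", "run_pipeline", "demo", "OUTPUT_FILES"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Paths are resolved relative to the config file's directory when
    loaded from YAML.  Defaults mirror the analysis this pipeline
    reimplements: 499 permutations, a top-500 ORA query, a top-300
    shortlist pool, a top-150 response-signature query and +/-0.5 LFC
    response thresholds.
    """

    # inputs
    tissue_expression: list[str] = field(default_factory=list)  # one TSV per cohort
    tissue_sample_meta: list[str] = field(default_factory=list)
    cellline_expression: str = ""
    cellline_sample_meta: str = ""
    dependency_matrix: str = ""
    dependency_meta: str = ""
    drug_response: str = ""
    gene_sets: str = ""
    surfaceome: str = ""
    secretome: str = ""
    drug_targets: str = ""
    # parameters
    class_a: str = CLASS_METASTASIS
    class_b: str = CLASS_PRIMARY
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    median_center: bool = False
    ora_top: int = 500
    top_pool: int = 300
    top_k: int = 150
    gsea_weight: float = 1.0
    high_gd: float = 0.9
    low_gd: float = 0.1
    lfc_low: float = -0.5
    lfc_high: float = 0.5
    # output
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent

        def resolve(p: str) -> str:
            return str((base / p)) if p and not Path(p).is_absolute() else p

        cfg.tissue_expression = [resolve(p) for p in cfg.tissue_expression]
        cfg.tissue_sample_meta = [resolve(p) for p in cfg.tissue_sample_meta]
        for name in ("cellline_expression", "cellline_sample_meta",
                     "dependency_matrix", "dependency_meta", "drug_response",
                     "gene_sets", "surfaceome", "secretome", "drug_targets",
                     "out_dir"):
            setattr(cfg, name, resolve(getattr(cfg, name)))
        return cfg

    def validate(self) -> None:
        if not self.tissue_expression:
            raise InvalidParameterError("config: tissue_expression paths are required")
        if len(self.tissue_sample_meta) != len(self.tissue_expression):
            raise InvalidParameterError(
                "config: one sample-meta file per tissue expression file required")
        required = list(self.tissue_expression) + list(self.tissue_sample_meta) + [
            self.cellline_expression, self.cellline_sample_meta,
            self.dependency_matrix, self.dependency_meta, self.drug_response,
            self.gene_sets, self.surfaceome, self.secretome, self.drug_targets,
        ]
        for p in required:
            if not p:
                raise InvalidParameterError("config: all input paths must be set")
            if not Path(p).is_file():
                raise InvalidParameterError(f"config: input file not found: {p}")
        if self.n_perm < 1:
            raise InvalidParameterError("config: n_perm must be >= 1")
        if not 0.0 <= self.low_gd < self.high_gd <= 1.0:
            raise InvalidParameterError("config: need 0 <= low_gd < high_gd <= 1")
        if self.lfc_low >= self.lfc_high:
            raise InvalidParameterError("config: lfc_low must be below lfc_high")
        for name in ("ora_top", "top_pool", "top_k"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"config: {name} must be >= 1")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _write_table(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write outputs plus ``manifest.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    # independent reproducible substreams per stochastic stage
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(config.seed).spawn(2)]

    def stage(name, fn):
        try:
            return fn()
        except MetIntegrateError:
            logger.error("pipeline stage %r failed", name)
            raise

    # --- merge tissue cohorts
    cohorts = [
        io_merge.read_expression(p, format="tsv", sample_meta=m)
        for p, m in zip(config.tissue_expression, config.tissue_sample_meta)
    ]
    merged = stage("merge", lambda: io_merge.merge_cohorts(
        cohorts, median_center=config.median_center))

    # --- differential ranking (class_a vs class_b)
    diff = stage("differential", lambda: rank_table(
        merged, config.class_a, config.class_b,
        n_perm=config.n_perm, seed=seeds[0]))
    counts["diff.tsv"] = _write_table(diff, out / "diff.tsv")

    # --- enrichment of the top upregulated genes
    sets = io_merge.read_gmt(config.gene_sets)
    universe = merged.gene_ids
    query = top_n(diff, config.ora_top)["gene"].tolist()
    ora_tab = stage("ora", lambda: ora(query, sets, universe))
    counts["ora.tsv"] = _write_table(ora_tab, out / "ora.tsv")

    gsea_tab = stage("gsea", lambda: gsea_all_sets(
        diff["gene"].tolist(), diff["snr"].to_numpy(), sets,
        weight=config.gsea_weight))
    counts["gsea.tsv"] = _write_table(gsea_tab, out / "gsea.tsv")

    # --- dependency triage
    dep = io_merge.read_dependency(config.dependency_matrix, config.dependency_meta)
    gd_means = stage("dependency", lambda: dependency.mean_gd_by_origin(dep))
    triage_tab = stage("triage", lambda: dependency.triage(
        diff, gd_means, high_gd=config.high_gd, low_gd=config.low_gd,
        top_pool=config.top_pool))
    counts["triage.tsv"] = _write_table(triage_tab, out / "triage.tsv")

    # --- pharmacogenomic stratification and signature ORA
    ccle = io_merge.read_expression(
        config.cellline_expression, format="tsv",
        sample_meta=config.cellline_sample_meta)
    response = io_merge.read_response(config.drug_response)
    strata = stage("stratify", lambda: pharmaco.stratify(
        response, low=config.lfc_low, high=config.lfc_high))
    signature = stage("response_signature", lambda: pharmaco.response_signature(
        ccle, strata, n_perm=config.n_perm, seed=seeds[1]))
    sig_ora = stage("signature_ora", lambda: pharmaco.signature_ora(
        signature, sets, ccle.gene_ids, top_k=config.top_k))
    counts["sig_ora.tsv"] = _write_table(sig_ora, out / "sig_ora.tsv")

    # --- annotation shortlists
    tables = io_merge.read_annotations(
        config.surfaceome, config.secretome, config.drug_targets)
    counts["surface.tsv"] = _write_table(
        annotate.surfaceome_shortlist(diff, tables, top_pool=config.top_pool),
        out / "surface.tsv")
    counts["secreted.tsv"] = _write_table(
        annotate.secretome_shortlist(diff, tables, top_pool=config.top_pool),
        out / "secreted.tsv")
    counts["druggable.tsv"] = _write_table(
        annotate.druggable_shortlist(diff, tables, top_pool=config.top_pool),
        out / "druggable.tsv")

    # hash parameters plus input-file digests (not paths, which would make
    # identical runs in different directories look different)
    path_fields = {"tissue_expression", "tissue_sample_meta",
                   "cellline_expression", "cellline_sample_meta",
                   "dependency_matrix", "dependency_meta", "drug_response",
                   "gene_sets", "surfaceome", "secretome", "drug_targets",
                   "out_dir"}
    cfg_dict = config.as_dict()
    params = {k: v for k, v in cfg_dict.items() if k not in path_fields}
    input_paths = list(config.tissue_expression) + list(config.tissue_sample_meta) + [
        config.cellline_expression, config.cellline_sample_meta,
        config.dependency_matrix, config.dependency_meta, config.drug_response,
        config.gene_sets, config.surfaceome, config.secretome, config.drug_targets]
    digests = [hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in input_paths]
    cfg_hash = hashlib.sha256(
        json.dumps({"params": params, "inputs": digests},
                   sort_keys=True).encode()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "n_samples_merged": merged.n_samples,
        "n_genes_merged": merged.n_genes,
        "strata_sizes": {
            "responsive": len(strata.responsive),
            "non_responsive": len(strata.non_responsive),
            "excluded": len(strata.excluded),
        },
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# demo: synthetic study + full run


def demo(seed: int = 7, out_dir: str | Path = "demo",
         n_genes: int = 3000, n_perm: int = DEFAULT_N_PERM) -> dict:
    """Generate a synthetic study under ``out_dir/inputs`` and run everything.

    The synthetic study mirrors the real one's shape: a merged tissue
    cohort of 41 normal / 140 primary / 31 metastasis samples with 300
    metastasis-upregulated genes, a 200-line cell panel with 60
    essential genes and a 40-gene co-expressed signature, drug response
    coupled to that signature, and 25 gene sets of which one is planted
    inside the upregulated genes and one is the response signature.
    """
    out_dir = Path(out_dir)
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_tis, s_pan, s_drug, s_ann, s_sets = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5))

    tissue, truth_t = synthdata.generate_tissue_expression(
        n_genes=n_genes, n_per_class=(41, 140, 31), n_de=300,
        effect_size=2.0, noise_sd=0.5, seed=s_tis)
    # split into two pseudo-cohorts (alternating samples) to exercise merging
    cols = tissue.sample_ids
    for i, part in enumerate((cols[0::2], cols[1::2]), start=1):
        sub = tissue.subset_samples(part)
        sub.cohort = pd.Series(f"cohort{i}", index=part)
        io_merge.write_expression(
            sub, inputs / f"tissue_cohort{i}.tsv", format="tsv",
            sample_meta=inputs / f"tissue_cohort{i}.samples.tsv")

    panel, dep, truth_c = synthdata.generate_cellline_panel(
        n_lines=200, frac_metastatic_origin=0.4, n_genes=n_genes,
        n_essential=60, seed=s_pan, expression_truth=truth_t,
        n_signature=40, signature_strength=1.0)
    io_merge.write_expression(panel, inputs / "celllines.tsv", format="tsv",
                              sample_meta=inputs / "celllines.samples.tsv")
    io_merge.write_dependency(dep, inputs / "dependency.tsv",
                              inputs / "dependency.lines.tsv")

    lfc = synthdata.generate_drug_response(
        panel, truth_c.planted_response_signature,
        coupling=1.0, noise_sd=0.3, seed=s_drug)
    io_merge.write_response(lfc, inputs / "drug_response.tsv")

    tables = synthdata.generate_annotations(
        tissue.gene_ids, frac_surface=0.15, frac_secreted=0.15,
        frac_druggable=0.1, seed=s_ann)
    io_merge.write_annotations(tables, inputs / "surfaceome.tsv",
                               inputs / "secretome.tsv", inputs / "drug_targets.tsv")

    sets, planted_ids = synthdata.generate_gene_sets(
        tissue.gene_ids, n_sets=24, set_size_range=(15, 60), n_planted=1,
        seed=s_sets, planted_pool=truth_t.de_gene_ids)
    sets.add("SET_RESPONSE", "planted response signature",
             truth_c.planted_response_signature)
    io_merge.write_gmt(sets, inputs / "sets.gmt")

    truth = truth_t
    truth.planted_enriched_sets = [(sid, "up") for sid in planted_ids]
    truth.planted_enriched_sets.append(("SET_RESPONSE", "up"))
    truth.planted_essential_genes = truth_c.planted_essential_genes
    truth.planted_response_signature = truth_c.planted_response_signature
    io_merge.write_truth(truth, inputs / "truth.tsv")

    config = PipelineConfig(
        tissue_expression=[str(inputs / "tissue_cohort1.tsv"),
                           str(inputs / "tissue_cohort2.tsv")],
        tissue_sample_meta=[str(inputs / "tissue_cohort1.samples.tsv"),
                            str(inputs / "tissue_cohort2.samples.tsv")],
        cellline_expression=str(inputs / "celllines.tsv"),
        cellline_sample_meta=str(inputs / "celllines.samples.tsv"),
        dependency_matrix=str(inputs / "dependency.tsv"),
        dependency_meta=str(inputs / "dependency.lines.tsv"),
        drug_response=str(inputs / "drug_response.tsv"),
        gene_sets=str(inputs / "sets.gmt"),
        surfaceome=str(inputs / "surfaceome.tsv"),
        secretome=str(inputs / "secretome.tsv"),
        drug_targets=str(inputs / "drug_targets.tsv"),
        n_perm=n_perm,
        seed=seed,
        out_dir=str(out_dir / "results"),
    )
    with open(out_dir / "run.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)
    return run_pipeline(config)
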