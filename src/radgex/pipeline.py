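"""End-to-end study orchestration.

``run_full_study`` executes scoring → zone aggregation → unsupervised
feature reduction → per-pathway supervised screens → the mixed-model
campaign → nested LOPO-CV for every gene set → nested permutation tests
for pathways with positive cross-validated R² → multiplicity corrections
→ sensitivity variants, and writes the result tables, a JSON bundle and a
run manifest (config hash + seed) to the output directory.  Exit-relevant
validation happens up front; per-pathway failures are isolated and
logged, never fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .cohort import CohortConfig, generate_cohort
from .lmm import run_lmm_campaign
from .mapping import ZoneMap, aggregate_to_subcompartments
from .multiplicity import bh_adjust
from .permutation import nested_cv_permutation
from .prediction import (ElasticNetConfig, bootstrap_ci, nested_lopo,
                         patient_level_table)
from .reduction import reduce_unsupervised, univariate_screen
from .scoring import derive_zone_modules, log_transform, ssgsea_scores
from .sensitivity import IMPLEMENTED as SENSITIVITY_IMPLEMENTED
from .sensitivity import run_variant

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # either paths to the five input files ...
    expression: str | None = None
    sample_metadata: str | None = None
    gene_sets: str | None = None
    radiomics: str | None = None
    covariates: str | None = None
    # ... or a synthetic-cohort block
    synthetic: dict | None = None

    derive_zone_modules: bool = True
    zone_module_top_k: int = 200
    ssgsea_weight_exponent: float = 0.25
    ssgsea_kernel: bool = True
    ssgsea_normalize: bool = True
    aggregation: str = "mean"
    screen_fdr: float = 0.10
    screen_cap: int = 5
    elastic_net: dict = field(default_factory=dict)
    n_perm_lmm: int = 1000
    n_perm_nested: int = 1000
    n_total_pathways: int | None = None  # default: number of scored sets
    lmm_fdr_threshold: float = 0.05
    nested_fdr_threshold: float = 0.10
    sensitivity_variants: tuple = SENSITIVITY_IMPLEMENTED
    run_sensitivity: bool = True
    run_permutations: bool = True
    bootstrap_B: int = 1000
    seed: int = 42
    output_dir: str = "radgex_output"

    def config_hash(self) -> str:
        """Hash of every semantic field (the output location is excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        cc = config.synthetic
        cohort = generate_cohort(cc if isinstance(cc, CohortConfig) else CohortConfig(**cc))
        return cohort.expression, cohort.gene_sets, cohort.radiomics, cohort.covariates
    required = ("expression", "sample_metadata", "gene_sets", "radiomics")
    missing = [k for k in required if getattr(config, k) is None]
    if missing:
        raise ValueError(f"missing input paths: {missing}")
    expr = rio.read_expression(config.expression, config.sample_metadata)
    sets = rio.read_gmt(config.gene_sets)
    rad = rio.read_radiomics(config.radiomics)
    cov = rio.read_covariates(config.covariates) if config.covariates else None
    return expr, sets, rad, cov


def run_full_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle (also written).

    The returned dict carries the observation table, stage report, LMM
    campaign table, nested-CV table, permutation results and sensitivity
    tables, plus the manifest.
    """
    outdir = rio.ensure_dir(config.output_dir)
    expr, gene_sets, radiomics, covariates = _load_inputs(config)

    # patient matching across expression and radiomics
    expr_patients = set(expr.samples["patient_id"])
    rad_patients = set(radiomics["patient_id"])
    matched = sorted(expr_patients & rad_patients)
    if not matched:
        raise RuntimeError("patient-id intersection of expression and radiomics is empty")
    log.info("matched %d patients (%d expression-only, %d radiomics-only)",
             len(matched), len(expr_patients - rad_patients), len(rad_patients - expr_patients))
    keep_samples = expr.samples["patient_id"].isin(matched)
    expr.values = expr.values.loc[:, keep_samples.to_numpy()]
    expr.samples = expr.samples[keep_samples]
    radiomics = radiomics[radiomics["patient_id"].isin(matched)].reset_index(drop=True)

    # scoring
    if config.derive_zone_modules:
        modules = derive_zone_modules(expr, top_k=config.zone_module_top_k)
        all_sets = dict(gene_sets.sets)
        all_cats = dict(gene_sets.categories)
        all_sets.update(modules.sets)
        all_cats.update(modules.categories)
        from .scoring import GeneSetCollection
        gene_sets = GeneSetCollection(all_sets, all_cats)
    lexpr = log_transform(expr)
    scores = ssgsea_scores(lexpr, gene_sets, config.ssgsea_weight_exponent,
                           config.ssgsea_kernel, config.ssgsea_normalize)
    set_names = list(scores.scores.columns)
    n_total = config.n_total_pathways or len(set_names)

    # mapping
    zmap = ZoneMap(aggregation=config.aggregation)
    obs = aggregate_to_subcompartments(scores, expr.samples, zmap)

    # unsupervised reduction
    reduced, stage_report = reduce_unsupervised(radiomics)
    feat_names = [c for c in reduced.columns if c not in ("patient_id", "subcompartment")]

    # associational branch
    screens = {s: univariate_screen(reduced, obs, s, "per_subcompartment",
                                    config.screen_fdr, config.screen_cap)
               for s in set_names}
    lmm_table = run_lmm_campaign(obs, reduced, screens, n_total)

    # predictive branch
    en_config = ElasticNetConfig(**{**config.elastic_net, "seed": config.seed})
    ptable = patient_level_table(obs, reduced, config.aggregation)
    nested_rows = []
    perm_results = {}
    rng = np.random.default_rng(config.seed)
    for s in set_names:
        try:
            res = nested_lopo(ptable, s, en_config, config.screen_fdr, config.screen_cap,
                              feature_names=feat_names)
        except Exception as err:  # noqa: BLE001 - isolate per-pathway failures
            log.warning("nested CV failed for %s: %s", s, err)
            continue
        ci = bootstrap_ci(res.y, res.y_hat, config.bootstrap_B,
                          seed=int(rng.integers(2**31)))
        perm_p = np.nan
        if config.run_permutations and res.r2_cv > 0:
            perm = nested_cv_permutation(ptable, s, en_config, config.n_perm_nested,
                                         seed=int(rng.integers(2**31)),
                                         fdr_cut=config.screen_fdr, cap=config.screen_cap,
                                         feature_names=feat_names, observed=res.r2_cv)
            perm_results[s] = perm
            perm_p = perm.p
        nested_rows.append({"set_name": s, "r2_cv": res.r2_cv, "ci_low": ci[0],
                            "ci_high": ci[1], "mae": res.mae, "spearman_rho": res.spearman_rho,
                            "n_stable": len(res.stable_features),
                            "stable_features": ";".join(res.stable_features),
                            "status": res.status, "perm_p": perm_p})
    nested_table = pd.DataFrame(nested_rows)
    # conservative padded correction: untested pathways enter at p = 1.0
    perm_p_all = nested_table["perm_p"].fillna(1.0).to_numpy()
    nested_table["fdr"] = bh_adjust(perm_p_all, m_override=max(n_total, len(perm_p_all))).adjusted
    tested = nested_table["perm_p"].notna()
    nested_table["fdr_restricted"] = np.nan
    if tested.any():
        nested_table.loc[tested, "fdr_restricted"] = bh_adjust(
            nested_table.loc[tested, "perm_p"].to_numpy()).adjusted
    nested_table = nested_table.sort_values(["fdr", "perm_p", "set_name"]).reset_index(drop=True)

    # sensitivity variants
    sens_tables = []
    if config.run_sensitivity:
        for vid in config.sensitivity_variants:
            try:
                sens_tables.append(run_variant(scores, expr.samples, reduced, vid,
                                               gene_sets.categories, n_total,
                                               config.screen_fdr, config.screen_cap))
            except Exception as err:  # noqa: BLE001
                log.warning("sensitivity variant %s failed: %s", vid, err)
    sensitivity = pd.concat(sens_tables, ignore_index=True) if sens_tables else pd.DataFrame()

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients_matched": len(matched),
        "n_gene_sets": len(set_names),
        "stage_report": {k: v for k, v in stage_report.items() if not k.endswith("dropped")},
    }
    bundle = {"observations": obs, "stage_report": stage_report, "lmm": lmm_table,
              "nested": nested_table, "permutations": perm_results,
              "sensitivity": sensitivity, "manifest": manifest,
              "scores": scores, "reduced_features": reduced}

    float_fmt = "%.10g"
    obs.drop(columns=["composition"]).assign(
        composition=obs["composition"].map(lambda t: "|".join(t))
    ).to_csv(outdir / "observations.csv", index=False, float_format=float_fmt)
    lmm_table.to_csv(outdir / "lmm_results.csv", index=False, float_format=float_fmt)
    nested_table.to_csv(outdir / "nested_cv_results.csv", index=False, float_format=float_fmt)
    if not sensitivity.empty:
        sensitivity.to_csv(outdir / "sensitivity_results.csv", index=False,
                           float_format=float_fmt)
    with open(outdir / "stage_report.json", "w") as fh:
        json.dump(stage_report, fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return bundle
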