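"""Synthetic cohort generator.

Emulates the statistical structure of a zone-resolved glioblastoma
radiogenomic cohort: an unbalanced patient x zone expression design
(CT present for every patient, the other zones for subsets, giving the
ET/NET/ED subcompartment counts 28/15/7 with 6 complete patients under the
defaults), FPKM-scale expression with set-coherent patient-level signal,
a radiomic feature table with near-zero-variance columns and highly
correlated feature blocks, and optional planted linear couplings between a
gene set's patient-level signal and chosen radiomic features.

All randomness flows from one integer seed through a hierarchical
``numpy.random.SeedSequence`` spawn (availability, expression, radiomics,
covariates), so sub-tables are reproducible without rebuilding the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ZONES, ExpressionMatrix, GeneSetCollection

SUBCOMPARTMENTS = ("ET", "NET", "ED")

#: zone -> subcompartment availability logic used when emitting radiomic rows
_ZONE_TO_SUB = {"CT": "ET", "CTmvp": "ET", "CTpan": "NET", "IT": "ED", "LE": "ED"}


@dataclass(frozen=True)
class Coupling:
    """Planted linear link between one gene set's patient signal and features.

    Each listed feature is generated as
    ``beta * t_p + b_p + Normal(0, noise_sd)`` where ``t_p`` is the set's
    per-patient latent signal and ``b_p`` a patient random intercept.
    """

    set_name: str
    feature_ids: tuple[int, ...]
    beta: float
    noise_sd: float = 1.0

    @staticmethod
    def beta_for_signal_fraction(fraction: float, noise_sd: float = 1.0,
                                 intercept_sd: float = 0.0) -> float:
        """Beta giving signal_var / (signal_var + noise_var) = fraction."""
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        noise_var = noise_sd**2 + intercept_sd**2
        return float(np.sqrt(fraction / (1 - fraction) * noise_var))


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    n_patients: int = 28
    #: zone -> fixed patient count (int) or inclusion probability (float in [0,1])
    zone_availability: dict = field(
        default_factory=lambda: {"CT": 28, "CTmvp": 9, "CTpan": 15, "IT": 7, "LE": 7}
    )
    #: patients carrying all three subcompartments under fixed counts
    n_complete: int = 6
    n_genes: int = 1200
    n_gene_sets: int = 19
    genes_per_set: int = 30
    zone_marker_genes: int = 40
    n_features: int = 3920
    n_nzv_features: int = 60
    n_corr_blocks: int = 40
    block_size: int = 8
    within_block_rho: float = 0.95
    planted_couplings: tuple[Coupling, ...] = ()
    patient_random_intercept_sd: float = 0.0
    #: sd of the per-patient latent driving each gene set's coherent shift
    set_patient_sd: float = 0.5
    #: sd of the per-sample coherent shift of a set's genes (within-patient
    #: pathway-activity noise; keeps the intraclass correlation moderate)
    set_sample_sd: float = 0.5
    #: log2-scale shift per unit latent applied to genes of a coupled set
    coupling_expression_shift: float = 1.0
    zone_effect_sd: float = 0.5
    expression_noise_sd: float = 0.4
    seed: int = 42

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")
        if self.n_nzv_features + self.n_corr_blocks * self.block_size > self.n_features:
            raise ConfigurationError("NZV + correlated block features exceed n_features")
        if not 0.0 <= self.within_block_rho <= 1.0:
            raise ConfigurationError("within_block_rho must be in [0, 1]")
        for z, a in self.zone_availability.items():
            if z not in ZONES:
                raise ConfigurationError(f"unknown zone {z!r}")
            if isinstance(a, (int, np.integer)) and not isinstance(a, bool):
                if not 0 <= a <= self.n_patients:
                    raise ConfigurationError(f"zone {z} count {a} exceeds n_patients")
            else:
                if not 0.0 <= float(a) <= 1.0:
                    raise ConfigurationError(f"zone {z} probability out of [0, 1]")
        if self.n_gene_sets * self.genes_per_set + 5 * self.zone_marker_genes > self.n_genes:
            raise ConfigurationError("gene sets + zone markers exceed n_genes")
        set_names = self._set_names()
        for c in self.planted_couplings:
            if c.set_name not in set_names:
                raise ConfigurationError(f"coupling references unknown set {c.set_name!r}")
            for fid in c.feature_ids:
                if not 0 <= fid < self.n_features:
                    raise ConfigurationError(f"coupled feature id {fid} out of range")

    def _set_names(self) -> list[str]:
        n_hallmark = min(15, self.n_gene_sets)
        names = [f"HALLMARK_SET_{i + 1:02d}" for i in range(n_hallmark)]
        names += [f"NEFTEL_SET_{i + 1}" for i in range(self.n_gene_sets - n_hallmark)]
        return names

    def _set_categories(self) -> dict[str, str]:
        names = self._set_names()
        return {n: ("hallmark" if n.startswith("HALLMARK") else "neftel") for n in names}


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    radiomics: pd.DataFrame  # columns: patient_id, subcompartment, feature_*
    covariates: pd.DataFrame  # patient_id, age, mgmt_status, subtype
    truth: dict
    config: CohortConfig


def _zone_assignment(cfg: CohortConfig, rng: np.random.Generator,
                     patients: list[str]) -> dict[str, list[str]]:
    """Which patients carry each zone; honors fixed counts exactly."""
    n = cfg.n_patients
    out: dict[str, list[str]] = {}
    fixed = {z: a for z, a in cfg.zone_availability.items()
             if isinstance(a, (int, np.integer)) and not isinstance(a, bool)}
    # With the default-style design (CT all, CTpan count, IT/LE counts) place
    # the necrosis-zone and edema-zone sets with a controlled overlap so that
    # exactly n_complete patients carry all three subcompartments.
    order = rng.permutation(n)
    for z, a in cfg.zone_availability.items():
        if z in fixed:
            continue
        mask = rng.random(n) < float(a)
        out[z] = [patients[i] for i in np.nonzero(mask)[0]]
    if "CT" in fixed:
        ct_idx = order[: fixed["CT"]]
        out["CT"] = [patients[i] for i in sorted(ct_idx)]
    npan = fixed.get("CTpan", 0)
    pan_idx = set(order[:npan].tolist())
    out.setdefault("CTpan", [patients[i] for i in sorted(pan_idx)])
    n_ed = max(fixed.get("IT", 0), fixed.get("LE", 0))
    if n_ed:
        k_overlap = min(cfg.n_complete, npan, n_ed)
        overlap = list(order[:k_overlap])
        rest_pool = [i for i in order[npan:]] or [i for i in order]
        extra = rest_pool[: n_ed - k_overlap]
        ed_idx = sorted(overlap + list(extra))
        for z in ("IT", "LE"):
            if z in fixed and fixed[z]:
                out[z] = [patients[i] for i in ed_idx[: fixed[z]]]
    for z in ("CTmvp",):
        if z in fixed:
            pick = rng.choice(n, size=fixed[z], replace=False)
            out[z] = [patients[i] for i in sorted(pick)]
    for z in cfg.zone_availability:
        out.setdefault(z, [])
    # invariant: every patient has >= 1 zone sample
    covered = set().union(*out.values()) if out else set()
    for p in patients:
        if p not in covered:
            out.setdefault("CT", []).append(p)
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort (see module docstring)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_avail, ss_expr, ss_rad, ss_cov = root.spawn(4)
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    zones_of = _zone_assignment(config, np.random.default_rng(ss_avail), patients)

    # ---- expression (log2 scale, then back to FPKM) ----
    rng_e = np.random.default_rng(ss_expr)
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    set_names = config._set_names()
    sets: dict[str, list[str]] = {}
    cursor = 0
    for name in set_names:
        sets[name] = genes[cursor: cursor + config.genes_per_set]
        cursor += config.genes_per_set
    zone_markers = {}
    for z in ZONES:
        zone_markers[z] = genes[cursor: cursor + config.zone_marker_genes]
        cursor += config.zone_marker_genes

    sample_rows = []
    for z in ZONES:
        for p in zones_of.get(z, []):
            sample_rows.append((f"{p}_{z}", p, z))
    sample_rows.sort()
    sample_ids = [r[0] for r in sample_rows]
    meta = pd.DataFrame(
        {"patient_id": [r[1] for r in sample_rows], "zone": [r[2] for r in sample_rows]},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    gene_mu = rng_e.normal(5.0, 2.0, size=config.n_genes)
    # per-patient latent per gene set (coherent shift of the set's genes)
    latents = pd.DataFrame(
        rng_e.normal(0.0, 1.0, size=(config.n_patients, len(set_names))),
        index=patients, columns=set_names,
    )
    # per-set zone affinity (drives subcompartment differences in scores)
    zone_affinity = {name: rng_e.normal(0.0, config.zone_effect_sd, size=len(ZONES))
                     for name in set_names}
    zone_pos = {z: i for i, z in enumerate(ZONES)}
    coupled_sets = {c.set_name for c in config.planted_couplings}

    gene_idx = {g: i for i, g in enumerate(genes)}
    X = gene_mu[:, None] + rng_e.normal(0.0, config.expression_noise_sd,
                                        size=(config.n_genes, len(sample_ids)))
    for j, (sid, p, z) in enumerate(sample_rows):
        for name in set_names:
            rows = [gene_idx[g] for g in sets[name]]
            shift = zone_affinity[name][zone_pos[z]]
            scale = (config.coupling_expression_shift if name in coupled_sets
                     else config.set_patient_sd)
            shift += scale * latents.loc[p, name]
            if name not in coupled_sets:
                # within-patient activity noise for background programs;
                # planted sets keep the exact latent -> expression chain
                shift += rng_e.normal(0.0, config.set_sample_sd)
            X[rows, j] += shift
        X[[gene_idx[g] for g in zone_markers[z]], j] += 2.0
    fpkm = np.maximum(np.exp2(X) - 1.0, 0.0)
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=sample_ids), meta)

    # ---- radiomics ----
    rng_r = np.random.default_rng(ss_rad)
    rad_rows = []
    for p in patients:
        subs = sorted({_ZONE_TO_SUB[z] for z, ps in zones_of.items() if p in ps},
                      key=SUBCOMPARTMENTS.index)
        for s in subs:
            rad_rows.append((p, s))
    n_rows = len(rad_rows)
    feat_names = [f"rad_{i + 1:04d}" for i in range(config.n_features)]
    F = rng_r.normal(0.0, 1.0, size=(n_rows, config.n_features))

    coupled_ids = sorted({fid for c in config.planted_couplings for fid in c.feature_ids})
    # near-zero-variance columns: one repeated value in >= 96% of rows
    nzv_ids = [i for i in range(config.n_nzv_features + len(coupled_ids))
               if i not in coupled_ids][: config.n_nzv_features]
    for i in nzv_ids:
        col = np.zeros(n_rows)
        n_other = max(1, int(np.floor(0.04 * n_rows)))
        pos = rng_r.choice(n_rows, size=n_other, replace=False)
        col[pos] = rng_r.integers(1, 3, size=n_other).astype(float)
        F[:, i] = col
    # correlated blocks
    block_start = config.n_features - config.n_corr_blocks * config.block_size
    rho = config.within_block_rho
    for b in range(config.n_corr_blocks):
        cols = [block_start + b * config.block_size + k for k in range(config.block_size)
                if (block_start + b * config.block_size + k) not in coupled_ids]
        u = rng_r.normal(0.0, 1.0, size=n_rows)
        for i in cols:
            F[:, i] = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng_r.normal(0.0, 1.0, n_rows)
    # planted couplings
    intercepts = {p: rng_r.normal(0.0, config.patient_random_intercept_sd) for p in patients}
    row_patient = np.array([p for p, _ in rad_rows])
    for c in config.planted_couplings:
        t = latents[c.set_name]
        for fid in c.feature_ids:
            noise = rng_r.normal(0.0, c.noise_sd, size=n_rows)
            F[:, fid] = np.array([c.beta * t[p] + intercepts[p] for p in row_patient]) + noise

    radiomics = pd.DataFrame(F, columns=feat_names)
    radiomics.insert(0, "subcompartment", [s for _, s in rad_rows])
    radiomics.insert(0, "patient_id", row_patient)

    # ---- covariates ----
    rng_c = np.random.default_rng(ss_cov)
    age = np.clip(rng_c.normal(58.5, 7.8, size=config.n_patients), 30.0, 85.0)
    mgmt = (rng_c.random(config.n_patients) < 13 / 28).astype(int)
    subtype = rng_c.choice(["CL", "MES", "PN", "NL"], size=config.n_patients)
    covariates = pd.DataFrame({
        "patient_id": patients,
        "age": np.round(age, 1),
        "mgmt_status": mgmt,
        "subtype": subtype,
    })

    truth = {
        "couplings": [
            {"set_name": c.set_name, "feature_ids": list(c.feature_ids),
             "beta": c.beta, "noise_sd": c.noise_sd}
            for c in config.planted_couplings
        ],
        "patient_latents": {name: {p: float(latents.loc[p, name]) for p in patients}
                            for name in set_names},
        "patient_intercepts": {p: float(intercepts[p]) for p in patients},
        "nzv_feature_ids": nzv_ids,
        "zone_assignment": {z: list(ps) for z, ps in zones_of.items()},
        "seed": config.seed,
    }

    gene_sets = GeneSetCollection(sets, config._set_categories())
    return SyntheticCohort(expr, gene_sets, radiomics, covariates, truth, config)


def write_fixture(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text tables; returns a manifest of paths.

    Emits: expression.tsv (genes x samples), sample_metadata.csv,
    gene_sets.gmt, radiomics.csv, covariates.csv, truth.json.  The tables
    round-trip losslessly through :mod:`radgex.io` readers (floats written
    at full precision).
    """
    from . import io as rio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "sample_metadata": directory / "sample_metadata.csv",
        "gene_sets": directory / "gene_sets.gmt",
        "radiomics": directory / "radiomics.csv",
        "covariates": directory / "covariates.csv",
        "truth": directory / "truth.json",
    }
    cohort.expression.values.to_csv(paths["expression"], sep="\t", index_label="gene_id",
                                    float_format="%.17g")
    cohort.expression.samples.to_csv(paths["sample_metadata"], index_label="sample_id")
    rio.write_gmt(cohort.gene_sets, paths["gene_sets"])
    cohort.radiomics.to_csv(paths["radiomics"], index=False, float_format="%.17g")
    cohort.covariates.to_csv(paths["covariates"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
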