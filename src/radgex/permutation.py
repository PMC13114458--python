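"""Permutation inference for both analytical frameworks.

Patient-level permutation (mixed-model branch) shuffles which patient's
pathway scores are paired with which patient's radiomic features, keeping
each patient's rows together so the within-patient correlation structure
survives; features stay fixed at their pre-selected set.  The fully
nested permutation (predictive branch) shuffles patient-level pathway
scores and re-executes the entire nested LOPO-CV pipeline, including the
in-fold feature screen, for every permutation.  P-values follow the
n_extreme / N_perm convention (one-sided, larger statistic = more
extreme); a (+1)/(N+1) smoothing is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import fit_lmm_pair
from .prediction import ElasticNetConfig, nested_lopo

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray = field(repr=False)
    p: float
    framework: str
    statistic: str
    seed: int
    n_redrawn: int = 0
    extras: dict = field(default_factory=dict)


def _perm_p(observed: float, null: np.ndarray, smoothed: bool) -> float:
    n_extreme = int(np.sum(null >= observed - 1e-12))
    if smoothed:
        return (n_extreme + 1) / (len(null) + 1)
    return n_extreme / len(null)


def lmm_patient_permutation(data: pd.DataFrame, feature_terms: list[str],
                            n_perm: int = 1000, seed: int = 42,
                            covariates: tuple = (), smoothed: bool = False,
                            max_row_loss: float = 0.5,
                            strict_pattern: bool = False) -> dict[str, PermutationResult]:
    """Patient-level permutation of the score-feature pairing.

    ``data`` is the prepared analysis table (see
    :func:`radgex.lmm.prepare_lmm_table`) with fixed, pre-selected feature
    terms.  Each permutation realigns patient q's scores onto patient p's
    feature rows by subcompartment; feature rows without a matching score
    subcompartment are dropped (permutations losing more than
    ``max_row_loss`` of rows are redrawn).  With ``strict_pattern`` the
    shuffle is restricted to patients sharing the same subcompartment
    availability pattern, so no rows are ever lost.
    """
    observed = fit_lmm_pair(data, feature_terms, covariates)
    if not observed.converged:
        raise RuntimeError("observed model did not converge")
    patients = list(pd.unique(data["patient_id"]))
    score_of = {(p, s): v for p, s, v in
                zip(data["patient_id"], data["subcompartment"], data["z_pathway"])}
    subs_of = {p: frozenset(data.loc[data["patient_id"] == p, "subcompartment"]) for p in patients}
    rng = np.random.default_rng(seed)
    null_chi2 = np.empty(n_perm)
    null_r2m = np.empty(n_perm)
    n_redrawn = 0
    n_rows = len(data)

    for b in range(n_perm):
        for _ in range(100):
            if strict_pattern:
                perm = {}
                for pattern in set(subs_of.values()):
                    grp = [p for p in patients if subs_of[p] == pattern]
                    shuf = rng.permutation(len(grp))
                    for i, p in enumerate(grp):
                        perm[p] = grp[shuf[i]]
            else:
                shuf = rng.permutation(len(patients))
                perm = {p: patients[shuf[i]] for i, p in enumerate(patients)}
            keep = np.array([(perm[p], s) in score_of
                             for p, s in zip(data["patient_id"], data["subcompartment"])])
            if keep.sum() >= (1.0 - max_row_loss) * n_rows:
                break
            n_redrawn += 1
        pdata = data[keep].copy()
        pdata["z_pathway"] = [score_of[(perm[p], s)]
                              for p, s in zip(pdata["patient_id"], pdata["subcompartment"])]
        res = fit_lmm_pair(pdata, feature_terms, covariates)
        if res.converged:
            null_chi2[b] = res.chi2
            null_r2m[b] = res.r2m_full
        else:
            null_chi2[b] = 0.0
            null_r2m[b] = 0.0
    out = {}
    for stat, obs_val, null in (("chi2", observed.chi2, null_chi2),
                                ("r2m", observed.r2m_full, null_r2m)):
        out[stat] = PermutationResult(obs_val, null, _perm_p(obs_val, null, smoothed),
                                      "patient_level_lmm", stat, seed, n_redrawn)
    return out


def nested_cv_permutation(table: pd.DataFrame, set_name: str,
                          en_config: ElasticNetConfig | None = None,
                          n_perm: int = 1000, seed: int = 42,
                          fdr_cut: float = 0.10, cap: int = 5,
                          feature_names: list[str] | None = None,
                          observed: float | None = None,
                          force: bool = False, smoothed: bool = False) -> PermutationResult:
    """Fully nested permutation test of the cross-validated R².

    Reruns the whole nested LOPO-CV (screen + elastic net inside every
    fold) on patient-shuffled pathway scores.  By default only pathways
    with observed R²cv > 0 are tested (``force`` overrides).
    """
    en_config = en_config or ElasticNetConfig()
    if observed is None:
        obs_res = nested_lopo(table, set_name, en_config, fdr_cut, cap,
                              feature_names=feature_names)
        observed = obs_res.r2_cv
    if observed <= 0 and not force:
        raise ValueError("observed R²cv <= 0; permutation skipped (use force=True)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    ptable = table.copy()
    y0 = table[set_name].to_numpy()
    for b in range(n_perm):
        ptable[set_name] = y0[rng.permutation(len(y0))]
        res = nested_lopo(ptable, set_name, en_config, fdr_cut, cap,
                          feature_names=feature_names)
        null[b] = res.r2_cv
    return PermutationResult(observed, null, _perm_p(observed, null, smoothed),
                             "fully_nested_cv", "r2_cv", seed)
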