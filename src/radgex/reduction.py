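"""Three-stage radiomic feature reduction.

Stage 1 removes near-zero-variance features (caret-style frequency-ratio
and unique-percentage rule), stage 2 prunes highly correlated pairs
(|Spearman| above a cutoff) with a deterministic drop rule, and stage 3 is
a supervised univariate Spearman screen against a pathway score with
BH-FDR and a top-k cap.  Stages 1-2 never see the outcome; stage 3 exists
in a per-subcompartment (full-data, associational) and a patient-level
(in-fold, predictive) mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .multiplicity import bh_adjust

from ._stats import spearman_corr_matrix, spearman_vector

ID_COLS = ("patient_id", "subcompartment")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLS]


def near_zero_variance_filter(table: pd.DataFrame, freq_ratio_cut: float = 95 / 5,
                              unique_pct_cut: float = 10.0) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant and near-zero-variance feature columns.

    A feature is dropped when it is constant, or when
    (count of most common value / count of second most common value)
    exceeds ``freq_ratio_cut`` AND the percentage of distinct values is
    below ``unique_pct_cut``.  Returns (filtered table, dropped ids).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    dropped = []
    n = len(table)
    for c in feature_columns(table):
        counts = table[c].value_counts().to_numpy()
        if counts.size == 1:
            dropped.append(c)
            continue
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * counts.size / n
        if freq_ratio > freq_ratio_cut and unique_pct < unique_pct_cut:
            dropped.append(c)
    return table.drop(columns=dropped), dropped


def correlation_prune(table: pd.DataFrame, rho_cut: float = 0.90) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop one member of every feature pair with |Spearman| > cut.

    Deterministic rule: while any retained pair exceeds the cutoff, take the
    worst offending pair and drop the member with the larger mean absolute
    correlation to all currently retained features; ties drop the
    lexicographically larger feature id.  Survivors have all pairwise
    |rho| <= ``rho_cut``.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    feats = feature_columns(table)
    if len(feats) < 2:
        return table, []
    C = np.abs(spearman_corr_matrix(table[feats].to_numpy(dtype=float)))
    np.fill_diagonal(C, 0.0)
    C = np.nan_to_num(C, nan=0.0)
    alive = np.ones(len(feats), dtype=bool)
    dropped = []
    while True:
        sub = np.where(np.outer(alive, alive), C, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= rho_cut:
            break
        mean_i = C[i, alive].mean()
        mean_j = C[j, alive].mean()
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:
            victim = i if feats[i] > feats[j] else j
        alive[victim] = False
        dropped.append(feats[victim])
    keep = [f for f, a in zip(feats, alive) if a]
    return table[list(ID_COLS) + keep] if all(c in table.columns for c in ID_COLS) \
        else table[keep], dropped


@dataclass
class ScreenResult:
    """Per-feature univariate Spearman screen outcome for one pathway."""

    set_name: str
    mode: str
    table: pd.DataFrame = field(repr=False)  # feature, rho_*, p_*, fdr_*, min_fdr, min_p
    selected: list[str] = field(default_factory=list)
    fdr_cut: float = 0.10
    cap: int = 5


def univariate_screen(features: pd.DataFrame, scores: pd.DataFrame, set_name: str,
                      mode: str = "per_subcompartment", fdr_cut: float = 0.10,
                      cap: int = 5) -> ScreenResult:
    """Supervised per-pathway Spearman screen.

    ``per_subcompartment``: correlate each feature with the pathway score
    within each subcompartment separately, BH-FDR within subcompartment
    across features; a feature is eligible when its minimum FDR across
    subcompartments is below ``fdr_cut``.  ``patient_level``: a single
    correlation/BH pass on one-row-per-patient tables (the in-fold mode of
    the nested CV).  Eligible features are ranked by minimum raw p
    (ties: feature id) and truncated at ``cap``.
    """
    feats = feature_columns(features)
    recs: dict[str, dict] = {f: {"feature": f} for f in feats}
    if mode == "per_subcompartment":
        merged = features.merge(scores[["patient_id", "subcompartment", set_name]],
                                on=["patient_id", "subcompartment"], how="inner")
        for sub, grp in merged.groupby("subcompartment"):
            if len(grp) < 4:
                continue
            rho, p = spearman_vector(grp[set_name].to_numpy(), grp[feats].to_numpy())
            p_filled = np.where(np.isfinite(p), p, 1.0)
            fdr = bh_adjust(p_filled).adjusted
            for k, f in enumerate(feats):
                recs[f][f"rho_{sub}"] = rho[k]
                recs[f][f"p_{sub}"] = p_filled[k]
                recs[f][f"fdr_{sub}"] = fdr[k]
    elif mode == "patient_level":
        merged = features.merge(scores[["patient_id", set_name]], on="patient_id", how="inner")
        rho, p = spearman_vector(merged[set_name].to_numpy(), merged[feats].to_numpy())
        p_filled = np.where(np.isfinite(p), p, 1.0)
        fdr = bh_adjust(p_filled).adjusted
        for k, f in enumerate(feats):
            recs[f]["rho_all"] = rho[k]
            recs[f]["p_all"] = p_filled[k]
            recs[f]["fdr_all"] = fdr[k]
    else:
        raise ValueError("mode must be 'per_subcompartment' or 'patient_level'")

    tab = pd.DataFrame(list(recs.values()))
    p_cols = [c for c in tab.columns if c.startswith("p_")]
    fdr_cols = [c for c in tab.columns if c.startswith("fdr_")]
    if not p_cols:
        tab["min_p"] = 1.0
        tab["min_fdr"] = 1.0
    else:
        tab["min_p"] = tab[p_cols].min(axis=1).fillna(1.0)
        tab["min_fdr"] = tab[fdr_cols].min(axis=1).fillna(1.0)
    eligible = tab[tab["min_fdr"] < fdr_cut]
    ranked = eligible.sort_values(["min_p", "feature"])
    selected = list(ranked["feature"].head(cap))
    tab["selected"] = tab["feature"].isin(selected)
    return ScreenResult(set_name, mode, tab, selected, fdr_cut, cap)


def reduce_unsupervised(table: pd.DataFrame, freq_ratio_cut: float = 95 / 5,
                        unique_pct_cut: float = 10.0,
                        rho_cut: float = 0.90) -> tuple[pd.DataFrame, dict]:
    """NZV filter then correlation pruning; returns (table, stage report)."""
    n0 = len(feature_columns(table))
    t1, nzv_dropped = near_zero_variance_filter(table, freq_ratio_cut, unique_pct_cut)
    t2, corr_dropped = correlation_prune(t1, rho_cut)
    report = {
        "n_initial": n0,
        "n_after_nzv": n0 - len(nzv_dropped),
        "n_after_corr": n0 - len(nzv_dropped) - len(corr_dropped),
        "nzv_dropped": nzv_dropped,
        "corr_dropped": corr_dropped,
    }
    return t2, report
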