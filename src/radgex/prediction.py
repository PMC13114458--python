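"""Nested leave-one-patient-out elastic-net prediction framework.

The primary predictive analysis holds out one patient per fold and
re-executes every adaptive step inside the training fold: the univariate
Spearman screen (BH-FDR < 0.10, top five by raw p) and the elastic-net
hyperparameter search (alpha grid 0.1..1.0, lambda by the one-standard-
error rule from inner 5-fold CV).  Pooled held-out predictions yield
R²cv, MAE and Spearman rho; per-feature selection fractions across folds
give the stability set (> 50% of folds).  The legacy comparator screens
once on all patients before the loop, deliberately reintroducing the
selection leakage the nested design removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .multiplicity import bh_adjust

from ._enet import enet_path, lambda_grid, lambda_max
from ._stats import spearman_pair, spearman_vector


@dataclass
class ElasticNetConfig:
    alpha_grid: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    lambda_rule: str = "one_se"
    inner_folds: int = 5
    standardize_in_fold: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if not all(0 < a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in (0, 1]")
        if self.inner_folds < 2:
            raise ValueError("need at least 2 inner folds")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValueError("lambda_rule must be 'min' or 'one_se'")


@dataclass
class EnetFit:
    coef: np.ndarray
    intercept: float
    alpha: float
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept


@dataclass
class FoldRecord:
    held_out: str
    selected: tuple
    alpha: float | None
    lam: float | None
    prediction: float
    n_train: int


@dataclass
class NestedCvResult:
    set_name: str
    r2_cv: float
    mae: float
    spearman_rho: float
    fold_records: list[FoldRecord] = field(repr=False, default_factory=list)
    stability: dict = field(default_factory=dict)
    stable_features: list = field(default_factory=list)
    ci: tuple | None = None
    status: str = "ok"
    y: np.ndarray = field(repr=False, default=None)
    y_hat: np.ndarray = field(repr=False, default=None)
    patients: list = field(default_factory=list, repr=False)
    permutation_p: float | None = None
    fdr: float | None = None
    apparent_r2: float | None = None


def patient_level_table(obs: pd.DataFrame, features: pd.DataFrame,
                        aggregation: str = "mean") -> pd.DataFrame:
    """One row per patient: scores and features averaged over subcompartments.

    ``aggregation`` 'mean' (primary) or 'median' (S3 variant).
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    set_cols = [c for c in obs.columns if c not in ("patient_id", "subcompartment", "composition")]
    feat_cols = [c for c in features.columns if c not in ("patient_id", "subcompartment")]
    merged = obs[["patient_id", "subcompartment"] + set_cols].merge(
        features, on=["patient_id", "subcompartment"], how="inner")
    grouped = merged.groupby("patient_id", sort=True)[set_cols + feat_cols]
    out = (grouped.mean() if aggregation == "mean" else grouped.median()).reset_index()
    return out


def _inner_fold_assignment(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified folds: rank-sort y, deal round-robin.

    A seeded permutation of the fold labels decouples the assignment from
    the raw fold index while staying reproducible.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k)
    order = np.argsort(y, kind="stable")
    folds = np.empty(len(y), dtype=np.intp)
    folds[order] = perm[np.arange(len(y)) % k]
    return folds


def elastic_net_fit(X: np.ndarray, y: np.ndarray, config: ElasticNetConfig) -> EnetFit:
    """Grid-search elastic net with inner-CV lambda selection.

    Alpha is chosen to minimize the minimum mean inner-CV MSE over its
    lambda path; lambda is then the largest value whose mean inner-CV MSE
    is within one standard error of that minimum (``one_se``) or the
    minimizer itself (``min``).  Features are standardized with the
    statistics of the supplied (training) data; coefficients are returned
    on the original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < config.inner_folds + 1:
        raise ValueError("need at least inner_folds + 1 rows")
    y_mean = y.mean()
    if p == 0 or np.allclose(y, y_mean):
        return EnetFit(np.zeros(p), float(y_mean), None, None)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    yc = y - y_mean

    k = min(config.inner_folds, n)
    folds = _inner_fold_assignment(y, k, config.seed)

    best = None  # (min_mse, alpha, lambdas, mean_mse, se_at_min)
    for alpha in config.alpha_grid:
        lams = lambda_grid(lambda_max(Xs, yc, alpha), config.n_lambda,
                           config.lambda_min_ratio)
        fold_mse = np.empty((k, len(lams)))
        for f in range(k):
            tr = folds != f
            va = ~tr
            coefs = enet_path(Xs[tr], yc[tr] - yc[tr].mean(), lams, alpha)
            pred = Xs[va] @ coefs.T + yc[tr].mean()
            fold_mse[f] = ((yc[va][:, None] - pred) ** 2).mean(axis=0)
        mean_mse = fold_mse.mean(axis=0)
        i_min = int(np.argmin(mean_mse))
        se_min = fold_mse[:, i_min].std(ddof=1) / np.sqrt(k)
        cand = (mean_mse[i_min], -alpha, lams, mean_mse, se_min)
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    _, neg_alpha, lams, mean_mse, se_min = best
    alpha = -neg_alpha
    if config.lambda_rule == "one_se":
        thresh = mean_mse.min() + se_min
        lam = float(lams[np.nonzero(mean_mse <= thresh)[0][0]])  # largest qualifying lambda
    else:
        lam = float(lams[int(np.argmin(mean_mse))])

    coefs = enet_path(Xs, yc, np.array([lam]), alpha)[0]
    coef_orig = coefs / sd_safe
    coef_orig[sd == 0] = 0.0
    intercept = float(y_mean - mu @ coef_orig)
    return EnetFit(coef_orig, intercept, float(alpha), lam)


def _fast_bh(p: np.ndarray) -> np.ndarray:
    return bh_adjust(p).adjusted


def screen_training(y: np.ndarray, X: np.ndarray, feature_names,
                    fdr_cut: float = 0.10, cap: int = 5) -> list[int]:
    """Patient-level univariate Spearman screen on training rows only.

    Mirrors the ``patient_level`` mode of
    :func:`radgex.reduction.univariate_screen` (BH across features,
    eligibility min FDR < cut, rank by raw p with feature-id tie-break,
    truncate at cap) on bare arrays for the in-fold hot path.
    """
    rho, p = spearman_vector(y, X)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = _fast_bh(p)
    eligible = np.nonzero(fdr < fdr_cut)[0]
    if eligible.size == 0:
        return []
    order = sorted(eligible, key=lambda i: (p[i], str(feature_names[i])))
    return list(order[:cap])


def _pooled_metrics(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    mae = float(np.abs(y - y_hat).mean())
    if np.unique(y_hat).size < 2:
        rho = np.nan
    else:
        rho, _ = spearman_pair(y, y_hat)
    return r2, mae, rho


def nested_lopo(table: pd.DataFrame, set_name: str, en_config: ElasticNetConfig | None = None,
                fdr_cut: float = 0.10, cap: int = 5, standardize_response: bool = True,
                feature_names: list[str] | None = None) -> NestedCvResult:
    """Nested leave-one-patient-out CV with in-fold screening.

    ``table`` is one row per patient (see :func:`patient_level_table`).
    Folds that select zero features predict the training mean, which
    naturally drives R²cv to zero or below for no-signal pathways.
    """
    en_config = en_config or ElasticNetConfig()
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c.startswith("rad_") or c.startswith("feat_")]
        if not feature_names:
            raise ValueError("no feature columns found; pass feature_names")
    patients = table["patient_id"].tolist()
    n = len(patients)
    if n < 8:
        raise ValueError("need at least 8 patients")
    y = table[set_name].to_numpy(dtype=float)
    if standardize_response:
        sd = y.std(ddof=1)
        if sd > 0:
            y = (y - y.mean()) / sd
    X = table[feature_names].to_numpy(dtype=float)

    y_hat = np.empty(n)
    records = []
    counts: dict[str, int] = {}
    any_selected = False
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        sel = screen_training(y[tr], X[tr], feature_names, fdr_cut, cap)
        if not sel:
            y_hat[i] = y[tr].mean()
            records.append(FoldRecord(patients[i], (), None, None, float(y_hat[i]), n - 1))
            continue
        any_selected = True
        fit = elastic_net_fit(X[np.ix_(tr, sel)], y[tr], en_config)
        y_hat[i] = float(fit.predict(X[i, sel][None, :])[0])
        names = tuple(feature_names[j] for j in sel)
        for f in names:
            counts[f] = counts.get(f, 0) + 1
        records.append(FoldRecord(patients[i], names, fit.alpha, fit.lam, y_hat[i], n - 1))

    r2, mae, rho = _pooled_metrics(y, y_hat)
    stability = {f: c / n for f, c in sorted(counts.items())}
    stable = [f for f, frac in stability.items() if frac > 0.5]
    status = "ok" if any_selected else "no_signal"
    return NestedCvResult(set_name, r2, mae, rho, records, stability, stable,
                          status=status, y=y, y_hat=y_hat, patients=patients)


def legacy_prescreened_cv(table: pd.DataFrame, set_name: str,
                          en_config: ElasticNetConfig | None = None,
                          fdr_cut: float = 0.10, cap: int = 5,
                          feature_names: list[str] | None = None) -> NestedCvResult:
    """LOPO-CV with the screen run ONCE on all patients (leaky comparator).

    Also reports ``apparent_r2``, the in-sample R² of the model refitted on
    all patients with the pre-screened features.
    """
    en_config = en_config or ElasticNetConfig()
    if feature_names is None:
        feature_names = [c for c in table.columns
                         if c.startswith("rad_") or c.startswith("feat_")]
    patients = table["patient_id"].tolist()
    n = len(patients)
    if n < 8:
        raise ValueError("need at least 8 patients")
    y = table[set_name].to_numpy(dtype=float)
    sd = y.std(ddof=1)
    if sd > 0:
        y = (y - y.mean()) / sd
    X = table[feature_names].to_numpy(dtype=float)

    sel = screen_training(y, X, feature_names, fdr_cut, cap)
    y_hat = np.empty(n)
    records = []
    if not sel:
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            y_hat[i] = y[tr].mean()
            records.append(FoldRecord(patients[i], (), None, None, float(y_hat[i]), n - 1))
        r2, mae, rho = _pooled_metrics(y, y_hat)
        return NestedCvResult(set_name, r2, mae, rho, records, {}, [], status="no_signal",
                              y=y, y_hat=y_hat, patients=patients, apparent_r2=0.0)
    names = tuple(feature_names[j] for j in sel)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        fit = elastic_net_fit(X[np.ix_(tr, sel)], y[tr], en_config)
        y_hat[i] = float(fit.predict(X[i, sel][None, :])[0])
        records.append(FoldRecord(patients[i], names, fit.alpha, fit.lam, y_hat[i], n - 1))
    full_fit = elastic_net_fit(X[:, sel], y, en_config)
    resid = y - full_fit.predict(X[:, sel])
    apparent = 1.0 - float((resid**2).sum()) / float(((y - y.mean()) ** 2).sum())
    r2, mae, rho = _pooled_metrics(y, y_hat)
    stability = {f: 1.0 for f in names}
    return NestedCvResult(set_name, r2, mae, rho, records, stability, list(names),
                          y=y, y_hat=y_hat, patients=patients, apparent_r2=apparent)


def bootstrap_ci(y: np.ndarray, y_hat: np.ndarray, B: int = 1000, level: float = 95.0,
                 seed: int = 42, max_redraws: int = 100) -> tuple[float, float]:
    """Percentile bootstrap CI for R²cv, resampling (y, y_hat) pairs.

    Conditions on the fitted predictions (pairs are resampled, models are
    not refitted).  Degenerate resamples with zero response variance are
    redrawn.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if len(y) < 8:
        raise ValueError("need at least 8 pairs")
    if B < 200:
        raise ValueError("need B >= 200")
    rng = np.random.default_rng(seed)
    stats_ = np.empty(B)
    n = len(y)
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.var() > 0:
                break
        yh = y_hat[idx]
        stats_[b] = 1.0 - ((yb - yh) ** 2).sum() / ((yb - yb.mean()) ** 2).sum()
    lo = (100 - level) / 2
    return (float(np.percentile(stats_, lo)), float(np.percentile(stats_, 100 - lo)))
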