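"""Single-sample gene-set scoring on zone-level bulk expression.

The scorer is a rank-based running-sum single-sample enrichment statistic
(ssGSEA-style): per sample, genes are ordered by decreasing expression and
the score accumulates the gap between the weighted in-set cumulative
fraction and the unweighted out-of-set cumulative fraction.  An optional
per-gene Gaussian-kernel CDF transform across samples (the GSVA-style
"kcdf" step) can be applied before ranking.

Zone-specific gene modules are derived by a per-zone Wilcoxon rank-sum
differential-expression screen on log2(FPKM+1) values with BH-FDR and a
mean-difference filter, truncated to the top-k genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from .multiplicity import bh_adjust

log = logging.getLogger(__name__)

ZONES = ("CT", "CTmvp", "CTpan", "IT", "LE")
SET_CATEGORIES = ("hallmark", "neftel", "ivygap_module")


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM matrix with per-sample patient/zone metadata.

    ``values``: DataFrame, index = gene ids, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns
    ``patient_id`` and ``zone``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if not self.log_scale and (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets with a category label per set."""

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 2:
                raise ValueError(f"gene set {name!r} has fewer than 2 genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")
        for name in self.sets:
            self.categories.setdefault(name, "hallmark")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.categories[n] for n in names},
        )


@dataclass
class PathwayScoreTable:
    """Enrichment score per analysis unit (rows) and gene set (columns).

    ``level`` records the unit: 'sample', 'patient_subcompartment' or
    'patient'.
    """

    scores: pd.DataFrame
    level: str = "sample"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("scores must be finite")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each FPKM value x by log2(x + 1); metadata preserved."""
    if expr.log_scale:
        return expr
    vals = expr.values.to_numpy()
    if (vals < 0).any():
        raise ValueError("negative expression values")
    out = pd.DataFrame(np.log2(vals + 1.0), index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, expr.samples.copy(), log_scale=True)


def _kernel_cdf_transform(values: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel CDF estimate across samples.

    For gene g and sample j the transformed value is the mean over samples k
    of Phi((x_gj - x_gk) / h_g) with bandwidth h_g = sd_g / 4 (floored to
    avoid degeneracy on constant genes).
    """
    from scipy.special import ndtr

    sd = values.std(axis=1, ddof=1, keepdims=True)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    out = np.empty_like(values, dtype=float)
    n = values.shape[1]
    # chunk genes to bound the (chunk, n, n) difference tensor
    chunk = max(1, int(2e7 // (n * n)))
    for g0 in range(0, values.shape[0], chunk):
        block = values[g0:g0 + chunk]
        d = (block[:, :, None] - block[:, None, :]) / h[g0:g0 + chunk, :, None]
        out[g0:g0 + chunk] = ndtr(d).mean(axis=2)
    return out


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    weight_exponent: float = 0.25,
    kernel_transform: bool = True,
    normalize: bool = True,
) -> PathwayScoreTable:
    """Rank-weighted running-sum enrichment score per sample and gene set.

    Per sample, genes are sorted by decreasing (optionally kernel-CDF
    transformed) expression; ties broken by gene id for determinism.  The
    score is the sum over rank positions of (weighted cumulative in-set
    fraction - unweighted cumulative out-of-set fraction), where the in-set
    weight of the gene at descending position i among G genes is
    (G - i)^weight_exponent (i zero-based), i.e. a pure rank statistic.
    With ``normalize``, all scores are divided by the (max - min) over the
    whole table.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be nonnegative")
    genes = np.array(expr.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    if G < 2:
        raise ValueError("need at least 2 genes")

    vals = expr.values.to_numpy(dtype=float)
    if kernel_transform:
        vals = _kernel_cdf_transform(vals)

    membership = {}
    for name, members in sets.sets.items():
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=np.intp)
        if idx.size == 0:
            log.warning("gene set %s has no genes in the expression matrix; skipped", name)
            continue
        if idx.size < len(members):
            log.warning(
                "gene set %s: %d/%d genes absent from expression matrix",
                name, len(members) - idx.size, len(members),
            )
        m = np.zeros(G, dtype=bool)
        m[idx] = True
        membership[name] = m
    if not membership:
        raise ValueError("no gene set overlaps the expression matrix")

    # descending rank statistic: position i (0-based) gets G - i
    rank_stat = (np.arange(G, dtype=float)[::-1] + 1.0) ** weight_exponent

    n_samples = vals.shape[1]
    out = np.empty((n_samples, len(membership)))
    set_names = list(membership)
    # deterministic ordering: decreasing value, gene id ascending as tiebreak
    gene_order_key = np.argsort(genes, kind="stable")
    for j in range(n_samples):
        col = vals[:, j]
        # sort by (-value, gene id): apply stable sort on -value over id-sorted genes
        order = gene_order_key[np.argsort(-col[gene_order_key], kind="stable")]
        for k, name in enumerate(set_names):
            in_set = membership[name][order]
            w = np.where(in_set, rank_stat, 0.0)
            cum_in = np.cumsum(w)
            total_in = cum_in[-1]
            n_out = G - in_set.sum()
            cum_out = np.cumsum(~in_set) / max(n_out, 1)
            out[j, k] = float(np.sum(cum_in / total_in - cum_out))
    if normalize:
        rng_ = out.max() - out.min()
        if rng_ > 0:
            out = out / rng_
    scores = pd.DataFrame(out, index=expr.sample_ids, columns=set_names)
    return PathwayScoreTable(scores, level="sample")


def derive_zone_modules(expr: ExpressionMatrix, top_k: int = 200,
                        fdr_cut: float = 0.05, lfc_cut: float = 1.0) -> GeneSetCollection:
    """Zone-specific gene modules from one-vs-rest differential expression.

    Per zone: per gene, a two-sided Wilcoxon rank-sum test of log2(FPKM+1)
    in-zone vs all other zones, BH-FDR across genes; genes retained when
    FDR < ``fdr_cut`` and |difference of mean log2(FPKM+1)| > ``lfc_cut``;
    ranked by ascending FDR (ties: descending |difference|, then gene id)
    and truncated at ``top_k``.
    """
    lexpr = log_transform(expr)
    vals = lexpr.values.to_numpy()
    zones = lexpr.samples["zone"].to_numpy()
    present = [z for z in pd.unique(zones)]
    if len(present) < 2:
        raise ValueError("need at least 2 zones")
    genes = np.array(lexpr.gene_ids)
    sets: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for z in present:
        in_z = zones == z
        if in_z.sum() < 2 or (~in_z).sum() < 2:
            log.warning("zone %s has <2 samples on one side; skipped", z)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(vals[:, in_z], vals[:, ~in_z], axis=1,
                                     alternative="two-sided", method="asymptotic")
        p = np.nan_to_num(res.pvalue, nan=1.0)
        fdr = bh_adjust(p).adjusted
        delta = vals[:, in_z].mean(axis=1) - vals[:, ~in_z].mean(axis=1)
        keep = (fdr < fdr_cut) & (np.abs(delta) > lfc_cut)
        if keep.sum() == 0:
            log.warning("zone %s: no differential genes pass the filters", z)
            continue
        idx = np.nonzero(keep)[0]
        order = sorted(idx, key=lambda i: (fdr[i], -abs(delta[i]), genes[i]))
        chosen = [genes[i] for i in order[:top_k]]
        if len(chosen) >= 2:
            name = f"IvyGAP_{z}_module"
            sets[name] = chosen
            cats[name] = "ivygap_module"
    return GeneSetCollection(sets, cats)


def jaccard_matrix(sets: GeneSetCollection) -> pd.DataFrame:
    """Pairwise Jaccard index |A∩B| / |A∪B| with unit diagonal."""
    names = sets.names()
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    J = np.eye(len(names))
    members = [set(sets.sets[n]) for n in names]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            inter = len(members[i] & members[j])
            union = len(members[i] | members[j])
            J[i, j] = J[j, i] = inter / union if union else 0.0
    return pd.DataFrame(J, index=names, columns=names)
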