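"""Pre-specified sensitivity variants as pure configuration deltas.

Each implemented variant re-runs the associational pipeline from zone
aggregation onward with exactly one lever moved:

S1a  ET restricted to the CT zone (microvascular-proliferation samples
     excluded from the enhancing-tumor score);
S1b  alternate mapping moving CTpan into ET;
S2   exclude patients contributing only one subcompartment;
S3   median instead of mean aggregation;
S4a  BH family restricted to the Hallmark sets (padded to their count);
S7   global instead of within-subcompartment feature standardization.

S6 (random slopes) and S8 (Kenward–Roger df) are declared but not
implemented here; S9 equals covariate model D of the ladder and is
aliased to it; S4b/S4c lack a subset definition and raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lmm import run_lmm_campaign
from .mapping import ZoneMap, aggregate_to_subcompartments
from .reduction import univariate_screen
from .scoring import PathwayScoreTable

IMPLEMENTED = ("S1a", "S1b", "S2", "S3", "S4a", "S7")
DECLARED_STUBS = {
    "S4b": "FDR-subset definition not specified; not implemented",
    "S4c": "FDR-subset definition not specified; not implemented",
    "S6": "random-slope models are out of scope (cannot be fitted at this design)",
    "S8": "Kenward–Roger denominator df is out of scope; LRT is the omnibus test",
    "S9": "alias of covariate ladder model D (radgex.lmm.covariate_ladder)",
}


@dataclass
class SensitivityVariant:
    id: str
    description: str
    zone_map_variant: str = "primary"
    aggregation: str = "mean"
    exclude_single_subcompartment: bool = False
    fdr_subset_category: str | None = None
    feature_standardization: str = "within_subcompartment"


def variant(variant_id: str) -> SensitivityVariant:
    table = {
        "S1a": SensitivityVariant("S1a", "ET = CT only (exclude CTmvp)",
                                  zone_map_variant="S1a"),
        "S1b": SensitivityVariant("S1b", "alternate mapping: CTpan -> ET",
                                  zone_map_variant="S1b"),
        "S2": SensitivityVariant("S2", "exclude single-subcompartment patients",
                                 exclude_single_subcompartment=True),
        "S3": SensitivityVariant("S3", "median aggregation", aggregation="median"),
        "S4a": SensitivityVariant("S4a", "Hallmark-only FDR re-correction",
                                  fdr_subset_category="hallmark"),
        "S7": SensitivityVariant("S7", "global feature standardization",
                                 feature_standardization="global"),
    }
    if variant_id in table:
        return table[variant_id]
    if variant_id in DECLARED_STUBS:
        raise NotImplementedError(f"{variant_id}: {DECLARED_STUBS[variant_id]}")
    raise ValueError(f"unknown sensitivity variant {variant_id!r}")


def run_variant(scores: PathwayScoreTable, samples: pd.DataFrame,
                features: pd.DataFrame, variant_id: str,
                set_categories: dict[str, str] | None = None,
                n_total_pathways: int = 24, fdr_cut: float = 0.10,
                cap: int = 5) -> pd.DataFrame:
    """Re-run aggregation → screening → LMM campaign under one variant."""
    v = variant(variant_id)
    zmap = ZoneMap.variant_map(v.zone_map_variant, v.aggregation)
    obs = aggregate_to_subcompartments(scores, samples, zmap)
    if v.exclude_single_subcompartment:
        counts = obs.groupby("patient_id")["subcompartment"].nunique()
        keep = counts[counts > 1].index
        obs = obs[obs["patient_id"].isin(keep)].reset_index(drop=True)
        features = features[features["patient_id"].isin(keep)].reset_index(drop=True)
    if obs.empty:
        raise RuntimeError(f"variant {variant_id}: no observations remain")

    set_names = [c for c in obs.columns if c not in ("patient_id", "subcompartment",
                                                     "composition")]
    fdr_subset = None
    n_total = n_total_pathways
    if v.fdr_subset_category is not None:
        if set_categories is None:
            raise ValueError("set_categories required for an FDR-subset variant")
        fdr_subset = [s for s in set_names
                      if set_categories.get(s) == v.fdr_subset_category]
        n_total = len(fdr_subset)
    screens = {s: univariate_screen(features, obs, s, "per_subcompartment", fdr_cut, cap)
               for s in set_names}
    out = run_lmm_campaign(obs, features, screens, n_total,
                           fdr_subset=fdr_subset,
                           feature_standardization=v.feature_standardization)
    out.insert(0, "variant", v.id)
    return out
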