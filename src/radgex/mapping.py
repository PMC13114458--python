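"""Anatomic-zone to MRI-subcompartment mapping and aggregation.

The primary map sends the cellular-tumor zones (CT, CTmvp) to enhancing
tumor (ET), pseudopalisading necrosis (CTpan) to non-enhancing tumor
(NET), and the infiltrative zones (IT, LE) to peritumoral edema (ED).
Zone-level pathway scores are aggregated per patient x subcompartment;
replicate samples within a zone are averaged first so patients with more
replicates do not dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import spearman_pair
from .scoring import PathwayScoreTable

log = logging.getLogger(__name__)

PRIMARY_MAP = {"CT": "ET", "CTmvp": "ET", "CTpan": "NET", "IT": "ED", "LE": "ED"}
#: S1a: enhancing tumor restricted to the cellular-tumor zone only
S1A_MAP = {"CT": "ET", "CTpan": "NET", "IT": "ED", "LE": "ED"}
#: S1b: shipped alternate map moving pseudopalisading necrosis into ET
S1B_MAP = {"CT": "ET", "CTmvp": "ET", "CTpan": "ET", "IT": "ED", "LE": "ED"}


@dataclass
class ZoneMap:
    mapping: dict = field(default_factory=lambda: dict(PRIMARY_MAP))
    aggregation: str = "mean"
    variant: str = "primary"

    def __post_init__(self) -> None:
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")
        if "ET" not in set(self.mapping.values()):
            raise ValueError("ET must receive at least one zone")

    @classmethod
    def variant_map(cls, variant: str, aggregation: str = "mean") -> "ZoneMap":
        maps = {"primary": PRIMARY_MAP, "S1a": S1A_MAP, "S1b": S1B_MAP}
        if variant not in maps:
            raise ValueError(f"unknown mapping variant {variant!r}")
        return cls(dict(maps[variant]), aggregation, variant)


def aggregate_to_subcompartments(scores: PathwayScoreTable, samples: pd.DataFrame,
                                 zone_map: ZoneMap | None = None) -> pd.DataFrame:
    """Aggregate sample-level pathway scores to patient x subcompartment rows.

    ``samples`` is the sample metadata (index sample_id, columns patient_id,
    zone).  Returns a long-format table with columns ``patient_id``,
    ``subcompartment``, ``composition`` (tuple of contributing zones) and one
    column per gene set.  Rows are emitted only for subcompartments with at
    least one contributing zone.
    """
    zone_map = zone_map or ZoneMap()
    df = scores.scores.join(samples[["patient_id", "zone"]])
    unmapped = sorted(set(df["zone"]) - set(zone_map.mapping))
    if unmapped:
        log.warning("dropping samples from unmapped zones: %s", unmapped)
        df = df[df["zone"].isin(zone_map.mapping)]
    if df.empty:
        raise RuntimeError("no mappable samples")
    set_cols = list(scores.scores.columns)
    # replicate samples within one zone are averaged first
    zone_level = df.groupby(["patient_id", "zone"], sort=True)[set_cols].mean().reset_index()
    zone_level["subcompartment"] = zone_level["zone"].map(zone_map.mapping)
    agg = np.mean if zone_map.aggregation == "mean" else np.median

    rows = []
    for (p, sub), grp in zone_level.groupby(["patient_id", "subcompartment"], sort=True):
        rec = {"patient_id": p, "subcompartment": sub,
               "composition": tuple(sorted(grp["zone"]))}
        for c in set_cols:
            rec[c] = float(agg(grp[c].to_numpy()))
        rows.append(rec)
    out = pd.DataFrame(rows)
    order = {"ET": 0, "NET": 1, "ED": 2}
    out = out.sort_values(["patient_id", "subcompartment"],
                          key=lambda s: s.map(order) if s.name == "subcompartment" else s)
    return out.reset_index(drop=True)


def composition_baseline_test(obs: pd.DataFrame, set_name: str,
                              subcompartment: str = "ET",
                              indicator=None) -> dict:
    """Spearman test of a pathway's patient score against a composition index.

    The default indicator is the number of distinct zones contributing to the
    patient's aggregated score in ``subcompartment`` (e.g. CT-only vs
    CT+CTmvp in ET); an alternative callable ``indicator(row) -> float`` can
    be supplied.  Returns a dict with ``rho``, ``p`` and ``n``; a constant
    indicator yields ``rho = None`` (not applicable).
    """
    sub = obs[obs["subcompartment"] == subcompartment]
    if len(sub) < 4:
        raise ValueError("need at least 4 patients")
    if indicator is None:
        ind = sub["composition"].map(len).to_numpy(dtype=float)
    else:
        ind = sub.apply(indicator, axis=1).to_numpy(dtype=float)
    y = sub[set_name].to_numpy(dtype=float)
    if np.unique(ind).size < 2 or np.unique(y).size < 2:
        return {"rho": None, "p": None, "n": len(sub), "applicable": False}
    rho, p = spearman_pair(ind, y)
    return {"rho": rho, "p": p, "n": len(sub), "applicable": True}
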