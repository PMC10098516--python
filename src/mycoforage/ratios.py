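"""Per-genus, per-cafeteria compositional log ratios.

Two contrasts summarise mycelial foraging for each genus in each cafeteria:

* bags vs roots — ``ln((mean abundance over all recovered bags + mu) /
  (abundance on roots + mu))``: how prolifically a genus grows away from the
  root into ingrowth bags;
* soil vs sand — ``ln((mean over soil bags + mu) / (mean over sand bags +
  mu))``: preference for soil substrates over inert sand.

``mu = 1 / (mean sequencing depth x 6)`` is the smallest expected relative
abundance, added to both numerator and denominator to avoid zeros.  A
cafeteria contributes a record for a genus only when the genus is present on
that cafeteria's roots; bags lost in the field are simply absent from the
means.  Natural logarithms are used throughout (the interpreted quantities —
sign and zero crossing — are base-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .synthdata import SAND_CLASSES, SOIL_CLASSES, Substrate

logger = logging.getLogger(__name__)

__all__ = [
    "MuParams",
    "compute_mu",
    "log_ratio_bags_vs_roots",
    "log_ratio_soil_vs_sand",
    "log_ratio_table",
]

BAGS_VS_ROOTS = "bags_vs_roots"
SOIL_VS_SAND = "soil_vs_sand"


@dataclass(frozen=True)
class MuParams:
    """The pseudocount mu and its ingredients."""

    mean_sequencing_depth: float
    n_substrates: int = 6

    @property
    def mu(self) -> float:
        return 1.0 / (self.mean_sequencing_depth * self.n_substrates)


def compute_mu(sample_depths, n_substrates: int = 6) -> MuParams:
    """mu from per-sample total read counts: 1 / (mean depth x substrates)."""
    depths = np.asarray(list(sample_depths), dtype=float)
    if depths.size == 0:
        raise ValueError("need at least one sample depth")
    if (depths <= 0).any():
        raise ValueError("sample depths must be positive")
    if n_substrates <= 0:
        raise ValueError("n_substrates must be positive")
    return MuParams(mean_sequencing_depth=float(depths.mean()), n_substrates=n_substrates)


def _cafeteria_slices(table: AbundanceTable, cafeteria: str):
    mask = table.meta["cafeteria"] == cafeteria
    data = table.data[mask]
    meta = table.meta[mask]
    root = data[meta["sample_type"] == "root"]
    bags = data[meta["sample_type"] != "root"]
    return root, bags, meta


def log_ratio_bags_vs_roots(
    table: AbundanceTable, genus: str, cafeteria: str, mu: float
) -> dict | None:
    """One bags-vs-roots record, or None when the inclusion rule excludes it.

    Excluded when the genus is absent on the cafeteria's roots, when there is
    no root sample, or when no recovered bag exists.
    """
    root, bags, meta = _cafeteria_slices(table, cafeteria)
    if root.empty:
        logger.info("cafeteria %s has no root sample; excluded", cafeteria)
        return None
    if bags.empty:
        logger.info("cafeteria %s has no recovered bags; excluded", cafeteria)
        return None
    root_ab = float(root[genus].iloc[0])
    if root_ab <= 0:
        return None
    bag_mean = float(bags[genus].mean())
    return {
        "genus": genus,
        "cafeteria": cafeteria,
        "site": meta["site"].iloc[0],
        "ratio_type": BAGS_VS_ROOTS,
        "numerator_mean": bag_mean,
        "denominator_value": root_ab,
        "log_ratio": float(np.log((bag_mean + mu) / (root_ab + mu))),
        "n_bags_used": int(len(bags)),
    }


def log_ratio_soil_vs_sand(
    table: AbundanceTable,
    genus: str,
    cafeteria: str,
    mu: float,
    substrates: list[Substrate],
) -> dict | None:
    """One soil-vs-sand record, or None when excluded.

    Soil bags are the four soil substrates, sand bags the sand and
    sand+apatite substrates; the same roots-presence inclusion rule applies,
    and cafeterias missing all soil bags or all sand bags are excluded.
    """
    root, bags, meta = _cafeteria_slices(table, cafeteria)
    if root.empty or float(root[genus].iloc[0]) <= 0:
        return None
    classes = {s.substrate_id: s.substrate_class for s in substrates}
    stypes = table.meta.loc[bags.index, "sample_type"].map(classes)
    soil = bags[stypes.isin(SOIL_CLASSES)]
    sand = bags[stypes.isin(SAND_CLASSES)]
    if soil.empty or sand.empty:
        logger.info(
            "cafeteria %s lacks recovered %s bags; excluded",
            cafeteria,
            "soil" if soil.empty else "sand",
        )
        return None
    soil_mean = float(soil[genus].mean())
    sand_mean = float(sand[genus].mean())
    return {
        "genus": genus,
        "cafeteria": cafeteria,
        "site": meta["site"].iloc[0],
        "ratio_type": SOIL_VS_SAND,
        "numerator_mean": soil_mean,
        "denominator_value": sand_mean,
        "log_ratio": float(np.log((soil_mean + mu) / (sand_mean + mu))),
        "n_bags_used": int(len(soil) + len(sand)),
    }


def log_ratio_table(
    table: AbundanceTable,
    genera: list[str],
    mu: float,
    substrates: list[Substrate],
) -> pd.DataFrame:
    """Long-format table of both log-ratio types for the selected genera.

    Columns: genus, cafeteria, site, ratio_type, numerator_mean,
    denominator_value, log_ratio, n_bags_used.  Only included
    genus x cafeteria combinations appear.
    """
    if table.mode != "rel_emf":
        raise ValueError("log ratios are defined on the rel_emf genus table")
    records = []
    for genus in genera:
        if genus not in table.data.columns:
            logger.warning("genus %s absent from table; skipped", genus)
            continue
        for caf in table.meta["cafeteria"].unique():
            rec = log_ratio_bags_vs_roots(table, genus, caf, mu)
            if rec is not None:
                records.append(rec)
            rec = log_ratio_soil_vs_sand(table, genus, caf, mu, substrates)
            if rec is not None:
                records.append(rec)
    cols = [
        "genus",
        "cafeteria",
        "site",
        "ratio_type",
        "numerator_mean",
        "denominator_value",
        "log_ratio",
        "n_bags_used",
    ]
    return pd.DataFrame(records, columns=cols)
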