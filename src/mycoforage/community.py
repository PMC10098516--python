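"""Community tables: relative abundance, background correction, EMF share.

The analysis works on a samples x taxa abundance matrix with per-sample
metadata (site, cafeteria, sample_type).  Counts are converted to relative
abundances of the total fungal community, the pre-incubation "background"
relative abundances of ectomycorrhizal species are subtracted per substrate
(clamped at zero), and the remaining ectomycorrhizal signal is renormalised
to its share of the ectomycorrhizal community and aggregated to genus level.
Genera enter the statistical analysis only if present on roots in at least
10 of the 50 cafeterias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "to_relative",
    "background_correct",
    "emf_share",
    "select_genera",
]

META_COLS = ("site", "cafeteria", "sample_type")


@dataclass
class AbundanceTable:
    """Samples x taxa matrix with aligned metadata.

    ``data`` is indexed by sample_id; ``meta`` shares that index and carries
    site, cafeteria and sample_type (a substrate id, or ``"root"``).
    ``mode`` is one of ``counts`` (nonnegative integers), ``rel_total``
    (shares of all reads) or ``rel_emf`` (shares of the ectomycorrhizal
    community, rows summing to 1 where any signal exists).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "rel_total", "rel_emf"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.data.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.data.index]
        missing = [c for c in META_COLS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if self.mode == "counts":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("counts must be nonnegative")

    # -- convenience -------------------------------------------------------
    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    def roots(self) -> "AbundanceTable":
        mask = self.meta["sample_type"] == "root"
        return AbundanceTable(self.data[mask], self.meta[mask], self.mode)

    def bags(self) -> "AbundanceTable":
        mask = self.meta["sample_type"] != "root"
        return AbundanceTable(self.data[mask], self.meta[mask], self.mode)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = pd.concat([self.meta[list(META_COLS)], self.data], axis=1)
        out.to_csv(path, sep="\t", index=True, index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, mode: str = "counts") -> "AbundanceTable":
        raw = pd.read_csv(path, sep="\t", index_col="sample_id")
        meta = raw[list(META_COLS)]
        data = raw.drop(columns=list(META_COLS))
        if mode == "counts":
            data = data.astype(np.int64)
        return cls(data=data, meta=meta, mode=mode)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Counts -> per-sample shares of total reads.

    Zero-depth samples cannot be normalised; they are dropped with a warning.
    """
    if table.mode != "counts":
        raise ValueError("to_relative expects a counts table")
    totals = table.data.sum(axis=1)
    zero = totals == 0
    if zero.any():
        for sid in table.data.index[zero]:
            logger.warning("dropping zero-depth sample %s", sid)
    data = table.data.loc[~zero].div(totals[~zero], axis=0)
    return AbundanceTable(data=data, meta=table.meta.loc[~zero], mode="rel_total")


def background_correct(
    table: AbundanceTable,
    background: pd.DataFrame,
    emf_taxa: list[str],
) -> AbundanceTable:
    """Subtract pre-incubation background from bag samples, clamped at zero.

    ``background`` is a substrates x taxa table of the relative abundances
    of ectomycorrhizal species in the non-incubated substrates (sands have
    zero rows).  Only ectomycorrhizal taxa in bag samples are corrected;
    root samples and non-ectomycorrhizal taxa pass through unchanged.
    """
    if table.mode != "rel_total":
        raise ValueError("background_correct expects a rel_total table")
    data = table.data.copy()
    emf_cols = [t for t in emf_taxa if t in data.columns]
    for sid in data.index:
        stype = table.meta.loc[sid, "sample_type"]
        if stype == "root":
            continue
        if stype not in background.index:
            raise KeyError(f"substrate {stype!r} missing from background table")
        bg = background.loc[stype].reindex(emf_cols).fillna(0.0)
        corrected = data.loc[sid, emf_cols] - bg
        data.loc[sid, emf_cols] = corrected.clip(lower=0.0)
    return AbundanceTable(data=data, meta=table.meta, mode="rel_total")


def emf_share(
    table: AbundanceTable,
    emf_taxa: list[str],
    genus_of: dict[str, str] | None = None,
) -> AbundanceTable:
    """Renormalise ectomycorrhizal taxa to their share of the EMF community
    and aggregate to genus level.

    Per sample, the (background-corrected) values of ectomycorrhizal taxa
    are rescaled to sum to 1 and summed within genus (``genus_of`` maps
    taxon -> genus; identity by default).  Samples with no ectomycorrhizal
    signal keep an all-zero row and are logged.
    """
    if table.mode != "rel_total":
        raise ValueError("emf_share expects a rel_total table")
    emf_cols = [t for t in emf_taxa if t in table.data.columns]
    if not emf_cols:
        raise ValueError("no annotated ectomycorrhizal taxa in table")
    emf = table.data[emf_cols]
    totals = emf.sum(axis=1)
    zero = totals == 0
    for sid in emf.index[zero]:
        logger.warning("sample %s has no ectomycorrhizal signal", sid)
    shares = emf.div(totals.where(~zero, 1.0), axis=0)
    shares.loc[zero, :] = 0.0
    genus_of = genus_of or {}
    genus = shares.T.groupby(lambda t: genus_of.get(t, t)).sum().T
    return AbundanceTable(data=genus, meta=table.meta, mode="rel_emf")


def select_genera(root_table: AbundanceTable, min_cafeterias: int = 10) -> list[str]:
    """Genera present on roots in at least ``min_cafeterias`` cafeterias.

    Presence means relative abundance > 0 in that cafeteria's root sample.
    """
    roots = root_table.roots() if (root_table.meta["sample_type"] != "root").any() else root_table
    if roots.data.empty:
        raise ValueError("no root samples in table")
    present = roots.data > 0
    by_caf = present.groupby(roots.meta["cafeteria"]).any()
    n_caf = by_caf.sum(axis=0)
    return sorted(n_caf.index[n_caf >= min_cafeterias])
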