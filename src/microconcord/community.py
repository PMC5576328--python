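"""Transformations of count tables: relative abundance, abundance filters,
genus-level collapsing and rarefaction.

Filter conventions: both the rare-OTU filter (default 0.005% of all
sequences) and the dominance filter (default 1%) compare an OTU's total
count against a fraction of the table grand total and retain the OTU when
the total is greater than *or equal to* the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import CountTable, TaxaTable, TaxonomyMap, RANK_PREFIXES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample fractional abundances on the same axes as a CountTable.

    Columns sum to 1 except for empty samples, which stay all-zero and are
    listed in ``zero_samples``.
    """

    data: pd.DataFrame
    zero_samples: tuple[str, ...] = ()

    @property
    def percent(self) -> pd.DataFrame:
        """The same table scaled to percent (columns sum to 100)."""
        return self.data * 100.0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def to_relative(table: CountTable | TaxaTable) -> RelAbundanceTable:
    """Normalize each sample column to fractions summing to 1."""
    df = table.data.astype(float)
    totals = df.sum(axis=0)
    zero = tuple(totals.index[totals == 0])
    if zero:
        logger.warning("to_relative: empty sample columns: %s", list(zero))
    safe = totals.replace(0, 1.0)
    return RelAbundanceTable(df.div(safe, axis=1), zero_samples=zero)


def _filter_by_fraction(
    table: CountTable, min_fraction: float, label: str
) -> CountTable:
    if not 0 <= min_fraction < 1:
        raise ParameterError(f"{label}: min_fraction must be in [0, 1)")
    if min_fraction == 0:
        return table
    totals = table.data.sum(axis=1)
    cut = min_fraction * float(totals.sum())
    keep = totals >= cut
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "%s: removed %d/%d OTUs below %.6g of the grand total",
            label, removed, len(keep), min_fraction,
        )
    if not keep.any():
        logger.warning("%s: no OTUs pass the %.6g cut", label, min_fraction)
    return CountTable(table.data.loc[keep])


def filter_rare(table: CountTable, min_fraction: float = 5e-5) -> CountTable:
    """Drop OTUs holding less than ``min_fraction`` of all sequences.

    The 0.005% default mirrors the standard QIIME-era guideline for
    open-reference OTU tables.
    """
    return _filter_by_fraction(table, min_fraction, "filter_rare")


def filter_dominant(table: CountTable, min_fraction: float = 0.01) -> CountTable:
    """Keep only dominating OTUs (>= ``min_fraction`` of all sequences)."""
    return _filter_by_fraction(table, min_fraction, "filter_dominant")


def collapse_taxonomy(
    table: CountTable, tax: TaxonomyMap, level: int = 6
) -> TaxaTable:
    """Sum OTU counts sharing the lineage prefix through ``level`` ranks.

    ``level`` follows the GreenGenes convention (6 = genus). OTUs without a
    taxonomy entry are pooled under ``Unassigned``. Per-sample totals are
    conserved exactly.
    """
    if not 1 <= level <= 7:
        raise ParameterError("level must be in 1..7")
    labels = []
    for otu in table.otu_ids:
        lineage = tax.lineage(otu)
        if lineage is None:
            labels.append("Unassigned")
            continue
        padded = list(lineage[:level])
        while len(padded) < level:
            padded.append(f"{RANK_PREFIXES[len(padded)]}_")
        labels.append(";".join(padded))
    grouped = table.data.groupby(pd.Index(labels, name="taxon"), sort=False).sum()
    return TaxaTable(grouped)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample column to exactly ``depth`` sequences without
    replacement (multivariate hypergeometric draw).

    Samples shallower than ``depth`` are dropped (logged); a sample at
    exactly ``depth`` is returned unchanged. The draw is deterministic for a
    given seed.
    """
    if depth <= 0:
        raise ParameterError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=0)
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        logger.info(
            "rarefy: dropping %d samples shallower than %d: %s",
            len(dropped), depth, dropped,
        )
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    if not kept:
        raise ParameterError(
            f"rarefy: every sample is shallower than depth {depth}"
        )
    out = {}
    for s in kept:
        col = table.column(s)
        if totals[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.otu_ids, columns=kept)
    return CountTable(df)
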