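"""Hypergeometric gene-set enrichment with Benjamini correction.

Produces DAVID-style chart records: for a query gene set and each annotation
category, the one-sided hypergeometric tail p = P(X >= k) with
X ~ Hypergeometric(N, K, n) where N is the background size, K the category
size within the background, n the query size and k the hits.  The
``benjamini`` column is the BH adjustment over exactly the tested terms.
The classical tail is the default; ``ease=True`` computes the tail with one
hit discounted (the EASE convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene categories plus a background universe."""

    categories: dict[str, set]
    background: set

    def __post_init__(self) -> None:
        if not self.background:
            raise InputError("background universe is empty")
        self.categories = {name: set(genes) for name, genes in
                           self.categories.items()}
        self.background = set(self.background)

    def restricted(self, background: set) -> "GeneSetCollection":
        """Same categories over a new background universe."""
        return GeneSetCollection(categories=self.categories,
                                 background=set(background))

    # -- GMT serialization ---------------------------------------------------
    @classmethod
    def from_gmt(cls, path, background: set | None = None) -> "GeneSetCollection":
        """Read categories from GMT (name, description, members per line).

        Unless given, the background is the union of all category members.
        """
        categories: dict[str, set] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise InputError(f"malformed GMT line: {line[:60]!r}")
                categories[fields[0]] = set(fields[2:])
        if background is None:
            background = set().union(*categories.values()) if categories else set()
        return cls(categories=categories, background=background)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.categories):
                members = "\t".join(sorted(self.categories[name]))
                fh.write(f"{name}\tna\t{members}\n")


def enrich(
    query,
    collection: GeneSetCollection,
    min_category: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """Chart of enrichment records, sorted by ascending p (term-name tiebreak).

    Query genes outside the background are dropped with a logged count.
    Categories with fewer than ``min_category`` members in the background
    are not tested.
    """
    query = set(query)
    bg = collection.background
    dropped = len(query - bg)
    if dropped:
        logger.info("%d query genes outside the background were dropped", dropped)
    query &= bg
    if not query:
        raise InputError("query is empty after intersection with background")

    N, n = len(bg), len(query)
    records = []
    for term in sorted(collection.categories):
        cat = collection.categories[term] & bg
        K = len(cat)
        if K < min_category:
            continue
        k = len(query & cat)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        records.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                        "p_value": min(p, 1.0)})
    if not records:
        raise InputError("no category passes the min_category filter")

    chart = pd.DataFrame.from_records(records)
    from .diffexp import bh_adjust

    chart["benjamini"] = bh_adjust(chart["p_value"].to_numpy())
    chart = chart.sort_values(["p_value", "term"], kind="mergesort")
    return chart.reset_index(drop=True)
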