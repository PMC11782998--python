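"""Over-representation analysis and cross-tissue overlap counting.

Enrichment of a differentially-expressed (query) set against named gene
sets uses the upper-tail hypergeometric test on a user-supplied universe
(by default, every protein quantified in the experiment — a
detection-matched background).  "% members" is the share of the query
found in a term, the statistic dot plots are usually sized by.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de_pipeline import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named identifier sets over a common universe.

    Sets are intersected with the universe on construction; set names
    must be unique (guaranteed by the dict container).
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_mapping(
        cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]
    ) -> "GeneSetCollection":
        uni = frozenset(universe)
        if not uni:
            raise ValueError("empty universe")
        harmonised = {
            name: frozenset(members) & uni for name, members in sets.items()
        }
        return cls(sets=harmonised, universe=uni)


def read_gmt(path_or_lines) -> dict[str, set[str]]:
    """Parse GMT (one set per line: name, description, members...)."""
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    sets: dict[str, set[str]] = {}
    for line in lines:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = {m for m in parts[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_hypergeometric(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against each
    gene set, BH-adjusted across sets and sorted by adjusted p.

    Query identifiers outside the universe are dropped (with a logged
    count).  Each row reports the overlap ``k``, set size ``K``, query
    size ``n``, universe size ``N``, the upper-tail p-value, its BH
    adjustment, and % members.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    query = set(query)
    dropped = query - collection.universe
    if dropped:
        logger.info(
            "ora_hypergeometric: %d query ids outside the universe dropped",
            len(dropped),
        )
    query &= collection.universe
    N, n = len(collection.universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        p = hypergeom_upper_tail(k, N, K, n) if n else 1.0
        rows.append(
            {
                "term": name,
                "k": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": p,
                "percent_members": 100.0 * k / n if n else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["adj_p", "p_value", "term"]).reset_index(drop=True)
    return out


def percent_members(query: Iterable[str], term_set: Iterable[str]) -> float:
    """Percentage of the query (dysregulated) set found in a term."""
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    return 100.0 * len(query & set(term_set)) / len(query)


def cross_tissue_overlap(
    de_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count, per protein, the tissues in which it is differentially
    expressed, with ≥k summaries.

    Returns a per-protein membership table (one boolean column per
    tissue plus ``n_tissues``) and a summary dict with the union size and
    the number of proteins DE in at least 2, 3 and 4 tissues.
    """
    if len(de_sets) < 2:
        raise ValueError("need >= 2 tissue sets")
    sets = {name: set(v) for name, v in de_sets.items()}
    union = sorted(set().union(*sets.values()))
    table = pd.DataFrame(
        {name: [p in s for p in union] for name, s in sets.items()},
        index=pd.Index(union, name="accession"),
    )
    table["n_tissues"] = table.sum(axis=1).astype(int)
    summary = {
        "union": len(union),
        "ge2": int((table["n_tissues"] >= 2).sum()),
        "ge3": int((table["n_tissues"] >= 3).sum()),
        "ge4": int((table["n_tissues"] >= 4).sum()),
    }
    return table, summary
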