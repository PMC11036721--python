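"""Hypergeometric over-representation analysis against user-supplied gene sets.

For a query of n genes drawn from a universe of N, and a set containing K
universe genes of which k overlap the query, the enrichment p-value is the
hypergeometric upper tail P(X >= k). Significance is raw p < alpha by
default (Benjamini-Hochberg adjusted values are reported alongside).
Gene-set collections come from GMT files or plain dicts; pattern-wise gene
groups feed the same test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to an explicit universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        self.universe = frozenset(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            restricted[name] = frozenset(members) & self.universe
        self.sets = restricted

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None) -> "GeneSetCollection":
        """Read a GMT file (set name, description, member genes per line)."""
        sets: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3 or not fields[0]:
                    continue
                if fields[0] in sets:
                    raise ValueError(f"duplicate set name {fields[0]!r}")
                sets[fields[0]] = frozenset(g for g in fields[2:] if g)
        if universe is None:
            universe = frozenset().union(*sets.values()) if sets else frozenset()
        return cls(sets=sets, universe=frozenset(universe))


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of *query* in each set of *collection*.

    Query genes outside the universe are dropped with a warning. Returns one
    row per set: overlap k, set size K, query size n, universe size N,
    hypergeometric upper-tail p, BH-adjusted p, and the raw-p significance
    flag (p < alpha).
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    outside = query_set - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped: "
            f"{sorted(outside)[:5]}",
            stacklevel=2,
        )
        query_set &= collection.universe
    if not query_set:
        raise ValueError("no query gene lies in the universe")

    big_n = len(collection.universe)
    n = len(query_set)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        big_k = len(members)
        k = len(members & query_set)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append([name, k, big_k, n, big_n, min(p, 1.0)])
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p_value"]
    )
    from txdyn.de import bh_adjust

    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    table["significant"] = table["p_value"] < alpha
    return table


def group_by_pattern(traj: pd.Series, min_genes: int = 3) -> tuple[dict[str, list[str]], list[str]]:
    """Group genes by identical trajectory pattern for pattern-wise enrichment.

    Groups with at least *min_genes* members are returned; smaller patterns
    are listed as skipped (reliable enrichment needs a minimum group size).
    """
    groups: dict[str, list[str]] = {}
    for gene, pattern in traj.items():
        groups.setdefault(pattern, []).append(str(gene))
    emitted = {p: sorted(g) for p, g in groups.items() if len(g) >= min_genes}
    skipped = sorted(p for p, g in groups.items() if len(g) < min_genes)
    return emitted, skipped
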