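"""U/D/M trajectory patterns and pattern-space statistics.

Each gene's dynamics over k adjacent intervals is the concatenation of its
per-interval DE statuses — a string over {U, D, M} of length k. With three
states per interval the pattern space holds 3^k strings (6,561 for the
nine-timepoint, k = 8 design); the coverage statistic reports what fraction
of that space a cohort actually realizes. Frequency tables rank observed
patterns by count, with percentages rounded half-up to two decimals as in
printed tables.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Optional

import pandas as pd

from txdyn._utils import round_half_up, validate_pattern


def encode_trajectories(records: pd.DataFrame, rna_class: Optional[str] = None) -> pd.Series:
    """Concatenate per-interval statuses into one pattern string per gene.

    *records* is the DE result frame (columns gene, interval, status, ...)
    with intervals in chronological order of first appearance. Every gene
    must have exactly one record per interval.
    """
    intervals = list(dict.fromkeys(records["interval"]))
    pivot = records.pivot_table(
        index="gene", columns="interval", values="status", aggfunc="first", sort=False
    )
    dup = records.duplicated(subset=["gene", "interval"])
    if dup.any():
        bad = records.loc[dup, ["gene", "interval"]].iloc[0]
        raise ValueError(f"duplicate record for gene {bad['gene']!r} interval {bad['interval']!r}")
    missing = pivot.isna()
    if missing.to_numpy().any():
        gene = missing.index[missing.any(axis=1)][0]
        interval = missing.columns[missing.loc[gene]][0]
        raise ValueError(f"gene {gene!r} is missing interval {interval!r}")
    patterns = pivot[intervals].agg("".join, axis=1)
    patterns.name = "pattern"
    patterns.attrs["rna_class"] = rna_class
    patterns.attrs["k"] = len(intervals)
    return patterns


def pattern_frequency_from_counts(counts: Mapping[str, int]) -> pd.DataFrame:
    """Ranked frequency table from {pattern: gene count}.

    Percentage = 100 * count / total, half-up to 2 decimals. Rank is by
    descending count with lexicographic tie-break on the pattern string.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty pattern counts")
    k = len(next(iter(counts)))
    for pattern in counts:
        validate_pattern(pattern, k)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["pattern", "count"])
    table["percentage"] = [round_half_up(100.0 * c / total, 2) for c in table["count"]]
    table.insert(0, "rank", range(1, len(table) + 1))
    return table


def pattern_frequency(traj: pd.Series) -> pd.DataFrame:
    """Ranked frequency table of a gene -> pattern series."""
    if traj.empty:
        raise ValueError("empty trajectory table")
    return pattern_frequency_from_counts(Counter(traj))


def pattern_space_coverage(n_unique: int, k: int) -> dict[str, float]:
    """How much of the 3^k pattern space a cohort realizes.

    Returns n_unique, space_size = 3^k and coverage_pct = 100 * n_unique /
    3^k rounded half-up to 2 decimals. The unique-pattern count includes the
    all-M pattern.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    space = 3**k
    if not 0 <= n_unique <= space:
        raise ValueError(f"n_unique = {n_unique} outside [0, 3^{k} = {space}]; corrupt input")
    return {
        "n_unique": n_unique,
        "space_size": space,
        "coverage_pct": round_half_up(100.0 * n_unique / space, 2),
    }


def coverage_of(traj: pd.Series, k: Optional[int] = None) -> dict[str, float]:
    """pattern_space_coverage evaluated on an encoded trajectory table."""
    if k is None:
        if traj.empty:
            raise ValueError("cannot infer k from an empty table")
        k = len(traj.iloc[0])
    return pattern_space_coverage(int(traj.nunique()), k)


def nonstationary_summary(traj: pd.Series) -> pd.DataFrame:
    """Per-interval-position tallies of U and D transitions.

    Row i (1-based position) counts genes whose pattern has U (resp. D) at
    that interval; the 'any_change' column marks genes with pattern != all-M
    only via the total row. Tallies are consistent with pattern_frequency by
    construction.
    """
    if traj.empty:
        return pd.DataFrame(columns=["position", "U", "D"]).set_index("position")
    k = len(traj.iloc[0])
    rows = []
    for pos in range(k):
        u = int(sum(1 for p in traj if p[pos] == "U"))
        d = int(sum(1 for p in traj if p[pos] == "D"))
        rows.append([pos + 1, u, d])
    table = pd.DataFrame(rows, columns=["position", "U", "D"]).set_index("position")
    table.attrs["n_nonstationary"] = int(sum(1 for p in traj if set(p) != {"M"}))
    return table
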