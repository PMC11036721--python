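"""ceRNA network assembly by joining miRNA-target pairs on shared miRNAs.

Under the competing-endogenous-RNA hypothesis, a lncRNA or circRNA that
shares miRNA-binding with an mRNA can sponge that miRNA. The pipeline keeps
only pairs whose molecule and miRNA are both differential on the interval of
interest, joins the sponge-class table with the miRNA-mRNA table on the
miRNA to emit (sponge, miRNA, mRNA) triples, and joins lncRNA- and
circRNA-triples on the miRNA again for circRNA-miRNA-lncRNA-mRNA records.
A molecule-miRNA link is one network edge regardless of how many triples
traverse it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

PAIR_COLUMNS = ["source_id", "mirna_id", "score"]


def _normalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    if {"source_id", "mirna_id"} <= set(pairs.columns):
        out = pairs.copy()
    else:
        out = pairs.iloc[:, : min(3, pairs.shape[1])].copy()
        out.columns = PAIR_COLUMNS[: out.shape[1]]
    if "score" not in out.columns:
        out["score"] = float("nan")
    return out[PAIR_COLUMNS]


def filter_differential(
    pairs: pd.DataFrame,
    de_records: pd.DataFrame,
    interval: Optional[str] = None,
    min_score: Optional[float] = None,
) -> pd.DataFrame:
    """Keep pairs whose molecule AND miRNA are differential on the interval.

    *de_records* is the DE frame (gene, interval, status, ...) covering every
    RNA class; molecules absent from it are treated as non-differential.
    Directions (U/D) of both endpoints are annotated. min_score optionally
    drops pairs below a prediction-score threshold.
    """
    table = _normalize_pairs(pairs)
    if min_score is not None:
        table = table[table["score"] >= min_score]
    if de_records.empty:
        status = pd.Series(dtype=object)
    else:
        de = de_records if interval is None else de_records[de_records["interval"] == interval]
        status = de.set_index("gene")["status"]
        status = status[~status.index.duplicated()]
    mol = table["source_id"].map(status).fillna("M")
    mir = table["mirna_id"].map(status).fillna("M")
    keep = (mol != "M") & (mir != "M")
    out = table[keep].copy()
    out["source_direction"] = mol[keep].map({"U": "up", "D": "down"})
    out["mirna_direction"] = mir[keep].map({"U": "up", "D": "down"})
    return out.reset_index(drop=True)


def join_triples(mol_pairs: pd.DataFrame, mrna_pairs: pd.DataFrame) -> pd.DataFrame:
    """(sponge, miRNA, mRNA) triples for every shared miRNA.

    A triple (x, m, g) is emitted iff (x, m) appears in the sponge-class
    table and (g, m) in the miRNA-mRNA table; triples are deduplicated and
    sorted for deterministic output.
    """
    left = _normalize_pairs(mol_pairs)[["source_id", "mirna_id"]].drop_duplicates()
    right = _normalize_pairs(mrna_pairs)[["source_id", "mirna_id"]].drop_duplicates()
    right = right.rename(columns={"source_id": "mrna_id"})
    merged = left.merge(right, on="mirna_id")
    merged = merged[["source_id", "mirna_id", "mrna_id"]].drop_duplicates()
    return merged.sort_values(list(merged.columns)).reset_index(drop=True)


def join_quadruples(lnc_triples: pd.DataFrame, circ_triples: pd.DataFrame) -> pd.DataFrame:
    """circRNA-miRNA-lncRNA-mRNA records joined on the shared miRNA.

    For each miRNA m, every circRNA sponging m is combined with every
    (lncRNA, m, mRNA) triple; records are deduplicated.
    """
    circs = circ_triples[["source_id", "mirna_id"]].drop_duplicates()
    circs = circs.rename(columns={"source_id": "circ_id"})
    lncs = lnc_triples.rename(columns={"source_id": "lnc_id"})
    merged = circs.merge(lncs, on="mirna_id")
    merged = merged[["circ_id", "mirna_id", "lnc_id", "mrna_id"]].drop_duplicates()
    return merged.sort_values(list(merged.columns)).reset_index(drop=True)


@dataclass
class CeRNANetwork:
    """Typed molecule-miRNA network assembled from triple tables."""

    nodes: pd.DataFrame  # columns: id, node_class, direction
    edges: pd.DataFrame  # columns: source_id, mirna_id
    triples: pd.DataFrame
    quadruples: Optional[pd.DataFrame] = None


def assemble_network(
    triples_by_class: dict[str, pd.DataFrame],
    directions: Optional[pd.Series] = None,
    quadruples: Optional[pd.DataFrame] = None,
) -> CeRNANetwork:
    """Build the node/edge tables from per-class triple frames.

    triples_by_class maps a sponge class ('lncRNA' or 'circRNA') to its
    triple frame; mRNA and miRNA nodes are collected from the triples.
    *directions* optionally maps molecule id -> 'up'/'down'.
    """
    node_rows: list[tuple[str, str]] = []
    edge_rows: list[tuple[str, str]] = []
    all_triples = []
    for cls, triples in triples_by_class.items():
        for _, row in triples.iterrows():
            node_rows.append((row["source_id"], cls))
            node_rows.append((row["mirna_id"], "miRNA"))
            node_rows.append((row["mrna_id"], "mRNA"))
            edge_rows.append((row["source_id"], row["mirna_id"]))
            edge_rows.append((row["mrna_id"], row["mirna_id"]))
        tagged = triples.copy()
        tagged.insert(0, "sponge_class", cls)
        all_triples.append(tagged)
    nodes = pd.DataFrame(node_rows, columns=["id", "node_class"]).drop_duplicates()
    nodes = nodes.sort_values(["node_class", "id"]).reset_index(drop=True)
    if directions is not None:
        nodes["direction"] = nodes["id"].map(directions)
    edges = (
        pd.DataFrame(edge_rows, columns=["source_id", "mirna_id"])
        .drop_duplicates()
        .sort_values(["mirna_id", "source_id"])
        .reset_index(drop=True)
    )
    triples = (
        pd.concat(all_triples, ignore_index=True)
        if all_triples
        else pd.DataFrame(columns=["sponge_class", "source_id", "mirna_id", "mrna_id"])
    )
    return CeRNANetwork(nodes=nodes, edges=edges, triples=triples, quadruples=quadruples)


def network_stats(net: CeRNANetwork) -> dict[str, int]:
    """Node counts by class (and direction when present), edge and triple counts.

    Each distinct molecule-miRNA link counts once; in a single-miRNA star
    the edge count therefore equals the total number of non-miRNA molecules.
    """
    stats: dict[str, int] = {}
    for cls, grp in net.nodes.groupby("node_class"):
        stats[f"n_{cls}"] = len(grp)
        if "direction" in net.nodes.columns:
            for direction, sub in grp.dropna(subset=["direction"]).groupby("direction"):
                stats[f"n_{cls}_{direction}"] = len(sub)
    stats["n_nodes"] = len(net.nodes)
    stats["n_edges"] = len(net.edges)
    stats["n_triples"] = len(net.triples)
    if net.quadruples is not None:
        stats["n_quadruples"] = len(net.quadruples)
    return stats
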