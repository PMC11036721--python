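"""Plain-text readers and writers for the pipeline's tabular formats.

Count tables are TSV with genes in rows and chronologically ordered sample
columns; gene lengths a 2-column TSV; pair tables 3-column TSV (source_id,
mirna_id, score); interaction graphs 3-column TSV (node1, node2,
combined_score). Normalized matrices carry a '# unit=' comment header.
SIF export follows the Cytoscape simple-interaction format.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import pandas as pd

from txdyn.containers import CountMatrix, NormalizedMatrix


def read_counts(
    path, lengths_path=None, rna_class: Optional[str] = None
) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    lengths = read_lengths(lengths_path) if lengths_path else None
    return CountMatrix(counts, lengths=lengths, rna_class=rna_class)


def write_counts(counts: CountMatrix, path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene")


def read_lengths(path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].to_dict()


def write_lengths(lengths: Mapping[str, float], path) -> None:
    pd.Series(lengths, name="length_bp").to_csv(path, sep="\t", index_label="gene")


def write_normalized(norm: NormalizedMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit={norm.unit}\n")
        norm.values.to_csv(fh, sep="\t", index_label="gene")


def read_normalized(path) -> NormalizedMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        unit = header.split("=", 1)[1] if header.startswith("# unit=") else "CPM"
        values = pd.read_csv(fh, sep="\t", index_col=0)
    return NormalizedMatrix(values, unit=unit)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    """STRING-like edge table; malformed rows are reported with line numbers."""
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed edge table {path}: {err}") from err


def write_edges(g: nx.Graph, path) -> None:
    rows = [
        (a, b, data.get("combined_score", 1.0))
        for a, b, data in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def write_sif(edges, path, interaction: str = "pp") -> None:
    """Cytoscape SIF: 'source interaction target' per line."""
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_de(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_de(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trajectories(traj: pd.Series, path) -> None:
    traj.rename("pattern").to_csv(path, sep="\t", index_label="gene")


def read_trajectories(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["pattern"]
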