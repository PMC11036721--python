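"""Synthetic data with planted ground truth.

Emulates the study design this toolkit targets: ordered timepoints (default
nine), one pooled library per timepoint, four RNA classes. Counts are
negative-binomial via a gamma-Poisson mixture with DESeq-style dispersion
(variance = mu + alpha * mu^2); expression dynamics are planted as U/D/M
strings whose U (D) steps multiply (divide) the mean by a fold step from that
timepoint onward. Interaction graphs are planted-partition graphs; miRNA
target tables plant shared-miRNA ceRNA triples.

All randomness flows from an explicit integer seed; nothing reads numpy's
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from txdyn._utils import validate_pattern
from txdyn.containers import CountMatrix


@dataclass
class SimConfig:
    """Configuration for count simulation.

    Parameters
    ----------
    n_timepoints
        Number of ordered samples (one pooled library each).
    pattern_assignments
        Mapping gene id -> U/D/M string of length n_timepoints - 1. Genes
        absent from the map are not simulated.
    baseline_log_mean, baseline_log_sd
        Gene baseline means are log-normal: exp(N(baseline_log_mean,
        baseline_log_sd)). Ignored for genes with an entry in baseline_means.
    baseline_means
        Optional explicit per-gene baseline mean, overriding the log-normal
        draw (useful for power studies at fixed mu).
    dispersion
        NB overdispersion alpha >= 0; variance = mu + alpha mu^2. Zero gives
        Poisson counts.
    fold_step
        Multiplier (> 1) applied to the mean at each U transition and divided
        at each D transition, cumulatively for all later timepoints.
    library_size_factors
        Per-sample scaling of every gene's mean; defaults to all ones.
    n_replicates
        Libraries per timepoint; the study design is 1 (pooled), >1 enables
        power studies. Replicate columns are suffixed ".1", ".2", ...
    seed
        Seed for the dedicated generator.
    """

    n_timepoints: int = 9
    pattern_assignments: Mapping[str, str] = field(default_factory=dict)
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    baseline_means: Optional[Mapping[str, float]] = None
    dispersion: float = 0.05
    fold_step: float = 2.0
    library_size_factors: Optional[Sequence[float]] = None
    n_replicates: int = 1
    rna_class: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.fold_step > 1:
            raise ValueError("fold_step must be > 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        k = self.n_timepoints - 1
        for gene, pattern in self.pattern_assignments.items():
            validate_pattern(pattern, k, name=f"gene {gene!r}")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if len(sf) != self.n_timepoints:
                raise ValueError(
                    f"library_size_factors has {len(sf)} entries for {self.n_timepoints} timepoints"
                )
            if (sf <= 0).any():
                raise ValueError("all size factors must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth recorded by the simulators."""

    patterns: Optional[Mapping[str, str]] = None
    baseline_means: Optional[Mapping[str, float]] = None
    mean_matrix: Optional[pd.DataFrame] = None
    module_membership: Optional[Mapping[str, int]] = None
    triples: Optional[list[tuple[str, str, str]]] = None


def _fold_profile(pattern: str, fold_step: float) -> np.ndarray:
    """Cumulative fold multiplier at each timepoint for a U/D/M string."""
    mult = np.ones(len(pattern) + 1)
    level = 1.0
    for i, ch in enumerate(pattern):
        if ch == "U":
            level *= fold_step
        elif ch == "D":
            level /= fold_step
        mult[i + 1] = level
    return mult


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw an integer count matrix with planted U/D/M dynamics.

    Gene g at timepoint t has expected count sf_t * mu_g * prod of planted
    fold multipliers up to t. Counts are NB (gamma-Poisson): with dispersion
    alpha > 0 a gamma multiplier of shape 1/alpha and mean 1 scales the
    Poisson rate; alpha = 0 gives exact Poisson. Deterministic under a fixed
    seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.pattern_assignments)
    if not genes:
        raise ValueError("pattern_assignments is empty: nothing to simulate")

    sf = (
        np.ones(config.n_timepoints)
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )

    baselines: dict[str, float] = {}
    for gene in genes:
        if config.baseline_means is not None and gene in config.baseline_means:
            baselines[gene] = float(config.baseline_means[gene])
        else:
            baselines[gene] = float(
                np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
            )

    means = np.empty((len(genes), config.n_timepoints))
    for i, gene in enumerate(genes):
        profile = _fold_profile(config.pattern_assignments[gene], config.fold_step)
        means[i] = baselines[gene] * profile * sf

    timepoints = [f"{w}w" for w in range(3, 3 + config.n_timepoints)]
    if config.n_replicates == 1:
        columns = timepoints
        mu = means
    else:
        columns = [f"{tp}.{r}" for tp in timepoints for r in range(1, config.n_replicates + 1)]
        mu = np.repeat(means, config.n_replicates, axis=1)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        rate = rng.gamma(shape, scale=1.0 / shape, size=mu.shape) * mu
        counts = rng.poisson(rate)

    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=columns)
    truth = SimTruth(
        patterns=dict(config.pattern_assignments),
        baseline_means=baselines,
        mean_matrix=pd.DataFrame(mu, index=frame.index, columns=columns),
    )
    return CountMatrix(frame, rna_class=config.rna_class), truth


def simulate_ppi(
    n_nodes: int,
    module_sizes: Sequence[int],
    intra_p: float,
    inter_p: float,
    score_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
) -> tuple["nx.Graph", SimTruth]:
    """Planted-partition interaction graph with uniform edge scores.

    Nodes inside a planted module are wired with probability intra_p, all
    other pairs with inter_p. Each realized edge receives a combined score
    drawn uniformly from score_range. Truth records the module id of every
    planted node (background nodes are absent from the map).
    """
    import networkx as nx

    if not 0 <= inter_p < intra_p <= 1:
        raise ValueError("need 0 <= inter_p < intra_p <= 1")
    if sum(module_sizes) > n_nodes:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)} but only {n_nodes} nodes available"
        )
    lo, hi = score_range
    if not 0 <= lo <= hi <= 1:
        raise ValueError("score_range must satisfy 0 <= lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    width = len(str(max(n_nodes - 1, 1)))
    nodes = [f"g{i:0{width}d}" for i in range(n_nodes)]
    membership: dict[str, int] = {}
    cursor = 0
    for mid, size in enumerate(module_sizes):
        for node in nodes[cursor : cursor + size]:
            membership[node] = mid
        cursor += size

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            a, b = nodes[i], nodes[j]
            same = membership.get(a) is not None and membership.get(a) == membership.get(b)
            p = intra_p if same else inter_p
            if rng.random() < p:
                g.add_edge(a, b, combined_score=float(rng.uniform(lo, hi)))
    return g, SimTruth(module_membership=membership)


def simulate_pairs(
    n_mirna: int,
    n_targets: Mapping[str, int],
    sharing_rate: float,
    seed: int = 0,
    score_range: tuple[float, float] = (120.0, 200.0),
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """miRNA-target pair tables with planted shared-miRNA ceRNA triples.

    Emits one table per non-miRNA class in n_targets (keys from mRNA, lncRNA,
    circRNA; values are target counts). Every mRNA is paired to one miRNA.
    Each lncRNA/circRNA target is, with probability sharing_rate, paired to a
    miRNA that also targets at least one mRNA — creating a planted
    (sponge, miRNA, mRNA) triple for each mRNA of that miRNA — and otherwise
    to a miRNA with no mRNA targets (no triple). Truth lists all planted
    triples.
    """
    if not 0 <= sharing_rate <= 1:
        raise ValueError("sharing_rate must be in [0, 1]")
    classes = set(n_targets) - {"mRNA"}
    unknown = classes - {"lncRNA", "circRNA"}
    if unknown:
        raise ValueError(f"unknown target classes: {sorted(unknown)}")
    if n_mirna < 1:
        raise ValueError("need at least one miRNA")

    rng = np.random.default_rng(seed)
    lo, hi = score_range
    mirnas = [f"miR-{i}" for i in range(n_mirna)]
    # Reserve a miRNA pool with mRNA targets and (if possible) one without,
    # so sharing_rate = 0 can be honoured exactly.
    n_shared_pool = n_mirna if sharing_rate == 1 else max(n_mirna - 1, 1)
    shared_pool = mirnas[:n_shared_pool]
    unshared_pool = mirnas[n_shared_pool:] or mirnas[:1]

    prefix = {"mRNA": "gene", "lncRNA": "lnc", "circRNA": "circ"}
    tables: dict[str, list[tuple[str, str, float]]] = {c: [] for c in n_targets}
    mrna_targets: dict[str, list[str]] = {m: [] for m in mirnas}

    for i in range(n_targets.get("mRNA", 0)):
        mol = f"{prefix['mRNA']}{i}"
        mir = shared_pool[int(rng.integers(len(shared_pool)))]
        tables["mRNA"].append((mol, mir, float(rng.uniform(lo, hi))))
        mrna_targets[mir].append(mol)

    triples: list[tuple[str, str, str]] = []
    for cls in sorted(classes):
        for i in range(n_targets[cls]):
            mol = f"{prefix[cls]}{i}"
            if rng.random() < sharing_rate:
                candidates = [m for m in shared_pool if mrna_targets[m]]
                mir = candidates[int(rng.integers(len(candidates)))] if candidates else None
            else:
                mir = None
            if mir is None:
                mir = unshared_pool[int(rng.integers(len(unshared_pool)))]
            tables[cls].append((mol, mir, float(rng.uniform(lo, hi))))
            # Truth tracks every realized shared-miRNA triple, so recovery
            # checks are exact even in degenerate single-miRNA configs.
            triples.extend((mol, mir, g) for g in mrna_targets[mir])

    frames = {
        cls: pd.DataFrame(rows, columns=["source_id", "mirna_id", "score"])
        for cls, rows in tables.items()
    }
    return frames, SimTruth(triples=sorted(set(triples)))
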