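"""Normalization, abundance profiling, library summaries, PCA and correlation.

CPM, TPM and FPKM follow their textbook definitions; size factors are
DESeq-style median-of-ratios against a geometric-mean pseudo-reference.
Abundance categories are the seven decade bins used to profile expression
levels: [0, 0.01), [0.01, 0.1), [0.1, 1), [1, 10), [10, 100), [100, 1000),
[1000, inf).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from txdyn._utils import round_half_up
from txdyn.containers import CountMatrix, LibrarySummary, NormalizedMatrix

ABUNDANCE_EDGES = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, np.inf)
ABUNDANCE_LABELS = (
    "0-0.01",
    "0.01-0.1",
    "0.1-1",
    "1-10",
    "10-100",
    "100-1000",
    ">1000",
)


def size_factors(counts: CountMatrix, pseudo_reference_all: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene expressed in every sample, compute count / geometric mean
    across samples; the sample's factor is the median of those ratios.
    Exactly proportional samples get factors in that proportion.

    If no gene is expressed in every sample this raises; passing
    pseudo_reference_all=True switches to the pseudo-reference fallback
    (geometric mean over positive counts only, per-sample median over the
    gene's positive ratios).
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        if not pseudo_reference_all:
            raise ValueError(
                "no gene has nonzero counts in every sample; rerun with "
                "pseudo_reference_all=True to use the positive-count fallback"
            )
        logs = np.full(mat.shape, np.nan)
        np.log(mat, out=logs, where=mat > 0)
        ref = np.exp(np.nanmean(logs, axis=1))
        usable = np.isfinite(ref) & (ref > 0)
        ratios = mat[usable] / ref[usable, None]
        factors = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    else:
        sub = mat[expressed]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.samples, name="size_factor")


def normalized_counts(counts: CountMatrix, sf: Optional[pd.Series] = None) -> NormalizedMatrix:
    """Counts divided by per-sample size factors."""
    if sf is None:
        sf = size_factors(counts)
    values = counts.counts.div(sf, axis=1)
    return NormalizedMatrix(values, unit="size-factor-normalized", rna_class=counts.rna_class)


def _check_totals(totals: pd.Series) -> None:
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero-total sample(s): {zero}")


def cpm(counts: CountMatrix) -> NormalizedMatrix:
    """Counts per million: count * 1e6 / column total."""
    totals = counts.counts.sum(axis=0)
    _check_totals(totals)
    values = counts.counts * 1e6 / totals
    return NormalizedMatrix(values, unit="CPM", rna_class=counts.rna_class)


def tpm(counts: CountMatrix) -> NormalizedMatrix:
    """Transcripts per million: length-normalized rates rescaled to 1e6."""
    lengths_kb = counts.length_vector() / 1000.0
    rates = counts.counts.div(lengths_kb, axis=0)
    totals = rates.sum(axis=0)
    _check_totals(totals)
    values = rates * 1e6 / totals
    return NormalizedMatrix(values, unit="TPM", rna_class=counts.rna_class)


def fpkm(counts: CountMatrix) -> NormalizedMatrix:
    """Fragments per kilobase per million mapped reads: count * 1e9 / (length * total)."""
    lengths = counts.length_vector()
    totals = counts.counts.sum(axis=0)
    _check_totals(totals)
    values = (counts.counts * 1e9).div(totals, axis=1).div(lengths, axis=0)
    return NormalizedMatrix(values, unit="FPKM", rna_class=counts.rna_class)


def abundance_bins(norm: NormalizedMatrix) -> pd.DataFrame:
    """Count genes per sample in the seven abundance categories.

    Bins are half-open, left-closed: a value of exactly 1 falls in '1-10'.
    Per-sample bin counts sum to the number of genes.
    """
    arr = norm.values.to_numpy()
    if arr.size and (arr < 0).any():
        raise ValueError("abundance values must be non-negative")
    out = {}
    for sample in norm.values.columns:
        binned = pd.cut(
            norm.values[sample],
            bins=list(ABUNDANCE_EDGES),
            labels=list(ABUNDANCE_LABELS),
            right=False,
            include_lowest=True,
        )
        out[sample] = binned.value_counts().reindex(list(ABUNDANCE_LABELS)).fillna(0).astype(int)
    table = pd.DataFrame(out).T
    table.index.name = "sample"
    return table


def library_rates(summary: LibrarySummary) -> dict[str, float]:
    """Clean-read and mapping rates as percentages, half-up to 2 decimals."""
    if summary.raw_reads == 0:
        raise ValueError("raw_reads is zero; rates undefined")
    rates = {"clean_rate": round_half_up(100.0 * summary.clean_reads / summary.raw_reads, 2)}
    if summary.mapped_reads is not None:
        if summary.clean_reads == 0:
            raise ValueError("clean_reads is zero; mapping rate undefined")
        rates["mapping_rate"] = round_half_up(
            100.0 * summary.mapped_reads / summary.clean_reads, 2
        )
    return rates


def pca_scores(norm: NormalizedMatrix, n_components: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Sample coordinates on principal components of log2(x+1) expression.

    Genes are centered; decomposition is exact SVD. Components are ordered by
    non-increasing explained variance and sign-fixed so the largest-magnitude
    gene loading on each component is positive. Returns (scores, explained
    variance per component). Requests beyond the available rank are truncated
    with a warning.
    """
    import warnings

    x = np.log2(norm.values.to_numpy(dtype=float) + 1.0)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = x - x.mean(axis=1, keepdims=True)
    max_comp = min(n_genes, n_samples)
    if n_components > max_comp:
        warnings.warn(
            f"requested {n_components} components but only {max_comp} available; truncating",
            stacklevel=2,
        )
        n_components = max_comp
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Sign convention: largest-|loading| gene positive on each component.
    for i in range(len(s)):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] *= -1
            vt[i] *= -1
    scores = (vt[:n_components].T * s[:n_components])
    cols = [f"PC{i + 1}" for i in range(n_components)]
    frame = pd.DataFrame(scores, index=norm.values.columns, columns=cols)
    var = pd.Series(
        (s[:n_components] ** 2) / max(n_samples - 1, 1), index=cols, name="explained_variance"
    )
    return frame, var


def correlation_matrix(norm: NormalizedMatrix) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of log2(x+1) expression."""
    x = np.log2(norm.values.to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=0)
    flat = norm.values.columns[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance sample(s): {flat}")
    r = np.corrcoef(x.T)
    return pd.DataFrame(r, index=norm.values.columns, columns=norm.values.columns)
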